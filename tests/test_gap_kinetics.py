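"""Kinetic schemes, stiff integration, C50 extraction, global fitting and
the enhancement decomposition."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from phgap import gap_kinetics as gk
from phgap import synthetic_data as sd

P = gk.DEFAULT_PARAMS


# ---------------------------------------------------------------------------
# gamma and scheme structure
# ---------------------------------------------------------------------------

def test_membrane_enhancement_value():
    # 1 / (3.011e20 lipids/L * 0.7e-18 m^2 * 5e-9 m / 1e-3 m^3)
    assert gk.membrane_enhancement(0.5e-3, 0.7, 5.0) == pytest.approx(9.49e2, rel=0.01)


def test_membrane_enhancement_clip_and_proportionality():
    assert gk.membrane_enhancement(0.5e-3, 700.0, 5000.0) == 1.0  # shell >= volume
    a = gk.membrane_enhancement(0.25e-3)
    b = gk.membrane_enhancement(0.5e-3)
    assert a == pytest.approx(2 * b, rel=1e-9)


@pytest.mark.parametrize("builder", [gk.build_trans_scheme, gk.build_tandem_scheme])
def test_schemes_have_eleven_state_variables(builder):
    assert len(builder().species) == 11


@pytest.mark.parametrize("builder", [gk.build_trans_scheme, gk.build_tandem_scheme])
def test_every_reaction_balances_conservation_groups(builder):
    scheme = builder()
    for group, members in scheme.conservation.items():
        counts = {s: 1 for s in members}
        for r in scheme.reactions:
            delta = sum(counts.get(s, 0) for s in r.products) \
                - sum(counts.get(s, 0) for s in r.reactants)
            assert delta == 0, f"{scheme.name}: {r} unbalances {group}"


def test_alpha_gamma_one_recover_baseline_models():
    base = replace(P, alpha=1.0, gamma=1.0)
    assert base.alpha == 1.0 and base.gamma == 1.0  # validity of the limits


# ---------------------------------------------------------------------------
# integration
# ---------------------------------------------------------------------------

def _run(condition, params=P, t_end=180.0, n=61):
    scheme, p = gk.scheme_for_condition(condition, params)
    return gk.simulate(scheme, p, condition, np.linspace(0.0, t_end, n))


def test_zero_enzyme_no_hydrolysis():
    traj = _run(gk.AssayCondition(construct="ZA", enzyme_total=0.0))
    assert gk.fraction_hydrolyzed(traj, 180.0) == 0.0
    assert gk.endpoint_fraction(gk.AssayCondition(construct="PZA", enzyme_total=0.0), P) == 0.0


def test_zero_catalysis_no_product():
    slow = replace(P, kcat0=1e-20)
    for construct in ("PZA", "PH+ZA"):
        c = gk.AssayCondition(construct=construct, enzyme_total=1e-6, ph_total=5e-6)
        traj = _run(c, slow)
        assert gk.fraction_hydrolyzed(traj, 180.0) == pytest.approx(0.0, abs=1e-9)


def test_saturating_enzyme_complete_hydrolysis():
    c = gk.AssayCondition(construct="PZA", enzyme_total=1e-6)
    traj = _run(c, P, t_end=3600.0)
    assert gk.fraction_hydrolyzed(traj, 3600.0) > 0.999


def test_mass_conservation_through_simulation():
    c = gk.AssayCondition(construct="PZA", enzyme_total=1e-8)
    traj = _run(c)  # simulate() raises if any group drifts beyond 1e-6
    for group, members in gk.build_tandem_scheme().conservation.items():
        tot = traj[members].sum(axis=1)
        assert np.max(np.abs(tot - tot.iloc[0])) <= 1e-6 * max(tot.iloc[0], 1e-30)


def test_states_stay_nonnegative():
    traj = _run(gk.AssayCondition(construct="PH+ZA", enzyme_total=2e-5, ph_total=5e-6))
    assert (traj.drop(columns="t").to_numpy() >= 0).all()


def _rk4_oracle(scheme, params, condition, t_end, dt=1e-3):
    """Fixed-step classical Runge-Kutta integration of the same RHS."""
    from phgap.gap_kinetics import _resolve_rates, _rhs_factory

    y = np.zeros(len(scheme.species))
    for s, v in scheme.initial(condition).items():
        y[scheme.index[s]] = v * 1e6
    rhs, _ = _rhs_factory(scheme, _resolve_rates(scheme, params, condition))
    n = int(round(t_end / dt))
    for _ in range(n):
        k1 = rhs(0, y)
        k2 = rhs(0, y + 0.5 * dt * k1)
        k3 = rhs(0, y + 0.5 * dt * k2)
        k4 = rhs(0, y + dt * k3)
        y = y + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
    return y * 1e-6


@pytest.mark.parametrize("construct, enzyme", [("PZA", 1e-8), ("PH+ZA", 1e-5)])
def test_stiff_integrator_agrees_with_fixed_step_oracle(construct, enzyme):
    c = gk.AssayCondition(construct=construct, enzyme_total=enzyme, ph_total=2e-6)
    scheme, p = gk.scheme_for_condition(c, P)
    t_end = 10.0
    traj = gk.simulate(scheme, p, c, np.linspace(0, t_end, 11))
    final = traj.iloc[-1][scheme.species].to_numpy(float)
    oracle = _rk4_oracle(scheme, p, c, t_end)
    scale = max(final.max(), oracle.max())
    np.testing.assert_allclose(final, oracle, atol=1e-4 * scale, rtol=1e-4)


def test_trans_scheme_with_no_ph_reduces_to_za_subsystem():
    """With PH absent the 11-ODE model must equal the 3-species ZA model."""
    from scipy.integrate import solve_ivp

    p = replace(P, alpha=1.0, gamma=1.0)
    c = gk.AssayCondition(construct="ZA", enzyme_total=5e-4, ph_total=0.0)
    traj = _run(c, p, t_end=60.0)

    kon = p.kon_z * 1e-6
    def rhs(t, y):  # [ZA, Arf, ZAArf, GDP] in uM
        za, arf, cplx, _ = y
        a = kon * za * arf - p.koff_z * cplx
        cat = p.kcat0 * cplx
        return [-a + cat, -a, a - cat, cat]
    sol = solve_ivp(rhs, (0, 60), [500.0, 1.0, 0.0, 0.0], rtol=1e-10,
                    atol=1e-12, dense_output=True)
    oracle_gdp = sol.sol(60.0)[3] * 1e-6
    assert gk.fraction_hydrolyzed(traj, 60.0) == pytest.approx(
        oracle_gdp / 1e-6, rel=1e-5)


def test_fraction_hydrolyzed_is_gdp_species_sum():
    c = gk.AssayCondition(construct="PZA", enzyme_total=1e-8)
    traj = _run(c)
    hand = traj[["ArfGDP", "EmArfGDP", "EsArfGDP"]].iloc[-1].sum() / 1e-6
    assert gk.fraction_hydrolyzed(traj, 180.0) == pytest.approx(hand, rel=1e-9)
    assert gk.fraction_hydrolyzed(traj, 0.0) == 0.0
    with pytest.raises(ValueError):
        gk.fraction_hydrolyzed(traj, 1e4)


# ---------------------------------------------------------------------------
# equilibrium against the closed-form single-site quadratic
# ---------------------------------------------------------------------------

def test_binding_equilibrium_matches_quadratic_closed_form():
    p = replace(P, kcat0=1e-20, alpha=1.0, gamma=1.0)
    ph_tot, arf_tot = 5e-6, 1e-6
    c = gk.AssayCondition(construct="PH+ZA", pip2_mol_percent=0.0,
                          enzyme_total=0.0, ph_total=ph_tot, arf_total=arf_tot)
    scheme, pp = gk.scheme_for_condition(c, p)
    traj = gk.simulate(scheme, pp, c, np.linspace(0, 30.0, 7))
    bound = traj["PHsArf"].iloc[-1]
    kd = p.koff_pa / p.kon_pa
    s = ph_tot + arf_tot + kd
    expected = 0.5 * (s - np.sqrt(s**2 - 4 * ph_tot * arf_tot))
    assert bound == pytest.approx(expected, rel=1e-4)


# ---------------------------------------------------------------------------
# monotonicity
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("params", [
    P, replace(P, alpha=1.0), replace(P, gamma=1.0, alpha=1.0)])
def test_fraction_monotone_in_time_and_concentration(params):
    c50_ref = gk.c50(gk.AssayCondition(construct="PZA"), params)
    concs = np.logspace(np.log10(c50_ref) - 1.5, np.log10(c50_ref) + 1.5, 5)
    fracs = []
    for conc in concs:
        c = gk.AssayCondition(construct="PZA", enzyme_total=float(conc))
        traj = _run(c, params)
        gdp = traj[traj.attrs["gdp_species"]].sum(axis=1).to_numpy()
        assert np.all(np.diff(gdp) >= -1e-12)  # nondecreasing in time
        fracs.append(gk.fraction_hydrolyzed(traj, 180.0))
    assert np.all(np.diff(fracs) >= -1e-9)  # nondecreasing in enzyme


# ---------------------------------------------------------------------------
# C50
# ---------------------------------------------------------------------------

def test_c50_on_synthetic_logistic_data():
    conc = np.logspace(-9, -7, 15)
    frac = conc / (conc + 1e-8)  # midpoint exactly 10 nM
    got = gk.c50_from_data(pd.DataFrame({"enzyme_M": conc, "fraction": frac}))
    assert got == pytest.approx(1e-8, rel=0.02)


def test_c50_from_data_grid_hit_and_no_crossing():
    tab = pd.DataFrame({"enzyme_M": [1e-9, 1e-8, 1e-7],
                        "fraction": [0.1, 0.5, 0.9]})
    assert gk.c50_from_data(tab) == 1e-8
    flat = pd.DataFrame({"enzyme_M": [1e-9, 1e-8], "fraction": [0.0, 0.0]})
    with pytest.raises(ValueError, match="never crosses"):
        gk.c50_from_data(flat)


def test_model_c50_bisection_consistency():
    c = gk.AssayCondition(construct="PZA")
    mid = gk.c50(c, P)
    f = gk.endpoint_fraction(replace(c, enzyme_total=mid), P)
    assert f == pytest.approx(0.5, abs=0.02)


# ---------------------------------------------------------------------------
# global fit
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def synthetic_fit_data():
    conds = [gk.AssayCondition(construct="PZA"),
             gk.AssayCondition(construct="PHdZA")]
    return sd.synth_dose_response(conds, P, noise_sd=0.05, seed=3,
                                  n_concentrations=8)


def test_refit_recovers_log_alpha(synthetic_fit_data):
    fixed = replace(P, alpha=10.0)
    res = gk.fit_global(synthetic_fit_data, free=["alpha"], fixed=fixed,
                        n_starts=3, seed=1)
    assert abs(np.log10(res.params.alpha / P.alpha)) <= 0.3


def test_two_conditions_separate_gamma_from_alpha(synthetic_fit_data):
    fixed = replace(P, alpha=10.0, gamma=10.0)
    res = gk.fit_global(synthetic_fit_data, free=["alpha", "gamma"],
                        fixed=fixed, n_starts=2, seed=2)
    assert abs(np.log10(res.params.alpha / P.alpha)) <= 0.3
    assert abs(np.log10(res.params.gamma / P.gamma)) <= 0.3


def test_all_fixed_returns_evaluation_only(synthetic_fit_data):
    res = gk.fit_global(synthetic_fit_data[:1], free=[], fixed=P)
    assert res.params == P and res.loss >= 0.0


# ---------------------------------------------------------------------------
# enhancement decomposition
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def shifts():
    tab = gk.decompose_enhancement(P)
    return dict(zip(tab["scenario"], tab["log10_shift"]))


def test_full_model_against_itself_is_zero_shift(shifts):
    tab = gk.decompose_enhancement(P)
    full = tab.loc[tab.scenario == "full", "c50_M"].item()
    assert np.log10(full / full) == 0.0


def test_alpha_one_full_model_equals_localization_only():
    tab = gk.decompose_enhancement(replace(P, alpha=1.0))
    d = dict(zip(tab["scenario"], tab["log10_shift"]))
    assert d["full"] == pytest.approx(d["localization-only"], abs=0.02)


def test_recruitment_only_shift_about_three_orders(shifts):
    assert shifts["recruitment-only"] == pytest.approx(3.0, abs=0.5)


def test_combined_shift_saturates_below_additivity(shifts):
    combined = shifts["localization-only"]
    assert combined < shifts["recruitment-only"] + shifts["binding-only"] - 0.5


def test_halved_ph_affinity_negligible_without_allostery():
    p = replace(P, alpha=1.0)
    c = gk.AssayCondition(construct="PZA")
    mid = gk.c50(c, p)
    grid = np.logspace(np.log10(mid) - 1.5, np.log10(mid) + 1.5, 7)
    a = gk.dose_response_curve(c, p, grid)["fraction"].to_numpy()
    b = gk.dose_response_curve(c, replace(p, koff_pa=2 * p.koff_pa),
                               grid)["fraction"].to_numpy()
    assert np.all(np.abs(b - a) <= 0.10 * np.clip(a, 0.01, None))
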
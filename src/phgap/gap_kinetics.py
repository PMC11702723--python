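"""Mass-action ODE models of GAP activity on membranes.

Two reaction schemes with 11 state variables each describe GTP hydrolysis on
membrane-anchored Arf1:

* ``in trans`` — isolated PH domain and isolated catalytic ZA fragment added
  separately.  PH partitions to PI(4,5)P2 sites, binds Arf·GTP (with the
  dimensional-reduction factor gamma when both partners are
  membrane-confined), and ZA engages the PH:Arf complex or free Arf from
  solution.  Catalysis from the ternary complex in which PH is
  simultaneously PI(4,5)P2- and Arf-bound runs at alpha*kcat0; every other
  catalytic route runs at kcat0.

* ``in tandem`` — a single enzyme (PZA-like) carrying both the PH and ZA
  units.  Membrane recruitment, PH:Arf capture and an intramolecular
  PH->ZA hand-off (tethered engagement at effective concentration
  ``tether_eff``) funnel into the catalytic complex; alpha applies only when
  the enzyme is PI(4,5)P2-anchored.

Dimensional reduction is represented by multiplying the association rate of
membrane-confined pairs by gamma (single-volume bookkeeping); gamma = 1
recovers the well-mixed solution model and alpha = 1 the no-allostery model.
Internally states are in uM to condition the stiff integration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares
from scipy.stats import qmc

__all__ = [
    "AVOGADRO",
    "RateParameters",
    "AssayCondition",
    "Reaction",
    "KineticScheme",
    "SolverError",
    "membrane_enhancement",
    "build_trans_scheme",
    "build_tandem_scheme",
    "scheme_for_condition",
    "simulate",
    "fraction_hydrolyzed",
    "endpoint_fraction",
    "dose_response_curve",
    "c50",
    "c50_from_data",
    "fit_global",
    "decompose_enhancement",
    "DEFAULT_PARAMS",
]

AVOGADRO = 6.02214076e23


class SolverError(RuntimeError):
    pass


def membrane_enhancement(accessible_lipid: float, area_per_lipid: float = 0.7,
                         shell_height: float = 5.0) -> float:
    """Dimensional-reduction factor gamma from membrane-shell geometry.

    gamma is the ratio of total solution volume to the reactive shell volume
    spanned by the accessible lipid (per liter): confining both reaction
    partners to the shell raises their effective concentration by gamma.

    accessible_lipid in M, area_per_lipid in nm^2, shell_height in nm.
    Clipped to >= 1 (the shell cannot exceed the solution volume).
    """
    if accessible_lipid <= 0 or area_per_lipid <= 0 or shell_height <= 0:
        raise ValueError("all geometry inputs must be positive")
    lipids_per_liter = accessible_lipid * AVOGADRO
    shell_m3 = lipids_per_liter * (area_per_lipid * 1e-18) * (shell_height * 1e-9)
    fraction = shell_m3 / 1e-3  # liter in m^3
    return max(1.0, 1.0 / fraction)


@dataclass(frozen=True)
class RateParameters:
    """Ground-truth/fit parameters of both schemes.

    kon_* in M^-1 s^-1, koff_* and kcat0 in s^-1; alpha and gamma are
    dimensionless.  alpha multiplies catalysis only from complexes in which
    the PH unit is simultaneously PI(4,5)P2- and Arf-bound; gamma multiplies
    association between two membrane-confined species.  ``tether_eff`` (M)
    is the effective concentration of the tethered ZA unit that drives the
    intramolecular engagement step of the tandem enzyme.
    """

    kon_pip2: float = 1e7
    koff_pip2: float = 10.0
    kon_pa: float = 1e6
    koff_pa: float = 4.0
    kon_z: float = 1e3
    koff_z: float = 60.0
    kcat0: float = 0.06
    alpha: float = 1e3
    gamma: float = membrane_enhancement(0.5e-3)
    tether_eff: float = 60e-3

    def __post_init__(self) -> None:
        for name, v in self.__dict__.items():
            if v <= 0:
                raise ValueError(f"{name} must be positive (got {v})")


DEFAULT_PARAMS = RateParameters()


@dataclass(frozen=True)
class AssayCondition:
    """One endpoint GAP assay configuration.

    ``enzyme_total`` is the titrated species (ZA for the in-trans scheme,
    the tandem enzyme otherwise); ``ph_total`` only matters in trans.
    """

    construct: str = "PZA"            # ZA | PH+ZA | PZA | DN14-PZA | PHdZA
    pip2_mol_percent: float = 5.0
    accessible_lipid: float = 0.5e-3  # M
    arf_total: float = 1e-6           # M
    enzyme_total: float = 1e-8        # M
    ph_total: float = 0.0             # M, in-trans only
    endpoint: float = 180.0           # s

    def __post_init__(self) -> None:
        if self.endpoint <= 0:
            raise ValueError("endpoint must be positive")
        for name in ("pip2_mol_percent", "accessible_lipid", "arf_total",
                     "enzyme_total", "ph_total"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    @property
    def pip2_sites(self) -> float:
        """Total PI(4,5)P2 site concentration in M."""
        return self.pip2_mol_percent / 100.0 * self.accessible_lipid


@dataclass(frozen=True)
class Reaction:
    """One mass-action reaction (all stoichiometries are 1).

    ``rate`` resolves the base constant from RateParameters;
    ``factors`` name multiplicative modifiers: "gamma" (membrane-confined
    association), "alpha" (allosteric catalysis), "pip2" (constant free-site
    concentration, in-trans bookkeeping), "tether" (intramolecular effective
    concentration).
    """

    reactants: tuple[str, ...]
    products: tuple[str, ...]
    rate: str
    factors: tuple[str, ...] = ()


@dataclass
class KineticScheme:
    name: str
    species: list[str]
    reactions: list[Reaction]
    conservation: dict[str, list[str]]
    gdp_species: list[str]
    initial: Callable[[AssayCondition], dict[str, float]]

    def __post_init__(self) -> None:
        if len(self.species) != 11:
            raise ValueError(f"{self.name}: expected 11 state variables, got {len(self.species)}")
        idx = {s: i for i, s in enumerate(self.species)}
        for r in self.reactions:
            for s in r.reactants + r.products:
                if s not in idx:
                    raise ValueError(f"{self.name}: unknown species {s!r}")
        self.index = idx

    def stoichiometry(self) -> np.ndarray:
        mat = np.zeros((len(self.species), len(self.reactions)))
        for j, r in enumerate(self.reactions):
            for s in r.reactants:
                mat[self.index[s], j] -= 1
            for s in r.products:
                mat[self.index[s], j] += 1
        return mat


def _resolve_rates(scheme: KineticScheme, params: RateParameters,
                   condition: AssayCondition) -> np.ndarray:
    """Per-reaction rate constants in uM/s units (uM^-1 s^-1 for order 2)."""
    out = np.empty(len(scheme.reactions))
    for j, r in enumerate(scheme.reactions):
        k = getattr(params, r.rate)
        order = len(r.reactants)
        for f in r.factors:
            if f == "gamma":
                k *= params.gamma
            elif f == "alpha":
                k *= params.alpha
            elif f == "pip2":
                k *= condition.pip2_sites  # pseudo-first-order recruitment
            elif f == "tether":
                k *= params.tether_eff
            else:
                raise ValueError(f"unknown rate factor {f!r}")
        if order == 2:
            k *= 1e-6  # M^-1 s^-1 -> uM^-1 s^-1
        out[j] = k
    return out


# ---------------------------------------------------------------------------
# scheme definitions
# ---------------------------------------------------------------------------

def build_trans_scheme() -> KineticScheme:
    """Isolated PH + isolated ZA acting on membrane-anchored Arf·GTP.

    11 state variables; PI(4,5)P2 enters as a constant free-site
    concentration in the PH recruitment steps (sites in large excess over
    protein in the assays this emulates).
    """
    species = [
        "PH_s", "PH_m", "Arf_m", "PHmArf", "PHsArf", "ZA_s",
        "Tm", "Ts", "ZAArf", "ArfGDP", "PHArfGDP",
    ]
    rx = [
        # PH membrane partitioning
        Reaction(("PH_s",), ("PH_m",), "kon_pip2", ("pip2",)),
        Reaction(("PH_m",), ("PH_s",), "koff_pip2"),
        # PH:Arf capture (membrane-confined pair gets gamma)
        Reaction(("PH_m", "Arf_m"), ("PHmArf",), "kon_pa", ("gamma",)),
        Reaction(("PHmArf",), ("PH_m", "Arf_m"), "koff_pa"),
        Reaction(("PH_s", "Arf_m"), ("PHsArf",), "kon_pa"),
        Reaction(("PHsArf",), ("PH_s", "Arf_m"), "koff_pa"),
        # membrane partitioning of the PH:Arf complex
        Reaction(("PHsArf",), ("PHmArf",), "kon_pip2", ("pip2",)),
        Reaction(("PHmArf",), ("PHsArf",), "koff_pip2"),
        # ZA engagement from solution
        Reaction(("ZA_s", "PHmArf"), ("Tm",), "kon_z"),
        Reaction(("Tm",), ("ZA_s", "PHmArf"), "koff_z"),
        Reaction(("ZA_s", "PHsArf"), ("Ts",), "kon_z"),
        Reaction(("Ts",), ("ZA_s", "PHsArf"), "koff_z"),
        Reaction(("ZA_s", "Arf_m"), ("ZAArf",), "kon_z"),
        Reaction(("ZAArf",), ("ZA_s", "Arf_m"), "koff_z"),
        # catalysis (irreversible); alpha only from the PIP2-anchored ternary
        Reaction(("Tm",), ("ZA_s", "PHArfGDP"), "kcat0", ("alpha",)),
        Reaction(("Ts",), ("ZA_s", "PHArfGDP"), "kcat0"),
        Reaction(("ZAArf",), ("ZA_s", "ArfGDP"), "kcat0"),
        # product release (PH has no measurable affinity for Arf·GDP)
        Reaction(("PHArfGDP",), ("PH_s", "ArfGDP"), "koff_pa"),
    ]
    conservation = {
        "Arf": ["Arf_m", "PHmArf", "PHsArf", "Tm", "Ts", "ZAArf", "ArfGDP", "PHArfGDP"],
        "PH": ["PH_s", "PH_m", "PHmArf", "PHsArf", "Tm", "Ts", "PHArfGDP"],
        "ZA": ["ZA_s", "Tm", "Ts", "ZAArf"],
    }

    def initial(c: AssayCondition) -> dict[str, float]:
        return {"Arf_m": c.arf_total, "PH_s": c.ph_total, "ZA_s": c.enzyme_total}

    return KineticScheme("in-trans", species, rx, conservation,
                         gdp_species=["ArfGDP", "PHArfGDP"], initial=initial)


def build_tandem_scheme() -> KineticScheme:
    """Single tandem enzyme (PZA-like) with PH and ZA units in one chain.

    11 state variables including the free PI(4,5)P2 sites; E_m species hold
    one site each.  The catalytic complex can be reached PH-first (capture
    then tethered ZA engagement) or ZA-first (direct engagement, the only
    route left to constructs whose PH cannot bind Arf).
    """
    species = [
        "E_s", "E_m", "Arf_m", "EmArfPH", "EsArfPH",
        "EmArfCat", "EsArfCat", "ArfGDP", "EmArfGDP", "EsArfGDP", "PIP2",
    ]
    rx = [
        # recruitment to free PI(4,5)P2 sites
        Reaction(("E_s", "PIP2"), ("E_m",), "kon_pip2"),
        Reaction(("E_m",), ("E_s", "PIP2"), "koff_pip2"),
        # PH-first capture of Arf·GTP
        Reaction(("E_m", "Arf_m"), ("EmArfPH",), "kon_pa", ("gamma",)),
        Reaction(("EmArfPH",), ("E_m", "Arf_m"), "koff_pa"),
        Reaction(("E_s", "Arf_m"), ("EsArfPH",), "kon_pa"),
        Reaction(("EsArfPH",), ("E_s", "Arf_m"), "koff_pa"),
        # membrane partitioning of the captured complex
        Reaction(("EsArfPH", "PIP2"), ("EmArfPH",), "kon_pip2"),
        Reaction(("EmArfPH",), ("EsArfPH", "PIP2"), "koff_pip2"),
        # intramolecular tethered ZA engagement
        Reaction(("EmArfPH",), ("EmArfCat",), "kon_z", ("tether",)),
        Reaction(("EmArfCat",), ("EmArfPH",), "koff_z"),
        Reaction(("EsArfPH",), ("EsArfCat",), "kon_z", ("tether",)),
        Reaction(("EsArfCat",), ("EsArfPH",), "koff_z"),
        # ZA-first direct engagement (gamma on the membrane-confined pair)
        Reaction(("E_m", "Arf_m"), ("EmArfCat",), "kon_z", ("gamma",)),
        Reaction(("E_s", "Arf_m"), ("EsArfCat",), "kon_z"),
        # catalysis; alpha only while PI(4,5)P2-anchored
        Reaction(("EmArfCat",), ("EmArfGDP",), "kcat0", ("alpha",)),
        Reaction(("EsArfCat",), ("EsArfGDP",), "kcat0"),
        # product release
        Reaction(("EmArfGDP",), ("E_m", "ArfGDP"), "koff_pa"),
        Reaction(("EsArfGDP",), ("E_s", "ArfGDP"), "koff_pa"),
    ]
    conservation = {
        "Arf": ["Arf_m", "EmArfPH", "EsArfPH", "EmArfCat", "EsArfCat",
                "ArfGDP", "EmArfGDP", "EsArfGDP"],
        "E": ["E_s", "E_m", "EmArfPH", "EsArfPH", "EmArfCat", "EsArfCat",
              "EmArfGDP", "EsArfGDP"],
        "PIP2": ["PIP2", "E_m", "EmArfPH", "EmArfCat", "EmArfGDP"],
    }

    def initial(c: AssayCondition) -> dict[str, float]:
        return {"Arf_m": c.arf_total, "E_s": c.enzyme_total, "PIP2": c.pip2_sites}

    return KineticScheme("in-tandem", species, rx, conservation,
                         gdp_species=["ArfGDP", "EmArfGDP", "EsArfGDP"],
                         initial=initial)


def scheme_for_condition(condition: AssayCondition,
                         params: RateParameters) -> tuple[KineticScheme, RateParameters]:
    """Map an assay construct onto a scheme plus parameter overrides.

    ZA        -> in-trans with no PH
    PH+ZA     -> in-trans
    PZA       -> in-tandem
    DN14-PZA  -> in-tandem, alpha = 1 and halved PH:Arf affinity
    PHdZA     -> in-tandem, PH cannot bind Arf (recruitment only)
    """
    c = condition.construct
    if c in ("ZA", "PH+ZA"):
        return build_trans_scheme(), params
    if c == "PZA":
        return build_tandem_scheme(), params
    if c == "DN14-PZA":
        return build_tandem_scheme(), replace(params, alpha=1.0,
                                              koff_pa=2 * params.koff_pa)
    if c == "PHdZA":
        # the surrogate PH cannot hold Arf: association off and any
        # transiently PH-tagged state decays instantly (no tethered trapping)
        return build_tandem_scheme(), replace(params, alpha=1.0,
                                              kon_pa=1e-12, koff_pa=1e5)
    raise KeyError(f"unknown construct {condition.construct!r}")


# ---------------------------------------------------------------------------
# integration
# ---------------------------------------------------------------------------

def _rhs_factory(scheme: KineticScheme, rates_um: np.ndarray):
    stoich = scheme.stoichiometry()
    r_idx = [tuple(scheme.index[s] for s in r.reactants) for r in scheme.reactions]

    def rhs(t, y):
        flux = rates_um.copy()
        for j, idx in enumerate(r_idx):
            for i in idx:
                flux[j] *= y[i]
        return stoich @ flux

    def jac(t, y):
        n = len(y)
        jm = np.zeros((len(r_idx), n))
        for j, idx in enumerate(r_idx):
            for pos, i in enumerate(idx):
                term = rates_um[j]
                for q, k in enumerate(idx):
                    if q != pos:
                        term *= y[k]
                jm[j, i] += term
        return stoich @ jm

    return rhs, jac


def simulate(scheme: KineticScheme, params: RateParameters,
             condition: AssayCondition, t_grid: Sequence[float],
             rtol: float = 1e-8, atol: float | None = None) -> pd.DataFrame:
    """Integrate the scheme over ``t_grid`` (s); states returned in M.

    Implicit stiff integration (LSODA with analytic Jacobian); states in uM
    internally.  The absolute tolerance defaults to 1e-12 M scaled down
    further when a conserved pool (e.g. a sub-nM enzyme titration point) is
    smaller than 1 nM, so conservation holds to 1e-6 relative on every
    group; that invariant is verified after each run.
    """
    t_grid = np.asarray(t_grid, float)
    y0 = np.zeros(len(scheme.species))
    for s, v in scheme.initial(condition).items():
        y0[scheme.index[s]] = v * 1e6  # M -> uM
    if atol is None:
        totals = [sum(y0[scheme.index[s]] for s in members)
                  for members in scheme.conservation.values()]
        smallest = min([t for t in totals if t > 0], default=1.0)
        atol = max(1e-16, min(1e-6, 1e-8 * smallest))
    rates = _resolve_rates(scheme, params, condition)
    rhs, jac = _rhs_factory(scheme, rates)
    sol = solve_ivp(rhs, (t_grid[0], t_grid[-1]), y0, method="LSODA", jac=jac,
                    t_eval=t_grid, rtol=rtol, atol=atol)
    if not sol.success:
        raise SolverError(f"{scheme.name}: integration failed: {sol.message}")
    y = np.clip(sol.y, 0.0, None) * 1e-6  # back to M
    traj = pd.DataFrame(y.T, columns=scheme.species)
    traj.insert(0, "t", sol.t)
    _check_conservation(scheme, traj)
    traj.attrs["scheme"] = scheme.name
    traj.attrs["gdp_species"] = scheme.gdp_species
    traj.attrs["arf_total"] = float(sum(
        traj.iloc[0][s] for s in scheme.conservation["Arf"]))
    return traj


def _check_conservation(scheme: KineticScheme, traj: pd.DataFrame,
                        rel: float = 1e-6) -> None:
    for group, members in scheme.conservation.items():
        tot = traj[members].sum(axis=1).to_numpy()
        ref = tot[0]
        if ref <= 0:
            continue
        drift = np.max(np.abs(tot - ref)) / ref
        if drift > rel:
            raise SolverError(
                f"{scheme.name}: conservation of {group} violated ({drift:.2e} relative)")


def fraction_hydrolyzed(traj: pd.DataFrame, endpoint: float) -> float:
    """Fraction of total Arf in GDP-containing species at ``endpoint`` (s)."""
    t = traj["t"].to_numpy()
    if endpoint > t[-1] + 1e-9 or endpoint < t[0] - 1e-9:
        raise ValueError(f"endpoint {endpoint} s outside simulated range [{t[0]}, {t[-1]}]")
    arf_total = traj.attrs.get("arf_total", 0.0)
    if arf_total <= 0:
        return 0.0
    gdp = traj[traj.attrs["gdp_species"]].sum(axis=1).to_numpy()
    return float(np.interp(endpoint, t, gdp) / arf_total)


def endpoint_fraction(condition: AssayCondition, params: RateParameters,
                      n_times: int = 60) -> float:
    """Fraction hydrolyzed at the assay endpoint for one condition."""
    if condition.enzyme_total == 0:
        return 0.0  # the titrated species carries all catalytic routes
    scheme, p = scheme_for_condition(condition, params)
    t_grid = np.linspace(0.0, condition.endpoint, n_times)
    traj = simulate(scheme, p, condition, t_grid)
    return fraction_hydrolyzed(traj, condition.endpoint)


def dose_response_curve(condition: AssayCondition, params: RateParameters,
                        concentrations: Sequence[float]) -> pd.DataFrame:
    rows = [(c, endpoint_fraction(replace(condition, enzyme_total=float(c)), params))
            for c in concentrations]
    return pd.DataFrame(rows, columns=["enzyme_M", "fraction"])


# ---------------------------------------------------------------------------
# C50 and fitting
# ---------------------------------------------------------------------------

def c50(condition: AssayCondition, params: RateParameters,
        bracket: tuple[float, float] = (1e-13, 1e-1),
        rel_precision: float = 0.01) -> float:
    """Enzyme concentration giving 50% hydrolysis at the endpoint.

    Bisection on log10 concentration to 1% relative precision.
    """
    lo, hi = np.log10(bracket[0]), np.log10(bracket[1])
    f_lo = endpoint_fraction(replace(condition, enzyme_total=10**lo), params)
    f_hi = endpoint_fraction(replace(condition, enzyme_total=10**hi), params)
    if not (f_lo < 0.5 <= f_hi):
        raise ValueError(
            f"response does not cross 0.5 in bracket ({f_lo:.3g} .. {f_hi:.3g})")
    tol = np.log10(1 + rel_precision)
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if endpoint_fraction(replace(condition, enzyme_total=10**mid), params) >= 0.5:
            hi = mid
        else:
            lo = mid
    return float(10 ** (0.5 * (lo + hi)))


def c50_from_data(dose_response: pd.DataFrame) -> float:
    """Monotone log-interpolated midpoint of a tabulated dose-response."""
    d = dose_response.sort_values("enzyme_M")
    conc = d["enzyme_M"].to_numpy(float)
    frac = d["fraction"].to_numpy(float)
    if frac.max() < 0.5 or frac.min() > 0.5:
        raise ValueError("tabulated response never crosses 0.5")
    hits = np.where(np.isclose(frac, 0.5))[0]
    if len(hits):
        return float(conc[hits[0]])
    return float(10 ** np.interp(0.5, frac, np.log10(conc)))


_FITTABLE = ["kon_pip2", "koff_pip2", "kon_pa", "koff_pa", "kon_z", "koff_z",
             "kcat0", "alpha", "gamma", "tether_eff"]
_DEFAULT_BOUNDS = {name: (-3, 10) for name in _FITTABLE}
_DEFAULT_BOUNDS.update({"alpha": (0, 5), "gamma": (0, 5), "kcat0": (-5, 3),
                        "tether_eff": (-6, 0)})


@dataclass
class GlobalFitResult:
    params: RateParameters
    loss: float
    per_start: pd.DataFrame
    identifiability_warning: bool = False


def fit_global(datasets: list[tuple[AssayCondition, pd.DataFrame]],
               free: Sequence[str], fixed: RateParameters,
               n_starts: int = 5, seed: int = 0,
               bounds: dict[str, tuple[float, float]] | None = None) -> GlobalFitResult:
    """Simultaneous weighted least-squares fit over several dose-response sets.

    Free parameters are optimized in log10 space from Latin-hypercube starts
    within bounds; residuals are (model - data)/sd on the hydrolyzed
    fraction.  A flat objective across distinct optima raises an
    identifiability warning rather than an error.

    ``datasets``: (condition, table) pairs, table columns enzyme_M, fraction
    and optional sd.
    """
    if len(datasets) < 1:
        raise ValueError("need at least one dataset")
    free = list(free)
    for name in free:
        if name not in _FITTABLE:
            raise KeyError(f"unknown parameter {name!r}")
    bnds = {**_DEFAULT_BOUNDS, **(bounds or {})}

    def with_params(logvals: np.ndarray) -> RateParameters:
        return replace(fixed, **{n: float(10 ** v) for n, v in zip(free, logvals)})

    def residuals(logvals: np.ndarray) -> np.ndarray:
        p = with_params(logvals)
        res = []
        for condition, table in datasets:
            sd = table["sd"].to_numpy(float) if "sd" in table else np.full(len(table), 0.05)
            for conc, frac, s in zip(table["enzyme_M"], table["fraction"], sd):
                model = endpoint_fraction(replace(condition, enzyme_total=float(conc)), p)
                res.append((model - frac) / max(s, 1e-3))
        return np.asarray(res)

    if not free:
        r = residuals(np.empty(0))
        loss = float(r @ r)
        table = pd.DataFrame([{"start": 0, "loss": loss}])
        return GlobalFitResult(fixed, loss, table)

    lo = np.array([bnds[n][0] for n in free])
    hi = np.array([bnds[n][1] for n in free])
    sampler = qmc.LatinHypercube(d=len(free), seed=seed)
    starts = lo + sampler.random(n_starts) * (hi - lo)

    rows, best = [], None
    for i, x0 in enumerate(starts):
        try:
            fit = least_squares(residuals, x0, bounds=(lo, hi), xtol=1e-4,
                                ftol=1e-6, diff_step=1e-3)
        except SolverError:
            continue
        loss = float(fit.fun @ fit.fun)
        rows.append({"start": i, "loss": loss,
                     **{n: float(10 ** v) for n, v in zip(free, fit.x)}})
        if best is None or loss < best[0]:
            best = (loss, fit.x)
    if best is None:
        raise SolverError("every fit start failed")
    table = pd.DataFrame(rows)

    warning = False
    if len(table) > 1:
        # ties: within 1e-3 relative, or indistinguishable at the residual
        # scale (rms difference < 1e-3 on the hydrolyzed fraction)
        n_res = sum(len(t) for _, t in datasets)
        tie = best[0] * (1 + 1e-3) + n_res * 1e-6
        good = table[table["loss"] <= tie]
        if len(good) > 1:
            vecs = np.log10(good[free].to_numpy(float))
            if np.max(np.ptp(vecs, axis=0)) > 0.1:  # distinct optima, same loss
                warning = True
    return GlobalFitResult(with_params(best[1]), best[0], table, warning)


# ---------------------------------------------------------------------------
# enhancement decomposition
# ---------------------------------------------------------------------------

SCENARIOS = ("ZA-alone", "recruitment-only", "binding-only",
             "localization-only", "full")


def decompose_enhancement(params: RateParameters,
                          base_condition: AssayCondition | None = None) -> pd.DataFrame:
    """log10 C50 shifts (vs ZA alone) of the mechanistic scenarios.

    ZA-alone           isolated catalytic fragment (in-trans, no PH)
    recruitment-only   membrane recruitment active, PH cannot bind Arf, alpha=1
    binding-only       PH:Arf binding active, gamma=1, alpha=1
    localization-only  recruitment + tethered binding, alpha=1 (the
                       hypothetical enzyme whose PI(4,5)P2 engagement only
                       localizes)
    full               complete model (alpha and gamma active)
    """
    base = base_condition or AssayCondition()
    rows = []
    c50_za = c50(replace(base, construct="ZA", ph_total=0.0), params)
    for scenario in SCENARIOS:
        if scenario == "ZA-alone":
            value = c50_za
        elif scenario == "recruitment-only":
            value = c50(replace(base, construct="PHdZA"), params)
        elif scenario == "binding-only":
            p = replace(params, gamma=1.0, alpha=1.0)
            value = c50(replace(base, construct="PZA"), p)
        elif scenario == "localization-only":
            p = replace(params, alpha=1.0)
            value = c50(replace(base, construct="PZA"), p)
        else:
            value = c50(replace(base, construct="PZA"), params)
        rows.append({"scenario": scenario, "c50_M": value,
                     "log10_shift": float(np.log10(c50_za / value))})
    return pd.DataFrame(rows)
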
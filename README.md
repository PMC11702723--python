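# phgap

Computational machinery for dissecting how a pleckstrin-homology (PH) domain
turns a weak Arf GTPase-activating fragment into an efficient membrane
enzyme.  The package covers the two quantitative arms of that analysis:

1. **Structural arm** — paramagnetic relaxation enhancement (PRE) and
   chemical-shift perturbation (CSP) processing for the membrane-bound
   myrArf1 : ASAP1-PH complex: spin-label ensemble placement,
   Solomon–Bloembergen back-calculation of methyl PRE rates, docking
   restraint generation, and a two-state population fit that asks which of
   two docked orientations dominates in solution.
2. **Kinetic arm** — mass-action ODE models (11 state variables each) of GAP
   activity on membranes for the "in trans" (isolated PH + catalytic ZA
   fragment) and "in tandem" (single PZA-like enzyme) configurations, with
   endpoint dose-response extraction (C50), global fitting, and a
   decomposition of activity enhancement into membrane recruitment,
   substrate binding, and allosteric catalytic activation.

It is aimed at structural biologists and enzymologists who want a tested,
scriptable reference implementation of these analyses; everything runs from
Python with no external data downloads (a synthetic-data module generates
all inputs with the statistical structure the analyses assume).

## The models in brief

**PRE forward model.**  For a methyl proton at distance *r* (cm) from the
unpaired electron of a nitroxide label,

    Γ₂ = κ (4τc + 3τc / (1 + ωH²τc²)) r⁻⁶,     1/τc = 1/τR + 1/τS

with κ = 1.23×10⁻³² cm⁶s⁻², τR = 70 ns, τS = 100 ns.  Rates are averaged in
rate space over label orientations, frames, and conformational states
(Γ₂ = ρ_A Γ₂ᴬ + ρ_B Γ₂ᴮ), and only then converted to the measured
paramagnetic/diamagnetic intensity ratio

    I/I₀ = R₂ exp(−Γ₂ t) / (R₂ + Γ₂),     t = 6.89 ms.

Under the defaults, I/I₀ = 0.2 corresponds to ≈ 16 Å — the cutoff used to
assign 1.8–16 Å docking restraints.

**Kinetic model.**  Membrane confinement multiplies association between two
membrane-bound species by a dimensional-reduction factor γ =
V_solution/V_shell (≈ 10³ at 0.5 mM accessible lipid, 0.7 nm² per lipid,
5 nm shell).  The allosteric factor α multiplies the catalytic rate k_cat
only when the PH unit is simultaneously PI(4,5)P₂- and Arf-bound.  γ = 1
recovers the well-mixed model, α = 1 the no-allostery model.

## Worked example

```bash
python examples/two_state_pre_fit.py
```

```
methyls used:        40
major population:    0.900  (state A)
major:minor ratio:   9.0
slope / Pearson r:   1.000 / 1.000
```

Forty reporter methyls see a spin label from two docked poses; mixing the
pose rates 9:1 and refitting recovers the 90% major-state population
exactly, with unit slope and correlation between predicted and observed
ratios.  `examples/enhancement_decomposition.py` prints the kinetic
scenario table:

```
         scenario    c50_M  log10_shift
         ZA-alone  0.00413            0
 recruitment-only  4.6e-06         2.95
     binding-only 3.92e-07         4.02
localization-only 9.38e-08         4.64
             full 8.46e-10         6.69
```

C50 is the enzyme concentration hydrolyzing half the Arf-bound GTP in
3 minutes; the shifts say that recruitment alone buys ~3 orders of
magnitude, recruitment plus substrate binding 4–5 (catalysis becomes rate
limiting), and the allosteric k_cat change the remainder.  Two further
examples cover restraint generation (`csp_restraints.py`) and K_d
extraction from dissociation-rate modulation (`dissociation_kd.py`).

A thin CLI mirrors the main entry points (`phgap run pre|kinetics --config
cfg.yaml`, `phgap place-label`, `phgap csp`, `phgap expfit`, `phgap kd`,
`phgap decompose`).

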
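# Methods

## Coordinate handling and reporter methyls

Structures are multi-model PDB files (one MODEL block per ensemble frame);
coordinates are Å and residue numbering is taken verbatim.  Insertion codes
and models with differing atom lists are rejected up front, since every
downstream average indexes atoms by (model, residue, atom name).

Two methyl labeling schemes are supported: ILV (Ile δ1, Leu δ1/δ2,
Val γ1/γ2) and ILV-proS-AT (Ile δ1, Leu δ1, Val γ1, Ala β, Thr γ2).  When
methyl protons are present they are used directly; otherwise the
three-proton centroid is reconstructed on the methyl symmetry axis at
1.09·cos(70.5°) ≈ 0.36 Å beyond the methyl carbon, along the direction away
from the preceding carbon.  Because PRE averages over fast methyl rotation,
the centroid is the standard proxy; entries using it are flagged.

## Spin-label ensembles

Full nitroxide rotamer libraries are deliberately not used.  The label is
represented by its paramagnetic-center position only, rejection-sampled on
a spherical shell of radius 6–9 Å around the attachment Cβ (radius uniform
on the interval, direction uniform on the sphere) with a 1.5 Å clash radius
against all protein heavy atoms.  The 6–9 Å range brackets the
Cβ-to-nitroxide-oxygen distance of extended label rotamers.  What matters
for the observable is that orientation averaging happens in rate space over
many candidate positions — the contract this sampler preserves — not the
rotamer weighting itself, which affects profiles far less than the r⁻⁶
distance dependence.  Sampling is expressed in a local frame built from the
attachment atom, Cα, and the first non-collinear heavy atom, so ensembles
co-rotate with the structure; a fixed fallback rule covers degenerate
(< 3 usable atoms) inputs.  Each model keeps its surviving candidates with
uniform weights; a model with no survivor is an error, not a silent skip.

## Relative solvent accessibility

Shrake–Rupley surfaces (biotite, 500 points/atom, probe 1.4 Å,
single-element van der Waals radii) are summed per residue and divided by
embedded theoretical Gly-X-Gly maxima, clipped to [0, 1].  Residues without
a reference value are excluded with a warning.  Tests cross-check against
an independent 960-point Fibonacci-sphere sampler; agreement is within 10%
on small structures, which is ample for a 20% exposure threshold.

## CSP and restraint rules

CSP = √(ΔδH² + A·ΔδX²), A = 0.17 (¹⁵N) or 0.185 (¹³C).  The error on a PRE
intensity ratio is (I/I₀)·√(1/SN² + 1/SN₀²).  Restraint classification:
active = exposed (relative SASA ≥ 0.20, threshold inclusive) and CSP >
0.1 ppm; passive = exposed and (within 6.5 Å heavy-atom distance of an
active residue **or** CSP inside the partner-specific 1σ–2σ window:
0.047–0.095 ppm methyl / 0.02–0.04 ppm amide for the PH side, 0.03–0.06 /
0.02–0.04 ppm for the Arf side) and not active.  The OR reading of
proximity/window was chosen because the classification text joins them with
"and/or".  Where a dataset-level σ is needed, it is the standard deviation
of the CSPs after one round of 2σ trimming; the absolute windows above take
precedence when supplied.  Undetectable resonances are explicit flags (with
intensity 0), never missing rows, so "broadened beyond detection" and "not
measured" stay distinguishable; both I/I₀ < 0.2 and flagged-undetectable
protons receive 1.8–16 Å bounds.  Restraints are emitted as TSV (canonical)
and CNS-style `assign` lines.

## PRE forward model and the two-state fit

Γ₂(r) uses the full spectral-density term at all fields (no ωH²τc² ≫ 1
shortcut).  Defaults: κ = 1.23×10⁻³² cm⁶s⁻², τR = 70 ns, τS = 100 ns,
850 MHz proton frequency (configurable per dataset — acquisition field is
dataset-dependent), t = 6.89 ms, global R₂ = 100 s⁻¹ unless per-methyl
linewidths (R₂ = π·Δν½) are given.

Averaging order is fixed: candidate positions within a frame (weighted),
then frames (uniform), then states (population-weighted), always on rates;
conversion to I/I₀ happens last.  Mixing intensity ratios instead of rates
is quantitatively wrong (the two differ by > 0.05 in ratio units on generic
cases) and is guarded against by a dedicated test.

The two-state fit minimizes error-weighted squared deviations between mixed
ratios and observed ratios over ρ ∈ [0, 1]: a 0.01 grid scan followed by
bounded golden-section refinement to 10⁻⁴ within the bracketing grid cell.
The quality metrics (slope and Pearson r of predicted vs observed ratios)
are reported at the optimum.  Identical state profiles make ρ
unidentifiable; the fit then returns the grid minimizer flagged degenerate.
Fewer than 5 shared methyls is an error.

## Kinetic schemes

Both assay configurations are modeled with 11 mass-action state variables
(all stoichiometries 1); the exact species partition was reconstructed from
the described mechanisms under that dimensionality constraint.

*In trans* (isolated PH + isolated ZA): PH_s, PH_m, Arf·GTP_m, PH_m:Arf,
PH_s:Arf, ZA_s, two ternary complexes (PIP₂-anchored, catalyzing at α·kcat0,
and solution-PH, at kcat0), the binary ZA:Arf (kcat0), Arf·GDP and
PH:Arf·GDP.  PI(4,5)P₂ enters the recruitment steps as a constant free-site
concentration (mol% × accessible lipid) because sites are in ~25-fold
excess over protein under the emulated conditions.

*In tandem* (single PZA-like enzyme): solution and membrane enzyme, membrane
Arf·GTP, PH-captured and catalytically engaged complexes in both
compartments, three product-holding states, and free PI(4,5)P₂ sites as an
explicit conserved species.  The catalytic complex is reachable PH-first
(capture, then intramolecular hand-off to the catalytic unit at rate
kon_Z × tether_eff) or ZA-first (direct engagement — the only route left to
constructs whose PH cannot bind Arf).

Dimensional reduction is a single multiplicative factor γ on associations
between membrane-confined pairs (single-volume bookkeeping), computed from
shell geometry as γ = V_solution/V_shell and clipped to ≥ 1; this gives the
same steady-state enhancement as explicit 2D concentrations while keeping
conservation checks trivial.  α multiplies catalysis only from complexes
whose PH unit is simultaneously PI(4,5)P₂- and Arf-bound.

Construct mapping: ZA and PH+ZA use the in-trans scheme; PZA the tandem
scheme; ΔN14-PZA is tandem with α = 1 and doubled PH:Arf off-rate (halved
affinity); PHdZA is tandem with PH:Arf association off and instantaneous
decay of transiently PH-tagged states.

### Ground-truth parameters

Defaults were chosen once to satisfy the system's quantitative anchors, and
all are overridable:

| parameter | default | rationale |
|---|---|---|
| kon_pip2 / koff_pip2 | 10⁷ M⁻¹s⁻¹ / 10 s⁻¹ | µM-range membrane partitioning, ~96% membrane-bound at 25 µM sites |
| kon_PA / koff_PA | 10⁶ M⁻¹s⁻¹ / 4 s⁻¹ | PH:Arf K_d = 4 µM (measured half-max / K_m range) |
| kon_Z / koff_Z | 10³ M⁻¹s⁻¹ / 60 s⁻¹ | productive ZA–Arf engagement, K ≈ 60 mM (see below) |
| kcat0 | 0.06 s⁻¹ | ZA-alone catalytic efficiency kcat0·kon_Z/koff_Z ≈ 1 M⁻¹s⁻¹ |
| α | 10³ | 1000-fold allosteric k_cat enhancement |
| γ | ≈ 949 (computed) | 0.5 mM lipid, 0.7 nm²/lipid, 5 nm shell |
| tether_eff | 60 mM | short-tether effective concentration; half-engaged complexes |

The productive-engagement constant (60 mM) is deliberately weaker than the
measured ZA:Arf dissociation constant (0.1–1 mM): in this reduced scheme a
single step stands in for binding *and* productive orientation, and the
combination of anchors (ZA-alone efficiency ~1 M⁻¹s⁻¹, individual
recruitment/binding gains of ~10³, combined gain 10⁴–10⁵ before allostery)
is only mutually consistent if most measured binding is nonproductive.
This is the package's own coarse-graining choice, recorded here because the
original supplementary scheme definitions are not available for comparison.

### Numerics

States are integrated in µM (LSODA, analytic Jacobian, rtol 10⁻⁸; absolute
tolerance 10⁻¹² M, tightened automatically when a conserved pool — e.g. a
sub-nM enzyme titration point — is smaller than 1 nM).  Every run verifies
conservation of each group to 10⁻⁶ relative and is cross-checked in tests
against a fixed-step fourth-order integrator at 1 ms steps (10⁻⁴ relative
on the final state) and, for pure binding subsystems, against the
closed-form quadratic equilibrium (10⁻⁴ relative).  C50 is found by
bisection on log₁₀ concentration to 1% relative precision (model curves) or
monotone log-interpolation (tabulated data).  Global fits run in log₁₀
parameter space from Latin-hypercube multi-starts; residuals are
sd-weighted hydrolyzed-fraction differences; ties among distinct optima
(within 10⁻³ relative, or indistinguishable at 10⁻³ rms on the fraction
scale) raise an identifiability warning.

The assay endpoint is 180 s unless overridden.  Typical problem sizes — the
sizes used throughout the tests and examples — are 8–12 concentrations per
condition, ≤ 5 conditions per fit, 10-model ensembles with ≤ 200 label
candidates; these are the scales at which the analyses are intended to run.

## Assay fits

Dissociation traces are fit as offset + amplitude·exp(−kt) (single
exponential; residual diagnostics are exposed since a double-exponential
alternative cannot be excluded a priori).  Constant traces return rate 0
rather than failing.  K_d from rate modulation fits
k_obs(c) = (k_free·K_d + k_sat·c)/(K_d + c), the fractional-occupancy
mixture whose half-modulation point equals K_d by construction; a flat
titration (k_free ≈ k_sat within 2%) is an explicit unidentifiable-K_d
error.  IC50 is the fitted four-parameter-logistic midpoint, with monotone
interpolation as fallback for degenerate fits.  Rates are s⁻¹ internally
with min⁻¹ conversion at I/O.

## Synthetic data: what it does and does not emulate

Generators are pure functions of (parameters, seed).  The two-pose
generator produces a rigid cylindrical "reporter" body with 24
methyl-bearing residues and a labeled probe body docked on opposite faces
(0.5 Å RMS model jitter), giving label–methyl distance distributions that
span the full sensitivity range of the PRE observable and differ by > 5 Å
between poses for well over 30% of methyls.  PRE noise is additive Gaussian
on the ratio scale (matching how ratio errors are quoted), with ratios
below 0.05 flagged undetectable with probability 0.5 to exercise the
bleached-peak branch.  Dose-response noise is multiplicative (error bars
scale with signal); traces get additive Gaussian noise.

These generators reproduce the *statistical structure* the estimators
assume — not MD-like conformational realism, spectral line shapes, peak
overlap, or systematic errors (incomplete labeling, label mobility beyond
the shell model, lipid-composition effects).  Passing tests therefore
demonstrate estimator correctness and pipeline integrity under the assumed
noise model, not robustness to every pathology of real spectra.

## Known limitations

- No Curie-spin or cross-correlated relaxation terms; populations only, no
  exchange-rate modeling between poses.
- The 11-ODE schemes omit nucleotide exchange (loading is an initial
  condition), multi-turnover GTP regeneration, and spatial effects beyond
  the single γ factor.
- Docking itself (restraint consumption) is out of scope; restraints are
  emitted, not used.
- The label model ignores rotamer-weighting; sites whose accessible volume
  is strongly anisotropic will be less well approximated.
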
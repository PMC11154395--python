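# Methods

## The model

`tktd` implements the coupled toxicokinetic–toxicodynamic (TK–TD) model used
to describe copper accumulation and mortality in the razor clam
*Sinonovacula constricta* under varying humic-acid (HA) / dissolved organic
carbon (DOC) levels, with enriched ⁶⁵Cu as a tracer.

**Toxicokinetics.** Tissue copper follows a linear one-compartment balance,

    dC_int/dt = k_u · C_w(t) − k_e · C_int(t),        J_int = k_u · C_w,

with C_int the tracer-corrected tissue concentration (µg g⁻¹ dry weight),
C_w the waterborne concentration (µg L⁻¹), k_u the uptake rate constant
(L g⁻¹ h⁻¹) and k_e the first-order elimination rate (h⁻¹). Growth dilution
is excluded (body mass is effectively constant over the ~8-day design).
Exposure profiles are constant, piecewise-constant or piecewise-linear;
the trajectory is composed from the exact integrating-factor solution on
each segment (`A + Bτ + Qτ² + D e^{−k_e τ}`), so the forward model carries
no discretisation error. The k_e = 0 case uses the analytic limit rather
than a small-k_e substitution, avoiding catastrophic cancellation.

**Toxicodynamics.** Mortality is the stochastic-death threshold-hazard
form (the GUTS reduced stochastic-death structure): hazard accrues at rate
`k_k · max(C_int − C_IT, 0) + h_0` and survival is `S = e^{−H}`. C_IT
(µg g⁻¹) is the internal threshold, k_k ((µg g⁻¹)⁻¹ h⁻¹) the killing rate,
h_0 (h⁻¹) the background hazard, 0 by default because control animals show
no mortality. The excess integral is evaluated exactly on the trajectory's
closed-form segments: within a segment C_int is unimodal, threshold
crossings are found in closed form (constant forcing) or by Brent's method
at ~machine precision, and the polynomial–exponential antiderivative is
applied between crossings. An adaptive-quadrature route (`method="quad"`,
abs. tol 1e−8) is retained purely as an independent cross-check.

**Tracer correction.** Newly accumulated ⁶⁵Cu is obtained from raw
⁶⁵Cu/⁶³Cu readings. Two conventions are implemented because the commonly
printed formula differs from the standard natural-abundance subtraction and
the field's usage is ambiguous:

* `as_printed` (default): `(⁶⁵Cu − ⁶³Cu) · F65`, F65 = 0.3085;
* `abundance_ratio`: `⁶⁵Cu − ⁶³Cu · (F65/F63)`, the subtraction of the
  natural-background ⁶⁵Cu implied by the ⁶³Cu signal.

Neither is silently preferred; the mode is explicit everywhere. Negative
corrected values (possible under noise) are clipped to 0 and flagged rather
than dropped, so downstream fits can exclude them deliberately.

**Units.** Hours internally, everywhere. Elimination rates are reported in
d⁻¹ alongside h⁻¹ at I/O boundaries only, because the bivalve literature
mixes both conventions and that mixing is a recurring source of
inconsistency.

## Estimation

All fits are Levenberg–Marquardt nonlinear least squares (lmfit/MINPACK)
with parameter SDs from `rss/(n−p) · (JᵀJ)⁻¹`, gradient tolerance 1e−10.
The default strategy is staged, reflecting identifiability:

1. **Shared k_e** from all depuration series jointly (elimination is
   treated as organism physiology, independent of HA and Cu level); each
   series keeps its own free concentration at depuration start. Only the
   15 µg L⁻¹ groups carry depuration data, which is why a joint
   all-parameter fit (`fit_tk_joint`, available behind the API) is weakly
   identified and not the default.
2. **Per-treatment k_u** with k_e fixed, from the 12-h uptake series,
   C_int(0) = 0 (the tracer correction removes background).
   Initialisation: k_u⁰ = C_last/(C_w·t_last); k_e⁰ = log-linear
   depuration slope.
3. **Per-HA (C_IT, k_k)** from pooled replicate survival fractions at the
   300 µg L⁻¹ toxicity test, using that HA level's fitted 300 µg L⁻¹ k_u.
   Least squares on survival fractions is the default; an
   interval-censored multinomial likelihood (`objective=
   "multinomial_likelihood"`) is provided and is statistically preferable
   for counts — the two agree in the small-noise limit.

TD initialisation is data-driven: C_IT⁰ is half the tissue concentration at
the first observed death, and k_k⁰ reproduces the hazard implied by the
observation nearest 50% survival given C_IT⁰. (A fixed k_k⁰ of 0.01 stalls
on a flat S≈0 plateau whenever realistic killing rates are orders of
magnitude smaller.) A small multistart over the threshold guards against
the flat C_IT direction collapsing onto a boundary.

**Identifiability of C_IT.** A toxicity test run at a single waterborne
concentration identifies k_k well but C_IT only weakly: once tissue Cu is
far above threshold, C_IT enters the hazard only through a term linear in
t that is dominated by the quadratic k_k term. With 60 animals per
treatment, C_IT estimates can wander to 0 or several times the true value
while the survival curve itself is recovered within binomial error. The
reported SDs are large in the interior but unreliable when the fit sits on
the C_IT ≥ 0 boundary; the multinomial objective's Hessian-based intervals
are more honest there. Tests therefore assert recovery of k_k and of the
survival curve, not a tight C_IT.

## Dose metrics

Uptake flux versus waterborne Cu is summarised by Michaelis–Menten
saturation `J = J_max[Cu]/(K_m + [Cu])`, fitted through the same LM
machinery (initialisation J_max⁰ = 1.2·max J, K_m⁰ = median [Cu]).

LC50 comes in two deliberately distinct routes: model-implied (root
bracketing on `C_w ↦ S(duration | constant C_w)` at S = 0.5, from fitted
TK–TD parameters) and empirical (maximum-likelihood probit on log₁₀ dose,
LC50 = 10^(−intercept/slope), delta-method CI — the convention of the
standard ecotoxicological R tooling). The probit route refuses completely
separated data, where the MLE does not exist.

## The virtual-experiment generator

`simulate` reproduces the study design: 4 HA levels (nominal 0/5/10/20
mg L⁻¹ → measured DOC 0.58/3.05/5.61/8.98 mg L⁻¹), 3 nominal ⁶⁵Cu levels
(15/150/300 µg L⁻¹), uptake sampled at 0/3/6/9/12 h with 6 tissue
measurements per point, 168-h depuration at 12/24/48/72/120/168 h for the
15 µg L⁻¹ groups, and a 96-h toxicity test at 300 µg L⁻¹ with 3 × 20
animals checked every 8 h (the upper end of the reported 6–8-h cadence,
fixed for determinism).

Noise structure: concentrations get multiplicative unit-mean lognormal
noise, `LogNormal(−σ²/2, σ)` with `σ = sqrt(ln(1+CV²))`, default CV 0.15 —
the minimal structure consistent with strictly positive ratio-scale
measurements. Deaths are binomial per check interval with conditional
probability `1 − S(t₂)/S(t₁)`; at `noise_cv = 0` the generator switches to
its deterministic limit (expected counts, rounded), so noise-free
generate-then-fit round trips are exact up to count rounding. Removal of
sampled animals during uptake is not modelled, matching the pooled-mean
one-compartment formulation. Everything is reproducible from one integer
seed, and CSV output is byte-stable.

**Ground-truth parameter sets.** `GroundTruth.reported()` carries the
published best-fit grid verbatim: k_u per treatment, shared k_e
(0.0582 d⁻¹ → 2.425e−3 h⁻¹), and per-HA (C_IT, k_k) with k_k taken at its
printed numerical value in (µg g⁻¹)⁻¹ h⁻¹. Taken at face value this TD/TK
combination is internally inconsistent: at 300 µg L⁻¹ the tissue burden
passes C_IT within the first hour and the printed killing rates then
extinguish the cohort within ~2 h — before the first mortality check —
whereas the experiment it summarises observed deaths spread over 96 h.
No unit reading of the printed killing rate resolves this.
`GroundTruth.calibrated()` therefore keeps every TK parameter and every
C_IT unchanged and rescales all four k_k by one common factor, computed at
run time so that the most sensitive treatment's 96-h survival equals 1%
(matching the reported near-total mortality at the lowest DOC). The
calibrated set preserves the published between-treatment k_k ratios and
yields survival curves that actually span the test duration; it is the
default for TD recovery exercises and the pipeline's `recover` command.
TK recovery (the headline reproduction exercise) is identical under either
set.

What passing recovery tests does and does not show: the generator draws
from the same model family the estimators assume, so recovery demonstrates
correctness of the fitting machinery and adequacy of the design's
information content — not robustness to model misspecification, measured
water-concentration decline, inter-individual tolerance variation, or
sampling-induced depletion, none of which are emulated.

## Problem sizes and numerical choices

Parameter-recovery summaries use 200 seeded replicates of the relevant
design cell, a size at which Monte-Carlo error on a median or mean is well
below the tolerances being checked; the probit CI-coverage check uses 1000
replicates so the ~0.7% Monte-Carlo error on the coverage rate is small
against the 93% floor. The numerical oracle for the forward model is naive
fixed-step RK4 at 1e−3 h, independent of the closed-form path it checks;
agreement is required at 1e−6 relative. Root bracketing (threshold
crossings, LC50) uses Brent's method at tolerances far below any reported
precision. Degenerate inputs are first-class: k_e = 0, empty depuration,
all-zero uptake, zero deaths (raises an unidentifiability error carrying
the C_IT lower bound = peak tissue concentration), complete separation in
probit data.

## Known limitations

* One compartment, pooled mean; no inter-individual kinetics or
  individual-tolerance (GUTS-IT) mortality variant.
* Measured water concentrations are accepted via `ExposureProfile` but the
  generator defaults to nominal constant exposure (optional first-order
  loss); no speciation or DOC-binding chemistry is computed.
* C_IT from a single-concentration toxicity test is weakly identified (see
  above); a multi-concentration design is the remedy, not more data at the
  same concentration.
* The published LC50 table cannot be reproduced from the published model
  parameters (the per-dose mortality counts behind it are not available,
  and forward prediction from the printed parameter set is inconsistent
  with it); the package's LC50 operations are therefore generic tools, and
  no test asserts those printed values.
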
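# Methods

## Model structure

The state vector holds 24 cell counts: four thymocyte stages (DN, DP, SP4,
SP8) and six peripheral CD4+ subpopulations (RTE, N, A, CM, EM, EFF)
distributed over blood, lymphoid tissue, gut and lung.  RTE and activated
cells occupy only the blood/lymphoid recirculation loop; N, CM, EM and EFF
additionally reach gut and lung.  All peripheral kinetics are first-order
mass action except the logistic clonal expansion of activated cells.

**Thymocyte submodel.** The intrathymic block is a reconstruction built to
the following design: DN and DP grow logistically against a shared
cortical capacity `Tcortmax(age)`, DP cells surviving selection split
between SP4 (fraction 0.67) and SP8, SP cells grow logistically against a
medullary capacity `Tmedmax(age)`, and SP4 egresses into blood at
0.1 d⁻¹.  The zero state is a fixed point (no external source); it is
unstable whenever DN proliferation exceeds DN loss, so simulations start
from a small DN seed (10⁴ cells).  Both capacities scale with a thymus
wet-weight curve `W(age) = W₀·(1+g·(1−e^{−age/τ}))·e^{−k_inv·age}`
(g = 1.5, τ = 0.5 y, k_inv = 0.044 y⁻¹): growth peaking in the first
couple of years, then exponential involution.  The birth capacities
(3.2×10⁹ cortical, 1.28×10⁹ medullary) were scaled once so that the
newborn steady state reproduces the meta-analytic newborn blood total
(~2.2×10³ CD4 cells/µL); they are flagged `reconstructed` and are
configuration, not biology we claim to have measured.

**Placement decisions.** Three placements are deliberate and matter for
stability at the reference rates:

* *Activated-cell proliferation acts in lymphoid tissue only*, co-located
  with differentiation.  The reference rates put proliferation
  (λ_A4 = 1.725 d⁻¹) within 0.2% of differentiation (φ_A4 = 1.727 d⁻¹);
  if proliferation also acted in blood — where the only exits are slow —
  the pool would be unconditionally unstable.  With co-location the pool
  is source-limited and its size is controlled by the small margin
  (φ_A4 + μ_A4 + net recirculation loss) − λ_A4 ≈ 0.046 d⁻¹.  This margin
  is the lever of the model: a 2% age-related rise in λ_A4 triples the
  activated pool and with it the downstream memory supply, which is how
  the model accumulates memory cells over a lifetime without invoking the
  logistic ceiling (`TA4max = 10¹³` stays far away under nominal
  parameters and only becomes active under large sensitivity-analysis
  perturbations).
* *Naive homeostatic proliferation acts in the blood/lymphoid pool only.*
  In gut and lung the exit rate (7.5×10⁻⁴ d⁻¹) is so close to
  λ_N4's adapted ceiling (1.2×10⁻³ d⁻¹) that proliferation there would
  outrun removal and destabilise the whole naive system at old age.
* *Naive activation (φ_N4) and RTE maturation (φ_RTE4) act in lymphoid
  tissue*, the antigen-presentation site; CM→EM and EM→EFF differentiation
  act wherever the source resides.

`ω*_bl_tis` flows are irreversible losses to unmodelled tissues; effector
cells never return from peripheral organs; SP8 egress leaves the model
(the CD8 lineage is out of scope).

## Age dependence and feedback

Three nested variants: STATIC (only thymic capacities and blood volume
vary with age), AGE (thirteen empirical modulations), AGE_PLUS_FEEDBACK
(eleven age modulations plus two RTE-concentration feedbacks).  The
saturating (hyperbolic Hill) form is the default: `base·(1 ± m·ageʰ/
(age50ʰ + ageʰ))`.  Structural constants follow the reference analysis:
Hill coefficients fixed at 10 (λ_N4) and 3 (φ_CM4), h = 1 elsewhere; the
maximal relative decrease pinned at 1 for the six fully-vanishing
down-modulations; one shared age50 for the five late-life trafficking
dependencies ({φ_EM4, ω_EM4,lung→bl, ω_EFF4,bl→git/lung/tis}).  The
remaining amplitudes and half-effect ages are not printed anywhere we can
cite, so the packaged defaults were chosen once to honour the anchors the
reference analysis does print — λ_N4 moving from 0.0007 d⁻¹ (young) to
0.0012 d⁻¹ (old) across a sharp late-life transition, and a λ_A4 rise
small enough to respect the activated-pool stability margin (amax = 0.026,
age50 = 10 y) — and then frozen; they define both the packaged calibrated
model and the synthetic-data generator.

The feedback variant replaces λ_N4(age) and μ_RTE4(age) by Hill functions
of the blood RTE concentration (coefficient 10, switch-like).  Half-effect
concentrations are set on the model's own RTE trajectory: 22 cells/µL for
the naive-proliferation adaptation (crossed at ~55–60 y, reproducing the
late-life rise) and 70 cells/µL for the RTE-death adaptation (crossed by
young adulthood, so that disabling it already costs ~20–25% of lymphoid
CD4 cells at age 20).  Body physiology: Gompertz body-weight growth
(3.5 → 70 kg, 95% of adult mass by 18 y) scaled to a 5 L adult blood
volume.

## Observation model and inference

The 20 calibration observables are blood concentrations (cells/µL) of the
six subpopulations plus within-organ percentages (all six in lymphoid
tissue; N/CM/EM/EFF in gut and lung).  Validation quantities are derived
totals (total and memory blood concentration, per-organ total counts).
Observations are treated as steady states at the age-bin midpoint.  The
likelihood is Gaussian with sd = CV·|prediction| (CVs fixed, derived from
CI half-widths as (ci_hi − mean)/(1.96·mean) when absent).  Note that with
prediction-proportional noise the NLL minimum sits O(CV²) away from the
observation, so "noiseless" recovery experiments use small CVs (2%) to
keep that bias below the 1% acceptance band.  AIC = 2k + 2·NLL with k the
number of estimated structural parameters; RSE comes from the inverse
observed information (central-difference Hessian), with RSE > 51%
flagged unidentifiable; profile-likelihood CIs use the χ²₁/2 = 1.92
threshold and flag profiles with total range < 0.01 as practically
non-identifiable.

Optimization is Nelder–Mead on log-parameters (bounds nominal×[0.01, 100]
enforced by penalty), multi-started from seeded log-uniform draws, with an
optional Powell polish.  Stepwise age-function selection scans all
remaining (parameter, form) pairs each forward round, accepts the lowest
AIC whose new parameters are identifiable, stops when no addition improves
the AIC, then backward-eliminates.  Fitted constants of already-selected
terms stay frozen during later candidate fits (a deliberate economy; the
backward pass re-checks every term).  Because the hyperbolic-amplitude
landscape is stiff near the activated-pool margin, candidate fits are
seeded from a coarse NLL grid scan in addition to random starts.

## Steady states and integration

Trajectories use LSODA (rtol 10⁻⁸, atol 10⁻³ cells) with age-dependent
rates re-evaluated continuously; outputs are clipped at zero only within
solver tolerance.  `solve_steady_state` integrates the frozen-age system
for 10⁶ days and polishes the endpoint with a hybrid Newton solve on
log-states (positivity-preserving); it reports the final residual on
failure.  `steady_state_direct` is the fast path used inside calibration
and sensitivity analysis: closed forms plus one scalar root for the
thymocyte block, one scalar root for the RTE block (the death-rate
feedback depends on the block's own concentration), and a linear solve for
the remaining 18 states at a frozen logistic factor `s`, closed by
bisection on the self-consistency of `s`.  Past the activated-pool
stability margin the linear solve turns spuriously negative; that region
is treated as infeasible so the bisection backs off to the true
logistic-limited fixed point.  The two solvers agree to ~10⁻⁷ relative;
the direct path is ~10³× faster (≈1.5 ms).

## Perturbations

Complete thymectomy: initial state = healthy steady state at the surgery
age; SP4 is clamped to zero (state reset plus zeroed derivative and
egress), and a paired healthy trajectory from the same initial state is
the reference.  Baseline correction rescales each observed subpopulation
(all compartments) by its observed/predicted blood-concentration ratio,
and unobserved subpopulations by the total-CD4 ratio.  Adaptation
knockouts replace a feedback by the constant rate the full model exhibits
at the healthy newborn operating point (so scenario differences isolate
the adaptive response, not baseline shifts); freezing at the
zero-concentration base value is available behind a flag.

## Sensitivity analysis

Latin-hypercube sampling (scipy's stratified sampler) over ±25% uniform
ranges around nominal for kinetic, thymocyte and age/feedback constants;
steady-state outputs at ages {0, 1, 20, 50, 80}; PRCC by rank transform
and explicit residualization of each parameter and the output on all
remaining parameters (QR least squares, average ranks for ties), with
degenerate flags for constant outputs or collinear parameters.
Monotonicity is screened by Spearman correlation plus a binned-mean
direction-consistency check (monotone when ≥75% of adjacent bin moves
share a direction).  |PRCC| ≥ 0.5 is flagged significant.  The reference
sample size is 10,000; the desk-scale default is 2,000 with an optional
half-sample drift report.  Two-parameter contour surfaces hold all other
parameters at nominal.

## Synthetic data

The generator emulates a meta-analytic calibration table: steady-state
predictions at bin midpoints, multiplicative lognormal noise with fixed CV
(10% blood, 15% tissue percentages — typical between-study spreads), CI
half-width 1.96·CV·mean/√n for a synthetic pooled-study count n = 6.
Blood observables use seven bins over 0–80 y, tissue percentages two bins
(0–18, 18–60 y), reflecting the sparser tissue literature.  Thymectomy
cohorts sample surgery ages uniformly within the six surgery-age groups
(the open-ended oldest group capped at 6 y).  The generator reproduces the
*statistical structure* the inference assumes — proportional noise,
age-binned weighted averages, steady-state observables — but not
real-world violations of it (between-study heterogeneity beyond a shared
CV, non-steady-state sampling, assay differences), so green recovery tests
certify the pipeline's internal consistency, not field performance on raw
literature data.

## Problem sizes

Desk-scale defaults keep the full test suite and the acceptance script to
a few minutes: stepwise-selection experiments use four candidate rates ×
two forms with grid-seeded single-start fits; GSA probes use n = 1000–2000
with reduced parameter subsets; thymectomy and knockout simulations use
120–160 point lifetime grids.  All are configuration parameters and scale
up unchanged.

## Known limitations

* The thymocyte block and all age-function constants are reconstructions;
  absolute organ counts (e.g. lymphoid maxima) sit several-fold below
  literature whole-body estimates, as expected for a homeostatic model
  calibrated to early-life blood data.
* Newborn memory concentrations are ~2× below the meta-analytic anchor:
  with activation, death and differentiation rates fixed at their
  reference values, the newborn memory pool is fully determined and the
  reconstruction has no remaining lever.
* The CD8 lineage exists only inside the thymus; stem-cell-like and
  resident-memory subsets, infection dynamics, sex and microbiome
  covariates, and thymic regrowth after partial thymectomy are out of
  scope.
* Steady-state calibration requires a stable fixed point at every age;
  the reference rates sit close to instability in two places (documented
  above), which is physiologically interesting but numerically demanding —
  the direct solver's infeasibility handling exists for exactly that
  reason.
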
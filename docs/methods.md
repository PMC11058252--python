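# Methods

## Growth model family

The core model is multiplicative Monod colimitation,

µ(L, N) = µmax · (L + L₀)/(K_L + L + L₀) · (N + N₀)/(K_N + N + N₀),

with light L in µmol·m⁻²·s⁻¹ (PAR), nitrogen N in µM, and rates in
day⁻¹. The storage offsets shift each saturating factor: L₀ captures
the light-independent energy supply from acetate in the growth medium
(cells grow in the dark when acetate is present), N₀ intracellular
nitrogen reserves (zero for starved cells). Both half-saturation
constants are constrained strictly positive so no denominator can
vanish for non-negative inputs; µ is then non-decreasing in both
resources and bounded by µmax.

Three related forms are implemented for model comparison:

- **generalized product** — the same construction over any number of
  independent, non-substitutable factors, Πᵢ (Eᵢ+Eᵢ₀)/(K_Eᵢ+Eᵢ+Eᵢ₀);
  with the factor list [light, nitrogen] it reproduces the two-resource
  model bit-for-bit.
- **reduced multiplicative** — storages pinned at zero and the
  amplitude µ₀ free alongside K_L and K_N.
- **law of minimum (Liebig)** — µmax·min(f_L, f_N) with the *same*
  saturating factors, including storages. The exact algebraic form of
  a Liebig analogue is a genuine design choice; we keep the factors
  identical to the multiplicative form so the two families are nested
  over one parameter space and differences in fit reflect only the
  combination rule (product vs minimum). Everywhere, product ≤ minimum
  ≤ µmax, since each factor is ≤ 1.

## Environment grid

At steady state the diffusive gradient between source (35.3 µM) and
sink (5.3 µM) channels is linear across the gap, so each row takes the
concentration at its centerline. The default geometry places 8
centerlines equally spaced from one quarter of the 2308 µm gap to the
sink boundary (≈247 µm pitch), which reproduces both the working row
range 27.8→5.3 µM and a slope of 1.3 µM per 100 µm; the geometry is
fully configurable because real devices vary in habitat pitch. Column
light values use the linear-endpoint convention (equally spaced from
0.1 to 45 PAR by default) rather than integrating a measured
profile — measured profiles are only "almost linear" and are not
tabulated, and the calibration utilities (two-point linear maps with
exact inverses) let users substitute their own measurements.

## Synthetic experiments

The simulator emulates the statistical structure the analysis assumes,
not the device physics. Per habitat: an initial cell count drawn
uniformly from {1..6} (empty with probability `p_empty`, default 0.05
— seeding is random and some habitats stay empty), exponential growth
at the model rate for that habitat's (L, N) — closed form per sampling
interval rather than an ODE stepper, since the perfused environment is
static, which removes integrator tolerance from the test surface — and
fluorescence read-out gain·cells·m + background, with m lognormal with
mean 1 and coefficient of variation `intensity_cv` (default 0.05) plus
additive Gaussian background jitter (default sd 2 on a level of 100).
Defaults mirror the study design: 8×8 array, 3 replicates, samples
every 4 h over 7 days. Options: a logistic carrying capacity (default
off — the plateau mechanism in real curves is not identified) and a
lag phase (default off) to exercise the time-threshold rule.

What the simulator does **not** emulate: photoacclimation and lag
dynamics, nutrient drawdown, cell motility, quenching, or spatial
coupling between habitats. Passing recovery tests therefore shows the
*analysis* is correct and well-calibrated under its own assumptions,
not that the model is true of any particular organism.

## Rate extraction

Growth curves are ln((I_t − background)/(I₀ − background)). The
background is a per-replicate scalar, supplied or estimated as the
minimum observed intensity (a habitat-free floor); the estimator is
deliberately simple and replaceable. Habitats seeded empty or with
initial signal at or below background are excluded with logged reason
codes; later non-positive net intensities are masked, never silently
dropped.

The maximum specific growth rate is the largest OLS slope over any n
consecutive points (n = 9 at 4 h sampling: long enough to suppress
read-out noise, short enough not to flatten the maximum — estimates are
stable for n up to 25) among windows whose **center** time is ≥ 1.3
days, skipping the early acclimation phase. "Center" (rather than
window start or end) is a design choice: it is symmetric and stable
under changes of window length; both the threshold and its
interpretation are configurable. Ties go to the earliest window. The
standard error attached to each maximum is sd/√k of the k = 4 window
slopes nearest the maximizer (positions max−1…max+2, clamped at the
ends); "4 values around the maximum" could also be read as 4 raw data
points, but the window-slope reading keeps the se in rate units and
degrades gracefully on short series.

## Fitting and uncertainty

Point fits minimize Σ(µ_obs − µ_model)² over the free parameters with
scipy's trust-region-reflective least squares, all parameters bounded
below at 0 (half-saturations at 10⁻⁶). Default protocol: µmax fixed at
2.4 day⁻¹ (the maximum rate previously measured in the same device),
N₀ fixed at 0 (starved cells), L₀ free with acetate or fixed at 0
without. Initialisation: amplitude at the observed maximum rate, K's
at the median of the corresponding environmental grid, L₀ at 10% of
the maximum PAR; 5 multiplicatively jittered restarts (fixed internal
seed, so fits are deterministic) guard against local minima and the
best-SSE solution is kept. Degenerate inputs — fewer observations than
free parameters, a single condition, or identical observations — raise
before optimisation.

Uncertainty comes from a replicate-resampling bootstrap: in each of
B = 1000 runs, every (row, col) condition independently draws one
replicate's rate with probability ∝ 1/se², the resampled matrix is
refitted (unweighted — the weights act only in selection), and the
reported estimate of each parameter is the mean of its B values, with
the bootstrap sd and pairwise correlations alongside. Weights are
normalised per condition, the only reading that keeps probabilities
valid when a replicate lacks a record at some condition. Zero-se
records (noise-free data) take the largest finite weight at their
condition, or uniform weight if all are zero — avoiding infinities
while preserving the ordering of informative replicates. Significance
of a parameter against a null value is reported two ways, a Wald
normal approximation 2(1−Φ(|mean−null|/sd)) and the two-sided
bootstrap tail fraction (floored at 2/B, its resolution), since either
is a reasonable convention.

Model comparison fits every candidate form to the *same* B resampled
matrices and reports mean SSE, mean R² and mean small-sample AIC
(AICc = n·ln(SSE/n) + 2k + 2k(k+1)/(n−k−1)); no single goodness-of-fit
metric is privileged, so any reasonable reading is covered. Forms
failing to converge in more than 10% of runs are excluded with a
warning.

## Numerical and calibration notes

- Time is hours in files, rates day⁻¹ everywhere; the conversion
  factor 24 is fixed. CSV round trips use 17-significant-digit output
  and round-trip float parsing, so file-mediated pipelines are
  byte-reproducible.
- One master seed derives per-stage substreams (via `SeedSequence`),
  so pipeline stages can be rerun independently yet reproducibly.
- Under multiplicative read-out noise the max-over-windows rule is
  slightly optimistic (it prefers windows with upward fluctuations),
  which propagates to mildly low half-saturation estimates with µmax
  fixed; the bootstrap sd reflects sampling variability around that
  procedure, not this procedural bias. This is a property of the
  max-window estimator itself, shared with its use on real data.
- Problem sizes in the acceptance script (8×8 array, 3 replicates,
  B = 1000 bootstrap, 50 comparison datasets at B = 10) are the study's
  own design sizes where stated and otherwise chosen to make
  Monte-Carlo error small relative to the tolerances checked.

## Known limitations

- The fitted constants are condition-specific: they depend on
  starvation history, light spectrum and nitrogen form, so predictions
  outside the calibrated ranges (e.g. lake scenarios) are indicative
  extrapolations.
- Estimation of the generalized product beyond two factors is
  implemented but untested against data.
- Droop internal-quota models, photoinhibition, and substitutable-
  resource colimitation forms are out of scope.
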
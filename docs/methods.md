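# Methods

## Model and conventions

All times are hours relative to the diet switch (t = 0); equilibration
samples are negative. Isotope values are δ¹³C in ‰ vs. VPDB. Each output
stream of each animal is modelled as a delayed multi-pool exponential

    δ(t) = c + Σ_p a_p · exp(−(t − d)/τ_p),   t > d,

with the pre-switch plateau `c + Σ a_p` for t ≤ d. The pools are treated
as independent outputs (parallel, not catenary/mammillary): for a lactating
ruminant the outputs are distinct biosynthetic products, and interacting
layouts are statistically indistinguishable from this form anyway, so the
parallel reading is the physiologically defensible one. Pools are stored in
ascending τ (exponential mixtures are permutation-invariant) and pool
amplitudes must share one sign: an abrupt diet switch drives every pool in
the same direction, and mixed-sign solutions arise only as artifacts that
mimic short-term input fluctuations. The model value is defined on both
sides of the delay (plateau before, decay after) so that the
intersection-based delay refinement and plotting are well-posed.

Derived quantities: pool half-life t½ = τ·ln 2; gross half-life = the
t > d with Σ a_p e^{−(t−d)/τ_p} = ½ Σ a_p, found by Brent's method
(tolerance 1e-6 h; closed form `d + τ·ln 2` for one pool).

## Delay detection

Post-switch sampling times are scanned in order. At each time, the
per-animal paired differences against the sample at the switch are tested
with a two-sided Wilcoxon signed-rank test using the exact null
distribution for ≤ 25 pairs (herd sizes are small; the normal approximation
is unreliable); zero differences are dropped before ranking. The first
time with p < α (default 0.05) starts the chase period; all earlier
samples form the delay period, whose pooled mean and SD are the baseline.
The scan is sequential and stops at the first significant time, with no
multiplicity correction — the decision rule, not a simultaneous inference.
Time points sharing fewer than 5 animals with the reference are skipped and
recorded. A statistical floor to be aware of: with exactly 5 pairs the
two-sided exact test's smallest attainable p is 2/32 = 0.0625, so at
α = 0.05 detection requires at least 6 animals.

The partition quantizes the delay to the sampling interval, so it is
refined as the time where the fitted model crosses the delay-period
baseline. Because a shift of the delay anchor is absorbed exactly by
rescaling each amplitude (a_p → a_p·e^{Δ/τ_p}), the fit is anchored at the
*end of the delay period*; its backward extrapolation then crosses the
baseline at the underlying delay, whether that lies before or after the
anchor. The crossing is found by Brent's method (1e-6 h) and clipped to the
bracket the partition established (after the last non-significant sample,
before the first significant one). The fit–refine cycle runs twice: fit at
the partition anchor, refine, refit the selected candidate at the refined
anchor, refine again. If the baseline lies outside the fitted model's range
(possible under heavy noise), the partition boundary is reported instead,
flagged `partition_boundary`.

## Fitting and model selection

Chase-period series of all animals are fitted jointly by Gaussian least
squares. Sharing structures assign each parameter class (c, a_p, τ_p)
either one shared value or per-animal values; this enumerated fixed-effects
comparison reproduces the scientific question ("do individuals share the
same kinetics?") without random-effects marginal likelihoods, which are out
of scope. The log-likelihood is the Gaussian profile likelihood with the
residual variance at its MLE; AIC = 2k − 2·logL with k counting mean
parameters plus one residual variance.

Numerics: the model is linear in c and the amplitudes given the residence
times, so the inner linear problem is solved exactly (ordinary least
squares; bounded least squares when the common-sign amplitude constraint
becomes active — the sign is set once from early-vs-late chase means) and
the outer optimizer searches only log-τ (positivity by construction),
using `scipy.optimize.least_squares` (trust region, ftol 1e-10) from eight
deterministic multistarts with initial τ log-spaced in [2, 200] h. Fits are
canonicalized to ascending τ; pools whose τ collapse within 1e-6 are
merged. Standard errors come from the Gauss–Newton covariance
σ̂²(JᵀJ)⁻¹ of the full parameter vector (forward-difference Jacobian).
Half-life CIs use the delta method, SE(t½) = ln 2 · SE(τ), with
t½ ± SE·T, T the 97.5th Student-t percentile at (n_animals − 1) degrees
of freedom — the animal, not the sample, is the replication unit.

Model selection fits every (pool count, structure) candidate and keeps the
converged, non-degenerate fit with minimal AIC; when a simpler candidate
(fewer parameters) is within 2 AIC of the best, the simpler one wins. A
candidate is degenerate when its nominal pool count is not supported:
adjacent τ within a factor 1.1, a pool amplitude below 1e-3 of the total,
or a pool half-life longer than the post-delay observation span (such a
pool is collinear with the constant c and cannot be estimated from the
experiment). Multi-exponential fits without this screen will happily
"explain" shared smooth deviations with spurious pools. The end-to-end
pipeline searches hierarchically — pool count first with all parameters
shared, then per-animal relaxations at the selected count — which is both
faster and closer to how such analyses are actually decided; `select_model`
itself stays exhaustive over the grid it is given.

### Identifiability limits

Sums of exponentials with nearby rates are notoriously ill-conditioned. At
this study design (15 twice-daily chase samples, 8 animals, first usable
sample one delay + one sampling interval after the switch), a mixture of
half-lives 10 h and ~18–19 h lies within ~0.006–0.008 ‰ rms of the best
single exponential, so pool-count recovery of such mixtures requires
analytical noise well below 0.02 ‰ — far below realistic instrument SDs
(0.11–0.19 ‰). The corresponding pool-resolution test is therefore
expected to fail at realistic noise, and does; the *functionals* that
remain identifiable (the fitted curve, the asymptote, the gross half-life)
are recovered and tested instead. Practically: a two-pool finding on real
whole milk should be read as a statement about that dataset's realized
separation, not something the design guarantees.

## Forward prediction

A fitted model implies a normalized weighting of the diet history. Weights
are the model's decay values |Σ a_p e^{−u/τ_p}| at ages u = 0, s, 2s, …
up to six half-lives of the slowest pool, normalized to sum 1 (default
step s = 1 h). The impulse-response variant (a_p/τ_p weights) is available
as an option for sensitivity analysis; the default follows the model-value
convention. Truncating at six half-lives leaves a tail mass of roughly
2⁻⁶ ≈ 1.6% for a one-pool kernel (not 0.01%); the kernel records the
actual truncated fraction.

The prediction at time *now* is Σ_u w_u · input(now − d − u − s/2) + shift:
the diet series is resampled onto the kernel grid with carried-forward
values (feed is batch-offered, so a step function is the right
interpolation dialect), and each weight cell reads the input at its
midpoint, which aligns the discrete sum with the continuous convolution
(midpoint rule) — against the exact continuous step response the engine is
within 2% at s = 1 h, and halving s moves predictions by < 0.01 ‰.
Insufficient input history raises a coverage error; there is no silent
extrapolation. Because the weights are a convex combination, input
fluctuations are always attenuated, never amplified.

The trophic shift is estimated on equilibration-period data as the mean
measured-minus-predicted difference (SE = sd/√n); it should not be added
on top of the switch shift ε, which compares the delay-period baseline δ_b
with the fitted asymptote δ_a. ε defaults to the plain difference
δ_a − δ_b; the ratio convention ((1000+δ_a)/(1000+δ_b) − 1)·1000 is a flag
(the two differ by ≤ 0.1 ‰ for shifts up to ~2.7 ‰, growing to ~3.6% of
the shift at δ_b = −35 ‰). Validation reports RMSE of the raw paired
differences (not the regression residual), OLS of measured on predicted
with t-tests of slope vs. 1 and intercept vs. 0, and a prediction-interval
half-width SD·T at n − 1 df, with SD the standard deviation of the paired
differences.

## Synthetic data generator

`gen_study` emulates the study design: 8 animals; a herd-level diet whose
δ¹³C fluctuates as an AR(1) process (marginal SD 0.45 ‰ in equilibration,
0.38 ‰ in chase, lag-1 ρ = 0.5 at 12 h sampling) around −27.40 ‰ with a
−2.64 ‰ step at t = 0; outputs generated per animal by convolving the
input with the stream's true kernel (1 h grid) plus a constant trophic
shift, an optional animal-level offset (default 0 — the reference finding
is that animals share kinetics; a nonzero value exists to exercise
per-animal structures), and i.i.d. analytical noise. Default streams:
feces (delay 20 h, t½ 9 h, noise 0.12 ‰), lactose (12, 10, 0.13), casein
(12, 18, 0.11), milk fat (12, 19, 0.14); whole milk is the carbon-weighted
mixture of the three milk-component signals (fractions 0.40/0.30/0.30
lactose/casein/fat — configurable stand-ins, as published component carbon
contents vary) plus its own 0.19 ‰ noise. Sampling is twice daily, 32
equilibration + 15 chase samples per output (47 each); the diet is
generated over an extended history (from −552 h) so every output time has
full kernel coverage, and the dataset view of the diet is subsampled to
the standard grid. Everything is reproducible bit-for-bit from one seed.

The ρ of the input fluctuation is an assumption, not a measured quantity;
it is recorded in the study config. One deliberate simplification matters
for interpretation: the generator feeds the *recorded* diet series directly
into the animals, so its short-term fluctuations pass into every output,
attenuated but **common to all animals**. Real diet sampling noise is
partly sampling/measurement error that animals never ingest, and real
intake decorrelates across animals. Consequently, parameter-recovery
precision under the fluctuating-input generator is far worse than in a
real experiment with the same analytical noise (the shared deviations act
as unmodelled, perfectly correlated errors). Recovery and selection
properties are therefore benchmarked on `gen_switch_experiment` — the
idealized clean-switch setting (exact model response + i.i.d. noise) that
diet-switch designs aim to approximate — while the fluctuating generator
backs the end-to-end workflow, attenuation and forward-validation checks.
Passing recovery tests thus demonstrate estimator correctness at the
stated noise, not robustness to strongly correlated shared input noise.

## Problem sizes and tolerances

Simulation-based tests use 100 seeded replicates for recovery and
selection rates (8 animals × 15 chase samples each), 200 replicates for
the partition-boundary mode, and 1000 random models for kernel invariants;
these sizes keep the full suite under a few minutes while making the
asserted rates (≥ 90%, ≥ 95%, majority) stable to resampling. Root-finding
tolerances are 1e-6 h; SSR convergence 1e-10 (relative); CSV round-trips
preserve values to 1e-6 ‰ (9 significant digits on disk).

## Known limitations

- No random-effects (marginal likelihood) estimation; sharing structures
  are enumerated fixed effects.
- Delay is held fixed during each fit rather than estimated jointly; the
  fit–refine cycle converges in two passes under the model but is not a
  joint MLE.
- The residual model is a single i.i.d. Gaussian variance across animals
  and times; no heteroscedasticity or autocorrelation.
- Multi-pool resolution is design-limited (see identifiability above).
- The ε ratio-vs-difference choice is a convention toggle; reported shifts
  default to plain differences.
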
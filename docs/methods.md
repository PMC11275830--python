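# Methods

This note documents the models, algorithms, defaults, and design
choices behind `csfpolar`, in the order data flows through the
pipeline.

## CSF model and psychometric function

Sensitivity is a log-parabola in log10 frequency. The stored bandwidth
parameter is the full width at half-maximum sensitivity in **octaves**;
since one octave spans `log10 2` units of the log10-frequency axis, the
parabola's width parameter is `w = bandwidth_oct · log10 2`. This
convention makes the two half-sensitivity frequencies exactly
`bandwidth_oct` octaves apart (a property the tests assert to 1e-9) and
keeps bandwidth values on the familiar ~2–4 octave scale.

All three parameters are handled internally on the log10 scale — the
scale on which priors are uniform and the hierarchical Gaussians act —
with linear values only at the API boundary.

The 2AFC psychometric function uses fixed non-CSF parameters: guessing
rate g = 0.5, lapse rate λ = 0.04 (upper asymptote 0.98), Weibull slope
β = 2. `(c·S)^β` is evaluated in log space with clipping so extreme
sensitivities neither overflow nor lose the exact limits p(c→0) = g and
p(c→∞) = 1 − λ/2.

Derived attributes: cutoff-SF is the upper root of `log10 S = 0`,
computed in closed form (`log10 cutoff = log10 peakSF + (bw/2)·
sqrt(log10 peakCS · log10 2)`); it is undefined (flagged) when peak-CS
< 1. AULCSF integrates `max(log10 S, 0)` against `d(log10 f)` over the
measured stimulus range 0.5–16 cpd. Because the truncated integrand is
piecewise polynomial, the integral is evaluated exactly as a closed
form rather than by quadrature; the integration bounds and the
truncation at sensitivity 1 are package choices (sub-threshold
frequencies contribute nothing to a window of visibility), exposed as
arguments.

## Adaptive testing (qCSF)

The stimulus space is 60 contrasts log-evenly spanning [0.001, 1] × 12
spatial frequencies log-evenly spanning [0.5, 16] cpd. The posterior
over CSF parameters lives on a fixed product grid, by default 30 × 30 ×
20 nodes covering the prior boxes (log10 peak-CS ∈ [1, log10 200], plus
0.1 headroom above the ceiling for adaptive testing only; log10 peak-SF
∈ [log10 0.31, log10 3.16]; bandwidth log-spaced over [1.58, 3.98]
octaves). Resolution balances EIG ranking quality against the cost of
exhaustive per-trial EIG tables.

Each trial is placed at the (SF, contrast) pair maximising the one-step
expected information gain, computed in bits (the base only scales the
ranking; base 2 is fixed for reproducibility) through the mutual-
information identity `I(θ; R) = H(R) − H(R|θ)`, which equals the
expected-posterior-entropy-reduction definition exactly and lets all
720 stimuli be scored with two matrix products against a precomputed
node × stimulus probability table. Exact EIG ties break toward the
lowest SF, then the lowest contrast (deterministic; an arbitrary but
fixed rule). Only greedy one-step-ahead selection is implemented. Each
observer-location runs its own grid posterior; cohort simulations run
all sessions in lockstep sharing one likelihood table.

## Synthetic observer generator

The generator mirrors the hierarchy the model assumes. Observer-level
stacked mean vectors (3 parameters × 3 locations; log10 peak-CS, log10
peak-SF, bandwidth in octaves) are drawn from N(μ, Σ); test-level
parameters add per-location Gaussian noise φ_j; responses are Bernoulli
draws from the psychometric function. One root seed spawns per-observer
substreams, so cohorts are reproducible under partial regeneration.

Default calibration constants (synthetic choices, fixed once for
plausibility at 6° eccentricity; they are not measured values):

- location means of log10 peak-CS: grand mean 1.60 with an HVA offset
  of 0.15 (horizontal minus vertical-meridian average) and VMA offset
  of 0.10 (lower minus upper vertical): (1.70, 1.60, 1.50);
- log10 peak-SF means (0.25, 0.18, 0.12) — peak SFs ≈ 1.8/1.5/1.3 cpd;
- mean bandwidth 2.9 octaves at every location;
- population SDs (0.18, 0.15, 0.35 octaves);
- same-attribute cross-location correlations 0.7 (0.8 for bandwidth);
- a peak-CS/peak-SF coupling of 0.6 at the horizontal meridian only;
- bandwidth negatively coupled (−0.3) to both other parameters;
- test-retest (individual-level) SDs (0.08, 0.10, 0.15 octaves),
  diagonal.

The hand-specified correlation matrix is projected to the nearest
unit-diagonal positive-definite matrix (eigenvalue floor 1e-3), which
perturbs the stated entries slightly (e.g. the horizontal coupling
becomes ≈0.52). With `shared_bandwidth` (the default, matching the
translation-invariant-shape regime) each observer receives a single
bandwidth — the mean of the three location components of their drawn
vector — copied across locations, which slightly reduces the marginal
bandwidth variance relative to Σ.

Default trials per observer-location is 150 (configurable); the
generator emulates a 28-observer, 3-location design.

What the generator does **not** emulate: aborted/repeated trials, eye
movements, left/right horizontal asymmetries (collapsed by design),
learning or fatigue (stationary parameters), and lapse-rate
variability. Passing recovery tests therefore demonstrates correctness
of the inference machinery under the model's own assumptions, not
robustness to violations found in human data.

## BIP (independent per-cell fits)

Each observer-location is fit on a uniform 40³ grid spanning the prior
boxes exactly (finer than the adaptive grid; resolution is a package
choice). The point estimate is the posterior mean in log10 space, so
estimates always lie inside the prior support.

The across-observer summaries seed the hierarchical priors: Σ_BIP is
the sample covariance of the stacked per-observer estimate vectors;
φ_BIP,j is the covariance, per location, of each observer's deviation
from their own across-location mean. The latter construction is not
uniquely determined by independent per-cell fits; this definition is a
documented choice. Covariances that are rank-deficient (inevitable when
observers number fewer than the stacked dimension) or otherwise
degenerate receive a diagonal ridge of 1e-6 and are flagged.

## Hierarchical model and sampler

Levels: θ_ij ~ N(ρ_ij, φ_j) (test level, K = 1 test per cell — all of
an observer's trials at a location form one test), stacked ρ_i ~ N(μ,
Σ) (individual level), uniform priors on each component of μ (the
boxes above), Wishart priors on Σ⁻¹ and φ_j⁻¹.

Wishart convention: `W(Y, v)` with *expected precision* Y uses scale
`V = Y/v`, so `E[X] = Y`. With v = 4 and stacked dimensions 7 or 9 the
prior itself is improper (v < p); kernels are used unnormalised, and
every Gibbs conditional has degrees of freedom v + I ≥ p and is proper.

The fixed-bandwidth variant gives each participant one test-level
bandwidth shared across locations (7 free parameters: 2 × 3 + 1). The
stacked vector drops to 7 dimensions — Σ_BIP is mapped down by the
linear operator that keeps the six (peak-CS, peak-SF) components and
averages the three bandwidth components — and the individual-level
bandwidth covariance reduces to a scalar variance (mean of the three
per-location bandwidth variances). The varying variant keeps all 9.

Sampling is Metropolis-within-Gibbs. Conjugate draws: ρ_i (Gaussian,
one shared Cholesky per iteration), μ (Gaussian restricted to the
uniform box by rejection, clipped only in pathological states), Σ⁻¹ and
φ_j⁻¹ (Wishart with df v + I and scale `(v·Cov_prior + scatter)⁻¹`; the
scalar bandwidth precision is the 1-D special case, a Gamma draw).
Test-level parameters use random-walk Metropolis against the trial
likelihood — per-cell (peak-CS, peak-SF) blocks plus per-observer
bandwidth in the fixed variant — with three Metropolis sweeps per Gibbs
cycle, since these updates dominate the chain autocorrelation and cost
far less than the conjugate updates. Proposal scales adapt toward a
20–50% acceptance rate during the adaptation phase only and are frozen
before burn-in ends, preserving detailed balance for every retained
draw.

Profiles: the desk-scale default runs 3 chains × 2000 retained samples
(6000 pooled) with 5000 adaptation + 2000 burn-in iterations per chain
— sized so a 28 × 3 × 150-trial cohort fits in a few minutes on one
core. A full-scale profile (500000 adaptation / 20000 burn-in) is
available by configuration. Chains are deterministic under the run
seed; initial states are BIP estimates with chain-indexed jitter.

Convergence uses the classic Gelman–Rubin statistic (between- vs
within-chain variance, no rank normalisation) on every test-level
scalar and population-mean component, with threshold 1.05; an
unconverged fit is returned flagged, and BPIC refuses it unless
explicitly overridden (reduced-length exploratory chains).

Point estimates are pooled-sample means per observer-location in log10
space.

## Model comparison

BPIC = `mean deviance + 2·p_D`, with mean deviance `−2 E[log p(Y|X)]`
over pooled draws (likelihood term only) and `p_D = mean deviance −
deviance at the pooled posterior-mean parameters`. The exact
small-sample bias term of the original criterion is not reproduced; the
raw posterior-mean deviance is exposed so alternative penalties can be
formed. `compare_models` fits both variants on identical data, seeds,
and BIP seeding, and selects the lower BPIC.

## Covariance analyses

The attribute table stacks 5 attributes × 3 locations per observer.
Analysis space: log10 for peak-CS, peak-SF, and cutoff-SF; linear for
bandwidth (octaves) and AULCSF (the assignment is configurable; the
choice keeps each attribute on the scale on which it is modelled).

Covariance uses Schäfer–Strimmer shrinkage: off-diagonal correlations
are scaled by `1 − λ*` with the analytic intensity `λ* = Σ Var(r_ij) /
Σ r_ij²` (clipped to [0, 1]); variances are kept at their sample
values. Correlation CIs and p-values propagate from the MCMC posterior:
each of 1000 evenly-thinned pooled draws yields an attribute table,
hence a correlation and its analytic two-sided p; the CI is the
percentile interval of the per-draw correlations, and a coefficient is
significant when the **median** per-draw p, BH-FDR adjusted across the
tested pairs, falls below α = 0.05 (the median rule and the 95% CI
level are package choices). Without posterior samples the observed
table's unshrunk correlations provide a single analytic p (the shrunk
values would be conservative).

Cross-location cells ("one attribute, two locations") and
within-location triangles ("two attributes, one location") are exposed
as pair generators; bandwidth is excluded from cross-location tests
under fixed-bandwidth fits, where its columns are identical by
construction. The coefficient of variation (SD/mean) is computed on
linear scales by default so attributes with different units compare.

## Group statistics

Location effects use a one-way repeated-measures ANOVA with the
standard within-subject decomposition, df (2, 2(n−1)) — i.e. (2, 54)
at n = 28 — and partial η². The permutation null relabels the three
location values independently within each observer (the exchangeable
unit for repeated measures), sampled with replacement. Contrasts (HVA =
horizontal − mean of verticals; VMA = lower − upper; pairwise
differences) use the paired t statistic with a within-observer
sign-flip null and Cohen's d. Both report `p = max(#{permuted ≥
observed}/N, 1/N)` — one-sided exceedance with floor 0.001 at the
default N = 1000. Contrast p-values within an attribute form one
BH-FDR family. Degenerate inputs (zero error variance) resolve to F = 0
/ signed-infinite t by explicit rule rather than 0/0.

## Numerical choices and limitations

- Grid posteriors are renormalised after every update; likelihood
  tables are evaluated in float64 except the BIP's bulk node ×
  stimulus tables (float32, with final normalisation in float64).
- The μ rejection sampler falls back to clipping into the box after
  200 misses (only reachable from pathological states).
- The PD projection used for hand-specified correlation structures
  floors eigenvalues at 1e-3 and rescales the diagonal.
- Recovery and model-selection behaviour is validated on synthetic
  cohorts at desk scale (e.g. 28 × 3 × 150 trials; 12-observer
  replicates for model recovery); real-data effect sizes, lapse
  behaviour, and non-stationarity are outside the generator's scope.
- The sampler is a single-machine implementation; chains run
  sequentially.
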
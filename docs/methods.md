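# Methods

## The umbrella: model and conventions

A rating scale is an integer interval [x_min, x_max] with unit steps and
k = x_max − x_min thresholds. Scales not starting at zero are shifted
internally to 0-based and shifted back for reporting; equally spaced
non-integer scales map affinely (divide means and SDs by the step width), an
extension the API supports by rescaling rather than by a separate type.

All umbrella computations use the **population SD** (n in the denominator).
The unbiased (n−1) convention enters only at module boundaries through
`convert_sd`; in particular meta-analytic pooling uses unbiased SDs. The I/O
layer refuses to guess a convention — it must be declared when a CSV is read.

Continuous bounds at a mean x̄, with p = (x̄ − x_min)/k and f = frac(x̄ − x_min):

- `s_max(x̄) = k·√(p(1−p))` — attained by a two-point sample on the scale
  limits; symmetric about the midpoint, apex k/2, zero at the limits.
- `s_min(x̄) = √(f(1−f))` — attained by a two-point sample on the adjacent
  integers; periodic with unit period, zero exactly at integer means. This is
  the sample-size-free bound; the exact n-specific minimum is handled by
  `discrete_extrema`.

`discrete_extrema` is constructive and exact. With S = n·(x̄ − x_min)
(integral, else the mean is unattainable — the GRIM granularity condition):
the minimum splits responses between ⌊x̄⌋ and ⌊x̄⌋+1 (minimizes Σx² subject to
Σx = S); the maximum puts ⌊S/k⌋ responses at the upper limit, the remainder
S mod k on a single interior value, the rest at the lower limit. Σx² is
convex, so its maximum over the integer allocation polytope sits at a vertex
with at most one non-extreme coordinate; the test suite confirms both
extrema against exhaustive enumeration for every attainable mean with k ≤ 6,
n ≤ 8.

`enumerate_samples` iterates all C(n+k, k) multisets and deduplicates
(mean, SD) pairs on values rounded to 10 decimals (avoids float-identity
artifacts); it refuses when C(n+k, k) > 5·10⁶, since exhaustive plots are
only informative at small n anyway.

### Consistency checking

`check_consistency` treats reported summaries as rounded to a stated number
of decimals. The rounding tolerance is half a unit in the last reported digit
plus a 1e−9 float guard. The mean is feasible iff some attainable mean S/n
falls in its rounding interval; the SD (converted to the population
convention) must then lie inside the exact discrete [s_min, s_max] band of at
least one such candidate mean, up to the same tolerance. Using the
n-specific discrete band rather than the continuous outline makes the check
sharper without reconstructing response distributions; it remains a
necessary-condition (bounds-only) check, less precise in small samples than
full enumeration of candidate samples.

### Polarity

`polarity_index = (s − s_min)/(s_max − s_min)` uses the continuous bounds,
so it is sample-size-free and invariant under reflecting the mean about the
scale midpoint. It is undefined at the scale limits, where both bounds
vanish.

## Nominal Welch power

Power is **analytic, not simulated**: the test statistic is modelled as
noncentral t with noncentrality MD/SE, SE = √(sd_c²/n_c + sd_t²/n_t), and
Welch–Satterthwaite degrees of freedom evaluated at the supplied true SDs.
This is nominal power — the power the test would have if the data were
normal with those moments — not the effective power on discrete bounded
data, which is out of scope here. The Bernoulli-bound SDs are fed to the
power routine as true population SDs with no n/(n−1) correction.

Numerical notes:

- scipy's noncentral-t quadrature can return NaN deep in a tail at large
  noncentrality; the kernel works with |ncp| (two-sided power is symmetric in
  the sign), zeroes a NaN far tail, and falls back to the normal
  approximation Φ(ncp − t_crit) for a NaN near tail.
- Zero SE with a nonzero MD (both means at scale limits) returns power 1.0
  with a `DegenerateCaseWarning` rather than an error — it arises naturally
  in placement scans.
- Placement searches (`min_power_over_positions`, `smallest_d_of_interest`)
  use a 0.01-scale-point grid refined by bounded scalar minimization
  (xatol 1e−10) around the best cell, ties broken toward the scale midpoint.
  Equal per-group allocation is the planning default; unequal n is supported
  in `welch_power` itself.
- `required_n` doubles the per-group n until the worst-case power reaches
  the target, then bisects; the result satisfies power(n) ≥ target and
  power(n−1) < target.

`smallest_d_of_interest(MD)` divides MD by the largest pooled SD over all
placements, with pooled variance the mean of the two Bernoulli-maximum
variances (equal-n convention). For MD = 1 on a 0–6 scale the maximizing
placement is (2.5, 3.5) with pooled SD √8.75 ≈ 2.958, giving d ≥ 0.338.

## Meta-analysis of MD vs d

Per study: MD = mean_t − mean_c with var = s_c²/n_c + s_t²/n_t (unbiased
variances); pooled SD is the df-weighted combination, which at equal n is the
square root of the average variance; d = MD/s_pooled. The small-sample
(Hedges) factor 1 − 3/(4(n_c+n_t) − 9) is applied by default (matching
standard random-effects software), with a flag for raw d; var_d uses the
large-sample form (n_c+n_t)/(n_c·n_t) + d²/(2(n_c+n_t)) with the corrected d,
as common meta-analytic software does. A study whose pooled SD is zero has no
defined d and also zero MD sampling variance; `compare_meta` excludes such
studies from both fits and reports the count.

REML: the restricted log-likelihood profiled over μ is maximized in τ² by a
deterministic coarse log-spaced bracket scan followed by bounded scalar
minimization (xatol 1e−12), compared against the τ² = 0 boundary and floored
at zero. This matches the homoscedastic closed form max(0, S² − v), a
grid/golden-section likelihood oracle to 1e−6, and the R reference
implementation (metafor) to ~1e−5 on test instances; a scoring iteration
would add complexity without changing the optimum. μ is the
inverse-variance-weighted mean at the fitted τ², Q uses fixed-effect weights
with a χ²(K−1) p value, and I²/H² use the Higgins–Thompson typical
within-study variance s² = (K−1)Σw/((Σw)² − Σw²), w = 1/v. CV = τ/|μ| is
reported as NaN (with a warning) when μ = 0, since a relative heterogeneity
measure is meaningless at a null mean; the remaining statistics are still
returned.

Correlations between MD and s_pooled: Pearson with the classical Fisher-z
interval, Spearman (average ranks) with the Bonett–Wright variance-inflated
Fisher-z interval, SE = √((1 + ρ²/2)/(n−3)). Other interval constructions
exist for Spearman; this one is simple and close to exact for the K
typical of multi-lab projects.

The CV decomposition `CV_d = √(CV_MD² + CV_σ² − 2·r·CV_MD·CV_σ)` is a
**first-order (delta-method) identity** for the ratio d = MD/σ. Its accuracy
degrades as CV_σ grows (the ratio acquires heavy tails as σ approaches
zero); the test suite validates it against the Monte-Carlo CV of a jointly
lognormal (MD, σ) construction — lognormal keeps σ bounded away from zero so
the ratio has stable moments — at a documented first-order tolerance of 10%
relative for CVs ≤ 0.3 (measured discrepancy ≈ 5% at CVs 0.3/0.2, ≈ 0.5% at
0.2/0.1). `compare_meta` plugs the MD-fit CV, the sample CV of the pooled
SDs, and the observed Pearson r into the formula; the radicand is clamped at
zero with a warning if float error drives it negative.

## Synthetic multi-lab generator

The generator's defaults describe a direct-replication multi-lab on a 0–6
scale: K = 36 labs, 100 participants per condition, true effect
MD ~ N(0.8, 0.25²) scale points (relative heterogeneity CV ≈ 0.3), baseline
mean 2.5, latent response SD 0.2·k = 1.2 scale points — magnitudes typical
of published multi-lab rating-scale replications. Scenarios:

- **centered / ceiling**: latent normal responses rounded and clamped to the
  scale. `centered` keeps both latent means on the scale; `ceiling` lets the
  latent treatment mean exceed x_max (by at most half the range), so
  censoring piles responses at the limit — treatment means approach x_max
  and treatment SDs fall below control SDs.
- **polarized**: two-point responses on the scale extremes with the mixture
  weight chosen to hit the target mean — points on the upper outline.
- **opposed**: conditions pushed symmetrically from the midpoint by
  ±MD_lab/2 with polarized responses; larger lab effects move both groups
  toward the limits, shrinking both SDs and inducing a negative MD–s_pooled
  correlation across labs.

True effects are defined on the latent scale, so observed MDs are slightly
attenuated by rounding and censoring; recovery tests therefore use the
`centered` scenario away from the limits, where the attenuation is small
(measured ≈ 0.006 of 0.8 at the defaults). Reproducibility is bit-for-bit:
one global seed spawns a per-lab `SeedSequence` substream keyed by lab
index, so increasing K appends labs without reshuffling earlier ones.

What the generator does **not** emulate: multi-item composite scores,
item-level measurement models, participant-level covariates, non-normal
latent distributions, or unequal per-lab sample sizes. Tests passing on
these simulations show the pipeline's estimators behave correctly under a
clean latent-normal / two-point response process; they do not certify
behaviour on real response distributions.

## Problem sizes used in tests

Exhaustive enumeration checks run at k ≤ 6, n ≤ 12 (≤ 18 564 multisets per
case); Monte-Carlo power validation uses 10⁵ replicates per configuration
(MC SE ≈ 0.0013); the CV-decomposition check uses 10⁶ draws; parameter
recovery uses 200 replicates of K = 60 labs at 100 per group. These sizes
give simulation error well below the tolerances they are tested against
while keeping the default suite fast.

## Known limitations

- The consistency check is bounds-only: it can prove a summary impossible
  but never reconstructs the responses that would realize a possible one
  (granularity testing of the SD itself, beyond the umbrella band, is out of
  scope).
- Nominal power only; effective power of Welch's test on discrete bounded
  data can differ, especially at small n and near the limits.
- The CV decomposition is first-order and unreliable when CV_σ is large or
  μ is near zero.
- Ordinal/location-scale modelling, moderator analyses, and one-stage IPD
  meta-analysis are deliberately out of scope.
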
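# umbrellas

Tools for the dependency between means and standard deviations on bounded
integer rating scales — the "umbrella" of attainable (mean, SD) pairs — and
its consequences for error checking, statistical power, and meta-analytic
heterogeneity.

## The problem

Rating scales (e.g. a seven-point Likert item scored 0–6) are bounded,
integer-valued, and aggregated over finite samples. The sample mean x̄ and the
population-convention standard deviation *s* of such data cannot vary
independently: writing k = x_max − x_min and mapping the mean to a Bernoulli
proportion p = (x̄ − x_min)/k,

- the largest attainable SD at a mean is `s_max = k·√(p(1−p))` (responses
  split between the two scale limits),
- the smallest is `s_min = √(f(1−f))` with f the fractional part of the
  shifted mean (responses split between the two adjacent integers),

so all (x̄, s) pairs scatter inside an umbrella-shaped region whose apex is
k/2 at the scale midpoint. The package implements:

- **`umbrellas.scales`** — the continuous outline, exact discrete enumeration
  and extrema at finite n, GRIM-style granularity checking of reported
  (mean, SD, n) triples, and a polarity index locating an SD between its
  mean-specific bounds;
- **`umbrellas.power`** — analytic nominal power of Welch's t-test
  (noncentral t, Welch–Satterthwaite df), the power *range* implied by the
  umbrella for a mean difference MD, worst-case placement searches, the
  smallest standardized effect d = MD/s_pooled consistent with an MD, and
  maximally conservative sample-size planning;
- **`umbrellas.meta`** — per-study MD and d with sampling variances, REML
  random-effects fits for both, heterogeneity measures (τ, CV = τ/|μ|, H²,
  I², Cochran's Q), MD–s_pooled correlations with Fisher-z CIs, and the
  first-order decomposition
  `CV_d² ≈ CV_MD² + CV_σ² − 2·r·CV_MD·CV_σ`;
- **`umbrellas.synthetic`** — a seeded generator of multi-lab two-group
  rating-scale experiments (centered, ceiling, polarized, opposed response
  regimes) for testing the whole pipeline without external data;
- **`umbrellas.io` / `umbrellas.cli`** — a multi-lab aggregate CSV schema and
  the `umbrellas` command-line tool (`umbrella`, `check`, `power`, `meta`,
  `simulate`).

## Worked example

```python
>>> from umbrellas import (RatingScale, s_min_continuous, s_max_continuous,
...                        check_consistency, power_bounds, smallest_d_of_interest)
>>> sc = RatingScale(0, 6)                      # seven-point scale, k = 6
>>> round(s_min_continuous(0.5, sc), 3), round(s_max_continuous(0.5, sc), 3)
(0.5, 1.658)
>>> check_consistency(2.5, 3.2, 20, sc).overall # SD above the apex of 3
False
>>> lo, hi = power_bounds(sc, 5.5, 6.0, 96, 96) # MD = 0.5 at the scale limit
>>> round(lo, 3)
0.833
>>> lo, hi = power_bounds(sc, 3.0, 3.5, 96, 96) # same MD at the center
>>> round(lo, 3)
0.212
>>> round(smallest_d_of_interest(sc, 1.0), 3)   # any MD >= 1 implies |d| > 1/3
0.338
```

At mean 0.5 the SD must lie between 0.5 and 1.658; an SD of 3.2 is impossible
anywhere on a 0–6 scale (apex 3). The same half-point mean difference with
192 participants has at least 83% nominal power when the two means sit at
5.5 and 6 (worst case), but can drop to 21% when they sit at 3 and 3.5 —
the umbrella forces small SDs near the limits and permits large ones at the
center. And because the pooled SD can never exceed ~2.96 for means one point
apart, an unstandardized effect of 1 scale point always corresponds to a
standardized effect of at least 0.34.

From the shell:

```sh
umbrellas check --scale 0 6 --mean 2.5 --sd 3.2 --n 20
umbrellas umbrella --scale 1 7 --n 12 --plot umbrella.png
umbrellas simulate --scale 0 6 --labs 36 --n 100 --seed 7 --out sim
umbrellas meta --scale 0 6 --in sim_aggregates.csv --sd-convention unbiased
```

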
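"""Bounded integer rating scales and the umbrella of attainable (mean, SD) pairs.

A rating scale with integer responses between ``x_min`` and ``x_max`` constrains
which sample means are observable at a given sample size and, for every mean,
which standard deviations can accompany it.  Writing ``k = x_max - x_min`` for
the number of unit thresholds and ``p = (mean - x_min) / k`` for the mean mapped
to the unit interval, the extremal samples are binary (Bernoulli):

* the largest population SD at a mean is attained by splitting responses between
  the two scale limits, ``s_max = k * sqrt(p * (1 - p))``;
* the smallest is attained by splitting between the two integers adjacent to the
  mean, ``s_min = sqrt(f * (1 - f))`` with ``f`` the fractional part of the mean.

Plotting ``s_min`` and ``s_max`` over all means traces the outline of an
umbrella; every observable (mean, SD) pair lies on or inside it.  This module
implements the continuous outline, exact discrete enumeration at finite ``n``,
GRIM-style consistency checking of reported summaries, and a polarity index
locating an observed SD between its mean-specific bounds.

All umbrella computations use the population SD (``n`` in the denominator);
:func:`convert_sd` moves between conventions at module boundaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations_with_replacement
from typing import Iterator, Literal

import numpy as np
import pandas as pd

__all__ = [
    "RatingScale",
    "SampleSummary",
    "UmbrellaOutline",
    "DiscretePoint",
    "ConsistencyVerdict",
    "ScaleDomainError",
    "InfeasibleMeanError",
    "UndefinedPolarityError",
    "EnumerationLimitError",
    "bernoulli_p",
    "s_max_continuous",
    "s_min_continuous",
    "outline",
    "enumerate_samples",
    "discrete_extrema",
    "check_consistency",
    "polarity_index",
    "convert_sd",
]

SDConvention = Literal["population", "unbiased"]

#: Refuse enumeration when the number of multisets C(n + k, k) exceeds this.
ENUMERATION_CAP = 5_000_000

_EPS = 1e-9


class ScaleDomainError(ValueError):
    """An input lies outside the domain the scale admits."""


class InfeasibleMeanError(ScaleDomainError):
    """The requested mean is not attainable at this sample size (GRIM failure)."""


class UndefinedPolarityError(ScaleDomainError):
    """Polarity is undefined where s_min = s_max = 0 (the scale limits)."""


class EnumerationLimitError(RuntimeError):
    """Exhaustive enumeration would exceed the documented multiset cap."""


@dataclass(frozen=True)
class RatingScale:
    """An integer-bounded response scale with unit steps.

    Scales that do not start at zero (e.g. 1–7) are handled by shifting means
    internally to the 0-based scale and shifting back for reporting; all
    formulas below are shift-invariant.  Equally spaced non-integer scales map
    affinely onto an integer scale (divide means and SDs by the step width).
    """

    x_min: int
    x_max: int

    def __post_init__(self) -> None:
        if int(self.x_min) != self.x_min or int(self.x_max) != self.x_max:
            raise ScaleDomainError("scale limits must be integers")
        if self.x_max <= self.x_min:
            raise ScaleDomainError(
                f"x_max must exceed x_min (got [{self.x_min}, {self.x_max}])"
            )

    @property
    def k(self) -> int:
        """Number of unit thresholds, ``x_max - x_min``."""
        return self.x_max - self.x_min

    @property
    def values(self) -> range:
        return range(self.x_min, self.x_max + 1)

    def contains(self, mean: float) -> bool:
        return self.x_min - _EPS <= mean <= self.x_max + _EPS

    def _require(self, mean: float) -> None:
        if not self.contains(mean):
            raise ScaleDomainError(
                f"mean {mean} outside scale [{self.x_min}, {self.x_max}]"
            )


@dataclass(frozen=True)
class SampleSummary:
    """Reported (mean, sd, n) triple with an explicit SD-denominator convention."""

    mean: float
    sd: float
    n: int
    sd_convention: SDConvention = "unbiased"

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ScaleDomainError("n must be >= 1")
        if self.sd < 0:
            raise ScaleDomainError("sd must be >= 0")
        if self.sd_convention not in ("population", "unbiased"):
            raise ScaleDomainError(f"unknown sd convention {self.sd_convention!r}")

    def validate_against(self, scale: RatingScale) -> None:
        scale._require(self.mean)
        at_limit = (
            abs(self.mean - scale.x_min) < _EPS or abs(self.mean - scale.x_max) < _EPS
        )
        if at_limit and self.sd > _EPS:
            raise ScaleDomainError(
                f"sd must be 0 at the scale limit (mean={self.mean}, sd={self.sd})"
            )

    def as_population_sd(self) -> float:
        return convert_sd(self.sd, self.n, self.sd_convention, "population")

    def as_unbiased_sd(self) -> float:
        return convert_sd(self.sd, self.n, self.sd_convention, "unbiased")


@dataclass(frozen=True)
class UmbrellaOutline:
    """The continuous umbrella outline sampled on a regular mean grid."""

    scale: RatingScale
    grid: tuple[tuple[float, float, float], ...]  # (mean, s_min, s_max)
    grid_step: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.grid, columns=["mean", "s_min", "s_max"])

    @property
    def means(self) -> np.ndarray:
        return np.array([g[0] for g in self.grid])


@dataclass(frozen=True)
class DiscretePoint:
    """A distinct (mean, population SD) pair attainable at some sample size.

    ``multiplicity`` counts the multisets of responses mapping to the pair.
    """

    mean: float
    sd: float
    multiplicity: int


@dataclass(frozen=True)
class ConsistencyVerdict:
    """Outcome of the summary-statistic consistency check."""

    mean_feasible: bool
    sd_within_bounds: bool
    diagnostics: tuple[str, ...] = field(default_factory=tuple)

    @property
    def overall(self) -> bool:
        return self.mean_feasible and self.sd_within_bounds

    def report(self) -> str:
        lines = [
            "consistent" if self.overall else "INCONSISTENT",
            f"  mean feasible (granularity): {'yes' if self.mean_feasible else 'no'}",
            f"  sd within umbrella bounds:   {'yes' if self.sd_within_bounds else 'no'}",
        ]
        lines.extend(f"  - {d}" for d in self.diagnostics)
        return "\n".join(lines)


def bernoulli_p(mean: float, scale: RatingScale) -> float:
    """Map a scale mean to the Bernoulli success proportion p = (mean - x_min)/k."""
    scale._require(mean)
    p = (mean - scale.x_min) / scale.k
    return min(max(p, 0.0), 1.0)


def s_max_continuous(mean: float, scale: RatingScale) -> float:
    """Largest population SD attainable at ``mean``: k * sqrt(p(1-p)).

    The maximizing sample is binary on the two scale limits, so the variance is
    the Bernoulli variance rescaled by k².  Independent of sample size.
    """
    p = bernoulli_p(mean, scale)
    return scale.k * math.sqrt(p * (1.0 - p))


def s_min_continuous(mean: float, scale: RatingScale) -> float:
    """Smallest population SD attainable at ``mean`` for some sample size.

    The minimizing sample is binary on the two integers adjacent to the mean;
    only the fractional part ``f`` of the (shifted) mean matters:
    sqrt(f(1-f)).  Vanishes exactly at integer means.
    """
    scale._require(mean)
    f = (mean - scale.x_min) % 1.0
    # guard against float wrap: means within eps of an integer have f ~ 1
    if f > 1.0 - _EPS:
        f = 0.0
    return math.sqrt(f * (1.0 - f))


def outline(scale: RatingScale, grid_step: float = 0.01) -> UmbrellaOutline:
    """Sample the continuous umbrella outline over [x_min, x_max] inclusive."""
    if not 0 < grid_step <= 1:
        raise ScaleDomainError(f"grid_step must be in (0, 1], got {grid_step}")
    n_steps = int(round(scale.k / grid_step))
    means = np.linspace(scale.x_min, scale.x_max, n_steps + 1)
    if not math.isclose(means[1] - means[0], grid_step, rel_tol=1e-6):
        # step does not divide the range evenly; keep the requested step and
        # append the upper limit explicitly
        means = np.arange(scale.x_min, scale.x_max, grid_step)
        means = np.append(means, scale.x_max)
    grid = tuple(
        (float(m), s_min_continuous(float(m), scale), s_max_continuous(float(m), scale))
        for m in means
    )
    return UmbrellaOutline(scale=scale, grid=grid, grid_step=grid_step)


def _multisets(scale: RatingScale, n: int) -> Iterator[tuple[int, ...]]:
    yield from combinations_with_replacement(scale.values, n)


def enumerate_samples(scale: RatingScale, n: int) -> list[DiscretePoint]:
    """All distinct (mean, population SD) pairs over multisets of size ``n``.

    Multiplicities count multisets, so they sum to C(n + k, k).  Refuses when
    that count exceeds :data:`ENUMERATION_CAP`.
    """
    if n < 1:
        raise ScaleDomainError("n must be >= 1")
    total = math.comb(n + scale.k, scale.k)
    if total > ENUMERATION_CAP:
        raise EnumerationLimitError(
            f"C({n}+{scale.k}, {scale.k}) = {total} multisets exceeds the "
            f"enumeration cap of {ENUMERATION_CAP}; use discrete_extrema or the "
            "continuous outline instead"
        )
    counts: dict[tuple[float, float], int] = {}
    for sample in _multisets(scale, n):
        arr = np.asarray(sample, dtype=float)
        mean = float(arr.mean())
        sd = float(arr.std())  # population convention
        key = (round(mean, 10), round(sd, 10))
        counts[key] = counts.get(key, 0) + 1
    return [
        DiscretePoint(mean=m, sd=s, multiplicity=c)
        for (m, s), c in sorted(counts.items())
    ]


def _attainable_sum(scale: RatingScale, n: int, mean: float) -> int:
    """Integer response total for ``mean`` at size ``n``, or raise (GRIM)."""
    shifted = (mean - scale.x_min) * n
    total = round(shifted)
    if abs(shifted - total) > 1e-6:
        raise InfeasibleMeanError(
            f"mean {mean} is not attainable with n={n} on "
            f"[{scale.x_min}, {scale.x_max}] (n*mean is not an integer)"
        )
    if not 0 <= total <= n * scale.k:
        raise InfeasibleMeanError(f"mean {mean} outside the scale at n={n}")
    return int(total)


def discrete_extrema(
    scale: RatingScale, n: int, mean: float
) -> tuple[float, float]:
    """Exact feasible (min, max) population SD at this mean and sample size.

    Both extrema are constructive.  Writing ``S = n * (mean - x_min)`` for the
    shifted response total:

    * minimum: split responses between the two integers adjacent to the mean
      (``S mod n`` responses on ``floor(mean)+1``, the rest on ``floor(mean)``),
      which minimizes the sum of squares;
    * maximum: put ``S // k`` responses on the upper limit, the remainder
      ``S mod k`` (if any) on a single interior value, the rest on the lower
      limit.  The sum of squares is convex, so its maximum over the integer
      allocation polytope sits at a vertex with at most one interior value.
    """
    if n < 1:
        raise ScaleDomainError("n must be >= 1")
    scale._require(mean)
    total = _attainable_sum(scale, n, mean)
    k = scale.k
    xbar = total / n

    a = total // n  # floor of the shifted mean
    r = total - n * a
    sumsq_min = (n - r) * a**2 + r * (a + 1) ** 2

    q, rem = divmod(total, k)
    sumsq_max = q * k**2 + rem**2

    def _sd(sumsq: int) -> float:
        var = sumsq / n - xbar**2
        return math.sqrt(max(var, 0.0))

    return _sd(sumsq_min), _sd(sumsq_max)


def check_consistency(
    mean: float,
    sd: float,
    n: int,
    scale: RatingScale,
    reported_decimals: int = 2,
    sd_convention: SDConvention = "population",
) -> ConsistencyVerdict:
    """GRIM-style granularity check of a reported mean plus umbrella SD bounds.

    A reported mean rounded to ``reported_decimals`` is feasible iff some
    attainable mean (an integer response total divided by ``n``) lies in its
    rounding interval.  The reported SD (converted to the population
    convention) must then fall inside the exact discrete [s_min, s_max] band of
    at least one such attainable mean, up to rounding tolerance.  This is a
    quick necessary-condition check; it does not reconstruct response
    distributions and is less precise than exhaustive reconstruction in small
    samples.
    """
    if n < 1:
        raise ScaleDomainError("n must be >= 1")
    if reported_decimals < 0:
        raise ScaleDomainError("reported_decimals must be >= 0")
    if sd < 0:
        raise ScaleDomainError("sd must be >= 0")
    if mean < scale.x_min - 1 or mean > scale.x_max + 1:
        raise ScaleDomainError(
            f"reported mean {mean} is not plausibly on [{scale.x_min}, {scale.x_max}]"
        )

    half_ulp = 0.5 * 10.0 ** (-reported_decimals) + _EPS
    diagnostics: list[str] = []

    lo = (mean - half_ulp - scale.x_min) * n
    hi = (mean + half_ulp - scale.x_min) * n
    s_lo = max(math.ceil(lo), 0)
    s_hi = min(math.floor(hi), n * scale.k)
    mean_feasible = s_lo <= s_hi
    if not mean_feasible:
        diagnostics.append(
            f"no multiple of 1/{n} rounds to {mean:.{reported_decimals}f} "
            f"(granularity/GRIM failure)"
        )

    sd_pop = convert_sd(sd, n, sd_convention, "population") if n > 1 else sd
    sd_within = False
    if mean_feasible:
        best: tuple[float, float] | None = None
        for total in range(s_lo, s_hi + 1):
            cand = scale.x_min + total / n
            smin, smax = discrete_extrema(scale, n, cand)
            best = (smin, smax) if best is None else (
                min(best[0], smin), max(best[1], smax)
            )
            if smin - half_ulp <= sd_pop <= smax + half_ulp:
                sd_within = True
                break
        if not sd_within and best is not None:
            diagnostics.append(
                f"population sd {sd_pop:.4f} outside the attainable band "
                f"[{best[0]:.4f}, {best[1]:.4f}] for every mean rounding to "
                f"{mean:.{reported_decimals}f} at n={n}"
            )
    else:
        # still informative: compare against the global umbrella
        apex = scale.k / 2
        if sd_pop > apex + half_ulp:
            diagnostics.append(
                f"sd {sd_pop:.4f} also exceeds the umbrella apex {apex:.1f}"
            )
    return ConsistencyVerdict(
        mean_feasible=mean_feasible,
        sd_within_bounds=sd_within,
        diagnostics=tuple(diagnostics),
    )


def polarity_index(mean: float, sd: float, scale: RatingScale) -> float:
    """Relative position of an observed SD between its mean-specific bounds.

    0 means maximal agreement (SD at the attainable minimum), 1 maximal
    polarization (SD at the Bernoulli maximum).  Undefined at the scale limits
    where both bounds are zero.
    """
    scale._require(mean)
    smin = s_min_continuous(mean, scale)
    smax = s_max_continuous(mean, scale)
    if smax - smin < _EPS:
        raise UndefinedPolarityError(
            f"polarity undefined at mean {mean}: s_min = s_max = {smax:.4f}"
        )
    if sd < smin - _EPS or sd > smax + _EPS:
        raise ScaleDomainError(
            f"sd {sd} outside attainable band [{smin:.4f}, {smax:.4f}] at mean {mean}"
        )
    idx = (sd - smin) / (smax - smin)
    return min(max(idx, 0.0), 1.0)


def convert_sd(sd: float, n: int, from_: SDConvention, to: SDConvention) -> float:
    """Convert an SD between the population (n) and unbiased (n-1) denominators."""
    for conv in (from_, to):
        if conv not in ("population", "unbiased"):
            raise ScaleDomainError(f"unknown sd convention {conv!r}")
    if from_ == to:
        return sd
    if n < 2:
        raise ScaleDomainError("convention conversion requires n >= 2")
    if from_ == "population":
        return sd * math.sqrt(n / (n - 1))
    return sd * math.sqrt((n - 1) / n)
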
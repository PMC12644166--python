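"""Nominal power of Welch's two-sample t-test under umbrella SD constraints.

The umbrella couples each group mean on a bounded rating scale to a range of
attainable standard deviations, so a fixed unstandardized mean difference (MD)
implies a *range* of nominal power at a given sample size: the lower end with
both group SDs at their Bernoulli maxima, the upper end with both at their
minima.  Power here is always nominal — computed analytically from the
noncentral t distribution with Welch–Satterthwaite degrees of freedom, treating
the supplied SDs as true population SDs — not the effective power of the test
on discrete data.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .scales import RatingScale, ScaleDomainError, s_max_continuous, s_min_continuous

__all__ = [
    "WelchSpec",
    "PowerCurve",
    "DegenerateCaseWarning",
    "welch_se",
    "welch_df",
    "welch_power",
    "power_bounds",
    "power_bounds_curve",
    "min_power_over_positions",
    "smallest_d_of_interest",
    "required_n",
]

_GRID_STEP = 0.01  # scale points, placement searches


class DegenerateCaseWarning(UserWarning):
    """Both SDs are zero with a nonzero mean difference: power is trivially 1."""


@dataclass(frozen=True)
class WelchSpec:
    """A two-group configuration for Welch's t-test power.

    SDs are treated as true group SDs (population convention); the test is the
    alpha-level Welch t-test with Welch–Satterthwaite degrees of freedom.
    """

    mean_c: float
    mean_t: float
    sd_c: float
    sd_t: float
    n_c: int
    n_t: int
    alpha: float = 0.05
    sides: Literal["two", "one"] = "two"

    def __post_init__(self) -> None:
        if self.n_c < 2 or self.n_t < 2:
            raise ScaleDomainError("group sizes must be >= 2")
        if self.sd_c < 0 or self.sd_t < 0:
            raise ScaleDomainError("SDs must be >= 0")
        if not 0 < self.alpha < 1:
            raise ScaleDomainError("alpha must be in (0, 1)")
        if self.sides not in ("two", "one"):
            raise ScaleDomainError("sides must be 'two' or 'one'")
        if self.sd_c == 0 and self.sd_t == 0 and self.mean_c == self.mean_t:
            raise ScaleDomainError("degenerate spec: zero SDs and zero effect")

    @property
    def md(self) -> float:
        return self.mean_t - self.mean_c


@dataclass(frozen=True)
class PowerCurve:
    """Power as a function of total sample size for a fixed configuration."""

    label: str
    points: tuple[tuple[int, float], ...]  # (n_total, power)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.points, columns=["n_total", "power"])


def welch_se(sd_c: float, n_c: int, sd_t: float, n_t: int) -> float:
    """Standard error of the mean difference, sqrt(sd_c²/n_c + sd_t²/n_t)."""
    if n_c < 1 or n_t < 1:
        raise ScaleDomainError("group sizes must be >= 1")
    if sd_c < 0 or sd_t < 0:
        raise ScaleDomainError("SDs must be >= 0")
    return math.sqrt(sd_c**2 / n_c + sd_t**2 / n_t)


def welch_df(sd_c: float, n_c: int, sd_t: float, n_t: int) -> float:
    """Welch–Satterthwaite degrees of freedom for the given true SDs."""
    vc = sd_c**2 / n_c
    vt = sd_t**2 / n_t
    if vc + vt == 0:
        raise ScaleDomainError("degrees of freedom undefined with both SDs zero")
    denom = vc**2 / (n_c - 1) + vt**2 / (n_t - 1)
    return (vc + vt) ** 2 / denom


def _power_from_arrays(
    md: np.ndarray,
    sd_c: np.ndarray,
    sd_t: np.ndarray,
    n_c: int,
    n_t: int,
    alpha: float,
    sides: str = "two",
) -> np.ndarray:
    """Vectorized analytic Welch power; zero-SE cells resolve to 1 (md != 0)."""
    md = np.asarray(md, dtype=float)
    vc = np.asarray(sd_c, dtype=float) ** 2 / n_c
    vt = np.asarray(sd_t, dtype=float) ** 2 / n_t
    se2 = vc + vt
    md, se2, vc, vt = np.broadcast_arrays(md, se2, vc, vt)
    out = np.ones_like(se2, dtype=float)
    ok = se2 > 0
    if np.any(ok):
        df = se2[ok] ** 2 / (vc[ok] ** 2 / (n_c - 1) + vt[ok] ** 2 / (n_t - 1))
        # two-sided power is symmetric in the noncentrality sign; work with
        # |ncp| so the far tail is always the negligible one
        ncp = np.abs(md[ok]) / np.sqrt(se2[ok])
        if sides == "two":
            tcrit = stats.t.ppf(1 - alpha / 2, df)
            upper = np.atleast_1d(stats.nct.sf(tcrit, df, ncp))
            lower = np.atleast_1d(stats.nct.cdf(-tcrit, df, ncp))
            # scipy's noncentral-t quadrature can yield NaN deep in a tail;
            # the far tail is then vanishing, the near one ~ normal
            lower[np.isnan(lower)] = 0.0
            bad = np.isnan(upper)
            if np.any(bad):
                upper[bad] = stats.norm.sf(np.atleast_1d(tcrit - ncp)[bad])
            power = (upper + lower).reshape(df.shape)
        else:
            tcrit = stats.t.ppf(1 - alpha, df)
            power = np.atleast_1d(stats.nct.sf(tcrit, df, ncp))
            bad = np.isnan(power)
            if np.any(bad):
                power[bad] = stats.norm.sf(np.atleast_1d(tcrit - ncp)[bad])
            power = power.reshape(df.shape)
        out[ok] = power
    return out


def welch_power(spec: WelchSpec) -> float:
    """Analytic nominal power of Welch's t-test for the given configuration.

    Noncentrality is MD / SE with SE from :func:`welch_se`; the critical value
    comes from the central t at Welch–Satterthwaite df, the rejection
    probability from the noncentral t.  A zero SE with a nonzero MD returns
    power 1.0 with a :class:`DegenerateCaseWarning` (this occurs naturally when
    both means sit at scale limits).
    """
    se = welch_se(spec.sd_c, spec.n_c, spec.sd_t, spec.n_t)
    if se == 0:
        if spec.md == 0:
            raise ScaleDomainError("power undefined: zero SE and zero effect")
        warnings.warn(
            "both SDs are zero: any nonzero effect is detected with certainty",
            DegenerateCaseWarning,
            stacklevel=2,
        )
        return 1.0
    return float(
        _power_from_arrays(
            np.array(spec.md),
            np.array(spec.sd_c),
            np.array(spec.sd_t),
            spec.n_c,
            spec.n_t,
            spec.alpha,
            spec.sides,
        )
    )


def power_bounds(
    scale: RatingScale,
    mean_c: float,
    mean_t: float,
    n_c: int,
    n_t: int,
    alpha: float = 0.05,
) -> tuple[float, float]:
    """(min, max) nominal power for fixed group means on the scale.

    The minimum uses the Bernoulli-maximum SD at both means, the maximum the
    continuous minimum SD (zero at integer means; both SDs zero with a nonzero
    MD gives power 1).
    """
    if mean_c == mean_t:
        raise ScaleDomainError("power range undefined for MD = 0")
    lo_spec = WelchSpec(
        mean_c=mean_c,
        mean_t=mean_t,
        sd_c=s_max_continuous(mean_c, scale),
        sd_t=s_max_continuous(mean_t, scale),
        n_c=n_c,
        n_t=n_t,
        alpha=alpha,
    )
    min_power = welch_power(lo_spec)
    sd_c = s_min_continuous(mean_c, scale)
    sd_t = s_min_continuous(mean_t, scale)
    if sd_c == 0 and sd_t == 0:
        max_power = 1.0
    else:
        max_power = welch_power(
            WelchSpec(
                mean_c=mean_c,
                mean_t=mean_t,
                sd_c=sd_c,
                sd_t=sd_t,
                n_c=n_c,
                n_t=n_t,
                alpha=alpha,
            )
        )
    return min_power, max_power


def power_bounds_curve(
    scale: RatingScale,
    mean_c: float,
    mean_t: float,
    n_grid: list[int],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Table of (n_total, min_power, max_power) for equal per-group sizes."""
    rows = []
    for n_total in n_grid:
        n = n_total // 2
        lo, hi = power_bounds(scale, mean_c, mean_t, n, n_total - n, alpha)
        rows.append({"n_total": n_total, "min_power": lo, "max_power": hi})
    return pd.DataFrame(rows)


def min_power_over_positions(
    scale: RatingScale,
    MD: float,
    n_c: int,
    n_t: int,
    alpha: float = 0.05,
) -> tuple[float, float]:
    """Worst-case nominal power for a mean difference, over all placements.

    Both group SDs sit on the umbrella's upper outline (Bernoulli maxima); the
    control-mean placement is searched on a 0.01-point grid over
    [x_min, x_max - MD] and refined with bounded scalar minimization.  Returns
    (min_power, argmin mean_c), ties broken toward the scale midpoint.
    """
    if MD <= 0:
        raise ScaleDomainError("MD must be > 0")
    if MD > scale.k:
        raise ScaleDomainError(f"MD {MD} exceeds the scale range {scale.k}")
    if MD == scale.k:
        warnings.warn(
            "MD spans the whole scale: only placement is the two limits, "
            "both SDs zero, power 1",
            DegenerateCaseWarning,
            stacklevel=2,
        )
        return 1.0, float(scale.x_min)

    lo, hi = scale.x_min, scale.x_max - MD
    grid = np.arange(lo, hi + _GRID_STEP / 2, _GRID_STEP)
    grid = np.clip(grid, lo, hi)
    smax_c = np.array([s_max_continuous(m, scale) for m in grid])
    smax_t = np.array([s_max_continuous(m + MD, scale) for m in grid])
    powers = _power_from_arrays(
        np.full_like(grid, MD), smax_c, smax_t, n_c, n_t, alpha
    )
    best = powers.min()
    # ties toward the midpoint of the scale
    candidates = grid[powers <= best + 1e-12]
    center = (scale.x_min + scale.x_max - MD) / 2
    m0 = float(candidates[np.argmin(np.abs(candidates - center))])

    def objective(m: float) -> float:
        return float(
            _power_from_arrays(
                np.array(MD),
                np.array(s_max_continuous(m, scale)),
                np.array(s_max_continuous(m + MD, scale)),
                n_c,
                n_t,
                alpha,
            )
        )

    res = optimize.minimize_scalar(
        objective,
        bounds=(max(lo, m0 - _GRID_STEP), min(hi, m0 + _GRID_STEP)),
        method="bounded",
        options={"xatol": 1e-10},
    )
    if res.fun <= best:
        best, m0 = float(res.fun), float(res.x)
    if abs(m0 - center) < 1e-6:
        m0 = center
    return float(best), m0


def smallest_d_of_interest(scale: RatingScale, MD: float) -> float:
    """Smallest standardized effect consistent with an unstandardized MD.

    Divides MD by the largest pooled SD attainable over all placements of the
    two group means (pooled variance = mean of the two Bernoulli-maximum
    variances, equal-n convention).  Any observed effect of at least MD scale
    points therefore has |d| at least this value.
    """
    if MD <= 0:
        raise ScaleDomainError("MD must be > 0")
    if MD >= scale.k:
        raise ScaleDomainError(
            f"MD {MD} >= scale range {scale.k}: pooled SD degenerates to 0"
        )

    def pooled_sd(m: float) -> float:
        v_c = s_max_continuous(m, scale) ** 2
        v_t = s_max_continuous(m + MD, scale) ** 2
        return math.sqrt((v_c + v_t) / 2)

    lo, hi = scale.x_min, scale.x_max - MD
    grid = np.arange(lo, hi + _GRID_STEP / 2, _GRID_STEP)
    grid = np.clip(grid, lo, hi)
    best_m = float(grid[np.argmax([pooled_sd(m) for m in grid])])
    res = optimize.minimize_scalar(
        lambda m: -pooled_sd(m),
        bounds=(max(lo, best_m - _GRID_STEP), min(hi, best_m + _GRID_STEP)),
        method="bounded",
        options={"xatol": 1e-10},
    )
    s_pooled_max = max(pooled_sd(best_m), -float(res.fun))
    return MD / s_pooled_max


def required_n(
    scale: RatingScale,
    MD: float,
    target_power: float = 0.80,
    alpha: float = 0.05,
) -> int:
    """Smallest equal per-group n whose worst-case power reaches the target.

    Maximally conservative: uses :func:`min_power_over_positions`, i.e. both
    group SDs at their Bernoulli maxima at the least favourable placement.
    Found by doubling then bisection; satisfies power(n) >= target and
    power(n-1) < target.
    """
    if not alpha < target_power < 1:
        raise ScaleDomainError("target_power must be in (alpha, 1)")
    if MD <= 0 or MD >= scale.k:
        raise ScaleDomainError("MD must be in (0, k)")

    def worst(n: int) -> float:
        return min_power_over_positions(scale, MD, n, n, alpha)[0]

    n_hi = 2
    while worst(n_hi) < target_power:
        n_hi *= 2
        if n_hi > 2**22:
            raise ScaleDomainError("target power unreachable at feasible n")
    n_lo = max(2, n_hi // 2)
    while n_lo < n_hi:
        mid = (n_lo + n_hi) // 2
        if worst(mid) >= target_power:
            n_hi = mid
        else:
            n_lo = mid + 1
    return n_hi
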
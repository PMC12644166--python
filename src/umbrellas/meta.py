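"""Random-effects meta-analysis of unstandardized vs standardized effects.

On a bounded rating scale the pooled SD is coupled to the group means, so the
mean difference MD (in scale points) and the standardized mean difference
d = MD / s_pooled carry different heterogeneity.  Relative heterogeneity is
compared through the coefficient of variation of true effects, CV = tau / |mu|,
which for the ratio d decomposes to first order as

    CV_d² ≈ CV_MD² + CV_sigma² − 2 r CV_MD CV_sigma,

with r the correlation between MD and the pooled SD across studies.  When MD is
homogeneous this collapses to CV_d = CV_sigma: all heterogeneity in d comes
from the SDs.

The random-effects model is the standard normal–normal one, y_i ~ N(theta_i,
v_i), theta_i ~ N(mu, tau²), with tau² estimated by restricted maximum
likelihood (REML) and heterogeneity summarized by tau, CV, H², I² (via the
Higgins–Thompson "typical" within-study variance), and Cochran's Q with its
chi-square p value.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .scales import RatingScale, SampleSummary, ScaleDomainError, convert_sd

__all__ = [
    "StudyArms",
    "EffectRecord",
    "MetaResult",
    "CorrelationResult",
    "DecompositionResult",
    "CompareReport",
    "compute_effects",
    "reml_re",
    "correlations",
    "cv_decomposition",
    "compare_meta",
]


@dataclass(frozen=True)
class StudyArms:
    """Control/treatment summary pair for one study on a common scale."""

    study_id: str
    control: SampleSummary
    treatment: SampleSummary
    scale: RatingScale

    def __post_init__(self) -> None:
        for arm in (self.control, self.treatment):
            self.scale._require(arm.mean)
            if arm.n < 2:
                raise ScaleDomainError(
                    f"study {self.study_id!r}: each arm needs n >= 2"
                )


@dataclass(frozen=True)
class EffectRecord:
    """Per-study effects: MD with variance, pooled SD, and d with variance.

    ``d`` is None (flagged) when the pooled SD is zero.  With the small-sample
    correction on, ``d`` carries the Hedges factor 1 − 3/(4(n_c+n_t) − 9).
    """

    study_id: str
    MD: float
    var_MD: float
    s_pooled: float
    d: float | None
    var_d: float | None
    n_c: int
    n_t: int
    small_sample_corrected: bool


@dataclass(frozen=True)
class MetaResult:
    """Random-effects fit with absolute and relative heterogeneity measures."""

    K: int
    mu: float
    se_mu: float
    tau: float
    tau2: float
    CV: float
    H2: float
    I2: float  # percent
    Q: float
    QEp: float
    typical_v: float

    def to_series(self, label: str = "") -> pd.Series:
        return pd.Series(
            {
                "K": self.K,
                "mu": self.mu,
                "se_mu": self.se_mu,
                "tau": self.tau,
                "CV": self.CV,
                "H2": self.H2,
                "I2": self.I2,
                "Q": self.Q,
                "QEp": self.QEp,
            },
            name=label,
        )


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson and Spearman correlations with Fisher-z confidence intervals."""

    r_pearson: float
    pearson_CI: tuple[float, float]
    r_spearman: float
    spearman_CI: tuple[float, float]
    n: int
    level: float


@dataclass(frozen=True)
class DecompositionResult:
    """First-order CV decomposition of d into MD and pooled-SD components."""

    CV_MD: float
    CV_sigma_pooled: float
    r: float
    CV_d_predicted: float


@dataclass(frozen=True)
class CompareReport:
    """Side-by-side MD vs d meta-analysis with correlation and decomposition."""

    effects: tuple[EffectRecord, ...]
    meta_MD: MetaResult
    meta_d: MetaResult
    correlation: CorrelationResult | None
    decomposition: DecompositionResult | None
    n_excluded_d: int
    umbrella_points: pd.DataFrame  # per-arm (study_id, condition, mean, sd_pop)

    def heterogeneity_table(self) -> pd.DataFrame:
        """Rows per effect measure, columns mu, tau, CV, H2, I2, QEp, df."""
        rows = []
        for label, m in (("MD", self.meta_MD), ("d", self.meta_d)):
            rows.append(
                {
                    "measure": label,
                    "mu": m.mu,
                    "tau": m.tau,
                    "CV": m.CV,
                    "H2": m.H2,
                    "I2": m.I2,
                    "QEp": m.QEp,
                    "df": m.K - 1,
                }
            )
        return pd.DataFrame(rows)

    def correlation_table(self) -> pd.DataFrame:
        c = self.correlation
        if c is None:
            return pd.DataFrame()
        return pd.DataFrame(
            [
                {
                    "r_pearson": c.r_pearson,
                    "pearson_LL": c.pearson_CI[0],
                    "pearson_UL": c.pearson_CI[1],
                    "r_spearman": c.r_spearman,
                    "spearman_LL": c.spearman_CI[0],
                    "spearman_UL": c.spearman_CI[1],
                    "K": c.n,
                }
            ]
        )


def _hedges_j(n_total: int) -> float:
    return 1.0 - 3.0 / (4.0 * n_total - 9.0)


def compute_effects(
    studies: Sequence[StudyArms], correction: bool = True
) -> list[EffectRecord]:
    """Per-study MD and d with sampling variances.

    SDs are converted to the unbiased (n−1) convention first.  MD = mean_t −
    mean_c with var_MD = s_c²/n_c + s_t²/n_t; the pooled SD is the
    df-weighted combination (at equal n, the square root of the average
    variance); d = MD/s_pooled, optionally Hedges-corrected, with the
    large-sample variance (n_c+n_t)/(n_c n_t) + d²/(2(n_c+n_t)).  Studies with
    zero pooled SD get a flagged record (d is None).
    """
    records: list[EffectRecord] = []
    for st in studies:
        n_c, n_t = st.control.n, st.treatment.n
        s_c = st.control.as_unbiased_sd()
        s_t = st.treatment.as_unbiased_sd()
        md = st.treatment.mean - st.control.mean
        var_md = s_c**2 / n_c + s_t**2 / n_t
        s_pooled = math.sqrt(
            ((n_c - 1) * s_c**2 + (n_t - 1) * s_t**2) / (n_c + n_t - 2)
        )
        if s_pooled == 0:
            records.append(
                EffectRecord(
                    study_id=st.study_id,
                    MD=md,
                    var_MD=var_md,
                    s_pooled=0.0,
                    d=None,
                    var_d=None,
                    n_c=n_c,
                    n_t=n_t,
                    small_sample_corrected=correction,
                )
            )
            continue
        d = md / s_pooled
        if correction:
            d *= _hedges_j(n_c + n_t)
        var_d = (n_c + n_t) / (n_c * n_t) + d**2 / (2 * (n_c + n_t))
        records.append(
            EffectRecord(
                study_id=st.study_id,
                MD=md,
                var_MD=var_md,
                s_pooled=s_pooled,
                d=d,
                var_d=var_d,
                n_c=n_c,
                n_t=n_t,
                small_sample_corrected=correction,
            )
        )
    return records


def _restricted_nll(tau2: float, y: np.ndarray, v: np.ndarray) -> float:
    w = 1.0 / (v + tau2)
    mu = np.sum(w * y) / np.sum(w)
    return 0.5 * (
        np.sum(np.log(v + tau2))
        + math.log(np.sum(w))
        + np.sum(w * (y - mu) ** 2)
    )


def reml_re(y: Sequence[float], v: Sequence[float]) -> MetaResult:
    """Fit the random-effects model by REML and summarize heterogeneity.

    tau² maximizes the restricted log-likelihood (profiled over mu), floored at
    zero.  mu is the inverse-variance weighted mean at the fitted tau², Q is
    Cochran's statistic with fixed-effect weights, and I²/H² use the
    Higgins–Thompson typical within-study variance
    s² = (K−1) Σw_i / ((Σw_i)² − Σw_i²) with w_i = 1/v_i.

    The 1-D maximization is deterministic: a coarse logarithmic bracket scan
    followed by bounded scalar minimization to xatol 1e-12, compared against
    the tau² = 0 boundary.
    """
    y = np.asarray(list(y), dtype=float)
    v = np.asarray(list(v), dtype=float)
    K = y.size
    if K < 2:
        raise ScaleDomainError("random-effects fit requires K >= 2 studies")
    if np.any(v <= 0):
        raise ScaleDomainError("all sampling variances must be > 0")

    # scan a log-spaced grid to bracket the optimum, then polish
    spread = float(np.var(y, ddof=1)) if K > 1 else 0.0
    upper = 10.0 * (spread + float(v.max())) + 1e-8
    grid = np.concatenate([[0.0], np.geomspace(1e-10, upper, 200)])
    nll = np.array([_restricted_nll(t, y, v) for t in grid])
    i = int(np.argmin(nll))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, grid.size - 1)]
    tau2, best = float(grid[i]), float(nll[i])
    if hi > lo:
        res = optimize.minimize_scalar(
            _restricted_nll,
            args=(y, v),
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-12},
        )
        if res.fun < best:
            tau2 = float(res.x)
    tau2 = max(tau2, 0.0)
    if tau2 < 1e-12:
        tau2 = 0.0
    tau = math.sqrt(tau2)

    w = 1.0 / (v + tau2)
    mu = float(np.sum(w * y) / np.sum(w))
    se_mu = float(math.sqrt(1.0 / np.sum(w)))

    w_fe = 1.0 / v
    mu_fe = float(np.sum(w_fe * y) / np.sum(w_fe))
    Q = float(np.sum(w_fe * (y - mu_fe) ** 2))
    QEp = float(stats.chi2.sf(Q, K - 1))

    typical_v = float((K - 1) * np.sum(w_fe) / (np.sum(w_fe) ** 2 - np.sum(w_fe**2)))
    H2 = (tau2 + typical_v) / typical_v
    I2 = 100.0 * tau2 / (tau2 + typical_v)

    if abs(mu) < 1e-12:
        warnings.warn(
            "meta-analytic mean is zero: CV = tau/|mu| undefined, reported as NaN",
            UserWarning,
            stacklevel=2,
        )
        CV = math.nan
    else:
        CV = tau / abs(mu)

    return MetaResult(
        K=K,
        mu=mu,
        se_mu=se_mu,
        tau=tau,
        tau2=tau2,
        CV=CV,
        H2=H2,
        I2=I2,
        Q=Q,
        QEp=QEp,
        typical_v=typical_v,
    )


def _fisher_ci(r: float, se_z: float, level: float) -> tuple[float, float]:
    z = math.atanh(max(min(r, 1 - 1e-15), -1 + 1e-15))
    zc = stats.norm.ppf(0.5 + level / 2)
    return math.tanh(z - zc * se_z), math.tanh(z + zc * se_z)


def correlations(
    md: Sequence[float], s_pooled: Sequence[float], level: float = 0.95
) -> CorrelationResult:
    """Pearson and Spearman correlations between MD and pooled SD, with CIs.

    Pearson uses the classical Fisher-z interval (SE 1/sqrt(n−3)); Spearman
    (average ranks for ties) uses the Bonett–Wright variance-inflated Fisher-z
    interval with SE sqrt((1 + rho²/2)/(n − 3)).
    """
    x = np.asarray(list(md), dtype=float)
    s = np.asarray(list(s_pooled), dtype=float)
    n = x.size
    if n < 4:
        raise ScaleDomainError("correlations require K >= 4 studies")
    if not 0 < level < 1:
        raise ScaleDomainError("confidence level must be in (0, 1)")
    if np.std(x) == 0 or np.std(s) == 0:
        raise ScaleDomainError("correlation undefined: a vector has zero variance")

    r_p = float(stats.pearsonr(x, s).statistic)
    ci_p = _fisher_ci(r_p, 1.0 / math.sqrt(n - 3), level)
    r_s = float(stats.spearmanr(x, s).statistic)
    ci_s = _fisher_ci(r_s, math.sqrt((1 + r_s**2 / 2) / (n - 3)), level)
    return CorrelationResult(
        r_pearson=r_p,
        pearson_CI=ci_p,
        r_spearman=r_s,
        spearman_CI=ci_s,
        n=n,
        level=level,
    )


def cv_decomposition(CV_MD: float, CV_sigma: float, r: float) -> float:
    """First-order CV of d from the CVs of MD and pooled SD and their correlation.

    CV_d = sqrt(CV_MD² + CV_sigma² − 2 r CV_MD CV_sigma); with homogeneous MD
    (CV_MD = 0) this reduces to CV_d = CV_sigma.  The radicand is clamped at
    zero (with a warning) if float error drives it negative.
    """
    if CV_MD < 0 or CV_sigma < 0:
        raise ScaleDomainError("CVs must be >= 0")
    if abs(r) > 1:
        raise ScaleDomainError("correlation must lie in [-1, 1]")
    radicand = CV_MD**2 + CV_sigma**2 - 2 * r * CV_MD * CV_sigma
    if radicand < 0:
        if radicand < -1e-12:
            warnings.warn(
                f"negative radicand {radicand:.3e} clamped to 0",
                UserWarning,
                stacklevel=2,
            )
        radicand = 0.0
    return math.sqrt(radicand)


def compare_meta(
    studies: Sequence[StudyArms], correction: bool = True
) -> CompareReport:
    """Side-by-side random-effects meta-analysis of MD and d.

    Fits REML to both effect measures, correlates MD with the pooled SD, and
    plugs the MD-fit CV, the sample CV of the pooled SDs, and the Pearson
    correlation into the first-order decomposition.  Studies with undefined d
    (zero pooled SD, hence also zero MD sampling variance) are excluded from
    both fits and counted.
    """
    if len(studies) < 2:
        raise ScaleDomainError("compare_meta requires K >= 2 studies")
    effects = compute_effects(studies, correction=correction)

    with_var = [e for e in effects if e.var_MD > 0]
    if len(with_var) < 2:
        raise ScaleDomainError("fewer than 2 studies with positive MD variance")
    meta_MD = reml_re([e.MD for e in with_var], [e.var_MD for e in with_var])
    defined = [e for e in effects if e.d is not None and e.var_MD > 0]
    n_excluded = len(effects) - len(defined)
    if len(defined) < 2:
        raise ScaleDomainError("fewer than 2 studies with a defined d")
    meta_d = reml_re([e.d for e in defined], [e.var_d for e in defined])

    corr: CorrelationResult | None = None
    decomp: DecompositionResult | None = None
    md_vec = np.array([e.MD for e in defined])
    sp_vec = np.array([e.s_pooled for e in defined])
    try:
        corr = correlations(md_vec, sp_vec)
    except ScaleDomainError:
        corr = None
    if corr is not None and sp_vec.mean() > 0 and not math.isnan(meta_MD.CV):
        cv_sigma = float(np.std(sp_vec, ddof=1) / sp_vec.mean())
        decomp = DecompositionResult(
            CV_MD=meta_MD.CV,
            CV_sigma_pooled=cv_sigma,
            r=corr.r_pearson,
            CV_d_predicted=cv_decomposition(meta_MD.CV, cv_sigma, corr.r_pearson),
        )

    pts = []
    for st in studies:
        for cond, arm in (("control", st.control), ("treatment", st.treatment)):
            pts.append(
                {
                    "study_id": st.study_id,
                    "condition": cond,
                    "mean": arm.mean,
                    "sd_pop": arm.as_population_sd(),
                }
            )
    return CompareReport(
        effects=tuple(effects),
        meta_MD=meta_MD,
        meta_d=meta_d,
        correlation=corr,
        decomposition=decomp,
        n_excluded_d=n_excluded,
        umbrella_points=pd.DataFrame(pts),
    )
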
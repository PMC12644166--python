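"""Synthetic multi-lab two-group rating-scale experiments.

Generates individual responses and per-lab aggregates for K labs running the
same two-condition design on a bounded integer scale, with a true
unstandardized effect drawn per lab from Normal(mu_MD, tau_MD²).  Four response
regimes cover the qualitative patterns seen in multi-lab umbrella plots:

``centered``
    Latent-normal responses (SD = dispersion * k) rounded and clamped to the
    scale, with both group means away from the limits — points scatter around
    the middle of the umbrella.
``ceiling``
    Same mechanism, but the latent treatment mean may exceed the upper limit;
    censoring piles responses at x_max, so treatment means approach the limit
    and treatment SDs shrink below control SDs.
``polarized``
    Two-point responses on the scale extremes with the mixture weight set to
    hit the target group mean — points sit on the umbrella's upper outline.
``opposed``
    Conditions pushed symmetrically from the scale midpoint by ±MD_lab/2 with
    polarized response style; as the lab effect grows, both SDs fall, inducing
    a negative MD–s_pooled correlation across labs.

Every generated aggregate lies inside the umbrella by construction (it is
computed from actual on-scale responses).  Reproducibility: one global seed
drives a per-lab spawned substream, so changing K leaves earlier labs' data
untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from .scales import RatingScale, SampleSummary, ScaleDomainError

__all__ = ["SimConfig", "ConfigError", "DataError", "generate_multilab",
           "aggregate_ipd", "aggregate_table"]

Scenario = Literal["centered", "ceiling", "polarized", "opposed"]


class ConfigError(ValueError):
    """The simulation configuration is infeasible on the given scale."""


class DataError(ValueError):
    """Individual responses violate the scale or the table is malformed."""


@dataclass(frozen=True)
class SimConfig:
    """Configuration of a simulated multi-lab experiment.

    Defaults emulate a direct-replication multi-lab on a seven-point (0–6)
    scale: 36 labs of 100 participants per condition, a true mean effect of
    0.8 scale points with between-lab SD 0.25 (CV ≈ 0.3), baseline mean 2.5,
    and latent response SD of 0.2·k = 1.2 scale points.
    """

    scale: RatingScale = field(default_factory=lambda: RatingScale(0, 6))
    K: int = 36
    n_c: int = 100
    n_t: int = 100
    scenario: Scenario = "centered"
    mu_MD: float = 0.8
    tau_MD: float = 0.25
    baseline_mean: float = 2.5
    dispersion: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ConfigError("K must be >= 1")
        if self.n_c < 2 or self.n_t < 2:
            raise ConfigError("per-lab group sizes must be >= 2")
        if self.scenario not in ("centered", "ceiling", "polarized", "opposed"):
            raise ConfigError(f"unknown scenario {self.scenario!r}")
        if self.tau_MD < 0:
            raise ConfigError("tau_MD must be >= 0")
        if not 0 < self.dispersion <= 1:
            raise ConfigError("dispersion must be in (0, 1]")
        if self.seed is None:
            raise ConfigError("a seed is mandatory for reproducibility")
        lo, hi = self.scale.x_min, self.scale.x_max
        if not lo <= self.baseline_mean <= hi:
            raise ConfigError(f"baseline_mean {self.baseline_mean} outside scale")
        # scenario-specific feasibility of the mean targets (checked before
        # sampling; individual labs clip their drawn effect to the feasible
        # range, see generate_multilab)
        if self.scenario in ("centered", "polarized"):
            if not lo <= self.baseline_mean + self.mu_MD <= hi:
                raise ConfigError(
                    "baseline_mean + mu_MD must stay on the scale for "
                    f"scenario {self.scenario!r}"
                )
        elif self.scenario == "opposed":
            if abs(self.mu_MD) > self.scale.k:
                raise ConfigError("|mu_MD| must not exceed the scale range")
        elif self.scenario == "ceiling":
            # censoring is the point; only the baseline must be on-scale, and
            # the latent treatment target must overshoot at most a half range
            if self.baseline_mean + self.mu_MD > hi + self.scale.k / 2:
                raise ConfigError("ceiling overshoot beyond half the scale range")


def _lab_rng(seed: int, lab: int) -> np.random.Generator:
    # spawn_key-based substream: lab i's stream does not depend on K
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(lab,)))


def _latent_normal(
    rng: np.random.Generator, scale: RatingScale, mean: float, sd: float, n: int
) -> np.ndarray:
    latent = rng.normal(mean, sd, size=n)
    return np.clip(np.rint(latent), scale.x_min, scale.x_max).astype(int)


def _two_point(
    rng: np.random.Generator, scale: RatingScale, mean: float, n: int
) -> np.ndarray:
    p = (mean - scale.x_min) / scale.k
    p = min(max(p, 0.0), 1.0)
    hits = rng.random(n) < p
    return np.where(hits, scale.x_max, scale.x_min).astype(int)


def generate_multilab(config: SimConfig) -> tuple[pd.DataFrame, list["StudyArmsList"]]:
    """Simulate IPD and aggregates for a multi-lab experiment.

    Returns the long-format IPD table (study_id, condition, response) and the
    per-lab :class:`~umbrellas.meta.StudyArms` aggregates computed from it.
    Per-lab true effects are drawn from Normal(mu_MD, tau_MD²) and clipped to
    the feasible range of the scenario's mean targets.
    """
    scale = config.scale
    lo, hi = scale.x_min, scale.x_max
    frames: list[pd.DataFrame] = []
    for i in range(config.K):
        rng = _lab_rng(config.seed, i)
        md_lab = rng.normal(config.mu_MD, config.tau_MD)
        sd_latent = config.dispersion * scale.k
        if config.scenario in ("centered", "ceiling"):
            m_c = config.baseline_mean
            m_t = config.baseline_mean + md_lab
            if config.scenario == "centered":
                m_t = min(max(m_t, lo), hi)
            resp_c = _latent_normal(rng, scale, m_c, sd_latent, config.n_c)
            resp_t = _latent_normal(rng, scale, m_t, sd_latent, config.n_t)
        elif config.scenario == "polarized":
            m_c = config.baseline_mean
            m_t = min(max(config.baseline_mean + md_lab, lo), hi)
            resp_c = _two_point(rng, scale, m_c, config.n_c)
            resp_t = _two_point(rng, scale, m_t, config.n_t)
        else:  # opposed
            mid = (lo + hi) / 2
            half = min(max(md_lab, -scale.k), scale.k) / 2
            m_c = min(max(mid - half, lo), hi)
            m_t = min(max(mid + half, lo), hi)
            resp_c = _two_point(rng, scale, m_c, config.n_c)
            resp_t = _two_point(rng, scale, m_t, config.n_t)
        study = f"lab{i + 1:03d}"
        frames.append(
            pd.DataFrame(
                {
                    "study_id": study,
                    "condition": ["control"] * config.n_c
                    + ["treatment"] * config.n_t,
                    "response": np.concatenate([resp_c, resp_t]),
                }
            )
        )
    ipd = pd.concat(frames, ignore_index=True)
    return ipd, aggregate_ipd(ipd, scale)


def aggregate_ipd(ipd: pd.DataFrame, scale: RatingScale) -> list:
    """Per-lab, per-condition aggregates as StudyArms (unbiased-SD convention).

    Validates that every response is an integer on the scale; an empty
    condition is a data error.
    """
    from .meta import StudyArms  # local import to avoid a cycle

    required = {"study_id", "condition", "response"}
    if not required.issubset(ipd.columns):
        raise DataError(f"IPD table must have columns {sorted(required)}")
    resp = ipd["response"].to_numpy()
    if not np.all(np.isfinite(resp)) or not np.all(resp == np.rint(resp)):
        raise DataError("responses must be integers")
    if resp.min() < scale.x_min or resp.max() > scale.x_max:
        raise DataError(
            f"responses outside scale [{scale.x_min}, {scale.x_max}]"
        )
    arms: list[StudyArms] = []
    for study, grp in ipd.groupby("study_id", sort=True):
        summaries = {}
        for cond in ("control", "treatment"):
            sub = grp.loc[grp["condition"] == cond, "response"].to_numpy(dtype=float)
            if sub.size == 0:
                raise DataError(f"study {study!r}: empty {cond} condition")
            summaries[cond] = SampleSummary(
                mean=float(sub.mean()),
                sd=float(sub.std(ddof=1)) if sub.size > 1 else 0.0,
                n=int(sub.size),
                sd_convention="unbiased",
            )
        try:
            arms.append(
                StudyArms(
                    study_id=str(study),
                    control=summaries["control"],
                    treatment=summaries["treatment"],
                    scale=scale,
                )
            )
        except ScaleDomainError as exc:  # pragma: no cover - defensive
            raise DataError(str(exc)) from exc
    return arms


def aggregate_table(ipd: pd.DataFrame, scale: RatingScale) -> pd.DataFrame:
    """Wide aggregate table with SDs in both denominator conventions."""
    arms = aggregate_ipd(ipd, scale)
    rows = []
    for a in arms:
        rows.append(
            {
                "study_id": a.study_id,
                "n_c": a.control.n,
                "mean_c": a.control.mean,
                "sd_c_unbiased": a.control.as_unbiased_sd(),
                "sd_c_population": a.control.as_population_sd(),
                "n_t": a.treatment.n,
                "mean_t": a.treatment.mean,
                "sd_t_unbiased": a.treatment.as_unbiased_sd(),
                "sd_t_population": a.treatment.as_population_sd(),
            }
        )
    return pd.DataFrame(rows)


# typing alias for the docstring above
StudyArmsList = list
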
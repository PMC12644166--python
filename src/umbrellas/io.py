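"""CSV interchange for multi-lab aggregate tables.

The canonical schema is one row per study with columns
``study_id, n_c, mean_c, sd_c, n_t, mean_t, sd_t`` (RFC-4180, UTF-8, '.'
decimal).  The scale and the SD-denominator convention are *not* stored in the
file; they must be declared when reading — the package refuses to guess
between the population and unbiased conventions.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .meta import StudyArms
from .scales import (
    RatingScale,
    SampleSummary,
    SDConvention,
    check_consistency,
)

__all__ = ["MultiLabTable", "ParseError", "read_multilab_csv", "write_multilab_csv"]

REQUIRED_COLUMNS = ["study_id", "n_c", "mean_c", "sd_c", "n_t", "mean_t", "sd_t"]


class ParseError(ValueError):
    """The CSV file does not conform to the multi-lab schema."""


@dataclass(frozen=True)
class MultiLabTable:
    """A validated multi-lab aggregate table bound to a scale and SD convention.

    ``flags`` holds per-row diagnostics for rows whose summaries fall outside
    the umbrella (flagged, never dropped).
    """

    frame: pd.DataFrame
    scale: RatingScale
    sd_convention: SDConvention
    flags: tuple[tuple[int, str], ...] = ()

    def to_study_arms(self) -> list[StudyArms]:
        arms = []
        for _, row in self.frame.iterrows():
            arms.append(
                StudyArms(
                    study_id=str(row["study_id"]),
                    control=SampleSummary(
                        mean=float(row["mean_c"]),
                        sd=float(row["sd_c"]),
                        n=int(row["n_c"]),
                        sd_convention=self.sd_convention,
                    ),
                    treatment=SampleSummary(
                        mean=float(row["mean_t"]),
                        sd=float(row["sd_t"]),
                        n=int(row["n_t"]),
                        sd_convention=self.sd_convention,
                    ),
                    scale=self.scale,
                )
            )
        return arms


def read_multilab_csv(
    path: str | Path,
    scale: RatingScale,
    sd_convention: SDConvention,
    reported_decimals: int = 6,
) -> MultiLabTable:
    """Read and validate a multi-lab aggregate CSV.

    Structural problems (missing columns, non-numeric cells, means outside the
    scale) raise :class:`ParseError` with the offending row number.
    Summaries that are merely inconsistent with the umbrella are flagged row by
    row via :func:`~umbrellas.scales.check_consistency`, not dropped.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    try:
        frame = pd.read_csv(path)
    except Exception as exc:
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    frame = frame[REQUIRED_COLUMNS].copy()

    for col in REQUIRED_COLUMNS[1:]:
        coerced = pd.to_numeric(frame[col], errors="coerce")
        bad = frame.index[coerced.isna()].tolist()
        if bad:
            raise ParseError(
                f"{path}: non-numeric value in column {col!r}, data row(s) "
                f"{[i + 2 for i in bad]}"  # +2: header line and 1-based
            )
        frame[col] = coerced

    flags: list[tuple[int, str]] = []
    for idx, row in frame.iterrows():
        rowno = int(idx) + 2
        for side in ("c", "t"):
            mean, sd, n = row[f"mean_{side}"], row[f"sd_{side}"], int(row[f"n_{side}"])
            if n < 2:
                raise ParseError(f"{path}: n_{side} < 2 in data row {rowno}")
            if sd < 0:
                raise ParseError(f"{path}: negative sd_{side} in data row {rowno}")
            if not scale.contains(mean):
                raise ParseError(
                    f"{path}: mean_{side}={mean} outside scale "
                    f"[{scale.x_min}, {scale.x_max}] in data row {rowno}"
                )
            verdict = check_consistency(
                mean,
                sd,
                n,
                scale,
                reported_decimals=reported_decimals,
                sd_convention=sd_convention,
            )
            if not verdict.overall:
                arm = "control" if side == "c" else "treatment"
                flags.append(
                    (rowno, f"{arm} arm inconsistent with the umbrella: "
                            + "; ".join(verdict.diagnostics))
                )
    return MultiLabTable(
        frame=frame, scale=scale, sd_convention=sd_convention, flags=tuple(flags)
    )


def write_multilab_csv(
    arms: Sequence[StudyArms],
    path: str | Path,
    sd_convention: SDConvention = "unbiased",
) -> None:
    """Write StudyArms to the canonical multi-lab CSV schema."""
    rows = []
    for a in arms:
        conv = lambda s: (
            s.as_unbiased_sd() if sd_convention == "unbiased" else s.as_population_sd()
        )
        rows.append(
            {
                "study_id": a.study_id,
                "n_c": a.control.n,
                "mean_c": a.control.mean,
                "sd_c": conv(a.control),
                "n_t": a.treatment.n,
                "mean_t": a.treatment.mean,
                "sd_t": conv(a.treatment),
            }
        )
    pd.DataFrame(rows, columns=REQUIRED_COLUMNS).to_csv(path, index=False)
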
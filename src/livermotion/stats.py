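"""Per-segment displacement statistics between imaging states.

Displacements are destination minus origin, per axis, under the package-wide
sign convention (positive = left / posterior / superior).  Cohort summaries
report the mean and sample SD (n-1 denominator) of the signed displacement
component over patients, per segment, axis and state pair, plus a pooled
overall row.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import AXES, SEGMENTS, Cohort, DisplacementVector, PointObservation

__all__ = [
    "StatePair",
    "AxisStats",
    "AmplitudeTable",
    "displacement",
    "cohort_displacements",
    "amplitude_stats",
    "amplitude_table",
    "round_half_away",
]

OVERALL = "ALL"


class StatePair(str, enum.Enum):
    """The three origin->destination imaging-state pairs of interest."""

    PHASE0_TO_PHASE50 = "PHASE0_TO_PHASE50"
    HELICAL_TO_PHASE0 = "HELICAL_TO_PHASE0"
    HELICAL_TO_PHASE50 = "HELICAL_TO_PHASE50"

    @property
    def origin(self) -> str:
        return "phase0" if self is StatePair.PHASE0_TO_PHASE50 else "helical"

    @property
    def destination(self) -> str:
        return "phase0" if self is StatePair.HELICAL_TO_PHASE0 else "phase50"


@dataclass(frozen=True)
class AxisStats:
    """Mean +/- sample SD (mm) of one signed displacement component."""

    segment: str  # a Couinaud label, or OVERALL for the pooled row
    axis: str
    pair: StatePair
    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        if self.n < 2:
            raise ValueError("cohort statistics need n >= 2")


@dataclass(frozen=True)
class AmplitudeTable:
    """Nine per-segment rows plus a pooled overall row, for one state pair."""

    pair: StatePair
    rows: dict[str, dict[str, AxisStats]]  # segment (or OVERALL) -> axis -> stats

    def __post_init__(self) -> None:
        expected = set(SEGMENTS) | {OVERALL}
        if set(self.rows) != expected:
            raise ValueError("amplitude table must have 9 segment rows + overall row")

    def to_frame(self, ndigits: int | None = None) -> pd.DataFrame:
        """Long-format DataFrame; optionally rounded for reporting."""
        records = []
        for seg in (*SEGMENTS, OVERALL):
            for axis in AXES:
                s = self.rows[seg][axis]
                mean, sd = s.mean, s.sd
                if ndigits is not None:
                    mean = round_half_away(mean, ndigits)
                    sd = round_half_away(sd, ndigits)
                records.append(
                    {
                        "segment": seg,
                        "axis": axis,
                        "pair": self.pair.value,
                        "mean_mm": mean,
                        "sd_mm": sd,
                        "n": s.n,
                    }
                )
        return pd.DataFrame.from_records(records)

    def to_text(self) -> str:
        """Aligned plain-text rendering (segment rows, LR/AP/SI columns)."""
        lines = [
            f"Signed displacement {self.pair.value} (mm), mean +/- SD",
            f"{'Segment':<8}{'LR':>14}{'AP':>14}{'SI':>14}",
        ]
        for seg in (*SEGMENTS, OVERALL):
            cells = []
            for axis in AXES:
                s = self.rows[seg][axis]
                cells.append(
                    f"{round_half_away(s.mean, 1):.1f} ± {round_half_away(s.sd, 1):.1f}"
                )
            label = "mean" if seg == OVERALL else seg
            lines.append(f"{label:<8}{cells[0]:>14}{cells[1]:>14}{cells[2]:>14}")
        lines.append(
            "Positive values denote excursion in the left, posterior, or "
            "superior directions; negative, right, anterior, or inferior."
        )
        return "\n".join(lines)


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (reporting convention, 0.1 mm)."""
    factor = 10.0**ndigits
    return float(np.sign(x) * np.floor(abs(x) * factor + 0.5) / factor)


def displacement(obs: PointObservation, pair: StatePair) -> DisplacementVector:
    """Signed displacement of one observation: destination minus origin."""
    pair = StatePair(pair)
    origin = getattr(obs, f"pos_{pair.origin}")
    dest = getattr(obs, f"pos_{pair.destination}")
    return DisplacementVector(*(dest - origin))


def cohort_displacements(cohort: Cohort, pair: StatePair) -> np.ndarray:
    """(n_patients, 9, 3) array of signed displacements for one state pair."""
    pair = StatePair(pair)
    return cohort.positions(pair.destination) - cohort.positions(pair.origin)


def amplitude_stats(
    cohort: Cohort, segment: str, axis: str, pair: StatePair
) -> AxisStats:
    """Mean and sample SD of one segment/axis displacement over the cohort."""
    if cohort.n < 2:
        raise ValueError("cohort statistics need at least 2 patients")
    if segment not in SEGMENTS:
        raise ValueError(f"unknown segment {segment!r}")
    if axis not in AXES:
        raise ValueError(f"unknown axis {axis!r}; expected one of {AXES}")
    pair = StatePair(pair)
    values = cohort_displacements(cohort, pair)[
        :, SEGMENTS.index(segment), AXES.index(axis)
    ]
    return AxisStats(
        segment=segment,
        axis=axis,
        pair=pair,
        mean=float(np.mean(values)),
        sd=float(np.std(values, ddof=1)),
        n=cohort.n,
    )


def amplitude_table(
    cohort: Cohort, pair: StatePair, overall: str = "pooled"
) -> AmplitudeTable:
    """Per-segment displacement summary plus an overall row.

    The overall row pools all 9 x n per-patient values per axis: its mean is
    the pooled mean (equal to the unweighted mean of segment means, since
    every segment has the same n) and, with ``overall="pooled"`` (default),
    its SD is the SD of the pooled values.  ``overall="mean_of_sds"``
    averages the nine segment SDs instead.
    """
    if overall not in ("pooled", "mean_of_sds"):
        raise ValueError(f"unknown overall-row rule {overall!r}")
    pair = StatePair(pair)
    disp = cohort_displacements(cohort, pair)  # (n, 9, 3)
    rows: dict[str, dict[str, AxisStats]] = {
        seg: {axis: amplitude_stats(cohort, seg, axis, pair) for axis in AXES}
        for seg in SEGMENTS
    }
    overall_row = {}
    for k, axis in enumerate(AXES):
        pooled = disp[:, :, k].ravel()
        if overall == "pooled":
            sd = float(np.std(pooled, ddof=1))
        else:
            sd = float(np.mean([rows[seg][axis].sd for seg in SEGMENTS]))
        overall_row[axis] = AxisStats(
            segment=OVERALL,
            axis=axis,
            pair=pair,
            mean=float(np.mean(pooled)),
            sd=sd,
            n=pooled.size,
        )
    rows[OVERALL] = overall_row
    return AmplitudeTable(pair=pair, rows=rows)
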
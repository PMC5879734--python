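"""Asymmetric ITV expansion margins from helical->4DCT displacement statistics.

For each segment and axis the margin derives from the two cohort summaries
of the signed displacement from the helical snapshot to each extreme 4DCT
phase.  Each summary yields a Student-t interval for the cohort mean,

    mean +/- t * sd / sqrt(n),

with t the two-sided 95% quantile at n-1 degrees of freedom (2.093 at
n = 20).  The margin is the envelope of the two intervals, clamped so it
always contains zero:

    neg = min(0, lo_phase0, lo_phase50)      (expansion right/anterior/inferior)
    pos = max(0, hi_phase0, hi_phase50)      (expansion left/posterior/superior)

so an ITV expansion never shrinks the delineated volume in either direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .cohort import AXES, SEGMENTS, Cohort
from .stats import OVERALL, AxisStats, StatePair, amplitude_stats, round_half_away

__all__ = [
    "MarginConfig",
    "Interval",
    "MarginPair",
    "MarginTable",
    "t_halfwidth",
    "phase_interval",
    "itv_margin",
    "margin_table",
    "margin_table_from_stats",
]


@dataclass(frozen=True)
class MarginConfig:
    """Cohort size and t multiplier of the margin formula.

    ``coverage_t`` defaults to the two-sided 95% Student-t quantile at n-1
    degrees of freedom; at the reference cohort size n = 20 the conventional
    printed value 2.093 is used verbatim.
    """

    n: int = 20
    coverage_t: float | None = None

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("margin derivation needs n >= 2")
        if self.coverage_t is None:
            t = 2.093 if self.n == 20 else float(_sps.t.ppf(0.975, self.n - 1))
            object.__setattr__(self, "coverage_t", t)
        if self.coverage_t <= 0:
            raise ValueError("coverage_t must be positive")


class Interval(NamedTuple):
    lo: float
    hi: float


@dataclass(frozen=True)
class MarginPair:
    """Asymmetric expansion for one segment/axis: neg <= 0 <= pos (mm)."""

    segment: str
    axis: str
    neg: float
    pos: float

    def __post_init__(self) -> None:
        if not (self.neg <= 0.0 <= self.pos):
            raise ValueError(
                f"margin must satisfy neg <= 0 <= pos, got ({self.neg}, {self.pos})"
            )

    def contains(self, x: float) -> bool:
        return self.neg <= x <= self.pos


def t_halfwidth(sd: float, cfg: MarginConfig) -> float:
    """Half-width of the t-interval for the cohort mean: t * sd / sqrt(n)."""
    if sd < 0:
        raise ValueError("sd must be >= 0")
    return cfg.coverage_t * sd / np.sqrt(cfg.n)


def phase_interval(stats: AxisStats, cfg: MarginConfig) -> Interval:
    """t-interval for the cohort-mean displacement of one helical->phase pair."""
    h = t_halfwidth(stats.sd, cfg)
    return Interval(stats.mean - h, stats.mean + h)


def itv_margin(stats_h0: AxisStats, stats_h50: AxisStats, cfg: MarginConfig) -> MarginPair:
    """Envelope of the two phase intervals, clamped to contain zero."""
    if (stats_h0.segment, stats_h0.axis) != (stats_h50.segment, stats_h50.axis):
        raise ValueError(
            "mismatched inputs: "
            f"({stats_h0.segment}, {stats_h0.axis}) vs "
            f"({stats_h50.segment}, {stats_h50.axis})"
        )
    i0 = phase_interval(stats_h0, cfg)
    i50 = phase_interval(stats_h50, cfg)
    return MarginPair(
        segment=stats_h0.segment,
        axis=stats_h0.axis,
        neg=min(0.0, i0.lo, i50.lo),
        pos=max(0.0, i0.hi, i50.hi),
    )


@dataclass
class MarginTable:
    """Complete 9-segment x 3-axis margin grid with its input statistics.

    The overall row averages the nine per-segment margins per axis and
    direction (not the formula applied to pooled statistics).
    """

    cfg: MarginConfig
    margins: dict[str, dict[str, MarginPair]]  # segment -> axis -> margin
    stats_h0: dict[str, dict[str, AxisStats]] = field(default_factory=dict)
    stats_h50: dict[str, dict[str, AxisStats]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.margins) != set(SEGMENTS) or any(
            set(row) != set(AXES) for row in self.margins.values()
        ):
            raise ValueError("margin table must cover all 9 segments x 3 axes")

    def overall(self) -> dict[str, tuple[float, float]]:
        """Mean of the nine per-segment (neg, pos) margins, per axis."""
        out = {}
        for axis in AXES:
            negs = [self.margins[s][axis].neg for s in SEGMENTS]
            poss = [self.margins[s][axis].pos for s in SEGMENTS]
            out[axis] = (float(np.mean(negs)), float(np.mean(poss)))
        return out

    def to_frame(self, ndigits: int | None = None) -> pd.DataFrame:
        records = []
        for seg in SEGMENTS:
            for axis in AXES:
                m = self.margins[seg][axis]
                rec = {"segment": seg, "axis": axis, "neg_mm": m.neg, "pos_mm": m.pos}
                if self.stats_h0 and self.stats_h50:
                    s0 = self.stats_h0[seg][axis]
                    s50 = self.stats_h50[seg][axis]
                    rec.update(
                        h0_mean_mm=s0.mean,
                        h0_sd_mm=s0.sd,
                        h50_mean_mm=s50.mean,
                        h50_sd_mm=s50.sd,
                    )
                records.append(rec)
        for axis, (neg, pos) in self.overall().items():
            records.append(
                {"segment": OVERALL, "axis": axis, "neg_mm": neg, "pos_mm": pos}
            )
        df = pd.DataFrame.from_records(records)
        if ndigits is not None:
            for col in df.columns:
                if col.endswith("_mm"):
                    df[col] = df[col].map(
                        lambda x: round_half_away(x, ndigits) if pd.notna(x) else x
                    )
        return df

    def to_text(self, directional: bool = False) -> str:
        """Aligned text report; ``directional`` labels magnitudes by direction."""
        neg_dir = {"lr": "right", "ap": "anterior", "si": "inferior"}
        pos_dir = {"lr": "left", "ap": "posterior", "si": "superior"}
        lines = [
            f"Asymmetric ITV expansion margins (mm), t = {self.cfg.coverage_t:g}, "
            f"n = {self.cfg.n}",
            f"{'Segment':<8}{'LR':>22}{'AP':>22}{'SI':>22}",
        ]
        rows = [(seg, self.margins[seg]) for seg in SEGMENTS]
        overall = self.overall()
        rows.append(
            (
                "mean",
                {
                    a: MarginPair(segment=SEGMENTS[0], axis=a, neg=v[0], pos=v[1])
                    for a, v in overall.items()
                },
            )
        )
        for label, row in rows:
            cells = []
            for axis in AXES:
                m = row[axis]
                neg = round_half_away(m.neg, 1)
                pos = round_half_away(m.pos, 1)
                if directional:
                    cells.append(
                        f"{abs(neg):.1f} {neg_dir[axis]}/{pos:.1f} {pos_dir[axis]}"
                    )
                else:
                    cells.append(f"{neg:.1f} and {pos:.1f}")
            lines.append(f"{label:<8}{cells[0]:>22}{cells[1]:>22}{cells[2]:>22}")
        lines.append(
            "Positive values denote ITV expansion in the left, posterior, or "
            "superior directions; negative, right, anterior, or inferior."
        )
        return "\n".join(lines)


def margin_table(cohort: Cohort, cfg: MarginConfig | None = None) -> MarginTable:
    """Derive the full margin table from a cohort's helical->phase statistics."""
    if cfg is None:
        cfg = MarginConfig(n=cohort.n)
    elif cfg.n != cohort.n:
        raise ValueError(f"config n={cfg.n} does not match cohort size {cohort.n}")
    stats_h0 = {
        seg: {
            axis: amplitude_stats(cohort, seg, axis, StatePair.HELICAL_TO_PHASE0)
            for axis in AXES
        }
        for seg in SEGMENTS
    }
    stats_h50 = {
        seg: {
            axis: amplitude_stats(cohort, seg, axis, StatePair.HELICAL_TO_PHASE50)
            for axis in AXES
        }
        for seg in SEGMENTS
    }
    return margin_table_from_stats(stats_h0, stats_h50, cfg)


def margin_table_from_stats(
    stats_h0: dict[str, dict[str, AxisStats]],
    stats_h50: dict[str, dict[str, AxisStats]],
    cfg: MarginConfig,
) -> MarginTable:
    """Margin table from pre-computed helical->phase statistics.

    Accepts either ``AxisStats`` values or plain ``(mean, sd)`` pairs, so
    published summary tables can be fed in directly.
    """

    def as_stats(v, seg, axis, pair):
        if isinstance(v, AxisStats):
            return v
        mean, sd = v
        return AxisStats(segment=seg, axis=axis, pair=pair, mean=mean, sd=sd, n=cfg.n)

    margins = {
        seg: {
            axis: itv_margin(
                as_stats(stats_h0[seg][axis], seg, axis, StatePair.HELICAL_TO_PHASE0),
                as_stats(stats_h50[seg][axis], seg, axis, StatePair.HELICAL_TO_PHASE50),
                cfg,
            )
            for axis in AXES
        }
        for seg in SEGMENTS
    }
    norm_h0 = {
        seg: {
            axis: as_stats(stats_h0[seg][axis], seg, axis, StatePair.HELICAL_TO_PHASE0)
            for axis in AXES
        }
        for seg in SEGMENTS
    }
    norm_h50 = {
        seg: {
            axis: as_stats(stats_h50[seg][axis], seg, axis, StatePair.HELICAL_TO_PHASE50)
            for axis in AXES
        }
        for seg in SEGMENTS
    }
    return MarginTable(cfg=cfg, margins=margins, stats_h0=norm_h0, stats_h50=norm_h50)
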
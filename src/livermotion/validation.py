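"""Verification machinery: overlap index, lung-volume bracketing, coverage.

Three independent checks support the margin derivation:

* the volume overlap index (VOI), a Dice-type agreement score between a
  deformed and a reference contour volume;
* the lung-volume bracket — with free breathing, the helical-snapshot lung
  volume should lie between the end-expiration and end-inspiration volumes;
* a Monte-Carlo coverage simulation asking how often margins derived from a
  finite cohort actually contain the model's true mean displacements.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cohort import AXES, SEGMENTS, Cohort, LungVolumes, SimulationParams, generate_cohort
from .margin import MarginConfig, MarginPair, margin_table, phase_interval
from .stats import StatePair, amplitude_stats, cohort_displacements

__all__ = [
    "VolumeTriple",
    "CoverageResult",
    "voi",
    "lung_bracket_check",
    "coverage_simulation",
]

_HELICAL_PAIRS = (StatePair.HELICAL_TO_PHASE0, StatePair.HELICAL_TO_PHASE50)


@dataclass(frozen=True)
class VolumeTriple:
    """Deformed volume, reference volume and their intersection (ml)."""

    v_a: float
    v_b: float
    v_intersection: float

    def __post_init__(self) -> None:
        if self.v_a <= 0 or self.v_b <= 0:
            raise ValueError("volumes must be positive")
        if not 0.0 <= self.v_intersection <= min(self.v_a, self.v_b):
            raise ValueError(
                "intersection must satisfy 0 <= v_intersection <= min(v_a, v_b)"
            )


def voi(vols: VolumeTriple) -> float:
    """Volume overlap index: 2 * intersection / (v_a + v_b), in [0, 1].

    0 means no spatial overlap; 1 means perfect agreement (identical, fully
    overlapping volumes).
    """
    return 2.0 * vols.v_intersection / (vols.v_a + vols.v_b)


def lung_bracket_check(lv: LungVolumes) -> dict[str, bool]:
    """Check phase50 <= helical <= phase0 (inclusive) per lung and in total.

    End-inspiration (phase 0) holds the largest lung volume and
    end-expiration (phase 50) the smallest; a free-breathing helical
    snapshot should fall in between.
    """
    out = {}
    for part in ("left", "right", "total"):
        h = getattr(lv.helical, part)
        p0 = getattr(lv.phase0, part)
        p50 = getattr(lv.phase50, part)
        out[part] = bool(p50 <= h <= p0)
    return out


@dataclass
class CoverageResult:
    """Outcome of the Monte-Carlo margin-coverage simulation.

    ``coverage_pct`` is the percentage of (replicate x segment x axis) cells
    whose derived margin contains the model's true mean helical->phase
    displacement for every state pair examined.  ``per_tumor_pct`` applies
    the same margins to individual simulated displacements instead of the
    cohort mean (the stricter, per-lesion reading of coverage).
    """

    coverage_pct: float
    n_reps: int
    n_patients: int
    seed: int | None
    per_axis: dict[str, float] = field(default_factory=dict)
    per_cell: dict[tuple[str, str], float] = field(default_factory=dict)
    per_tumor_pct: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.coverage_pct <= 100.0:
            raise ValueError("coverage_pct must lie in [0, 100]")

    def min_cell(self) -> tuple[tuple[str, str], float]:
        key = min(self.per_cell, key=self.per_cell.get)
        return key, self.per_cell[key]


def coverage_simulation(
    params: SimulationParams,
    cfg: MarginConfig | None = None,
    n_patients: int = 20,
    n_reps: int = 1000,
    seed: int | None = None,
    margin_override: float | None = None,
    clamp: bool = True,
    pairs: tuple[StatePair, ...] = _HELICAL_PAIRS,
) -> CoverageResult:
    """Monte-Carlo coverage of the margin formula.

    For each replicate a fresh cohort of ``n_patients`` is generated, the
    margin table derived, and each segment/axis cell scored a success if the
    model's true mean displacement for every requested state pair lies
    inside the derived [neg, pos] interval.

    ``margin_override`` replaces every derived margin by the fixed interval
    [-override, +override] (a sensitivity handle).  ``clamp=False`` drops
    the clamp-to-zero step, and a single entry in ``pairs`` reduces the
    margin to that pair's plain t-interval — together these recover the
    textbook t-interval whose coverage of a normal mean is exactly the
    nominal 95%.
    """
    params.validate()
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if cfg is None:
        cfg = MarginConfig(n=n_patients)
    pairs = tuple(StatePair(p) for p in pairs)
    if not pairs or any(p not in _HELICAL_PAIRS for p in pairs):
        raise ValueError("pairs must be a non-empty subset of the helical->phase pairs")

    truth = params.true_mean_displacements()
    true_means = np.stack([truth[p.value] for p in pairs])  # (n_pairs, 9, 3)

    rng = np.random.default_rng(seed)
    success = np.zeros((n_reps, len(SEGMENTS), len(AXES)), dtype=bool)
    tumor_hits = 0
    tumor_total = 0
    for r in range(n_reps):
        cohort = generate_cohort(params, n_patients, seed=rng)
        neg, pos = _derive_margins(cohort, cfg, pairs, clamp)
        if margin_override is not None:
            neg = np.full_like(neg, -abs(margin_override))
            pos = np.full_like(pos, abs(margin_override))
        # containment with a 1e-9 mm tolerance: degenerate zero-variance
        # margins are point intervals and must not fail on rounding noise
        atol = 1e-9
        success[r] = np.all(
            (true_means >= neg - atol) & (true_means <= pos + atol), axis=0
        )
        # per-lesion reading: individual displacements of this cohort
        disp = np.stack([cohort_displacements(cohort, p) for p in pairs])
        inside = np.all((disp >= neg - atol) & (disp <= pos + atol), axis=0)
        tumor_hits += int(inside.sum())
        tumor_total += inside.size

    per_cell = {
        (seg, axis): float(100.0 * success[:, i, k].mean())
        for i, seg in enumerate(SEGMENTS)
        for k, axis in enumerate(AXES)
    }
    per_axis = {
        axis: float(100.0 * success[:, :, k].mean()) for k, axis in enumerate(AXES)
    }
    return CoverageResult(
        coverage_pct=float(100.0 * success.mean()),
        n_reps=n_reps,
        n_patients=n_patients,
        seed=seed,
        per_axis=per_axis,
        per_cell=per_cell,
        per_tumor_pct=float(100.0 * tumor_hits / tumor_total),
    )


def _derive_margins(
    cohort: Cohort,
    cfg: MarginConfig,
    pairs: tuple[StatePair, ...],
    clamp: bool,
) -> tuple[np.ndarray, np.ndarray]:
    """(9, 3) lower/upper margin bounds for one cohort."""
    if clamp and set(pairs) == set(_HELICAL_PAIRS):
        mt = margin_table(cohort, cfg)
        neg = np.array(
            [[mt.margins[s][a].neg for a in AXES] for s in SEGMENTS]
        )
        pos = np.array(
            [[mt.margins[s][a].pos for a in AXES] for s in SEGMENTS]
        )
        return neg, pos
    los = np.full((len(SEGMENTS), len(AXES)), np.inf)
    his = np.full((len(SEGMENTS), len(AXES)), -np.inf)
    for pair in pairs:
        for i, seg in enumerate(SEGMENTS):
            for k, axis in enumerate(AXES):
                iv = phase_interval(amplitude_stats(cohort, seg, axis, pair), cfg)
                los[i, k] = min(los[i, k], iv.lo)
                his[i, k] = max(his[i, k], iv.hi)
    if clamp:
        los = np.minimum(los, 0.0)
        his = np.maximum(his, 0.0)
    return los, his
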
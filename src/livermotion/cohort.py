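"""Synthetic cohort model for respiration-induced liver segment motion.

The liver is described by nine representative points, one per Couinaud
segment (1, 2, 3, 4a, 4b, 5, 6, 7, 8).  Each point is observed in three
imaging states:

* ``helical`` — a conventional helical CT snapshot taken at an uncontrolled,
  effectively random moment of the breathing cycle;
* ``phase0`` — the end-inspiration bin of a 10-phase-gated 4DCT;
* ``phase50`` — the end-expiration bin.

The generative model draws, per patient, segment and axis, a total
expiration displacement ``d ~ Normal(mu, sd)`` (phase 0 -> phase 50) and a
single per-patient helical sampling fraction ``u`` in [0, 1] locating the
helical snapshot along that excursion::

    pos_phase0  = reference position
    pos_phase50 = pos_phase0 + d
    pos_helical = pos_phase0 + u * d

``u`` follows a truncated normal on [0, 1]; one helical scan is taken per
patient, so ``u`` is shared by all nine segments.  Axes and segments are
drawn independently by default (no covariance structure is imposed); an
optional per-patient shared scaling factor can model breathing-depth
correlation between segments.

A simplified quasi-periodic breathing surrogate (one amplitude sample per
time step, with cycle-to-cycle amplitude and period jitter) stands in for an
external-marker respiratory trace, and a maximum-phase-error statistic
quantifies cycle-to-cycle variability at a gated phase.

Sign convention throughout: axis order (lr, ap, si) with positive =
left / posterior / superior.  All distances in mm, times in s.
"""

from __future__ import annotations

import copy
import dataclasses
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy import stats as _sps

from .reference import (
    AXES,
    EXPIRATION_AMPLITUDE_MM,
    LUNG_VOLUME_MEAN_ML,
    SEGMENTS,
)

__all__ = [
    "SEGMENTS",
    "AXES",
    "STATES",
    "SEGMENT_REFERENCE_POSITION_MM",
    "DisplacementVector",
    "PointObservation",
    "StateVolumes",
    "LungVolumes",
    "BreathingTrace",
    "SimulationParams",
    "Patient",
    "Cohort",
    "validate_segment",
    "generate_cohort",
    "simulate_breathing_trace",
    "compute_max_phase_error",
]

STATES: tuple[str, ...] = ("helical", "phase0", "phase50")

# Fixed reference layout of the nine representative points (lr, ap, si) in
# mm, loosely following the Couinaud arrangement: the portal plane separates
# upper segments (2, 4a, 7, 8) from lower ones (3, 4b, 5, 6); lateral-left
# segments (2, 3) sit at positive lr, right-lobe segments at negative lr;
# the caudate (1) is central and posterior.  Only displacements enter any
# statistic, so the exact coordinates are immaterial.
SEGMENT_REFERENCE_POSITION_MM: dict[str, tuple[float, float, float]] = {
    "S1": (0.0, 30.0, 20.0),
    "S2": (45.0, 10.0, 40.0),
    "S3": (50.0, -10.0, 0.0),
    "S4a": (20.0, -5.0, 40.0),
    "S4b": (25.0, -20.0, 0.0),
    "S5": (-30.0, -25.0, 0.0),
    "S6": (-60.0, 10.0, -10.0),
    "S7": (-65.0, 20.0, 40.0),
    "S8": (-35.0, -15.0, 45.0),
}


def validate_segment(segment: str) -> str:
    """Return *segment* if it is one of the nine admissible Couinaud labels."""
    if segment not in SEGMENTS:
        raise ValueError(
            f"unknown liver segment {segment!r}; expected one of {SEGMENTS}"
        )
    return segment


class DisplacementVector(NamedTuple):
    """Signed displacement (mm): positive = left / posterior / superior."""

    lr: float
    ap: float
    si: float

    def as_array(self) -> np.ndarray:
        return np.array(self, dtype=float)


def _as_point(value) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if arr.shape != (3,):
        raise ValueError(f"a 3D point needs exactly 3 coordinates, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"non-finite coordinates: {arr}")
    return arr


@dataclass
class PointObservation:
    """One segment's representative point observed in all three imaging states."""

    patient_id: str
    segment: str
    pos_helical: np.ndarray
    pos_phase0: np.ndarray
    pos_phase50: np.ndarray

    def __post_init__(self) -> None:
        validate_segment(self.segment)
        self.pos_helical = _as_point(self.pos_helical)
        self.pos_phase0 = _as_point(self.pos_phase0)
        self.pos_phase50 = _as_point(self.pos_phase50)


class StateVolumes(NamedTuple):
    """Left, right and total lung volume (ml) in one imaging state."""

    left: float
    right: float
    total: float


@dataclass
class LungVolumes:
    """Per-state lung volumes; total must equal left + right within 1 ml."""

    helical: StateVolumes
    phase0: StateVolumes
    phase50: StateVolumes

    def __post_init__(self) -> None:
        for state in STATES:
            sv = StateVolumes(*getattr(self, state))
            setattr(self, state, sv)
            if not (sv.left > 0 and sv.right > 0 and sv.total > 0):
                raise ValueError(f"lung volumes must be positive in state {state}: {sv}")
            if abs(sv.total - (sv.left + sv.right)) > 1.0:
                raise ValueError(
                    f"total lung volume inconsistent in state {state}: "
                    f"{sv.total} vs {sv.left} + {sv.right}"
                )


@dataclass
class BreathingTrace:
    """A respiratory surrogate trace with uniform sampling.

    ``cycle_bounds`` holds k+1 sample indices delimiting k complete breathing
    cycles; cycle c spans samples ``[cycle_bounds[c], cycle_bounds[c+1])``.
    Phase 0 of the gating grid coincides with the cycle start.
    """

    samples: np.ndarray
    dt: float
    cycle_bounds: np.ndarray
    n_phases: int = 10

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        self.cycle_bounds = np.asarray(self.cycle_bounds, dtype=int)
        if self.dt <= 0:
            raise ValueError("sampling interval must be positive")
        if self.n_phases < 1:
            raise ValueError("need at least one gating phase")
        if self.cycle_bounds.ndim != 1 or len(self.cycle_bounds) < 2:
            raise ValueError("cycle_bounds must delimit at least one complete cycle")
        if np.any(np.diff(self.cycle_bounds) <= 0):
            raise ValueError("cycle_bounds must be strictly increasing")
        if self.cycle_bounds[-1] > len(self.samples):
            raise ValueError("cycle_bounds exceed the trace length")

    @property
    def n_cycles(self) -> int:
        return len(self.cycle_bounds) - 1

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.samples)) * self.dt


@dataclass
class SimulationParams:
    """Distributional parameters of the synthetic cohort.

    ``amplitude_mm`` maps segment -> axis -> (mu, sd) of the total
    phase 0 -> phase 50 displacement; the default reproduces the reference
    study's per-segment expiration amplitudes.  The helical sampling
    fraction u is truncated-normal on [0, 1] with the given mean/sd; the
    default mean 0.42 places the helical snapshot slightly inspiration-side
    of mid-excursion, consistent with the reference study's split of total
    amplitudes into helical->phase0 and helical->phase50 components.
    """

    amplitude_mm: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=lambda: copy.deepcopy(EXPIRATION_AMPLITUDE_MM)
    )
    helical_fraction_mean: float = 0.42
    helical_fraction_sd: float = 0.15
    # optional per-patient multiplicative breathing-depth factor (off by default)
    shared_scaling: bool = False
    shared_scaling_sd: float = 0.2
    # breathing-trace parameters
    trace_period_s: float = 4.0
    trace_amplitude_au: float = 10.0
    trace_amplitude_jitter: float = 0.1
    trace_period_jitter: float = 0.05
    trace_n_cycles: int = 20
    trace_dt_s: float = 0.05
    n_phases: int = 10
    # lung-volume model: per-patient size factor ~ TruncNormal(1, lung_scale_sd)
    lung_mean_ml: dict[str, dict[str, float]] = field(
        default_factory=lambda: copy.deepcopy(LUNG_VOLUME_MEAN_ML)
    )
    lung_scale_sd: float = 0.15
    seed: int | None = None

    def validate(self) -> "SimulationParams":
        for seg in SEGMENTS:
            if seg not in self.amplitude_mm:
                raise ValueError(f"amplitude_mm is missing segment {seg}")
            for axis in AXES:
                mu, sd = self.amplitude_mm[seg][axis]
                if not (np.isfinite(mu) and np.isfinite(sd)):
                    raise ValueError(f"non-finite amplitude parameters for {seg}/{axis}")
                if sd < 0:
                    raise ValueError(f"sd must be >= 0 for {seg}/{axis}, got {sd}")
        if not 0.0 <= self.helical_fraction_mean <= 1.0:
            raise ValueError("helical_fraction_mean must lie in [0, 1]")
        if self.helical_fraction_sd < 0:
            raise ValueError("helical_fraction_sd must be >= 0")
        if self.trace_period_s <= 0 or self.trace_amplitude_au <= 0:
            raise ValueError("trace period and amplitude must be positive")
        if self.trace_amplitude_jitter < 0 or self.trace_period_jitter < 0:
            raise ValueError("jitter fractions must be >= 0")
        if self.trace_n_cycles < 3:
            raise ValueError("at least 3 breathing cycles are required")
        if self.trace_dt_s <= 0:
            raise ValueError("trace sampling interval must be positive")
        if self.lung_scale_sd < 0:
            raise ValueError("lung_scale_sd must be >= 0")
        return self

    # -- derived quantities -------------------------------------------------

    def mu_sd_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """(9, 3) arrays of mu and sd in canonical segment/axis order."""
        mu = np.array(
            [[self.amplitude_mm[s][a][0] for a in AXES] for s in SEGMENTS]
        )
        sd = np.array(
            [[self.amplitude_mm[s][a][1] for a in AXES] for s in SEGMENTS]
        )
        return mu, sd

    def expected_helical_fraction(self) -> float:
        """Exact mean of the truncated-normal helical sampling fraction."""
        if self.helical_fraction_sd == 0:
            return float(np.clip(self.helical_fraction_mean, 0.0, 1.0))
        a = (0.0 - self.helical_fraction_mean) / self.helical_fraction_sd
        b = (1.0 - self.helical_fraction_mean) / self.helical_fraction_sd
        return float(
            _sps.truncnorm.mean(
                a, b, loc=self.helical_fraction_mean, scale=self.helical_fraction_sd
            )
        )

    def true_mean_displacements(self) -> dict[str, np.ndarray]:
        """Model-implied mean displacement (9, 3) for each state pair.

        With u independent of d: E[phase0->phase50] = mu,
        E[helical->phase0] = -E[u] mu, E[helical->phase50] = (1-E[u]) mu.
        The optional shared scaling factor has unit mean and leaves these
        unchanged.
        """
        mu, _ = self.mu_sd_arrays()
        ubar = self.expected_helical_fraction()
        return {
            "PHASE0_TO_PHASE50": mu,
            "HELICAL_TO_PHASE0": -ubar * mu,
            "HELICAL_TO_PHASE50": (1.0 - ubar) * mu,
        }

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationParams":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown simulation parameters: {sorted(unknown)}")
        params = cls(**d)
        # YAML/JSON round-trips turn tuples into lists; normalise back
        params.amplitude_mm = {
            seg: {axis: tuple(v) for axis, v in axes.items()}
            for seg, axes in params.amplitude_mm.items()
        }
        return params.validate()


@dataclass
class Patient:
    """One patient: nine point observations, lung volumes, optional trace."""

    patient_id: str
    points: dict[str, PointObservation]
    lung_volumes: LungVolumes
    trace: BreathingTrace | None = None
    helical_fraction: float | None = None

    def __post_init__(self) -> None:
        if sorted(self.points) != sorted(SEGMENTS):
            missing = sorted(set(SEGMENTS) - set(self.points))
            extra = sorted(set(self.points) - set(SEGMENTS))
            raise ValueError(
                f"patient {self.patient_id!r} must have exactly one point per "
                f"segment; missing {missing}, unexpected {extra}"
            )


@dataclass
class Cohort:
    """A collection of patients, each with all nine segment points."""

    patients: list[Patient]
    _pos_cache: dict = field(default_factory=dict, init=False, repr=False, compare=False)

    @property
    def n(self) -> int:
        return len(self.patients)

    def positions(self, state: str) -> np.ndarray:
        """(n_patients, 9, 3) array of point positions in one imaging state.

        Cached after the first call; cohorts are treated as immutable once
        built.
        """
        if state not in STATES:
            raise ValueError(f"unknown imaging state {state!r}; expected one of {STATES}")
        if state not in self._pos_cache:
            attr = f"pos_{state}"
            self._pos_cache[state] = np.array(
                [
                    [getattr(p.points[seg], attr) for seg in SEGMENTS]
                    for p in self.patients
                ],
                dtype=float,
            ).reshape(self.n, len(SEGMENTS), 3)
        return self._pos_cache[state]


# ---------------------------------------------------------------------------
# generation


def _rng(seed: int | np.random.Generator | None) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _draw_truncnorm(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float, size=None
) -> np.ndarray:
    """Truncated-normal draws via the inverse CDF (vectorised, reproducible)."""
    if sd == 0:
        val = np.clip(mean, lo, hi)
        return np.full(size, val) if size is not None else np.asarray(val)
    a, b = (lo - mean) / sd, (hi - mean) / sd
    q = rng.uniform(size=size)
    return _sps.truncnorm.ppf(q, a, b, loc=mean, scale=sd)


def generate_cohort(
    params: SimulationParams,
    n_patients: int,
    seed: int | np.random.Generator | None = None,
    with_traces: bool = False,
) -> Cohort:
    """Generate a synthetic cohort of *n_patients* patients.

    Per patient: one helical fraction u ~ TruncNormal on [0, 1]; per
    segment/axis a total displacement d ~ Normal(mu, sd); positions follow
    the three-state model (phase0 at the reference layout, phase50 offset by
    d, helical offset by u*d).  Lung volumes scale with a per-patient size
    factor, and the helical-state volume is interpolated between the phase
    volumes at the same fraction u, so the physiological bracketing
    phase50 <= helical <= phase0 holds by construction.

    Deterministic for a fixed integer seed.
    """
    params.validate()
    if n_patients < 0:
        raise ValueError(f"n_patients must be >= 0, got {n_patients}")
    rng = _rng(seed if seed is not None else params.seed)
    mu, sd = params.mu_sd_arrays()
    ref = np.array([SEGMENT_REFERENCE_POSITION_MM[s] for s in SEGMENTS])

    # all stochastic draws up front, in a fixed order, for reproducibility
    n = n_patients
    u_all = np.atleast_1d(
        _draw_truncnorm(
            rng,
            params.helical_fraction_mean,
            params.helical_fraction_sd,
            0.0,
            1.0,
            size=n,
        )
    )
    d_all = rng.normal(mu, sd, size=(n, len(SEGMENTS), len(AXES)))
    if params.shared_scaling and params.shared_scaling_sd > 0:
        d_all = d_all * np.atleast_1d(
            _draw_truncnorm(rng, 1.0, params.shared_scaling_sd, 0.05, np.inf, size=n)
        ).reshape(n, 1, 1)
    size_all = np.atleast_1d(
        _draw_truncnorm(rng, 1.0, params.lung_scale_sd, 0.3, np.inf, size=n)
    )
    side_jitter_all = 1.0 + rng.normal(0.0, 0.02, size=(n, 2))

    patients: list[Patient] = []
    for i in range(n_patients):
        pid = f"P{i + 1:03d}"
        u = float(u_all[i])
        d = d_all[i]
        pos0 = ref
        pos50 = ref + d
        posh = ref + u * d

        points = {
            seg: PointObservation(
                patient_id=pid,
                segment=seg,
                pos_helical=posh[j],
                pos_phase0=pos0[j],
                pos_phase50=pos50[j],
            )
            for j, seg in enumerate(SEGMENTS)
        }

        size = float(size_all[i])
        side_jitter = {
            "left": float(side_jitter_all[i, 0]),
            "right": float(side_jitter_all[i, 1]),
        }
        state_vols = {}
        p0 = {
            side: params.lung_mean_ml["phase0"][side] * size * side_jitter[side]
            for side in ("left", "right")
        }
        p50 = {
            side: params.lung_mean_ml["phase50"][side] * size * side_jitter[side]
            for side in ("left", "right")
        }
        hel = {side: p0[side] + u * (p50[side] - p0[side]) for side in ("left", "right")}
        for state, vols in (("helical", hel), ("phase0", p0), ("phase50", p50)):
            state_vols[state] = StateVolumes(
                vols["left"], vols["right"], vols["left"] + vols["right"]
            )
        lungs = LungVolumes(**state_vols)

        trace = None
        if with_traces:
            trace = simulate_breathing_trace(params, seed=rng)

        patients.append(
            Patient(
                patient_id=pid,
                points=points,
                lung_volumes=lungs,
                trace=trace,
                helical_fraction=u,
            )
        )
    return Cohort(patients=patients)


def simulate_breathing_trace(
    params: SimulationParams, seed: int | np.random.Generator | None = None
) -> BreathingTrace:
    """Simulate a quasi-periodic respiratory surrogate trace.

    Each cycle c has amplitude ``A_c = A (1 + ja z_c)`` and period
    ``T_c = T (1 + jp w_c)`` with independent standard-normal z, w truncated
    so both stay positive; within a cycle the surrogate follows a raised
    cosine ``A_c (1 + cos(2 pi t/T_c)) / 2``, peaking at the cycle start
    (end-inspiration, gating phase 0).
    """
    params.validate()
    rng = _rng(seed if seed is not None else params.seed)
    n_cycles = params.trace_n_cycles
    amps = _draw_truncnorm(
        rng,
        1.0,
        params.trace_amplitude_jitter,
        0.05,
        np.inf,
        size=n_cycles,
    ) * params.trace_amplitude_au if params.trace_amplitude_jitter > 0 else np.full(
        n_cycles, params.trace_amplitude_au
    )
    periods = _draw_truncnorm(
        rng,
        1.0,
        params.trace_period_jitter,
        0.1,
        np.inf,
        size=n_cycles,
    ) * params.trace_period_s if params.trace_period_jitter > 0 else np.full(
        n_cycles, params.trace_period_s
    )

    dt = params.trace_dt_s
    segments = []
    bounds = [0]
    for A, T in zip(amps, periods):
        n_samp = max(2, int(round(T / dt)))
        tau = np.arange(n_samp) * dt / T
        segments.append(A * 0.5 * (1.0 + np.cos(2.0 * np.pi * tau)))
        bounds.append(bounds[-1] + n_samp)
    samples = np.concatenate(segments)
    return BreathingTrace(
        samples=samples,
        dt=dt,
        cycle_bounds=np.array(bounds),
        n_phases=params.n_phases,
    )


def compute_max_phase_error(trace: BreathingTrace, phase_index: int) -> float:
    """Maximum phase error (%) of the surrogate at one gated phase.

    The surrogate amplitude at phase p of cycle c is the trace value at time
    ``start_c + (p / n_phases) * T_c`` (linearly interpolated).  The error is
    the range of these values over cycles, as a percentage of the mean
    peak-to-peak cycle amplitude.  Invariant to rescaling the whole trace by
    a positive constant; 0 for perfectly repeating cycles.
    """
    if trace.n_cycles < 2:
        raise ValueError("phase error needs at least 2 complete breathing cycles")
    if not 0 <= phase_index < trace.n_phases:
        raise ValueError(
            f"phase_index must lie in [0, {trace.n_phases}), got {phase_index}"
        )
    times = trace.times
    phase_vals = []
    p2p = []
    for c in range(trace.n_cycles):
        i0, i1 = trace.cycle_bounds[c], trace.cycle_bounds[c + 1]
        t0 = times[i0]
        period = (i1 - i0) * trace.dt
        t_phase = t0 + (phase_index / trace.n_phases) * period
        cyc_t = times[i0:i1]
        cyc_v = trace.samples[i0:i1]
        phase_vals.append(float(np.interp(t_phase, cyc_t, cyc_v)))
        p2p.append(float(cyc_v.max() - cyc_v.min()))
    mean_p2p = float(np.mean(p2p))
    if mean_p2p <= 0:
        raise ValueError("degenerate trace: zero peak-to-peak amplitude")
    return 100.0 * (max(phase_vals) - min(phase_vals)) / mean_p2p
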
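"""Synthetic cohort generator, breathing trace and phase-error statistic."""

import numpy as np
import pytest

from livermotion import (
    AXES,
    SEGMENTS,
    BreathingTrace,
    SimulationParams,
    compute_max_phase_error,
    generate_cohort,
    lung_bracket_check,
    simulate_breathing_trace,
)


def degenerate_params(u: float = 0.5) -> SimulationParams:
    """All displacement SDs zero and the helical fraction pinned at *u*."""
    p = SimulationParams(helical_fraction_mean=u, helical_fraction_sd=0.0)
    p.amplitude_mm = {
        seg: {axis: (mu, 0.0) for axis, (mu, _) in axes.items()}
        for seg, axes in p.amplitude_mm.items()
    }
    return p


class TestGenerateCohort:
    def test_empty_cohort(self, default_params):
        cohort = generate_cohort(default_params, 0, seed=0)
        assert cohort.n == 0
        assert cohort.patients == []

    def test_negative_n_rejected(self, default_params):
        with pytest.raises(ValueError, match="n_patients"):
            generate_cohort(default_params, -1, seed=0)

    def test_invalid_params_rejected(self):
        p = SimulationParams()
        p.amplitude_mm["S1"]["si"] = (5.5, -1.0)
        with pytest.raises(ValueError, match="sd"):
            generate_cohort(p, 2, seed=0)

    def test_degenerate_variance_reproduces_means_exactly(self):
        """sd=0 and u=0.5: total displacement equals mu, helical half of it."""
        p = degenerate_params(u=0.5)
        cohort = generate_cohort(p, 3, seed=0)
        for patient in cohort.patients:
            for seg in SEGMENTS:
                obs = patient.points[seg]
                total = obs.pos_phase50 - obs.pos_phase0
                half = obs.pos_helical - obs.pos_phase0
                mu = np.array([p.amplitude_mm[seg][a][0] for a in AXES])
                np.testing.assert_allclose(total, mu, rtol=0, atol=1e-12)
                np.testing.assert_allclose(half, 0.5 * mu, rtol=0, atol=1e-12)

    def test_displacement_vector_identity(self, small_cohort):
        """helical->phase50 plus phase0->helical equals phase0->phase50."""
        for patient in small_cohort.patients:
            for obs in patient.points.values():
                lhs = (obs.pos_phase50 - obs.pos_helical) + (
                    obs.pos_helical - obs.pos_phase0
                )
                rhs = obs.pos_phase50 - obs.pos_phase0
                np.testing.assert_allclose(lhs, rhs, rtol=0, atol=1e-9)

    def test_seed_determinism(self, default_params):
        a = generate_cohort(default_params, 5, seed=77)
        b = generate_cohort(default_params, 5, seed=77)
        c = generate_cohort(default_params, 5, seed=78)
        for state in ("helical", "phase0", "phase50"):
            assert np.array_equal(a.positions(state), b.positions(state))
        assert not np.array_equal(a.positions("helical"), c.positions("helical"))

    def test_parameter_recovery_large_cohort(self, default_params):
        """2000 patients recover every mu within 3 sd/sqrt(n), SD within 10%."""
        n = 2000
        cohort = generate_cohort(default_params, n, seed=2024)
        disp = cohort.positions("phase50") - cohort.positions("phase0")
        mu, sd = default_params.mu_sd_arrays()
        sample_mu = disp.mean(axis=0)
        sample_sd = disp.std(axis=0, ddof=1)
        assert np.all(np.abs(sample_mu - mu) <= 3.0 * sd / np.sqrt(n) + 1e-12)
        assert np.all(np.abs(sample_sd - sd) <= 0.10 * sd)

    def test_helical_fraction_within_unit_interval(self, small_cohort):
        for patient in small_cohort.patients:
            assert 0.0 <= patient.helical_fraction <= 1.0

    def test_lung_volumes_bracket_and_additivity(self, small_cohort):
        """Generated lungs satisfy phase50 <= helical <= phase0 and L+R=total."""
        for patient in small_cohort.patients:
            lv = patient.lung_volumes
            assert lung_bracket_check(lv) == {
                "left": True,
                "right": True,
                "total": True,
            }
            for state in ("helical", "phase0", "phase50"):
                sv = getattr(lv, state)
                assert sv.total == pytest.approx(sv.left + sv.right, abs=1e-9)


class TestBreathingTrace:
    def test_zero_jitter_cycles_identical(self):
        p = SimulationParams(trace_amplitude_jitter=0.0, trace_period_jitter=0.0)
        trace = simulate_breathing_trace(p, seed=0)
        cycles = [
            trace.samples[trace.cycle_bounds[c] : trace.cycle_bounds[c + 1]]
            for c in range(trace.n_cycles)
        ]
        ref = cycles[0]
        assert all(np.array_equal(cyc, ref) for cyc in cycles)

    def test_determinism(self, default_params):
        a = simulate_breathing_trace(default_params, seed=5)
        b = simulate_breathing_trace(default_params, seed=5)
        assert np.array_equal(a.samples, b.samples)
        assert np.array_equal(a.cycle_bounds, b.cycle_bounds)

    def test_amplitude_jitter_coefficient_of_variation(self):
        """10% amplitude jitter gives a cycle-amplitude CV near 0.1."""
        p = SimulationParams(trace_amplitude_jitter=0.1, trace_n_cycles=20)
        cvs = []
        for seed in range(100):
            trace = simulate_breathing_trace(p, seed=seed)
            amps = [
                trace.samples[trace.cycle_bounds[c] : trace.cycle_bounds[c + 1]].max()
                for c in range(trace.n_cycles)
            ]
            cvs.append(np.std(amps, ddof=1) / np.mean(amps))
        assert 0.05 <= np.mean(cvs) <= 0.15

    def test_invalid_trace_params_rejected(self):
        with pytest.raises(ValueError):
            simulate_breathing_trace(SimulationParams(trace_period_s=0.0), seed=0)
        with pytest.raises(ValueError):
            simulate_breathing_trace(SimulationParams(trace_amplitude_au=-1.0), seed=0)
        with pytest.raises(ValueError):
            simulate_breathing_trace(SimulationParams(trace_n_cycles=2), seed=0)


def two_cycle_trace(a0: float, a1: float) -> BreathingTrace:
    """Hand-built triangular two-cycle trace starting each cycle at its peak."""
    cyc = lambda peak: [peak, peak / 2, peak - 10.0, peak / 2]  # noqa: E731
    samples = np.array(cyc(a0) + cyc(a1), dtype=float)
    return BreathingTrace(
        samples=samples, dt=1.0, cycle_bounds=np.array([0, 4, 8]), n_phases=4
    )


class TestMaxPhaseError:
    def test_zero_for_identical_cycles(self):
        p = SimulationParams(trace_amplitude_jitter=0.0, trace_period_jitter=0.0)
        trace = simulate_breathing_trace(p, seed=0)
        for phase in range(trace.n_phases):
            assert compute_max_phase_error(trace, phase) == pytest.approx(0.0, abs=1e-9)

    def test_hand_built_two_cycle_trace(self):
        """Phase-0 amplitudes 10 and 11 over a mean peak-to-peak of 10 -> 10%."""
        trace = two_cycle_trace(10.0, 11.0)
        # peak-to-peak: cycle 1 spans 10..0, cycle 2 spans 11..1 -> mean 10
        assert compute_max_phase_error(trace, 0) == pytest.approx(10.0)

    def test_scale_invariance(self):
        trace = two_cycle_trace(10.0, 11.0)
        scaled = BreathingTrace(
            samples=trace.samples * 3.7,
            dt=trace.dt,
            cycle_bounds=trace.cycle_bounds,
            n_phases=trace.n_phases,
        )
        for phase in range(trace.n_phases):
            assert compute_max_phase_error(scaled, phase) == pytest.approx(
                compute_max_phase_error(trace, phase)
            )

    def test_requires_two_cycles(self):
        trace = BreathingTrace(
            samples=np.array([1.0, 0.5, 0.0, 0.5]),
            dt=1.0,
            cycle_bounds=np.array([0, 4]),
            n_phases=4,
        )
        with pytest.raises(ValueError, match="2 complete"):
            compute_max_phase_error(trace, 0)

    def test_phase_index_bounds(self):
        trace = two_cycle_trace(10.0, 11.0)
        with pytest.raises(ValueError, match="phase_index"):
            compute_max_phase_error(trace, 4)
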
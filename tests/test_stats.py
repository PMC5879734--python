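"""Displacement computation and per-segment amplitude statistics."""

import numpy as np
import pytest

from livermotion import (
    AXES,
    SEGMENTS,
    Cohort,
    Patient,
    PointObservation,
    StatePair,
    amplitude_stats,
    amplitude_table,
    cohort_displacements,
    displacement,
    generate_cohort,
    round_half_away,
)
from livermotion.stats import OVERALL


def make_patient(pid: str, offset=(0.0, 0.0, 0.0), si_by_segment=None) -> Patient:
    """A patient whose every point sits at *offset*, phase50 shifted in SI."""
    off = np.asarray(offset, dtype=float)
    points = {}
    for seg in SEGMENTS:
        si = 0.0 if si_by_segment is None else si_by_segment.get(seg, 0.0)
        points[seg] = PointObservation(
            patient_id=pid,
            segment=seg,
            pos_helical=off,
            pos_phase0=off,
            pos_phase50=off + np.array([0.0, 0.0, si]),
        )
    return Patient(patient_id=pid, points=points, lung_volumes=None)


class TestDisplacement:
    def test_origin_at_zero(self):
        obs = PointObservation("p", "S1", [0, 0, 0], [0, 0, 0], [1, 2, 3])
        d = displacement(obs, StatePair.PHASE0_TO_PHASE50)
        assert tuple(d) == (1.0, 2.0, 3.0)

    def test_no_motion(self):
        obs = PointObservation("p", "S1", [4, 4, 4], [4, 4, 4], [4, 4, 4])
        for pair in StatePair:
            assert tuple(displacement(obs, pair)) == (0.0, 0.0, 0.0)

    def test_sign_convention_helical_to_phase50(self):
        """(5,5,5) -> (4,7,10): 1 mm right, 2 mm posterior, 5 mm superior."""
        obs = PointObservation("p", "S7", [5, 5, 5], [0, 0, 0], [4, 7, 10])
        d = displacement(obs, StatePair.HELICAL_TO_PHASE50)
        assert tuple(d) == (-1.0, 2.0, 5.0)

    def test_pair_identity_per_observation(self, small_cohort):
        """helical->p50 minus helical->p0 equals phase0->phase50, exactly."""
        d_h0 = cohort_displacements(small_cohort, StatePair.HELICAL_TO_PHASE0)
        d_h50 = cohort_displacements(small_cohort, StatePair.HELICAL_TO_PHASE50)
        d_tot = cohort_displacements(small_cohort, StatePair.PHASE0_TO_PHASE50)
        np.testing.assert_allclose(d_h50 - d_h0, d_tot, rtol=0, atol=1e-9)


class TestAmplitudeStats:
    def test_two_patient_hand_computation(self):
        cohort = Cohort(
            [
                make_patient("a", si_by_segment={"S1": 4.0}),
                make_patient("b", si_by_segment={"S1": 6.0}),
            ]
        )
        s = amplitude_stats(cohort, "S1", "si", StatePair.PHASE0_TO_PHASE50)
        assert s.mean == pytest.approx(5.0)
        assert s.sd == pytest.approx(np.sqrt(2.0))
        assert s.n == 2

    def test_identical_patients_zero_sd(self):
        cohort = Cohort([make_patient(p, si_by_segment={"S3": 2.5}) for p in "abc"])
        s = amplitude_stats(cohort, "S3", "si", StatePair.PHASE0_TO_PHASE50)
        assert s.mean == pytest.approx(2.5)
        assert s.sd == 0.0

    def test_single_patient_rejected(self):
        cohort = Cohort([make_patient("solo")])
        with pytest.raises(ValueError, match="2 patients"):
            amplitude_stats(cohort, "S1", "si", StatePair.PHASE0_TO_PHASE50)

    def test_degenerate_cohort_recovers_segment_means(self, default_params):
        """With all SDs forced to zero the stats equal mu exactly (S7 row)."""
        p = default_params.__class__()
        p.amplitude_mm = {
            seg: {axis: (mu, 0.0) for axis, (mu, _) in axes.items()}
            for seg, axes in p.amplitude_mm.items()
        }
        cohort = generate_cohort(p, 4, seed=0)
        for axis, expected in zip(AXES, (-1.4, 3.5, 8.6)):
            s = amplitude_stats(cohort, "S7", axis, StatePair.PHASE0_TO_PHASE50)
            assert s.mean == pytest.approx(expected, abs=1e-12)
            assert s.sd == pytest.approx(0.0, abs=1e-12)

    def test_translation_invariance(self, small_cohort):
        """A rigid shift of all of a patient's positions leaves stats unchanged."""
        shifted = Cohort(
            [
                Patient(
                    patient_id=p.patient_id,
                    points={
                        seg: PointObservation(
                            p.patient_id,
                            seg,
                            obs.pos_helical + 11.0,
                            obs.pos_phase0 + 11.0,
                            obs.pos_phase50 + 11.0,
                        )
                        for seg, obs in p.points.items()
                    },
                    lung_volumes=None,
                )
                for p in small_cohort.patients
            ]
        )
        for pair in StatePair:
            a = amplitude_stats(small_cohort, "S5", "ap", pair)
            b = amplitude_stats(shifted, "S5", "ap", pair)
            assert b.mean == pytest.approx(a.mean)
            assert b.sd == pytest.approx(a.sd)


class TestAmplitudeTable:
    def test_overall_mean_equals_mean_of_segment_means(self, small_cohort):
        """With equal n per segment, the pooled mean is the mean of means."""
        table = amplitude_table(small_cohort, StatePair.PHASE0_TO_PHASE50)
        for axis in AXES:
            seg_means = [table.rows[s][axis].mean for s in SEGMENTS]
            assert table.rows[OVERALL][axis].mean == pytest.approx(np.mean(seg_means))
            assert table.rows[OVERALL][axis].n == 9 * small_cohort.n

    def test_overall_sd_rules(self, small_cohort):
        pooled = amplitude_table(small_cohort, StatePair.PHASE0_TO_PHASE50)
        averaged = amplitude_table(
            small_cohort, StatePair.PHASE0_TO_PHASE50, overall="mean_of_sds"
        )
        disp = cohort_displacements(small_cohort, StatePair.PHASE0_TO_PHASE50)
        for k, axis in enumerate(AXES):
            assert pooled.rows[OVERALL][axis].sd == pytest.approx(
                np.std(disp[:, :, k].ravel(), ddof=1)
            )
            assert averaged.rows[OVERALL][axis].sd == pytest.approx(
                np.mean([averaged.rows[s][axis].sd for s in SEGMENTS])
            )

    def test_frame_layout(self, small_cohort):
        df = amplitude_table(small_cohort, StatePair.HELICAL_TO_PHASE0).to_frame()
        assert len(df) == 30  # 9 segments x 3 axes + overall row x 3
        assert set(df["segment"]) == set(SEGMENTS) | {OVERALL}


@pytest.mark.parametrize(
    "x, expected",
    [(0.25, 0.3), (-0.25, -0.3), (2.34, 2.3), (-5.65, -5.7), (0.0, 0.0)],
)
def test_round_half_away(x, expected):
    assert round_half_away(x, 1) == expected
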
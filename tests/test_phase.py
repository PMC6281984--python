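import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hybridphase import phase
from hybridphase.preproc import HemoSeries

SQRT2 = np.sqrt(2.0)


class TestRotate:
    def test_diagonal_maps_to_pure_total_hemoglobin(self):
        hbt, coe = phase.rotate(1.0, 1.0)
        assert hbt == pytest.approx(SQRT2) and coe == pytest.approx(0.0)

    def test_anti_diagonal_maps_to_pure_oxygen_exchange(self):
        hbt, coe = phase.rotate(1.0, -1.0)
        assert hbt == pytest.approx(0.0) and coe == pytest.approx(-SQRT2)

    def test_phase_identity_against_rotated_frame(self):
        """angle(p) equals atan2(coe, hbt) + 45 degrees."""
        hbt, coe = phase.rotate(2.0, 1.0)
        lhs = phase.angle_deg(2.0, 1.0)
        rhs = np.degrees(np.arctan2(coe, hbt)) + 45.0
        assert lhs == pytest.approx(rhs)
        assert lhs == pytest.approx(np.degrees(np.arctan(0.5)))

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        st.floats(-1e6, 1e6, allow_nan=False),
        st.floats(-1e6, 1e6, allow_nan=False),
    )
    def test_rotation_preserves_magnitude(self, hbo, hbr):
        hbt, coe = phase.rotate(hbo, hbr)
        assert float(np.hypot(hbt, coe)) == pytest.approx(
            float(np.hypot(hbo, hbr)), rel=1e-12, abs=1e-12
        )


def octant_oracle(angle):
    """Brute-force octant table on the angle in (-180, 180]."""
    a = angle if angle > 0 else angle + 360.0  # (0, 360]
    for k in range(1, 9):
        if (k - 1) * 45.0 < a <= k * 45.0:
            return k
    raise AssertionError(a)


class TestClassifyPhase:
    @pytest.mark.parametrize(
        "hbo,hbr,expected",
        [
            (1.0, 0.5, 1),  # dHbO > dHbR > 0
            (-1.0, 0.5, 4),  # angle ~ 153.4
            (1.0, -0.5, 8),  # angle ~ -26.6: hemodynamic
            (0.5, 1.0, 2),
            (-0.5, -1.0, 6),
        ],
    )
    def test_reference_points(self, hbo, hbr, expected):
        assert phase.phase_of_point(hbo, hbr) == expected

    def test_agrees_with_octant_oracle_on_dense_polar_grid(self):
        angles = np.concatenate(
            [
                np.arange(-179.5, 180.0, 0.5),
                np.arange(-135.0, 181.0, 45.0),  # all boundary angles
            ]
        )
        hbo = np.cos(np.radians(angles))
        hbr = np.sin(np.radians(angles))
        got = phase.classify_phase(hbo, hbr)
        expected = [octant_oracle(a) for a in angles]
        np.testing.assert_array_equal(got, expected)

    def test_boundary_closed_on_counterclockwise_edge(self):
        assert phase.phase_of_point(1.0, 1.0) == 1  # 45 deg belongs to phase 1
        assert phase.phase_of_point(0.0, 1.0) == 2  # 90 deg to phase 2
        assert phase.phase_of_point(1.0, 0.0) == 8  # 0 deg closes phase 8

    def test_zero_vector_has_no_phase(self):
        with pytest.raises(ValueError, match="zero"):
            phase.phase_of_point(0.0, 0.0)

    def test_sign_pattern_table(self):
        """Each octant's (hbo, hbr, hbt, coe) signs follow the geometry.

        dHbT is negative exactly on the half-plane below the -45-degree
        line (octants 4-7) and dCOE positive exactly above the +45-degree
        line (octants 2-5); together they pin each octant's sign pattern.
        """
        table = {
            1: (1, 1, 1, -1), 2: (1, 1, 1, 1), 3: (-1, 1, 1, 1), 4: (-1, 1, -1, 1),
            5: (-1, -1, -1, 1), 6: (-1, -1, -1, -1), 7: (1, -1, -1, -1),
            8: (1, -1, 1, -1),
        }
        for k, signs in table.items():
            mid = np.radians(k * 45.0 - 22.5)
            hbo, hbr = np.cos(mid), np.sin(mid)
            assert phase.phase_of_point(hbo, hbr) == k
            hbt, coe = phase.rotate(hbo, hbr)
            assert np.sign([hbo, hbr, hbt, coe]).astype(int).tolist() == list(signs)

    def test_dip_and_hemodynamic_flag_sets(self):
        assert phase.DIP_PHASES == {3, 4, 5}
        assert phase.HEMODYNAMIC_PHASES == {7, 8}
        # phases 7-8 are exactly the fourth quadrant
        rng = np.random.default_rng(2)
        hbo, hbr = rng.standard_normal(2000), rng.standard_normal(2000)
        labels = phase.classify_phase(hbo, hbr)
        in_q4 = (hbo > 0) & (hbr < 0)
        np.testing.assert_array_equal(np.isin(labels, (7, 8)), in_q4)


class TestRadii:
    def test_resting_radius_of_flat_baseline_is_zero(self):
        assert phase.resting_radius(HemoSeries(np.zeros(5), np.zeros(5), 9.19)) == 0.0

    def test_resting_radius_takes_max_paired_magnitude(self):
        h = HemoSeries([0.1, -0.2], [0.05, 0.1], 9.19)
        assert phase.resting_radius(h) == pytest.approx(np.sqrt(0.05), abs=1e-12)

    def test_resting_radius_three_four_five(self):
        assert phase.resting_radius(HemoSeries([3.0], [4.0], 9.19)) == 5.0

    def test_window_radius_of_zero_window_is_zero(self):
        assert phase.eeg_window_radius(HemoSeries(np.zeros(9), np.zeros(9), 9.19)) == 0.0

    def test_window_radius_uses_separate_component_maxima(self):
        h = HemoSeries([0.1, 0.3], [-0.2, -0.1], 9.19)
        assert phase.eeg_window_radius(h) == pytest.approx(np.sqrt(0.13), abs=1e-12)

    def test_window_radius_bounds_each_component(self):
        rng = np.random.default_rng(4)
        h = HemoSeries(rng.standard_normal(40), rng.standard_normal(40), 9.19)
        r2 = phase.eeg_window_radius(h)
        assert r2 >= np.abs(h.hbo).max() and r2 >= np.abs(h.hbr).max()

    @pytest.mark.parametrize("c", [0.5, 2.0, 117.0])
    def test_radii_scale_equivariance(self, c):
        rng = np.random.default_rng(8)
        hbo, hbr = rng.standard_normal(60), rng.standard_normal(60)
        h = HemoSeries(hbo, hbr, 9.19)
        hc = HemoSeries(c * hbo, c * hbr, 9.19)
        assert phase.resting_radius(hc) == pytest.approx(c * phase.resting_radius(h))
        assert phase.eeg_window_radius(hc) == pytest.approx(
            c * phase.eeg_window_radius(h)
        )

    def test_empty_segments_rejected(self):
        empty = HemoSeries(np.array([]), np.array([]), 9.19)
        with pytest.raises(ValueError):
            phase.resting_radius(empty)
        with pytest.raises(ValueError):
            phase.eeg_window_radius(empty)


class TestTrajectory:
    def test_origin_trajectory_stays_inside_both_circles(self):
        h = HemoSeries(np.zeros(30), np.zeros(30), 9.19)
        traj = phase.track_trajectory(h, phase.ThresholdPair(r1=1.0, r2=0.5))
        assert traj["in_r1"].all() and traj["in_r2"].all()
        assert (traj["phase"] == 0).all()

    def test_ray_crossings_match_line_circle_closed_form(self, ray_series):
        """Crossing times of an origin ray follow t = 3 r / (v sqrt(10))."""
        h, v = ray_series
        times = h.times_s
        mags = phase.magnitude(h.hbo, h.hbr)
        for r in (2e-4, 3.5e-4):
            expected = 3.0 * r / (v * np.sqrt(10.0))
            got = phase.crossing_time(times, mags, r)
            assert got == pytest.approx(expected, abs=1e-12)

    def test_trajectory_record_columns_and_time_monotone(self, ray_series):
        h, _ = ray_series
        traj = phase.track_trajectory(h, phase.ThresholdPair(1.0, 0.5), start_index=3)
        assert list(traj.columns) == [
            "time", "hbo", "hbr", "hbt", "coe", "magnitude", "angle_deg",
            "phase", "in_r2", "in_r1",
        ]
        assert (np.diff(traj["time"]) > 0).all()
        assert traj["time"].iloc[0] == pytest.approx(3 / h.rate)

    def test_start_beyond_series_end_rejected(self, ray_series):
        h, _ = ray_series
        with pytest.raises(IndexError):
            phase.track_trajectory(h, phase.ThresholdPair(1.0, 0.5), start_index=len(h))

    def test_decaying_trajectory_never_crosses_upward(self):
        """An elevated magnitude relaxing toward the origin is not a crossing."""
        t = np.arange(50) / 9.19
        mags = 2.0 * np.exp(-t)
        assert phase.crossing_time(t, mags, radius=1.0, t_from=0.0) is None

    def test_q4_restriction_blocks_second_quadrant_crossings(self):
        t = np.arange(30) / 9.19
        hbo = -0.1 * t  # second quadrant: hbo < 0, hbr > 0
        hbr = 0.1 * t
        mags = phase.magnitude(hbo, hbr)
        q4 = (hbo > 0) & (hbr < 0)
        assert phase.crossing_time(t, mags, 0.1, in_q4=q4) is None
        assert phase.crossing_time(t, mags, 0.1) is not None

    def test_threshold_pair_validation(self):
        with pytest.raises(ValueError):
            phase.ThresholdPair(r1=-1.0, r2=0.0)
        with pytest.raises(ValueError):
            phase.ThresholdPair(r1=np.inf, r2=0.0)
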
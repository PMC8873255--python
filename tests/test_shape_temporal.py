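"""Turning angles, complexity, total turning angle, gyration radius, stops."""

import numpy as np
import pytest
from conftest import brute_stops

from navtrace import (
    detect_stops,
    radius_of_gyration,
    segment_complexity,
    total_turning_angle,
    turning_angles,
)


def staircase_ccw(m, step=10.0):
    """m successive +90 deg (counterclockwise) turns: a rectangular spiral."""
    pos = np.zeros(2)
    heading = 0.0
    pts = [pos.copy()]
    for _ in range(m + 1):
        pos = pos + step * np.array([np.cos(heading), np.sin(heading)])
        pts.append(pos.copy())
        heading += np.pi / 2
    return np.array(pts)


def hairpin():
    """Straight out, exact-ish reversal, straight back (one sharp feature)."""
    return np.array(
        [[0.0, 0.0], [10.0, 0.0], [20.0, 0.0],
         [10.0, 0.001], [0.0, 0.001], [-10.0, 0.001]]
    )


class TestTurningAngles:
    def test_collinear_points_turn_zero(self):
        xy = np.column_stack([np.arange(6) * 5.0, np.zeros(6)])
        ang = turning_angles(xy)
        assert np.allclose(ang.theta1, 0.0, atol=1e-9)

    def test_left_turn_is_ninety_right_turn_is_two_seventy(self):
        left = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0]])
        right = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, -1.0]])
        assert turning_angles(left).theta1[0] == pytest.approx(90.0)
        assert turning_angles(right).theta1[0] == pytest.approx(270.0)

    def test_exact_reversal_is_one_eighty(self):
        xy = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1e-9]])
        assert turning_angles(xy).theta1[0] == pytest.approx(180.0, abs=1e-4)

    def test_duplicate_points_are_merged_first(self):
        xy = np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 0.0], [1.0, 0.0], [2.0, 0.0]])
        ang = turning_angles(xy)
        assert len(ang.theta1) == 1 and ang.theta1[0] == pytest.approx(0.0)

    def test_fewer_than_three_distinct_points_gives_empty_angles(self):
        xy = np.array([[0.0, 0.0], [0.0, 0.0], [5.0, 0.0]])
        ang = turning_angles(xy)
        assert len(ang.theta1) == len(ang.theta2) == len(ang.theta_avg) == 0


class TestComplexity:
    def test_straight_path_has_zero_complexity(self):
        xy = np.column_stack([np.arange(20) * 7.0, np.zeros(20)])
        assert segment_complexity(turning_angles(xy)) == 0

    def test_single_hairpin_counts_once(self):
        assert segment_complexity(turning_angles(hairpin())) == 1

    def test_reversing_travel_direction_preserves_complexity(self):
        rng = np.random.default_rng(8)
        for _ in range(100):
            xy = np.cumsum(rng.normal(0.0, 6.0, (30, 2)), axis=0)
            fwd = segment_complexity(turning_angles(xy))
            rev = segment_complexity(turning_angles(xy[::-1]))
            assert fwd == rev


class TestTotalTurningAngle:
    def test_straight_path_sums_to_zero(self):
        xy = np.column_stack([np.arange(10) * 3.0, np.zeros(10)])
        assert total_turning_angle(turning_angles(xy)) == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("m", [1, 3, 5])
    def test_ccw_staircase_sums_to_turn_count(self, m):
        tta = total_turning_angle(turning_angles(staircase_ccw(m)))
        assert tta == pytest.approx(m, abs=1e-9)

    def test_opposite_turns_cancel(self):
        xy = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [2.0, 1.0]])  # L then R
        assert total_turning_angle(turning_angles(xy)) == pytest.approx(0.0, abs=1e-12)

    def test_bounded_by_interior_count(self):
        rng = np.random.default_rng(9)
        for _ in range(30):
            n = int(rng.integers(4, 50))
            xy = np.cumsum(rng.normal(0.0, 5.0, (n, 2)), axis=0)
            ang = turning_angles(xy)
            assert abs(total_turning_angle(ang)) <= len(ang.theta1) + 1e-9

    def test_reflection_negates_the_sum(self):
        rng = np.random.default_rng(10)
        xy = np.cumsum(rng.normal(0.0, 5.0, (40, 2)), axis=0)
        tta = total_turning_angle(turning_angles(xy))
        mirrored = xy * np.array([1.0, -1.0])
        assert total_turning_angle(turning_angles(mirrored)) == pytest.approx(-tta)


class TestRotationInvariance:
    def test_rigid_rotation_preserves_shape_features(self):
        rng = np.random.default_rng(11)
        xy = np.cumsum(rng.normal(0.0, 8.0, (60, 2)), axis=0)
        t = np.arange(60) * 3.0
        c, s = np.cos(0.7), np.sin(0.7)
        rot = xy @ np.array([[c, s], [-s, c]])
        assert segment_complexity(turning_angles(rot)) == segment_complexity(turning_angles(xy))
        assert radius_of_gyration(rot) == pytest.approx(radius_of_gyration(xy))
        assert total_turning_angle(turning_angles(rot)) == pytest.approx(
            total_turning_angle(turning_angles(xy))
        )
        assert detect_stops(t, rot).durations == detect_stops(t, xy).durations


class TestRadiusOfGyration:
    def test_identical_points_have_zero_radius(self):
        assert radius_of_gyration(np.tile([[3.0, 4.0]], (9, 1))) == 0.0

    def test_points_on_circle_give_its_radius(self):
        ang = np.linspace(0.0, 2 * np.pi, 37)[:-1]
        xy = 250.0 * np.column_stack([np.cos(ang), np.sin(ang)])
        assert radius_of_gyration(xy) == pytest.approx(250.0)

    def test_two_points_give_half_separation(self):
        xy = np.array([[0.0, 0.0], [0.0, 84.0]])
        assert radius_of_gyration(xy) == pytest.approx(42.0)


class TestStops:
    def test_stationary_block_inside_movement_is_one_stop(self):
        dt = 3.0
        move1 = np.column_stack([np.arange(10) * 12.0, np.zeros(10)])
        # block offset 12 m from the last moving sample so the window
        # anchors exactly at the block: 40 intervals of 3 s = 120 s
        still = np.tile(move1[-1] + [12.0, 0.0], (41, 1))
        move2 = move1 + still[-1] + [12.0, 0.0]
        xy = np.vstack([move1, still, move2])
        t = np.arange(len(xy)) * dt
        stops = detect_stops(t, xy)
        assert stops.count == 1
        assert stops.durations[0] == pytest.approx(120.0)

    def test_continuous_movement_has_no_stops(self):
        xy = np.column_stack([np.arange(200) * 12.0, np.zeros(200)])
        assert detect_stops(np.arange(200) * 3.0, xy).count == 0

    def test_half_minute_pause_is_below_threshold(self):
        move = np.column_stack([np.arange(10) * 12.0, np.zeros(10)])
        still = np.tile(move[-1], (11, 1))  # 30 s
        xy = np.vstack([move, still, move + move[-1] + [12.0, 0.0]])
        t = np.arange(len(xy)) * 3.0
        assert detect_stops(t, xy).count == 0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_bruteforce_scan_on_random_segments(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(50, 300))
        # mix of dwell and movement phases
        xy = np.cumsum(
            rng.normal(0.0, rng.choice([0.5, 6.0], n)[:, None], (n, 2)), axis=0
        )
        t = np.cumsum(rng.choice([3.0, 5.0], n))
        got = detect_stops(t, xy).durations
        assert got == pytest.approx(brute_stops(t, xy, 10.0, 60.0))
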
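"""Stimulus simulator: motion process, orientation, collision, trial assembly."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wolfpack import kinematics as K
from wolfpack.kinematics import (
    DisplayGeometry,
    InvalidInputError,
    MotionParams,
    apply_pivot_shift,
    assign_orientation,
    build_trial,
    detect_collision,
    generate_agent_trajectory,
    quadrant_bounds,
    quadrant_of,
)


class TestTrajectory:
    def test_straight_line_without_turns(self, geometry):
        """With turn_rate 0 the agent moves on a straight line with exact
        per-frame steps of speed/frame_rate."""
        m = MotionParams(turn_rate=0.0)
        pos, dirs = generate_agent_trajectory(
            quadrant_bounds(0, geometry), m, geometry, seed=1,
            start=np.array([2.95, 2.95]), n_frames=20,
        )
        steps = np.diff(pos, axis=0)
        assert np.allclose(np.linalg.norm(steps, axis=1), 7.8 / 75, atol=1e-9)
        # all steps parallel to the initial direction
        cross = steps[:, 0] * dirs[0, 1] - steps[:, 1] * dirs[0, 0]
        assert np.allclose(cross, 0.0, atol=1e-9)

    def test_speed_conservation_and_containment(self, geometry, motion):
        pos, dirs = generate_agent_trajectory(
            quadrant_bounds(0, geometry), motion, geometry, seed=7, n_frames=75 * 30
        )
        steps = np.linalg.norm(np.diff(pos, axis=0), axis=1)
        expected = 7.8 / 75
        # non-reflection frames carry the exact step; reflections shorten the
        # chord but preserve path length
        non_reflect = np.isclose(steps, expected, atol=1e-9)
        assert non_reflect.mean() > 0.9
        assert steps.max() <= expected + 1e-9
        assert pos[:, 0].min() >= 0 and pos[:, 0].max() <= 5.9
        assert pos[:, 1].min() >= 0 and pos[:, 1].max() <= 5.9

    def test_mean_speed_approaches_constant(self, geometry, motion):
        """Long-run chord length per second matches the constant speed (the
        small deficit comes from chords cut short at wall bounces)."""
        pos, _ = generate_agent_trajectory(
            quadrant_bounds(1, geometry), motion, geometry, seed=3, n_frames=75 * 100
        )
        steps = np.linalg.norm(np.diff(pos, axis=0), axis=1)
        assert steps.sum() / 100 == pytest.approx(7.8, rel=0.01)
        # away from walls the speed is exact
        exact = np.isclose(steps, 7.8 / 75, atol=1e-9)
        assert np.allclose(steps[exact], 7.8 / 75, atol=1e-9)

    def test_turn_rate_statistic(self, geometry):
        """Direction changes occur at 3/s on average (within 3 SE over 1000 s)."""
        m = MotionParams()
        _, _, n_turns = K.generate_agent_trajectories(
            np.array([quadrant_bounds(0, geometry)]), m, geometry, seed=11,
            n_frames=75 * 1000, return_turn_count=True,
        )
        rate = n_turns / 1000
        se = np.sqrt(3.0 * 1000) / 1000
        assert abs(rate - 3.0) < 3 * se

    def test_reflection_mirrors_direction(self, geometry):
        """A 30-degree ray hitting a vertical wall reflects to its mirror
        image (hand-computed single-bounce oracle)."""
        d0 = np.array([np.cos(np.deg2rad(30)), np.sin(np.deg2rad(30))])
        p, d = K._reflect_into_bounds(
            np.array([[5.95, 2.06]]), d0[None, :], np.array([quadrant_bounds(0, geometry)])
        )
        assert np.allclose(d[0], [-d0[0], d0[1]])
        assert np.allclose(p[0], [2 * 5.9 - 5.95, 2.06])

    def test_start_outside_bounds_rejected(self, geometry, motion):
        with pytest.raises(InvalidInputError):
            generate_agent_trajectory(
                quadrant_bounds(0, geometry), motion, geometry, seed=0,
                start=np.array([-1.0, 1.0]), n_frames=10,
            )

    def test_step_exceeding_quadrant_rejected(self, geometry):
        m = MotionParams(speed=1000.0)
        with pytest.raises(InvalidInputError):
            generate_agent_trajectory(quadrant_bounds(0, geometry), m, geometry, seed=0)

    def test_reproducibility(self, geometry, motion):
        a = generate_agent_trajectory(quadrant_bounds(2, geometry), motion, geometry, seed=5, n_frames=400)
        b = generate_agent_trajectory(quadrant_bounds(2, geometry), motion, geometry, seed=5, n_frames=400)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])


class TestOrientation:
    @pytest.mark.parametrize(
        "agent,chasee,expected",
        [((1, 0), (0, 0), (-1, 0)), ((3, 4), (0, 0), (-0.6, -0.8))],
    )
    def test_head_on_points_at_chasee(self, agent, chasee, expected):
        ori = assign_orientation(np.array(agent, float), np.array(chasee, float), "head_on")
        assert np.allclose(ori, expected)

    def test_perpendicular_is_orthogonal(self):
        ori = assign_orientation(np.array([1.0, 0.0]), np.zeros(2), "perpendicular", perp_side=1)
        assert abs(np.dot(ori, [-1.0, 0.0])) < 1e-12
        assert np.linalg.norm(ori) == pytest.approx(1.0)

    def test_coincident_positions_error(self):
        with pytest.raises(InvalidInputError):
            assign_orientation(np.ones(2), np.ones(2), "head_on")

    @given(st.floats(-3, 3), st.floats(-3, 3), st.floats(0.1, 2 * np.pi - 0.1))
    @settings(max_examples=50, deadline=None)
    def test_rotation_equivariance(self, x, y, theta):
        """Rotating agent and chasee together rotates the orientation."""
        agent = np.array([x + 4.0, y])  # keep away from the chasee at origin
        chasee = np.zeros(2)
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        o1 = assign_orientation(agent, chasee, "head_on")
        o2 = assign_orientation(R @ agent, R @ chasee, "head_on")
        assert np.allclose(R @ o1, o2, atol=1e-9)


class TestPivotShift:
    def test_zero_shift_is_identity(self):
        p = np.array([1.2, -0.7])
        assert np.allclose(apply_pivot_shift(p, np.array([0.0, 1.0]), 0.0), p)

    def test_shift_along_orientation(self):
        ref = apply_pivot_shift(np.zeros(2), np.array([1.0, 0.0]), 0.2)
        assert np.allclose(ref, [0.2, 0.0])

    def test_dart_block_sets_render_distinct_offsets(self):
        """The dart pivot-shift sets map to four distinct reference offsets
        along the nose axis."""
        ori = np.array([0.0, 1.0])
        offsets = [apply_pivot_shift(np.zeros(2), ori, d)[1] for d in (-0.4, -0.2, 0.2, 0.4)]
        assert len(set(np.round(offsets, 9))) == 4
        assert offsets == sorted(offsets)


class TestCollision:
    def test_bug_circle_overlap(self, geometry):
        from wolfpack.kinematics import AgentState

        def bug_at(x):
            return AgentState(
                pivot_pos=np.zeros(2), ref_pos=np.zeros(2),
                orientation=np.array([1.0, 0.0]), motion_dir=np.array([1.0, 0.0]),
                kind="bug",
            )

        assert not detect_collision(bug_at(0), np.array([2.0, 0.0]), geometry)  # 2.0 > 1.55
        assert detect_collision(bug_at(0), np.array([1.0, 0.0]), geometry)

    def test_chasee_on_dart_concave_vertex(self, geometry):
        from wolfpack.kinematics import AgentState

        dart = AgentState(
            pivot_pos=np.zeros(2), ref_pos=np.zeros(2),
            orientation=np.array([1.0, 0.0]), motion_dir=np.array([1.0, 0.0]),
            kind="dart",
        )
        assert detect_collision(dart, np.zeros(2), geometry)

    def test_dart_polygon_tighter_than_circle(self, geometry):
        """A point behind the dart's tail misses the polygon even though it
        is inside the circumscribed circle."""
        from wolfpack.kinematics import AgentState

        dart = AgentState(
            pivot_pos=np.zeros(2), ref_pos=np.zeros(2),
            orientation=np.array([1.0, 0.0]), motion_dir=np.array([1.0, 0.0]),
            kind="dart",
        )
        # directly behind the concave vertex, between the rear wings
        assert not detect_collision(dart, np.array([-1.3, 0.0]), geometry)

    def test_dart_centroid_exposed(self, geometry):
        off = K.dart_centroid_offset(geometry)
        assert 0.0 < off < 0.95


class TestBuildTrial:
    def test_lma_layout(self):
        trial = build_trial("LMA", layout_seed=2, motion_seed=3)
        assert trial.n_agents == 12
        assert len(trial.wolfpack_quadrants) == 2
        per_quadrant = {q: trial.agent_quadrant.count(q) for q in range(4)}
        assert all(v == 3 for v in per_quadrant.values())
        layout = trial.quadrant_layout
        assert sum(v == "head_on" for v in layout.values()) == 2

    def test_chasee_starts_away_from_agents(self):
        trial = build_trial("LMA", layout_seed=4, motion_seed=5)
        dists = np.linalg.norm(trial.pivot[0] - trial.chasee[0], axis=1)
        assert dists.min() >= 4.0

    def test_bisection_midpoint_and_conditions(self):
        trial = build_trial("bisection", layout_seed=6, motion_seed=7)
        assert trial.n_agents == 2
        assert sorted(trial.conditions) == ["head_on", "perpendicular"]
        assert trial.agent_quadrant[0] != trial.agent_quadrant[1]
        assert np.allclose(trial.chasee[0], 0.5 * (trial.pivot[0, 0] + trial.pivot[0, 1]))

    def test_determinism(self):
        a = build_trial("LMA", layout_seed=8, motion_seed=9)
        b = build_trial("LMA", layout_seed=8, motion_seed=9)
        assert np.array_equal(a.pivot, b.pivot)
        assert np.array_equal(a.motion_dir, b.motion_dir)
        assert a.wolfpack_quadrants == b.wolfpack_quadrants
        assert np.array_equal(a.chasee[0], b.chasee[0])

    def test_head_on_lock_after_finalize(self, rng):
        """Head-on agents point exactly at the chasee at every frame."""
        trial = build_trial("LMA", layout_seed=10, motion_seed=11, duration=2.0)
        chasee = trial.chasee + 0.01 * rng.standard_normal(trial.chasee.shape)
        trial.finalize(chasee)
        for a in range(trial.n_agents):
            if trial.conditions[a] != "head_on":
                continue
            toward = chasee - trial.pivot[:, a]
            toward /= np.linalg.norm(toward, axis=1, keepdims=True)
            assert np.allclose(trial.orientation[:, a], toward, atol=1e-9)

    def test_missing_agent_among_nearest(self, rng):
        trial = build_trial("recall_probe", layout_seed=12, motion_seed=13, duration=2.0)
        trial.finalize(trial.chasee)
        a = K.choose_missing_agent(trial, rng)
        dists = np.linalg.norm(trial.pivot[-1] - trial.chasee[-1], axis=1)
        assert dists[a] <= np.sort(dists)[2] + 1e-12


class TestQuadrants:
    def test_half_open_boundary_convention(self):
        assert quadrant_of(np.array([0.0, 0.0])) == 0
        assert quadrant_of(np.array([0.0, -0.1])) == 3
        assert quadrant_of(np.array([-0.1, 0.0])) == 1
        assert quadrant_of(np.array([-0.1, -0.1])) == 2


class TestSerialization:
    def test_jsonl_round_trip(self, tmp_path):
        trial = build_trial("bisection", d=0.2, layout_seed=14, motion_seed=15, duration=1.0)
        trial.finalize(trial.chasee)
        path = tmp_path / "trial.jsonl"
        trial.to_jsonl(path)
        back = K.TrialRecord.from_jsonl(path)
        assert np.array_equal(back.pivot, trial.pivot)
        assert np.array_equal(back.chasee, trial.chasee)
        assert back.d == trial.d
        assert back.conditions == trial.conditions
        assert back.wolfpack_quadrants == trial.wolfpack_quadrants

    def test_csv_export(self, tmp_path):
        import pandas as pd

        trial = build_trial("LMA", layout_seed=1, motion_seed=2, duration=0.2)
        trial.to_csv(tmp_path / "t.csv")
        df = pd.read_csv(tmp_path / "t.csv")
        assert len(df) == trial.n_frames * trial.n_agents
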
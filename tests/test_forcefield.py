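"""Force-field analysis: events, field algebra, grid search, pooling."""

import numpy as np
import pytest

from wolfpack import forcefield as F
from wolfpack import kinematics as K
from wolfpack import synthetic_participant as S


def brute_force_events(speed, threshold, min_frames):
    """Exhaustive scan over all below-threshold runs (independent oracle)."""
    events = []
    start = None
    for t, s in enumerate(speed):
        if s < threshold and start is None:
            start = t
        elif s >= threshold and start is not None:
            if t - start >= min_frames:
                events.append((start, t))
            start = None
    if start is not None and len(speed) - start >= min_frames:
        events.append((start, len(speed)))
    return events


class TestDetectEvents:
    def _series_from_speed(self, speeds, fps=75.0):
        """Build a 1-D cursor path whose raw per-frame speed is ``speeds``."""
        steps = np.asarray(speeds) / fps
        x = np.concatenate([[0.0], np.cumsum(steps)])
        return np.column_stack([x, np.zeros_like(x)])

    def test_short_slow_episode_rejected(self):
        """250 ms below threshold does not qualify as an event."""
        speeds = np.r_[np.full(40, 30.0), np.full(18, 5.0), np.full(40, 30.0)]
        series = self._series_from_speed(speeds)
        assert F.detect_events(series, 75.0) == []

    def test_long_slow_episode_detected_and_first_flagged(self):
        speeds = np.r_[np.full(30, 5.0), np.full(40, 30.0), np.full(30, 5.0)]
        series = self._series_from_speed(speeds)
        events = F.detect_events(series, 75.0)
        assert len(events) == 2
        assert events[0].is_first and not events[1].is_first
        assert all(e.n_frames >= 23 for e in events)

    def test_agrees_with_brute_force_oracle(self, rng):
        """Detection matches an exhaustive below-threshold scan on random
        series (smoothed speed fed to both)."""
        for rep in range(20):
            steps = rng.choice([0.02, 0.5], size=500, p=[0.7, 0.3])
            x = np.cumsum(steps * rng.standard_normal(500))
            series = np.column_stack([x, np.zeros(500)])
            speed = F.cursor_speed(series, 75.0)
            expected = brute_force_events(speed, F.SPEED_THRESHOLD, 23)
            got = [(e.onset, e.offset) for e in F.detect_events(series, 75.0)]
            assert got == expected

    def test_empty_series(self):
        assert F.detect_events(np.zeros((1, 2)), 75.0) == []


class TestNetForce:
    def test_single_agent_inverse_square(self):
        field = F.ForceField(np.array([[0.0, 0.0]]), c=0.0)
        f = F.net_force(np.array([1.0, 0.0]), field)
        assert np.allclose(f, [1.0, 0.0])
        f = F.net_force(np.array([0.0, 2.0]), field)
        assert np.allclose(f, [0.0, 0.25])

    def test_symmetric_agents_cancel(self):
        field = F.ForceField(np.array([[1.0, 0.0], [-1.0, 0.0]]), c=0.0)
        assert np.allclose(F.net_force(np.array([0.0, 0.0]), field), 0.0, atol=1e-12)

    @pytest.mark.parametrize("r", [0.5, 1.0, 3.0])
    def test_agent_force_is_gradient_of_potential(self, r):
        """F_a = -grad(1/r): central-difference oracle at several radii."""
        field = F.ForceField(np.array([[0.0, 0.0]]), c=0.0)
        h = np.array([r / np.sqrt(2), r / np.sqrt(2)])
        eps = 1e-6

        def potential(p):
            return 1.0 / np.linalg.norm(p)

        grad = np.array(
            [
                (potential(h + [eps, 0]) - potential(h - [eps, 0])) / (2 * eps),
                (potential(h + [0, eps]) - potential(h - [0, eps])) / (2 * eps),
            ]
        )
        assert np.allclose(F.net_force(h, field), -grad, atol=1e-6)

    def test_boundary_force_pushes_inward_far_out(self):
        field = F.ForceField(np.zeros((0, 2)).reshape(0, 2), c=1.0)
        # no agents: only boundary term; beyond r = sqrt(2) it points inward
        f = F.net_force(np.array([3.0, 0.0]), field)
        assert f[0] < 0

    def test_rotational_equivariance(self, rng):
        origins = rng.uniform(-4, 4, (5, 2))
        h = np.array([1.3, -2.1])
        theta = 1.1
        Rm = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        f1 = F.net_force(h, F.ForceField(origins, c=0.7))
        f2 = F.net_force(Rm @ h, F.ForceField(origins @ Rm.T, c=0.7))
        assert np.allclose(Rm @ f1, f2, atol=1e-10)

    def test_singularity_raises(self):
        field = F.ForceField(np.array([[1.0, 1.0]]))
        with pytest.raises(F.SingularPointError):
            F.net_force(np.array([1.0, 1.0]), field)


class TestEquilibrium:
    def test_symmetric_square_converges_to_center(self):
        origins = np.array([[2.0, 2.0], [-2.0, 2.0], [-2.0, -2.0], [2.0, -2.0]])
        res = F.find_equilibrium(np.array([0.3, 0.1]), F.ForceField(origins, c=0.0))
        assert res["converged"]
        assert np.allclose(res["point"], 0.0, atol=1e-4)

    def test_basin_stability(self):
        origins = np.array([[2.0, 2.0], [-2.0, 2.0], [-2.0, -2.0], [2.0, -2.0]])
        r1 = F.find_equilibrium(np.array([0.2, 0.0]), F.ForceField(origins, c=0.0))
        r2 = F.find_equilibrium(np.array([-0.1, 0.2]), F.ForceField(origins, c=0.0))
        assert np.allclose(r1["point"], r2["point"], atol=1e-3)

    def test_single_agent_with_boundary_on_symmetry_line(self):
        field = F.ForceField(np.array([[3.0, 0.0]]), c=2.0)
        res = F.find_equilibrium(np.array([-1.0, 0.0]), field)
        assert res["converged"]
        assert abs(res["point"][1]) < 1e-4  # on the agent-center line


class TestGridSearch:
    def test_coarse_argmin_matches_fine_grid(self, rng):
        """Grid argmin agrees with a 10x-finer grid within one coarse step
        (nested-grid oracle) on synthetic equilibrium configurations."""
        d_true, c_true = 0.15, 1.0
        hs, refs, oris = [], [], []
        for i in range(60):
            piv = rng.uniform(-5, 5, (6, 2))
            ori = rng.standard_normal((6, 2))
            ori /= np.linalg.norm(ori, axis=1, keepdims=True)
            res = F.find_equilibrium(
                rng.uniform(-1, 1, 2), F.ForceField(piv + d_true * ori, c=c_true)
            )
            if not res["converged"]:
                continue
            hs.append(res["point"])
            refs.append(piv)
            oris.append(ori)
        hs, refs, oris = map(np.array, (hs, refs, oris))

        def median_force(d_grid):
            out = []
            for d_f in d_grid:
                Fv = F.net_force_batch(hs, refs + d_f * oris, c_true)
                out.append(np.median(np.linalg.norm(Fv, axis=1)))
            return np.array(out)

        coarse = F.DEFAULT_D_GRID
        fine = np.round(np.arange(-0.2, 0.5001, 0.005), 10)
        d_coarse = coarse[np.argmin(median_force(coarse))]
        d_fine = fine[np.argmin(median_force(fine))]
        assert abs(d_coarse - d_fine) <= 0.05 + 1e-9
        assert abs(d_fine - d_true) < 0.02

    def test_tie_break_takes_smallest_displacement(self):
        med = np.zeros((1, len(F.DEFAULT_D_GRID)))  # all-tied row
        ci = int(np.argmin(med.min(axis=1)))
        di = int(np.argmin(med[ci]))
        assert F.DEFAULT_D_GRID[di] == F.DEFAULT_D_GRID[0]


class TestStudentT:
    def test_location_recovery(self, rng):
        vals = rng.standard_t(5, size=200) * 0.05 + 0.13
        fit = F.fit_student_t(vals, seed=1)
        assert fit["summary"].mean == pytest.approx(0.13, abs=0.02)


class TestEstimateDisplacement:
    def test_zero_displacement_controller_recovers_zero(self):
        """A controller minimizing the undisplaced field yields per-
        participant argmins at 0 within one grid step."""
        trials_by, chasee_by = {}, {}
        for p in range(3):
            prof = S.ParticipantProfile(d_perceived=0.0, c_boundary=1.0)
            trials, series = [], []
            for t in range(12):
                tr = K.build_trial("LMA", layout_seed=300 + p * 50 + t, motion_seed=400 + p * 50 + t)
                trials.append(tr)
                series.append(S.simulate_lma_chasee(tr, prof, seed=p * 100 + t))
            trials_by[p] = trials
            chasee_by[p] = series
        res = F.estimate_displacement(trials_by, chasee_by, seed=2)
        d_min = res["participants"]["d_min"].to_numpy()
        assert np.all(np.abs(d_min) <= 0.1 + 1e-9)
        assert abs(d_min.mean()) <= 0.075
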
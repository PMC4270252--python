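"""Synthetic behavior generators: means, identities, determinism."""

import numpy as np
import pandas as pd
import pytest

from wolfpack import kinematics as K
from wolfpack import synthetic_participant as S


class TestRecallGenerator:
    def test_noise_free_zero_alpha_is_exact(self):
        prof = S.ParticipantProfile(alpha=np.zeros(4), noise_sd=1e-12)
        dirs = np.array([[0, -1], [1, 0], [0, 1], [1, 0]], float)
        judged = S.simulate_recall_judgment(np.array([2.0, 3.0]), dirs, prof, seed=0)
        assert np.allclose(judged, [2.0, 3.0], atol=1e-9)

    def test_directional_vector_sum(self):
        """alpha=(0,0,0.38,0.14), hand (1,0), orientation (0,1) offsets by
        exactly (0.38, 0.14) without noise."""
        prof = S.ParticipantProfile(alpha=np.array([0, 0, 0.38, 0.14]), noise_sd=1e-12)
        dirs = np.array([[0, -1], [1, 0], [1, 0], [0, 1]], float)
        judged = S.simulate_recall_judgment(np.zeros(2), dirs, prof, seed=0)
        assert np.allclose(judged, [0.38, 0.14], atol=1e-9)

    def test_law_of_large_numbers(self, rng):
        prof = S.ParticipantProfile(alpha=np.array([0.1, 0.2, 0.3, 0.4]), noise_sd=0.5)
        dirs = np.array([[0, -1], [0.6, 0.8], [1, 0], [0, 1]], float)
        expected = (prof.alpha[:, None] * dirs).sum(axis=0)
        draws = np.array(
            [S.simulate_recall_judgment(np.zeros(2), dirs, prof, rng) for _ in range(20000)]
        )
        assert np.allclose(draws.mean(axis=0), expected, atol=3 * 0.5 / np.sqrt(20000))

    def test_absent_predictors_skipped(self):
        prof = S.ParticipantProfile(alpha=np.array([5.0, 5.0, 5.0, 0.2]), noise_sd=1e-12)
        dirs = np.array([[np.nan, np.nan]] * 3 + [[1.0, 0.0]])
        judged = S.simulate_recall_judgment(np.zeros(2), dirs, prof, seed=0)
        assert np.allclose(judged, [0.2, 0.0], atol=1e-9)


class TestOccupancyGenerator:
    def test_degenerate_beta_concentrates(self):
        prof = S.ParticipantProfile(lma_mu=0.5, lma_kappa=1e7)
        df = S.simulate_occupancy(prof, 200, seed=1)
        assert np.allclose(df["w"], 0.5, atol=0.01)

    def test_mean_matches_parameter(self):
        prof = S.ParticipantProfile(lma_mu=0.478, lma_kappa=25.0)
        df = S.simulate_occupancy(prof, 10000, seed=2)
        se = np.sqrt(0.478 * 0.522 / 26) / np.sqrt(10000)
        assert df["w"].mean() == pytest.approx(0.478, abs=4 * se)

    def test_slope_shifts_mean(self):
        prof = S.ParticipantProfile(lma_mu=0.5, lma_kappa=50.0)
        d = np.full(8000, 0.4)
        df = S.simulate_occupancy(prof, 8000, d=d, slope=-0.1, seed=3)
        assert df["w"].mean() == pytest.approx(0.46, abs=0.005)

    def test_determinism(self):
        prof = S.ParticipantProfile()
        a = S.simulate_occupancy(prof, 50, seed=9)
        b = S.simulate_occupancy(prof, 50, seed=9)
        pd.testing.assert_frame_equal(a, b)


class TestBisectionController:
    def test_instant_noise_free_tracks_ref_midpoint(self):
        """Zero displacement, no noise, no lag: the chasee sits at the
        midpoint of the reference positions every frame."""
        prof = S.ParticipantProfile(bis_mu_x=0.0, bis_mu_y=0.0, bis_noise_sd=1e-12, bis_rate=None)
        trial = K.build_trial("bisection", d=0.0, layout_seed=1, motion_seed=2, duration=2.0)
        chasee = S.simulate_bisection_chasee(trial, prof, seed=0)
        mid = 0.5 * (trial.pivot[:, 0] + trial.pivot[:, 1])
        # orientation shifts vanish at zero displacement, so target = pivot midpoint
        assert np.allclose(chasee[1:], mid[1:], atol=1e-6)

    def test_head_on_displacement_moves_midpoint_by_half(self):
        """Per-agent shift 0.3 on the head-on agent displaces the tracked
        point by ~0.15 away from that agent."""
        prof = S.ParticipantProfile(bis_mu_x=0.3, bis_mu_y=0.0, bis_noise_sd=1e-12, bis_rate=None)
        trial = K.build_trial("bisection", d=0.0, layout_seed=3, motion_seed=4, duration=4.0)
        chasee = S.simulate_bisection_chasee(trial, prof, seed=0)
        mid = 0.5 * (trial.pivot[:, 0] + trial.pivot[:, 1])
        i_head = trial.conditions.index("head_on")
        away = mid - trial.pivot[:, i_head]
        away /= np.linalg.norm(away, axis=1, keepdims=True)
        proj = np.einsum("ij,ij->i", chasee - mid, away)
        assert np.mean(proj[150:]) == pytest.approx(0.15, abs=0.03)

    def test_same_seed_identical(self):
        prof = S.ParticipantProfile()
        trial = K.build_trial("bisection", layout_seed=5, motion_seed=6, duration=1.0)
        a = S.simulate_bisection_chasee(trial, prof, seed=42)
        b = S.simulate_bisection_chasee(trial, prof, seed=42)
        assert np.array_equal(a, b)


class TestLmaController:
    def test_determinism_and_containment(self, geometry):
        prof = S.ParticipantProfile(d_perceived=0.1)
        trial = K.build_trial("LMA", layout_seed=7, motion_seed=8, duration=3.0)
        a = S.simulate_lma_chasee(trial, prof, seed=5)
        b = S.simulate_lma_chasee(trial, prof, seed=5)
        assert np.array_equal(a, b)
        assert np.linalg.norm(a, axis=1).max() <= geometry.boundary_radius + 1e-9

    def test_requires_lma_trial(self):
        prof = S.ParticipantProfile()
        trial = K.build_trial("bisection", layout_seed=1, motion_seed=1, duration=1.0)
        with pytest.raises(ValueError):
            S.simulate_lma_chasee(trial, prof)

    def test_avoidance_emerges_with_forward_displacement(self):
        """A forward-perceived center lowers wolfpack occupancy below chance;
        an orientation-blind controller does not."""
        occ = {0.0: [], 0.4: []}
        for dp in occ:
            prof = S.ParticipantProfile(d_perceived=dp)
            for i in range(25):
                trial = K.build_trial("LMA", layout_seed=100 + i, motion_seed=200 + i, duration=8.0)
                ch = S.simulate_lma_chasee(trial, prof, seed=i)
                q = K.quadrant_of(ch)
                occ[dp].append(np.isin(q, trial.wolfpack_quadrants).mean())
        assert np.mean(occ[0.4]) < np.mean(occ[0.0]) - 0.02
        assert np.mean(occ[0.0]) == pytest.approx(0.5, abs=0.08)


class TestPopulation:
    def test_correlation_structure_honored(self):
        corr = np.array([[1.0, 0.6, 0.4], [0.6, 1.0, 0.5], [0.4, 0.5, 1.0]])
        spec = S.PopulationSpec(corr=corr)
        profs = spec.draw(10000, 3)
        from scipy.special import logit

        triples = np.array(
            [[p.alpha[3], p.bis_mu_x, logit(p.lma_mu)] for p in profs]
        )
        sample_corr = np.corrcoef(triples.T)
        assert np.allclose(sample_corr, corr, atol=0.05)

    def test_invalid_correlation_rejected(self):
        bad = np.array([[1.0, 0.99, -0.99], [0.99, 1.0, 0.99], [-0.99, 0.99, 1.0]])
        with pytest.raises(ValueError):
            S.PopulationSpec(corr=bad)

    def test_draw_deterministic(self):
        spec = S.PopulationSpec()
        a = spec.draw(5, 7)
        b = spec.draw(5, 7)
        assert all(np.allclose(x.alpha, y.alpha) for x, y in zip(a, b))
        assert [x.lma_mu for x in a] == [y.lma_mu for y in b]
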
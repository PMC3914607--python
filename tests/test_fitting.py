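"""Parameter estimation: move extraction, exponential and von Mises fits."""

import math

import numpy as np
import pytest

import reefrange as rr
from reefrange.fitting import KAPPA_CAP
from reefrange.movement import discernible_move_probability, truncated_step_mean


class TestExtractMoves:
    def test_psi_ratio(self):
        # 1000 intervals: 8 jumps >= 200 m, the rest stationary
        pts = np.zeros((1001, 2))
        jump_at = np.arange(100, 900, 100)
        x = 0.0
        for i in range(1, 1001):
            if i in set(jump_at + 1):
                x += 300.0
            pts[i, 0] = x
        ext = rr.extract_moves(pts)
        assert len(ext.moves) == 8
        assert ext.psi_hat == pytest.approx(0.008)

    def test_identical_fixes_no_moves(self):
        ext = rr.extract_moves(np.tile([100.0, 100.0], (50, 1)))
        assert len(ext.moves) == 0 and ext.psi_hat == 0.0

    def test_too_few_fixes(self):
        ext = rr.extract_moves(np.array([[0.0, 0.0]]))
        assert ext.moves == [] and ext.n_intervals == 0

    def test_centroid_default_and_turn_wrapping(self):
        pts = np.array([[0.0, 0.0], [400.0, 0.0], [0.0, 0.0], [0.0, 400.0]])
        ext = rr.extract_moves(pts)
        assert ext.center == pytest.approx((100.0, 100.0))
        for m in ext.moves:
            assert -math.pi < m.turn_rel <= math.pi
            assert m.d_prev >= 200.0


class TestFitExponential:
    def test_mle_is_mean(self):
        lam, se = rr.fit_exponential([100.0, 200.0, 300.0])
        assert lam == 200.0
        assert se == pytest.approx(200.0 / math.sqrt(3))

    def test_parameter_recovery(self, rng):
        d = rng.exponential(561.0, size=16_821)
        lam, se = rr.fit_exponential(d)
        assert se == pytest.approx(lam / math.sqrt(16_821))
        assert abs(lam - 561.0) < 3 * 561.0 / math.sqrt(16_821)

    def test_single_value(self):
        lam, se = rr.fit_exponential([437.0])
        assert lam == 437.0 and se == 437.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            rr.fit_exponential([])

    def test_clamped_sample_underestimates_by_truncated_mean(self, rng):
        """Clamping at 6000 m biases the fitted mean to the closed-form
        truncated-exponential mean, not to the true lambda."""
        lam_true = 2000.0  # heavy enough that the clamp bites
        d = np.minimum(rng.exponential(lam_true, size=200_000), 6000.0)
        lam_hat, _ = rr.fit_exponential(d)
        expected = lam_true * (1 - math.exp(-6000.0 / lam_true))
        assert lam_hat == pytest.approx(expected, rel=0.01)
        assert lam_hat < lam_true


class TestFitVonMises:
    def test_uniform_angles_give_near_zero_kappa(self, rng):
        th = rng.uniform(-math.pi, math.pi, size=10_000)
        kappa, se, _ = rr.fit_von_mises(th)
        assert kappa < 0.05

    def test_recovery_at_table_concentration(self, rng):
        th = rng.vonmises(0.0, 3.67, size=100_000)
        kappa, se, mean_dir = rr.fit_von_mises(th)
        assert kappa == pytest.approx(3.67, abs=0.05)
        assert abs(mean_dir) < 0.02

    def test_degenerate_identical_angles_capped(self):
        kappa, se, _ = rr.fit_von_mises(np.full(100, 0.73))
        assert kappa == KAPPA_CAP

    def test_too_few_angles(self):
        with pytest.raises(ValueError):
            rr.fit_von_mises([0.1])


class TestBootstraps:
    def test_subsample_mean_unbiased(self, rng):
        pop = rng.exponential(561.4, size=16_821)
        out = rr.bootstrap_subsample(pop, m=437, B=400, rng=rng)
        assert abs(out["mean"] - pop.mean()) < 3 * out["sd"]

    def test_single_subsample(self, rng):
        pop = rng.exponential(500.0, size=1000)
        out = rr.bootstrap_subsample(pop, m=437, B=1, rng=rng)
        assert out["sd"] == 0.0 and out["B"] == 1

    def test_full_sample_equals_plain_fit(self, rng):
        pop = rng.exponential(500.0, size=437)
        out = rr.bootstrap_subsample(pop, m=437, B=10, rng=rng)
        assert out["sd"] == pytest.approx(0.0, abs=1e-9)
        assert out["mean"] == pytest.approx(pop.mean())

    def test_oversized_subsample_rejected(self, rng):
        with pytest.raises(ValueError):
            rr.bootstrap_subsample(np.ones(10), m=11, B=1, rng=rng)

    def test_pairs_exchangeable_population(self, rng):
        fish = {f"f{i}": rng.exponential(561.0, size=600) for i in range(8)}
        out = rr.bootstrap_pairs(fish, n_pairs=20, m=437, B=50, rng=rng)
        assert out["mean"] == pytest.approx(561.0, rel=0.05)

    def test_pairs_mixture_spans_both_modes(self, rng):
        fish = {f"a{i}": rng.exponential(300.0, size=600) for i in range(4)}
        fish |= {f"b{i}": rng.exponential(800.0, size=600) for i in range(4)}
        out = rr.bootstrap_pairs(fish, n_pairs=40, m=437, B=30, rng=rng)
        assert out["min"] < 450.0 < 650.0 < out["max"]

    def test_pairs_single_iteration(self, rng):
        fish = {"a": rng.exponential(500.0, 500), "b": rng.exponential(500.0, 500)}
        out = rr.bootstrap_pairs(fish, n_pairs=1, m=437, B=1, rng=rng)
        assert out["sd"] == 0.0

    def test_small_pair_flagged_with_replacement(self, rng):
        fish = {"a": rng.exponential(500.0, 100), "b": rng.exponential(500.0, 100)}
        out = rr.bootstrap_pairs(fish, n_pairs=2, m=437, B=5, rng=rng)
        assert out["n_flagged_with_replacement"] == 2


class TestEndToEndRecovery:
    def test_recover_parameters_from_simulated_tracks(self, mutton_snapper):
        """Fitting the three-step model to its own simulated tracks recovers
        psi (suppression-adjusted), lambda (truncation-adjusted) and kappa."""
        world = rr.default_world()
        agents = [
            rr.FishAgent(f"f{i}", mutton_snapper, home_center=(0.0, 0.0))
            for i in range(3)
        ]
        tracks = rr.run_simulation(world, agents, duration=rr.YEAR_SECONDS, rng=2024)
        dists, turns, n_moves, n_int = [], [], 0, 0
        for tr in tracks:
            ext = rr.extract_moves(tr.positions(), center=tr.home_center)
            dists.append(ext.distances)
            turns.append(ext.turn_rels)
            n_moves += len(ext.moves)
            n_int += ext.n_intervals
        assert n_moves >= 10_000
        psi_hat = n_moves / n_int
        psi_expected = discernible_move_probability(mutton_snapper)
        assert psi_hat == pytest.approx(psi_expected, rel=0.10)
        lam_hat, _ = rr.fit_exponential(np.concatenate(dists))
        assert lam_hat == pytest.approx(truncated_step_mean(mutton_snapper), rel=0.05)
        kappa_hat, _, _ = rr.fit_von_mises(np.concatenate(turns))
        assert kappa_hat == pytest.approx(mutton_snapper.kappa, rel=0.10)
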
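"""Movement kernel: headings, step lengths, von Mises turning."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad
from scipy.special import i0

import reefrange as rr
from reefrange.movement import (
    discernible_move_probability,
    truncated_step_mean,
    wrap_angle,
)
from reefrange.params import MovementParameters


class TestHeading:
    @pytest.mark.parametrize(
        "origin,target,expected",
        [
            ((0, 0), (1, 1), math.pi / 4),
            ((0, 0), (-1, 0), math.pi),
            ((2, 3), (5, 7), math.atan2(4, 3)),
        ],
    )
    def test_quadrant_aware(self, origin, target, expected):
        assert rr.heading(origin, target) == pytest.approx(expected)

    def test_coincident_points_error(self):
        with pytest.raises(ValueError, match="undefined heading"):
            rr.heading((3.0, 4.0), (3.0, 4.0))

    @given(
        x=st.floats(-1e5, 1e5), y=st.floats(-1e5, 1e5),
        dx=st.floats(-1e4, 1e4), dy=st.floats(-1e4, 1e4),
    )
    @settings(max_examples=50, derandomize=True)
    def test_range_and_reversal(self, x, y, dx, dy):
        if x + dx == x and y + dy == y:
            return
        th = rr.heading((x, y), (x + dx, y + dy))
        assert -math.pi < th <= math.pi
        back = rr.heading((x + dx, y + dy), (x, y))
        assert math.cos(th - back) == pytest.approx(-1.0, abs=1e-9)


class TestDisplacement:
    @pytest.mark.parametrize(
        "origin,dest,expected",
        [((0, 0), (3, 4), 5.0), ((7.5, -2.0), (7.5, -2.0), 0.0),
         ((100, 200), (400, 600), 500.0)],
    )
    def test_euclidean(self, origin, dest, expected):
        assert rr.displacement(origin, dest) == pytest.approx(expected)


class TestVonMisesDensity:
    def test_uniform_limit(self):
        theta = np.linspace(-3, 3, 7)
        assert rr.von_mises_density(theta, 0.7, 0.0) == pytest.approx(
            np.full(7, 1 / (2 * math.pi))
        )

    def test_peak_value_kappa_one(self):
        # at the mode the density is e^kappa / (2 pi I0(kappa))
        expected = math.e / (2 * math.pi * i0(1.0))
        assert rr.von_mises_density(0.3, 0.3, 1.0) == pytest.approx(expected)
        assert expected == pytest.approx(0.3417, abs=5e-5)

    def test_normalises_to_one(self):
        val, _ = quad(lambda t: rr.von_mises_density(t, 0.5, 3.67), -math.pi, math.pi)
        assert abs(val - 1.0) < 1e-8

    def test_peak_at_mean_direction(self):
        grid = np.linspace(-math.pi, math.pi, 1001)
        dens = rr.von_mises_density(grid, 1.2, 2.0)
        assert grid[np.argmax(dens)] == pytest.approx(1.2, abs=0.01)

    def test_negative_kappa_rejected(self):
        with pytest.raises(ValueError):
            rr.von_mises_density(0.0, 0.0, -1.0)


class TestSampleTurn:
    def test_uniform_when_kappa_zero(self, rng):
        # Rayleigh test of circular uniformity
        th = rr.sample_turn(0.0, 0.0, rng, size=100_000)
        n = len(th)
        rbar = np.hypot(np.cos(th).sum(), np.sin(th).sum()) / n
        z = n * rbar**2
        p = math.exp(-z) * (1 + (2 * z - z**2) / (4 * n))
        assert p > 0.01

    def test_circular_mean_recovers_center(self, rng):
        th = rr.sample_turn(0.0, 3.67, rng, size=100_000)
        mean_dir = math.atan2(np.sin(th).sum(), np.cos(th).sum())
        assert abs(mean_dir) < 0.02

    def test_wrapped_normal_limit(self, rng):
        kappa = 500.0
        th = rr.sample_turn(0.0, kappa, rng, size=100_000)
        assert th.std() == pytest.approx(1 / math.sqrt(kappa), rel=0.05)


class _ForcedRng:
    """Deterministic stand-in driving sample_move through chosen branches."""

    def __init__(self, exponential_value, uniform=0.0):
        self._exp = exponential_value
        self._u = uniform

    def random(self):
        return self._u

    def exponential(self, scale):
        return self._exp

    def vonmises(self, mu, kappa, size=None):
        return mu

    def uniform(self, lo, hi, size=None):
        return 0.0


class TestSampleMove:
    def test_psi_zero_never_moves(self, rng):
        p = MovementParameters(psi=0.0, lambda_mean=561, kappa=3.67)
        assert all(
            rr.sample_move(p, (0, 0), (1000, 0), rng) is None for _ in range(1000)
        )

    def test_forced_draw_clamped_at_max_move(self, red_grouper):
        step = rr.sample_move(red_grouper, (0.0, 0.0), (1000.0, 0.0), _ForcedRng(9000.0))
        assert step is not None and step.d == 6000.0

    def test_forced_small_draw_suppressed(self, red_grouper):
        assert rr.sample_move(red_grouper, (0.0, 0.0), (1000.0, 0.0), _ForcedRng(150.0)) is None

    def test_step_geometry(self, red_grouper):
        step = rr.sample_move(red_grouper, (0.0, 0.0), (1000.0, 0.0), _ForcedRng(500.0))
        assert step.theta_bar == pytest.approx(0.0)
        assert step.dest == pytest.approx((500.0, 0.0))
        assert rr.displacement(step.origin, step.dest) == pytest.approx(step.d)

    def test_realised_move_rate_matches_suppression_adjusted_psi(self, red_grouper, rng):
        n = 200_000
        moved = sum(
            rr.sample_move(red_grouper, (0, 0), (1000, 0), rng) is not None
            for _ in range(n)
        )
        p_exp = discernible_move_probability(red_grouper)
        se = math.sqrt(p_exp * (1 - p_exp) / n)
        assert abs(moved / n - p_exp) < 3 * se

    def test_accepted_step_mean_matches_truncated_closed_form(self, red_grouper, rng):
        steps = [
            rr.sample_move(red_grouper, (0, 0), (1000, 0), rng) for _ in range(400_000)
        ]
        d = np.array([s.d for s in steps if s is not None])
        mu = truncated_step_mean(red_grouper)
        assert d.mean() == pytest.approx(mu, rel=3 / math.sqrt(len(d)))


class TestCenterAffinity:
    def test_time_averaged_distance_decreases_with_kappa(self):
        """Stronger turning concentration -> tighter attachment to the center."""
        mean_r = {}
        for kappa in (0.5, 1.19, 3.67):
            params = MovementParameters(psi=0.05, lambda_mean=561, kappa=kappa)
            rs = []
            for seed in range(3):
                rng = np.random.default_rng(1000 + seed)
                pos = np.zeros(2)
                acc = 0.0
                for _ in range(20_000):
                    step = rr.sample_move(params, pos, (0.0, 0.0), rng)
                    if step is not None:
                        pos = np.array(step.dest)
                    acc += math.hypot(*pos)
                rs.append(acc / 20_000)
            mean_r[kappa] = np.mean(rs)
        assert mean_r[3.67] < mean_r[1.19] < mean_r[0.5]


def test_wrap_angle_range():
    vals = wrap_angle(np.array([-7.0, -math.pi, 0.0, math.pi, 9.0]))
    assert np.all(vals > -math.pi) and np.all(vals <= math.pi)
    assert wrap_angle(math.pi + 0.1) == pytest.approx(-math.pi + 0.1)
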
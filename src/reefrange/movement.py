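"""Three-step movement kernel: move decision, step length, biased turning.

A fish's routine movement within a home range is modelled as a sequence of
independent decisions per time interval:

1. with probability ``psi`` the fish makes a move attempt;
2. the move distance is drawn from an exponential distribution with mean
   ``lambda_mean``, clamped at ``max_move``; draws below ``min_move`` are
   beneath positioning resolution and collapse to "no move";
3. the move direction is drawn from a von Mises distribution centred on
   the bearing from the current position toward the home-range center,
   with concentration ``kappa``.

The von Mises density is the standard one with +kappa*cos(theta - theta_bar)
in the exponent, so the density peaks toward the center and larger kappa
means greater home-range affinity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .params import MovementParameters

__all__ = [
    "Step",
    "heading",
    "displacement",
    "von_mises_density",
    "sample_turn",
    "sample_move",
    "wrap_angle",
]

#: below this concentration the von Mises is numerically uniform
_KAPPA_UNIFORM = 1e-9


@dataclass(frozen=True)
class Step:
    """One realised move.

    ``theta`` is the movement direction, ``theta_bar`` the bearing from the
    origin to the home-range center (both rad, in (-pi, pi]), ``d`` the
    Euclidean displacement in metres.
    """

    origin: tuple[float, float]
    dest: tuple[float, float]
    theta: float
    theta_bar: float
    d: float


def wrap_angle(theta: float | np.ndarray) -> float | np.ndarray:
    """Wrap an angle (rad) into (-pi, pi]."""
    wrapped = np.negative(np.mod(np.negative(theta) + np.pi, 2.0 * np.pi) - np.pi)
    return wrapped


def heading(origin, target) -> float:
    """Quadrant-aware bearing from ``origin`` to ``target``, rad in (-pi, pi].

    Raises
    ------
    ValueError
        If the two points coincide (undefined heading).
    """
    dx = target[0] - origin[0]
    dy = target[1] - origin[1]
    if dx == 0.0 and dy == 0.0:
        raise ValueError("undefined heading: origin and target coincide")
    return math.atan2(dy, dx)


def displacement(origin, dest) -> float:
    """Euclidean distance (m) between two planar positions."""
    return math.hypot(dest[0] - origin[0], dest[1] - origin[1])


def von_mises_density(theta, theta_bar, kappa: float):
    """von Mises density of direction ``theta`` about mean ``theta_bar``.

    Normalised over (-pi, pi]; reduces to the uniform density 1/(2*pi)
    at kappa = 0.  ``theta`` may be an array.
    """
    if kappa < 0:
        raise ValueError(f"kappa must be >= 0, got {kappa}")
    theta = np.asarray(theta, dtype=float)
    # exp(kappa*(cos(.) - 1)) / (2*pi*I0(kappa)*exp(-kappa)) is stable at
    # large kappa; i0e = I0(kappa)*exp(-kappa)
    from scipy.special import i0e

    out = np.exp(kappa * (np.cos(theta - theta_bar) - 1.0)) / (2.0 * np.pi * i0e(kappa))
    return out if out.ndim else float(out)


def sample_turn(theta_bar: float, kappa: float, rng: np.random.Generator, size=None):
    """Sample movement direction(s) from von Mises(theta_bar, kappa).

    Falls back to the uniform circular distribution for kappa below 1e-9.
    """
    if kappa < 0:
        raise ValueError(f"kappa must be >= 0, got {kappa}")
    if kappa < _KAPPA_UNIFORM:
        draw = rng.uniform(-np.pi, np.pi, size=size)
    else:
        draw = rng.vonmises(theta_bar, kappa, size=size)
    return wrap_angle(draw)


def sample_move(
    params: MovementParameters,
    current,
    center,
    rng: np.random.Generator,
) -> Optional[Step]:
    """Draw one interval's movement; ``None`` means "no move".

    With probability 1 - psi no move attempt occurs.  Otherwise the step
    length is drawn from Exponential(lambda_mean), clamped at ``max_move``
    and suppressed to "no move" below ``min_move``; the direction is von
    Mises about the bearing to the home-range center.  When the fish sits
    exactly at its center the bearing is undefined and the direction is
    uniform (the limiting case of vanishing displacement).
    """
    if rng.random() >= params.psi:
        return None
    d = min(rng.exponential(params.lambda_mean), params.max_move)
    if d < params.min_move:
        return None
    try:
        theta_bar = heading(current, center)
    except ValueError:
        theta_bar = rng.uniform(-np.pi, np.pi)
    theta = sample_turn(theta_bar, params.kappa, rng)
    dest = (current[0] + d * math.cos(theta), current[1] + d * math.sin(theta))
    return Step(
        origin=(float(current[0]), float(current[1])),
        dest=dest,
        theta=float(theta),
        theta_bar=float(theta_bar),
        d=float(d),
    )


def discernible_move_probability(params: MovementParameters) -> float:
    """Realised probability of a discernible move per interval.

    Suppression of sub-``min_move`` draws happens after the Bernoulli move
    decision, so the realised rate is psi * P(d >= min_move) under the
    clamped exponential; the clamp does not affect this probability as long
    as ``max_move > min_move``.
    """
    return params.psi * math.exp(-params.min_move / params.lambda_mean)


def truncated_step_mean(params: MovementParameters) -> float:
    """Closed-form mean of accepted step lengths.

    Accepted steps are Exponential(lambda) draws conditioned on
    d >= min_move, with values above max_move clamped to max_move:
    E = min_move + lambda * (1 - exp(-(max_move - min_move)/lambda)).
    """
    lam = params.lambda_mean
    return params.min_move + lam * (1.0 - math.exp(-(params.max_move - params.min_move) / lam))
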
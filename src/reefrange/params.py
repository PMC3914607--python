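"""Movement parameter sets for the three-step home-range movement model.

Each species is described by three behavioural parameters estimated from
passive acoustic telemetry:

* ``psi`` -- probability that the fish makes a discernible move (>= the
  positioning resolution) during one 5-minute interval;
* ``lambda_mean`` -- mean of the exponential distribution of nonzero move
  distances, in metres;
* ``kappa`` -- von Mises concentration of turning angles measured relative
  to the bearing from the fish's current position toward its home-range
  center.  Larger ``kappa`` means stronger affinity to the center.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class MovementParameters:
    """Parameters of the three-step movement kernel for one species.

    Parameters
    ----------
    psi : float
        Probability of a discernible move per interval, in [0, 1].
    lambda_mean : float
        Mean of the exponential step-length distribution (m), > 0.
    kappa : float
        von Mises concentration of turning angles (dimensionless), >= 0.
    max_move : float
        Hard clamp on a single move (m).  The default 6000 m corresponds to
        a sustained swimming speed of 72 km/h over one 5-minute interval,
        beyond which reef fish movement is implausible.
    min_move : float
        Moves below this distance (m) are beneath the spatial resolution of
        acoustic positioning and are treated as "no move".
    interval : float
        Duration of one time step (s).
    species : str
        Free-form label.
    """

    psi: float
    lambda_mean: float
    kappa: float
    max_move: float = 6000.0
    min_move: float = 200.0
    interval: float = 300.0
    species: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.psi <= 1.0:
            raise ValueError(f"psi must be in [0, 1], got {self.psi}")
        if self.lambda_mean <= 0:
            raise ValueError(f"lambda_mean must be > 0, got {self.lambda_mean}")
        if self.kappa < 0:
            raise ValueError(f"kappa must be >= 0, got {self.kappa}")
        if not 0 < self.min_move < self.max_move:
            raise ValueError(
                f"require 0 < min_move < max_move, got {self.min_move}, {self.max_move}"
            )
        if self.interval <= 0:
            raise ValueError(f"interval must be > 0, got {self.interval}")


#: Species-level parameter sets estimated from the Dry Tortugas acoustic
#: tracking program (pooled within species).
SPECIES_PARAMETERS: dict[str, MovementParameters] = {
    "red_grouper": MovementParameters(
        psi=0.0080, lambda_mean=561.0, kappa=3.67, species="red_grouper"
    ),
    "black_grouper": MovementParameters(
        psi=0.0056, lambda_mean=456.0, kappa=1.19, species="black_grouper"
    ),
    "mutton_snapper": MovementParameters(
        psi=0.0576, lambda_mean=608.0, kappa=3.20, species="mutton_snapper"
    ),
}


def get_species(name: str) -> MovementParameters:
    """Look up a packaged species parameter set by name."""
    try:
        return SPECIES_PARAMETERS[name]
    except KeyError:
        known = ", ".join(sorted(SPECIES_PARAMETERS))
        raise KeyError(f"unknown species {name!r}; known: {known}") from None
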
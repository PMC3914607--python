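"""Grid world, fish agents, and one-year path generation ("Sim-Actual").

The study region is tiled by square cells (default 200 m).  Fish positions
are always snapped to cell centers; the lattice is anchored so that cell
centers fall on integer multiples of the cell size.  Movement itself is
unconstrained by depth or land -- depth is carried only as metadata -- and
the world auto-expands rather than reflecting at its edges, since a fish
may leave the mapped region.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .movement import sample_turn, heading
from .params import MovementParameters

__all__ = [
    "GridWorld",
    "FishAgent",
    "TrackRecord",
    "build_world",
    "instantiate_cohort",
    "run_simulation",
]

#: one year of 5-minute intervals
YEAR_SECONDS = 365 * 24 * 3600


@dataclass
class GridWorld:
    """Square-cell tiling of a rectangular region.

    ``extent`` is (xmin, ymin, xmax, ymax) in metres.  Cell ids are assigned
    row-major from the south-west corner.  The depth field is metadata only.
    """

    cell_size: float
    extent: tuple[float, float, float, float]
    depth_field: Optional[Callable[[np.ndarray, np.ndarray], np.ndarray]] = None

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError(f"cell_size must be > 0, got {self.cell_size}")
        xmin, ymin, xmax, ymax = self.extent
        if xmax <= xmin or ymax <= ymin:
            raise ValueError("extent must have positive area")

    @property
    def shape(self) -> tuple[int, int]:
        xmin, ymin, xmax, ymax = self.extent
        nx = int(round((xmax - xmin) / self.cell_size))
        ny = int(round((ymax - ymin) / self.cell_size))
        return ny, nx

    @property
    def n_cells(self) -> int:
        ny, nx = self.shape
        return ny * nx

    def snap(self, xy: np.ndarray) -> np.ndarray:
        """Snap continuous coordinates to the nearest cell center."""
        return np.round(np.asarray(xy, dtype=float) / self.cell_size) * self.cell_size

    def cell_id(self, x: float, y: float) -> int:
        """Deterministic row-major id of the cell containing (x, y)."""
        xmin, ymin, _, _ = self.extent
        ny, nx = self.shape
        ix = int((x - xmin) // self.cell_size)
        iy = int((y - ymin) // self.cell_size)
        ix = min(max(ix, 0), nx - 1)
        iy = min(max(iy, 0), ny - 1)
        return iy * nx + ix

    def depth(self, x, y):
        """Depth (m) at coordinates; synthetic smooth field by default."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if self.depth_field is not None:
            return self.depth_field(x, y)
        # gentle synthetic shelf: 10-30 m with long-wavelength undulation
        return 20.0 + 8.0 * np.sin(x / 4000.0) * np.cos(y / 5000.0)

    def expand_to(self, x: float, y: float, margin: float = 0.0) -> None:
        """Grow the extent so that (x, y) lies inside it."""
        xmin, ymin, xmax, ymax = self.extent
        xmin = min(xmin, x - margin)
        ymin = min(ymin, y - margin)
        xmax = max(xmax, x + margin)
        ymax = max(ymax, y + margin)
        self.extent = (xmin, ymin, xmax, ymax)


def build_world(
    extent: tuple[float, float, float, float],
    cell_size: float = 200.0,
    depth_field: Optional[Callable] = None,
) -> GridWorld:
    """Construct a grid world over ``extent`` (xmin, ymin, xmax, ymax)."""
    return GridWorld(cell_size=cell_size, extent=tuple(extent), depth_field=depth_field)


def default_world(center: tuple[float, float] = (0.0, 0.0), half_size: float = 10000.0,
                  cell_size: float = 200.0) -> GridWorld:
    """A synthetic rectangular region >= 20 km on a side centred on the array."""
    cx, cy = center
    return build_world(
        (cx - half_size, cy - half_size, cx + half_size, cy + half_size), cell_size
    )


@dataclass
class FishAgent:
    """One simulated fish: a fixed home-range center and movement parameters."""

    fish_id: str
    params: MovementParameters
    home_center: tuple[float, float]
    current: tuple[float, float] = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.current is None:
            self.current = tuple(self.home_center)

    @property
    def species(self) -> str:
        return self.params.species


@dataclass
class TrackRecord:
    """A one-year (or shorter) path recorded at every interval.

    Positions are piecewise constant between moves, so the track is stored
    as dwell segments: ``move_idx[k]`` is the interval index at which the
    fish arrived at ``move_xy[k]``; it remains there until the next move.
    ``move_idx[0] == 0`` always (the starting position).
    """

    fish_id: str
    interval: float
    n_intervals: int
    move_idx: np.ndarray  # (k,) int
    move_xy: np.ndarray  # (k, 2) float
    home_center: tuple[float, float] = (0.0, 0.0)
    species: str = ""

    def positions(self) -> np.ndarray:
        """Materialise one (x, y) row per interval."""
        out = np.empty((self.n_intervals, 2), dtype=float)
        bounds = np.append(self.move_idx, self.n_intervals)
        for k in range(len(self.move_idx)):
            out[bounds[k]: bounds[k + 1]] = self.move_xy[k]
        return out

    def weighted_points(self) -> tuple[np.ndarray, np.ndarray]:
        """Distinct positions with their dwell weights (interval counts)."""
        dwell = np.diff(np.append(self.move_idx, self.n_intervals)).astype(float)
        pts, inv = np.unique(self.move_xy, axis=0, return_inverse=True)
        w = np.zeros(len(pts))
        np.add.at(w, inv, dwell)
        return pts, w

    def move_points(self) -> np.ndarray:
        """Positions at move events only (including the start)."""
        return self.move_xy.copy()

    def to_frame(self, t0: str = "2000-01-01") -> pd.DataFrame:
        """Full per-interval table: fish_id, timestamp, x_m, y_m, moved."""
        pos = self.positions()
        t = pd.date_range(t0, periods=self.n_intervals, freq=f"{int(self.interval)}s")
        moved = np.zeros(self.n_intervals, dtype=int)
        moved[self.move_idx[1:]] = 1
        return pd.DataFrame(
            {
                "fish_id": self.fish_id,
                "timestamp": t,
                "x_m": pos[:, 0],
                "y_m": pos[:, 1],
                "moved": moved,
            }
        )


def instantiate_cohort(
    world: GridWorld,
    array,
    species_params: MovementParameters,
) -> list[FishAgent]:
    """One agent per receiver, home range centred atop the receiver's cell."""
    receivers = list(array)
    if not receivers:
        raise ValueError("receiver array is empty")
    agents = []
    for rec in receivers:
        center = tuple(world.snap(np.array([rec.x, rec.y])))
        agents.append(
            FishAgent(
                fish_id=f"{species_params.species or 'fish'}_{rec.receiver_id}",
                params=species_params,
                home_center=center,
            )
        )
    return agents


def _simulate_agent(
    world: GridWorld,
    agent: FishAgent,
    n_intervals: int,
    rng: np.random.Generator,
) -> TrackRecord:
    params = agent.params
    # event-driven: draw the Bernoulli move screen for all intervals at once,
    # then only iterate over move attempts
    attempts = np.flatnonzero(rng.random(n_intervals) < params.psi)
    pos = np.array(agent.home_center, dtype=float)
    idx = [0]
    xy = [pos.copy()]
    cell = world.cell_size
    for t in attempts:
        if t == 0:
            continue
        d = min(rng.exponential(params.lambda_mean), params.max_move)
        if d < params.min_move:
            continue
        r = math.hypot(agent.home_center[0] - pos[0], agent.home_center[1] - pos[1])
        if r < 1e-9:
            theta_bar = rng.uniform(-np.pi, np.pi)
        else:
            theta_bar = heading(pos, agent.home_center)
        theta = sample_turn(theta_bar, params.kappa, rng)
        dest = pos + d * np.array([math.cos(theta), math.sin(theta)])
        dest = world.snap(dest)
        # snapping can push a clamped move slightly past max_move; re-clamp
        # by retreating along the move direction one cell at a time
        while math.hypot(dest[0] - pos[0], dest[1] - pos[1]) > params.max_move:
            dest = world.snap(dest - cell * np.array([math.cos(theta), math.sin(theta)]))
        if dest[0] == pos[0] and dest[1] == pos[1]:
            continue
        pos = dest
        world.expand_to(pos[0], pos[1], margin=cell)
        idx.append(int(t))
        xy.append(pos.copy())
    agent.current = tuple(pos)
    return TrackRecord(
        fish_id=agent.fish_id,
        interval=params.interval,
        n_intervals=n_intervals,
        move_idx=np.asarray(idx, dtype=int),
        move_xy=np.asarray(xy, dtype=float),
        home_center=tuple(agent.home_center),
        species=agent.species,
    )


def run_simulation(
    world: GridWorld,
    agents: Sequence[FishAgent],
    duration: float = YEAR_SECONDS,
    interval: Optional[float] = None,
    rng: np.random.Generator | int | None = None,
) -> list[TrackRecord]:
    """Simulate every agent for ``duration`` seconds; one position per interval.

    ``duration`` must be a whole multiple of the interval.  Reproducible for
    a given seed: each agent gets an independent child generator derived
    from ``rng``.
    """
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    tracks = []
    for agent in agents:
        step = interval if interval is not None else agent.params.interval
        n_intervals = duration / step
        if abs(n_intervals - round(n_intervals)) > 1e-9:
            raise ValueError("duration must be a multiple of the interval")
        child = np.random.default_rng(rng.integers(2**31))
        tracks.append(_simulate_agent(world, agent, int(round(n_intervals)), child))
    return tracks
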
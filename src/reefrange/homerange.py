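"""Home-range estimation: minimum convex polygon and kernel density.

Two estimators of home-range area from position fixes:

* **MCP** -- the area of the convex hull of all fixes (the 100% minimum
  convex polygon).  Collinear fix sets have zero hull area and are flagged
  ``linear`` rather than reported as 0 km².

* **KD** -- a bivariate Gaussian kernel density with an unconstrained
  (full-matrix) bandwidth chosen by smoothed cross-validation (SCV),
  evaluated on a 20 m grid.  The x% home range is the smallest set of grid
  cells containing x% of the total density volume.  Passive acoustic
  telemetry produces heavily duplicated fixes, which is the regime in which
  cross-validated bandwidth selection degenerates; the selector therefore
  operates on binned data with multiplicity weights and hard failures are
  reported as ``failed`` estimates instead of raising.

The SCV criterion for bandwidth matrix H with pilot G is

    SCV(H) = (4 pi)^(-d/2) n^(-1) |H|^(-1/2)
             + n^(-2) sum_{i,j} [phi_{2H+2G} - 2 phi_{H+2G} + phi_{2G}](X_i - X_j)

with phi_S the centred bivariate normal density with covariance S.  The
double sum runs over all pairs including i = j.  On binned data the pair
differences live on a lattice, so the sum collapses to an autocorrelation
of the bin-count grid (computed once by FFT) against the kernel evaluated
on the difference lattice; each objective evaluation is then linear in the
number of occupied difference cells.  The pilot is the normal-scale matrix
G = n^(-1/3) * S with S the weighted sample covariance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.signal import fftconvolve
from scipy.spatial import ConvexHull, QhullError

__all__ = [
    "HomeRangeEstimate",
    "mcp_area",
    "mcp_polygon",
    "kd_homerange",
    "scv_bandwidth",
    "cumulative_area_curve",
    "classify_asymptote",
]

M2_PER_KM2 = 1e6


@dataclass
class HomeRangeEstimate:
    """One home-range area estimate.

    ``level`` is 100 for MCP and the volume-contour percentage for KD.
    ``bandwidth`` (KD only) is the 2x2 bandwidth matrix in m^2; ``status``
    is ``ok``, ``linear`` (collinear MCP) or ``failed`` (KD degenerate).
    """

    fish_id: str
    method: str
    level: float
    area_km2: float
    n_points: int
    status: str = "ok"
    bandwidth: Optional[np.ndarray] = None
    grid_cell: Optional[float] = None

    @property
    def ok(self) -> bool:
        return self.status == "ok"


# ---------------------------------------------------------------------------
# MCP


def _unique_points(points) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array")
    if len(pts) == 0:
        raise ValueError("need at least one point")
    return np.unique(pts, axis=0)


def mcp_area(points, fish_id: str = "") -> HomeRangeEstimate:
    """100% minimum convex polygon area (km²) of a set of position fixes.

    Duplicate points are ignored; fewer than three distinct points, or a
    collinear set, yields status ``linear`` with zero area.
    """
    pts = _unique_points(points)
    if len(pts) < 3:
        return HomeRangeEstimate(fish_id, "MCP", 100.0, 0.0, len(pts), "linear")
    try:
        hull = ConvexHull(pts)
    except QhullError:
        return HomeRangeEstimate(fish_id, "MCP", 100.0, 0.0, len(pts), "linear")
    area = hull.volume / M2_PER_KM2  # 2-D "volume" is the area
    status = "linear" if area == 0.0 else "ok"
    return HomeRangeEstimate(fish_id, "MCP", 100.0, float(area), len(pts), status)


def mcp_polygon(points):
    """Convex hull of the fixes as a shapely polygon (None if degenerate)."""
    from shapely.geometry import Polygon

    pts = _unique_points(points)
    if len(pts) < 3:
        return None
    try:
        hull = ConvexHull(pts)
    except QhullError:
        return None
    return Polygon(pts[hull.vertices])


# ---------------------------------------------------------------------------
# Kernel density with SCV bandwidth


def _bin_points(
    pts: np.ndarray, weights: np.ndarray, cell: float, pad_cells: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram points onto a square-cell grid; returns (grid, origin)."""
    lo = np.floor(pts.min(axis=0) / cell).astype(int) - pad_cells
    hi = np.floor(pts.max(axis=0) / cell).astype(int) + pad_cells
    shape = (hi - lo + 1).astype(int)
    idx = np.floor(pts / cell).astype(int) - lo
    grid = np.zeros(shape, dtype=float)
    np.add.at(grid, (idx[:, 0], idx[:, 1]), weights)
    origin = (lo + 0.5) * cell  # centre of cell (0, 0)
    return grid, origin


def _phi2(delta: np.ndarray, cov: np.ndarray) -> np.ndarray:
    """Centred bivariate normal density at rows of ``delta``."""
    det = cov[0, 0] * cov[1, 1] - cov[0, 1] * cov[1, 0]
    if det <= 0:
        return np.full(len(delta), np.inf)
    inv = np.array([[cov[1, 1], -cov[0, 1]], [-cov[1, 0], cov[0, 0]]]) / det
    q = (
        inv[0, 0] * delta[:, 0] ** 2
        + 2.0 * inv[0, 1] * delta[:, 0] * delta[:, 1]
        + inv[1, 1] * delta[:, 1] ** 2
    )
    return np.exp(-0.5 * q) / (2.0 * np.pi * math.sqrt(det))


def _chol_to_H(p: np.ndarray) -> np.ndarray:
    l11, l21, l22 = math.exp(p[0]), p[1], math.exp(p[2])
    L = np.array([[l11, 0.0], [l21, l22]])
    return L @ L.T


def scv_bandwidth(
    points,
    weights=None,
    cell: float = 20.0,
) -> tuple[Optional[np.ndarray], str]:
    """Smoothed-cross-validation bandwidth matrix on binned data.

    Returns (H, status).  H is ``None`` with status ``failed`` when the
    sample is degenerate (fewer than 5 distinct points, singular
    covariance) or the optimiser lands on a bandwidth below the bin
    resolution -- the regime of fixes massed at one or two sites.
    """
    pts = np.asarray(points, dtype=float)
    w = np.ones(len(pts)) if weights is None else np.asarray(weights, dtype=float)
    if len(np.unique(pts, axis=0)) < 5:
        return None, "failed"
    n = float(w.sum())
    mu = np.average(pts, axis=0, weights=w)
    dev = pts - mu
    S = (dev * w[:, None]).T @ dev / n
    det_S = S[0, 0] * S[1, 1] - S[0, 1] ** 2
    if det_S <= 0 or S[0, 0] <= 0 or S[1, 1] <= 0:
        return None, "failed"

    grid, _ = _bin_points(pts, w, cell)
    corr = fftconvolve(grid, grid[::-1, ::-1])
    nz = np.nonzero(corr > 1e-12 * n * n)
    cvals = corr[nz]
    centre = np.array(grid.shape) - 1
    delta = (np.stack(nz, axis=1) - centre) * cell

    G = S * n ** (-1.0 / 3.0)  # normal-scale pilot

    def objective(p: np.ndarray) -> float:
        H = _chol_to_H(p)
        det_H = H[0, 0] * H[1, 1] - H[0, 1] ** 2
        if det_H <= 0 or not np.isfinite(det_H):
            return np.inf
        t1 = 1.0 / (4.0 * np.pi * n * math.sqrt(det_H))
        psi = (
            _phi2(delta, 2.0 * H + 2.0 * G)
            - 2.0 * _phi2(delta, H + 2.0 * G)
            + _phi2(delta, 2.0 * G)
        )
        t2 = float(np.dot(cvals, psi)) / (n * n)
        return t1 + t2

    # start from the bivariate normal-scale bandwidth
    H0 = S * n ** (-1.0 / 3.0)
    L0 = np.linalg.cholesky(H0)
    p0 = np.array([math.log(L0[0, 0]), L0[1, 0], math.log(L0[1, 1])])
    res = minimize(objective, p0, method="Nelder-Mead",
                   options={"xatol": 1e-3, "fatol": 1e-12, "maxiter": 400})
    H = _chol_to_H(res.x)
    eigs = np.linalg.eigvalsh(H)
    if not np.all(np.isfinite(H)) or eigs[0] < (cell / 2.0) ** 2:
        return None, "failed"
    return H, "ok"


def _kd_density_grid(
    pts: np.ndarray, w: np.ndarray, H: np.ndarray, cell: float
) -> np.ndarray:
    """Weighted KD evaluated on the cell grid (integrates to ~1)."""
    sigma_max = math.sqrt(np.linalg.eigvalsh(H)[1])
    pad = int(math.ceil(4.0 * sigma_max / cell)) + 1
    grid, _ = _bin_points(pts, w, cell, pad_cells=pad)
    k = int(math.ceil(4.0 * sigma_max / cell))
    ax = np.arange(-k, k + 1) * cell
    gx, gy = np.meshgrid(ax, ax, indexing="ij")
    kd = _phi2(np.stack([gx.ravel(), gy.ravel()], axis=1), H).reshape(gx.shape)
    dens = fftconvolve(grid, kd, mode="same") / w.sum()
    return np.maximum(dens, 0.0)


def _volume_contour_areas(dens: np.ndarray, cell: float, levels) -> dict[float, float]:
    """Area (km²) of the smallest density region holding each volume level."""
    mass = np.sort(dens.ravel())[::-1] * cell * cell
    total = mass.sum()
    if total <= 0:
        return {lv: 0.0 for lv in levels}
    cum = np.cumsum(mass) / total
    out = {}
    for lv in levels:
        k = int(np.searchsorted(cum, lv / 100.0)) + 1
        out[lv] = k * cell * cell / M2_PER_KM2
    return out


def kd_homerange(
    points,
    weights=None,
    levels: Sequence[float] = (50.0, 90.0, 95.0),
    cell: float = 20.0,
    bandwidth: Union[str, float, np.ndarray] = "SCV",
    fish_id: str = "",
) -> list[HomeRangeEstimate]:
    """Kernel-density home-range areas at the requested volume levels.

    ``bandwidth`` is ``"SCV"`` (default), a scalar standard deviation h in
    metres (isotropic, H = h² I), or an explicit 2x2 matrix in m².  A
    degenerate SCV fit returns ``failed`` estimates with no area.
    """
    pts = np.asarray(points, dtype=float)
    w = np.ones(len(pts)) if weights is None else np.asarray(weights, dtype=float)
    levels = sorted(float(lv) for lv in levels)
    n_distinct = len(np.unique(pts, axis=0))

    status = "ok"
    H: Optional[np.ndarray]
    if isinstance(bandwidth, str):
        if bandwidth.upper() != "SCV":
            raise ValueError(f"unknown bandwidth method {bandwidth!r}")
        H, status = scv_bandwidth(pts, w, cell=cell)
    elif np.isscalar(bandwidth):
        H = np.eye(2) * float(bandwidth) ** 2
    else:
        H = np.asarray(bandwidth, dtype=float)
        if H.shape != (2, 2):
            raise ValueError("bandwidth matrix must be 2x2")

    if status != "ok" or H is None:
        return [
            HomeRangeEstimate(fish_id, "KD", lv, float("nan"), n_distinct,
                              "failed", None, cell)
            for lv in levels
        ]

    dens = _kd_density_grid(pts, w, H, cell)
    areas = _volume_contour_areas(dens, cell, levels)
    return [
        HomeRangeEstimate(fish_id, "KD", lv, areas[lv], n_distinct, "ok", H, cell)
        for lv in levels
    ]


# ---------------------------------------------------------------------------
# Area-observation curves


def cumulative_area_curve(
    times,
    points,
    method: str = "MCP",
    step: float = 30.4375 * 86400.0,
    weights=None,
    **kd_kwargs,
) -> pd.DataFrame:
    """Estimated home-range area versus elapsed tracking time.

    The estimator is applied to all fixes up to each multiple of ``step``
    seconds (default: one mean month).  Returns a table with columns
    ``elapsed_s``, ``area_km2`` and ``pct_of_final``; estimator failures at
    a step leave a NaN gap.  The MCP curve is non-decreasing by
    construction (the hull of a superset contains the hull of the subset).
    """
    t = np.asarray(times, dtype=float)
    pts = np.asarray(points, dtype=float)
    if len(t) != len(pts):
        raise ValueError("times and points must align")
    w = None if weights is None else np.asarray(weights, dtype=float)
    span = t.max() - t.min()
    if span < step:
        raise ValueError("track must span at least two steps")
    n_steps = int(math.floor(span / step)) + 1
    rows = []
    order = np.argsort(t)
    t, pts = t[order], pts[order]
    if w is not None:
        w = w[order]
    for k in range(1, n_steps + 1):
        cut = t.min() + k * step
        sel = t <= cut
        sub = pts[sel]
        if method.upper() == "MCP":
            est = mcp_area(sub)
            area = est.area_km2 if est.status != "failed" else float("nan")
        else:
            sub_w = None if w is None else w[sel]
            ests = kd_homerange(sub, weights=sub_w, levels=(95.0,), **kd_kwargs)
            area = ests[0].area_km2
        rows.append((min(cut, t.max()) - t.min(), area))
    df = pd.DataFrame(rows, columns=["elapsed_s", "area_km2"])
    final = df["area_km2"].dropna().iloc[-1] if df["area_km2"].notna().any() else np.nan
    df["pct_of_final"] = 100.0 * df["area_km2"] / final if final and final > 0 else np.nan
    return df


def classify_asymptote(
    areas: Sequence[float], tol_yes: float = 0.05, tol_maybe: float = 0.15
) -> str:
    """Classify an area-observation curve as asymptotic.

    ``Yes`` if the relative area increase over the final step is below
    ``tol_yes``; ``Maybe`` below ``tol_maybe``; otherwise ``No``.  The
    thresholds are explicit configuration: no standard cut-offs exist in
    the home-range literature.
    """
    a = [x for x in np.asarray(areas, dtype=float) if np.isfinite(x)]
    if len(a) < 2:
        return "No"
    prev, last = a[-2], a[-1]
    if prev <= 0:
        return "Yes" if last <= 0 else "No"
    rel = (last - prev) / prev
    if rel < tol_yes:
        return "Yes"
    if rel < tol_maybe:
        return "Maybe"
    return "No"
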
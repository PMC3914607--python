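"""Position estimation from multi-receiver detection records.

Detections are grouped into 5-minute batches per fish; each batch yields one
position fix.  The estimator is a model-weighted centroid: receiver
positions are averaged with weights w_i = count_i / p_at(r_i), where the
detection probability is evaluated at the distance from a provisional fix
to each receiver and refined over two passes (the first pass uses raw
counts).  Inverse-probability weighting compensates for the fall-off of
detection probability with distance, which otherwise drags fixes toward
whichever receiver happens to be closest.  A single-receiver batch fixes
the fish at that receiver.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .receivers import DetectionModel, ReceiverArray
from .world import TrackRecord

__all__ = ["PositionFix", "batch_detections", "estimate_position", "fixes_for_track"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PositionFix:
    fish_id: str
    batch_start: float  # s since track origin
    x: float
    y: float
    n_receivers: int
    total_weight: float


def batch_detections(log: pd.DataFrame, batch: float = 300.0) -> pd.DataFrame:
    """Group detection records into (fish, batch-index) groups.

    Accepts either a ``timestamp`` column (parseable datetimes; unparseable
    rows are rejected with a warning) or an ``interval_idx`` column already
    aligned to the batch length.  Returns the input with an added
    ``batch_idx`` column; empty batches simply do not appear.
    """
    if batch <= 0:
        raise ValueError("batch must be > 0")
    log = log.copy()
    if "timestamp" in log.columns:
        ts = pd.to_datetime(log["timestamp"], errors="coerce", format="mixed")
        bad = ts.isna()
        if bad.any():
            warnings.warn(f"dropping {int(bad.sum())} records with unparseable timestamps")
            log = log[~bad]
            ts = ts[~bad]
        # anchor batches on the epoch clock so batch membership does not
        # depend on when the first detection happened
        epoch_s = (ts - pd.Timestamp("1970-01-01")).dt.total_seconds()
        log["batch_idx"] = (epoch_s // batch).astype(int)
    elif "interval_idx" in log.columns:
        # interval index is in units of the recording interval; when the
        # batch equals that interval this is the identity
        log["batch_idx"] = log["interval_idx"].astype(int)
    else:
        raise ValueError("detection log needs a 'timestamp' or 'interval_idx' column")
    return log


def estimate_position(
    batch: pd.DataFrame,
    array: ReceiverArray,
    model: DetectionModel,
    n_passes: int = 2,
) -> Optional[PositionFix]:
    """One fix from the detections of a single (fish, batch) group."""
    counts = batch.groupby("receiver_id")["expected_count"].sum()
    counts = counts[counts > 0]
    if counts.empty:
        return None
    pos_by_id = {r.receiver_id: (r.x, r.y) for r in array}
    pts = np.array([pos_by_id[rid] for rid in counts.index], dtype=float)
    c = counts.to_numpy(dtype=float)
    xy, w = _weighted_fix(pts, c, model, n_passes)
    fish = batch["fish_id"].iloc[0] if "fish_id" in batch.columns else ""
    start = float(batch["batch_idx"].iloc[0]) if "batch_idx" in batch.columns else 0.0
    return PositionFix(
        fish_id=str(fish),
        batch_start=start,
        x=float(xy[0]),
        y=float(xy[1]),
        n_receivers=len(c),
        total_weight=float(w),
    )


def _weighted_fix(
    pts: np.ndarray, counts: np.ndarray, model: DetectionModel, n_passes: int = 2
) -> tuple[np.ndarray, float]:
    """Two-pass inverse-detection-probability weighted centroid."""
    if len(pts) == 1:
        return pts[0], float(counts[0])
    w = counts.astype(float)
    xy = np.average(pts, axis=0, weights=w)
    for _ in range(max(n_passes - 1, 0)):
        r = np.hypot(pts[:, 0] - xy[0], pts[:, 1] - xy[1])
        p = np.maximum(model.p_at(r), 1e-12)
        w = counts / p
        xy = np.average(pts, axis=0, weights=w)
    return xy, float(np.sum(w))


def estimate_positions(
    log: pd.DataFrame,
    array: ReceiverArray,
    model: DetectionModel,
    batch: float = 300.0,
) -> pd.DataFrame:
    """Fix table (fish_id, batch_idx, x_m, y_m, n_receivers) from a log."""
    batched = batch_detections(log, batch)
    rows = []
    for (fish, b), grp in batched.groupby(["fish_id", "batch_idx"], sort=True):
        fix = estimate_position(grp, array, model)
        if fix is None:
            continue
        rows.append((fish, int(b), fix.x, fix.y, fix.n_receivers))
    return pd.DataFrame(rows, columns=["fish_id", "batch_idx", "x_m", "y_m", "n_receivers"])


def fixes_for_track(
    track: TrackRecord,
    array: ReceiverArray,
    model: DetectionModel,
    threshold: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sim-Detect fixes for a simulated track, with dwell weights.

    Because expected detections are deterministic and the fish position is
    piecewise constant between moves, every interval of a dwell segment
    yields the identical fix; this computes each segment's fix once and
    returns (points (m, 2), weights in intervals, n_receivers per point,
    dwell-segment index per point).  Segments out of range of every
    receiver produce no fix.
    """
    from scipy.spatial import cKDTree

    pos = array.positions
    tree = cKDTree(pos)
    reach = model.max_range(threshold)
    bounds = np.append(track.move_idx, track.n_intervals)
    dwell = np.diff(bounds).astype(float)
    out_pts, out_w, out_n, out_seg = [], [], [], []
    neighbours = tree.query_ball_point(track.move_xy, reach)
    for k, nbrs in enumerate(neighbours):
        if not nbrs:
            continue
        d = np.hypot(pos[nbrs, 0] - track.move_xy[k, 0], pos[nbrs, 1] - track.move_xy[k, 1])
        counts = (track.interval / model.ping_interval) * model.p_at(d)
        keep = counts > threshold
        if not np.any(keep):
            continue
        pts = pos[np.asarray(nbrs)[keep]]
        xy, _ = _weighted_fix(pts, np.atleast_1d(counts)[keep], model)
        out_pts.append(xy)
        out_w.append(dwell[k])
        out_n.append(int(np.sum(keep)))
        out_seg.append(k)
    if not out_pts:
        return (np.empty((0, 2)), np.empty(0), np.empty(0, dtype=int),
                np.empty(0, dtype=int))
    return (np.array(out_pts), np.array(out_w), np.array(out_n),
            np.array(out_seg, dtype=int))
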
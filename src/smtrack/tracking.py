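"""Stage 4: frame-to-frame trajectory linking.

Localizations are linked into tracks with a per-frame-pair optimal
(Hungarian) assignment restricted to pairs within a maximum distance --
deterministic and order-independent, unlike greedy nearest-neighbor
matching.  Tracks whose emitter goes dark may be bridged across up to
``max_gap`` missing frames; the allowed linking radius grows with the square
root of the elapsed frame interval, the scaling expected for diffusive
motion.  Tracks shorter than ``min_length`` points are discarded.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .core_io import ResultTable

__all__ = ["link_nearest_neighbor", "assign_frame_pair"]


def assign_frame_pair(a: np.ndarray, b: np.ndarray, max_dist: float) -> list:
    """Optimal one-to-one pairing between two position sets.

    Returns index pairs ``(i, j)`` into ``a`` and ``b`` such that the pairing
    has maximum cardinality among pairings with all distances <= ``max_dist``
    and, among those, minimum total distance.
    """
    if len(a) == 0 or len(b) == 0:
        return []
    d = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=2)
    feasible = d <= max_dist
    if not feasible.any():
        return []
    # infeasible links get a cost so large that any feasible link is always
    # preferred; the assignment then maximizes pair count, then distance sum
    big = max_dist * (len(a) + len(b) + 1) * 1e6 + 1.0
    cost = np.where(feasible, d, big)
    rows, cols = linear_sum_assignment(cost)
    return [(int(i), int(j)) for i, j in zip(rows, cols) if feasible[i, j]]


def link_nearest_neighbor(
    locs,
    max_dist: float,
    max_gap: int = 0,
    min_length: int = 1,
) -> ResultTable:
    """Link a localization table into trajectories.

    Parameters
    ----------
    locs
        Localization table (:class:`ResultTable` or DataFrame) with at least
        ``frame, x, y`` columns.
    max_dist
        Maximum link distance (px) per single-frame interval; for a gap of
        ``g`` elapsed frames the radius is ``max_dist * sqrt(g)``.
    max_gap
        Number of consecutive frames a track may go undetected and still be
        continued.
    min_length
        Minimum number of points for a track to be kept.

    Returns
    -------
    ResultTable
        Stage ``tracking`` table with columns ``track_id, frame, x, y,
        loc_index`` (``loc_index`` is the row index into ``locs``), sorted by
        ``(track_id, frame)``.  Track ids are assigned in order of track
        start ``(frame, y, x)``.
    """
    if max_dist <= 0:
        raise ValueError("max_dist must be positive")
    if max_gap < 0 or min_length < 1:
        raise ValueError("max_gap must be >= 0 and min_length >= 1")
    df = locs.df if isinstance(locs, ResultTable) else locs
    empty = ResultTable(
        pd.DataFrame({c: pd.Series(dtype=t) for c, t in
                      [("track_id", int), ("frame", int), ("x", float),
                       ("y", float), ("loc_index", int)]}),
        "tracking",
    )
    if len(df) == 0:
        return empty

    frames = df["frame"].to_numpy().astype(int)
    xs = df["x"].to_numpy().astype(float)
    ys = df["y"].to_numpy().astype(float)
    order = np.lexsort((xs, ys, frames))  # deterministic processing order

    by_frame: dict = {}
    for idx in order:
        by_frame.setdefault(int(frames[idx]), []).append(int(idx))

    open_tracks: list = []  # dicts: points [(frame, x, y, loc_index)], last_*
    closed: list = []

    for f in range(frames.min(), frames.max() + 1):
        rows = by_frame.get(f, [])
        pts = np.array([[xs[i], ys[i]] for i in rows]) if rows else np.empty((0, 2))

        candidates = [t for t in open_tracks if f - t["last_frame"] <= max_gap + 1]
        matched_tracks, matched_pts = set(), set()
        if candidates and len(pts):
            tp = np.array([[t["last_x"], t["last_y"]] for t in candidates])
            gaps = np.array([f - t["last_frame"] for t in candidates], dtype=float)
            d = np.linalg.norm(tp[:, None, :] - pts[None, :, :], axis=2)
            radius = max_dist * np.sqrt(gaps)[:, None]
            feasible = d <= radius
            if feasible.any():
                big = (max_dist * np.sqrt(max_gap + 1.0)
                       * (len(candidates) + len(pts) + 1) * 1e6 + 1.0)
                cost = np.where(feasible, d, big)
                for i, j in zip(*linear_sum_assignment(cost)):
                    if feasible[i, j]:
                        t = candidates[i]
                        li = rows[j]
                        t["points"].append((f, xs[li], ys[li], li))
                        t["last_frame"], t["last_x"], t["last_y"] = f, xs[li], ys[li]
                        matched_tracks.add(id(t))
                        matched_pts.add(j)
        # close tracks that have exhausted their gap allowance
        still_open = []
        for t in open_tracks:
            if id(t) in matched_tracks or f - t["last_frame"] <= max_gap:
                still_open.append(t)
            else:
                closed.append(t)
        open_tracks = still_open
        # unmatched localizations start new tracks
        for j, li in enumerate(rows):
            if j not in matched_pts:
                open_tracks.append({
                    "points": [(f, xs[li], ys[li], li)],
                    "last_frame": f, "last_x": xs[li], "last_y": ys[li],
                })
    closed.extend(open_tracks)

    kept = [t for t in closed if len(t["points"]) >= min_length]
    kept.sort(key=lambda t: (t["points"][0][0], t["points"][0][2], t["points"][0][1]))

    records = []
    for tid, t in enumerate(kept):
        for (f, x, y, li) in t["points"]:
            records.append((tid, f, x, y, li))
    if not records:
        return empty
    out = pd.DataFrame(records, columns=["track_id", "frame", "x", "y", "loc_index"])
    return ResultTable(out, "tracking")
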
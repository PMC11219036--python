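"""Frame-to-frame linking of per-frame detections into cell tracks.

Two modes are provided: a greedy nearest-pair matcher (fast, deterministic,
ties broken by smaller detection index) and an exact mode that solves the
minimum-total-distance assignment (maximum cardinality first) with the
Hungarian algorithm.  Tracks missing for more than ``memory`` consecutive
frames are closed; unmatched detections open new tracks.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

__all__ = ["link", "TRACK_COLUMNS"]

TRACK_COLUMNS = ["track_id", "frame", "time_s", "x_um", "y_um", "label"]

_BIG = 1e9  # forbidden pairing
_UNMATCHED = 1e4  # cost of leaving a node unmatched; >> max_disp so cardinality wins


def link(
    detections,
    max_disp: float = 15.0,
    memory: int = 2,
    times=None,
    labels=None,
    mode: str = "greedy",
) -> pd.DataFrame:
    """Link per-frame centroid lists (µm) into a track table.

    Parameters
    ----------
    detections : sequence of (N_f, 2) arrays
        (x, y) positions per frame, µm.
    max_disp : float
        Maximum link distance, µm.
    memory : int
        Number of consecutive frames a track may go undetected before closing.
    times : sequence of float, optional
        Per-frame times (s); defaults to the frame index.
    labels : sequence of arrays, optional
        Per-detection instance labels to carry through; defaults to the
        detection index within the frame.
    mode : {"greedy", "exact"}
        Matching strategy per frame transition.

    Returns
    -------
    DataFrame with columns track_id, frame, time_s, x_um, y_um, label,
    sorted by (track_id, frame).
    """
    if max_disp <= 0:
        raise ValueError("max_disp must be positive")
    if memory < 0:
        raise ValueError("memory must be >= 0")
    if mode not in ("greedy", "exact"):
        raise ValueError("mode must be 'greedy' or 'exact'")
    n_frames = len(detections)
    times = np.arange(n_frames, dtype=float) if times is None else np.asarray(times)

    rows = []
    active = []  # dicts: id, pos, last_frame
    next_id = 0
    for f in range(n_frames):
        dets = np.asarray(detections[f], dtype=float).reshape(-1, 2)
        labs = (
            np.arange(len(dets)) if labels is None else np.asarray(labels[f])
        )
        active = [tr for tr in active if f - tr["last_frame"] <= memory + 1]
        assign = _match(active, dets, max_disp, mode)
        new_rows = []
        matched_dets = set()
        for ti, di in assign:
            tr = active[ti]
            tr["pos"] = dets[di]
            tr["last_frame"] = f
            matched_dets.add(di)
            new_rows.append((tr["id"], f, times[f], dets[di, 0], dets[di, 1], labs[di]))
        fresh = [di for di in range(len(dets)) if di not in matched_dets]
        # canonical id order for new tracks: by position, so exact-mode output
        # does not depend on detection ordering within the frame
        fresh.sort(key=lambda di: (dets[di, 0], dets[di, 1]))
        for di in fresh:
            active.append({"id": next_id, "pos": dets[di], "last_frame": f})
            new_rows.append((next_id, f, times[f], dets[di, 0], dets[di, 1], labs[di]))
            next_id += 1
        rows.extend(new_rows)

    df = pd.DataFrame(rows, columns=TRACK_COLUMNS)
    if len(df):
        df = df.sort_values(["track_id", "frame"], ignore_index=True)
        if not df.groupby("track_id")["frame"].apply(
            lambda s: s.is_monotonic_increasing
        ).all():
            raise AssertionError("frames within a track must increase")
    return df


def _match(active, dets, max_disp, mode):
    """Return list of (active_index, detection_index) pairs."""
    if not active or len(dets) == 0:
        return []
    tpos = np.array([tr["pos"] for tr in active])
    d = np.hypot(
        tpos[:, None, 0] - dets[None, :, 0], tpos[:, None, 1] - dets[None, :, 1]
    )
    if mode == "greedy":
        pairs = [
            (d[i, j], j, i)
            for i in range(d.shape[0])
            for j in range(d.shape[1])
            if d[i, j] <= max_disp
        ]
        pairs.sort()  # distance, then smaller detection index
        used_t, used_d, out = set(), set(), []
        for dist, j, i in pairs:
            if i in used_t or j in used_d:
                continue
            used_t.add(i)
            used_d.add(j)
            out.append((i, j))
        return out
    # exact: pad to a square matrix so nodes may stay unmatched at fixed cost;
    # _UNMATCHED >> max_disp makes the solver maximize link count first, then
    # minimize total distance.
    n, m = d.shape
    cost = np.full((n + m, m + n), 0.0)
    cost[:n, :m] = np.where(d <= max_disp, d, _BIG)
    cost[:n, m:] = _BIG
    cost[n:, :m] = _BIG
    np.fill_diagonal(cost[:n, m:], _UNMATCHED)
    np.fill_diagonal(cost[n:, :m], _UNMATCHED)
    ri, ci = linear_sum_assignment(cost)
    return [
        (i, j)
        for i, j in zip(ri, ci)
        if i < n and j < m and d[i, j] <= max_disp
    ]
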
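"""Track kinematics: windowed velocity, angular alignment, population summaries.

Velocity at frame i is the chord displacement over a symmetric window of
±tau frames divided by the elapsed time (reported in µm/min).  Angular
alignment measures persistence on a fixed path-length scale: for each frame i
(position B), anchors A (backward) and C (forward) are the first positions
separated from B by at least ``distance_offset`` µm of cumulative distance
traveled; the angle between BA and BC is mapped affinely from [0, π] to
[-1, +1], so a straight path scores +1, an immediate reversal -1, and an
uncorrelated random walk has median ≈ 0.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "velocity",
    "cumulative_distance",
    "angular_alignment",
    "population_summary",
]


def velocity(positions, times, tau: int = 3):
    """Windowed chord speed ν_i = |r_{i+τ} − r_{i−τ}| / (t_{i+τ} − t_{i−τ}), µm/min.

    Undefined (NaN) at the first and last ``tau`` frames.
    """
    if tau < 1:
        raise ValueError("tau must be >= 1")
    xy = np.asarray(positions, dtype=float).reshape(-1, 2)
    t = np.asarray(times, dtype=float)
    if len(t) != len(xy):
        raise ValueError("positions and times must have equal length")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    n = len(xy)
    v = np.full(n, np.nan)
    if n > 2 * tau:
        d = np.hypot(
            xy[2 * tau :, 0] - xy[: n - 2 * tau, 0],
            xy[2 * tau :, 1] - xy[: n - 2 * tau, 1],
        )
        dt = t[2 * tau :] - t[: n - 2 * tau]
        v[tau : n - tau] = d / dt * 60.0
    return v


def cumulative_distance(positions):
    """Path length traveled up to each frame, µm."""
    xy = np.asarray(positions, dtype=float).reshape(-1, 2)
    steps = np.hypot(*np.diff(xy, axis=0).T)
    return np.concatenate([[0.0], np.cumsum(steps)])


def angular_alignment(positions, distance_offset: float = 10.0):
    """Per-frame persistence in [-1, 1] anchored at ``distance_offset`` µm of path.

    NaN where either anchor does not exist or an anchor coincides with the
    current position.
    """
    xy = np.asarray(positions, dtype=float).reshape(-1, 2)
    if not np.all(np.isfinite(xy)):
        raise ValueError("positions must be finite")
    n = len(xy)
    cum = cumulative_distance(xy)
    out = np.full(n, np.nan)
    for i in range(n):
        # latest prior j with cum[i] - cum[j] >= offset
        j = np.searchsorted(cum, cum[i] - distance_offset, side="right") - 1
        if j < 0 or cum[i] - cum[j] < distance_offset:
            continue
        # earliest subsequent k with cum[k] - cum[i] >= offset
        k = np.searchsorted(cum, cum[i] + distance_offset, side="left")
        if k >= n:
            continue
        ba = xy[j] - xy[i]
        bc = xy[k] - xy[i]
        nba = np.hypot(*ba)
        nbc = np.hypot(*bc)
        if nba == 0 or nbc == 0:
            continue
        cross = abs(ba[0] * bc[1] - ba[1] * bc[0])
        dot = ba @ bc
        angle = np.arctan2(cross, dot)  # [0, π]
        out[i] = 2.0 * angle / np.pi - 1.0
    return out


def population_summary(df: pd.DataFrame, value: str = "value") -> pd.DataFrame:
    """Replicate-aware per-timepoint summary of a per-cell quantity.

    ``df`` needs columns replicate, time_s, and ``value`` (one row per cell per
    timepoint).  Within each replicate the median across cells is taken at
    each timepoint; across replicates the mean, SD and normal-approximation
    95% CI of those medians are reported.  A replicate with no cells at a
    timepoint is omitted there; with a single replicate the SD is 0 by
    convention.
    """
    required = {"replicate", "time_s", value}
    if not required.issubset(df.columns):
        raise ValueError(f"summary input needs columns {sorted(required)}")
    rows = []
    for t, sub in df.dropna(subset=[value]).groupby("time_s"):
        med = sub.groupby("replicate")[value].median()
        n_rep = len(med)
        if n_rep == 0:
            continue
        mean = float(med.mean())
        sd = float(med.std(ddof=1)) if n_rep > 1 else 0.0
        half = 1.96 * sd / np.sqrt(n_rep) if n_rep > 1 else 0.0
        rows.append(
            (t, mean, sd, mean - half, mean + half, n_rep, len(sub))
        )
    return pd.DataFrame(
        rows,
        columns=[
            "time_s",
            "mean_of_medians",
            "sd",
            "ci95_lo",
            "ci95_hi",
            "n_replicates",
            "n_cells",
        ],
    )
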
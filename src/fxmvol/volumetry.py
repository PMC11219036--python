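"""Per-cell volume extraction from flatfield-corrected FxM frames.

The excluded volume of a cell with footprint A is

    V = (pixel_size^2 / alpha) * sum_{(x,y) in A} (Imax - I(x, y))

where Imax is the median corrected intensity of the cell's local background
(an annulus 2-10 px outside its border, avoiding other cells and pillars) —
the counterfactual signal had the cell not been there — and the calibration

    alpha = (I_background - I_pillar) / h_chamber

converts corrected intensity to microns of dye column: pillars touch the
chamber roof (zero dye), open background carries the full chamber height.
Traces are normalized to the median volume in the two-minute window before
stimulation and smoothed with a centered rolling median.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "CalibrationInfo",
    "EdgeTouching",
    "LocalityOccluded",
    "alpha_calibration",
    "local_background",
    "cell_volume",
    "build_volume_trace",
]


class EdgeTouching(ValueError):
    """Cell footprint touches the field-of-view border; volume excluded."""


class LocalityOccluded(ValueError):
    """Too few free pixels in the local-background annulus."""


@dataclass(frozen=True)
class CalibrationInfo:
    """Per-frame intensity-to-height calibration (corrected-intensity units)."""

    alpha: float  # per µm
    h_chamber: float  # µm
    i_pillar: float
    i_background: float


def alpha_calibration(corrected, pillar_mask, background_mask, h_chamber: float) -> CalibrationInfo:
    """Calibrate intensity per micron of dye column from one corrected frame."""
    pillar_mask = np.asarray(pillar_mask, dtype=bool)
    background_mask = np.asarray(background_mask, dtype=bool)
    if not pillar_mask.any():
        raise ValueError("pillar mask is empty")
    if not background_mask.any():
        raise ValueError("background mask is empty")
    i_pil = float(np.median(corrected[pillar_mask]))
    i_bg = float(np.median(corrected[background_mask]))
    alpha = (i_bg - i_pil) / h_chamber
    if alpha <= 0:
        raise ValueError("inverted calibration: background signal not above pillars")
    return CalibrationInfo(alpha, h_chamber, i_pil, i_bg)


def local_background(
    corrected,
    labels,
    cell_id: int,
    pillar_mask=None,
    r_in: float = 2.0,
    r_out: float = 10.0,
    min_pixels: int = 30,
) -> float:
    """Median corrected intensity in the annulus ``r_in``-``r_out`` px outside the cell.

    Pixels belonging to any labeled cell or a pillar are excluded.  Raises
    :class:`EdgeTouching` if the footprint touches the frame border and
    :class:`LocalityOccluded` if fewer than ``min_pixels`` annulus pixels
    remain.
    """
    labels = np.asarray(labels)
    footprint = labels == cell_id
    if not footprint.any():
        raise ValueError(f"cell {cell_id} not present in label image")
    rows = np.flatnonzero(footprint.any(axis=1))
    cols = np.flatnonzero(footprint.any(axis=0))
    H, W = labels.shape
    if rows[0] == 0 or cols[0] == 0 or rows[-1] == H - 1 or cols[-1] == W - 1:
        raise EdgeTouching(f"cell {cell_id} touches the frame border")
    pad = int(np.ceil(r_out)) + 1
    r0, r1 = max(rows[0] - pad, 0), min(rows[-1] + pad + 1, H)
    c0, c1 = max(cols[0] - pad, 0), min(cols[-1] + pad + 1, W)
    win = np.s_[r0:r1, c0:c1]
    dist = ndimage.distance_transform_edt(~footprint[win])
    annulus = (dist >= r_in) & (dist <= r_out) & (labels[win] == 0)
    if pillar_mask is not None:
        annulus &= ~np.asarray(pillar_mask, dtype=bool)[win]
    if annulus.sum() < min_pixels:
        raise LocalityOccluded(
            f"cell {cell_id}: only {int(annulus.sum())} free annulus pixels"
        )
    return float(np.median(np.asarray(corrected, dtype=float)[win][annulus]))


def cell_volume(corrected, footprint, imax: float, alpha: float, pixel_size: float) -> float:
    """Excluded volume (µm³) over a boolean footprint mask.

    Negative values under noise are preserved (not clamped), so population
    statistics stay unbiased.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    footprint = np.asarray(footprint, dtype=bool)
    if not footprint.any():
        raise ValueError("empty footprint")
    deficit = imax - np.asarray(corrected, dtype=float)[footprint]
    return float(pixel_size**2 / alpha * deficit.sum())


def footprint_area(footprint, pixel_size: float) -> float:
    """Footprint area in µm²."""
    return float(np.count_nonzero(footprint) * pixel_size**2)


def build_volume_trace(
    volumes,
    times,
    stim_time: float,
    rolling_window: int = 7,
    baseline_window_s: float = 120.0,
) -> pd.DataFrame:
    """Normalize a per-frame volume series to its pre-stimulation baseline.

    The baseline is the median volume over [stim_time - baseline_window_s,
    stim_time); the rolling median uses a centered window that shrinks at the
    ends.  Returns a DataFrame with time_s, volume_um3, volume_norm,
    volume_rollmed_um3 plus a ``baseline_um3`` attribute column.
    """
    v = pd.Series(np.asarray(volumes, dtype=float))
    t = np.asarray(times, dtype=float)
    if len(v) != len(t):
        raise ValueError("volumes and times must have equal length")
    pre = (t >= stim_time - baseline_window_s) & (t < stim_time)
    if not pre.any() or v[pre].isna().all():
        raise ValueError("baseline undefined: no frames in the pre-stimulation window")
    baseline = float(v[pre].median())
    if baseline <= 0:
        raise ValueError("baseline volume must be positive")
    roll = v.rolling(rolling_window, center=True, min_periods=1).median()
    return pd.DataFrame(
        {
            "time_s": t,
            "volume_um3": v,
            "volume_norm": v / baseline,
            "volume_rollmed_um3": roll,
            "baseline_um3": baseline,
        }
    )
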
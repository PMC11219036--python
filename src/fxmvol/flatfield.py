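"""Per-frame illumination correction for FxM stacks.

The dye signal far from any cell samples the illumination field directly, so a
smooth surface fit to background points doubles as the flatfield.  Sample
points are laid out along a sinusoidal path spanning the frame (densest near
the top and bottom edges, where a sine spends most of its time), relocated or
dropped where they hit cells or pillars, and interpolated with a multiquadric
radial basis expansion carrying an affine tail:

    s(p) = sum_j w_j * sqrt(||p - p_j||^2 + eps^2) + a0 + a1*x + a2*y

The tail makes constant and linearly ramped fields reproduce exactly (the
multiquadric kernel is conditionally positive definite of order 1); a small
ridge on the kernel block keeps near-duplicate points after relocation
harmless.  Correction divides the darkfield-subtracted raw frame by the
darkfield-subtracted interpolant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

__all__ = ["BackgroundField", "sample_points", "fit_interpolant", "correct"]


@dataclass
class BackgroundField:
    """Fitted multiquadric background surface, evaluable at any pixel."""

    points: np.ndarray  # (N, 2) (row, col) px
    values: np.ndarray  # (N,)
    epsilon: float  # kernel shape parameter, px
    ridge: float
    weights: np.ndarray  # (N,) kernel weights
    poly: np.ndarray  # (3,) affine tail: const, row, col

    def evaluate_at(self, coords) -> np.ndarray:
        """Evaluate at (M, 2) (row, col) coordinates."""
        coords = np.asarray(coords, dtype=float).reshape(-1, 2)
        out = np.empty(len(coords))
        # chunked so a full-frame evaluation never materializes M x N at once
        step = max(1, int(2e6 / max(len(self.points), 1)))
        for s in range(0, len(coords), step):
            block = coords[s : s + step]
            d2 = (
                (block[:, None, 0] - self.points[None, :, 0]) ** 2
                + (block[:, None, 1] - self.points[None, :, 1]) ** 2
            )
            out[s : s + step] = np.sqrt(d2 + self.epsilon**2) @ self.weights
        out += self.poly[0] + self.poly[1] * coords[:, 0] + self.poly[2] * coords[:, 1]
        return out

    def evaluate(self, shape) -> np.ndarray:
        """Evaluate on a full (rows, cols) grid."""
        rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
        return self.evaluate_at(np.column_stack([rr.ravel(), cc.ravel()])).reshape(shape)


def sample_points(
    shape,
    exclusion_mask=None,
    n_points: int = 200,
    n_periods: int = 4,
    margin: int = 10,
    min_spacing: float = 8.0,
):
    """Background sample locations along a sinusoidal path avoiding the mask.

    Points are uniform in x; y follows ``center + (H/2 - margin) * sin``, which
    concentrates samples near the frame's top and bottom.  A point landing in
    the exclusion mask moves to the nearest free pixel within 20 px, or is
    dropped.  Points closer than ``min_spacing`` px to an already kept point
    are also dropped: the path clusters samples near its turning points, and
    near-coincident noisy samples destabilize the interpolation without
    adding information.  Returns an (N, 2) int array of (row, col); raises if
    fewer than 3 points survive.
    """
    H, W = shape
    j = np.arange(n_points)
    cols = np.round(margin + (W - 1 - 2 * margin) * j / max(n_points - 1, 1)).astype(int)
    amp = (H - 1) / 2 - margin
    rows = np.round((H - 1) / 2 + amp * np.sin(2 * np.pi * n_periods * j / n_points)).astype(int)
    rows = np.clip(rows, 0, H - 1)
    cols = np.clip(cols, 0, W - 1)
    if exclusion_mask is None:
        pts = np.column_stack([rows, cols])
    else:
        mask = np.asarray(exclusion_mask, dtype=bool)
        if mask.shape != tuple(shape):
            raise ValueError("exclusion mask shape mismatch")
        pts = []
        for r, c in zip(rows, cols):
            if not mask[r, c]:
                pts.append((r, c))
                continue
            moved = _relocate(mask, r, c, radius=20)
            if moved is not None:
                pts.append(moved)
        pts = np.asarray(pts, dtype=int).reshape(-1, 2)
    if min_spacing > 0 and len(pts):
        kept = []
        for p in pts:
            if all(
                (p[0] - q[0]) ** 2 + (p[1] - q[1]) ** 2 >= min_spacing**2
                for q in kept
            ):
                kept.append(p)
        pts = np.asarray(kept, dtype=int).reshape(-1, 2)
    if len(pts) < 3:
        raise ValueError("background unsampleable: fewer than 3 valid sample points")
    return pts


def sample_values(frame, points, exclusion_mask=None, radius: int = 3):
    """Robust background value at each sample point: the median over a small
    neighborhood restricted to non-excluded pixels (falls back to the center
    pixel when the window is almost fully excluded).  Pooling suppresses read
    noise so the interpolant fits illumination, not pixel noise."""
    frame = np.asarray(frame, dtype=float)
    H, W = frame.shape
    mask = None if exclusion_mask is None else np.asarray(exclusion_mask, dtype=bool)
    vals = np.empty(len(points))
    for i, (r, c) in enumerate(points):
        r0, r1 = max(r - radius, 0), min(r + radius + 1, H)
        c0, c1 = max(c - radius, 0), min(c + radius + 1, W)
        win = frame[r0:r1, c0:c1]
        if mask is not None:
            free = ~mask[r0:r1, c0:c1]
            vals[i] = np.median(win[free]) if free.sum() >= 5 else frame[r, c]
        else:
            vals[i] = np.median(win)
    return vals


def _relocate(mask, r, c, radius):
    H, W = mask.shape
    r0, r1 = max(r - radius, 0), min(r + radius + 1, H)
    c0, c1 = max(c - radius, 0), min(c + radius + 1, W)
    window = mask[r0:r1, c0:c1]
    free = np.argwhere(~window)
    if len(free) == 0:
        return None
    d2 = (free[:, 0] + r0 - r) ** 2 + (free[:, 1] + c0 - c) ** 2
    best = free[np.argmin(d2)]
    if d2.min() > radius**2:
        return None
    return int(best[0] + r0), int(best[1] + c0)


def fit_interpolant(points, values, epsilon=None, ridge: float = 1e-8) -> BackgroundField:
    """Fit the multiquadric + affine surface through (points, values).

    ``epsilon`` (surface stiffness) defaults to the mean nearest-neighbor
    spacing of the points.  The kernel block receives a ridge of
    ``ridge * epsilon`` on its diagonal.
    """
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    values = np.asarray(values, dtype=float).ravel()
    n = len(points)
    if n < 3 or len(values) != n:
        raise ValueError("need at least 3 sample points with matching values")
    if epsilon is None:
        d, _ = cKDTree(points).query(points, k=2)
        epsilon = float(np.mean(d[:, 1]))
        if epsilon <= 0:
            epsilon = 1.0
    d2 = (
        (points[:, None, 0] - points[None, :, 0]) ** 2
        + (points[:, None, 1] - points[None, :, 1]) ** 2
    )
    K = np.sqrt(d2 + epsilon**2)
    P = np.column_stack([np.ones(n), points[:, 0], points[:, 1]])
    A = np.zeros((n + 3, n + 3))
    A[:n, :n] = K + ridge * epsilon * np.eye(n)
    A[:n, n:] = P
    A[n:, :n] = P.T
    b = np.concatenate([values, np.zeros(3)])
    try:
        sol = np.linalg.solve(A, b)
    except np.linalg.LinAlgError as err:
        raise ValueError("singular background system after regularization") from err
    return BackgroundField(points, values, float(epsilon), ridge, sol[:n], sol[n:])


def correct(raw, darkfield, bg_field: BackgroundField):
    """Flatfield-correct: (raw - darkfield) / (field - darkfield).

    ``darkfield`` may be a scalar or an image.  Background pixels come out
    near 1; pillar pixels (no dye column) come out near 0.  Raises if the
    darkfield meets or exceeds the background model anywhere.
    """
    raw = np.asarray(raw, dtype=float)
    df = np.asarray(darkfield, dtype=float)
    field = bg_field.evaluate(raw.shape)
    denom = field - df
    if np.any(denom <= 0):
        raise ValueError("darkfield exceeds background model")
    return (raw - df) / denom
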
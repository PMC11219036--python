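"""Synthetic fluorescence-exclusion microscopy (FxM) experiments with ground truth.

FxM measures single-cell volume by filling a shallow chamber of known height
with a fluorescent dye that cells exclude: the local intensity deficit,
integrated over the cell footprint and divided by the intensity-per-micron
calibration, is the excluded (cell) volume.  This module renders such
experiments synthetically — dome-shaped dye-excluding cells executing a
persistent random walk over a smoothly varying illumination field, with
pillar landmarks and a darkfield offset — and records exact per-cell,
per-frame ground truth so every downstream stage (segmentation, tracking,
flatfield correction, volumetry, motility statistics) can be validated by
parameter recovery.

Cells follow a biphasic volume program around a stimulation event: a brief
spreading-induced volume dip of a few percent, then a saturating swell to a
plateau ~15% above the resting volume, with minute-scale fluctuations
superposed.  Motility switches from a quiescent to a fast persistent walk at
stimulation.  Bulk-assay generators (density-gradient fraction counts and
Coulter-counter volume samples) with matching statistical structure are
included as well.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

__all__ = [
    "MotilityProgram",
    "VolumeProgram",
    "SimConfig",
    "GroundTruth",
    "SyntheticDataset",
    "volume_schedule",
    "simulate_track",
    "render_frame",
    "simulate_experiment",
    "simulate_gradient_counts",
    "simulate_coulter_run",
]


@dataclass(frozen=True)
class MotilityProgram:
    """Two-phase persistent-random-walk speeds (µm/min) and per-step turning noise (rad)."""

    speed_pre: float = 0.5
    speed_post: float = 12.0
    turn_sd: float = 0.3


@dataclass(frozen=True)
class VolumeProgram:
    """Biphasic volume response parameters.

    ``V0_median``/``V0_cv`` set the lognormal resting-volume distribution (µm³).
    After stimulation the multiplicative volume factor dips by ``dip_fraction``
    over ``dip_duration`` seconds (spreading), then rises to 1 + ``swell_fraction``
    with time constant ``swell_tau``.  A sinusoidal fluctuation of relative
    amplitude ``fluct_amplitude`` and period ``fluct_period`` (seconds) rides on
    top throughout, emulating motility-cycle volume fluctuations.
    """

    V0_median: float = 300.0
    V0_cv: float = 0.15
    dip_fraction: float = 0.06
    dip_duration: float = 60.0
    swell_fraction: float = 0.15
    swell_tau: float = 240.0
    fluct_amplitude: float = 0.02
    fluct_period: float = 60.0


@dataclass(frozen=True)
class SimConfig:
    """Complete description of one synthetic FxM experiment.

    Intensities are arbitrary camera units.  ``alpha_true`` is the intensity
    emitted per micron of dye column (before the multiplicative flatfield);
    ``flatfield_amplitude`` is the peak fractional deviation of the
    illumination field from 1.  ``noise_sd`` is additive Gaussian read noise.
    """

    fov_rows: int = 500
    fov_cols: int = 500
    pixel_size: float = 0.65  # µm / px
    chamber_height: float = 6.0  # µm
    frame_interval: float = 10.0  # s
    n_frames: int = 120
    stim_frame: int = 18
    darkfield_level: float = 100.0
    flatfield_amplitude: float = 0.2
    alpha_true: float = 100.0  # intensity units per µm of dye
    noise_sd: float = 6.0
    n_cells: int = 50
    pillar_centers: tuple = None  # ((row, col), ...) px; None -> border layout
    pillar_radius: float = 10.0  # px
    motility: MotilityProgram = field(default_factory=MotilityProgram)
    volume_program: VolumeProgram = field(default_factory=VolumeProgram)
    dome_aspect: float = 0.6  # peak height / footprint radius of the cell dome
    nuclear_sigma: float = 2.0  # µm
    seed: int = 0

    def __post_init__(self):
        if self.chamber_height <= 0:
            raise ValueError("chamber_height must be positive")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        vp = self.volume_program
        if not 0 <= vp.dip_fraction < 1:
            raise ValueError("dip_fraction must lie in [0, 1)")
        if vp.swell_fraction < 0:
            raise ValueError("swell_fraction must be non-negative")
        if self.n_frames < 1:
            raise ValueError("need at least one frame")

    @property
    def shape(self):
        return (self.fov_rows, self.fov_cols)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


@dataclass
class GroundTruth:
    """Per-cell, per-frame truth plus the static scene elements.

    ``table`` has columns cell_id, frame, x_um, y_um, true_volume_um3 where the
    volume is the *rasterized* one — pixel_size² times the sum of the rendered
    height map — so pipeline recovery is compared against exactly what was drawn.
    ``footprints`` maps (cell_id, frame) to (row0, col0, bool patch).
    """

    table: pd.DataFrame
    footprints: dict
    flatfield: np.ndarray
    darkfield: np.ndarray
    pillar_mask: np.ndarray

    def footprint_mask(self, cell_id: int, frame: int, shape) -> np.ndarray:
        r0, c0, patch = self.footprints[(cell_id, frame)]
        full = np.zeros(shape, dtype=bool)
        full[r0 : r0 + patch.shape[0], c0 : c0 + patch.shape[1]] = patch
        return full


@dataclass
class SyntheticDataset:
    fxm_stack: np.ndarray
    nuclear_stack: np.ndarray
    cyto_stack: np.ndarray
    timestamps: np.ndarray  # s
    config: SimConfig
    truth: GroundTruth

    @property
    def stim_time(self) -> float:
        return float(self.timestamps[self.config.stim_frame])

    def write(self, outdir):
        """Write TIFF stacks, masks and CSV tables to ``outdir``."""
        from . import io as _io

        _io.write_dataset(self, outdir)


# ---------------------------------------------------------------------------
# volume program


def volume_schedule(t_rel, program: VolumeProgram, phase: float = 0.0):
    """Multiplicative volume factor at time ``t_rel`` (s) relative to stimulation.

    Before stimulation the factor is 1 plus the fluctuation term.  From t=0 a
    half-sine dip of depth ``dip_fraction`` spans ``dip_duration``; afterwards
    the factor relaxes to 1 + ``swell_fraction`` with time constant ``swell_tau``.
    ``phase`` offsets the fluctuation sinusoid (per-cell dephasing).
    """
    t = np.asarray(t_rel, dtype=float)
    scalar = t.ndim == 0
    t = np.atleast_1d(t)
    factor = np.ones_like(t)
    p = program
    if p.dip_duration > 0:
        in_dip = (t >= 0) & (t < p.dip_duration)
        factor[in_dip] -= p.dip_fraction * np.sin(np.pi * t[in_dip] / p.dip_duration)
    after = t >= p.dip_duration
    if p.swell_tau > 0:
        factor[after] += p.swell_fraction * (
            1.0 - np.exp(-(t[after] - p.dip_duration) / p.swell_tau)
        )
    else:
        factor[after] += p.swell_fraction
    if p.fluct_amplitude:
        factor = factor + p.fluct_amplitude * np.sin(
            2 * np.pi * t / p.fluct_period + phase
        )
    return float(factor[0]) if scalar else factor


# ---------------------------------------------------------------------------
# motility


def simulate_track(
    n_frames: int,
    speed_schedule,
    turn_sd: float,
    arena,
    seed: int,
    dt: float = 10.0,
    start=None,
):
    """Persistent random walk confined to a rectangular arena.

    ``speed_schedule`` is a scalar or per-step array in µm/min; step length is
    speed × ``dt``.  Heading increments are N(0, turn_sd²) per step; positions
    are reflected at the arena boundary.  ``arena`` is a scalar extent or
    (width, height) in µm.  Returns an (n_frames, 2) array of (x, y) µm.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    speeds = np.broadcast_to(
        np.asarray(speed_schedule, dtype=float), (max(n_frames - 1, 1),)
    ).copy()
    if np.any(speeds < 0):
        raise ValueError("speeds must be non-negative")
    extent = np.atleast_1d(np.asarray(arena, dtype=float))
    if extent.size == 1:
        extent = np.repeat(extent, 2)
    rng = np.random.default_rng(seed)
    pos = np.empty((n_frames, 2))
    if start is None:
        pos[0] = rng.uniform(0, extent)
    else:
        pos[0] = start
    heading = rng.uniform(0, 2 * np.pi)
    for i in range(1, n_frames):
        heading += rng.normal(0.0, turn_sd)
        step = speeds[i - 1] / 60.0 * dt
        p = pos[i - 1] + step * np.array([np.cos(heading), np.sin(heading)])
        pos[i] = _reflect(p, extent)
    return pos


def _reflect(p, extent):
    p = np.array(p, dtype=float)
    for k in range(2):
        L = extent[k]
        # fold into [0, 2L) then mirror the upper half
        x = p[k] % (2 * L)
        p[k] = 2 * L - x if x > L else x
    return p


# ---------------------------------------------------------------------------
# cell shape


def _dome_volume(R: float, aspect: float, h_max: float) -> float:
    """Analytic volume of h(r) = min(h_max, aspect·R·(1 − (r/R)²)^1.5)."""
    h_peak = aspect * R
    if h_peak <= h_max:
        return 0.4 * np.pi * h_peak * R * R
    u = (h_max / h_peak) ** (2.0 / 3.0)  # 1 − (r_c/R)²
    rc2 = R * R * (1.0 - u)
    return np.pi * rc2 * h_max + 0.4 * np.pi * h_peak * R * R * u ** 2.5


def dome_radius_for_volume(volume: float, aspect: float, h_max: float) -> float:
    """Footprint radius R (µm) whose clipped dome has the target volume."""
    if volume <= 0:
        raise ValueError("volume must be positive")
    lo, hi = 1e-3, 10.0
    while _dome_volume(hi, aspect, h_max) < volume:
        hi *= 2.0
        if hi > 1e4:
            raise ValueError("volume unreasonably large")
    return brentq(
        lambda R: _dome_volume(R, aspect, h_max) - volume, lo, hi, xtol=1e-9, rtol=1e-8
    )


def _height_patch(cx_um, cy_um, R_um, h_peak, h_max, pixel_size, shape):
    """Rasterize one dome on the pixel grid; returns (r0, c0, patch µm)."""
    rows, cols = shape
    R_px = R_um / pixel_size
    c_px = cx_um / pixel_size
    r_px = cy_um / pixel_size
    r0 = max(int(np.floor(r_px - R_px)) - 1, 0)
    r1 = min(int(np.ceil(r_px + R_px)) + 2, rows)
    c0 = max(int(np.floor(c_px - R_px)) - 1, 0)
    c1 = min(int(np.ceil(c_px + R_px)) + 2, cols)
    if r1 <= r0 or c1 <= c0:
        return r0, c0, np.zeros((0, 0))
    rr = (np.arange(r0, r1) - r_px) * pixel_size
    cc = (np.arange(c0, c1) - c_px) * pixel_size
    d2 = rr[:, None] ** 2 + cc[None, :] ** 2
    u = 1.0 - d2 / (R_um * R_um)
    patch = np.where(u > 0, h_peak * np.clip(u, 0, None) ** 1.5, 0.0)
    return r0, c0, np.minimum(patch, h_max)


@dataclass
class CellRender:
    """One cell's rasterized height patch plus its centroid in pixel coords."""

    r0: int
    c0: int
    height: np.ndarray  # µm
    center_rc: tuple  # (row, col) float px


# ---------------------------------------------------------------------------
# rendering


def _default_pillars(config: SimConfig):
    R, C = config.fov_rows, config.fov_cols
    inset = 25
    return (
        (inset, inset),
        (inset, C - 1 - inset),
        (R - 1 - inset, inset),
        (R - 1 - inset, C - 1 - inset),
        (inset, C // 2),
        (R - 1 - inset, C // 2),
        (R // 2, inset),
        (R // 2, C - 1 - inset),
    )


def make_pillar_mask(config: SimConfig) -> np.ndarray:
    centers = config.pillar_centers or _default_pillars(config)
    rr = np.arange(config.fov_rows)[:, None]
    cc = np.arange(config.fov_cols)[None, :]
    mask = np.zeros(config.shape, dtype=bool)
    for r, c in centers:
        mask |= (rr - r) ** 2 + (cc - c) ** 2 <= config.pillar_radius**2
    return mask


def make_flatfield(config: SimConfig, rng=None) -> np.ndarray:
    """Multiplicative illumination field with peak fractional deviation = amplitude.

    Modeled as off-center quadratic vignetting plus a gentle plane tilt — the
    dominant structure of real widefield illumination; the vignette center and
    tilt direction are drawn from the seed.
    """
    if config.flatfield_amplitude == 0:
        return np.ones(config.shape)
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    u = np.linspace(-1, 1, config.fov_rows)[:, None]
    v = np.linspace(-1, 1, config.fov_cols)[None, :]
    cu, cv = rng.uniform(-0.3, 0.3, size=2)
    tu, tv = rng.uniform(-0.5, 0.5, size=2)
    g = -((u - cu) ** 2 + (v - cv) ** 2) + tu * u + tv * v
    g -= g.mean()
    g /= np.max(np.abs(g))
    return 1.0 + config.flatfield_amplitude * g


def make_darkfield(config: SimConfig) -> np.ndarray:
    """Camera offset image: constant level with a gentle row gradient."""
    ramp = np.linspace(0, 0.02, config.fov_rows)[:, None]
    return config.darkfield_level * (1.0 + ramp) * np.ones(config.shape)


def render_frame(cells, config: SimConfig, flatfield, pillar_mask, rng):
    """Render one frame triple (fxm, nuclear, cyto) from rasterized cells.

    fxm = darkfield + FF·alpha_true·(dye column) + noise, where the dye column
    is chamber_height − Σ cell heights off-pillar and 0 over pillars.  The
    nuclear channel carries a Gaussian spot per cell centroid; the cytoplasmic
    channel a constant-brightness filled footprint.
    """
    h_cells = np.zeros(config.shape)
    for cell in cells:
        hp = cell.height
        if hp.size == 0:
            continue
        sl = np.s_[cell.r0 : cell.r0 + hp.shape[0], cell.c0 : cell.c0 + hp.shape[1]]
        h_cells[sl] += hp
    if np.any(h_cells > config.chamber_height + 1e-9):
        raise ValueError("cell height exceeds chamber height")
    dye = config.chamber_height - h_cells
    dye[pillar_mask] = 0.0
    fxm = config.darkfield_level + flatfield * config.alpha_true * dye
    darkfield = make_darkfield(config)
    fxm = fxm + (darkfield - config.darkfield_level)

    sigma_px = config.nuclear_sigma / config.pixel_size
    nuclear = np.full(config.shape, 10.0)
    cyto = np.full(config.shape, 10.0)
    rr = np.arange(config.fov_rows)
    cc = np.arange(config.fov_cols)
    for cell in cells:
        r, c = cell.center_rc
        r0 = max(int(r - 4 * sigma_px), 0)
        r1 = min(int(r + 4 * sigma_px) + 2, config.fov_rows)
        c0 = max(int(c - 4 * sigma_px), 0)
        c1 = min(int(c + 4 * sigma_px) + 2, config.fov_cols)
        if r1 <= r0 or c1 <= c0:
            continue
        g = np.exp(
            -((rr[r0:r1, None] - r) ** 2 + (cc[None, c0:c1] - c) ** 2)
            / (2 * sigma_px**2)
        )
        nuclear[r0:r1, c0:c1] += 500.0 * g
        hp = cell.height
        if hp.size:
            sl = np.s_[cell.r0 : cell.r0 + hp.shape[0], cell.c0 : cell.c0 + hp.shape[1]]
            cyto[sl] += 300.0 * (hp > 0)
    if config.noise_sd > 0 and rng is not None:
        fxm = fxm + rng.normal(0.0, config.noise_sd, config.shape)
        nuclear = nuclear + rng.normal(0.0, 2.0, config.shape)
        cyto = cyto + rng.normal(0.0, 2.0, config.shape)
    return fxm, nuclear, cyto


# ---------------------------------------------------------------------------
# full experiment


def _max_cell_radius(config: SimConfig) -> float:
    vp = config.volume_program
    vmax = vp.V0_median * np.exp(2 * np.sqrt(np.log1p(vp.V0_cv**2))) * (
        1 + vp.swell_fraction + vp.fluct_amplitude + 0.05
    )
    return dome_radius_for_volume(vmax, config.dome_aspect, config.chamber_height)


def simulate_experiment(config: SimConfig) -> SyntheticDataset:
    """Generate a full synthetic FxM experiment, deterministic given the config.

    Cells are placed and walked inside an inner arena that keeps their
    footprints clear of the pillar band and the field-of-view border; a simple
    excluded-volume rule (steps that would bring two centroids closer than one
    cell diameter are re-drawn) keeps footprints from overlapping, so per-cell
    ground truth stays exact.
    """
    rng = np.random.default_rng(config.seed)
    pillar_mask = make_pillar_mask(config)
    flatfield = make_flatfield(config, rng=np.random.default_rng(config.seed + 1))
    darkfield = make_darkfield(config)
    vp, mp = config.volume_program, config.motility

    n = config.n_cells
    V0 = (
        vp.V0_median * np.exp(rng.normal(0.0, np.sqrt(np.log1p(vp.V0_cv**2)), n))
        if n
        else np.zeros(0)
    )
    phases = rng.uniform(0, 2 * np.pi, n) if n else np.zeros(0)
    peak_factor = 1 + vp.swell_fraction + vp.fluct_amplitude + 0.02
    R_max_um = (
        dome_radius_for_volume(
            float(V0.max()) * peak_factor, config.dome_aspect, config.chamber_height
        )
        if n
        else _max_cell_radius(config)
    )
    pillar_band_px = 25 + config.pillar_radius  # pillars live within this border band
    margin_um = (pillar_band_px + 3) * config.pixel_size + R_max_um
    ext_x = config.fov_cols * config.pixel_size
    ext_y = config.fov_rows * config.pixel_size
    lo = np.array([margin_um, margin_um])
    hi = np.array([ext_x - margin_um, ext_y - margin_um])
    if np.any(hi <= lo):
        raise ValueError("field of view too small for the pillar layout")
    min_sep = 2 * R_max_um + 3.0  # µm, centroid separation floor

    positions = np.zeros((config.n_frames, n, 2))
    if n:
        placed = []
        attempts = 0
        while len(placed) < n:
            p = rng.uniform(lo, hi)
            if all(np.hypot(*(p - q)) >= min_sep for q in placed):
                placed.append(p)
            attempts += 1
            if attempts > 2000 * n:
                raise ValueError("cells denser than packable in the field of view")
        positions[0] = np.array(placed)
        headings = rng.uniform(0, 2 * np.pi, n)
        dt = config.frame_interval
        for f in range(1, config.n_frames):
            speed = mp.speed_pre if f <= config.stim_frame else mp.speed_post
            step = speed / 60.0 * dt
            for i in range(n):
                cur = positions[f - 1, i]
                ok = cur
                for _ in range(8):
                    headings[i] += rng.normal(0.0, mp.turn_sd)
                    cand = cur + step * np.array(
                        [np.cos(headings[i]), np.sin(headings[i])]
                    )
                    cand = np.clip(cand, lo, hi)  # arena walls confine the walk
                    others = np.delete(positions[f - 1], i, axis=0) if n > 1 else None
                    if others is None or np.all(
                        np.hypot(*(others - cand).T) >= min_sep
                    ):
                        ok = cand
                        break
                positions[f, i] = ok

    timestamps = np.arange(config.n_frames) * config.frame_interval
    stim_time = timestamps[config.stim_frame]

    fxm = np.empty((config.n_frames,) + config.shape, dtype=np.float32)
    nuc = np.empty_like(fxm)
    cyt = np.empty_like(fxm)
    rows = []
    footprints = {}
    px2 = config.pixel_size**2
    for f in range(config.n_frames):
        t_rel = timestamps[f] - stim_time
        cells = []
        for i in range(n):
            v_target = V0[i] * volume_schedule(t_rel, vp, phase=phases[i])
            R_um = dome_radius_for_volume(
                v_target, config.dome_aspect, config.chamber_height
            )
            h_peak = config.dome_aspect * R_um
            x, y = positions[f, i]
            r0, c0, patch = _height_patch(
                x, y, R_um, h_peak, config.chamber_height, config.pixel_size, config.shape
            )
            cells.append(
                CellRender(r0, c0, patch, (y / config.pixel_size, x / config.pixel_size))
            )
            true_v = px2 * float(patch.sum())
            rows.append((i, f, x, y, true_v))
            footprints[(i, f)] = (r0, c0, patch > 0)
        fr, nr, cr = render_frame(cells, config, flatfield, pillar_mask, rng)
        fxm[f], nuc[f], cyt[f] = fr, nr, cr

    table = pd.DataFrame(
        rows, columns=["cell_id", "frame", "x_um", "y_um", "true_volume_um3"]
    )
    truth = GroundTruth(table, footprints, flatfield, darkfield, pillar_mask)
    return SyntheticDataset(fxm, nuc, cyt, timestamps, config, truth)


# ---------------------------------------------------------------------------
# bulk assays


def simulate_gradient_counts(
    median_density_a: float,
    median_density_b: float,
    sd: float,
    n_cells: int,
    fraction_edges,
    calibration,
    seed: int = 0,
) -> pd.DataFrame:
    """Histogram two normally distributed cell-density populations into fractions.

    Cells falling outside the gradient range are counted in the end fractions
    (they pellet or float to the interface).  Each fraction's refractive index
    is the calibration line inverted at the fraction-center density.  Returns a
    DataFrame with columns fraction, ri, count_pop1, count_pop2.
    """
    edges = np.asarray(fraction_edges, dtype=float)
    if edges.ndim != 1 or edges.size < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("fraction_edges must be strictly increasing")
    if sd <= 0:
        raise ValueError("sd must be positive")
    rng = np.random.default_rng(seed)
    centers = 0.5 * (edges[:-1] + edges[1:])
    out = {"fraction": np.arange(centers.size)}
    out["ri"] = (centers - calibration.intercept) / calibration.slope
    for name, med in (("count_pop1", median_density_a), ("count_pop2", median_density_b)):
        rho = rng.normal(med, sd, n_cells)
        rho = np.clip(rho, edges[0], np.nextafter(edges[-1], edges[0]))
        out[name], _ = np.histogram(rho, bins=edges)
    df = pd.DataFrame(out)
    df["density"] = centers
    return df


def simulate_coulter_run(
    median_fl: float = 300.0,
    cv: float = 0.2,
    swell_fraction: float = 0.15,
    swell_tau_s: float = 240.0,
    n_timepoints: int = 20,
    n_per_timepoint: int = 5000,
    stim_timepoint: int = 3,
    dt_s: float = 60.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-timepoint Coulter-counter volume samples (fL), long-form.

    Volumes are lognormal with median following saturating swell kinetics after
    ``stim_timepoint``; emulates a suspension run sampled once per minute with
    a few pre-stimulus baseline timepoints.
    """
    if n_per_timepoint < 1:
        raise ValueError("n_per_timepoint must be >= 1")
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(np.log1p(cv**2))
    frames = []
    for k in range(n_timepoints):
        t = k * dt_s
        t_rel = (k - stim_timepoint) * dt_s
        med = median_fl
        if t_rel >= 0 and swell_tau_s > 0:
            med = median_fl * (1 + swell_fraction * (1 - np.exp(-t_rel / swell_tau_s)))
        elif t_rel >= 0:
            med = median_fl * (1 + swell_fraction)
        v = med * np.exp(rng.normal(0.0, sigma, n_per_timepoint))
        frames.append(pd.DataFrame({"time_s": t, "volume_fl": v}))
    return pd.concat(frames, ignore_index=True)
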
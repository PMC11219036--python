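"""End-to-end FxM analysis: segmentation → tracking → flatfield → volumetry → motility.

The pipeline consumes a :class:`FrameSet` (multi-channel stack plus darkfield,
pillar mask, timestamps and physical parameters), runs every stage per frame,
links detections into tracks, and emits a :class:`ResultBundle` of tidy tables
with a reproducibility manifest.  Per-cell-frame failures (occluded local
background, edge-touching cells) are recorded, not fatal.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skimage import morphology

from . import flatfield as ff
from . import io as _io
from . import motility as mot
from . import segmentation as seg
from . import tracking as trk
from . import volumetry as vol

__version__ = "0.1.0"

logger = logging.getLogger("fxmvol")

VOLUME_COLUMNS = [
    "track_id",
    "frame",
    "time_s",
    "area_um2",
    "imax",
    "volume_um3",
    "volume_norm",
    "volume_rollmed_um3",
    "edge_touching",
]
MOTILITY_COLUMNS = [
    "track_id",
    "frame",
    "time_s",
    "velocity_um_min",
    "alignment",
    "cumdist_um",
]


@dataclass
class PipelineParams:
    """Stage parameters for one run (physical geometry lives in FrameSet)."""

    seg: seg.SegParams = field(default_factory=seg.SegParams)
    max_disp_um: float = 15.0
    memory: int = 2
    link_mode: str = "greedy"
    ff_n_points: int = 200
    ff_n_periods: int = 4
    ff_margin: int = 10
    ff_epsilon: float = None
    ff_ridge: float = 1e-8
    exclusion_dilation: int = 3
    annulus_in: float = 2.0
    annulus_out: float = 10.0
    rolling_window: int = 7
    velocity_tau: int = 3
    alignment_offset_um: float = 10.0


@dataclass
class FrameSet:
    """In-memory experiment: stacks, reference images and physical geometry.

    Coordinates are image-convention: x = col·pixel_size, y = row·pixel_size,
    origin at the top-left pixel, 0-based.
    """

    fxm: np.ndarray
    nuclear: np.ndarray
    cyto: np.ndarray
    darkfield: np.ndarray
    pillar_mask: np.ndarray
    timestamps: np.ndarray
    pixel_size: float
    chamber_height: float
    stim_time: float

    def __post_init__(self):
        shapes = {self.fxm.shape, self.nuclear.shape, self.cyto.shape}
        if len(shapes) != 1:
            raise ValueError("channel stacks must share one shape")
        if self.fxm.shape[1:] != self.pillar_mask.shape:
            raise ValueError("pillar mask shape does not match the stacks")
        if len(self.timestamps) != self.fxm.shape[0]:
            raise ValueError("timestamp count does not match frame count")
        if np.any(np.diff(self.timestamps) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if self.pixel_size <= 0 or self.chamber_height <= 0:
            raise ValueError("pixel_size and chamber_height must be positive")

    @classmethod
    def from_dataset(cls, dataset) -> "FrameSet":
        """Wrap a simulated experiment without a disk round-trip."""
        c = dataset.config
        return cls(
            fxm=np.asarray(dataset.fxm_stack, dtype=float),
            nuclear=np.asarray(dataset.nuclear_stack, dtype=float),
            cyto=np.asarray(dataset.cyto_stack, dtype=float),
            darkfield=dataset.truth.darkfield,
            pillar_mask=dataset.truth.pillar_mask,
            timestamps=np.asarray(dataset.timestamps, dtype=float),
            pixel_size=c.pixel_size,
            chamber_height=c.chamber_height,
            stim_time=dataset.stim_time,
        )


@dataclass
class ResultBundle:
    tracks: pd.DataFrame
    volumes: pd.DataFrame
    motility: pd.DataFrame
    volume_summary: pd.DataFrame
    velocity_summary: pd.DataFrame
    labels: np.ndarray  # (n_frames, H, W) uint16 instance labels per frame
    manifest: dict

    def write(self, outdir):
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.tracks.to_csv(out / "tracks.csv", index=False)
        self.volumes.to_csv(out / "volumes.csv", index=False)
        self.motility.to_csv(out / "motility.csv", index=False)
        self.volume_summary.to_csv(out / "volume_summary.csv", index=False)
        self.velocity_summary.to_csv(out / "velocity_summary.csv", index=False)
        import tifffile

        tifffile.imwrite(out / "labels.tif", self.labels, photometric="minisblack")
        _io.write_manifest(self.manifest, out / "manifest.json")


def load_frameset(config: dict) -> FrameSet:
    """Build a FrameSet from a flat config mapping of paths and parameters."""
    root = Path(config.get("input_dir", "."))

    def _p(key, default):
        return root / config.get(key, default)

    fxm = _io.read_stack(_p("fxm_stack", "fxm.tif"))
    nuclear = _io.read_stack(_p("nuclear_stack", "nuclear.tif"))
    cyto = _io.read_stack(_p("cyto_stack", "cyto.tif"))
    darkfield = _io.read_image(_p("darkfield", "darkfield.tif"))
    pillar = _io.read_image(_p("pillar_mask", "pillar_mask.tif")) > 0
    timestamps = _io.read_timestamps(_p("timestamps", "timestamps.csv"), fxm.shape[0])
    return FrameSet(
        fxm=fxm,
        nuclear=nuclear,
        cyto=cyto,
        darkfield=darkfield,
        pillar_mask=pillar,
        timestamps=timestamps,
        pixel_size=float(config["pixel_size"]),
        chamber_height=float(config["chamber_height"]),
        stim_time=float(config["stim_time"]),
    )


def run_pipeline(
    frames: FrameSet, params: PipelineParams = None, seed: int = 0
) -> ResultBundle:
    """Run every stage over a FrameSet and return tidy result tables.

    Deterministic given (frames, params, seed): no stage draws random numbers,
    the seed is recorded in the manifest for provenance.
    """
    params = params or PipelineParams()
    t = frames.timestamps
    if not np.any((t >= frames.stim_time - 120.0) & (t < frames.stim_time)):
        raise ValueError(
            "baseline undefined: no frames in the 2 min window before stimulation"
        )
    n_frames = frames.fxm.shape[0]
    px = frames.pixel_size
    pillar = frames.pillar_mask
    pillar_dil = morphology.dilation(
        pillar, morphology.disk(params.exclusion_dilation)
    )

    all_labels = np.zeros(frames.fxm.shape, dtype=np.uint16)
    detections, det_labels = [], []
    per_frame_measures = {}  # (frame, label) -> dict
    counts = {"occluded": 0, "edge_touching": 0, "unseeded_seeds": 0}

    for f in range(n_frames):
        raw = frames.fxm[f]
        den = seg.denoise(raw, params.seg.denoise_sigma)
        mag = seg.edge_magnitude(den)
        fg = seg.threshold_foreground(mag, params.seg, pillar_mask=pillar)
        seeds = seg.detect_seeds(frames.nuclear[f], params.seg)
        labels, seed_labels = seg.split_instances(fg, seeds)
        all_labels[f] = labels.astype(np.uint16)

        fg_dil = morphology.dilation(
            fg, morphology.disk(params.exclusion_dilation)
        )
        exclusion = fg_dil | pillar_dil
        pts = ff.sample_points(
            raw.shape,
            exclusion,
            n_points=params.ff_n_points,
            n_periods=params.ff_n_periods,
            margin=params.ff_margin,
        )
        bg_field = ff.fit_interpolant(
            pts,
            ff.sample_values(raw, pts, exclusion_mask=exclusion),
            epsilon=params.ff_epsilon,
            ridge=params.ff_ridge,
        )
        corrected = ff.correct(raw, frames.darkfield, bg_field)
        calib = vol.alpha_calibration(
            corrected, pillar, ~exclusion, frames.chamber_height
        )

        kept = []
        kept_labs = []
        for i, lab in enumerate(seed_labels):
            if lab == 0:
                counts["unseeded_seeds"] += 1
                continue
            footprint = labels == lab
            area = vol.footprint_area(footprint, px)
            rec = {"area_um2": area, "imax": np.nan, "volume_um3": np.nan,
                   "edge_touching": False}
            try:
                imax = vol.local_background(
                    corrected, labels, lab, pillar_mask=pillar,
                    r_in=params.annulus_in, r_out=params.annulus_out,
                )
                rec["imax"] = imax
                rec["volume_um3"] = vol.cell_volume(
                    corrected, footprint, imax, calib.alpha, px
                )
            except vol.EdgeTouching:
                rec["edge_touching"] = True
                counts["edge_touching"] += 1
            except vol.LocalityOccluded:
                counts["occluded"] += 1
            per_frame_measures[(f, int(lab))] = rec
            r, c = seeds[i]
            kept.append((c * px, r * px))
            kept_labs.append(int(lab))
        detections.append(np.asarray(kept, dtype=float).reshape(-1, 2))
        det_labels.append(np.asarray(kept_labs, dtype=int))
        logger.debug("frame %d: %d cells, alpha=%.4g", f, len(kept), calib.alpha)

    tracks = trk.link(
        detections,
        max_disp=params.max_disp_um,
        memory=params.memory,
        times=frames.timestamps,
        labels=det_labels,
        mode=params.link_mode,
    )

    volumes, motility = _per_track_tables(
        tracks, per_frame_measures, frames, params
    )
    volume_summary = _summary(volumes, "volume_norm")
    velocity_summary = _summary(motility, "velocity_um_min")

    manifest = {
        "software": f"fxmvol {__version__}",
        "seed": seed,
        "n_frames": n_frames,
        "n_tracks": int(tracks["track_id"].nunique()) if len(tracks) else 0,
        "n_cell_frames": len(volumes),
        "counts": counts,
        "config_hash": config_hash(
            {
                "pixel_size": px,
                "chamber_height": frames.chamber_height,
                "stim_time": frames.stim_time,
                "params": _params_dict(params),
                "seed": seed,
            }
        ),
    }
    return ResultBundle(
        tracks, volumes, motility, volume_summary, velocity_summary, all_labels, manifest
    )


def _per_track_tables(tracks, measures, frames, params):
    vol_rows = []
    mot_rows = []
    if not len(tracks):
        return (
            pd.DataFrame(columns=VOLUME_COLUMNS),
            pd.DataFrame(columns=MOTILITY_COLUMNS),
        )
    for tid, sub in tracks.groupby("track_id"):
        sub = sub.sort_values("frame")
        t = sub["time_s"].to_numpy(dtype=float)
        recs = [
            measures.get((int(fr), int(lb)), None)
            for fr, lb in zip(sub["frame"], sub["label"])
        ]
        v = np.array(
            [np.nan if r is None else r["volume_um3"] for r in recs], dtype=float
        )
        try:
            trace = vol.build_volume_trace(
                v, t, frames.stim_time, rolling_window=params.rolling_window
            )
        except ValueError:
            trace = None  # no usable pre-stimulation baseline for this track
        xy = sub[["x_um", "y_um"]].to_numpy(dtype=float)
        vel = (
            mot.velocity(xy, t, tau=params.velocity_tau)
            if len(xy) > 2 * params.velocity_tau
            else np.full(len(xy), np.nan)
        )
        align = mot.angular_alignment(xy, distance_offset=params.alignment_offset_um)
        cum = mot.cumulative_distance(xy)
        for i, (fr, lb) in enumerate(zip(sub["frame"], sub["label"])):
            r = recs[i] or {}
            vol_rows.append(
                (
                    tid,
                    int(fr),
                    t[i],
                    r.get("area_um2", np.nan),
                    r.get("imax", np.nan),
                    v[i],
                    trace["volume_norm"].iloc[i] if trace is not None else np.nan,
                    trace["volume_rollmed_um3"].iloc[i] if trace is not None else np.nan,
                    bool(r.get("edge_touching", False)),
                )
            )
            mot_rows.append((tid, int(fr), t[i], vel[i], align[i], cum[i]))
    volumes = pd.DataFrame(vol_rows, columns=VOLUME_COLUMNS)
    motility = pd.DataFrame(mot_rows, columns=MOTILITY_COLUMNS)
    return volumes, motility


def _summary(table, value_col):
    df = table.rename(columns={value_col: "value"})[["time_s", "value"]].copy()
    df["replicate"] = 1  # single-replicate run; multi-replicate merging upstream
    return mot.population_summary(df, value="value")


def _params_dict(params: PipelineParams) -> dict:
    import dataclasses

    d = dataclasses.asdict(params)
    return d


def config_hash(obj) -> str:
    payload = json.dumps(_io._plain(obj), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]
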
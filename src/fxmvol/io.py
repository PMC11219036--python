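"""File I/O: TIFF stacks, CSV tables, configuration documents."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml


def write_dataset(dataset, outdir):
    """Write a synthetic experiment as TIFFs + CSVs (the on-disk layout the
    pipeline consumes): one stack per channel, darkfield and pillar-mask
    images, a timestamps CSV and the ground-truth table."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(out / "fxm.tif", dataset.fxm_stack.astype(np.float32), photometric="minisblack")
    tifffile.imwrite(out / "nuclear.tif", dataset.nuclear_stack.astype(np.float32), photometric="minisblack")
    tifffile.imwrite(out / "cyto.tif", dataset.cyto_stack.astype(np.float32), photometric="minisblack")
    tifffile.imwrite(out / "darkfield.tif", dataset.truth.darkfield.astype(np.float32))
    tifffile.imwrite(
        out / "pillar_mask.tif", dataset.truth.pillar_mask.astype(np.uint16)
    )
    pd.DataFrame(
        {"frame": np.arange(len(dataset.timestamps)), "time_s": dataset.timestamps}
    ).to_csv(out / "timestamps.csv", index=False)
    dataset.truth.table.to_csv(out / "ground_truth.csv", index=False)
    cfg = dataset.config.to_dict()
    with open(out / "sim_config.yaml", "w") as fh:
        yaml.safe_dump(_plain(cfg), fh, sort_keys=True)


def _plain(obj):
    """Recursively convert numpy scalars/arrays to plain python for YAML/JSON."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def read_stack(path) -> np.ndarray:
    arr = tifffile.imread(path).astype(float)
    if arr.ndim == 2:
        arr = arr[None]
    return arr


def read_image(path) -> np.ndarray:
    return tifffile.imread(path).astype(float)


def read_timestamps(path, n_frames: int) -> np.ndarray:
    df = pd.read_csv(path)
    if {"frame", "time_s"} - set(df.columns):
        raise ValueError("timestamps CSV needs columns frame, time_s")
    df = df.sort_values("frame")
    missing = set(range(n_frames)) - set(df["frame"].astype(int))
    if missing:
        raise ValueError(f"missing timestamp for frame {sorted(missing)[0]}")
    t = df["time_s"].to_numpy(dtype=float)[:n_frames]
    if np.any(np.diff(t) <= 0):
        raise ValueError("timestamps must be strictly increasing")
    return t


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config must be a mapping of keys to values")
    return cfg


def write_manifest(manifest: dict, path):
    with open(path, "w") as fh:
        json.dump(_plain(manifest), fh, indent=2, sort_keys=True)
        fh.write("\n")
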
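import warnings

import numpy as np
import pandas as pd
import pytest

import fxmvol as fx

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def small_config():
    """Compact experiment used across the suite: same physics as the default
    conditions (1% noise, 20% flatfield), smaller field and fewer cells."""
    return fx.SimConfig(
        fov_rows=400, fov_cols=400, n_frames=30, n_cells=10, stim_frame=13
    )


@pytest.fixture(scope="session")
def small_ds(small_config):
    return fx.simulate_experiment(small_config)


@pytest.fixture(scope="session")
def small_result(small_ds):
    return fx.run_pipeline(fx.FrameSet.from_dataset(small_ds))


def match_tracks_to_truth(result, dataset) -> pd.DataFrame:
    """Assign each pipeline detection to its nearest ground-truth cell."""
    rows = []
    gt = dataset.truth.table
    for f in sorted(result.tracks["frame"].unique()):
        g = gt[gt["frame"] == f].reset_index(drop=True)
        sub = result.tracks[result.tracks["frame"] == f]
        for _, row in sub.iterrows():
            d = np.hypot(g["x_um"] - row["x_um"], g["y_um"] - row["y_um"])
            j = int(d.idxmin())
            rows.append((row["track_id"], f, g.loc[j, "cell_id"], float(d.min())))
    return pd.DataFrame(rows, columns=["track_id", "frame", "cell_id", "dist_um"])


@pytest.fixture(scope="session")
def small_match(small_result, small_ds):
    return match_tracks_to_truth(small_result, small_ds)
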
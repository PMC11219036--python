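"""Bulk swelling assays: buoyant-density gradients and Coulter-counter series.

A Percoll gradient is fractionated into wells whose refractive index (RI) is
measured; density is linear in RI, so a two-point calibration converts RI to
g/mL.  Per-fraction cell counts give a density distribution per population;
the population median is the count-weighted median with linear interpolation
inside the median fraction (fractions are density intervals), and the
stimulation-induced density shift is the difference of medians.  For CRISPR
screening, fractions are partitioned into contiguous bins each holding about a
third of the population.  Coulter runs reduce to a per-timepoint median volume
normalized to the first few baseline timepoints.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DensityCalibration",
    "fit_density_calibration",
    "ri_to_density",
    "weighted_median_density",
    "gradient_profile",
    "partition_bins",
    "coulter_median_series",
    "water_content_increase",
]


@dataclass(frozen=True)
class DensityCalibration:
    """density [g/mL] = slope * RI + intercept."""

    slope: float
    intercept: float

    def density(self, ri):
        return self.slope * np.asarray(ri, dtype=float) + self.intercept

    def ri(self, density):
        return (np.asarray(density, dtype=float) - self.intercept) / self.slope


def fit_density_calibration(pairs) -> DensityCalibration:
    """Least-squares line through (RI, density) pairs; exact through two points."""
    arr = np.asarray(pairs, dtype=float).reshape(-1, 2)
    if len(arr) < 2 or np.ptp(arr[:, 0]) == 0:
        raise ValueError("need at least 2 distinct refractive indices")
    slope, intercept = np.polyfit(arr[:, 0], arr[:, 1], 1)
    return DensityCalibration(float(slope), float(intercept))


def ri_to_density(calibration: DensityCalibration, ri):
    return calibration.density(ri)


def weighted_median_density(densities, counts) -> float:
    """Count-weighted median density, interpolating within the median fraction.

    Fractions are treated as contiguous density intervals whose edges are the
    midpoints between neighboring fraction densities (end fractions extend
    symmetrically); the grouped-data median formula places the median inside
    its fraction proportionally to the cumulative count.
    """
    rho = np.asarray(densities, dtype=float)
    cnt = np.asarray(counts, dtype=float)
    if rho.shape != cnt.shape or rho.ndim != 1:
        raise ValueError("densities and counts must be 1-D and equal length")
    if np.any(cnt < 0):
        raise ValueError("counts must be non-negative")
    total = cnt.sum()
    if total <= 0:
        raise ValueError("population has no cells")
    order = np.argsort(rho)
    rho, cnt = rho[order], cnt[order]
    if len(rho) == 1:
        return float(rho[0])
    mids = 0.5 * (rho[:-1] + rho[1:])
    lower = np.concatenate([[rho[0] - (mids[0] - rho[0])], mids])
    upper = np.concatenate([mids, [rho[-1] + (rho[-1] - mids[-1])]])
    cum = np.cumsum(cnt)
    k = int(np.searchsorted(cum, total / 2.0, side="left"))
    before = cum[k] - cnt[k]
    width = upper[k] - lower[k]
    return float(lower[k] + (total / 2.0 - before) / cnt[k] * width)


def gradient_profile(counts, ri, calibration: DensityCalibration):
    """Build a fraction-level density profile and per-population medians.

    ``counts`` is (n_fractions,) for one population or (n_fractions, n_pop);
    with two populations (unstimulated, stimulated) the density shift
    Δρ = median(pop2) − median(pop1) is reported.  Returns (profile DataFrame,
    medians list, shift or None).
    """
    cnt = np.asarray(counts, dtype=float)
    if cnt.ndim == 1:
        cnt = cnt[:, None]
    ri = np.asarray(ri, dtype=float)
    if len(ri) != cnt.shape[0]:
        raise ValueError("counts and RI arrays must have the same length")
    rho = calibration.density(ri)
    profile = pd.DataFrame({"fraction": np.arange(len(ri)), "ri": ri, "density": rho})
    medians = []
    for p in range(cnt.shape[1]):
        if cnt[:, p].sum() <= 0:
            raise ValueError(f"population {p + 1} has all-zero counts")
        profile[f"count_pop{p + 1}"] = cnt[:, p]
        medians.append(weighted_median_density(rho, cnt[:, p]))
    shift = medians[1] - medians[0] if len(medians) >= 2 else None
    return profile, medians, shift


def partition_bins(counts, n_bins: int = 3):
    """Split fractions into contiguous bins of roughly equal population.

    Cut points fall where the cumulative count first reaches k/n_bins of the
    total.  Returns a list of (start, stop) fraction-index ranges (stop
    exclusive); raises if the counts cannot form ``n_bins`` nonempty bins.
    """
    cnt = np.asarray(counts, dtype=float)
    total = cnt.sum()
    if total <= 0:
        raise ValueError("total counts must be positive")
    if len(cnt) < n_bins:
        raise ValueError("fewer fractions than bins")
    cum = np.cumsum(cnt)
    cuts = []
    for k in range(1, n_bins):
        idx = int(np.searchsorted(cum, k * total / n_bins, side="left"))
        cuts.append(idx + 1)  # bin boundary after the crossing fraction
    edges = [0] + cuts + [len(cnt)]
    if any(edges[i + 1] <= edges[i] for i in range(n_bins)):
        raise ValueError(f"cannot form {n_bins} nonempty bins from these counts")
    bins = [(edges[i], edges[i + 1]) for i in range(n_bins)]
    if any(cnt[a:b].sum() <= 0 for a, b in bins):
        raise ValueError(f"cannot form {n_bins} nonempty bins from these counts")
    return bins


def coulter_median_series(samples, times=None, baseline_n: int = 3) -> pd.DataFrame:
    """Median-volume time series from per-timepoint Coulter samples.

    ``samples`` is either a long DataFrame with columns time_s and volume_fl,
    or a sequence of per-timepoint arrays (with ``times`` supplied).  The
    normalized series divides each median by the mean of the first
    ``baseline_n`` medians.
    """
    if isinstance(samples, pd.DataFrame):
        grouped = [
            (float(t), np.asarray(g["volume_fl"], dtype=float))
            for t, g in samples.groupby("time_s", sort=True)
        ]
    else:
        if times is None:
            times = np.arange(len(samples), dtype=float)
        grouped = [(float(t), np.asarray(s, dtype=float)) for t, s in zip(times, samples)]
    if len(grouped) < baseline_n:
        raise ValueError(f"need at least {baseline_n} timepoints for the baseline")
    t = np.array([g[0] for g in grouped])
    med = np.array([np.median(g[1]) for g in grouped])
    if np.any(med <= 0):
        raise ValueError("medians must be positive")
    baseline = med[:baseline_n].mean()
    return pd.DataFrame(
        {"time_s": t, "median_fl": med, "median_norm": med / baseline}
    )


def water_content_increase(volume_increase: float = 0.15, water_fraction: float = 0.65) -> float:
    """Fractional increase in cell water content for a given whole-cell swell.

    If the added volume is all water, a cell that is ``water_fraction`` water
    and swells by ``volume_increase`` gains volume_increase / water_fraction
    of its initial water content (0.15 on 65% water ≈ 0.23).
    """
    if not 0 < water_fraction <= 1:
        raise ValueError("water_fraction must lie in (0, 1]")
    return volume_increase / water_fraction
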
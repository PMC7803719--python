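"""Depth-quantile binning and per-bin ROI mean time courses.

Voxels inside a region of interest are divided into equal-count bins of
normalized cortical depth (0 = gray/white border, 1 = pial surface) and
averaged, yielding one mean time course per (ROI, depth bin).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["DepthBinning", "DepthTimecourses", "depth_quantile_bins", "roi_depth_timecourse"]


@dataclass
class DepthBinning:
    """Equal-count depth bins for the voxels of one ROI."""

    n_bins: int
    edges: np.ndarray        # length n_bins + 1, spanning the in-mask depths
    assignment: np.ndarray   # bin index per in-mask voxel
    voxel_index: np.ndarray  # flat indices of the in-mask voxels


@dataclass
class DepthTimecourses:
    """Mean percent-BOLD signal per (depth bin, time sample) for one ROI."""

    roi: int
    signals: np.ndarray      # (n_runs, n_bins, n_samples)
    counts: np.ndarray       # voxels per bin
    mean_depth: np.ndarray   # mean normalized depth per bin
    dt: float


def depth_quantile_bins(
    depth_map: np.ndarray, roi_mask: np.ndarray, n_bins: int = 5
) -> DepthBinning:
    """Bin in-mask voxels into ``n_bins`` depth quantiles.

    Edges sit at the empirical quantiles of the in-mask depths, so bin
    sizes differ by at most one voxel when depths are distinct. Voxels
    exactly on an inner edge go to the deeper (lower) bin.
    """
    depth = np.asarray(depth_map, dtype=float).ravel()
    mask = np.asarray(roi_mask, dtype=bool).ravel()
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise ValueError("ROI mask is empty")
    if idx.size < n_bins:
        raise ValueError(f"only {idx.size} in-mask voxels for {n_bins} bins")
    d = depth[idx]
    if np.any((d < 0) | (d > 1)):
        raise ValueError("depth values must lie in [0, 1]")
    edges = np.quantile(d, np.linspace(0.0, 1.0, n_bins + 1))
    if np.any(np.diff(edges) <= 0):
        raise ValueError("degenerate depth quantiles (too many tied depths)")
    assignment = np.searchsorted(edges[1:-1], d, side="left")
    return DepthBinning(n_bins, edges, assignment, idx)


def roi_depth_timecourse(
    series: np.ndarray,
    binning: DepthBinning,
    depth_map: np.ndarray,
    roi: int,
    dt: float,
) -> DepthTimecourses:
    """Average conditioned voxel series within each depth bin.

    ``series`` is (n_runs, n_voxels_flat, n_samples) in percent units; the
    unweighted voxel mean is taken per bin at each time sample. The per-bin
    mean normalized depth is reported alongside, for use as the regressor
    in the depth-trend fit.
    """
    series = np.asarray(series, dtype=float)
    depth = np.asarray(depth_map, dtype=float).ravel()
    n_runs, _, n_samp = series.shape
    signals = np.empty((n_runs, binning.n_bins, n_samp))
    counts = np.empty(binning.n_bins, dtype=int)
    mean_depth = np.empty(binning.n_bins)
    for b in range(binning.n_bins):
        vox = binning.voxel_index[binning.assignment == b]
        if vox.size == 0:
            raise ValueError(f"depth bin {b} of ROI {roi} is empty")
        signals[:, b, :] = series[:, vox, :].mean(axis=1)
        counts[b] = vox.size
        mean_depth[b] = depth[vox].mean()
    return DepthTimecourses(roi, signals, counts, mean_depth, dt)
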
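"""Per-voxel time-series conditioning: despike, scale, detrend, resample.

The stages mirror the standard per-voxel preparation of block-design BOLD
runs: isolated signal spikes are replaced, the series is converted to
percent signal change around a zero mean, slow scanner drift is removed
with a low-order polynomial, and the series is linearly resampled onto the
analysis grid (half the volume TR, matching the onset jitter). The order
is fixed — despike -> scale -> detrend -> resample — and each run is
conditioned independently.
"""

from __future__ import annotations

import numpy as np
from numpy.polynomial import polynomial as P
from scipy import ndimage

__all__ = [
    "despike",
    "scale_percent",
    "detrend_poly",
    "resample_linear",
    "condition_run",
    "DespikeError",
    "ZeroMeanError",
]

_MED_WINDOW = 5


class DespikeError(ValueError):
    pass


class ZeroMeanError(ValueError):
    pass


def _spike_mask(x: np.ndarray, z_thresh: float) -> np.ndarray:
    """Flag isolated outliers via robust z of the rolling-median residual.

    The residual from a centered rolling median tracks smooth signal while
    exposing single-point excursions; sigma is the MAD-based robust scale
    of that residual. When the MAD collapses to zero (locally flat series)
    any nonzero residual counts as a spike.
    """
    med = ndimage.median_filter(x, size=_MED_WINDOW, mode="reflect")
    resid = x - med
    mad = np.median(np.abs(resid - np.median(resid)))
    sigma = 1.4826 * mad
    if sigma > 0:
        return np.abs(resid) > z_thresh * sigma
    scale = max(np.max(np.abs(x)), 1.0)
    return np.abs(resid) > 1e-12 * scale


def _replace_spikes(x: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Replace flagged samples with the mean of the closest clean neighbors.

    One neighbor is taken on each side (single-sided at the series edges).
    """
    if mask.all():
        raise DespikeError("every sample flagged as a spike; cannot despike")
    good = np.flatnonzero(~mask)
    out = np.array(x, copy=True)
    for i in np.flatnonzero(mask):
        pos = np.searchsorted(good, i)
        neighbors = []
        if pos > 0:
            neighbors.append(x[good[pos - 1]])
        if pos < len(good):
            neighbors.append(x[good[pos]])
        out[i] = np.mean(neighbors)
    return out


def despike(x: np.ndarray, z_thresh: float = 5.0) -> tuple[np.ndarray, int]:
    """Despike along the last (time) axis; returns (series, spikes replaced)."""
    x = np.asarray(x, dtype=float)
    if x.shape[-1] < 3:
        raise ValueError("despike needs at least 3 time points")
    flat = x.reshape(-1, x.shape[-1])
    out = np.empty_like(flat)
    n_spikes = 0
    for v in range(flat.shape[0]):
        mask = _spike_mask(flat[v], z_thresh)
        n_spikes += int(mask.sum())
        out[v] = _replace_spikes(flat[v], mask) if mask.any() else flat[v]
    return out.reshape(x.shape), n_spikes


def scale_percent(x: np.ndarray) -> np.ndarray:
    """Convert to percent signal change: 100*x/mean(x) - 100, per voxel.

    The output has temporal mean exactly zero (to floating tolerance). A
    voxel with zero temporal mean is reported by index.
    """
    x = np.asarray(x, dtype=float)
    mean = x.mean(axis=-1, keepdims=True)
    scale = np.max(np.abs(x), axis=-1, keepdims=True)
    bad = np.abs(mean) <= 1e-12 * np.maximum(scale, 1.0)
    if np.any(bad):
        idx = tuple(int(i) for i in np.argwhere(bad[..., 0])[0])
        raise ZeroMeanError(f"zero temporal mean at voxel index {idx}")
    return 100.0 * x / mean - 100.0


def detrend_poly(x: np.ndarray, max_degree: int = 4) -> np.ndarray:
    """Remove a least-squares polynomial of degree ``max_degree`` in time.

    The residual is orthogonal to all polynomial basis terms up to that
    degree. Fitted on time normalized to [-1, 1] for conditioning.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[-1]
    if n <= max_degree + 1:
        raise ValueError(f"need more than {max_degree + 1} samples to detrend")
    t = np.linspace(-1.0, 1.0, n)
    flat = x.reshape(-1, n)
    coeffs = P.polyfit(t, flat.T, max_degree)
    fit = P.polyval(t, coeffs)
    return (flat - fit).reshape(x.shape)


def resample_linear(x: np.ndarray, dt_in: float, dt_out: float) -> np.ndarray:
    """Linear temporal resampling onto the grid t = 0, dt_out, ...

    The output grid spans the same closed interval as the input (the last
    input time point is included when it is a multiple of ``dt_out``);
    endpoints are preserved exactly.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[-1]
    total = (n - 1) * dt_in
    if dt_out <= 0:
        raise ValueError("dt_out must be positive")
    if dt_out > total:
        raise ValueError("dt_out exceeds the series duration")
    n_out = int(np.floor(total / dt_out + 1e-9)) + 1
    t_in = np.arange(n) * dt_in
    t_out = np.arange(n_out) * dt_out
    flat = x.reshape(-1, n)
    out = np.empty((flat.shape[0], n_out))
    for v in range(flat.shape[0]):
        out[v] = np.interp(t_out, t_in, flat[v])
    return out.reshape(x.shape[:-1] + (n_out,))


def condition_run(
    x: np.ndarray,
    dt_in: float,
    dt_out: float,
    despike_z: float = 5.0,
    detrend_degree: int = 4,
) -> tuple[np.ndarray, int]:
    """Full fixed-order conditioning of one run: despike, scale, detrend, resample.

    Returns the conditioned series (percent units, zero mean before
    resampling) and the number of spikes replaced.
    """
    y, n_spikes = despike(x, despike_z)
    y = scale_percent(y)
    y = detrend_poly(y, detrend_degree)
    y = resample_linear(y, dt_in, dt_out)
    return y, n_spikes
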
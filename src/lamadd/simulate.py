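"""Forward simulator for laminar BOLD with known ground truth.

The generative chain is: boxcar neuronal drive -> local hemodynamic
response per depth (drive convolved with an HRF, scaled by a depth profile)
-> draining mixture across depth (superficial depths inherit a weighted
integral of the responses below them, emulating venous blood pooling
toward the pial surface) -> baseline/drift/AR(1) measurement noise.

Two switches create known additivity violations for power analyses:

* ``saturation`` / ``adaptation`` nonlinearities on the response or drive;
* per-duration draining weights (``drain_weights_alt``), the case where the
  pooled response to a long stimulus is drained differently from the
  responses to the short stimuli that compose it.

Pearson correlation — the additivity statistic downstream — is invariant to
per-depth scaling, so a depth-graded *shape* violation additionally needs
shape heterogeneity across depth; the optional per-depth HRF peak delay
provides it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

from .design import StimulusDesign, neuronal_drive
from .hrf import HrfParams, double_gamma

__all__ = [
    "LaminarModel",
    "NoiseSpec",
    "SyntheticDataset",
    "local_response",
    "apply_draining",
    "add_noise",
    "inject_nonlinearity",
    "simulate_depth_series",
    "render_voxels",
]


@dataclass
class LaminarModel:
    """Depth grid, local amplitude profile and draining weights.

    Depth is normalized to [0, 1]: 0 at the gray/white border, 1 at the
    pial surface. ``drain_weights[j]`` weights the contribution of source
    depth j to all more superficial depths; ``drain_weights_alt`` optionally
    maps a stimulus duration to a different weight vector, simulating a
    violation of laminar temporal additivity. ``hrf_peak_delay_by_depth``
    optionally varies the HRF peak delay across depth (shape heterogeneity).
    """

    n_depths: int = 5
    depth_values: np.ndarray | None = None
    local_amplitude: np.ndarray | None = None
    drain_weights: np.ndarray | None = None
    drain_weights_alt: dict[float, np.ndarray] | None = None
    hrf: HrfParams = field(default_factory=HrfParams)
    hrf_peak_delay_by_depth: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = self.n_depths
        if self.depth_values is None:
            self.depth_values = (np.arange(n) + 0.5) / n
        if self.local_amplitude is None:
            # peak percent-BOLD profile rising toward the surface (1.3-3.4%
            # after draining with the default weights, for 10.4 s blocks)
            self.local_amplitude = 0.25 + 0.35 * np.asarray(self.depth_values)
        if self.drain_weights is None:
            self.drain_weights = np.full(n, 0.5)
        self.depth_values = np.asarray(self.depth_values, dtype=float)
        self.local_amplitude = np.asarray(self.local_amplitude, dtype=float)
        self.drain_weights = np.asarray(self.drain_weights, dtype=float)
        if np.any(np.diff(self.depth_values) <= 0):
            raise ValueError("depth_values must be sorted ascending")
        if not np.all(np.isfinite(self.drain_weights)) or np.any(self.drain_weights < 0):
            raise ValueError("draining weights must be finite and >= 0")
        self.hrf.validate()

    def weights_for(self, duration: float) -> np.ndarray:
        if self.drain_weights_alt:
            for d, w in self.drain_weights_alt.items():
                if abs(d - duration) < 1e-9:
                    return np.asarray(w, dtype=float)
        return self.drain_weights

    def hrf_kernel(self, dt: float, depth_index: int | None = None) -> np.ndarray:
        params = self.hrf
        if depth_index is not None and self.hrf_peak_delay_by_depth is not None:
            params = replace(params, peak_delay_s=float(self.hrf_peak_delay_by_depth[depth_index]))
        return double_gamma(dt, params)


@dataclass(frozen=True)
class NoiseSpec:
    """Measurement-noise model: polynomial drift plus AR(1) noise.

    ``sigma`` is the innovation standard deviation in raw signal units
    (equal to percent-BOLD for the default baseline of 100); the stationary
    standard deviation is sigma / sqrt(1 - ar1^2). ``drift_coeffs`` are
    polynomial coefficients over normalized run time in [0, 1], raw units.
    """

    sigma: float = 0.6
    ar1: float = 0.35
    drift_coeffs: tuple[float, ...] = (0.0, 2.0, -1.5, 0.8, -0.3)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if not (0 <= self.ar1 < 1):
            raise ValueError("ar1 must lie in [0, 1)")
        if len(self.drift_coeffs) > 5:
            raise ValueError("drift polynomial supports up to degree 4")


@dataclass
class SyntheticDataset:
    """Voxel-rendered session: raw series plus depth/ROI maps and truth."""

    series: np.ndarray        # (n_runs, nx, ny, nz, n_volumes), raw units
    depth_map: np.ndarray     # (nx, ny, nz) in [0, 1]
    roi_labels: np.ndarray    # (nx, ny, nz) integer, 0 = outside
    design: StimulusDesign
    truth: LaminarModel
    tr_s: float

    @property
    def n_runs(self) -> int:
        return self.series.shape[0]

    @property
    def n_volumes(self) -> int:
        return self.series.shape[-1]


def local_response(drive: np.ndarray, model: LaminarModel, dt: float) -> np.ndarray:
    """Hemodynamic transform of the drive at each depth.

    Returns an array with a depth axis inserted before time:
    ``drive`` (..., T) -> L (..., n_depths, T), percent BOLD. The response
    is a causal discrete convolution of the drive with the HRF, scaled by
    the per-depth local amplitude.
    """
    drive = np.asarray(drive, dtype=float)
    if not np.all(np.isfinite(drive)):
        raise ValueError("drive must be finite")
    T = drive.shape[-1]
    out = np.empty(drive.shape[:-1] + (model.n_depths, T))
    shared = None
    if model.hrf_peak_delay_by_depth is None:
        shared = model.hrf_kernel(dt)
    for d in range(model.n_depths):
        kernel = shared if shared is not None else model.hrf_kernel(dt, d)
        conv = np.apply_along_axis(np.convolve, -1, drive, kernel)[..., :T]
        out[..., d, :] = model.local_amplitude[d] * conv
    return out


def apply_draining(L: np.ndarray, model: LaminarModel, weights: np.ndarray | None = None) -> np.ndarray:
    """Mix local responses across depth via the draining recursion.

    Discretizes the depth integral of pooled blood from the gray/white
    border up to each depth: with depth step dy = 1/n_depths,

        H[0] = L[0];  H[i] = L[i] + dy * sum_{j<i} w[j] * H[j]

    where ``w`` indexes the *source* depth. Deterministic; negative weights
    are rejected.
    """
    L = np.asarray(L, dtype=float)
    w = model.drain_weights if weights is None else np.asarray(weights, dtype=float)
    n = model.n_depths
    if L.shape[-2] != n or len(w) != n:
        raise ValueError("depth axis / weight length mismatch with model")
    if np.any(w < 0):
        raise ValueError("draining weights must be >= 0")
    dy = 1.0 / n
    H = np.array(L, copy=True)
    for i in range(1, n):
        H[..., i, :] += dy * np.einsum("j,...jt->...t", w[:i], H[..., :i, :])
    return H


def add_noise(
    H: np.ndarray,
    noise: NoiseSpec,
    baseline: float = 100.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Render percent-BOLD responses as raw signal with drift and AR(1) noise.

    output = baseline * (1 + H/100) + drift(t) + ar(t). Reproducible: the
    same ``NoiseSpec.seed`` yields bit-identical output (unless an explicit
    ``rng`` is passed).
    """
    H = np.asarray(H, dtype=float)
    T = H.shape[-1]
    out = baseline * (1.0 + H / 100.0)
    u = np.linspace(0.0, 1.0, T) if T > 1 else np.zeros(1)
    out = out + np.polynomial.polynomial.polyval(u, np.asarray(noise.drift_coeffs))
    if noise.sigma > 0:
        rng = rng or np.random.default_rng(noise.seed)
        innov = noise.sigma * rng.standard_normal(H.shape)
        stat_sd = noise.sigma / np.sqrt(1.0 - noise.ar1**2)
        x0 = (stat_sd / noise.sigma) * innov[..., :1]  # stationary start, N(0, stat_sd^2)
        ar = signal.lfilter([1.0], [1.0, -noise.ar1], innov[..., 1:], axis=-1)
        powers = noise.ar1 ** np.arange(1, T)
        out[..., :1] += x0
        out[..., 1:] += ar + x0 * powers
    return out


def inject_nonlinearity(
    values: np.ndarray,
    kind: str,
    strength: float,
    design: StimulusDesign | None = None,
    dt: float | None = None,
) -> np.ndarray:
    """Apply a known nonlinearity to a drive or response array.

    ``saturation`` compresses amplitudes as x / (1 + strength*|x|) and is
    meant for the local response L. ``adaptation`` multiplies the drive by
    exp(-strength * t_since_block_onset) within each stimulus block and
    requires ``design`` and ``dt`` to locate block onsets. Strength 0 is
    the identity for both.
    """
    if strength < 0:
        raise ValueError("strength must be >= 0")
    values = np.asarray(values, dtype=float)
    if kind == "saturation":
        return values / (1.0 + strength * np.abs(values))
    if kind == "adaptation":
        if design is None or dt is None:
            raise ValueError("adaptation requires design and dt")
        out = np.array(values, copy=True)
        for b in design.blocks:
            i0 = int(round(b.onset_s / dt))
            n = int(round(b.duration_s / dt))
            decay = np.exp(-strength * dt * np.arange(n))
            out[b.run, i0 : i0 + n] *= decay
        return out
    raise ValueError(f"unknown nonlinearity kind: {kind!r}")


def simulate_depth_series(
    design: StimulusDesign,
    model: LaminarModel,
    dt: float,
    nonlinearity: str | None = None,
    strength: float = 0.0,
) -> np.ndarray:
    """Noise-free percent-BOLD depth time courses, (n_runs, n_depths, T).

    Each duration's blocks are simulated as a separate stream and drained
    with that duration's weights, then summed. With uniform weights and no
    nonlinearity this equals a single pass over the full drive (linearity),
    and temporal additivity holds by construction.
    """
    total = None
    for dur in design.durations_s:
        sub = StimulusDesign(
            [b for b in design.blocks if abs(b.duration_s - dur) < 1e-9],
            design.run_length_s,
            design.n_runs,
            (dur,),
        )
        drive = neuronal_drive(sub, dt)
        if nonlinearity == "adaptation":
            drive = inject_nonlinearity(drive, "adaptation", strength, sub, dt)
        L = local_response(drive, model, dt)
        if nonlinearity == "saturation":
            L = inject_nonlinearity(L, "saturation", strength)
        H = apply_draining(L, model, model.weights_for(dur))
        total = H if total is None else total + H
    if total is None:
        n_samp = int(round(design.run_length_s / dt))
        total = np.zeros((design.n_runs, model.n_depths, n_samp))
    return total


def render_voxels(
    H_runs: np.ndarray,
    model: LaminarModel,
    n_voxels_per_depth: int,
    roi_id: int,
    noise: NoiseSpec,
    rng: np.random.Generator,
    tr_s: float,
    dt_sim: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Expand depth time courses into noisy voxel time series at the scan TR.

    Voxels in depth bin d carry H[d, :] (sampled at the volume TR) plus
    independent drift + AR(1) noise; their depth-map values are drawn
    uniformly inside bin d's depth interval, so quantile binning recovers
    the generating bins. Returns (series (n_runs, n_vox, n_volumes),
    depth values (n_vox,), roi labels (n_vox,)).
    """
    if n_voxels_per_depth < 1:
        raise ValueError("n_voxels_per_depth must be >= 1")
    n_runs, n_depths, T_sim = H_runs.shape
    step = int(round(tr_s / dt_sim))
    n_vol = T_sim // step
    H_tr = H_runs[..., : n_vol * step : step]
    n_vox = n_depths * n_voxels_per_depth
    clean = np.repeat(H_tr, n_voxels_per_depth, axis=1)  # (runs, vox, vol)
    series = add_noise(clean, noise, rng=rng)
    edges = np.linspace(0.0, 1.0, n_depths + 1)
    depths = np.concatenate(
        [rng.uniform(edges[d] + 1e-6, edges[d + 1] - 1e-6, n_voxels_per_depth)
         for d in range(n_depths)]
    )
    labels = np.full(n_vox, roi_id, dtype=np.int16)
    return series, depths, labels
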
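"""Reference simulation scenarios for depth-level additivity experiments.

These factories pin down the study conditions used by the package's own
validation experiments: a linear model under which temporal additivity
holds exactly, and a violation model in which the draining weights for
long-duration stimulation differ from those for short stimulation (the
u != w case of laminar additivity failure).

Both use the compact HRF so that, noise-free, the linear scenario is
additive to machine precision. The violation scenario also imposes a
depth gradient of HRF peak delay: because the Pearson statistic is
invariant to per-depth scaling, a draining-weight violation is only
visible when response *shapes* differ across depth, and the delay
gradient supplies that heterogeneity (under uniform weights it is
perfectly linear and therefore harmless).

Bin-level noise is scaled per depth in proportion to the linear-case
signal amplitude, keeping SNR flat across depth — otherwise the
depth-increasing amplitude profile alone induces a depth trend in
correlation that has nothing to do with additivity.
"""

from __future__ import annotations

import numpy as np

from .design import StimulusDesign, make_design
from .hrf import compact_hrf
from .simulate import LaminarModel, NoiseSpec, add_noise, simulate_depth_series

__all__ = [
    "linear_depth_model",
    "violation_depth_model",
    "simulate_depth_session",
    "VIOLATION_TARGET_S",
]

VIOLATION_TARGET_S = 10.4
_ALT_WEIGHT = 2.0        # draining weight for the long-duration stream (vs 0.5)
_DELAY_GRADIENT_S = 2.6  # HRF peak-delay span from deep to superficial


def _delays(n_depths: int, gradient_s: float) -> np.ndarray:
    depth = (np.arange(n_depths) + 0.5) / n_depths
    return compact_hrf().peak_delay_s + gradient_s * (depth - 0.5)


def linear_depth_model(n_depths: int = 5, delay_gradient_s: float = 0.0) -> LaminarModel:
    """Temporally additive model (optionally with a depth delay gradient)."""
    return LaminarModel(
        n_depths=n_depths,
        hrf=compact_hrf(),
        hrf_peak_delay_by_depth=(
            _delays(n_depths, delay_gradient_s) if delay_gradient_s else None
        ),
    )


def violation_depth_model(
    n_depths: int = 5,
    alt_weight: float = _ALT_WEIGHT,
    delay_gradient_s: float = _DELAY_GRADIENT_S,
) -> LaminarModel:
    """Model violating additivity: long blocks drain with different weights."""
    return LaminarModel(
        n_depths=n_depths,
        hrf=compact_hrf(),
        hrf_peak_delay_by_depth=_delays(n_depths, delay_gradient_s),
        drain_weights_alt={VIOLATION_TARGET_S: np.full(n_depths, alt_weight)},
    )


def simulate_depth_session(
    seed: int,
    model: LaminarModel,
    dt: float = 1.3,
    noise_sigma: float = 0.0,
    noise_ar1: float = 0.3,
    nonlinearity: str | None = None,
    strength: float = 0.0,
) -> tuple[StimulusDesign, np.ndarray]:
    """One session of percent-BOLD depth time courses under a scenario.

    Noise (when ``noise_sigma > 0``) is AR(1) at the analysis grid, scaled
    per depth by the linear-case signal standard deviation so that SNR is
    depth-flat. Deterministic per seed.
    """
    design = make_design(seed=seed)
    H = simulate_depth_series(design, model, dt, nonlinearity=nonlinearity, strength=strength)
    if noise_sigma > 0:
        reference = LaminarModel(
            n_depths=model.n_depths,
            hrf=model.hrf,
            hrf_peak_delay_by_depth=model.hrf_peak_delay_by_depth,
        )
        scale = simulate_depth_series(design, reference, dt).std(axis=(0, 2))
        scale = scale / scale.mean()
        rng = np.random.default_rng([seed, 77])
        noise = add_noise(
            np.zeros_like(H),
            NoiseSpec(noise_sigma, noise_ar1, (0.0,)),
            baseline=0.0,
            rng=rng,
        )
        H = H + noise * scale[None, :, None]
    return design, H
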
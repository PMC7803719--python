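"""Stimulus-locked epoching and trial averaging.

Depth-bin time courses are cut into blocks starting at each stimulus
onset, spanning the presentation duration plus a fixed post-stimulus
baseline. Blocks of the same duration are averaged with a Student-t 95%
confidence interval of the between-block variability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .design import StimulusDesign

__all__ = ["EpochSet", "extract_blocks", "average_blocks"]

_GRID_TOL = 1e-6


@dataclass
class EpochSet:
    """Per-duration trial grids, optionally with mean and CI.

    ``trials[d]`` is (n_trials, n_bins, n_samples) for duration d; the
    block time axis runs from stimulus onset in steps of ``dt``.
    """

    trials: dict[float, np.ndarray]
    trial_runs: dict[float, np.ndarray]
    dt: float
    baseline_s: float
    mean: dict[float, np.ndarray] = field(default_factory=dict)
    ci_half: dict[float, np.ndarray | None] = field(default_factory=dict)
    n_blocks: dict[float, int] = field(default_factory=dict)

    @property
    def durations(self) -> list[float]:
        return sorted(self.trials)

    def n_samples(self, duration: float) -> int:
        return int(round((duration + self.baseline_s) / self.dt))

    def to_frame(self, roi=None, bin_depths=None) -> pd.DataFrame:
        """Tidy per-sample mean/CI table (roi, bin, duration, time_s, ...)."""
        rows = []
        for dur in self.durations:
            mean = self.mean.get(dur)
            if mean is None:
                continue
            ci = self.ci_half.get(dur)
            for b in range(mean.shape[0]):
                for i in range(mean.shape[1]):
                    half = np.nan if ci is None else ci[b, i]
                    rows.append(
                        {
                            "roi": roi,
                            "bin": b,
                            "mean_depth": None if bin_depths is None else bin_depths[b],
                            "duration_s": dur,
                            "time_s": i * self.dt,
                            "mean": mean[b, i],
                            "ci_lo": mean[b, i] - half,
                            "ci_hi": mean[b, i] + half,
                            "n": self.n_blocks.get(dur),
                        }
                    )
        return pd.DataFrame(rows)


def extract_blocks(
    signals: np.ndarray,
    design: StimulusDesign,
    dt: float,
    baseline_s: float = 15.6,
) -> EpochSet:
    """Cut (n_runs, n_bins, n_samples) series into stimulus-locked trials.

    Each design block yields one trial over [onset, onset + duration +
    baseline). Onsets must lie on the ``dt`` grid (exact by construction
    when the grid matches the jitter step); a window that runs past the
    end of its run raises an error naming the block.
    """
    signals = np.asarray(signals, dtype=float)
    n_runs, n_bins, n_samp = signals.shape
    trials: dict[float, list[np.ndarray]] = {}
    runs: dict[float, list[int]] = {}
    for b in design.blocks:
        pos = b.onset_s / dt
        if abs(pos - round(pos)) > _GRID_TOL:
            raise ValueError(f"onset {b.onset_s}s of run {b.run} not on the {dt}s grid")
        i0 = int(round(pos))
        length = int(round((b.duration_s + baseline_s) / dt))
        if i0 + length > n_samp:
            raise ValueError(
                f"block at {b.onset_s}s in run {b.run} needs samples up to "
                f"{i0 + length} but the run has {n_samp}"
            )
        trials.setdefault(b.duration_s, []).append(signals[b.run, :, i0 : i0 + length])
        runs.setdefault(b.duration_s, []).append(b.run)
    return EpochSet(
        trials={d: np.stack(v) for d, v in trials.items()},
        trial_runs={d: np.asarray(v) for d, v in runs.items()},
        dt=dt,
        baseline_s=baseline_s,
    )


def average_blocks(epochs: EpochSet, ci_level: float = 0.95) -> EpochSet:
    """Average same-duration trials samplewise with a t-based CI.

    CI half-width = t(1 - (1-level)/2, n-1) * sd / sqrt(n) across trials;
    with a single trial the mean is returned and the CI marked unavailable
    (None). Averaging is invariant to trial order.
    """
    for dur, grid in epochs.trials.items():
        n = grid.shape[0]
        epochs.mean[dur] = grid.mean(axis=0)
        epochs.n_blocks[dur] = n
        if n >= 2:
            sd = grid.std(axis=0, ddof=1)
            tcrit = stats.t.ppf(0.5 + ci_level / 2.0, n - 1)
            epochs.ci_half[dur] = tcrit * sd / np.sqrt(n)
        else:
            epochs.ci_half[dur] = None
    return epochs
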
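"""Shift-and-sum temporal-additivity test with split-half cross-validation.

Under linear-systems temporal additivity, the response to a long stimulus
equals the sum of time-shifted copies of the response to a shorter one.
The test builds such predictions from the mean response of a training half
of the runs, correlates them (Pearson) with the observed long-duration
response of the held-out half, repeats this over every ordered split of
the runs into two halves, and summarizes by the median correlation. The
noise ceiling — the best any prediction could do given measurement noise —
is the median split-half correlation of the observed long response with
itself.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd

from .epochs import EpochSet

__all__ = [
    "PredictionCondition",
    "shift_sum_predict",
    "enumerate_splits",
    "crossval_correlation",
    "noise_ceiling",
    "additivity_table",
]

_VAR_TOL = 1e-24


@dataclass(frozen=True)
class PredictionCondition:
    """A (source duration -> target duration) prediction, seconds."""

    source_s: float
    target_s: float

    def __post_init__(self) -> None:
        k = self.target_s / self.source_s
        if abs(k - round(k)) > 1e-9 or round(k) < 2:
            raise ValueError(
                f"target {self.target_s}s must be an integer multiple >= 2 "
                f"of source {self.source_s}s"
            )

    @property
    def k(self) -> int:
        return int(round(self.target_s / self.source_s))

    def label(self) -> str:
        return f"{self.source_s:g}->{self.target_s:g}"


def shift_sum_predict(
    response: np.ndarray,
    condition: PredictionCondition,
    dt: float,
    baseline_s: float = 15.6,
) -> np.ndarray:
    """Predict the target-duration response by shifting and summing.

    ``response`` (..., n_source_samples) is the mean trial for the source
    duration, assumed back at baseline (zero) beyond its window; it is
    zero-padded to the target length and k copies shifted by multiples of
    the source duration are summed. The shift must be an integer number of
    samples.
    """
    response = np.asarray(response, dtype=float)
    shift = condition.source_s / dt
    if abs(shift - round(shift)) > 1e-9:
        raise ValueError(f"shift of {condition.source_s}s is not integer at dt={dt}")
    s = int(round(shift))
    n_src = response.shape[-1]
    expected = int(round((condition.source_s + baseline_s) / dt))
    if n_src != expected:
        raise ValueError(f"source response has {n_src} samples, expected {expected}")
    n_tgt = int(round((condition.target_s + baseline_s) / dt))
    out = np.zeros(response.shape[:-1] + (n_tgt,))
    for i in range(condition.k):
        out[..., i * s : i * s + n_src] += response
    return out


def enumerate_splits(n_runs: int = 8, k: int = 4) -> list[tuple[tuple[int, ...], tuple[int, ...]]]:
    """All ordered (train, test) splits of ``n_runs`` runs with |train| = k.

    Train and test roles are distinct, so 8 runs split 4+4 yield C(8,4) =
    70 splits, in deterministic lexicographic order of the train set.
    """
    if not 0 < k < n_runs:
        raise ValueError("need 0 < k < n_runs")
    runs = range(n_runs)
    out = []
    for train in combinations(runs, k):
        test = tuple(r for r in runs if r not in train)
        out.append((train, test))
    assert len(out) == comb(n_runs, k)
    return out


def _run_means(epochs: EpochSet, duration: float, n_runs: int) -> np.ndarray:
    """Per-run mean trial, (n_runs, n_bins, n_samples)."""
    grid = epochs.trials[duration]
    runs = epochs.trial_runs[duration]
    out = np.empty((n_runs,) + grid.shape[1:])
    for r in range(n_runs):
        sel = runs == r
        if not sel.any():
            raise ValueError(f"run {r} has no trials of duration {duration}s")
        out[r] = grid[sel].mean(axis=0)
    return out


def _pearson_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise Pearson r over the last axis; zero-variance rows give nan."""
    a = a - a.mean(axis=-1, keepdims=True)
    b = b - b.mean(axis=-1, keepdims=True)
    va = np.sum(a * a, axis=-1)
    vb = np.sum(b * b, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.sum(a * b, axis=-1) / np.sqrt(va * vb)
    r[(va < _VAR_TOL) | (vb < _VAR_TOL)] = np.nan
    return r


def _median_over_splits(per_split: np.ndarray, what: str) -> np.ndarray:
    """Median per bin over splits, excluding flagged (nan) splits."""
    bad = np.isnan(per_split)
    if bad.any():
        warnings.warn(
            f"{int(bad.any(axis=1).sum())} split(s) excluded from {what} "
            "(zero-variance vector)",
            stacklevel=3,
        )
    if np.all(bad, axis=0).any():
        raise ValueError(f"all splits excluded in {what}")
    return np.nanmedian(per_split, axis=0)


def crossval_correlation(
    epochs: EpochSet,
    condition: PredictionCondition,
    splits: list[tuple[tuple[int, ...], tuple[int, ...]]],
    n_runs: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Cross-validated prediction correlations per depth bin.

    For each split, the source-duration trials of the training runs are
    averaged, shift-and-summed into a target-duration prediction, and
    correlated with the held-out runs' mean observed target response over
    the full target window. Returns (median r per bin, per-split r of
    shape (n_splits, n_bins)). Splits containing a zero-variance vector
    are excluded with a warning; if every split is excluded, an error is
    raised.
    """
    src = _run_means(epochs, condition.source_s, n_runs)
    tgt = _run_means(epochs, condition.target_s, n_runs)
    per_split = np.empty((len(splits), src.shape[1]))
    for i, (train, test) in enumerate(splits):
        pred = shift_sum_predict(
            src[list(train)].mean(axis=0), condition, epochs.dt, epochs.baseline_s
        )
        obs = tgt[list(test)].mean(axis=0)
        per_split[i] = _pearson_rows(pred, obs)
    median = _median_over_splits(per_split, f"condition {condition.label()}")
    return median, per_split


def noise_ceiling(
    epochs: EpochSet,
    duration: float,
    splits: list[tuple[tuple[int, ...], tuple[int, ...]]],
    n_runs: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Split-half reliability of the observed response, per depth bin.

    For each split, the Pearson correlation between the two half-averages
    of the observed ``duration`` response; the median over splits is the
    noise ceiling for predictions of that duration.
    """
    tgt = _run_means(epochs, duration, n_runs)
    per_split = np.empty((len(splits), tgt.shape[1]))
    for i, (train, test) in enumerate(splits):
        a = tgt[list(train)].mean(axis=0)
        b = tgt[list(test)].mean(axis=0)
        per_split[i] = _pearson_rows(a, b)
    median = _median_over_splits(per_split, f"noise ceiling {duration:g}s")
    return median, per_split


def additivity_table(
    epochs: EpochSet,
    conditions: list[PredictionCondition],
    n_runs: int,
    roi: int,
    mean_depth: np.ndarray,
    splits: list[tuple[tuple[int, ...], tuple[int, ...]]] | None = None,
) -> pd.DataFrame:
    """Tidy per-(bin, condition) results for one ROI.

    Columns: roi, bin, mean_depth, condition, source_s, target_s,
    median_r, ceiling_r, n_splits.
    """
    if splits is None:
        splits = enumerate_splits(n_runs, n_runs // 2)
    rows = []
    ceilings: dict[float, np.ndarray] = {}
    for cond in conditions:
        med, per = crossval_correlation(epochs, cond, splits, n_runs)
        if cond.target_s not in ceilings:
            ceilings[cond.target_s], _ = noise_ceiling(epochs, cond.target_s, splits, n_runs)
        ceil = ceilings[cond.target_s]
        for b in range(len(med)):
            rows.append(
                {
                    "roi": roi,
                    "bin": b,
                    "mean_depth": mean_depth[b],
                    "condition": cond.label(),
                    "source_s": cond.source_s,
                    "target_s": cond.target_s,
                    "median_r": med[b],
                    "ceiling_r": ceil[b],
                    "n_splits": len(splits),
                }
            )
    return pd.DataFrame(rows)
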
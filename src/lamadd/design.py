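"""Block-design construction for the duration-manipulation experiment.

A session consists of ``n_runs`` identical-length runs. Each run opens with
one rest (mean-luminance) block and then presents ``reps_per_duration``
stimulus blocks of each duration, counterbalanced in order and interleaved
with rest periods. Half of the stimulus blocks (stratified within each
duration) have their onset delayed by one jitter step so that, after
temporal resampling to the jitter grid, onsets tile the sampling phase.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["Block", "StimulusDesign", "make_design"]

_GRID_TOL = 1e-6


@dataclass(frozen=True)
class Block:
    run: int
    onset_s: float
    duration_s: float
    jittered: bool = False


@dataclass
class StimulusDesign:
    """Onsets/durations/run indices of all stimulus blocks in a session."""

    blocks: list[Block]
    run_length_s: float
    n_runs: int
    durations_s: tuple[float, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.durations_s:
            self.durations_s = tuple(sorted({b.duration_s for b in self.blocks}))
        self._check()

    def _check(self) -> None:
        for r in range(self.n_runs):
            onsets = [b.onset_s for b in self.blocks_for_run(r)]
            if any(b <= a for a, b in zip(onsets, onsets[1:])):
                raise ValueError(f"onsets not strictly increasing in run {r}")

    def blocks_for_run(self, run: int) -> list[Block]:
        return [b for b in self.blocks if b.run == run]

    @property
    def n_blocks_per_run(self) -> int:
        return len(self.blocks_for_run(0))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "run": [b.run for b in self.blocks],
                "onset_s": [b.onset_s for b in self.blocks],
                "duration_s": [b.duration_s for b in self.blocks],
            }
        )

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# run_length_s = {self.run_length_s}\n")
            fh.write(f"# n_runs = {self.n_runs}\n")
            self.to_frame().to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "StimulusDesign":
        meta: dict[str, float] = {}
        with open(path) as fh:
            for line in fh:
                if not line.startswith("#"):
                    break
                key, _, value = line.lstrip("# ").partition("=")
                meta[key.strip()] = float(value)
        frame = pd.read_csv(path, sep="\t", comment="#")
        blocks = [
            Block(int(r.run), float(r.onset_s), float(r.duration_s))
            for r in frame.itertuples()
        ]
        return cls(blocks, meta["run_length_s"], int(meta["n_runs"]))


def _on_grid(value: float, dt: float) -> bool:
    return abs(value / dt - round(value / dt)) < _GRID_TOL


def make_design(
    n_runs: int = 8,
    durations: tuple[float, ...] = (2.6, 5.2, 10.4),
    reps_per_duration: int = 4,
    rest_mean: float = 15.6,
    jitter: float = 1.3,
    run_length: float = 265.2,
    dt: float = 1.3,
    seed: int = 0,
    end_margin: float = 2.6,
) -> StimulusDesign:
    """Build a counterbalanced, jittered block design.

    Each run opens with a ``rest_mean`` rest block and reserves a final
    ``rest_mean`` (+ jitter) post-stimulus window after the last block,
    plus ``end_margin`` for the part of the nominal run length beyond the
    last acquired sample (one volume TR: a series of n volumes covers
    (n-1) TR). The remaining rest budget is spread over the inter-block
    gaps on the ``dt`` grid (realized rests therefore vary around their
    mean, as in a jittered block design). Block order, jitter assignment
    and the placement of the longer rests are drawn per run from ``seed``,
    so identical seeds give identical designs.

    Raises
    ------
    ValueError
        If the blocks (including the post-stimulus window of the last
        block) do not fit inside the run, naming the overflowing run.
    """
    if reps_per_duration < 1:
        raise ValueError("reps_per_duration must be >= 1")
    for d in durations:
        if d <= 0 or not _on_grid(d, dt):
            raise ValueError(f"duration {d} is not a positive multiple of dt={dt}")
    if jitter and not _on_grid(jitter, dt):
        raise ValueError("jitter must lie on the dt grid")

    n_blocks = len(durations) * reps_per_duration
    total_stim = reps_per_duration * float(np.sum(durations))
    budget = run_length - rest_mean - total_stim - (rest_mean + jitter) - end_margin
    n_gaps = n_blocks - 1
    blocks: list[Block] = []
    for run in range(n_runs):
        rng = np.random.default_rng([seed, run])
        order = rng.permutation(np.repeat(durations, reps_per_duration))
        jittered = _assign_jitter(order, durations, rng)
        rests = _fill_gaps(budget, n_gaps, dt, rng, run)
        t = rest_mean  # each run starts with one rest block
        for i, (dur, jit) in enumerate(zip(order, jittered)):
            onset = t + (jitter if jit else 0.0)
            if onset + dur + rest_mean > run_length - end_margin + _GRID_TOL:
                raise ValueError(
                    f"design does not fit: block at {onset:.1f}s "
                    f"(duration {dur:.1f}s) overflows run {run}"
                )
            blocks.append(Block(run, round(onset, 6), float(dur), bool(jit)))
            t += dur + (rests[i] if i < n_gaps else 0.0)
    return StimulusDesign(blocks, run_length, n_runs, tuple(durations))


def _fill_gaps(budget: float, n_gaps: int, dt: float, rng, run: int) -> np.ndarray:
    """Spread the inter-block rest budget over gaps in multiples of dt."""
    if n_gaps == 0:
        return np.zeros(0)
    steps = int(np.floor(budget / n_gaps / dt + _GRID_TOL))
    if steps < 1:
        raise ValueError(f"design does not fit: no room for rests in run {run}")
    rests = np.full(n_gaps, steps * dt)
    leftover = int(np.floor((budget - rests.sum()) / dt + _GRID_TOL))
    if leftover > 0:
        rests[rng.choice(n_gaps, size=min(leftover, n_gaps), replace=False)] += dt
    return rests


def _assign_jitter(order, durations, rng) -> np.ndarray:
    """Mark floor(n/2) blocks for jitter, spread evenly across durations."""
    order = np.asarray(order)
    n_total = len(order) // 2
    flags = np.zeros(len(order), dtype=bool)
    picked = 0
    per_dur: dict[float, np.ndarray] = {
        d: np.flatnonzero(order == d) for d in durations
    }
    for d in durations:
        idx = per_dur[d]
        take = len(idx) // 2
        flags[rng.choice(idx, size=take, replace=False)] = True
        picked += take
    if picked < n_total:  # odd repetition counts: top up at random
        pool = np.flatnonzero(~flags)
        flags[rng.choice(pool, size=n_total - picked, replace=False)] = True
    return flags


def neuronal_drive(design: StimulusDesign, dt: float) -> np.ndarray:
    """Boxcar neuronal drive, one row per run, sampled at step ``dt``.

    The drive is 1 while a stimulus block is on and 0 elsewhere, so its sum
    times ``dt`` equals the total stimulation time. Onsets that do not lie
    on the ``dt`` grid are rejected.
    """
    n_samp = int(round(design.run_length_s / dt))
    drive = np.zeros((design.n_runs, n_samp))
    for b in design.blocks:
        if not _on_grid(b.onset_s, dt) or not _on_grid(b.duration_s, dt):
            raise ValueError(f"block onset {b.onset_s}s not on the dt={dt} grid")
        i0 = int(round(b.onset_s / dt))
        i1 = i0 + int(round(b.duration_s / dt))
        drive[b.run, i0:i1] = 1.0
    return drive
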
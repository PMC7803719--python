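"""Configuration and orchestration: ``simulate`` and ``analyze`` stages.

``simulate_study`` writes a complete synthetic session to disk (NIfTI
runs, depth map, ROI mask, design table, ground-truth file, manifest);
``run_pipeline`` executes conditioning -> depth sampling -> epoching ->
additivity -> depth trend on either real or synthetic inputs and writes
tidy result tables plus a plain-text report. The analysis never reads the
ground-truth file.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as lio
from .additivity import PredictionCondition, additivity_table, enumerate_splits
from .conditioning import condition_run
from .depth import depth_quantile_bins, roi_depth_timecourse
from .design import StimulusDesign, make_design
from .epochs import average_blocks, extract_blocks
from .hrf import HrfParams
from .simulate import (
    LaminarModel,
    NoiseSpec,
    SyntheticDataset,
    render_voxels,
    simulate_depth_series,
)
from .trend import TrendFit, fit_depth_trend, test_horizontal

logger = logging.getLogger("lamadd")

__all__ = ["RunConfig", "simulate_study", "run_pipeline", "analyze_depth_series"]


@dataclass
class RunConfig:
    """Validated flat configuration for both entry points."""

    # acquisition / simulator
    n_runs: int = 8
    tr_s: float = 2.6
    n_volumes: int = 102
    durations: tuple[float, ...] = (2.6, 5.2, 10.4)
    reps_per_duration: int = 4
    rest_s: float = 15.6
    jitter_s: float = 1.3
    n_depths: int = 5
    n_voxels_per_depth: int = 40
    rois: tuple[int, ...] = (1, 2, 3)
    hrf_peak_s: float = 6.0
    hrf_undershoot_s: float = 16.0
    hrf_ratio: float = 6.0
    hrf_length_s: float = 32.0
    noise_sigma: float = 0.6
    noise_ar1: float = 0.35
    drift_coeffs: tuple[float, ...] = (0.0, 2.0, -1.5, 0.8, -0.3)
    # conditioning
    despike_z: float = 5.0
    detrend_degree: int = 4
    resample_dt_s: float = 1.3
    # analysis
    n_bins: int = 5
    baseline_s: float = 15.6
    conditions: tuple[tuple[float, float], ...] = ((2.6, 5.2), (2.6, 10.4), (5.2, 10.4))
    alpha: float = 0.05
    seed: int = 0
    # input paths (analyze on existing data)
    series_paths: tuple[str, ...] | None = None
    depth_map_path: str | None = None
    roi_mask_path: str | None = None
    design_path: str | None = None

    @property
    def run_length_s(self) -> float:
        return self.tr_s * self.n_volumes

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {f.name for f in dc_fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**{k: _freeze(v) for k, v in raw.items()})
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(lio.read_config(path))

    def to_dict(self) -> dict:
        return {f.name: _thaw(getattr(self, f.name)) for f in dc_fields(self)}

    def validate(self) -> None:
        if self.n_runs < 2:
            raise ValueError("need at least 2 runs")
        if self.alpha <= 0 or self.alpha > 1:
            raise ValueError("alpha must lie in (0, 1]")
        if self.tr_s <= 0 or self.resample_dt_s <= 0:
            raise ValueError("time steps must be positive")

    def hrf_params(self) -> HrfParams:
        return HrfParams(
            self.hrf_peak_s, self.hrf_undershoot_s, self.hrf_ratio, self.hrf_length_s
        )

    def prediction_conditions(self) -> list[PredictionCondition]:
        return [PredictionCondition(s, t) for s, t in self.conditions]


def _freeze(v):
    if isinstance(v, list):
        return tuple(_freeze(x) for x in v)
    return v


def _thaw(v):
    if isinstance(v, tuple):
        return [_thaw(x) for x in v]
    return v


def simulate_study(
    config: RunConfig,
    out_dir,
    model: LaminarModel | None = None,
) -> SyntheticDataset:
    """Simulate a session and write it under ``out_dir``.

    Deterministic per ``config.seed``: the design, truth file and all
    volumes are byte-identical across repeated calls.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    design = make_design(
        n_runs=config.n_runs,
        durations=config.durations,
        reps_per_duration=config.reps_per_duration,
        rest_mean=config.rest_s,
        jitter=config.jitter_s,
        run_length=config.run_length_s,
        dt=config.resample_dt_s,
        seed=config.seed,
        end_margin=config.tr_s,
    )
    if model is None:
        model = LaminarModel(n_depths=config.n_depths, hrf=config.hrf_params())
    dt_sim = config.resample_dt_s
    H = simulate_depth_series(design, model, dt_sim)
    m = config.n_voxels_per_depth
    series_rois, depth_rois = [], []
    for i, roi in enumerate(config.rois):
        rng = np.random.default_rng([config.seed, 1000 + i])
        noise = NoiseSpec(config.noise_sigma, config.noise_ar1, config.drift_coeffs)
        svox, dvox, _ = render_voxels(H, model, m, roi, noise, rng, config.tr_s, dt_sim)
        series_rois.append(svox)
        depth_rois.append(dvox)

    n_vol = series_rois[0].shape[-1]
    shape = (m, config.n_depths, len(config.rois))
    series = np.empty((config.n_runs,) + shape + (n_vol,), dtype=np.float64)
    depth_map = np.empty(shape)
    roi_labels = np.zeros(shape, dtype=np.int16)
    for i, roi in enumerate(config.rois):
        # voxel order within an ROI: depth-major, voxel-minor
        block = series_rois[i].reshape(config.n_runs, config.n_depths, m, n_vol)
        series[:, :, :, i, :] = block.transpose(0, 2, 1, 3)
        depth_map[:, :, i] = depth_rois[i].reshape(config.n_depths, m).T
        roi_labels[:, :, i] = roi

    files = []
    for r in range(config.n_runs):
        name = f"run_{r:02d}.nii"
        lio.save_nifti(series[r], out_dir / name)
        files.append(name)
    lio.save_nifti(depth_map, out_dir / "depth_map.nii")
    lio.save_nifti(roi_labels, out_dir / "roi_mask.nii", dtype=np.int16)
    design.to_tsv(out_dir / "design.tsv")
    truth = {
        "depth_values": [float(v) for v in model.depth_values],
        "local_amplitude": [float(v) for v in model.local_amplitude],
        "drain_weights": [float(v) for v in model.drain_weights],
        "hrf": {
            "peak_delay_s": model.hrf.peak_delay_s,
            "undershoot_delay_s": model.hrf.undershoot_delay_s,
            "ratio": model.hrf.ratio,
            "length_s": model.hrf.length_s,
        },
        "seed": config.seed,
    }
    lio.write_config(truth, out_dir / "truth.yaml")
    lio.write_config(config.to_dict(), out_dir / "config.yaml")
    files += ["depth_map.nii", "roi_mask.nii", "design.tsv", "truth.yaml", "config.yaml"]
    lio.write_manifest(out_dir, files)
    logger.info("simulated %d runs x %d volumes into %s", config.n_runs, n_vol, out_dir)
    return SyntheticDataset(series, depth_map, roi_labels, design, model, config.tr_s)


def analyze_depth_series(
    bin_signals: dict[int, np.ndarray],
    mean_depth: dict[int, np.ndarray],
    design: StimulusDesign,
    dt: float,
    config: RunConfig,
) -> tuple[pd.DataFrame, dict[int, TrendFit], dict[int, str], pd.DataFrame]:
    """Core analysis on per-(ROI, bin) time courses.

    ``bin_signals[roi]`` is (n_runs, n_bins, n_samples) in percent units.
    Returns (additivity table, per-ROI trend fits, per-ROI verdicts,
    tidy epoch-average table).
    """
    conditions = config.prediction_conditions()
    splits = enumerate_splits(design.n_runs, design.n_runs // 2)
    tables, epoch_rows = [], []
    fits: dict[int, TrendFit] = {}
    verdicts: dict[int, str] = {}
    for roi, signals in bin_signals.items():
        epochs = extract_blocks(signals, design, dt, config.baseline_s)
        epochs = average_blocks(epochs)
        epoch_rows.append(epochs.to_frame(roi=roi, bin_depths=mean_depth[roi]))
        table = additivity_table(
            epochs, conditions, design.n_runs, roi, mean_depth[roi], splits
        )
        tables.append(table)
        fit = fit_depth_trend(table, roi)
        fits[roi] = fit
        verdicts[roi] = test_horizontal(fit, config.alpha)
    return (
        pd.concat(tables, ignore_index=True),
        fits,
        verdicts,
        pd.concat(epoch_rows, ignore_index=True),
    )


def run_pipeline(config: RunConfig, data_dir, out_dir) -> dict[int, str]:
    """File-based end-to-end analysis; returns the per-ROI verdicts.

    Reads the 4D runs, depth map, ROI mask and design table from
    ``data_dir`` (or from explicit paths in the config), runs every stage
    in fixed order and writes ``additivity.tsv``, ``epochs.tsv``,
    ``trend.tsv``, ``report.txt`` and a manifest under ``out_dir``. Stage
    failures abort with the failing stage named.
    """
    data_dir = Path(data_dir)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    def _path(explicit, default):
        return Path(explicit) if explicit else data_dir / default

    run_paths = (
        [Path(p) for p in config.series_paths]
        if config.series_paths
        else sorted(data_dir.glob("run_*.nii"))
    )
    depth_path = _path(config.depth_map_path, "depth_map.nii")
    mask_path = _path(config.roi_mask_path, "roi_mask.nii")
    design_path = _path(config.design_path, "design.tsv")
    for p in [depth_path, mask_path, design_path, *run_paths]:
        if not p.exists():
            raise FileNotFoundError(f"input missing before analysis: {p}")
    if not run_paths:
        raise FileNotFoundError(f"no functional runs found in {data_dir}")

    design = StimulusDesign.from_tsv(design_path)
    depth_map = lio.load_nifti(depth_path)
    roi_labels = lio.load_nifti(mask_path).astype(int)

    stage = "conditioning"
    try:
        runs_pct = []
        for p in run_paths:
            vol = lio.load_nifti(p)
            flat = vol.reshape(-1, vol.shape[-1])
            pct, n_spk = condition_run(
                flat, config.tr_s, config.resample_dt_s,
                config.despike_z, config.detrend_degree,
            )
            logger.info("%s: replaced %d spikes", p.name, n_spk)
            runs_pct.append(pct)
        series = np.stack(runs_pct)  # (n_runs, n_vox, n_samples)

        stage = "depth sampling"
        bin_signals, mean_depth = {}, {}
        labels = np.unique(roi_labels[roi_labels > 0])
        for roi in labels:
            binning = depth_quantile_bins(depth_map, roi_labels == roi, config.n_bins)
            tc = roi_depth_timecourse(series, binning, depth_map, int(roi), config.resample_dt_s)
            bin_signals[int(roi)] = tc.signals
            mean_depth[int(roi)] = tc.mean_depth

        stage = "epoching/additivity/trend"
        table, fits, verdicts, epoch_table = analyze_depth_series(
            bin_signals, mean_depth, design, config.resample_dt_s, config
        )
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage: {stage}") from exc

    table.to_csv(out_dir / "additivity.tsv", sep="\t", index=False)
    epoch_table.to_csv(out_dir / "epochs.tsv", sep="\t", index=False)
    trend_rows = [
        {
            "roi": roi, "intercept": f.intercept, "slope": f.slope,
            "t_intercept": f.t_intercept, "t_slope": f.t_slope,
            "p_intercept": f.p_intercept, "p_slope": f.p_slope,
            "df": f.df, "n_points": f.n_points, "verdict": verdicts[roi],
        }
        for roi, f in fits.items()
    ]
    pd.DataFrame(trend_rows).to_csv(out_dir / "trend.tsv", sep="\t", index=False)
    with open(out_dir / "report.txt", "w") as fh:
        fh.write("Temporal additivity across cortical depth\n")
        fh.write(f"runs: {design.n_runs}; alpha = {config.alpha}\n\n")
        for roi, f in fits.items():
            fh.write(f"{f.report_line()} -> {verdicts[roi]}\n")
    lio.write_manifest(out_dir, ["additivity.tsv", "epochs.tsv", "trend.tsv", "report.txt"])
    return verdicts
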
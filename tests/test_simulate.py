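"""Forward model: local responses, draining, noise, nonlinearities, rendering."""

import numpy as np
import pytest

from lamadd import (
    LaminarModel,
    NoiseSpec,
    add_noise,
    apply_draining,
    inject_nonlinearity,
    local_response,
    make_design,
    neuronal_drive,
    render_voxels,
    simulate_depth_series,
)
from lamadd.design import StimulusDesign, Block
from lamadd.hrf import HrfParams, compact_hrf, double_gamma

DT = 1.3


class TestLocalResponse:
    def test_zero_drive_zero_response(self, compact_model):
        L = local_response(np.zeros((2, 50)), compact_model, DT)
        assert not L.any()

    def test_amplitude_scaling_is_linear(self, compact_model):
        drive = np.zeros(60)
        drive[10:14] = 1.0
        L1 = local_response(drive, compact_model, DT)
        doubled = LaminarModel(
            hrf=compact_model.hrf, local_amplitude=2 * compact_model.local_amplitude
        )
        L2 = local_response(drive, doubled, DT)
        np.testing.assert_allclose(L2, 2 * L1, rtol=1e-12)

    def test_impulse_reproduces_hrf(self, compact_model):
        drive = np.zeros(60)
        drive[0] = 1.0
        L = local_response(drive, compact_model, DT)
        h = double_gamma(DT, compact_model.hrf)
        for d in range(compact_model.n_depths):
            np.testing.assert_allclose(
                L[d, : len(h)], compact_model.local_amplitude[d] * h, rtol=1e-12
            )

    def test_causality(self, compact_model):
        drive = np.zeros(60)
        drive[30] = 1.0
        L = local_response(drive, compact_model, DT)
        assert not L[:, :30].any()


class TestApplyDraining:
    def test_zero_weights_identity(self, rng):
        m = LaminarModel(drain_weights=np.zeros(5))
        L = rng.random((5, 40))
        np.testing.assert_array_equal(apply_draining(L, m), L)

    def test_single_depth_identity(self, rng):
        m = LaminarModel(n_depths=1)
        L = rng.random((1, 40))
        np.testing.assert_array_equal(apply_draining(L, m), L)

    def test_matches_bruteforce_recursion(self, rng):
        """Independent elementwise evaluation of the cumulative-sum rule."""
        m = LaminarModel(drain_weights=rng.random(5))
        L = rng.random((5, 30))
        H = apply_draining(L, m)
        dy = 1.0 / 5
        expected = np.zeros_like(L)
        for t in range(30):
            for i in range(5):
                acc = L[i, t]
                for j in range(i):
                    acc += dy * m.drain_weights[j] * expected[j, t]
                expected[i, t] = acc
        np.testing.assert_allclose(H, expected, rtol=1e-12)

    def test_peak_nondecreasing_for_nondecreasing_profile(self, rng):
        """With a local profile rising toward the surface and positive
        weights, pooled peaks never decrease with depth index."""
        m = LaminarModel()  # default amplitude profile is depth-increasing
        shape = np.abs(rng.standard_normal(40))
        L = m.local_amplitude[:, None] * shape[None, :]
        H = apply_draining(L, m)
        peaks = H.max(axis=1)
        assert np.all(np.diff(peaks) >= -1e-12)

    def test_negative_weights_rejected(self, rng):
        m = LaminarModel()
        with pytest.raises(ValueError, match=">= 0"):
            apply_draining(rng.random((5, 10)), m, weights=np.array([1, 1, -1, 1, 1.0]))


class TestAddNoise:
    def test_noise_free_is_affine(self, rng):
        H = rng.random((3, 50))
        out = add_noise(H, NoiseSpec(sigma=0.0, ar1=0.0, drift_coeffs=(0.0,)))
        np.testing.assert_allclose(out, 100 * (1 + H / 100), rtol=1e-14)

    def test_seed_reproducibility(self, rng):
        H = rng.random((2, 40))
        spec = NoiseSpec(sigma=0.5, ar1=0.3, seed=9)
        np.testing.assert_array_equal(add_noise(H, spec), add_noise(H, spec))

    def test_ar1_stationary_std(self):
        """Sample std of pure noise matches sigma/sqrt(1-ar1^2) within 5%."""
        spec = NoiseSpec(sigma=0.7, ar1=0.6, drift_coeffs=(0.0,), seed=1)
        out = add_noise(np.zeros((1, 100_000)), spec, baseline=0.0)
        expected = 0.7 / np.sqrt(1 - 0.6**2)
        assert abs(out.std() / expected - 1) < 0.05


class TestInjectNonlinearity:
    def test_strength_zero_identity(self, rng, default_design):
        x = rng.random((8, 204))
        np.testing.assert_array_equal(inject_nonlinearity(x, "saturation", 0.0), x)
        np.testing.assert_array_equal(
            inject_nonlinearity(x, "adaptation", 0.0, default_design, DT), x
        )

    def test_saturation_compresses(self):
        x = np.array([[0.0, 1.0, 2.0]])
        out = inject_nonlinearity(x, "saturation", 1.0)
        np.testing.assert_allclose(out, [[0.0, 0.5, 2.0 / 3]])

    def test_adaptation_decays_within_block(self, default_design):
        drive = neuronal_drive(default_design, DT)
        out = inject_nonlinearity(drive, "adaptation", 0.5, default_design, DT)
        long_blocks = [b for b in default_design.blocks if b.duration_s == 10.4]
        b = long_blocks[0]
        i0 = int(round(b.onset_s / DT))
        i1 = i0 + int(round(b.duration_s / DT))
        assert out[b.run, i1 - 1] < out[b.run, i0]

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="unknown nonlinearity"):
            inject_nonlinearity(np.zeros((1, 4)), "ceiling", 1.0)


class TestTemporalAdditivityByConstruction:
    def test_long_response_equals_shift_sum_of_short(self, compact_model):
        """Noise-free, a 5.2 s response equals the 2.6 s response plus its
        copy shifted by 2.6 s, at every depth."""
        run_len = 130.0
        short = StimulusDesign([Block(0, 26.0, 2.6)], run_len, 1)
        long = StimulusDesign([Block(0, 26.0, 5.2)], run_len, 1)
        Hs = simulate_depth_series(short, compact_model, DT)
        Hl = simulate_depth_series(long, compact_model, DT)
        shifted = np.zeros_like(Hs)
        shifted[..., 2:] = Hs[..., :-2]
        np.testing.assert_allclose(Hl, Hs + shifted, atol=1e-10)

    def test_adaptation_breaks_additivity(self, compact_model):
        run_len = 130.0
        short = StimulusDesign([Block(0, 26.0, 2.6)], run_len, 1)
        long = StimulusDesign([Block(0, 26.0, 5.2)], run_len, 1)
        Hs = simulate_depth_series(short, compact_model, DT, "adaptation", 0.3)
        Hl = simulate_depth_series(long, compact_model, DT, "adaptation", 0.3)
        shifted = np.zeros_like(Hs)
        shifted[..., 2:] = Hs[..., :-2]
        assert np.abs(Hl - (Hs + shifted)).max() > 1e-3


class TestRenderVoxels:
    def test_single_voxel_no_noise_passthrough(self, compact_model, default_design):
        H = simulate_depth_series(default_design, compact_model, DT)
        rng = np.random.default_rng(0)
        quiet = NoiseSpec(sigma=0.0, ar1=0.0, drift_coeffs=(0.0,))
        series, depths, labels = render_voxels(
            H, compact_model, 1, roi_id=1, noise=quiet, rng=rng, tr_s=2.6, dt_sim=DT
        )
        np.testing.assert_allclose(series, 100 * (1 + H[..., ::2] / 100), rtol=1e-14)
        assert labels.tolist() == [1] * 5

    def test_depth_map_recovers_generating_bins(self, compact_model, default_design):
        H = simulate_depth_series(default_design, compact_model, DT)
        rng = np.random.default_rng(1)
        _, depths, _ = render_voxels(
            H, compact_model, 40, 1, NoiseSpec(), rng, tr_s=2.6, dt_sim=DT
        )
        generating = np.repeat(np.arange(5), 40)
        from lamadd import depth_quantile_bins

        binning = depth_quantile_bins(depths, np.ones_like(depths, dtype=bool), 5)
        np.testing.assert_array_equal(binning.assignment, generating)

    def test_nifti_round_trip(self, tmp_path, rng):
        from lamadd.io import load_nifti, save_nifti

        data = rng.standard_normal((4, 3, 2, 10))
        save_nifti(data, tmp_path / "x.nii")
        back = load_nifti(tmp_path / "x.nii")
        np.testing.assert_allclose(back, data.astype(np.float32), rtol=1e-7)


def test_hrf_onset_delay_zeroes_early_samples():
    h = double_gamma(DT, compact_hrf())
    assert h[0] == 0.0 and h[1] == 0.0 and h[2] == 0.0
    assert h[3] > 0
    assert h.max() == 1.0


def test_hrf_integral_finite_positive():
    for params in (HrfParams(), compact_hrf()):
        h = double_gamma(DT, params)
        assert np.isfinite(h.sum()) and h.sum() > 0
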
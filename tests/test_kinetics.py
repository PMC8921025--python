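"""Concentration conversion, AIF extraction, deconvolution and maps."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.linalg import solve_triangular

from lungdce import (
    AIFCurve,
    AcquisitionConfig,
    ConcentrationSeries,
    DynamicSeries,
    KineticGroundTruth,
    KineticsConfig,
    build_convolution_matrix,
    compute_parameters,
    deconvolve_tsvd,
    extract_aif,
    make_maps,
    make_phantom,
    render_dce,
    signal_to_concentration,
    tissue_curve,
)
from lungdce.containers import ResidueEstimate
from lungdce.kinetics import DegenerateAIFError, tsvd_operator

from conftest import prompt_bolus


def _series_from_curves(curves, n_baseline=5, dt=1.5, voxel_size=2.0):
    """Wrap per-voxel curves (n, t) into a (n,1,1,t) DynamicSeries."""
    curves = np.asarray(curves, dtype=float)
    values = curves.reshape(curves.shape[0], 1, 1, curves.shape[1])
    t = np.arange(curves.shape[1]) * dt
    return DynamicSeries(values, t, voxel_size, n_baseline)


class TestSignalToConcentration:
    def test_constant_signal_gives_zero_concentration(self):
        series = _series_from_curves(np.full((1, 20), 37.0))
        c = signal_to_concentration(series, voxel=(0, 0, 0))
        assert np.all(c.values == 0.0)

    def test_baseline_subtraction_arithmetic(self):
        series = _series_from_curves([[10, 10, 10, 10, 10, 12, 14]], n_baseline=5)
        c = signal_to_concentration(series, voxel=(0, 0, 0))
        np.testing.assert_array_equal(c.values, [0, 0, 0, 0, 0, 2, 4])

    def test_noiseless_phantom_voxel_proportional_to_forward_model(
        self, phantom32, truth32, noiseless_series, noiseless_acq
    ):
        vox = tuple(np.argwhere(phantom32.right_lung_mask)[10])
        c = signal_to_concentration(noiseless_series, voxel=vox)
        from lungdce.synthetic import gamma_variate_aif

        t = noiseless_acq.frame_times
        ca = gamma_variate_aif(t, 7.5, 3.0, 1.5)
        expected = tissue_curve(ca, truth32.pbf_map[vox], truth32.mtt_map[vox], dt=1.5)
        # gain: S = S0*(1 + k*C) with S0=100, k=1 -> measured C is 100x truth
        np.testing.assert_allclose(c.values, 100.0 * expected, atol=1e-9)

    def test_relative_mode_divides_by_s0(self):
        series = _series_from_curves([[10, 10, 10, 10, 10, 12, 14]], n_baseline=5)
        c = signal_to_concentration(series, voxel=(0, 0, 0), mode="relative")
        np.testing.assert_allclose(c.values, [0, 0, 0, 0, 0, 0.2, 0.4])


class TestExtractAIF:
    def test_single_voxel_roi_equals_that_voxel(self, noisy_series, phantom32):
        mask = np.zeros(phantom32.grid_shape, dtype=bool)
        vox = tuple(np.argwhere(phantom32.trunk_mask)[0])
        mask[vox] = True
        aif = extract_aif(noisy_series, mask)
        direct = signal_to_concentration(noisy_series, voxel=vox)
        np.testing.assert_allclose(aif.values, np.clip(direct.values, 0, None))
        assert aif.source_roi_size == 1

    def test_two_voxel_roi_is_frame_wise_mean(self, noiseless_series, phantom32):
        voxels = np.argwhere(phantom32.trunk_mask)[:2]
        mask = np.zeros(phantom32.grid_shape, dtype=bool)
        mask[tuple(voxels.T)] = True
        aif = extract_aif(noiseless_series, mask)
        u = signal_to_concentration(noiseless_series, voxel=tuple(voxels[0])).values
        v = signal_to_concentration(noiseless_series, voxel=tuple(voxels[1])).values
        np.testing.assert_allclose(aif.values, np.clip((u + v) / 2.0, 0, None))

    def test_empty_mask_raises(self, noiseless_series, phantom32):
        with pytest.raises(ValueError, match="empty AIF ROI"):
            extract_aif(noiseless_series, np.zeros(phantom32.grid_shape, bool))


class TestConvolutionMatrix:
    def test_unit_impulse_aif_gives_identity(self):
        dt = 1.5
        ca = np.zeros(10)
        ca[0] = 1.0 / dt
        A = build_convolution_matrix(AIFCurve(ca, dt))
        np.testing.assert_allclose(A, np.eye(10), atol=1e-12)

    def test_matches_brute_force_convolution(self):
        rng = np.random.default_rng(4)
        ca = rng.uniform(0, 1, 8)
        r = rng.uniform(0, 1, 8)
        dt = 1.5
        A = build_convolution_matrix(AIFCurve(ca, dt))
        brute = np.array(
            [dt * sum(ca[i - j] * r[j] for j in range(i + 1)) for i in range(8)]
        )
        np.testing.assert_allclose(A @ r, brute, rtol=1e-12)

    def test_constant_aif_gives_scaled_ramp(self):
        dt, c = 0.5, 3.0
        A = build_convolution_matrix(AIFCurve(np.full(6, c), dt))
        np.testing.assert_allclose(A @ np.ones(6), dt * c * np.arange(1, 7))

    def test_lower_triangular_toeplitz_structure(self, prompt_aif):
        A = build_convolution_matrix(AIFCurve(prompt_aif, 1.5))
        assert np.all(A[np.triu_indices_from(A, k=1)] == 0)
        for k in range(len(prompt_aif)):
            diag = np.diagonal(A, offset=-k)
            assert np.allclose(diag, diag[0])


class TestDeconvolveTSVD:
    def test_identity_system_returns_tissue_curve(self):
        dt = 1.5
        ca = np.zeros(20)
        ca[0] = 1.0 / dt
        A = build_convolution_matrix(AIFCurve(ca, dt))
        c = ConcentrationSeries(np.sin(np.arange(20)) ** 2, dt)
        for thr in (0.0, 0.15, 0.5):
            fr = deconvolve_tsvd(A, c, thr)
            np.testing.assert_allclose(fr.fr_values, c.values, atol=1e-10)

    def test_noiseless_boxcar_matches_triangular_solve(self, prompt_aif):
        dt, pbf, mtt = 1.5, 60.0, 6.0
        ct = tissue_curve(prompt_aif, pbf, mtt, "boxcar", dt)
        A = build_convolution_matrix(AIFCurve(prompt_aif, dt))
        fr = deconvolve_tsvd(A, ConcentrationSeries(ct, dt), 0.0)
        exact = solve_triangular(A, ct, lower=True)
        np.testing.assert_allclose(fr.fr_values, exact, atol=1e-8 * np.abs(exact).max())
        # the known step function f*1{t<mtt}
        expected = (pbf / 6000.0) * (np.arange(40) * dt < mtt)
        np.testing.assert_allclose(fr.fr_values, expected, atol=1e-8)

    def test_exponential_recovery_within_ten_percent_at_default_threshold(self):
        # bolus arriving after the baseline frames, as acquired
        from lungdce.synthetic import gamma_variate_aif

        dt, pbf, mtt = 1.5, 60.4, 6.3
        t = np.arange(40) * dt
        ca = gamma_variate_aif(t, t0=7.5, alpha=3.0, beta=1.5)
        ct = tissue_curve(ca, pbf, mtt, "exponential", dt)
        A = build_convolution_matrix(AIFCurve(ca, dt))
        fr = deconvolve_tsvd(A, ConcentrationSeries(ct, dt), 0.15)
        assert 6000.0 * fr.fr_values.max() == pytest.approx(pbf, rel=0.10)

    def test_forward_convolving_recovered_residue_reproduces_tissue(self, prompt_aif):
        dt = 1.5
        ct = tissue_curve(prompt_aif, 90.0, 8.0, "exponential", dt)
        A = build_convolution_matrix(AIFCurve(prompt_aif, dt))
        for thr, tol in ((0.0, 1e-6), (0.15, 0.05)):
            fr = deconvolve_tsvd(A, ConcentrationSeries(ct, dt), thr)
            resid = np.linalg.norm(A @ fr.fr_values - ct) / np.linalg.norm(ct)
            assert resid <= tol

    def test_degenerate_aif_raises(self):
        A = np.zeros((10, 10))
        with pytest.raises(DegenerateAIFError):
            deconvolve_tsvd(A, ConcentrationSeries(np.ones(10), 1.5), 0.15)

    def test_invalid_threshold_rejected(self, prompt_aif):
        A = build_convolution_matrix(AIFCurve(prompt_aif, 1.5))
        with pytest.raises(ValueError):
            deconvolve_tsvd(A, ConcentrationSeries(np.ones(40), 1.5), 1.2)


class TestComputeParameters:
    def _unit_inputs(self, n=20, dt=1.5):
        aif = AIFCurve(np.ones(n), dt)
        ct = ConcentrationSeries(np.ones(n), dt)
        return ct, aif

    def test_constant_residue_pbf_unit_conversion(self):
        ct, aif = self._unit_inputs()
        fr = ResidueEstimate(np.full(20, 0.01), 1.5, 0.0)
        pbf, _, _ = compute_parameters(fr, ct, aif)
        assert pbf == pytest.approx(60.0)

    def test_equal_areas_give_pbv_100(self):
        ct, aif = self._unit_inputs()
        fr = ResidueEstimate(np.full(20, 0.01), 1.5, 0.0)
        _, pbv, _ = compute_parameters(fr, ct, aif)
        assert pbv == pytest.approx(100.0)

    def test_central_volume_mtt(self):
        # PBF 60, PBV 6 -> MTT 6 s
        n, dt = 20, 1.5
        aif = AIFCurve(np.ones(n), dt)
        ct = ConcentrationSeries(np.full(n, 0.06), dt)
        fr = ResidueEstimate(np.full(n, 0.01), dt, 0.0)
        pbf, pbv, mtt = compute_parameters(fr, ct, aif)
        assert (pbf, pbv, mtt) == (pytest.approx(60.0), pytest.approx(6.0), pytest.approx(6.0))

    def test_zero_aif_area_raises(self):
        aif = AIFCurve(np.zeros(10) + 1e-30, 1.5)
        aif.values[:] = 0.0
        ct = ConcentrationSeries(np.ones(10), 1.5)
        fr = ResidueEstimate(np.ones(10), 1.5, 0.0)
        with pytest.raises(ZeroDivisionError):
            compute_parameters(fr, ct, aif)

    def test_nonpositive_flow_flags_invalid(self):
        ct, aif = self._unit_inputs()
        fr = ResidueEstimate(np.full(20, -0.01), 1.5, 0.0)
        pbf, pbv, mtt = compute_parameters(fr, ct, aif)
        assert np.isnan(pbf) and np.isnan(pbv) and np.isnan(mtt)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(scale=st.floats(0.01, 100.0))
    def test_scaling_both_curves_leaves_parameters_unchanged(self, scale):
        dt = 1.5
        ca = prompt_bolus()
        ct_vals = tissue_curve(ca, 60.4, 6.3, dt=dt)
        A = build_convolution_matrix(AIFCurve(ca, dt))
        fr0 = deconvolve_tsvd(A, ConcentrationSeries(ct_vals, dt), 0.15)
        p0 = compute_parameters(fr0, ConcentrationSeries(ct_vals, dt), AIFCurve(ca, dt))

        As = build_convolution_matrix(AIFCurve(scale * ca, dt))
        frs = deconvolve_tsvd(As, ConcentrationSeries(scale * ct_vals, dt), 0.15)
        ps = compute_parameters(
            frs, ConcentrationSeries(scale * ct_vals, dt), AIFCurve(scale * ca, dt)
        )
        np.testing.assert_allclose(ps, p0, rtol=1e-8)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(scale=st.floats(0.01, 100.0))
    def test_scaling_tissue_only_scales_pbf_and_pbv(self, scale):
        dt = 1.5
        ca = prompt_bolus()
        ct_vals = tissue_curve(ca, 60.4, 6.3, dt=dt)
        aif = AIFCurve(ca, dt)
        A = build_convolution_matrix(aif)
        fr0 = deconvolve_tsvd(A, ConcentrationSeries(ct_vals, dt), 0.15)
        p0 = compute_parameters(fr0, ConcentrationSeries(ct_vals, dt), aif)
        frs = deconvolve_tsvd(A, ConcentrationSeries(scale * ct_vals, dt), 0.15)
        ps = compute_parameters(frs, ConcentrationSeries(scale * ct_vals, dt), aif)
        assert ps[0] == pytest.approx(scale * p0[0], rel=1e-8)
        assert ps[1] == pytest.approx(scale * p0[1], rel=1e-8)
        assert ps[2] == pytest.approx(p0[2], rel=1e-8)


class TestMakeMaps:
    def test_uniform_phantom_gives_constant_maps(self):
        ph = make_phantom((24, 24, 24), "left", seed=2)
        truth = KineticGroundTruth.from_side_values(
            ph, pbf={"left": 60.0, "right": 60.0}, mtt={"left": 6.0, "right": 6.0},
            vessel_mtt_factor=1.0,
        )
        series = render_dce(ph, truth, AcquisitionConfig(noise_sigma=0.0, seed=0))
        aif = extract_aif(series, ph.trunk_mask)
        mask = ph.left_lung_mask | ph.right_lung_mask
        maps = make_maps(series, aif, mask)
        vals = maps.pbf[mask]
        assert np.nanstd(vals) / np.nanmean(vals) < 1e-6

    def test_side_means_ordered_with_ground_truth(
        self, phantom32, noiseless_series
    ):
        # left lung truth 60.4, right 90.0
        aif = extract_aif(noiseless_series, phantom32.trunk_mask)
        mask = phantom32.left_lung_mask | phantom32.right_lung_mask
        maps = make_maps(noiseless_series, aif, mask)
        left_mean = np.nanmean(maps.pbf[phantom32.left_lung_mask])
        right_mean = np.nanmean(maps.pbf[phantom32.right_lung_mask])
        assert left_mean < right_mean

    def test_noisy_maps_deterministic_per_seed(self, phantom32, truth32):
        acq = AcquisitionConfig(noise_sigma=1.0, seed=31)
        mask = phantom32.left_lung_mask
        out = []
        for _ in range(2):
            series = render_dce(phantom32, truth32, acq)
            aif = extract_aif(series, phantom32.trunk_mask)
            maps = make_maps(series, aif, mask)
            out.append(maps.pbf)
        np.testing.assert_array_equal(out[0], out[1])

    def test_empty_mask_raises(self, noiseless_series, phantom32):
        aif = extract_aif(noiseless_series, phantom32.trunk_mask)
        with pytest.raises(ValueError, match="empty"):
            make_maps(noiseless_series, aif, np.zeros(phantom32.grid_shape, bool))


class TestTSVDOperator:
    def test_operator_matches_per_curve_deconvolution(self, prompt_aif):
        dt = 1.5
        A = build_convolution_matrix(AIFCurve(prompt_aif, dt))
        pinv = tsvd_operator(A, 0.15)
        rng = np.random.default_rng(8)
        curves = rng.normal(size=(5, 40))
        bulk = curves @ pinv.T
        for i in range(5):
            fr = deconvolve_tsvd(A, ConcentrationSeries(curves[i], dt), 0.15)
            np.testing.assert_allclose(bulk[i], fr.fr_values, rtol=1e-10, atol=1e-12)
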
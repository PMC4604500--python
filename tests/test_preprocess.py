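"""Preprocessing chain: masking, despiking, interpolation, baseline, norm."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ramanresp import (
    HyperspectralCube,
    baseline_correct,
    despike,
    interpolate_to_reference,
    mask_background,
    preprocess_cube,
    vector_normalize,
)
from ramanresp.preprocess import DEFAULT_NORM_REGIONS

GRID = np.arange(600.0, 3102.0, 2.0)


def gauss(w, center, fwhm, amp):
    sigma = fwhm / (2 * np.sqrt(2 * np.log(2)))
    return amp * np.exp(-((w - center) ** 2) / (2 * sigma**2))


class TestMaskBackground:
    def test_zero_ch_region_pixel_is_background(self):
        cube_arr = np.zeros((2, 2, len(GRID)))
        cube_arr[0, 0] = gauss(GRID, 2900, 40, 1.0)  # one cell-like pixel
        cube_arr[0, 1] = gauss(GRID, 1400, 40, 1.0)  # fingerprint only, flat C-H
        cube = HyperspectralCube(cube_arr, GRID, 0.5)
        mask = mask_background(cube)
        assert mask[0, 0]
        assert not mask[0, 1]
        assert not mask[1, 1]

    def test_noiseless_phantom_mask_equals_ground_truth(self, noiseless_phantom):
        cube, truth = noiseless_phantom
        mask = mask_background(cube)
        np.testing.assert_array_equal(mask, truth.label_map > 0)

    def test_noisy_phantom_mask_agreement_over_95_percent(self, noisy_phantom):
        cube, truth = noisy_phantom
        mask = mask_background(cube)
        agreement = (mask == (truth.label_map > 0)).mean()
        assert agreement >= 0.95

    def test_region_outside_grid_raises(self, noisy_phantom):
        cube, _ = noisy_phantom
        with pytest.raises(ValueError, match="region"):
            mask_background(cube, ch_region=(5000.0, 5100.0))


class TestDespike:
    def test_spike_free_spectrum_returned_bit_identical(self):
        spec = 0.05 + gauss(GRID, 1450, 20, 1.0) + gauss(GRID, 2900, 40, 0.8)
        assert np.array_equal(despike(spec), spec)

    def test_large_impulse_restored_others_untouched(self):
        rng = np.random.default_rng(4)
        sigma_noise = 0.01
        clean = 0.1 + gauss(GRID, 1450, 20, 1.0)
        noisy = clean + rng.normal(0, sigma_noise, GRID.shape)
        i = 300
        spiked = noisy.copy()
        spiked[i] += 10.0  # 10x the max genuine band
        out = despike(spiked)
        assert abs(out[i] - noisy[i]) < 3 * sigma_noise + abs(out[i] - clean[i])
        assert abs(out[i] - clean[i]) < 3 * sigma_noise
        mask = np.ones(GRID.shape, bool)
        mask[i] = False
        np.testing.assert_array_equal(out[mask], spiked[mask])

    def test_genuine_fwhm10_band_distorted_below_1_percent(self):
        spec = 0.02 + gauss(GRID, 1008, 10.0, 1.0)
        out = despike(spec)
        i = np.argmin(np.abs(GRID - 1008))
        assert abs(out[i] - spec[i]) < 0.01 * 1.0

    def test_window_larger_than_spectrum_raises(self):
        with pytest.raises(ValueError, match="window"):
            despike(np.arange(5.0), window=7)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            despike(np.arange(50.0), window=6)

    @settings(max_examples=25, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_gaussian_noise_below_threshold_never_flagged(self, seed):
        # z=6 robust sigmas: flagging pure Gaussian noise is probability-bounded
        rng = np.random.default_rng(seed)
        spec = 0.5 + rng.normal(0, 0.02, 400)
        assert np.array_equal(despike(spec, z_threshold=6.0), spec)


class TestInterpolate:
    def test_identity_on_same_grid(self):
        spec = gauss(GRID, 1200, 30, 1.0)
        np.testing.assert_array_equal(
            interpolate_to_reference(spec, GRID, GRID), spec
        )

    def test_affine_spectra_reproduced_exactly(self):
        src = np.linspace(700, 3000, 901)
        ref = np.linspace(710, 2990, 557)
        spec = 0.003 * src + 1.7
        np.testing.assert_allclose(
            interpolate_to_reference(spec, src, ref), 0.003 * ref + 1.7, rtol=1e-12
        )

    def test_gaussian_resampling_error_below_1_percent(self):
        src = np.arange(600.0, 3100.0, 1.7)
        ref = np.arange(605.0, 3095.0, 2.0)
        out = interpolate_to_reference(gauss(src, 1450, 16, 1.0), src, ref)
        dense = gauss(ref, 1450, 16, 1.0)
        assert np.max(np.abs(out - dense)) < 0.01

    def test_extrapolation_refused(self):
        src = np.arange(700.0, 1800.0, 2.0)
        ref = np.arange(600.0, 1800.0, 2.0)
        with pytest.raises(ValueError, match="outside source span"):
            interpolate_to_reference(np.ones_like(src), src, ref)


class TestBaseline:
    def test_pure_cubic_fully_removed(self):
        x = np.linspace(-1, 1, len(GRID))
        spec = 5.0 + 2.0 * x - 1.5 * x**2 + 0.8 * x**3
        corrected, baseline = baseline_correct(spec)
        assert np.max(np.abs(corrected)) < 1e-6 * np.max(np.abs(spec))

    def test_flat_zero_unchanged(self):
        corrected, baseline = baseline_correct(np.zeros(100))
        np.testing.assert_allclose(corrected, 0.0, atol=1e-12)
        np.testing.assert_allclose(baseline, 0.0, atol=1e-12)

    def test_band_plus_cubic_recovery_within_5_percent(self):
        x = np.linspace(-1, 1, len(GRID))
        true_coeffs = np.array([0.4, 0.25, 0.15, -0.1])
        true_base = np.vander(x, 4, increasing=True) @ true_coeffs
        band = gauss(GRID, 1400, 30, 1.0)
        spec = true_base + band
        corrected, baseline = baseline_correct(spec)
        # oracle: least squares restricted to channels > 3 FWHM from the band
        far = np.abs(GRID - 1400) > 3 * 30
        V = np.vander(x, 4, increasing=True)
        oracle_coeffs, *_ = np.linalg.lstsq(V[far], spec[far], rcond=None)
        oracle_baseline = V @ oracle_coeffs
        # recovered baseline within 5% of the band amplitude everywhere
        assert np.max(np.abs(baseline - oracle_baseline)) < 0.05 * 1.0
        band_area = np.trapezoid(band, GRID)
        corrected_area = np.trapezoid(corrected[~far], GRID[~far])
        assert corrected_area == pytest.approx(band_area, rel=0.05)

    def test_non_finite_rejected(self):
        spec = np.ones(50)
        spec[3] = np.nan
        with pytest.raises(ValueError, match="finite"):
            baseline_correct(spec)

    @settings(max_examples=20, deadline=None)
    @given(
        c0=st.floats(-2, 2),
        c1=st.floats(-2, 2),
        c2=st.floats(-2, 2),
        c3=st.floats(-2, 2),
    )
    def test_exact_on_any_band_free_cubic(self, c0, c1, c2, c3):
        x = np.linspace(-1, 1, 300)
        spec = c0 + c1 * x + c2 * x**2 + c3 * x**3
        corrected, _ = baseline_correct(spec)
        scale = max(np.max(np.abs(spec)), 1.0)
        assert np.max(np.abs(corrected)) < 1e-8 * scale


class TestVectorNormalize:
    def test_unit_norm(self):
        rng = np.random.default_rng(0)
        spec = rng.random(200) + 0.1
        out = vector_normalize(spec)
        assert np.linalg.norm(out) == pytest.approx(1.0, abs=1e-12)

    def test_scale_invariance(self):
        spec = gauss(GRID, 1450, 30, 1.0) + 0.05
        np.testing.assert_allclose(
            vector_normalize(7.0 * spec), vector_normalize(spec), rtol=1e-12
        )

    def test_idempotent(self):
        spec = gauss(GRID, 1450, 30, 2.0)
        once = vector_normalize(spec, GRID, DEFAULT_NORM_REGIONS)
        twice = vector_normalize(once, GRID, DEFAULT_NORM_REGIONS)
        np.testing.assert_allclose(twice, once, rtol=1e-12)

    def test_zero_spectrum_raises(self):
        with pytest.raises(ValueError, match="zero-norm"):
            vector_normalize(np.zeros(100))

    def test_region_restricted_norm(self):
        spec = gauss(GRID, 1450, 30, 1.0) + gauss(GRID, 2400, 30, 5.0)
        out = vector_normalize(spec, GRID, [(700.0, 1800.0)])
        sel = (GRID >= 700) & (GRID <= 1800)
        assert np.linalg.norm(out[sel]) == pytest.approx(1.0, abs=1e-12)


class TestPreprocessCube:
    def test_noiseless_chain_recovers_reference_spectra(self, noiseless_phantom):
        cube, truth = noiseless_phantom
        pre = preprocess_cube(cube)
        # oracle: the same deterministic chain applied directly to each
        # component's reference spectrum (identity mask/despike/interp here)
        expected = {}
        for name, ref in truth.reference_spectra.items():
            corrected, _ = baseline_correct(ref)
            expected[name] = vector_normalize(
                corrected, cube.wavenumbers, DEFAULT_NORM_REGIONS
            )
        labels = truth.label_map[pre.mask]
        from ramanresp.core import LABEL_NAMES

        for lab in np.unique(labels):
            sel = labels == lab
            got = pre.spectra[sel]
            np.testing.assert_allclose(
                got, np.tile(expected[LABEL_NAMES[lab]], (sel.sum(), 1)), atol=1e-6
            )
            # band content survives baseline removal: close to plain
            # unit-normalised reference up to the removed offset
            plain = vector_normalize(
                truth.reference_spectra[LABEL_NAMES[lab]]
                - truth.reference_spectra[LABEL_NAMES[lab]].min(),
                cube.wavenumbers,
                DEFAULT_NORM_REGIONS,
            )
            assert np.max(np.abs(got[0] - plain)) < 0.05

    def test_every_retained_spectrum_has_unit_norm(self, noisy_pre):
        from ramanresp.core import interval_indices

        idx = np.unique(
            np.concatenate(
                [interval_indices(noisy_pre.wavenumbers, lo, hi) for lo, hi in DEFAULT_NORM_REGIONS]
            )
        )
        norms = np.linalg.norm(noisy_pre.spectra[:, idx], axis=1)
        np.testing.assert_allclose(norms, 1.0, atol=1e-10)

    def test_channels_never_reordered_or_dropped(self, noisy_pre, noisy_phantom):
        cube, _ = noisy_phantom
        np.testing.assert_array_equal(noisy_pre.wavenumbers, cube.wavenumbers)

    def test_processing_log_records_each_stage(self, noisy_pre):
        steps = [e["step"] for e in noisy_pre.log]
        assert steps == [
            "mask_background",
            "despike",
            "interpolate_to_reference",
            "baseline_correct",
            "vector_normalize",
        ]

    def test_heavy_spike_load_leaves_no_residual_impulses(self):
        from conftest import make_small_config
        from ramanresp import generate_phantom
        from ramanresp.preprocess import _despike_batch

        def audit_fraction(spike_rate: float) -> float:
            cfg = make_small_config(seed=77, spike_rate=spike_rate)
            cube, _ = generate_phantom(cfg, "control")
            pre = preprocess_cube(cube)
            audited = _despike_batch(pre.spectra, 9, 5.0, 3.0)
            return float(np.any(audited != pre.spectra, axis=1).mean())

        # same noise draws with and without spikes: any *excess* of spectra
        # tripping a stricter impulse audit is residual spike contamination
        excess = audit_fraction(0.5) - audit_fraction(0.0)
        assert excess <= 0.001
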
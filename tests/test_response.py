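"""Response quantification: normalisation, differences, PCA, magnitudes."""

from __future__ import annotations

import numpy as np
import pytest

from ramanresp import (
    AnalysisRegion,
    ComponentSpectrum,
    build_report,
    cell_mean_spectrum,
    difference_spectrum,
    normalize_to_phenylalanine,
    pca_compare,
    permutation_pvalue,
    response_magnitude,
)
from ramanresp.peaks import chord_prominence

GRID = np.arange(600.0, 3102.0, 2.0)


def gauss(w, center, fwhm, amp):
    sigma = fwhm / (2 * np.sqrt(2 * np.log(2)))
    return amp * np.exp(-((w - center) ** 2) / (2 * sigma**2))


def make_cs(mean, sd=None, component="cytoplasm", n_pixels=100):
    sd = np.zeros_like(mean) if sd is None else sd
    return ComponentSpectrum(component, GRID, mean, sd, n_pixels)


class TestPhenylalanineNormalization:
    def test_peak_height_five_becomes_one(self):
        cs = make_cs(gauss(GRID, 1008, 10, 5.0) + gauss(GRID, 1450, 20, 2.0))
        out = normalize_to_phenylalanine(cs)
        assert chord_prominence(out.mean, GRID, 1008.0) == pytest.approx(1.0, rel=1e-9)

    def test_idempotent(self):
        cs = make_cs(gauss(GRID, 1008, 10, 3.0) + 0.2)
        once = normalize_to_phenylalanine(cs)
        twice = normalize_to_phenylalanine(once)
        np.testing.assert_allclose(twice.mean, once.mean, rtol=1e-12)

    def test_scale_invariant(self):
        mean = gauss(GRID, 1008, 10, 2.0) + gauss(GRID, 1660, 24, 1.0)
        a = normalize_to_phenylalanine(make_cs(mean))
        b = normalize_to_phenylalanine(make_cs(mean * 9.0))
        np.testing.assert_allclose(a.mean, b.mean, rtol=1e-12)

    def test_spectrum_without_1008_band_raises(self):
        cs = make_cs(gauss(GRID, 1750, 14, 1.0) + gauss(GRID, 2851, 22, 1.0),
                     component="lipid_only")
        with pytest.raises(ValueError, match="phenylalanine"):
            normalize_to_phenylalanine(cs)


class TestCellMeanSpectrum:
    def test_single_pixel_mean_is_pixel(self, noisy_pre):
        import dataclasses

        one = dataclasses.replace(noisy_pre)
        one.spectra = noisy_pre.spectra[:1]
        cs = cell_mean_spectrum(one)
        np.testing.assert_array_equal(cs.mean, noisy_pre.spectra[0])
        np.testing.assert_array_equal(cs.sd, 0.0)

    def test_matches_longhand_mean_sd(self, noisy_pre):
        cs = cell_mean_spectrum(noisy_pre)
        np.testing.assert_allclose(cs.mean, noisy_pre.spectra.mean(axis=0))
        np.testing.assert_allclose(cs.sd, noisy_pre.spectra.std(axis=0))
        assert cs.n_pixels == noisy_pre.spectra.shape[0]


class TestDifferenceSpectrum:
    def test_identical_conditions_zero_difference_no_peaks(self):
        cs = make_cs(gauss(GRID, 1008, 10, 1.0), sd=np.full(GRID.shape, 0.01))
        d = difference_spectrum(cs, cs)
        np.testing.assert_array_equal(d.values, 0.0)
        assert d.peaks == []

    def test_antisymmetry(self, rng):
        a = make_cs(rng.random(len(GRID)), sd=np.full(GRID.shape, 0.05))
        b = make_cs(rng.random(len(GRID)), sd=np.full(GRID.shape, 0.05))
        dab = difference_spectrum(a, b)
        dba = difference_spectrum(b, a)
        np.testing.assert_allclose(dab.values, -dba.values, rtol=1e-12)
        assert {(p.center, p.sign) for p in dab.peaks} == {
            (p.center, "+" if p.sign == "-" else "-") for p in dba.peaks
        }

    def test_grid_mismatch_rejected(self):
        a = make_cs(np.ones(len(GRID)))
        other = ComponentSpectrum(
            "cytoplasm", GRID + 1.0, np.ones(len(GRID)), np.zeros(len(GRID)), 10
        )
        with pytest.raises(ValueError, match="grid"):
            difference_spectrum(a, other)

    def test_known_band_change_detected_with_sign(self):
        base = gauss(GRID, 1008, 10, 1.0) + gauss(GRID, 1661, 24, 1.2) + gauss(
            GRID, 1750, 14, 0.9
        )
        treated = base + 0.3 * gauss(GRID, 1661, 24, 1.0) - 0.3 * gauss(GRID, 1750, 14, 1.0)
        sd = np.full(GRID.shape, 0.05)
        d = difference_spectrum(make_cs(base, sd), make_cs(treated, sd))
        kinds = {(p.center, p.sign) for p in d.peaks}
        assert any(abs(c - 1661) <= 4 and s == "-" for c, s in kinds)
        assert any(abs(c - 1750) <= 4 and s == "+" for c, s in kinds)


class TestPCACompare:
    def test_affine_subspace_single_component(self, rng):
        direction = rng.random(30)
        X = np.outer(np.linspace(0, 1, 6), direction) + rng.random(30)
        res = pca_compare(X, [("c", "control")] * 3 + [("c", "treated")] * 3)
        assert res.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-10)

    def test_matches_covariance_eigendecomposition(self, rng):
        X = rng.normal(size=(6, 30))
        labels = [(f"c{i}", "control") for i in range(6)]
        res = pca_compare(X, labels)
        # independent oracle: eigen-decomposition of the channel covariance
        Xc = X - X.mean(axis=0)
        C = Xc.T @ Xc / 1.0
        evals, evecs = np.linalg.eigh(C)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        np.testing.assert_allclose(
            res.explained_variance_ratio,
            (evals / evals.sum())[:3],
            atol=1e-8,
        )
        for i in range(3):
            v = evecs[:, i]
            assert min(
                np.max(np.abs(res.loadings[i] - v)), np.max(np.abs(res.loadings[i] + v))
            ) < 1e-8

    def test_duplicated_observations_leave_loadings_unchanged(self, rng):
        X = rng.normal(size=(4, 20))
        labels = [(f"c{i}", "control") for i in range(4)]
        a = pca_compare(X, labels)
        b = pca_compare(np.vstack([X, X]), labels + labels)
        np.testing.assert_allclose(np.abs(a.loadings), np.abs(b.loadings), atol=1e-8)

    def test_loading_sign_convention(self, rng):
        res = pca_compare(rng.normal(size=(5, 15)), [(f"c{i}", "control") for i in range(5)])
        for load in res.loadings:
            assert load[np.argmax(np.abs(load))] > 0

    def test_fewer_than_two_observations_rejected(self):
        with pytest.raises(ValueError, match="2 observations"):
            pca_compare(np.ones((1, 10)), [("c", "control")])

    def test_pc1_pairing_per_component(self, rng):
        X = rng.normal(size=(4, 25))
        labels = [("membrane", "control"), ("membrane", "treated"),
                  ("nucleus", "control"), ("nucleus", "treated")]
        res = pca_compare(X, labels)
        assert set(res.pc1_pairs) == {"membrane", "nucleus"}
        assert res.pc1_pairs["membrane"] == (
            pytest.approx(res.scores[0, 0]), pytest.approx(res.scores[1, 0])
        )


class TestResponseMagnitude:
    def test_zero_difference_zero_magnitude(self):
        cs = make_cs(gauss(GRID, 1008, 10, 1.0))
        d = difference_spectrum(cs, cs)
        assert response_magnitude(d) == 0.0

    def test_empty_region_rejected(self):
        cs = make_cs(np.ones(len(GRID)))
        d = difference_spectrum(cs, cs)
        with pytest.raises(ValueError, match="no channels"):
            response_magnitude(d, AnalysisRegion(((5000.0, 5100.0),)))

    def test_permutation_p_high_for_identical_groups(self, rng):
        base = gauss(GRID, 1450, 20, 1.0)
        cells = np.vstack([base + rng.normal(0, 0.01, GRID.shape) for _ in range(8)])
        _, p = permutation_pvalue(cells[:4], cells[4:], GRID, n_permutations=199, seed=0)
        assert p > 0.05

    def test_permutation_p_low_for_strong_shift(self, rng):
        base = gauss(GRID, 1450, 20, 1.0)
        c = np.vstack([base + rng.normal(0, 0.005, GRID.shape) for _ in range(4)])
        t = np.vstack(
            [base + gauss(GRID, 1661, 24, 0.5) + rng.normal(0, 0.005, GRID.shape) for _ in range(4)]
        )
        _, p = permutation_pvalue(c, t, GRID, n_permutations=199, seed=0)
        assert p < 0.05


class TestEffectLinearity:
    def test_doubling_effect_amplitudes_doubles_component_magnitudes(self):
        from conftest import make_noiseless, make_small_config
        from ramanresp import TreatmentEffect, analyze_pair

        half = TreatmentEffect(
            droplet_retention=0.5, protein_band_gain=1.06, droplet_band_attenuation=0.85
        )
        full = TreatmentEffect(
            droplet_retention=0.5, protein_band_gain=1.12, droplet_band_attenuation=0.70
        )
        mags = {}
        for name, eff in (("half", half), ("full", full)):
            cfg = make_noiseless(make_small_config(seed=13, effect=eff))
            rep = analyze_pair(cfg, n_cells=1, n_permutations=19).report
            mags[name] = rep.component_magnitudes
        for comp in mags["half"]:
            ratio = mags["full"][comp] / mags["half"][comp]
            assert ratio == pytest.approx(2.0, rel=0.10)


class TestBuildReport:
    def _diffs(self, scale=1.0, sd=0.02):
        comps = {
            "membrane": 0.3,
            "cytoplasm": 0.5,
            "nucleus": 0.4,
            "lipid_droplet": 1.0,
        }
        out = {}
        for comp, amp in comps.items():
            base = gauss(GRID, 1008, 10, 1.0) + gauss(GRID, 1661, 24, 1.0)
            treated = base + scale * amp * gauss(GRID, 1661, 24, 0.4)
            out[comp] = difference_spectrum(
                make_cs(base, np.full(GRID.shape, sd), comp),
                make_cs(treated, np.full(GRID.shape, sd), comp),
            )
        return out

    def test_largest_component_identified(self):
        diffs = self._diffs()
        report = build_report(diffs, 8, 4, diffs["cytoplasm"])
        assert report.largest_component == "lipid_droplet"
        assert report.droplet_ratio == pytest.approx(0.5)

    def test_identical_conditions_all_zero(self):
        cs = make_cs(gauss(GRID, 1008, 10, 1.0))
        zero = {
            comp: difference_spectrum(cs, cs)
            for comp in ("membrane", "cytoplasm", "nucleus", "lipid_droplet")
        }
        report = build_report(zero, 5, 5, difference_spectrum(cs, cs))
        assert all(m == 0.0 for m in report.component_magnitudes.values())
        assert report.whole_cell_magnitude == 0.0
        assert report.droplet_ratio == 1.0

    def test_missing_component_rejected(self):
        diffs = self._diffs()
        del diffs["nucleus"]
        with pytest.raises(ValueError, match="nucleus"):
            build_report(diffs, 8, 4, diffs["cytoplasm"])
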
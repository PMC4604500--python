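"""Drug-response quantification from segmented Raman maps.

Mean spectra of each subcellular component are normalised to the
phenylalanine ring-breathing band near 1008 cm^-1, and difference spectra
(control mean minus treated mean) are computed per component and for the
whole cell.  A positive difference peak means the band is weaker in
treated cells; a negative peak means it is stronger.  PCA over the
component x condition mean spectra provides loading comparison, and a
scalar response magnitude (RMS of the difference over the analysis
regions) with a label-permutation p-value reproduces the
large / small / none response ordering across mutation profiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .core import CELL_COMPONENTS, ComponentSpectrum
from .peaks import DetectedPeak, chord_prominence, detect_peaks
from .preprocess import PreprocessedCube
from .segment import AnalysisRegion

__all__ = [
    "DifferenceSpectrum",
    "PCAResult",
    "ResponseReport",
    "normalize_to_phenylalanine",
    "cell_mean_spectrum",
    "difference_spectrum",
    "pca_compare",
    "response_magnitude",
    "permutation_pvalue",
    "build_report",
]

PHENYLALANINE_CENTER = 1008.0


@dataclass
class DifferenceSpectrum:
    """Control mean minus treated mean, with signed detected peaks."""

    component: str
    wavenumbers: np.ndarray
    values: np.ndarray
    pooled_sd: np.ndarray
    peaks: list[DetectedPeak] = field(default_factory=list)


@dataclass
class PCAResult:
    """PCA over component x condition mean spectra."""

    row_labels: list[tuple[str, str]]          # (component, condition)
    loadings: np.ndarray                       # (n_pcs, n_channels), unit norm
    explained_variance_ratio: np.ndarray       # non-increasing, sums <= 1
    scores: np.ndarray                         # (n_obs, n_pcs)
    pc1_pairs: dict[str, tuple[float, float]]  # component -> (control, treated) PC1 score


@dataclass
class ResponseReport:
    """Scalar summary of the spectral drug response."""

    component_magnitudes: dict[str, float]
    whole_cell_magnitude: float
    droplet_ratio: float
    largest_component: str
    p_value: float | None = None
    mutation_profile: str | None = None

    def to_dict(self) -> dict:
        return {
            "component_magnitudes": {
                k: float(v) for k, v in self.component_magnitudes.items()
            },
            "whole_cell_magnitude": float(self.whole_cell_magnitude),
            "droplet_ratio": float(self.droplet_ratio),
            "largest_component": self.largest_component,
            "p_value": None if self.p_value is None else float(self.p_value),
            "mutation_profile": self.mutation_profile,
        }


def phenylalanine_height(
    mean: np.ndarray,
    wavenumbers: np.ndarray,
    center: float = PHENYLALANINE_CENTER,
    window: float = 8.0,
) -> float:
    """Chord prominence of the 1008 cm^-1 band in a mean spectrum."""
    return chord_prominence(mean, wavenumbers, center, window)


def normalize_to_phenylalanine(
    spectrum: ComponentSpectrum,
    center: float = PHENYLALANINE_CENTER,
    window: float = 8.0,
    min_rel_height: float = 0.01,
) -> ComponentSpectrum:
    """Divide a mean spectrum by its phenylalanine band height.

    After normalisation the 1008 cm^-1 chord prominence equals 1, which
    makes the operation idempotent and scale invariant.

    Raises
    ------
    ValueError
        If no phenylalanine band is detectable (e.g. a pure-lipid or
        background spectrum).
    """
    h = phenylalanine_height(spectrum.mean, spectrum.wavenumbers, center, window)
    if h <= min_rel_height * float(np.ptp(spectrum.mean)):
        raise ValueError(
            f"component {spectrum.component!r}: no detectable phenylalanine band "
            f"near {center} cm^-1 (height {h:.3g})"
        )
    return spectrum.scaled(h)


def cell_mean_spectrum(pre: PreprocessedCube) -> ComponentSpectrum:
    """Whole-cell mean and channel-wise sd over all foreground pixels."""
    if pre.spectra.shape[0] < 1:
        raise ValueError("no foreground pixels")
    return ComponentSpectrum(
        component="whole_cell",
        wavenumbers=pre.wavenumbers,
        mean=pre.spectra.mean(axis=0),
        sd=pre.spectra.std(axis=0),
        n_pixels=pre.spectra.shape[0],
    )


def difference_spectrum(
    control: ComponentSpectrum,
    treated: ComponentSpectrum,
    peak_snr: float = 3.0,
    min_separation: float = 8.0,
) -> DifferenceSpectrum:
    """Control mean minus treated mean with signed peak detection.

    Peaks are local extrema whose prominence exceeds ``peak_snr`` times the
    mean pooled channel sd; positive peaks mark bands weaker in treated
    cells, negative peaks bands stronger in treated cells.
    """
    if control.wavenumbers.shape != treated.wavenumbers.shape or not np.allclose(
        control.wavenumbers, treated.wavenumbers
    ):
        raise ValueError("control and treated spectra are not on the same grid")
    diff = control.mean - treated.mean
    pooled = np.sqrt(control.sd**2 + treated.sd**2)
    # detection threshold uses the standard error of the difference of means,
    # not the pixel-level sd shading
    sem = np.sqrt(
        control.sd**2 / control.n_pixels + treated.sd**2 / treated.n_pixels
    )
    thr = peak_snr * float(sem.mean())
    if thr <= 0:
        thr = 1e-12 * max(float(np.max(np.abs(diff))), 1.0)
    w = control.wavenumbers
    peaks = detect_peaks(diff, w, prominence=thr, min_separation=min_separation, sign="+")
    peaks += detect_peaks(diff, w, prominence=thr, min_separation=min_separation, sign="-")
    peaks.sort(key=lambda p: p.center)
    return DifferenceSpectrum(
        component=control.component,
        wavenumbers=w,
        values=diff,
        pooled_sd=pooled,
        peaks=peaks,
    )


def pca_compare(
    mean_matrix: np.ndarray,
    row_labels: Sequence[tuple[str, str]],
    n_pcs: int = 3,
) -> PCAResult:
    """Column-centred PCA of component x condition mean spectra.

    Loadings are unit-norm right singular vectors with the sign convention
    that each loading's maximum-absolute element is positive; PC1 scores of
    control and treated observations are paired per component.
    """
    X = np.asarray(mean_matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need at least 2 observations")
    if len(row_labels) != X.shape[0]:
        raise ValueError("row_labels length must match the observation count")
    Xc = X - X.mean(axis=0, keepdims=True)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    total = float(np.sum(s**2))
    evr = (s**2 / total) if total > 0 else np.zeros_like(s)
    n_pcs = min(n_pcs, len(s))
    loadings = Vt[:n_pcs].copy()
    scores = (U * s)[:, :n_pcs].copy()
    for i in range(n_pcs):
        j = int(np.argmax(np.abs(loadings[i])))
        if loadings[i, j] < 0:
            loadings[i] = -loadings[i]
            scores[:, i] = -scores[:, i]
    pairs: dict[str, tuple[float, float]] = {}
    for comp in {c for c, _ in row_labels}:
        idx = {cond: i for i, (c, cond) in enumerate(row_labels) if c == comp}
        if "control" in idx and "treated" in idx:
            pairs[comp] = (
                float(scores[idx["control"], 0]),
                float(scores[idx["treated"], 0]),
            )
    return PCAResult(
        row_labels=list(row_labels),
        loadings=loadings,
        explained_variance_ratio=evr[:n_pcs],
        scores=scores,
        pc1_pairs=pairs,
    )


def response_magnitude(
    diff: DifferenceSpectrum, region: AnalysisRegion | None = None
) -> float:
    """Root-mean-square of the difference spectrum over the analysis regions."""
    region = region or AnalysisRegion()
    idx = region.channel_indices(diff.wavenumbers)
    return float(np.sqrt(np.mean(diff.values[idx] ** 2)))


def permutation_pvalue(
    control_means: np.ndarray,
    treated_means: np.ndarray,
    wavenumbers: np.ndarray,
    region: AnalysisRegion | None = None,
    n_permutations: int = 199,
    seed: int = 0,
) -> tuple[float, float]:
    """Label-permutation test of the response magnitude across cells.

    ``control_means`` and ``treated_means`` are (n_cells, n_channels)
    per-cell mean spectra.  Condition labels are reshuffled over the pooled
    cells ``n_permutations`` times; the p-value is the add-one-corrected
    fraction of permuted magnitudes at least as large as the observed one.

    Returns ``(observed_magnitude, p_value)``.
    """
    region = region or AnalysisRegion()
    C = np.atleast_2d(np.asarray(control_means, dtype=float))
    T = np.atleast_2d(np.asarray(treated_means, dtype=float))
    idx = region.channel_indices(np.asarray(wavenumbers))

    def rms(a: np.ndarray, b: np.ndarray) -> float:
        d = a.mean(axis=0) - b.mean(axis=0)
        return float(np.sqrt(np.mean(d[idx] ** 2)))

    observed = rms(C, T)
    pooled = np.vstack([C, T])
    n_c = C.shape[0]
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(pooled.shape[0])
        stat = rms(pooled[perm[:n_c]], pooled[perm[n_c:]])
        if stat >= observed - 1e-15:
            hits += 1
    p = (1 + hits) / (n_permutations + 1)
    return observed, float(p)


def build_report(
    diffs: Mapping[str, DifferenceSpectrum],
    droplet_count_control: int,
    droplet_count_treated: int,
    whole_cell_diff: DifferenceSpectrum,
    pca: PCAResult | None = None,
    region: AnalysisRegion | None = None,
    p_value: float | None = None,
    mutation_profile: str | None = None,
) -> ResponseReport:
    """Assemble per-component magnitudes, droplet ratio and the verdict."""
    missing = [c for c in CELL_COMPONENTS if c not in diffs]
    if missing:
        raise ValueError(f"missing difference spectra for component(s) {missing}")
    region = region or AnalysisRegion()
    mags = {c: response_magnitude(diffs[c], region) for c in CELL_COMPONENTS}
    if droplet_count_control > 0:
        ratio = droplet_count_treated / droplet_count_control
    else:
        ratio = float("nan")
    largest = max(mags, key=mags.get)
    return ResponseReport(
        component_magnitudes=mags,
        whole_cell_magnitude=response_magnitude(whole_cell_diff, region),
        droplet_ratio=float(ratio),
        largest_component=largest,
        p_value=p_value,
        mutation_profile=mutation_profile,
    )
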
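"""Spectral preprocessing chain for Raman hyperspectral cubes.

The chain runs in this order: background deletion (pixels with no C-H band
at 2850-3000 cm^-1), cosmic-spike removal (impulse filter), interpolation
onto a reference wavenumber scale, third-order polynomial baseline
correction, and vector normalisation.  Every stage records its parameters
in a processing log.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .core import HyperspectralCube, interval_indices

__all__ = [
    "PreprocessParams",
    "PreprocessedCube",
    "mask_background",
    "despike",
    "interpolate_to_reference",
    "baseline_correct",
    "vector_normalize",
    "preprocess_cube",
]

#: Default support of vector normalisation: the union of the two analysis
#: regions (fingerprint and C-H stretching).
DEFAULT_NORM_REGIONS: tuple[tuple[float, float], ...] = ((700.0, 1800.0), (2800.0, 3050.0))


@dataclass
class PreprocessParams:
    """Tunable parameters of the preprocessing chain."""

    ch_region: tuple[float, float] = (2850.0, 3000.0)
    threshold_policy: str = "otsu"          # "otsu" | "quantile"
    background_quantile: float = 0.5        # fallback / quantile policy
    despike_window: int = 7                 # channels, odd
    despike_z: float = 6.0                  # robust sigmas
    reference_grid: np.ndarray | None = None
    baseline_degree: int = 3
    baseline_max_iter: int = 50
    baseline_tol: float = 1e-6
    norm_regions: tuple[tuple[float, float], ...] = DEFAULT_NORM_REGIONS


@dataclass
class PreprocessedCube:
    """Foreground spectra on the reference grid, plus mask and log.

    ``spectra`` has shape (n_foreground, n_channels) and is aligned with
    ``np.argwhere(mask)`` in row-major order.  Every retained spectrum has
    unit Euclidean norm over the normalisation region.
    """

    spectra: np.ndarray
    wavenumbers: np.ndarray
    mask: np.ndarray
    pixel_size: float
    log: list[dict[str, Any]] = field(default_factory=list)
    metadata: dict[str, Any] = field(default_factory=dict)

    @property
    def pixel_indices(self) -> np.ndarray:
        """(n_foreground, 2) array of (row, col) indices."""
        return np.argwhere(self.mask)

    def label_image(self, values: np.ndarray, fill: int = 0) -> np.ndarray:
        """Scatter a per-foreground-pixel vector back into image shape."""
        img = np.full(self.mask.shape, fill, dtype=np.asarray(values).dtype)
        img[self.mask] = values
        return img


def _chord(values: np.ndarray, axis_x: np.ndarray) -> np.ndarray:
    """Linear chord between the first and last sample (broadcast over rows)."""
    t = (axis_x - axis_x[0]) / (axis_x[-1] - axis_x[0])
    first = values[..., :1]
    last = values[..., -1:]
    return first + (last - first) * t


def mask_background(
    cube: HyperspectralCube,
    ch_region: tuple[float, float] = (2850.0, 3000.0),
    threshold_policy: str = "otsu",
    quantile: float = 0.5,
) -> np.ndarray:
    """Boolean foreground mask: pixels *with* a C-H band are kept.

    The per-pixel statistic is the integral of the spectrum over
    ``ch_region`` after subtracting a linear baseline anchored on the
    median intensity of two flanking windows just outside the region
    (robust to smooth fluorescence baselines without clipping bands whose
    flanks touch the region edges).  The kept/deleted split uses an Otsu
    threshold on that statistic by default, or a fixed quantile.
    """
    wn = cube.wavenumbers
    idx = interval_indices(wn, *ch_region)
    if len(idx) < 3:
        raise ValueError(
            f"C-H region {ch_region} lies outside the grid span "
            f"[{wn[0]}, {wn[-1]}]"
        )
    w = wn[idx]
    seg = cube.intensities[:, :, idx]
    flank = 40.0
    lo_idx = interval_indices(wn, ch_region[0] - flank, ch_region[0] - 1e-9)
    hi_idx = interval_indices(wn, ch_region[1] + 1e-9, ch_region[1] + flank)
    if len(lo_idx) == 0 and len(hi_idx) == 0:
        net = seg - _chord(seg, w)
    else:
        if len(lo_idx) == 0:
            lo_idx = hi_idx
        if len(hi_idx) == 0:
            hi_idx = lo_idx
        base_lo = np.median(cube.intensities[:, :, lo_idx], axis=2)
        base_hi = np.median(cube.intensities[:, :, hi_idx], axis=2)
        x_lo = float(np.mean(wn[lo_idx]))
        x_hi = float(np.mean(wn[hi_idx]))
        if x_hi == x_lo:
            baseline = base_lo[..., None] * np.ones_like(w)
        else:
            t = (w - x_lo) / (x_hi - x_lo)
            baseline = base_lo[..., None] + (base_hi - base_lo)[..., None] * t
        net = seg - baseline
    integral = np.trapezoid(net, w, axis=2)
    flat = integral.ravel()
    if threshold_policy == "otsu":
        try:
            thr = float(threshold_otsu(flat))
        except ValueError:  # degenerate distribution
            thr = float(np.quantile(flat, quantile))
    elif threshold_policy == "quantile":
        thr = float(np.quantile(flat, quantile))
    else:
        raise ValueError(f"unknown threshold_policy {threshold_policy!r}")
    return integral > thr


def _despike_batch(
    spectra: np.ndarray, window: int, z_threshold: float, impulse_ratio: float
) -> np.ndarray:
    """Vectorised impulse filter over rows of ``spectra`` (2-D)."""
    med = ndimage.median_filter(spectra, size=(1, window), mode="reflect")
    r = spectra - med
    center = np.median(r, axis=1, keepdims=True)
    sigma = 1.4826 * np.median(np.abs(r - center), axis=1, keepdims=True)
    rp = np.pad(r, ((0, 0), (1, 1)), mode="constant", constant_values=-np.inf)
    neighbour = np.maximum(rp[:, :-2], rp[:, 2:])
    flag = (
        (r > z_threshold * sigma)
        & (r > impulse_ratio * np.maximum(neighbour, 0.0))
        & (r > 0)
    )
    out = spectra.copy()
    out[flag] = med[flag]
    return out


def despike(
    spectrum: np.ndarray,
    window: int = 7,
    z_threshold: float = 6.0,
    impulse_ratio: float = 3.0,
) -> np.ndarray:
    """Remove cosmic spikes: sharp impulses far above the running median.

    A channel is replaced by its local median when its residual against a
    running median of ``window`` channels exceeds ``z_threshold`` robust
    standard deviations *and* dominates both neighbouring residuals by
    ``impulse_ratio`` (genuine bands several channels wide fail the second
    condition and pass through untouched).
    """
    spectrum = np.asarray(spectrum, dtype=float)
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    squeeze = spectrum.ndim == 1
    spec2d = np.atleast_2d(spectrum)
    if window > spec2d.shape[1]:
        raise ValueError(
            f"window {window} larger than spectrum length {spec2d.shape[1]}"
        )
    out = _despike_batch(spec2d, window, z_threshold, impulse_ratio)
    return out[0] if squeeze else out


def interpolate_to_reference(
    spectrum: np.ndarray, source_grid: np.ndarray, reference_grid: np.ndarray
) -> np.ndarray:
    """Linear interpolation onto the reference wavenumber scale.

    Values at shared grid points are preserved exactly; extrapolation
    outside the source span is refused.
    """
    source_grid = np.asarray(source_grid, dtype=float)
    reference_grid = np.asarray(reference_grid, dtype=float)
    if reference_grid[0] < source_grid[0] - 1e-9 or reference_grid[-1] > source_grid[-1] + 1e-9:
        raise ValueError(
            f"reference grid span [{reference_grid[0]}, {reference_grid[-1]}] "
            f"extends outside source span [{source_grid[0]}, {source_grid[-1]}]"
        )
    spectrum = np.asarray(spectrum, dtype=float)
    if spectrum.ndim == 1:
        return np.interp(reference_grid, source_grid, spectrum)
    return np.vstack([np.interp(reference_grid, source_grid, row) for row in spectrum])


def baseline_correct(
    spectrum: np.ndarray,
    degree: int = 3,
    max_iter: int = 50,
    tol: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray]:
    """Iterative polynomial baseline estimation (fit -> clamp -> refit).

    A degree-``degree`` polynomial is least-squares fitted; samples above
    the fit are clamped down to it and the fit repeats until the baseline
    changes by less than ``tol`` (relative to the data scale) or
    ``max_iter`` iterations.  Clamping makes the fit track the lower
    envelope, so bands do not bias the baseline upward.

    Returns ``(corrected, baseline)``.
    """
    spectrum = np.asarray(spectrum, dtype=float)
    if not np.all(np.isfinite(spectrum)):
        raise ValueError("spectrum contains non-finite values")
    squeeze = spectrum.ndim == 1
    y = np.atleast_2d(spectrum).copy()
    n_ch = y.shape[1]
    if n_ch < degree + 1:
        raise ValueError(f"need at least {degree + 1} channels for degree {degree}")
    x = np.linspace(-1.0, 1.0, n_ch)
    V = np.vander(x, degree + 1, increasing=True)
    pinv = np.linalg.pinv(V)
    scale = np.maximum(np.ptp(y, axis=1, keepdims=True), np.max(np.abs(y), axis=1, keepdims=True))
    scale = np.where(scale > 0, scale, 1.0)
    work = y.copy()
    baseline = work @ pinv.T @ V.T
    for _ in range(max_iter):
        work = np.minimum(work, baseline)
        new = work @ pinv.T @ V.T
        delta = np.max(np.abs(new - baseline), axis=1, keepdims=True)
        baseline = new
        if np.all(delta < tol * scale):
            break
    corrected = np.atleast_2d(spectrum) - baseline
    if squeeze:
        return corrected[0], baseline[0]
    return corrected, baseline


def vector_normalize(
    spectrum: np.ndarray,
    wavenumbers: np.ndarray | None = None,
    regions: Sequence[tuple[float, float]] | None = None,
) -> np.ndarray:
    """Scale to unit Euclidean norm over ``regions`` (whole grid if None)."""
    spectrum = np.asarray(spectrum, dtype=float)
    squeeze = spectrum.ndim == 1
    spec2d = np.atleast_2d(spectrum)
    if regions is not None:
        if wavenumbers is None:
            raise ValueError("wavenumbers required when regions are given")
        idx = np.unique(
            np.concatenate([interval_indices(wavenumbers, lo, hi) for lo, hi in regions])
        )
        if len(idx) == 0:
            raise ValueError(f"normalisation regions {regions} select no channels")
        support = spec2d[:, idx]
    else:
        support = spec2d
    norms = np.linalg.norm(support, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError("zero-norm spectrum cannot be vector normalised")
    out = spec2d / norms
    return out[0] if squeeze else out


def preprocess_cube(
    cube: HyperspectralCube, params: PreprocessParams | None = None
) -> PreprocessedCube:
    """Run the full chain: mask -> despike -> interpolate -> baseline -> normalise."""
    p = params or PreprocessParams()
    log: list[dict[str, Any]] = []

    mask = mask_background(
        cube, p.ch_region, p.threshold_policy, p.background_quantile
    )
    log.append(
        {
            "step": "mask_background",
            "ch_region": list(p.ch_region),
            "threshold_policy": p.threshold_policy,
            "n_foreground": int(mask.sum()),
        }
    )
    if not mask.any():
        raise ValueError("background masking removed every pixel")
    pix = np.argwhere(mask)
    spectra = cube.intensities[mask]

    spectra = _despike_batch(spectra, p.despike_window, p.despike_z, 3.0)
    log.append(
        {"step": "despike", "window": p.despike_window, "z_threshold": p.despike_z}
    )

    ref = (
        np.asarray(p.reference_grid, dtype=float)
        if p.reference_grid is not None
        else cube.wavenumbers
    )
    spectra = interpolate_to_reference(spectra, cube.wavenumbers, ref)
    log.append(
        {
            "step": "interpolate_to_reference",
            "n_channels": int(len(ref)),
            "span": [float(ref[0]), float(ref[-1])],
        }
    )

    spectra, _ = baseline_correct(
        spectra, p.baseline_degree, p.baseline_max_iter, p.baseline_tol
    )
    log.append(
        {
            "step": "baseline_correct",
            "degree": p.baseline_degree,
            "max_iter": p.baseline_max_iter,
            "tol": p.baseline_tol,
        }
    )

    try:
        spectra = vector_normalize(spectra, ref, p.norm_regions)
    except ValueError as err:
        idx = np.unique(
            np.concatenate(
                [interval_indices(ref, lo, hi) for lo, hi in p.norm_regions]
            )
        )
        norms = np.linalg.norm(spectra[:, idx], axis=1)
        bad = pix[norms == 0]
        raise ValueError(
            f"vector normalisation failed at pixel(s) {bad.tolist()[:5]}: {err}"
        ) from err
    log.append({"step": "vector_normalize", "regions": [list(r) for r in p.norm_regions]})

    return PreprocessedCube(
        spectra=spectra,
        wavenumbers=ref,
        mask=mask,
        pixel_size=cube.pixel_size,
        log=log,
        metadata=dict(cube.metadata),
    )
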
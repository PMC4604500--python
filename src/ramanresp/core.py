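"""Core in-memory containers shared by every pipeline stage.

A confocal Raman map is carried as a :class:`HyperspectralCube`: a
``(rows, cols, channels)`` intensity array plus a strictly increasing
wavenumber axis in cm^-1 and the pixel pitch in micrometres.  Per-component
summaries (mean spectrum, channel-wise standard deviation, pixel count) are
carried as :class:`ComponentSpectrum`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np

#: Canonical integer labels for the subcellular components a cell map is
#: segmented into.  0 is reserved for background/deleted pixels.
COMPONENT_LABELS: dict[str, int] = {
    "background": 0,
    "membrane": 1,
    "cytoplasm": 2,
    "nucleus": 3,
    "lipid_droplet": 4,
}

LABEL_NAMES: dict[int, str] = {v: k for k, v in COMPONENT_LABELS.items()}

#: The four foreground components, in label order.
CELL_COMPONENTS: tuple[str, ...] = ("membrane", "cytoplasm", "nucleus", "lipid_droplet")


@dataclass
class HyperspectralCube:
    """A hyperspectral Raman image: one full spectrum per pixel.

    Parameters
    ----------
    intensities
        Array of shape ``(rows, cols, n_channels)``, arbitrary units.
    wavenumbers
        Strictly increasing Raman-shift axis (cm^-1), length ``n_channels``.
    pixel_size
        Pixel pitch in micrometres.
    metadata
        Free-form provenance map (condition, seed, ...).
    """

    intensities: np.ndarray
    wavenumbers: np.ndarray
    pixel_size: float
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        if self.intensities.ndim != 3:
            raise ValueError(
                f"intensities must be (rows, cols, channels), got shape "
                f"{self.intensities.shape}"
            )
        if self.wavenumbers.ndim != 1 or len(self.wavenumbers) != self.intensities.shape[2]:
            raise ValueError(
                f"wavenumber axis length {self.wavenumbers.shape} does not match "
                f"channel count {self.intensities.shape[2]}"
            )
        if len(self.wavenumbers) > 1 and not np.all(np.diff(self.wavenumbers) > 0):
            raise ValueError("wavenumbers must be strictly increasing")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape

    @property
    def n_pixels(self) -> int:
        return self.intensities.shape[0] * self.intensities.shape[1]


@dataclass
class ComponentSpectrum:
    """Mean spectrum of one component (or the whole cell) of one condition."""

    component: str
    wavenumbers: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    n_pixels: int

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        if not (len(self.wavenumbers) == len(self.mean) == len(self.sd)):
            raise ValueError("wavenumbers, mean and sd must share one grid")
        if self.n_pixels < 1:
            raise ValueError("n_pixels must be >= 1")
        if np.any(self.sd < -1e-12):
            raise ValueError("channel-wise sd must be non-negative")

    def scaled(self, factor: float) -> "ComponentSpectrum":
        """Return a copy with mean and sd divided by ``factor``."""
        return replace(self, mean=self.mean / factor, sd=self.sd / factor)


def channel_index(wavenumbers: np.ndarray, center: float) -> int:
    """Index of the grid channel nearest to ``center`` (cm^-1)."""
    return int(np.argmin(np.abs(np.asarray(wavenumbers) - center)))


def interval_indices(wavenumbers: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Indices of channels inside the closed interval [lo, hi]."""
    w = np.asarray(wavenumbers)
    return np.nonzero((w >= lo) & (w <= hi))[0]
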
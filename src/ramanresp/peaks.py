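"""Band-presence tests and peak detection on spectra.

All prominence measures are taken above a local linear chord, which makes
them robust to residual baseline that survives polynomial correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .core import interval_indices

__all__ = ["DetectedPeak", "chord_prominence", "band_present", "detect_peaks"]


@dataclass(frozen=True)
class DetectedPeak:
    center: float          # cm^-1, on a grid channel
    sign: str              # "+" or "-"
    prominence: float


def chord_prominence(
    values: np.ndarray,
    wavenumbers: np.ndarray,
    center: float,
    window: float = 8.0,
) -> float:
    """Peak height above the linear chord across [center-window, center+window].

    Returns the maximum of (value - chord) inside the window; negative when
    the region dips below its own chord.
    """
    idx = interval_indices(wavenumbers, center - window, center + window)
    if len(idx) < 3:
        raise ValueError(
            f"window +-{window} around {center} cm^-1 covers fewer than 3 channels"
        )
    w = wavenumbers[idx]
    v = np.asarray(values, dtype=float)[idx]
    t = (w - w[0]) / (w[-1] - w[0])
    chord = v[0] + (v[-1] - v[0]) * t
    return float(np.max(v - chord))


def band_present(
    mean: np.ndarray,
    sd: np.ndarray,
    wavenumbers: np.ndarray,
    center: float,
    window: float = 8.0,
    snr: float = 2.0,
    floor_frac: float = 0.02,
) -> bool:
    """Marker-band test: local chord prominence above a noise threshold.

    The threshold is ``snr`` times the median channel-wise sd inside the
    window, floored at ``floor_frac`` of the spectrum's dynamic range so the
    test stays meaningful on (near-)noiseless data where sd collapses to 0.
    """
    prom = chord_prominence(mean, wavenumbers, center, window)
    idx = interval_indices(wavenumbers, center - window, center + window)
    med_sd = float(np.median(np.asarray(sd, dtype=float)[idx]))
    floor = floor_frac * float(np.ptp(mean))
    return prom > max(snr * med_sd, floor)


def detect_peaks(
    values: np.ndarray,
    wavenumbers: np.ndarray,
    region: tuple[float, float] | None = None,
    prominence: float | None = None,
    rel_prominence: float = 0.2,
    min_separation: float = 8.0,
    sign: str = "+",
) -> list[DetectedPeak]:
    """Local extrema with a minimum prominence, reported on grid channels.

    ``prominence`` is absolute; when None it defaults to ``rel_prominence``
    times the dynamic range of ``values`` inside ``region``.  ``sign='-'``
    detects minima.
    """
    values = np.asarray(values, dtype=float)
    wavenumbers = np.asarray(wavenumbers, dtype=float)
    if region is not None:
        idx = interval_indices(wavenumbers, *region)
        if len(idx) == 0:
            raise ValueError(f"region {region} selects no channels")
    else:
        idx = np.arange(len(values))
    v = values[idx]
    w = wavenumbers[idx]
    if prominence is None:
        rng = float(np.ptp(v))
        prominence = rel_prominence * rng if rng > 0 else np.inf
    step = float(np.median(np.diff(w))) if len(w) > 1 else 1.0
    distance = max(1, int(round(min_separation / step)))
    y = v if sign == "+" else -v
    locs, props = find_peaks(y, prominence=prominence, distance=distance)
    return [
        DetectedPeak(center=float(w[i]), sign=sign, prominence=float(p))
        for i, p in zip(locs, props["prominences"])
    ]
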
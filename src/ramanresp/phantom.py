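"""Synthetic confocal Raman phantoms of single cells.

The generator emulates the statistical structure of a confocal Raman map of
a fixed cell on a substrate: a 45 x 45 um^2 field sampled at 500 nm pixel
pitch (90 x 90 pixels by default), each pixel carrying a full spectrum on a
600-3100 cm^-1 grid.  A virtual cell is an ellipse with a plasma-membrane
ring, an interior cytoplasm, an elliptical nucleus and a configurable number
of disjoint lipid droplets.  Each component has a reference spectrum built
from Gaussian/Lorentzian bands at the field's standard marker positions
(DNA 790, phenylalanine 1008, ester C=O 1750, =C-H 3018 cm^-1, ...).

Measurement artefacts are layered on top: a random per-pixel polynomial
baseline (fluorescence/substrate), additive Gaussian noise, and
Poisson-count cosmic spikes (sharp single-channel impulses).

Drug treatment is modelled as (i) a reduction of the lipid-droplet count
(``droplet_retention``), (ii) an attenuation of droplet band amplitudes
(treated droplets smaller than the sampling voxel), and (iii) a gain on
designated protein bands of membrane/cytoplasm/nucleus.  A mutation profile
scales all three effects: ``wildtype`` = full response, ``braf_like`` =
small, ``kras_like`` = none, mirroring the large/small/no spectral response
of EGFR-inhibitor treatment in wild-type vs BRAF- vs KRAS-mutant cells.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import ndimage

from .core import COMPONENT_LABELS, HyperspectralCube

__all__ = [
    "SpectralBand",
    "ComponentModel",
    "TreatmentEffect",
    "PhantomConfig",
    "GroundTruth",
    "EFFECT_SCALE",
    "build_component_spectrum",
    "render_layout",
    "generate_phantom",
    "generate_paired_dataset",
]

#: How strongly each mutation profile expresses the treatment effect.
#: Free parameters of the generator mirroring the qualitative
#: large / small / none response ordering; not biological claims.
EFFECT_SCALE: dict[str, float] = {"wildtype": 1.0, "braf_like": 0.3, "kras_like": 0.0}

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class SpectralBand:
    """One vibrational band: centre (cm^-1), FWHM (cm^-1), peak amplitude."""

    center: float
    fwhm: float
    amplitude: float
    shape: Literal["gaussian", "lorentzian"] = "gaussian"

    def __post_init__(self) -> None:
        if self.fwhm <= 0:
            raise ValueError(f"band at {self.center} cm^-1: fwhm must be > 0")
        if self.amplitude < 0:
            raise ValueError(f"band at {self.center} cm^-1: amplitude must be >= 0")
        if self.shape not in ("gaussian", "lorentzian"):
            raise ValueError(f"unknown lineshape {self.shape!r}")

    def evaluate(self, grid: np.ndarray) -> np.ndarray:
        """Lineshape on ``grid``; peak value equals ``amplitude`` at ``center``."""
        grid = np.asarray(grid, dtype=float)
        if self.shape == "gaussian":
            sigma = self.fwhm * FWHM_TO_SIGMA
            return self.amplitude * np.exp(-0.5 * ((grid - self.center) / sigma) ** 2)
        half = self.fwhm / 2.0
        return self.amplitude * half**2 / ((grid - self.center) ** 2 + half**2)


@dataclass
class ComponentModel:
    """Band model of one subcellular component (or the background)."""

    name: str
    bands: list[SpectralBand] = field(default_factory=list)
    baseline_offset: float = 0.0

    def __post_init__(self) -> None:
        if self.baseline_offset < 0:
            raise ValueError("baseline_offset must be >= 0")


def build_component_spectrum(model: ComponentModel, grid: Sequence[float]) -> np.ndarray:
    """Reference spectrum of ``model`` on ``grid``: offset + sum of lineshapes.

    Raises
    ------
    ValueError
        If any band centre lies outside the grid span (names the band).
    """
    grid = np.asarray(grid, dtype=float)
    lo, hi = grid[0], grid[-1]
    out = np.full(grid.shape, float(model.baseline_offset))
    for band in model.bands:
        if not (lo <= band.center <= hi):
            raise ValueError(
                f"component {model.name!r}: band centre {band.center} cm^-1 "
                f"outside grid span [{lo}, {hi}]"
            )
        out += band.evaluate(grid)
    return out


@dataclass
class TreatmentEffect:
    """Spectral consequences of drug treatment, before profile scaling.

    droplet_retention
        Fraction of the control droplet count kept under treatment.
    protein_band_gain
        Multiplicative factor (>= 1) on designated protein bands of
        membrane / cytoplasm / nucleus in treated cells.
    droplet_band_attenuation
        Factor (<= 1) on lipid-droplet band amplitudes in treated cells;
        models treated droplets smaller than the confocal voxel, which is
        what makes the droplet difference spectrum positive.
    affected_bands
        Component name -> band centres the gain applies to.
    """

    droplet_retention: float = 0.5
    protein_band_gain: float = 1.12
    droplet_band_attenuation: float = 0.7
    affected_bands: dict[str, tuple[float, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.droplet_retention <= 1.0:
            raise ValueError("droplet_retention must be in [0, 1]")
        if self.protein_band_gain < 1.0:
            raise ValueError("protein_band_gain must be >= 1")
        if not 0.0 <= self.droplet_band_attenuation <= 1.0:
            raise ValueError("droplet_band_attenuation must be in [0, 1]")
        if not self.affected_bands:
            from .bands import DEFAULT_AFFECTED_BANDS

            self.affected_bands = dict(DEFAULT_AFFECTED_BANDS)


def _default_models() -> dict[str, ComponentModel]:
    from .bands import default_component_models

    return default_component_models()


@dataclass
class PhantomConfig:
    """Complete generative description of one control/treated phantom pair."""

    field_of_view: float = 45.0            # um per side
    pixel_size: float = 0.5                # um
    wavenumber_grid: tuple[float, float, float] = (600.0, 3100.0, 2.0)
    cell_semiaxes: tuple[float, float] = (16.0, 12.0)      # um
    membrane_thickness: float = 1.0                        # um
    nucleus_semiaxes: tuple[float, float] = (6.0, 4.5)     # um
    nucleus_offset: tuple[float, float] = (0.0, 0.0)       # um from cell centre
    droplet_count_range: tuple[int, int] = (6, 10)         # inclusive
    droplet_radius_range: tuple[float, float] = (0.75, 1.5)  # um
    geometry_jitter: float = 0.08          # relative jitter of axes/centre per cell
    noise_sd: float = 0.02                 # relative to max band amplitude
    baseline_coeff_ranges: tuple[tuple[float, float], ...] = (
        (0.10, 0.25),
        (-0.02, 0.05),
        (-0.02, 0.05),
        (-0.02, 0.05),
    )
    spike_rate: float = 0.1                # expected cosmic spikes per spectrum
    spike_amplitude_range: tuple[float, float] = (3.0, 10.0)  # x max band amplitude
    spike_width: int = 1                   # channels per spike
    effect: TreatmentEffect = field(default_factory=TreatmentEffect)
    mutation_profile: str = "wildtype"
    droplet_includes_cytoplasm: bool = True
    smoothing_sigma: float = 0.0           # optional isotropic spatial blur (px)
    components: dict[str, ComponentModel] = field(default_factory=_default_models)
    seed: int = 0

    def __post_init__(self) -> None:
        n = self.field_of_view / self.pixel_size
        if abs(n - round(n)) > 1e-9:
            raise ValueError(
                f"field_of_view / pixel_size = {n} is not an integer grid side"
            )
        start, stop, step = self.wavenumber_grid
        if step <= 0 or stop <= start:
            raise ValueError("wavenumber_grid must be (start, stop, step) with step > 0")
        if start > 700.0 or stop < 3050.0:
            raise ValueError("wavenumber grid must cover at least 700-3050 cm^-1")
        if self.mutation_profile not in EFFECT_SCALE:
            raise ValueError(
                f"mutation_profile must be one of {sorted(EFFECT_SCALE)}"
            )
        if self.noise_sd < 0 or self.spike_rate < 0:
            raise ValueError("noise_sd and spike_rate must be non-negative")
        if self.droplet_count_range[0] < 0 or self.droplet_count_range[1] < self.droplet_count_range[0]:
            raise ValueError("droplet_count_range must be 0 <= lo <= hi")
        if self.spike_width < 1:
            raise ValueError("spike_width must be >= 1")

    @property
    def grid_side(self) -> int:
        return int(round(self.field_of_view / self.pixel_size))

    @property
    def wavenumbers(self) -> np.ndarray:
        start, stop, step = self.wavenumber_grid
        n = int(round((stop - start) / step)) + 1
        return start + step * np.arange(n)

    @property
    def max_band_amplitude(self) -> float:
        return max(
            (b.amplitude for m in self.components.values() for b in m.bands),
            default=1.0,
        )

    def effect_scale(self) -> float:
        return EFFECT_SCALE[self.mutation_profile]


@dataclass
class GroundTruth:
    """Ground-truth layout of one generated phantom."""

    label_map: np.ndarray                  # (rows, cols) int, COMPONENT_LABELS ids
    droplet_count: int
    droplets: list[tuple[float, float, float]]   # (row_um, col_um, radius_um)
    reference_spectra: dict[str, np.ndarray] = field(default_factory=dict)
    legend: dict[int, str] = field(default_factory=dict)


def _ellipse_mask(
    rows_um: np.ndarray,
    cols_um: np.ndarray,
    center: tuple[float, float],
    semiaxes: tuple[float, float],
    theta: float,
) -> np.ndarray:
    dr = rows_um - center[0]
    dc = cols_um - center[1]
    u = dc * np.cos(theta) + dr * np.sin(theta)
    v = -dc * np.sin(theta) + dr * np.cos(theta)
    a, b = semiaxes
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _draw_geometry(config: PhantomConfig, rng: np.random.Generator) -> dict:
    """Per-cell geometry: jittered centre, semiaxes and orientation."""
    j = config.geometry_jitter
    half = config.field_of_view / 2.0
    a, b = config.cell_semiaxes
    geom = {
        "center": (
            half + rng.uniform(-j, j) * half * 0.5,
            half + rng.uniform(-j, j) * half * 0.5,
        ),
        "cell_semiaxes": (
            a * (1.0 + rng.uniform(-j, j)),
            b * (1.0 + rng.uniform(-j, j)),
        ),
        "theta": rng.uniform(0.0, np.pi),
        "nucleus_semiaxes": config.nucleus_semiaxes,
        "nucleus_offset": config.nucleus_offset,
    }
    return geom


def render_layout(
    config: PhantomConfig,
    *,
    rng: np.random.Generator | None = None,
    geometry: dict | None = None,
    droplet_plan: list[tuple[float, float, float]] | None = None,
    droplet_count: int | None = None,
) -> GroundTruth:
    """Rasterise one virtual cell into a per-pixel label map.

    Deterministic given the RNG state (by default seeded from
    ``config.seed``).  ``droplet_plan`` stamps a fixed droplet list instead
    of sampling (used for treated layouts that keep a subset of the control
    droplets); ``droplet_count`` overrides the sampled count.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    n = config.grid_side
    px = config.pixel_size
    coords = (np.arange(n) + 0.5) * px
    rows_um = coords[:, None] * np.ones((1, n))
    cols_um = np.ones((n, 1)) * coords[None, :]

    geom = geometry if geometry is not None else _draw_geometry(config, rng)
    center = geom["center"]
    a, b = geom["cell_semiaxes"]
    theta = geom["theta"]
    t = config.membrane_thickness
    na, nb = geom["nucleus_semiaxes"]
    n_off = geom["nucleus_offset"]
    nuc_center = (center[0] + n_off[0], center[1] + n_off[1])

    if na + abs(n_off[0]) >= min(a, b) - t or nb + abs(n_off[1]) >= min(a, b) - t:
        raise ValueError(
            f"nucleus (semiaxes {na} x {nb} um) does not fit inside the "
            f"cytoplasm of a cell with semiaxes {a:.2f} x {b:.2f} um and "
            f"membrane thickness {t} um"
        )
    half = config.field_of_view / 2.0
    if max(a, b) + max(abs(center[0] - half), abs(center[1] - half)) > half:
        raise ValueError("cell ellipse does not fit inside the field of view")

    cell = _ellipse_mask(rows_um, cols_um, center, (a, b), theta)
    inner = _ellipse_mask(rows_um, cols_um, center, (a - t, b - t), theta)
    nucleus = _ellipse_mask(rows_um, cols_um, nuc_center, (na, nb), theta)

    labels = np.zeros((n, n), dtype=np.int16)
    labels[cell] = COMPONENT_LABELS["cytoplasm"]
    labels[cell & ~inner] = COMPONENT_LABELS["membrane"]
    labels[nucleus & inner] = COMPONENT_LABELS["nucleus"]

    droplets: list[tuple[float, float, float]] = []
    if droplet_plan is not None:
        droplets = list(droplet_plan)
    else:
        lo, hi = config.droplet_count_range
        k = int(droplet_count) if droplet_count is not None else int(rng.integers(lo, hi + 1))
        r_lo, r_hi = config.droplet_radius_range
        margin = px  # keep a one-pixel clearance
        for _ in range(k):
            placed = False
            for _try in range(500):
                r = rng.uniform(r_lo, r_hi)
                # sample inside the inner ellipse's bounding box
                rr = center[0] + rng.uniform(-(a - t), (a - t))
                cc = center[1] + rng.uniform(-(a - t), (a - t))
                # disk fully inside cytoplasm: inside the inner ellipse shrunk
                # by r, outside the nucleus grown by r
                u = (cc - center[1]) * np.cos(theta) + (rr - center[0]) * np.sin(theta)
                v = -(cc - center[1]) * np.sin(theta) + (rr - center[0]) * np.cos(theta)
                if (u / (a - t - r - margin)) ** 2 + (v / (b - t - r - margin)) ** 2 > 1.0:
                    continue
                un = (cc - nuc_center[1]) * np.cos(theta) + (rr - nuc_center[0]) * np.sin(theta)
                vn = -(cc - nuc_center[1]) * np.sin(theta) + (rr - nuc_center[0]) * np.cos(theta)
                if (un / (na + r + margin)) ** 2 + (vn / (nb + r + margin)) ** 2 <= 1.0:
                    continue
                if any(
                    np.hypot(rr - d[0], cc - d[1]) < r + d[2] + margin for d in droplets
                ):
                    continue
                droplets.append((rr, cc, r))
                placed = True
                break
            if not placed:
                raise ValueError(
                    f"could not place droplet {len(droplets) + 1} of {k} after "
                    "bounded retries; reduce count or radius"
                )

    for rr, cc, r in droplets:
        disk = (rows_um - rr) ** 2 + (cols_um - cc) ** 2 <= r**2
        labels[disk] = COMPONENT_LABELS["lipid_droplet"]

    droplet_mask = labels == COMPONENT_LABELS["lipid_droplet"]
    n_cc = int(ndimage.label(droplet_mask, structure=np.ones((3, 3)))[1])

    legend = {v: k for k, v in COMPONENT_LABELS.items() if v in np.unique(labels)}
    return GroundTruth(
        label_map=labels, droplet_count=n_cc, droplets=droplets, legend=legend
    )


def treated_component_models(config: PhantomConfig) -> dict[str, ComponentModel]:
    """Component models with the profile-scaled treatment effect applied."""
    scale = config.effect_scale()
    eff = config.effect
    gain = 1.0 + scale * (eff.protein_band_gain - 1.0)
    atten = 1.0 - scale * (1.0 - eff.droplet_band_attenuation)
    out: dict[str, ComponentModel] = {}
    for name, model in config.components.items():
        bands = []
        affected = set(eff.affected_bands.get(name, ()))
        for band in model.bands:
            amp = band.amplitude
            if name == "lipid_droplet":
                amp *= atten
            elif band.center in affected:
                amp *= gain
            bands.append(dataclasses.replace(band, amplitude=amp))
        out[name] = ComponentModel(name=name, bands=bands, baseline_offset=model.baseline_offset)
    return out


def effective_droplet_retention(config: PhantomConfig) -> float:
    scale = config.effect_scale()
    return 1.0 - scale * (1.0 - config.effect.droplet_retention)


def _pixel_reference_spectra(
    config: PhantomConfig, models: dict[str, ComponentModel]
) -> dict[str, np.ndarray]:
    """Per-label pixel spectra; droplet pixels may mix in the cytoplasm."""
    grid = config.wavenumbers
    refs = {name: build_component_spectrum(m, grid) for name, m in models.items()}
    if config.droplet_includes_cytoplasm:
        refs["lipid_droplet"] = refs["lipid_droplet"] + refs["cytoplasm"]
    return refs


def _layout_pair(config: PhantomConfig) -> tuple[GroundTruth, GroundTruth]:
    """Control and treated layouts sharing one geometry/droplet draw."""
    ss = np.random.SeedSequence([config.seed, 1])
    rng = np.random.default_rng(ss)
    geom = _draw_geometry(config, rng)
    control = render_layout(config, rng=rng, geometry=geom)
    retention = effective_droplet_retention(config)
    m = int(np.round(control.droplet_count * retention))
    treated = render_layout(
        config, rng=rng, geometry=geom, droplet_plan=control.droplets[:m]
    )
    return control, treated


def _assemble_cube(
    config: PhantomConfig,
    truth: GroundTruth,
    refs: dict[str, np.ndarray],
    rng: np.random.Generator,
    condition: str,
) -> HyperspectralCube:
    grid = config.wavenumbers
    n = config.grid_side
    n_ch = len(grid)
    ref_stack = np.stack([refs[name] for name in COMPONENT_LABELS], axis=0)
    cube = ref_stack[truth.label_map.ravel()].reshape(n, n, n_ch).copy()

    if config.smoothing_sigma > 0:
        cube = ndimage.gaussian_filter(
            cube, sigma=(config.smoothing_sigma, config.smoothing_sigma, 0)
        )

    amp = config.max_band_amplitude
    # per-pixel random polynomial baseline on a normalised axis in [0, 1]
    tnorm = (grid - grid[0]) / (grid[-1] - grid[0])
    powers = np.stack([tnorm**p for p in range(len(config.baseline_coeff_ranges))])
    ranges = np.asarray(config.baseline_coeff_ranges, dtype=float)
    if np.any(ranges[:, 1] - ranges[:, 0] < 0):
        raise ValueError("baseline coefficient ranges must have lo <= hi")
    if np.any(ranges != 0.0):
        coeffs = rng.uniform(
            ranges[:, 0], ranges[:, 1], size=(n * n, len(ranges))
        )
        cube += (coeffs @ powers).reshape(n, n, n_ch) * amp

    if config.noise_sd > 0:
        cube += rng.normal(0.0, config.noise_sd * amp, size=cube.shape)

    if config.spike_rate > 0:
        counts = rng.poisson(config.spike_rate, size=n * n)
        flat = cube.reshape(n * n, n_ch)
        lo_a, hi_a = config.spike_amplitude_range
        for pix in np.nonzero(counts)[0]:
            for _ in range(counts[pix]):
                ch = int(rng.integers(0, n_ch))
                a = rng.uniform(lo_a, hi_a) * amp
                for w in range(config.spike_width):
                    if ch + w < n_ch:
                        flat[pix, ch + w] += a / (w + 1)

    return HyperspectralCube(
        intensities=cube,
        wavenumbers=grid,
        pixel_size=config.pixel_size,
        metadata={
            "condition": condition,
            "seed": config.seed,
            "mutation_profile": config.mutation_profile,
            "provenance": "ramanresp.phantom",
        },
    )


def generate_phantom(
    config: PhantomConfig, condition: str = "control"
) -> tuple[HyperspectralCube, GroundTruth]:
    """Generate one phantom cube plus its ground truth.

    Control and treated cubes from the same config share the cell layout;
    the treated one keeps ``round(count * retention)`` of the control
    droplets and applies the profile-scaled spectral treatment effect.
    """
    if condition not in ("control", "treated"):
        raise ValueError("condition must be 'control' or 'treated'")
    control_truth, treated_truth = _layout_pair(config)
    truth = control_truth if condition == "control" else treated_truth
    models = (
        config.components if condition == "control" else treated_component_models(config)
    )
    refs = _pixel_reference_spectra(config, models)
    truth.reference_spectra = refs
    stream = 2 if condition == "control" else 3
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, stream]))
    cube = _assemble_cube(config, truth, refs, rng, condition)
    return cube, truth


def generate_paired_dataset(
    config: PhantomConfig, n_cells: int
) -> list[tuple[HyperspectralCube, HyperspectralCube, GroundTruth, GroundTruth]]:
    """``n_cells`` independent (control, treated) phantom pairs.

    Per-cell seeds derive deterministically from ``config.seed``; layouts
    differ between cells while band tables and effect parameters are shared.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    seed_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 99]))
    cell_seeds = seed_rng.integers(0, 2**31 - 1, size=n_cells)
    out = []
    for s in cell_seeds:
        cell_cfg = dataclasses.replace(config, seed=int(s))
        c_cube, c_truth = generate_phantom(cell_cfg, "control")
        t_cube, t_truth = generate_phantom(cell_cfg, "treated")
        out.append((c_cube, t_cube, c_truth, t_truth))
    return out
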
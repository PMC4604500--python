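"""Default Raman band tables for the virtual-cell phantom.

Band positions follow the standard single-cell assignments: 790 cm^-1 DNA
phosphodiester backbone (nucleus marker), 1008 cm^-1 phenylalanine
ring-breathing (protein marker, the normalisation band), amide III
(~1231-1259), CH2 twisting (~1321), CH deformation (~1446-1483), C=C
(~1592), amide I (~1642-1688), ester C=O of fatty acids (1750, lipid-droplet
marker), CH stretching (2850-2950) and =C-H of unsaturated fatty acids
(3018, lipid-droplet marker).  Amplitudes and widths are free parameters of
the generator chosen to give realistic relative intensities; range
assignments enter as their midpoints.
"""

from __future__ import annotations

from .phantom import ComponentModel, SpectralBand

__all__ = ["default_component_models", "DEFAULT_AFFECTED_BANDS"]


def _g(center: float, fwhm: float, amplitude: float) -> SpectralBand:
    return SpectralBand(center=center, fwhm=fwhm, amplitude=amplitude, shape="gaussian")


def default_component_models() -> dict[str, ComponentModel]:
    """Fresh copies of the default per-component band models."""
    membrane = ComponentModel(
        name="membrane",
        baseline_offset=0.05,
        bands=[
            _g(1008, 10, 0.50),   # protein; membrane voxels carry cytoplasm/buffer bleed
            _g(1245, 20, 0.45),   # amide III + PO2- phospholipid, midpoint of 1231-1259
            _g(1321, 14, 0.40),   # CH2 twisting
            _g(1470, 18, 0.50),   # CH deformation, midpoint of 1458-1483
            _g(1666, 24, 0.70),   # amide I, midpoint of 1642-1688
            _g(2851, 24, 0.90),   # CH stretching (lipid-rich)
            _g(2891, 26, 0.85),   # CH stretching
        ],
    )
    cytoplasm = ComponentModel(
        name="cytoplasm",
        baseline_offset=0.05,
        bands=[
            _g(1008, 10, 0.60),   # phenylalanine ring breathing
            _g(1134, 14, 0.35),   # C-C / C-N stretching
            _g(1334, 16, 0.45),   # amide III / CH2
            _g(1455, 18, 0.50),   # CH deformation
            _g(1592, 14, 0.30),   # C=C bending
            _g(1661, 24, 0.75),   # amide I
            _g(2935, 30, 1.00),   # CH stretching (protein-rich)
        ],
    )
    nucleus = ComponentModel(
        name="nucleus",
        baseline_offset=0.05,
        bands=[
            _g(790, 12, 0.50),    # DNA O-P-O phosphodiester stretching
            _g(1008, 10, 0.50),   # phenylalanine
            _g(1334, 16, 0.55),   # nucleic acid / amide III
            _g(1658, 24, 0.70),   # amide I
            _g(2891, 30, 0.95),   # CH stretching
        ],
    )
    lipid_droplet = ComponentModel(
        name="lipid_droplet",
        baseline_offset=0.0,      # droplet pixels add on top of cytoplasm
        bands=[
            _g(1272, 14, 0.35),   # CH3 twisting
            _g(1308, 14, 0.40),   # CH2 twisting
            _g(1446, 16, 0.60),   # CH deformation
            _g(1660, 18, 0.45),   # C=C of unsaturated fatty acids
            _g(1750, 14, 0.55),   # ester C=O of fatty acids
            _g(2851, 22, 1.00),   # CH stretching
            _g(2935, 26, 0.80),   # CH stretching
            _g(3018, 18, 0.50),   # =C-H of unsaturated fatty acids
        ],
    )
    background = ComponentModel(
        name="background",
        baseline_offset=0.02,
        bands=[
            # weak broad buffer/substrate bumps; nothing inside 2850-3000 so
            # C-H based background deletion stays meaningful
            _g(980, 120, 0.06),
            _g(1630, 90, 0.08),
        ],
    )
    return {
        "membrane": membrane,
        "cytoplasm": cytoplasm,
        "nucleus": nucleus,
        "lipid_droplet": lipid_droplet,
        "background": background,
    }


#: Bands whose amplitude increases in treated cells (protein expression rises
#: under drug-induced apoptosis).  1008 is deliberately excluded: it is the
#: normalisation reference, so a gain applied to it would cancel out of every
#: phenylalanine-normalised difference spectrum.
DEFAULT_AFFECTED_BANDS: dict[str, tuple[float, ...]] = {
    "membrane": (1245, 1321, 1470, 1666),
    "cytoplasm": (1134, 1334, 1455, 1592, 1661, 2935),
    "nucleus": (1334, 1658, 2891),
}
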
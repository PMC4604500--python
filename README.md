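# ramanresp

Raman hyperspectral single-cell imaging analysis: hierarchical-cluster
segmentation of confocal Raman maps into subcellular components and
difference-spectroscopy readout of drug response — together with a synthetic
phantom generator so the whole pipeline can be exercised, tested and
benchmarked without instrument data.

## The problem

Confocal Raman microscopy records a full vibrational spectrum at every pixel
of a cell image (here: a 45 × 45 µm² field at 500 nm pixel pitch, i.e.
90 × 90 spectra spanning ~600–3100 cm⁻¹). Because the spectrum reflects the
local chemical composition, clustering the pixel spectra segments the cell
into subcellular components, and subtracting mean spectra of treated cells
from controls reveals drug-induced biochemical change — label-free. The
motivating application is EGFR-inhibitor (erlotinib) response in colon-cancer
cells: cells with wild-type *KRAS*/*BRAF* show a large spectral response,
*BRAF*-mutant cells a small one, and *KRAS*-mutant cells essentially none,
with the largest change located in lipid droplets.

## The method

For each hyperspectral cube the pipeline runs, in order:

1. **Background deletion** — pixels without a C–H stretching band at
   2850–3000 cm⁻¹ are background; the per-pixel baseline-robust C–H integral
   is thresholded (Otsu by default).
2. **Despiking** — cosmic-ray impulses are detected against a running median
   (window 7 channels, 6 robust σ, with an impulse-dominance condition so
   genuine bands pass untouched) and replaced by the local median.
3. **Interpolation** to a common reference wavenumber scale (linear).
4. **Baseline correction** with a third-order polynomial, fitted iteratively
   with clamping so bands do not bias the fit.
5. **Vector normalisation** to unit Euclidean norm over the analysis regions.
6. **HCA** — Ward's minimum-variance agglomeration applied to the Pearson
   correlation distance *d* = 1 − *r* between pixel spectra restricted to
   700–1800 ∪ 2800–3050 cm⁻¹; the dendrogram is cut into *k* = 8 raw
   clusters.
7. **Marker-band merging** into four components: DNA O–P–O at **790 cm⁻¹**
   → nucleus; phenylalanine ring breathing at **1008 cm⁻¹** → cytoplasm;
   ester C=O at **1750 cm⁻¹** plus =C–H at **3018 cm⁻¹** → lipid droplets;
   boundary-adjacent amide-I clusters → plasma membrane.
8. **Response readout** — component mean spectra are normalised to the
   1008 cm⁻¹ phenylalanine band; difference spectra (control − treated) are
   computed per component and for the whole cell, signed peaks are detected,
   lipid droplets are counted (8-connected regions), PCA compares component
   loadings, and an RMS response magnitude with a label-permutation p-value
   summarises the effect size.

The phantom generator renders virtual cells (elliptical cell + membrane ring
+ nucleus + lipid droplets) with band-model reference spectra, random
polynomial baselines, Gaussian noise and cosmic spikes, and applies a
parameterised treatment effect (droplet depletion, droplet band attenuation,
protein band gain) scaled by a mutation profile
(`wildtype` / `braf_like` / `kras_like`).

## Worked example

```python
import json
from ramanresp import PhantomConfig, analyze_pair

config = PhantomConfig(seed=11, mutation_profile="wildtype")
result = analyze_pair(config, n_cells=2, permutation_seed=5)
print(json.dumps(result.report.to_dict(), indent=2))
for peak in result.diffs["lipid_droplet"].peaks:
    if peak.center in (1750.0, 3018.0):
        print(f"{peak.center:.0f} cm^-1  sign {peak.sign}  prominence {peak.prominence:.2f}")
```

prints

```
{
  "component_magnitudes": {
    "membrane": 0.033423911806765044,
    "cytoplasm": 0.040698684621353835,
    "nucleus": 0.04532296239331199,
    "lipid_droplet": 0.09502150797908321
  },
  "whole_cell_magnitude": 0.0013250816567228312,
  "droplet_ratio": 0.47058823529411764,
  "largest_component": "lipid_droplet",
  "p_value": 0.315,
  "mutation_profile": "wildtype"
}
1750 cm^-1  sign +  prominence 0.36
3018 cm^-1  sign +  prominence 0.32
```

Reading this: the lipid-droplet compartment shows the largest response
magnitude; the droplet count in treated cells is ≈ 0.47 of the control count
(the programmed retention is 0.5); and the droplet difference spectrum has
*positive* peaks at the ester C=O (1750 cm⁻¹) and unsaturated =C–H
(3018 cm⁻¹) markers — droplet signal is weaker after treatment. Rerunning
with `mutation_profile="kras_like"` gives magnitudes at the noise floor, a
droplet ratio of ≈ 1 and a non-significant permutation p-value.

A shell interface wraps the same functions:

```sh
ramanresp simulate --out sim/ --n-cells 2 --seed 1
ramanresp preprocess --in sim/cell00_control.h5 --out pre.h5
ramanresp segment --in pre.h5 --out seg/ --k 8
ramanresp run --config pipeline.yaml --out run/   # end-to-end + manifest
```

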
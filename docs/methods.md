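# Methods

## Scope and model

`ramanresp` implements a single-cell Raman imaging analysis pipeline —
preprocessing, Ward/Pearson hierarchical clustering, marker-band component
merging, phenylalanine-normalised difference spectroscopy — plus a phantom
generator that emulates the statistical structure such an analysis assumes.
The phantom is the test bed: every pipeline claim made by the test suite is
a statement about recovery of the phantom's known ground truth, not about
any particular instrument's data.

## The phantom generative model

A virtual cell in a `field_of_view` × `field_of_view` µm² image
(default 45 µm at 0.5 µm pixels → 90 × 90 spectra) consists of

- an elliptical cell (default semi-axes 16 × 12 µm, per-cell jitter of ±8 %
  in axes and position and a random orientation),
- a plasma-membrane ring of `membrane_thickness` (1 µm),
- an elliptical nucleus (6 × 4.5 µm),
- `droplet_count ~ U{6..10}` disjoint lipid droplets (radius 0.75–1.5 µm)
  placed in the cytoplasm by rejection sampling (bounded retries, then
  error).

Every component has a reference spectrum: a small constant offset plus a sum
of Gaussian (optionally Lorentzian) bands on a 600–3100 cm⁻¹ grid with a
2 cm⁻¹ step. Band positions are the standard cellular assignments (DNA
phosphodiester 790, phenylalanine 1008, amide III ≈1245, CH₂ twisting 1321,
CH deformation ≈1446–1470, C=C 1592, amide I ≈1658–1666, ester C=O 1750,
C–H stretching 2851–2935, unsaturated =C–H 3018 cm⁻¹); amplitudes and widths
are free parameters chosen once for realistic relative intensities.
Droplet pixels add the droplet bands *on top of* the cytoplasm spectrum
(`droplet_includes_cytoplasm`), reflecting that a confocal voxel at a
sub-micron droplet always averages in surrounding cytoplasm — this is also
what makes droplet mean spectra phenylalanine-normalisable, as the analysis
requires. The membrane model carries a moderate 1008 cm⁻¹ band for the same
reason (optical bleed-through of cytoplasm/buffer at a sub-resolution
membrane). The background has weak broad bumps only *outside* 2850–3000 cm⁻¹,
so C–H-based background deletion is non-trivially tested.

Measurement artefacts per pixel: a random degree-≤3 polynomial baseline
(coefficients uniform in configurable ranges, scaled by the maximum band
amplitude; defaults keep noise-free intensities non-negative), additive
Gaussian noise (`noise_sd` = 0.02 of the maximum band amplitude) and
Poisson-count cosmic spikes (rate 0.1/spectrum, single-channel positive
impulses of 3–10 × the maximum band amplitude; width configurable).

### Treatment effect

Treatment is modelled by three parameters, each scaled by the mutation
profile factor (`wildtype` 1.0, `braf_like` 0.3, `kras_like` 0.0 — free
generator parameters mirroring the qualitative large/small/none ordering,
not biological claims):

- `droplet_retention` (0.5): the treated layout keeps
  `round(count × retention)` of the control droplets (layout otherwise
  shared between the pair).
- `droplet_band_attenuation` (0.7): treated droplet band amplitudes shrink —
  treated droplets smaller than the sampling voxel. This, not the count
  reduction, is what produces the *positive* droplet difference peaks at
  1750/3018 cm⁻¹: per-pixel component means are invariant to how many
  droplet pixels there are.
- `protein_band_gain` (1.12) on designated fingerprint/CH bands of membrane,
  cytoplasm and nucleus (protein expression rises under treatment), giving
  the *negative* amide/CH difference peaks. The 1008 cm⁻¹ band is excluded
  from the gained set: it is the normalisation reference, and a uniform gain
  including it would cancel identically out of every phenylalanine-normalised
  difference spectrum.

Defaults were chosen so the phantom reproduces the qualitative study
conditions the pipeline is meant to detect: the largest component response
in lipid droplets, and cytoplasm response larger than membrane.

### Determinism

All randomness derives from `PhantomConfig.seed` through separate
`SeedSequence` streams for layout, control noise and treated noise; per-cell
seeds in `generate_paired_dataset` derive from the dataset seed. Identical
configs give bit-identical cubes, truths and (via `run_pipeline`) artifact
checksums.

## Numerical choices

- **Background mask**: per-pixel integral over 2850–3000 cm⁻¹ above a linear
  baseline anchored on the median of 40 cm⁻¹ flanking windows *outside* the
  region (a chord between the region endpoints would clip the 2851 cm⁻¹ band,
  whose flank touches the region edge). Threshold: Otsu split of the
  integral distribution, with a fixed-quantile fallback for degenerate
  distributions.
- **Despiking**: residual against a running median (window 7) must exceed
  6 robust σ (1.4826 × MAD) *and* dominate both neighbouring residuals by
  3×. The second condition makes the filter the identity on noiseless
  spike-free spectra (where MAD collapses to zero) and protects genuine
  bands of FWHM ≥ ~8 cm⁻¹; single-channel impulses always satisfy it.
- **Baseline**: iterative clamped least squares (fit, clamp data above the
  fit to the fit, refit; ≤ 50 iterations, relative tolerance 1e-6) on a
  degree-3 Vandermonde basis over [-1, 1]. Exact (machine scale) on
  band-free polynomials of degree ≤ 3; on band-bearing spectra the fitted
  baseline tracks the band-free least-squares oracle to a few per cent of
  the band amplitude and preserves band area to < 5 %.
- **Vector normalisation** support: union of the analysis regions
  700–1800 ∪ 2800–3050 cm⁻¹. All intervals everywhere are closed on the
  channel grid.
- **HCA**: `scipy.cluster.hierarchy.linkage(method="ward")` on the condensed
  Pearson-distance matrix — the Lance–Williams Ward recurrence applied
  directly to a non-Euclidean distance. That combination is formally
  improper (Ward assumes squared Euclidean input) but is applied
  deliberately as specified; the test suite checks it against a brute-force
  agglomerator that recomputes the criterion over all pairs at every step
  (n ≤ 8, cophenetic-matrix equality). Raw cluster count `k` = 8 before
  merging, configurable; for large cubes a deterministic every-m-th-pixel
  subsample with nearest-centroid assignment is available (`subsample`,
  default off).
- **Marker-band presence**: chord prominence within ±8 cm⁻¹ of the stated
  centre must exceed max(2 × median channel sd in the window, 2 % of the
  spectrum's dynamic range); the floor keeps the test meaningful on
  near-noiseless data. Membrane additionally requires ≥ 20 % of cluster
  pixels 8-adjacent to background (spatial boundary prior), because its
  spectrum alone is ambiguous against cytoplasm. Clusters matching no rule
  inherit the best-correlated assigned component; an unmatched *component*
  is an error.
- **Droplet counting**: 8-connected regions of the droplet label with area
  ≥ 3 pixels.
- **Difference peaks**: local extrema with prominence above 3 × the mean
  standard error of the difference of means (sd pooled over both
  conditions / √n), minimum separation 8 cm⁻¹. The pixel-level pooled sd is
  also reported per channel (the "shading"), but it is not the detection
  scale: at realistic pixel counts it exceeds any real difference peak.
- **Phenylalanine normalisation**: band height = chord prominence across
  ±8 cm⁻¹ around 1008 cm⁻¹ (robust to residual baseline); spectra whose
  1008 prominence is below 1 % of their dynamic range raise an error.
- **PCA**: SVD of the column-centred observation matrix; loadings sign-fixed
  so each loading's maximum-absolute element is positive; PC1 scores paired
  control↔treated per component. Verified against a covariance
  eigen-decomposition oracle to 1e-8.
- **Response magnitude**: RMS of the difference spectrum over the analysis
  regions. Significance: pooled label-permutation of per-cell whole-cell
  mean spectra (default 199 permutations, add-one-corrected p).

## Problem sizes used by the test suite

Full-geometry runs (90 × 90 pixels, ≈ 2200 foreground spectra of 1251
channels) are used for the four-component recovery and marker-position
checks. Replicate studies (parameter recovery over 20 paired cells; the
wildtype > braf_like > kras_like ordering over 4 paired cells × 3 profiles)
use a 60 × 60-pixel phantom with a proportionally smaller cell — the same
generative model at a size chosen to keep many-replicate studies quick.
The end-to-end orchestration test uses a 30 × 30-pixel phantom.

## What passing tests do and do not show

The phantom emulates the *statistical* structure of confocal Raman maps:
component-wise band mixtures, smooth per-pixel baselines, Gaussian noise,
impulse spikes, paired treatment effects. It deliberately omits optical
physics (no PSF, no depth sectioning, no partial-volume mixing at component
boundaries beyond the droplet–cytoplasm case; spatial blur only as optional
isotropic smoothing), detector nonlinearity, wavenumber miscalibration, and
any spectral signature of the drug itself. Passing tests therefore show the
analysis correctly recovers structure *of the kind it assumes*; they do not
certify performance on real spectra whose artefacts violate those
assumptions (e.g. multi-channel spikes — configurable but defaulting to
width 1 — or strongly non-polynomial baselines).

## Known limitations

- Ward on Pearson distances lacks the variance-minimisation guarantee; we
  keep it because it is the field's stated practice for this analysis, and
  monotone merge heights are verified empirically in the tests.
- The marker-rule merging assumes the four components exist in every cube;
  a cube genuinely lacking droplets fails loudly rather than degrading.
- The permutation test pools cells across conditions; with few cells its
  resolution is coarse (min p = 1/(n_perm+1), granularity set by the cell
  count).
- CSV cubes store full float precision and are intended for small fixtures
  only.
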
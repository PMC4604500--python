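"""HCA segmentation of preprocessed cubes into subcellular components.

Pixel spectra restricted to the analysis regions (700-1800 and
2800-3050 cm^-1 by default) are agglomerated with Ward's minimum-variance
criterion applied to the Pearson correlation distance (the Lance-Williams
recurrence on the precomputed distance matrix; this pairing is formally
improper for a non-Euclidean distance but is applied deliberately and
documented).  The raw clusters are then merged into the four subcellular
components — plasma membrane, cytoplasm, nucleus, lipid droplets — by
marker-band rules: DNA 790 cm^-1 identifies the nucleus, phenylalanine
1008 cm^-1 the protein-rich cytoplasm, and the ester C=O 1750 plus =C-H
3018 cm^-1 pair the lipid droplets; the membrane additionally uses a
spatial prior (adjacency to the cell boundary) because its spectrum is
ambiguous at optical resolution.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from scipy import ndimage

from .core import COMPONENT_LABELS, CELL_COMPONENTS, ComponentSpectrum
from .peaks import band_present
from .preprocess import PreprocessedCube

__all__ = [
    "AnalysisRegion",
    "DEFAULT_REGIONS",
    "Dendrogram",
    "MarkerRule",
    "DEFAULT_RULES",
    "extract_features",
    "pearson_distance",
    "ward_hca",
    "cut_dendrogram",
    "merge_clusters",
    "count_lipid_droplets",
    "segment_cube",
]

DEFAULT_REGIONS: tuple[tuple[float, float], ...] = ((700.0, 1800.0), (2800.0, 3050.0))


@dataclass(frozen=True)
class AnalysisRegion:
    """Closed, non-overlapping wavenumber intervals used for clustering."""

    intervals: tuple[tuple[float, float], ...] = DEFAULT_REGIONS

    def __post_init__(self) -> None:
        ivals = sorted(self.intervals)
        for (lo, hi) in ivals:
            if hi <= lo:
                raise ValueError(f"interval [{lo}, {hi}] is empty")
        for (_, hi1), (lo2, _) in zip(ivals, ivals[1:]):
            if lo2 <= hi1:
                raise ValueError("analysis intervals must not overlap")

    def channel_indices(self, wavenumbers: np.ndarray) -> np.ndarray:
        w = np.asarray(wavenumbers)
        sel = np.zeros(len(w), dtype=bool)
        for lo, hi in self.intervals:
            sel |= (w >= lo) & (w <= hi)
        idx = np.nonzero(sel)[0]
        if len(idx) == 0:
            raise ValueError(
                f"analysis regions {self.intervals} select no channels on grid "
                f"[{w[0]}, {w[-1]}]"
            )
        return idx


@dataclass
class Dendrogram:
    """Agglomeration result: a scipy-format merge table plus leaf count."""

    linkage_matrix: np.ndarray
    n_leaves: int

    @property
    def heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]


def extract_features(
    pre: PreprocessedCube, region: AnalysisRegion | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel feature vectors: channels inside the analysis intervals.

    Returns ``(features, feature_wavenumbers)`` with pixel order preserved.
    """
    region = region or AnalysisRegion()
    idx = region.channel_indices(pre.wavenumbers)
    return pre.spectra[:, idx], pre.wavenumbers[idx]


def pearson_distance(x: np.ndarray, y: np.ndarray) -> float:
    """d = 1 - r (Pearson); in [0, 2]; shape-sensitive, scale-free."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2 or len(x) != len(y):
        raise ValueError("need two equal-length vectors with >= 2 channels")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Pearson distance undefined for zero-variance vectors")
    r = np.corrcoef(x, y)[0, 1]
    return float(1.0 - r)


def ward_hca(features: np.ndarray) -> Dendrogram:
    """Ward agglomeration on the Pearson correlation distance matrix."""
    features = np.asarray(features, dtype=float)
    if features.ndim != 2 or features.shape[0] < 2:
        raise ValueError("need at least 2 feature vectors")
    if np.any(np.ptp(features, axis=1) == 0):
        bad = np.nonzero(np.ptp(features, axis=1) == 0)[0]
        raise ValueError(f"zero-variance feature vector(s) at rows {bad[:5].tolist()}")
    d = pdist(features, metric="correlation")
    z = linkage(d, method="ward")
    return Dendrogram(linkage_matrix=z, n_leaves=features.shape[0])


def cut_dendrogram(dendrogram: Dendrogram, k: int) -> np.ndarray:
    """Flat labels (0..k-1, renumbered by first occurrence) at k clusters."""
    n = dendrogram.n_leaves
    if not 1 <= k <= n:
        raise ValueError(f"k={k} outside [1, {n}]")
    raw = fcluster(dendrogram.linkage_matrix, t=k, criterion="maxclust")
    _, labels = np.unique(raw, return_inverse=True)
    # renumber deterministically by first occurrence in pixel order
    order: dict[int, int] = {}
    out = np.empty_like(labels)
    for i, lab in enumerate(labels):
        if lab not in order:
            order[lab] = len(order)
        out[i] = order[lab]
    return out


@dataclass(frozen=True)
class MarkerRule:
    """Marker-band rule assigning a raw cluster to one component."""

    component: str
    required: tuple[tuple[float, float], ...] = ()   # (centre, window) pairs
    forbidden: tuple[tuple[float, float], ...] = ()
    priority: int = 0
    requires_boundary: bool = False                  # touches the cell edge


DEFAULT_RULES: tuple[MarkerRule, ...] = (
    MarkerRule(
        component="lipid_droplet",
        required=((1750.0, 8.0), (3018.0, 8.0)),
        priority=1,
    ),
    MarkerRule(
        component="nucleus",
        required=((790.0, 8.0),),
        forbidden=((1750.0, 8.0),),
        priority=2,
    ),
    MarkerRule(
        component="membrane",
        required=((1666.0, 14.0),),                  # amide I
        forbidden=((790.0, 8.0), (1750.0, 8.0)),
        priority=3,
        requires_boundary=True,
    ),
    MarkerRule(
        component="cytoplasm",
        required=((1008.0, 8.0),),
        forbidden=((790.0, 8.0), (1750.0, 8.0)),
        priority=4,
    ),
)


def _boundary_fraction(cluster_img: np.ndarray, mask: np.ndarray) -> float:
    """Fraction of cluster pixels 8-adjacent to background or the image edge."""
    outside = ~mask
    padded = np.pad(outside, 1, constant_values=True)
    near_bg = ndimage.binary_dilation(padded, structure=np.ones((3, 3)))[1:-1, 1:-1]
    n = cluster_img.sum()
    return float((cluster_img & near_bg).sum() / n) if n else 0.0


def _cluster_stats(
    raw_labels: np.ndarray, pre: PreprocessedCube
) -> tuple[list[np.ndarray], list[np.ndarray], list[int], list[float]]:
    means, sds, sizes, boundary = [], [], [], []
    for k in range(raw_labels.max() + 1):
        sel = raw_labels == k
        spec = pre.spectra[sel]
        means.append(spec.mean(axis=0))
        sds.append(spec.std(axis=0))
        sizes.append(int(sel.sum()))
        img = pre.label_image(sel.astype(bool), fill=False)
        boundary.append(_boundary_fraction(img, pre.mask))
    return means, sds, sizes, boundary


def merge_clusters(
    raw_labels: np.ndarray,
    pre: PreprocessedCube,
    rules: Sequence[MarkerRule] = DEFAULT_RULES,
    snr: float = 2.0,
    boundary_threshold: float = 0.2,
) -> tuple[np.ndarray, dict[str, ComponentSpectrum]]:
    """Merge raw HCA clusters into the four subcellular components.

    Each cluster's mean spectrum is scored against the marker rules in
    priority order and assigned to the first rule it satisfies; clusters
    matching no rule inherit the component of the assigned cluster mean
    they correlate with best.  Returns the component label map (image
    shape, ``COMPONENT_LABELS`` ids) and per-component mean spectra.

    Raises
    ------
    ValueError
        If any of the four components ends up with no cluster.
    """
    raw_labels = np.asarray(raw_labels)
    n_clusters = int(raw_labels.max()) + 1
    if n_clusters < len(CELL_COMPONENTS):
        raise ValueError(
            f"{n_clusters} raw clusters cannot cover {len(CELL_COMPONENTS)} components"
        )
    means, sds, sizes, boundary = _cluster_stats(raw_labels, pre)
    w = pre.wavenumbers

    ordered = sorted(rules, key=lambda r: r.priority)
    assignment: dict[int, str] = {}
    for c in range(n_clusters):
        for rule in ordered:
            if rule.requires_boundary and boundary[c] < boundary_threshold:
                continue
            ok = all(
                band_present(means[c], sds[c], w, ctr, win, snr)
                for ctr, win in rule.required
            )
            if ok:
                ok = not any(
                    band_present(means[c], sds[c], w, ctr, win, snr)
                    for ctr, win in rule.forbidden
                )
            if ok:
                assignment[c] = rule.component
                break

    missing = [
        r.component
        for r in ordered
        if r.component not in set(assignment.values())
    ]
    if missing:
        raise ValueError(
            f"no raw cluster satisfied the rule(s) for component(s) {missing}; "
            f"cluster sizes {sizes}, boundary fractions "
            f"{[round(b, 2) for b in boundary]}"
        )

    # leftovers: nearest assigned cluster mean by Pearson correlation
    for c in range(n_clusters):
        if c in assignment:
            continue
        best, best_d = None, np.inf
        for other, comp in list(assignment.items()):
            d = pearson_distance(means[c], means[other])
            if d < best_d:
                best, best_d = comp, d
        assignment[c] = best  # type: ignore[assignment]

    comp_of_pixel = np.array(
        [COMPONENT_LABELS[assignment[c]] for c in raw_labels], dtype=np.int16
    )
    label_map = pre.label_image(comp_of_pixel, fill=COMPONENT_LABELS["background"])

    spectra: dict[str, ComponentSpectrum] = {}
    for comp in CELL_COMPONENTS:
        sel = comp_of_pixel == COMPONENT_LABELS[comp]
        spec = pre.spectra[sel]
        spectra[comp] = ComponentSpectrum(
            component=comp,
            wavenumbers=w,
            mean=spec.mean(axis=0),
            sd=spec.std(axis=0),
            n_pixels=int(sel.sum()),
        )
    return label_map, spectra


def count_lipid_droplets(label_map: np.ndarray, min_size: int = 3) -> int:
    """Number of 8-connected lipid-droplet regions with area >= min_size."""
    mask = np.asarray(label_map) == COMPONENT_LABELS["lipid_droplet"]
    lab, n = ndimage.label(mask, structure=np.ones((3, 3)))
    if n == 0:
        return 0
    sizes = np.bincount(lab.ravel())[1:]
    return int(np.sum(sizes >= min_size))


def segment_cube(
    pre: PreprocessedCube,
    k: int = 8,
    region: AnalysisRegion | None = None,
    rules: Sequence[MarkerRule] = DEFAULT_RULES,
    snr: float = 2.0,
    subsample: int = 1,
) -> tuple[np.ndarray, dict[str, ComponentSpectrum], Dendrogram]:
    """Full segmentation: features -> Ward/Pearson HCA -> cut -> merge.

    ``subsample`` > 1 clusters every m-th foreground pixel and assigns the
    rest to the nearest cluster centroid (Pearson distance); the default
    clusters every pixel.
    """
    features, _ = extract_features(pre, region)
    if subsample > 1:
        sub_idx = np.arange(0, features.shape[0], subsample)
        dend = ward_hca(features[sub_idx])
        sub_labels = cut_dendrogram(dend, k)
        centroids = np.stack(
            [features[sub_idx][sub_labels == c].mean(axis=0) for c in range(k)]
        )
        fz = (features - features.mean(axis=1, keepdims=True))
        fz /= np.linalg.norm(fz, axis=1, keepdims=True)
        cz = centroids - centroids.mean(axis=1, keepdims=True)
        cz /= np.linalg.norm(cz, axis=1, keepdims=True)
        raw = np.argmax(fz @ cz.T, axis=1)
    else:
        dend = ward_hca(features)
        raw = cut_dendrogram(dend, k)
    label_map, spectra = merge_clusters(raw, pre, rules, snr)
    return label_map, spectra, dend
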
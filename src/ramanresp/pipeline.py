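"""End-to-end orchestration: simulate -> preprocess -> segment -> respond.

:func:`analyze_pair` is the library-level driver used by the tests, the
acceptance script and the CLI ``run`` command: it generates (or accepts)
paired control/treated cubes for ``n_cells`` virtual cells, runs the full
analysis and returns a :class:`~ramanresp.response.ResponseReport` plus all
intermediates.  :func:`run_pipeline` is the file-based variant that writes
every artifact and a checksummed run manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

from .core import CELL_COMPONENTS, ComponentSpectrum
from .phantom import PhantomConfig, generate_paired_dataset
from .preprocess import PreprocessParams, preprocess_cube
from .response import (
    PCAResult,
    ResponseReport,
    build_report,
    cell_mean_spectrum,
    difference_spectrum,
    normalize_to_phenylalanine,
    pca_compare,
    permutation_pvalue,
)
from .segment import AnalysisRegion, count_lipid_droplets, segment_cube

__all__ = ["PairAnalysis", "analyze_pair", "PipelineConfig", "run_pipeline"]


@dataclass
class PairAnalysis:
    """Everything :func:`analyze_pair` computes."""

    report: ResponseReport
    diffs: dict[str, Any]
    whole_cell_diff: Any
    pca: PCAResult
    component_spectra: dict[str, dict[str, ComponentSpectrum]]  # condition -> comp -> cs
    label_maps: dict[str, list[np.ndarray]]
    droplet_counts: dict[str, int]


def _aggregate(per_cell: list[ComponentSpectrum]) -> ComponentSpectrum:
    """Average per-cell component spectra into one condition-level spectrum."""
    mean = np.mean([cs.mean for cs in per_cell], axis=0)
    sd = np.sqrt(np.mean([cs.sd**2 for cs in per_cell], axis=0))
    return ComponentSpectrum(
        component=per_cell[0].component,
        wavenumbers=per_cell[0].wavenumbers,
        mean=mean,
        sd=sd,
        n_pixels=int(sum(cs.n_pixels for cs in per_cell)),
    )


def analyze_pair(
    config: PhantomConfig,
    n_cells: int = 1,
    k: int = 8,
    preprocess_params: PreprocessParams | None = None,
    region: AnalysisRegion | None = None,
    min_droplet_size: int = 3,
    n_permutations: int = 199,
    permutation_seed: int = 0,
    subsample: int = 1,
) -> PairAnalysis:
    """Generate paired phantoms and quantify the treatment response.

    Per cell and condition the cube is preprocessed and HCA-segmented; the
    four component mean spectra are phenylalanine-normalised per cell, then
    averaged across cells per condition.  Difference spectra, droplet
    counts, PCA over component x condition means, response magnitudes and a
    whole-cell permutation p-value are assembled into the report.
    """
    region = region or AnalysisRegion()
    dataset = generate_paired_dataset(config, n_cells)

    comp_cell: dict[str, dict[str, list[ComponentSpectrum]]] = {
        cond: {c: [] for c in CELL_COMPONENTS} for cond in ("control", "treated")
    }
    whole_cell: dict[str, list[np.ndarray]] = {"control": [], "treated": []}
    whole_cell_sd: dict[str, list[ComponentSpectrum]] = {"control": [], "treated": []}
    label_maps: dict[str, list[np.ndarray]] = {"control": [], "treated": []}
    droplet_counts = {"control": 0, "treated": 0}

    for c_cube, t_cube, _ct, _tt in dataset:
        for cond, cube in (("control", c_cube), ("treated", t_cube)):
            pre = preprocess_cube(cube, preprocess_params)
            labels, spectra, _ = segment_cube(
                pre, k=k, region=region, subsample=subsample
            )
            label_maps[cond].append(labels)
            droplet_counts[cond] += count_lipid_droplets(labels, min_droplet_size)
            for comp in CELL_COMPONENTS:
                comp_cell[cond][comp].append(
                    normalize_to_phenylalanine(spectra[comp])
                )
            wc = cell_mean_spectrum(pre)
            whole_cell[cond].append(wc.mean)
            whole_cell_sd[cond].append(wc)

    component_spectra = {
        cond: {c: _aggregate(comp_cell[cond][c]) for c in CELL_COMPONENTS}
        for cond in ("control", "treated")
    }
    diffs = {
        c: difference_spectrum(
            component_spectra["control"][c], component_spectra["treated"][c]
        )
        for c in CELL_COMPONENTS
    }
    wc_control = _aggregate(whole_cell_sd["control"])
    wc_treated = _aggregate(whole_cell_sd["treated"])
    whole_cell_diff = difference_spectrum(wc_control, wc_treated)

    rows, labels_rows = [], []
    for cond in ("control", "treated"):
        for comp in CELL_COMPONENTS:
            rows.append(component_spectra[cond][comp].mean)
            labels_rows.append((comp, cond))
    pca = pca_compare(np.vstack(rows), labels_rows)

    _, p = permutation_pvalue(
        np.vstack(whole_cell["control"]),
        np.vstack(whole_cell["treated"]),
        wc_control.wavenumbers,
        region,
        n_permutations=n_permutations,
        seed=permutation_seed,
    )

    report = build_report(
        diffs,
        droplet_counts["control"],
        droplet_counts["treated"],
        whole_cell_diff,
        pca=pca,
        region=region,
        p_value=p,
        mutation_profile=config.mutation_profile,
    )
    return PairAnalysis(
        report=report,
        diffs=diffs,
        whole_cell_diff=whole_cell_diff,
        pca=pca,
        component_spectra=component_spectra,
        label_maps=label_maps,
        droplet_counts=droplet_counts,
    )


@dataclass
class PipelineConfig:
    """File-based pipeline configuration (mirrors the YAML schema)."""

    phantom: PhantomConfig
    out_dir: Path
    n_cells: int = 1
    seed: int = 0
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    segment: dict[str, Any] = field(default_factory=lambda: {"k": 8, "min_droplet_size": 3})
    response: dict[str, Any] = field(default_factory=lambda: {"n_permutations": 199})
    log_level: str = "INFO"

    REQUIRED_BLOCKS = ("phantom", "preprocess", "segment", "response")

    @classmethod
    def from_dict(cls, d: dict, out_dir: str | Path) -> "PipelineConfig":
        missing = [b for b in cls.REQUIRED_BLOCKS if b not in d]
        if missing:
            raise ValueError(f"pipeline config missing stage block(s): {missing}")
        from .io import phantom_config_from_dict

        phantom = phantom_config_from_dict(d["phantom"])
        pp = PreprocessParams(**{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in d["preprocess"].items()
        }) if d["preprocess"] else PreprocessParams()
        if isinstance(pp.norm_regions, tuple):
            pp.norm_regions = tuple(tuple(r) for r in pp.norm_regions)
        return cls(
            phantom=phantom,
            out_dir=Path(out_dir),
            n_cells=int(d.get("n_cells", 1)),
            seed=int(d.get("seed", phantom.seed)),
            preprocess=pp,
            segment=dict(d["segment"]),
            response=dict(d["response"]),
            log_level=d.get("log_level", "INFO"),
        )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the file-based pipeline and return the run manifest.

    Writes cubes, label maps, component spectra tables, difference spectra
    and the response report under ``config.out_dir``; the manifest records
    parameters and a SHA-256 checksum for every artifact, so reruns with an
    unchanged config are verifiably identical.
    """
    from . import __version__
    from .io import write_component_spectra, write_cube, write_label_map
    from .core import LABEL_NAMES

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    phantom_cfg = dataclasses.replace(config.phantom, seed=config.seed)

    dataset = generate_paired_dataset(phantom_cfg, config.n_cells)
    artifacts: list[Path] = []
    for i, (c_cube, t_cube, _, _) in enumerate(dataset):
        for cond, cube in (("control", c_cube), ("treated", t_cube)):
            p = out / f"cell{i:02d}_{cond}.h5"
            write_cube(cube, p)
            artifacts.append(p)

    analysis = analyze_pair(
        phantom_cfg,
        n_cells=config.n_cells,
        k=int(config.segment.get("k", 8)),
        preprocess_params=config.preprocess,
        min_droplet_size=int(config.segment.get("min_droplet_size", 3)),
        n_permutations=int(config.response.get("n_permutations", 199)),
        permutation_seed=config.seed,
        subsample=int(config.segment.get("subsample", 1)),
    )

    for cond in ("control", "treated"):
        for i, labels in enumerate(analysis.label_maps[cond]):
            p = out / f"cell{i:02d}_{cond}_labels.tiff"
            write_label_map(labels, p, LABEL_NAMES)
            artifacts += [p, p.with_suffix(".json")]
        p = out / f"components_{cond}.csv"
        write_component_spectra(analysis.component_spectra[cond], p)
        artifacts.append(p)

    import pandas as pd

    diff_frames = []
    for comp, d in analysis.diffs.items():
        diff_frames.append(
            pd.DataFrame(
                {
                    "wavenumber": d.wavenumbers,
                    "value": d.values,
                    "pooled_sd": d.pooled_sd,
                    "component": comp,
                }
            )
        )
    p = out / "difference_spectra.csv"
    pd.concat(diff_frames, ignore_index=True).to_csv(p, index=False)
    artifacts.append(p)

    p = out / "report.json"
    with open(p, "w") as f:
        json.dump(analysis.report.to_dict(), f, indent=2)
    artifacts.append(p)

    manifest = {
        "tool_version": __version__,
        "seed": config.seed,
        "n_cells": config.n_cells,
        "parameters": {
            "segment": config.segment,
            "response": config.response,
            "preprocess": {
                "ch_region": list(config.preprocess.ch_region),
                "despike_window": config.preprocess.despike_window,
                "baseline_degree": config.preprocess.baseline_degree,
            },
        },
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "artifacts": {str(a.relative_to(out)): _sha256(a) for a in artifacts},
    }
    with open(out / "manifest.json", "w") as f:
        json.dump(manifest, f, indent=2)
    return manifest
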
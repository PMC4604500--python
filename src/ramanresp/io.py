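"""Readers and writers for cubes, label maps, spectra tables and configs.

The canonical cube container is HDF5 (datasets ``/intensities`` and
``/wavenumbers``, attributes ``pixel_size_um``, ``condition``, ``seed``).
A flat CSV dialect (columns: row, col, then one column per wavenumber)
exists for small human-inspectable fixtures.  Label maps go to
single-channel TIFF with a JSON legend next to them.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any

import h5py
import numpy as np
import pandas as pd
import tifffile
import yaml

from .core import ComponentSpectrum, HyperspectralCube
from .phantom import ComponentModel, PhantomConfig, SpectralBand, TreatmentEffect

__all__ = [
    "read_cube",
    "write_cube",
    "read_label_map",
    "write_label_map",
    "load_phantom_config",
    "save_phantom_config",
    "write_component_spectra",
    "read_component_spectra",
]


def write_cube(cube: HyperspectralCube, path: str | Path, dialect: str = "hdf5") -> None:
    """Write a cube; round-trips exactly with :func:`read_cube`."""
    path = Path(path)
    if dialect == "hdf5":
        with h5py.File(path, "w") as f:
            # track_times=False keeps files byte-identical across reruns
            f.create_dataset("intensities", data=cube.intensities, track_times=False)
            f.create_dataset("wavenumbers", data=cube.wavenumbers, track_times=False)
            f.attrs["pixel_size_um"] = float(cube.pixel_size)
            for key in ("condition", "seed"):
                if key in cube.metadata:
                    f.attrs[key] = cube.metadata[key]
            f.attrs["metadata_json"] = json.dumps(cube.metadata, default=str)
    elif dialect == "csv":
        rows, cols, _ = cube.shape
        rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
        data = np.column_stack(
            [rr.ravel(), cc.ravel(), cube.intensities.reshape(rows * cols, -1)]
        )
        header = ["row", "col"] + [repr(float(w)) for w in cube.wavenumbers]
        with open(path, "w") as f:
            f.write("# pixel_size_um=" + repr(float(cube.pixel_size)) + "\n")
            f.write(",".join(header) + "\n")
            for line in data:
                f.write(
                    f"{int(line[0])},{int(line[1])},"
                    + ",".join(repr(float(v)) for v in line[2:])
                    + "\n"
                )
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_cube(path: str | Path, dialect: str = "hdf5") -> HyperspectralCube:
    """Read a cube written by :func:`write_cube`; validates the layout."""
    path = Path(path)
    if dialect == "hdf5":
        with h5py.File(path, "r") as f:
            for name in ("intensities", "wavenumbers"):
                if name not in f:
                    raise ValueError(f"{path}: missing dataset '/{name}'")
            intensities = f["intensities"][()]
            wavenumbers = f["wavenumbers"][()]
            if intensities.ndim != 3 or intensities.shape[2] != len(wavenumbers):
                raise ValueError(
                    f"{path}: intensity shape {intensities.shape} does not match "
                    f"{len(wavenumbers)} wavenumber channels"
                )
            meta: dict[str, Any] = {}
            if "metadata_json" in f.attrs:
                meta = json.loads(f.attrs["metadata_json"])
            pixel_size = float(f.attrs.get("pixel_size_um", 1.0))
        if not np.all(np.diff(wavenumbers) > 0):
            raise ValueError(f"{path}: wavenumbers are not strictly increasing")
        return HyperspectralCube(intensities, wavenumbers, pixel_size, meta)
    if dialect == "csv":
        with open(path) as f:
            first = f.readline()
            pixel_size = 1.0
            if first.startswith("#"):
                if "pixel_size_um=" in first:
                    pixel_size = float(first.split("pixel_size_um=")[1])
                header = f.readline()
            else:
                header = first
            names = header.strip().split(",")
            if names[:2] != ["row", "col"]:
                raise ValueError(f"{path}: CSV cube must start with row,col columns")
            wavenumbers = np.array([float(x) for x in names[2:]])
            if not np.all(np.diff(wavenumbers) > 0):
                raise ValueError(f"{path}: wavenumber columns are not strictly increasing")
            body = np.loadtxt(f, delimiter=",")
        body = np.atleast_2d(body)
        rows = int(body[:, 0].max()) + 1
        cols = int(body[:, 1].max()) + 1
        cube = np.zeros((rows, cols, len(wavenumbers)))
        cube[body[:, 0].astype(int), body[:, 1].astype(int)] = body[:, 2:]
        return HyperspectralCube(cube, wavenumbers, pixel_size, {})
    raise ValueError(f"unknown dialect {dialect!r}")


def write_label_map(
    label_map: np.ndarray, path: str | Path, legend: dict[int, str]
) -> None:
    """Label map as single-channel TIFF plus a JSON legend alongside."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(label_map, dtype=np.uint8))
    with open(path.with_suffix(".json"), "w") as f:
        json.dump({str(k): v for k, v in legend.items()}, f, indent=2)


def read_label_map(path: str | Path) -> tuple[np.ndarray, dict[int, str]]:
    path = Path(path)
    labels = tifffile.imread(path).astype(np.int16)
    with open(path.with_suffix(".json")) as f:
        legend = {int(k): v for k, v in json.load(f).items()}
    return labels, legend


def _config_to_dict(config: PhantomConfig) -> dict:
    def encode(obj):
        if isinstance(obj, (SpectralBand, ComponentModel, TreatmentEffect)):
            return {k: encode(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, dict):
            return {k: encode(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [encode(v) for v in obj]
        if isinstance(obj, np.generic):
            return obj.item()
        return obj

    d = {}
    for f in dataclasses.fields(config):
        d[f.name] = encode(getattr(config, f.name))
    return d


def save_phantom_config(config: PhantomConfig, path: str | Path) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(_config_to_dict(config), f, sort_keys=False)


def load_phantom_config(path: str | Path) -> PhantomConfig:
    with open(path) as f:
        d = yaml.safe_load(f)
    return phantom_config_from_dict(d)


def phantom_config_from_dict(d: dict) -> PhantomConfig:
    d = dict(d)
    if "effect" in d and isinstance(d["effect"], dict):
        eff = dict(d["effect"])
        if "affected_bands" in eff and eff["affected_bands"]:
            eff["affected_bands"] = {
                k: tuple(v) for k, v in eff["affected_bands"].items()
            }
        d["effect"] = TreatmentEffect(**eff)
    if "components" in d and d["components"]:
        comps = {}
        for name, m in d["components"].items():
            bands = [SpectralBand(**b) for b in m.get("bands", [])]
            comps[name] = ComponentModel(
                name=m.get("name", name),
                bands=bands,
                baseline_offset=m.get("baseline_offset", 0.0),
            )
        d["components"] = comps
    for key in (
        "wavenumber_grid",
        "cell_semiaxes",
        "nucleus_semiaxes",
        "nucleus_offset",
        "droplet_count_range",
        "droplet_radius_range",
        "spike_amplitude_range",
    ):
        if key in d and d[key] is not None:
            d[key] = tuple(d[key])
    if "baseline_coeff_ranges" in d and d["baseline_coeff_ranges"] is not None:
        d["baseline_coeff_ranges"] = tuple(tuple(r) for r in d["baseline_coeff_ranges"])
    return PhantomConfig(**d)


def write_component_spectra(
    spectra: dict[str, ComponentSpectrum], path: str | Path
) -> None:
    """Long-format CSV: wavenumber, mean, sd, n_pixels, component."""
    frames = []
    for comp, cs in spectra.items():
        frames.append(
            pd.DataFrame(
                {
                    "wavenumber": cs.wavenumbers,
                    "mean": cs.mean,
                    "sd": cs.sd,
                    "n_pixels": cs.n_pixels,
                    "component": comp,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_component_spectra(path: str | Path) -> dict[str, ComponentSpectrum]:
    df = pd.read_csv(path)
    out = {}
    for comp, g in df.groupby("component", sort=False):
        out[comp] = ComponentSpectrum(
            component=comp,
            wavenumbers=g["wavenumber"].to_numpy(),
            mean=g["mean"].to_numpy(),
            sd=g["sd"].to_numpy(),
            n_pixels=int(g["n_pixels"].iloc[0]),
        )
    return out
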
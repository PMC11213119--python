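"""File formats for volumes, projection stacks and configuration.

Volumes are stored as multi-page TIFF stacks of z-slices with a JSON
sidecar carrying the grid metadata; projection stacks as HDF5 (dataset
``projections`` with the geometry serialized into attributes); geometry
and pipeline configuration as YAML.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import tifffile
import yaml

from .geometry import ScanGeometry, VolumeGrid

__all__ = [
    "save_volume",
    "load_volume",
    "save_projections",
    "load_projections",
    "save_yaml",
    "load_yaml",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def save_volume(path: str | Path, values: np.ndarray, grid: VolumeGrid) -> None:
    """Write a volume as a z-slice TIFF stack plus JSON grid sidecar."""
    path = Path(path)
    values = np.asarray(values)
    if values.shape != tuple(grid.shape):
        raise ValueError(f"volume shape {values.shape} does not match grid {grid.shape}")
    # pages are z-slices: page k is the in-plane (x, y) image at depth k
    tifffile.imwrite(path, np.moveaxis(values, 2, 0).astype(np.float32))
    _sidecar(path).write_text(json.dumps({"grid": grid.to_dict()}, indent=2))


def load_volume(path: str | Path) -> tuple[np.ndarray, VolumeGrid]:
    path = Path(path)
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    values = np.moveaxis(pages, 0, 2).astype(float)
    meta = json.loads(_sidecar(path).read_text())
    grid = VolumeGrid.from_dict(meta["grid"])
    if values.shape != tuple(grid.shape):
        raise ValueError("sidecar grid does not match TIFF data shape")
    return values, grid


def save_projections(path: str | Path, values: np.ndarray, geom: ScanGeometry) -> None:
    """Write a projection stack to HDF5 with the geometry in attributes."""
    values = np.asarray(values)
    with h5py.File(path, "w") as fh:
        ds = fh.create_dataset("projections", data=values.astype(np.float32))
        ds.attrs["geometry"] = json.dumps(geom.to_dict())


def load_projections(path: str | Path) -> tuple[np.ndarray, ScanGeometry]:
    with h5py.File(path, "r") as fh:
        ds = fh["projections"]
        values = ds[()].astype(float)
        geom = ScanGeometry.from_dict(json.loads(ds.attrs["geometry"]))
    expected = (geom.n_views,) + tuple(geom.detector_shape)
    if values.shape != expected:
        raise ValueError(f"stored stack shape {values.shape} does not match geometry {expected}")
    return values, geom


def save_yaml(path: str | Path, data: dict) -> None:
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def load_yaml(path: str | Path) -> dict:
    return yaml.safe_load(Path(path).read_text())
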
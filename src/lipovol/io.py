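"""Reading and writing the package's on-disk formats.

Volumes and image stacks are MRC2014 (mode 2 float) handled through gemmi's
CCP4/MRC support, with the voxel size recorded in the header cell.  Metadata
and result tables are tab-separated text with a header row.
"""

from __future__ import annotations

import os

import gemmi
import numpy as np
import pandas as pd

from .core import META_COLUMNS, ImageStack, VolumeMap

__all__ = [
    "read_volume",
    "write_volume",
    "read_stack",
    "write_stack",
    "read_metadata",
    "write_metadata",
]


def _write_mrc(path: str, data: np.ndarray, voxel_size: float) -> None:
    grid = gemmi.FloatGrid(np.ascontiguousarray(data, dtype=np.float32))
    grid.spacegroup = gemmi.SpaceGroup("P1")
    shape = data.shape
    grid.set_unit_cell(
        gemmi.UnitCell(
            shape[0] * voxel_size, shape[1] * voxel_size, shape[2] * voxel_size,
            90.0, 90.0, 90.0,
        )
    )
    ccp4 = gemmi.Ccp4Map()
    ccp4.grid = grid
    ccp4.update_ccp4_header()
    ccp4.write_ccp4_map(os.fspath(path))


def _read_mrc(path: str) -> tuple:
    ccp4 = gemmi.read_ccp4_map(os.fspath(path))
    data = np.array(ccp4.grid, copy=True).astype(np.float32)
    cell = ccp4.grid.unit_cell
    voxel = cell.a / data.shape[0]
    return data, float(voxel)


def write_volume(path: str, volume: VolumeMap) -> None:
    _write_mrc(path, volume.data, volume.voxel_size)


def read_volume(path: str) -> VolumeMap:
    data, voxel = _read_mrc(path)
    return VolumeMap(data, voxel)


def write_stack(path: str, stack: ImageStack) -> None:
    """Write an N x H x W stack as a 3-D MRC grid (one section per image)."""
    _write_mrc(path, stack.images, stack.pixel_size)


def read_stack(path: str, metadata: pd.DataFrame | None = None) -> ImageStack:
    data, voxel = _read_mrc(path)
    return ImageStack(data, voxel, metadata)


def write_metadata(path: str, metadata: pd.DataFrame) -> None:
    cols = [c for c in META_COLUMNS if c in metadata.columns]
    extra = [c for c in metadata.columns if c not in cols]
    metadata.to_csv(path, sep="\t", index=False, columns=cols + extra)


def read_metadata(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
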
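"""Core containers shared across the pipeline.

Arrays follow the (z, y, x) index convention; physical coordinates are in
ångströms.  A :class:`VolumeMap` is the central object: a cubic (or at least
rectangular) density grid with a known voxel size.  Stacks of 2-D particle or
background images carry their per-image metadata in a pandas DataFrame so
orientation/defocus bookkeeping survives every filtering step.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = ["VolumeMap", "ImageStack", "OrientationAngles"]

#: Columns every stack metadata table carries.
META_COLUMNS = ["image_index", "rot", "tilt", "psi", "defocus_um", "is_background"]


@dataclass
class VolumeMap:
    """3-D density grid with voxel size in Å (z, y, x indexing)."""

    data: np.ndarray
    voxel_size: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise ValueError("VolumeMap.data must be 3-dimensional")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")

    @property
    def box_size(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple:
        return self.data.shape

    def copy(self) -> "VolumeMap":
        return VolumeMap(self.data.copy(), self.voxel_size)

    def physical_extent(self) -> float:
        """Edge length of the box in Å."""
        return self.box_size * self.voxel_size


@dataclass
class OrientationAngles:
    """Euler triplet (intrinsic ZYZ, degrees) plus in-plane shift in pixels.

    ``rot`` and ``psi`` live on [0, 360); ``tilt`` on [0, 180].  (rot, tilt)
    select the viewing direction on the sphere; ``psi`` is the in-plane
    rotation of the projection (see the geometry module for the exact
    convention).
    """

    rot: float
    tilt: float
    psi: float
    shift_x: float = 0.0
    shift_y: float = 0.0
    correlation: float = float("nan")

    def normalized(self) -> "OrientationAngles":
        return replace(
            self,
            rot=self.rot % 360.0,
            tilt=float(np.clip(self.tilt, 0.0, 180.0)),
            psi=self.psi % 360.0,
        )


@dataclass
class ImageStack:
    """N×H×W image stack with per-image metadata.

    The metadata table has one row per image with columns
    ``image_index, rot, tilt, psi, defocus_um, is_background``; for phantom
    data the Euler angles are the *true* projection orientations (retained
    for validation only, never consumed by the reconstruction path).
    """

    images: np.ndarray
    pixel_size: float
    metadata: pd.DataFrame = field(default=None)

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=np.float32)
        if self.images.ndim != 3:
            raise ValueError("ImageStack.images must be N x H x W")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.metadata is None:
            self.metadata = pd.DataFrame(
                {
                    "image_index": np.arange(len(self.images)),
                    "rot": 0.0,
                    "tilt": 0.0,
                    "psi": 0.0,
                    "defocus_um": 0.0,
                    "is_background": False,
                }
            )
        if len(self.metadata) != len(self.images):
            raise ValueError("metadata row count must equal image count")

    def __len__(self) -> int:
        return len(self.images)

    def subset(self, indices) -> "ImageStack":
        indices = np.asarray(indices)
        return ImageStack(
            self.images[indices],
            self.pixel_size,
            self.metadata.iloc[indices].reset_index(drop=True),
        )

    def angles(self) -> list:
        """Per-image orientation metadata as OrientationAngles objects."""
        return [
            OrientationAngles(row.rot, row.tilt, row.psi)
            for row in self.metadata.itertuples()
        ]
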
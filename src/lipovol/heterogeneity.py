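"""Heterogeneity treatments: radial-profile filtering and bootstrap variance.

Two bespoke tools: (1) classes whose radial intensity profile correlates
poorly (< 0.2) with *every* model projection are rejected wholesale — a
cheap, robust way to drop off-size particles and artifacts; (2) voxelwise
variance across reconstructions from with-replacement resamples of the image
set (angles travel with their images), with the variance measured the same
way on particle-free background images subtracted off, so the corrected map
reflects conformational differences rather than noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .classify import ClassSet
from .core import ImageStack, VolumeMap
from .reconstruct import _ramp_filter
from .geometry import backproject_one

__all__ = [
    "RadialProfile",
    "VarianceResult",
    "radial_profile_2d",
    "profile_correlation",
    "filter_classes_by_profile",
    "bootstrap_variance",
]


@dataclass
class RadialProfile:
    """Mean intensity per annulus (2-D) or spherical shell (3-D)."""

    bin_centers: np.ndarray  # Å
    intensity: np.ndarray
    source: str = ""


def radial_profile_2d(
    image: np.ndarray,
    center: tuple | None = None,
    pixel_size: float = 1.0,
    bin_width_px: int = 1,
    source: str = "",
) -> RadialProfile:
    """Annular means at ``bin_width_px``-wide bins about ``center``
    (default: box center)."""
    n_y, n_x = image.shape
    if center is None:
        center = ((n_x - 1) / 2.0, (n_y - 1) / 2.0)
    cx, cy = center
    if not (0 <= cx < n_x and 0 <= cy < n_y):
        raise ValueError("center must lie inside the image")
    yy, xx = np.mgrid[:n_y, :n_x]
    r = np.sqrt((xx - cx) ** 2 + (yy - cy) ** 2)
    idx = (r / bin_width_px).astype(int)
    n_bins = idx.max() + 1
    sums = np.bincount(idx.ravel(), image.ravel().astype(np.float64), minlength=n_bins)
    counts = np.bincount(idx.ravel(), minlength=n_bins)
    means = sums / np.maximum(counts, 1)
    centers = (np.arange(n_bins) + 0.5) * bin_width_px * pixel_size
    return RadialProfile(centers, means, source)


def profile_correlation(a: RadialProfile, b: RadialProfile) -> float:
    """Pearson correlation of two radial profiles.

    Profiles with different binning are resampled onto the coarser grid.
    Zero-variance profiles are degenerate: the correlation is undefined and
    reported as 0 (with a warning).
    """
    xa, ya = a.bin_centers, a.intensity
    xb, yb = b.bin_centers, b.intensity
    if len(xa) != len(xb) or not np.allclose(xa, xb):
        if (xa[1] - xa[0]) >= (xb[1] - xb[0]):
            coarse_x, coarse_y = xa, ya
            fine_x, fine_y = xb, yb
        else:
            coarse_x, coarse_y = xb, yb
            fine_x, fine_y = xa, ya
        hi = min(xa[-1], xb[-1])
        keep = coarse_x <= hi
        coarse_x, coarse_y = coarse_x[keep], coarse_y[keep]
        other = np.interp(coarse_x, fine_x, fine_y)
        ya, yb = coarse_y, other
    da = ya - np.mean(ya)
    db = yb - np.mean(yb)
    denom = np.linalg.norm(da) * np.linalg.norm(db)
    if denom == 0:
        warnings.warn("zero-variance radial profile: correlation undefined, returning 0",
                      stacklevel=2)
        return 0.0
    return float(np.dot(da, db) / denom)


def filter_classes_by_profile(
    classes: ClassSet,
    model_projections: np.ndarray,
    threshold: float = 0.2,
    pixel_size: float = 1.0,
    bin_width_px: int = 2,
) -> tuple:
    """Reject classes whose radial profile matches no model projection.

    A class is rejected iff the *maximum* over all projections of the
    profile correlation falls below ``threshold``; all member images of
    rejected classes are removed.  Profiles are computed at 2x-binned
    sampling by default.  Returns ``(kept ClassSet, rejected_image_indices)``.
    """
    if len(model_projections) == 0:
        raise ValueError("empty projection set")
    proj_profiles = [
        radial_profile_2d(p, pixel_size=pixel_size, bin_width_px=bin_width_px)
        for p in model_projections
    ]
    keep_labels, rejected_images = [], []
    for label in range(classes.n_classes):
        prof = radial_profile_2d(classes.class_averages.images[label],
                                 pixel_size=pixel_size, bin_width_px=bin_width_px)
        best = max(profile_correlation(prof, pp) for pp in proj_profiles)
        if best < threshold:
            rejected_images.extend(classes.members(label).tolist())
        else:
            keep_labels.append(label)

    relabel = {old: new for new, old in enumerate(keep_labels)}
    keep_mask = np.isin(classes.assignments, keep_labels)
    new_assign = np.array([relabel.get(l, -1) for l in classes.assignments])
    kept = ClassSet(
        n_classes=len(keep_labels),
        assignments=new_assign,
        class_averages=ImageStack(
            classes.class_averages.images[keep_labels],
            classes.class_averages.pixel_size),
        counts=classes.counts[keep_labels],
        aligned_images=classes.aligned_images,
    )
    del keep_mask
    return kept, sorted(rejected_images)


@dataclass
class VarianceResult:
    """Bootstrap variance maps (raw, background, corrected)."""

    n_bootstrap: int
    mean_map: VolumeMap
    raw_variance_map: VolumeMap
    background_variance_map: VolumeMap
    corrected_variance_map: VolumeMap


def _bootstrap_maps(
    images: np.ndarray, angles: list, counts: np.ndarray,
    pixel_size: float, chunk: int = 32,
) -> tuple:
    """Mean and unbiased variance over reconstructions from multinomial
    resamples.  Exploits linearity: each bootstrap volume is a counts-
    weighted sum of per-image filtered back-projections, so the whole set of
    bootstrap volumes is accumulated with one pass over the images."""
    n_img = len(images)
    n = images.shape[-1]
    n_bootstrap = len(counts)
    vols = np.zeros((n_bootstrap, n * n * n), dtype=np.float32)
    filtered = _ramp_filter(images)
    for start in range(0, n_img, chunk):
        stop = min(start + chunk, n_img)
        block = np.stack([
            backproject_one(filtered[i].astype(np.float32), angles[i]).ravel()
            for i in range(start, stop)
        ])
        vols += (counts[:, start:stop].astype(np.float32) @ block) / n_img
    mean = vols.mean(axis=0)
    var = vols.var(axis=0, ddof=1)
    shape = (n, n, n)
    return (VolumeMap(mean.reshape(shape), pixel_size),
            VolumeMap(var.reshape(shape), pixel_size))


def bootstrap_variance(
    stack: ImageStack,
    angles: list,
    n_bootstrap: int = 200,
    background_stack: ImageStack | None = None,
    seed: int = 0,
) -> VarianceResult:
    """Bootstrap 3-D variance with background-noise variance subtraction.

    ``n_bootstrap`` volumes are reconstructed from with-replacement resamples
    of the image set (orientation assignments travel with their images; they
    are fixed before resampling).  The same procedure on an equally sized
    background-only stack estimates the noise-plus-alignment variance, which
    is subtracted voxelwise; negative values are floored at zero.  The
    background run reuses the particle run's resampling pattern (a paired,
    common-random-numbers design), so identical inputs cancel exactly and
    the subtraction carries no extra Monte-Carlo error.
    """
    if n_bootstrap < 2:
        raise ValueError("n_bootstrap must be at least 2")
    if len(angles) != len(stack):
        raise ValueError("angles must be fixed per image before resampling")
    rng = np.random.default_rng(seed)
    n_img = len(stack)
    counts = rng.multinomial(n_img, np.full(n_img, 1.0 / n_img), size=n_bootstrap)
    mean_map, raw_var = _bootstrap_maps(
        stack.images, angles, counts, stack.pixel_size)
    if background_stack is not None:
        if len(background_stack) != len(stack):
            raise ValueError("background stack must have the same number of images")
        _, bg_var = _bootstrap_maps(
            background_stack.images, angles, counts, stack.pixel_size)
    else:
        bg_var = VolumeMap(np.zeros_like(raw_var.data), stack.pixel_size)
    corrected = np.maximum(raw_var.data - bg_var.data, 0.0)
    return VarianceResult(
        n_bootstrap=n_bootstrap,
        mean_map=mean_map,
        raw_variance_map=raw_var,
        background_variance_map=bg_var,
        corrected_variance_map=VolumeMap(corrected, stack.pixel_size),
    )
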
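"""Reference-free 2-D classification into class averages.

The multivariate route: images are centered and rotationally aligned to the
(iteratively re-estimated) global mean, circularly masked, projected onto the
leading principal components, and clustered with k-means.  Initial centers
are drawn at quantiles of principal-axis projections, which makes the
partition a function of the image *set* rather than of the input order;
k-means is restarted once per leading axis (best of up to 10 restarts by
within-class sum of squares).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .align import align_stack_to_reference, apply_alignment
from .core import ImageStack

__all__ = ["ClassSet", "classify_reference_free"]


@dataclass
class ClassSet:
    """Result of reference-free classification."""

    n_classes: int
    assignments: np.ndarray  # image_index -> class label
    class_averages: ImageStack
    counts: np.ndarray
    aligned_images: np.ndarray | None = None

    def members(self, label: int) -> np.ndarray:
        return np.flatnonzero(self.assignments == label)


def _circular_mask(n: int, radius_frac: float = 0.45) -> np.ndarray:
    c = (n - 1) / 2.0
    yy, xx = np.mgrid[:n, :n]
    return ((yy - c) ** 2 + (xx - c) ** 2) <= (radius_frac * n) ** 2


def classify_reference_free(
    stack: ImageStack,
    n_classes: int,
    n_components: int = 20,
    seed: int = 0,
    rotation_step: float = 5.0,
    n_align_rounds: int = 2,
    mask: bool = True,
) -> ClassSet:
    """Cluster a (preprocessed) stack into ``n_classes`` class averages.

    Deterministic under a fixed seed; the partition is invariant to input
    order up to relabeling.
    """
    n_images = len(stack)
    if n_classes > n_images:
        raise ValueError(f"n_classes ({n_classes}) exceeds number of images ({n_images})")
    images = stack.images.astype(np.float64)
    n = images.shape[-1]

    aligned = images
    reference = aligned.mean(axis=0)
    for _ in range(n_align_rounds):
        results = align_stack_to_reference(aligned, reference, rotation_step=rotation_step)
        aligned = np.stack([apply_alignment(img, r) for img, r in zip(images, results)])
        reference = aligned.mean(axis=0)

    m = _circular_mask(n) if mask else np.ones((n, n), bool)
    flat = aligned[:, m]
    flat = flat - flat.mean(axis=0, keepdims=True)

    n_components = min(n_components, n_images - 1, flat.shape[1])
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(flat)

    best_labels, best_inertia = None, np.inf
    n_restarts = min(10, n_components)
    for axis in range(n_restarts):
        order = np.argsort(scores[:, axis], kind="stable")
        qs = (np.arange(n_classes) + 0.5) / n_classes
        init_idx = order[np.minimum((qs * n_images).astype(int), n_images - 1)]
        km = KMeans(n_clusters=n_classes, init=scores[init_idx], n_init=1,
                    random_state=seed, max_iter=300)
        labels = km.fit_predict(scores)
        if km.inertia_ < best_inertia and len(np.unique(labels)) == n_classes:
            best_inertia, best_labels = km.inertia_, labels
    if best_labels is None:  # all restarts collapsed a cluster; fall back
        km = KMeans(n_clusters=n_classes, n_init=10, random_state=seed)
        best_labels = km.fit_predict(scores)

    averages = np.zeros((n_classes, n, n), dtype=np.float32)
    counts = np.zeros(n_classes, dtype=int)
    for label in range(n_classes):
        idx = np.flatnonzero(best_labels == label)
        counts[label] = len(idx)
        if len(idx):
            averages[label] = aligned[idx].mean(axis=0)

    avg_stack = ImageStack(averages, stack.pixel_size)
    return ClassSet(n_classes, np.asarray(best_labels), avg_stack, counts,
                    aligned_images=aligned.astype(np.float32))
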
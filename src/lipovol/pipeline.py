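"""End-to-end single-particle reconstruction pipeline.

Chains the per-image corrections, reference-free classification, common-
lines initial model, radial-profile class filtering and projection-matching
refinement.  Two image versions are threaded throughout: the denoised stack
drives every classification/alignment decision, while the final
reconstructions consume only the non-denoised (phase-flipped) pixels.
One dataset per run: datasets from different conditions (e.g. the two
vitrification temperatures) are never pooled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .classify import ClassSet, classify_reference_free
from .core import ImageStack, VolumeMap
from .heterogeneity import filter_classes_by_profile
from .preprocess import denoise_stack, phase_flip_stack
from .reconstruct import (RefinementState, assign_angles_common_lines,
                          backproject_weighted, low_pass, projection_grid,
                          refine, project)

__all__ = ["PipelineConfig", "PipelineResult", "reconstruct_dataset",
           "initial_model_from_classes"]


@dataclass
class PipelineConfig:
    """Tunable parameters of the reconstruction pipeline."""

    n_classes: int = 50
    n_components: int = 20
    n_iterations: int = 3
    retention_fraction: float = 0.75
    angular_step: float = 15.0
    initial_lowpass_A: float = 60.0
    profile_filter_threshold: float = 0.2
    common_lines_step: float = 3.0
    seed: int = 0
    apply_profile_filter: bool = True


@dataclass
class PipelineResult:
    volume: VolumeMap
    history: list
    classes: ClassSet
    initial_volume: VolumeMap
    rejected_images: list
    final_used_nondenoised: bool = True


def initial_model_from_classes(
    classes: ClassSet, pixel_size: float, config: PipelineConfig
) -> VolumeMap:
    """Common-lines angles on the class averages, weighted back-projection,
    then a low-pass filter to the configured starting resolution."""
    angles, _scores = assign_angles_common_lines(
        classes.class_averages, angular_step=config.common_lines_step)
    vol = backproject_weighted(classes.class_averages.images, angles, pixel_size)
    return low_pass(vol, config.initial_lowpass_A)


def reconstruct_dataset(
    stack: ImageStack,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Run the full reconstruction pipeline on one particle stack."""
    config = config or PipelineConfig()
    flipped = phase_flip_stack(stack)
    denoised, _models = denoise_stack(flipped)

    classes = classify_reference_free(
        denoised, n_classes=min(config.n_classes, len(stack)),
        n_components=config.n_components, seed=config.seed)

    initial = initial_model_from_classes(classes, stack.pixel_size, config)

    rejected: list = []
    if config.apply_profile_filter:
        model_projections = np.stack(
            [project(initial, d) for d in projection_grid(30.0)])
        classes, rejected = filter_classes_by_profile(
            classes, model_projections,
            threshold=config.profile_filter_threshold,
            pixel_size=stack.pixel_size)
        if rejected:
            keep = np.setdiff1d(np.arange(len(stack)), rejected)
            if len(keep) < 10:
                warnings.warn("profile filter would reject nearly the whole "
                              "dataset; skipping rejection", stacklevel=2)
            else:
                flipped = flipped.subset(keep)
                denoised = denoised.subset(keep)

    history = refine(
        flipped, denoised, initial,
        n_iterations=config.n_iterations,
        retention_fraction=config.retention_fraction,
        seed=config.seed,
        angular_step=config.angular_step,
    )
    return PipelineResult(
        volume=history[-1].volume,
        history=history,
        classes=classes,
        initial_volume=initial,
        rejected_images=rejected,
        final_used_nondenoised=True,
    )
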
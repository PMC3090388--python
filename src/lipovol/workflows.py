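"""Turn-key experiments on synthetic phantoms.

Each function generates its inputs with the synthetic-data module's default
conditions, runs the relevant slice of the pipeline, and returns the
headline numbers.  Problem sizes are chosen to run in minutes on one CPU
(64³ boxes at 5.0 Å/voxel for reconstruction experiments, 128³ at 2.8 Å for
map-analysis experiments).
"""

from __future__ import annotations

import numpy as np

from .dataset import make_dataset
from .map_analysis import (layer_spacing, profile_convergence_radius,
                           radial_profile_3d, segment_components,
                           threshold_mass)
from .phantom import (PopulationSpec, analysis_phantom_spec,
                      default_phantom_spec, make_phantom, sample_population)
from .pipeline import PipelineConfig, reconstruct_dataset

__all__ = [
    "layer_spacing_experiment",
    "mass_threshold_experiment",
    "segmentation_experiment",
    "population_experiment",
    "classification_experiment",
    "core_contrast_experiment",
]


def _reconstruct(stack, seed, n_iterations=2):
    config = PipelineConfig(n_classes=min(50, max(2, len(stack) // 40)),
                            n_iterations=n_iterations, seed=seed)
    return reconstruct_dataset(stack, config)


def layer_spacing_experiment(seed: int = 1, n_projections: int = 2000,
                             n_iterations: int = 2) -> dict:
    """Recover the smectic core layer spacing from a reconstruction of the
    default ordered-core phantom (CTF + noise, full pipeline)."""
    spec = default_phantom_spec("ordered")
    stack, _bg = make_dataset([spec], n_projections, seed=seed)
    result = _reconstruct(stack, seed, n_iterations)
    profile = radial_profile_3d(result.volume)
    spacing = layer_spacing(profile, spec.core_radius)
    return dict(spacing_A=float(spacing), n=n_projections,
                generator_spacing_A=spec.layer_spacing,
                volume=result.volume, profile=profile)


def mass_threshold_experiment(target_mass_kda: float = 550.0) -> dict:
    """Round trip of the mass-based threshold on the analysis-scale default
    shell phantom (2.8 Å voxels)."""
    volume = make_phantom(analysis_phantom_spec())
    spec = threshold_mass(volume, target_mass_kda)
    return dict(achieved_mass_kda=float(spec.achieved_mass_kda),
                n=int(spec.n_voxels), threshold=spec.resolved_intensity)


def segmentation_experiment(target_mass_kda: float = 550.0) -> dict:
    """Mass-threshold segmentation of the default 4-domain shell phantom."""
    volume = make_phantom(analysis_phantom_spec())
    spec = threshold_mass(volume, target_mass_kda)
    seg = segment_components(volume, spec)
    return dict(n_segments=int(seg.n_segments), n=int(spec.n_voxels),
                masses_kda=seg.masses_kda.tolist())


def population_experiment(seed: int = 1, n_particles: int = 1000) -> dict:
    """Sample the default diameter population; mean reported in nm."""
    pop = PopulationSpec(n_particles=n_particles, seed=seed)
    specs = sample_population(pop)
    d = np.array([s.particle_diameter for s in specs])
    return dict(mean_diameter_nm=float(d.mean() / 10.0), n=n_particles,
                min_nm=float(d.min() / 10.0), max_nm=float(d.max() / 10.0))


def classification_experiment(seed: int = 1, n_images: int = 3000,
                              n_classes: int = 50) -> dict:
    """Reference-free classification of simulated images with the standard
    initial setting (50 classes)."""
    from .classify import classify_reference_free
    from .preprocess import denoise_stack, phase_flip_stack

    spec = default_phantom_spec("ordered")
    stack, _bg = make_dataset([spec], n_images, seed=seed)
    denoised, _ = denoise_stack(phase_flip_stack(stack))
    classes = classify_reference_free(denoised, n_classes=n_classes, seed=seed)
    return dict(n_class_averages=int(len(classes.class_averages.images)),
                n=n_images, counts=classes.counts.tolist())


def core_contrast_experiment(seed: int = 1, n_phantoms: int = 20,
                             n_projections_per_phantom: int = 100,
                             n_iterations: int = 2) -> dict:
    """Ordered vs disordered core contrast: reconstruct matched populations
    and report the radius where their scaled radial profiles converge.

    The two populations share the same sampled diameters (same seed), so the
    only difference is core organization.
    """
    template = default_phantom_spec()
    pop = PopulationSpec(n_particles=n_phantoms, seed=seed)
    base = sample_population(pop, template)
    profiles = {}
    for mode in ("ordered", "disordered"):
        from dataclasses import replace

        specs = [replace(s, core_mode=mode) for s in base]
        stack, _bg = make_dataset(specs, n_projections_per_phantom, seed=seed + 1)
        result = _reconstruct(stack, seed, n_iterations)
        profiles[mode] = radial_profile_3d(result.volume, scaled=True)
    radius = profile_convergence_radius(profiles["ordered"], profiles["disordered"])
    return dict(convergence_radius_A=float(radius),
                n=n_phantoms * n_projections_per_phantom,
                core_radius_A=template.core_radius, profiles=profiles)
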
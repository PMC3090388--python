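"""Simulated particle datasets: projections with CTF and noise, plus
matched background-only stacks for noise-variance estimation."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import ImageStack, OrientationAngles
from .ctf import CTFParams, apply_ctf_and_noise
from .geometry import project, uniform_orientations
from .phantom import PhantomSpec, make_phantom

__all__ = ["make_dataset", "DEFAULT_NOISE_SD", "DEFAULT_CTF_RANGE"]

#: Default additive white-noise SD in projection units; calibrated so that
#: class averages at ~60 images/class resolve the phantom shell (the source
#: micrograph noise level is not otherwise constrained).
DEFAULT_NOISE_SD = 5.0

#: Defocus range in µm sampled uniformly per image.
DEFAULT_CTF_RANGE = (1.5, 4.7)


def make_dataset(
    phantoms: list,
    n_projections_per_phantom: int,
    ctf_range: tuple = DEFAULT_CTF_RANGE,
    noise_sd: float = DEFAULT_NOISE_SD,
    seed: int = 0,
    ctf_template: CTFParams | None = None,
) -> tuple:
    """Simulate a particle stack and a same-sized background stack.

    Orientations are uniform over SO(3), defocus uniform over ``ctf_range``;
    true orientations are retained in the metadata for validation only.
    Returns ``(particle_stack, background_stack)``.
    """
    if not phantoms:
        raise ValueError("need at least one phantom")
    phantoms = [p if isinstance(p, PhantomSpec) else p for p in phantoms]
    pixel_size = phantoms[0].voxel_size
    box = phantoms[0].box_size
    rng = np.random.default_rng(seed)

    n_total = len(phantoms) * n_projections_per_phantom
    images = np.zeros((n_total, box, box), dtype=np.float32)
    rows = []
    k = 0
    for pid, spec in enumerate(phantoms):
        if spec.box_size != box or spec.voxel_size != pixel_size:
            raise ValueError("all phantoms must share box size and voxel size")
        volume = make_phantom(spec)
        orientations = uniform_orientations(n_projections_per_phantom, rng)
        defoci = rng.uniform(ctf_range[0], ctf_range[1], n_projections_per_phantom)
        for ang, dz in zip(orientations, defoci):
            clean = project(volume, ang)
            ctf = _with_defocus(ctf_template, float(dz))
            images[k] = apply_ctf_and_noise(clean, ctf, pixel_size, noise_sd, rng)
            rows.append(
                dict(
                    image_index=k, rot=ang.rot, tilt=ang.tilt, psi=ang.psi,
                    defocus_um=float(dz), is_background=False,
                    phantom_id=pid, core_mode=spec.core_mode,
                    diameter=spec.particle_diameter,
                )
            )
            k += 1

    meta = _meta_frame(rows, box)
    stack = ImageStack(images, pixel_size, meta)

    bg_images = rng.normal(0.0, noise_sd, (n_total, box, box)).astype(np.float32) \
        if n_total else np.zeros((0, box, box), dtype=np.float32)
    bg_rows = [
        dict(image_index=i, rot=0.0, tilt=0.0, psi=0.0,
             defocus_um=0.0, is_background=True, phantom_id=-1,
             core_mode="none", diameter=0.0)
        for i in range(n_total)
    ]
    bg_stack = ImageStack(bg_images, pixel_size, _meta_frame(bg_rows, box))
    return stack, bg_stack


def _with_defocus(template: CTFParams | None, defocus_um: float) -> CTFParams:
    if template is None:
        return CTFParams(defocus_um=defocus_um)
    return CTFParams(
        defocus_um=defocus_um,
        voltage_kv=template.voltage_kv,
        cs_mm=template.cs_mm,
        amplitude_contrast=template.amplitude_contrast,
    )


def _meta_frame(rows: list, box: int) -> pd.DataFrame:
    if rows:
        return pd.DataFrame(rows)
    return pd.DataFrame(
        columns=[
            "image_index", "rot", "tilt", "psi", "defocus_um",
            "is_background", "phantom_id", "core_mode", "diameter",
        ]
    )
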
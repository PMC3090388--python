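"""Per-image corrections applied before classification.

Two operations: CTF phase flipping (sign correction only, amplitudes
untouched) and a minimum-description-length denoiser.  The denoiser hard-
thresholds coefficients of an orthogonal wavelet transform, choosing the
per-image threshold by a two-part code length (bits to describe the retained
coefficients plus a Gaussian code for the residual).  Denoised images are
used only for classification and alignment decisions; final reconstructions
always consume the non-denoised pixels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt

from .core import ImageStack
from .ctf import CTFParams, ctf_2d

__all__ = ["DenoiseModel", "phase_flip", "denoise", "denoise_stack", "phase_flip_stack"]

_WAVELET = "db4"
_MODE = "periodization"  # orthogonal: Parseval holds, energy can only drop


@dataclass
class DenoiseModel:
    """Record of the transform and the per-image threshold that was chosen."""

    transform: str
    threshold_rule: str
    threshold: float
    n_detail_coeffs: int
    n_retained: int


def phase_flip(image: np.ndarray, ctf: CTFParams, pixel_size: float) -> np.ndarray:
    """Flip the sign of Fourier coefficients where the CTF is negative.

    An involution: applying it twice with the same CTF restores the input.
    Power spectra are preserved exactly (|F_out| = |F_in|).
    """
    if pixel_size is None or pixel_size <= 0:
        raise ValueError("phase_flip needs a known positive pixel size (CTF is in physical frequency units)")
    h = ctf_2d(ctf, image.shape, pixel_size)
    sign = np.where(h < 0, -1.0, 1.0)
    return np.fft.ifft2(np.fft.fft2(image) * sign).real.astype(np.float32)


def denoise(image: np.ndarray) -> tuple:
    """MDL-thresholded wavelet denoising.

    Detail coefficients of an orthogonal db4 decomposition are hard-
    thresholded; the number of retained coefficients k minimizes the
    two-part description length

        L(k) = 1.5 k log2 N + (N/2) log2(RSS(k) / N),

    where RSS(k) is the energy of the discarded coefficients.  The
    approximation band is always kept.  Returns ``(denoised, DenoiseModel)``.
    """
    image = np.asarray(image, dtype=np.float64)
    if not np.all(np.isfinite(image)):
        raise ValueError("denoise requires finite-valued input")
    max_level = pywt.dwtn_max_level(image.shape, _WAVELET)
    level = min(4, max_level)
    if level < 1:
        return image.astype(np.float32), DenoiseModel(_WAVELET, "mdl", 0.0, 0, 0)
    coeffs = pywt.wavedec2(image, _WAVELET, mode=_MODE, level=level)
    detail = np.concatenate([np.ravel(a) for lvl in coeffs[1:] for a in lvl])
    n = detail.size

    mags = np.sort(np.abs(detail))[::-1]
    energy = mags**2
    total = energy.sum()
    # RSS(k): residual energy after keeping the k largest coefficients
    rss = total - np.concatenate([[0.0], np.cumsum(energy)])[:-1]  # k = 0..n-1
    eps = max(total, 1.0) * 1e-12
    k_grid = np.arange(n)
    cost = 1.5 * k_grid * np.log2(n) + 0.5 * n * np.log2((rss + eps) / n)
    k_best = int(np.argmin(cost))
    threshold = float(mags[k_best - 1]) if k_best > 0 else float(mags[0]) + 1.0 if n else 0.0

    out_coeffs = [coeffs[0]]
    for lvl in coeffs[1:]:
        out_coeffs.append(tuple(np.where(np.abs(a) >= threshold, a, 0.0) for a in lvl))
    denoised = pywt.waverec2(out_coeffs, _WAVELET, mode=_MODE)
    denoised = denoised[: image.shape[0], : image.shape[1]]
    model = DenoiseModel(_WAVELET + "-" + _MODE, "mdl-two-part", threshold, n, k_best)
    return denoised.astype(np.float32), model


def phase_flip_stack(stack: ImageStack, ctf_template: CTFParams | None = None) -> ImageStack:
    """Phase flip every image of a stack using its metadata defocus."""
    out = np.empty_like(stack.images)
    for i, row in enumerate(stack.metadata.itertuples()):
        ctf = CTFParams(defocus_um=max(float(row.defocus_um), 0.0)) \
            if ctf_template is None else CTFParams(
                defocus_um=max(float(row.defocus_um), 0.0),
                voltage_kv=ctf_template.voltage_kv,
                cs_mm=ctf_template.cs_mm,
                amplitude_contrast=ctf_template.amplitude_contrast,
            )
        out[i] = phase_flip(stack.images[i], ctf, stack.pixel_size)
    return ImageStack(out, stack.pixel_size, stack.metadata.copy())


def denoise_stack(stack: ImageStack) -> tuple:
    """Denoise every image; returns ``(denoised_stack, list of DenoiseModel)``."""
    out = np.empty_like(stack.images)
    models = []
    for i in range(len(stack)):
        out[i], model = denoise(stack.images[i])
        models.append(model)
    return ImageStack(out, stack.pixel_size, stack.metadata.copy()), models
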
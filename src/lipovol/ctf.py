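"""Contrast transfer function model and simulation.

CTF(f) = -[sqrt(1 - A^2) sin chi + A cos chi] with
chi(f) = pi lambda dz f^2 - (pi/2) Cs lambda^3 f^4, underfocus positive.
The first zero sits at chi = pi.  Constants default to standard 200 kV
FEG-TEM values (Cs 2.0 mm, amplitude contrast 0.07).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["CTFParams", "apply_ctf_and_noise", "ctf_2d", "ctf_1d", "electron_wavelength"]


def electron_wavelength(voltage_kv: float) -> float:
    """Relativistic electron wavelength in Å (0.02508 Å at 200 kV)."""
    v = voltage_kv * 1e3
    return 12.2643 / np.sqrt(v * (1.0 + 0.978476e-6 * v))


@dataclass
class CTFParams:
    """Per-image CTF parameters (defocus in µm, underfocus positive)."""

    defocus_um: float
    voltage_kv: float = 200.0
    cs_mm: float = 2.0
    amplitude_contrast: float = 0.07

    def __post_init__(self) -> None:
        if self.defocus_um < 0:
            raise ValueError("defocus must be non-negative (underfocus positive)")
        if not 0.0 <= self.amplitude_contrast <= 1.0:
            raise ValueError("amplitude_contrast must lie in [0, 1]")

    @property
    def wavelength(self) -> float:
        return electron_wavelength(self.voltage_kv)

    def chi(self, f: np.ndarray) -> np.ndarray:
        """Aberration phase at spatial frequency f (1/Å)."""
        lam = self.wavelength
        dz = self.defocus_um * 1e4  # µm -> Å
        cs = self.cs_mm * 1e7  # mm -> Å
        f2 = np.square(f)
        return np.pi * lam * dz * f2 - 0.5 * np.pi * cs * lam**3 * f2 * f2

    def evaluate(self, f: np.ndarray) -> np.ndarray:
        a = self.amplitude_contrast
        chi = self.chi(f)
        return -(np.sqrt(1.0 - a * a) * np.sin(chi) + a * np.cos(chi))


def ctf_1d(ctf: CTFParams, f: np.ndarray) -> np.ndarray:
    return ctf.evaluate(np.asarray(f, dtype=float))


def ctf_2d(ctf: CTFParams, shape: tuple, pixel_size: float) -> np.ndarray:
    """CTF sampled on the 2-D FFT frequency grid of an image."""
    fy = np.fft.fftfreq(shape[0], d=pixel_size)
    fx = np.fft.fftfreq(shape[1], d=pixel_size)
    f = np.sqrt(fy[:, None] ** 2 + fx[None, :] ** 2)
    return ctf.evaluate(f)


def apply_ctf_and_noise(
    image: np.ndarray,
    ctf: CTFParams,
    pixel_size: float,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Multiply the image's Fourier transform by the CTF, add white noise.

    Seeded and reproducible: identical (image, ctf, noise_sd, seed) give
    bit-identical output.
    """
    h = ctf_2d(ctf, image.shape, pixel_size)
    out = np.fft.ifft2(np.fft.fft2(image) * h).real
    if noise_sd > 0:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        out = out + rng.normal(0.0, noise_sd, image.shape)
    return out.astype(np.float32)
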
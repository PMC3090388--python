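"""2-D image alignment primitives.

Two paths: an explicit rotation-grid search used for pairwise alignment
(``align_pairwise``), and a fast resampled-to-polar FFT correlator used when
many images must be matched against many references (classification rounds,
projection matching during refinement).  All correlations are normalized
(zero-mean, unit-norm), so scores live in [-1, 1] up to interpolation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = ["AlignResult", "align_pairwise", "align_stack_to_reference",
           "polar_resample", "match_stack_to_references"]


@dataclass
class AlignResult:
    shift_x: float
    shift_y: float
    rotation: float
    correlation: float
    degenerate: bool = False


def _norm(image: np.ndarray) -> np.ndarray:
    x = image - image.mean()
    n = np.linalg.norm(x)
    return x / n if n > 0 else x


def _rotate2d(image: np.ndarray, angle_deg: float) -> np.ndarray:
    return ndimage.rotate(image, angle_deg, reshape=False, order=1,
                          mode="constant", cval=0.0, prefilter=False)


def align_pairwise(
    image: np.ndarray,
    reference: np.ndarray,
    rotation_step: float = 5.0,
    max_shift: int | None = None,
) -> AlignResult:
    """Rotation/translation maximizing normalized cross-correlation.

    Searches in-plane rotations on a ``rotation_step`` grid and integer
    shifts within ±``max_shift`` (default box/4).  The returned transform is
    the one to apply to ``image`` (rotate, then shift) to match
    ``reference``.  Zero-variance inputs are flagged and scored 0.
    """
    if image.shape != reference.shape:
        raise ValueError("image and reference must have equal dimensions")
    if image.std() == 0 or reference.std() == 0:
        return AlignResult(0.0, 0.0, 0.0, 0.0, degenerate=True)
    n = image.shape[0]
    max_shift = max_shift if max_shift is not None else n // 4
    ref_f = np.conj(np.fft.fft2(_norm(reference)))
    best = AlignResult(0.0, 0.0, 0.0, -np.inf)
    angles = np.arange(0.0, 360.0, rotation_step)
    for a in angles:
        rot = _norm(_rotate2d(image, a))
        cc = np.fft.ifft2(np.fft.fft2(rot) * ref_f).real
        cc = np.fft.fftshift(cc)
        c0 = n // 2
        win = cc[c0 - max_shift: c0 + max_shift + 1, c0 - max_shift: c0 + max_shift + 1]
        iy, ix = np.unravel_index(np.argmax(win), win.shape)
        score = float(win[iy, ix])
        if score > best.correlation:
            # correlation peak at displacement d means the rotated image is the
            # reference shifted by +d, so the aligning shift is -d
            rot = float(a if a <= 180.0 else a - 360.0)
            best = AlignResult(float(max_shift - ix), float(max_shift - iy), rot, score)
    return best


def apply_alignment(image: np.ndarray, result: AlignResult) -> np.ndarray:
    """Apply the transform found by :func:`align_pairwise` to ``image``."""
    rot = _rotate2d(image, result.rotation)
    return ndimage.shift(rot, (result.shift_y, result.shift_x), order=1,
                         mode="constant", cval=0.0, prefilter=False)


def align_stack_to_reference(
    images: np.ndarray,
    reference: np.ndarray,
    rotation_step: float = 5.0,
    max_shift: int | None = None,
) -> list:
    """Batch variant of :func:`align_pairwise` against one fixed reference.

    Rotates the *reference* once per grid angle instead of every image, which
    is equivalent for the correlation maximum (shifts are rotated back into
    the image frame).
    """
    n = images.shape[-1]
    max_shift = max_shift if max_shift is not None else n // 4
    c0 = n // 2
    angles = np.arange(0.0, 360.0, rotation_step)
    if reference.std() == 0:
        return [AlignResult(0.0, 0.0, 0.0, 0.0, degenerate=True) for _ in images]
    refs_f = np.stack(
        [np.conj(np.fft.fft2(_norm(_rotate2d(reference, -a)))) for a in angles]
    )
    results = []
    for img in images:
        if img.std() == 0:
            results.append(AlignResult(0.0, 0.0, 0.0, 0.0, degenerate=True))
            continue
        f = np.fft.fft2(_norm(img))
        cc = np.fft.fftshift(np.fft.ifft2(f[None] * refs_f).real, axes=(1, 2))
        win = cc[:, c0 - max_shift: c0 + max_shift + 1, c0 - max_shift: c0 + max_shift + 1]
        k, iy, ix = np.unravel_index(np.argmax(win), win.shape)
        a = angles[k]
        # aligning shift in the unrotated frame, rotated into the frame of the
        # rotated image (array rows grow downward, hence the sign pattern)
        dy, dx = float(max_shift - iy), float(max_shift - ix)
        ca, sa = np.cos(np.radians(a)), np.sin(np.radians(a))
        dxr = ca * dx + sa * dy
        dyr = -sa * dx + ca * dy
        rot = float(a if a <= 180.0 else a - 360.0)
        results.append(AlignResult(dxr, dyr, rot, float(win[k, iy, ix])))
    return results


def polar_resample(
    images: np.ndarray, n_theta: int = 36, n_r: int | None = None,
    r_min: float = 2.0, r_max: float | None = None,
) -> np.ndarray:
    """Resample images onto a polar (theta, r) grid about the box center."""
    single = images.ndim == 2
    if single:
        images = images[None]
    n = images.shape[-1]
    r_max = r_max if r_max is not None else 0.45 * n
    n_r = n_r if n_r is not None else int(r_max - r_min)
    thetas = np.linspace(0.0, 2 * np.pi, n_theta, endpoint=False)
    radii = np.linspace(r_min, r_max, n_r)
    c = (n - 1) / 2.0
    ys = c + radii[None, :] * np.sin(thetas[:, None])
    xs = c + radii[None, :] * np.cos(thetas[:, None])
    coords = np.stack([ys, xs])
    out = np.stack(
        [ndimage.map_coordinates(img, coords, order=1, mode="constant", cval=0.0)
         for img in images]
    )
    return out[0] if single else out


def match_stack_to_references(
    images: np.ndarray,
    references: np.ndarray,
    n_theta: int = 36,
) -> tuple:
    """Best reference and in-plane rotation per image by polar correlation.

    Returns ``(ref_index, delta_deg, correlation)`` arrays where rotating the
    matched reference by ``delta_deg`` (counterclockwise, image convention)
    best overlays the image.  Normalized scores in [-1, 1].
    """
    pol_i = polar_resample(images, n_theta=n_theta)
    pol_r = polar_resample(references, n_theta=n_theta)

    def _normalize(p):
        p = p - p.mean(axis=(1, 2), keepdims=True)
        nrm = np.sqrt((p**2).sum(axis=(1, 2), keepdims=True))
        nrm[nrm == 0] = 1.0
        return p / nrm

    pol_i = _normalize(pol_i)
    pol_r = _normalize(pol_r)
    fi = np.fft.rfft(pol_i, axis=1)  # (N, T/2+1, R)
    fr = np.fft.rfft(pol_r, axis=1)  # (M, T/2+1, R)
    nt = pol_i.shape[1]
    # cross-power summed over radius, correlation over the theta circle
    cross = np.empty((len(images), len(references), fi.shape[1]), dtype=complex)
    for t in range(fi.shape[1]):
        cross[:, :, t] = np.conj(fi[:, t, :]) @ fr[:, t, :].T
    corr = np.fft.irfft(cross, n=nt, axis=2)  # (N, M, T)
    flat = corr.reshape(len(images), -1)
    best = np.argmax(flat, axis=1)
    m_idx, t_idx = np.unravel_index(best, (len(references), nt))
    delta = t_idx * (360.0 / nt)
    return m_idx, delta, flat[np.arange(len(images)), best]


def estimate_shift(image: np.ndarray, reference: np.ndarray, max_shift: int = 4) -> tuple:
    """Integer displacement (dx, dy) of ``image`` relative to ``reference``
    (image ≈ reference shifted by the returned amount), found by windowed
    circular cross-correlation."""
    n = image.shape[0]
    c0 = n // 2
    cc = np.fft.fftshift(
        np.fft.ifft2(np.fft.fft2(_norm(image)) * np.conj(np.fft.fft2(_norm(reference)))).real
    )
    win = cc[c0 - max_shift: c0 + max_shift + 1, c0 - max_shift: c0 + max_shift + 1]
    iy, ix = np.unravel_index(np.argmax(win), win.shape)
    return float(ix - max_shift), float(iy - max_shift)
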
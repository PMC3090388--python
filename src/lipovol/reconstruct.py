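"""Orientation assignment, weighted back-projection, refinement, FSC.

Conventions (fixed package-wide, see geometry module):
``R = Rz(rot) Ry(tilt) Rz(psi)`` intrinsic ZYZ, volume rotated actively by
``R^T``, projection along +z.  A 3-D point q appears in the projection at
``((R^T q)_x, (R^T q)_y)``, so the image frame vectors are the columns of
R: ``e1 = R x, e2 = R y``, and the viewing direction is ``d = R z``.

A sinogram row at angle theta is the 1-D projection of the image onto the
in-plane direction ``u(theta) = (cos theta, sin theta)``; by the central
slice theorem two projections of the same volume agree along their common
line ``u_ij ∝ d_i x d_j``, which is what the cross-common-lines search
exploits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, optimize

from .align import estimate_shift, match_stack_to_references, _rotate2d
from .core import ImageStack, OrientationAngles, VolumeMap
from .geometry import backproject_one, euler_to_matrix, matrix_to_euler, project

__all__ = [
    "sinogram",
    "assign_angles_common_lines",
    "backproject_weighted",
    "refine",
    "RefinementState",
    "fsc",
    "resolution_at",
    "low_pass",
    "projection_grid",
    "tilt_pair_hand_check",
]


# ---------------------------------------------------------------------------
# sinograms and common lines

def sinogram(image: np.ndarray, angular_step: float = 2.0) -> np.ndarray:
    """1-D line projections of a square image; one row per angle in
    [0, 180) on an ``angular_step`` grid.

    Row theta is the distribution of image mass projected onto the direction
    (cos theta, sin theta); bin t runs over the image width about the center.
    """
    if image.shape[0] != image.shape[1]:
        raise ValueError("sinogram requires a square image")
    n = image.shape[0]
    thetas = np.radians(np.arange(0.0, 180.0, angular_step))
    c = (n - 1) / 2.0
    t = np.arange(n) - c
    s = np.arange(n) - c
    rows = np.empty((len(thetas), n), dtype=np.float64)
    for i, th in enumerate(thetas):
        ux, uy = np.cos(th), np.sin(th)
        # position = center + t*u + s*v, v = (-sin, cos)
        xs = c + t[:, None] * ux - s[None, :] * uy
        ys = c + t[:, None] * uy + s[None, :] * ux
        vals = ndimage.map_coordinates(image, [ys, xs], order=1,
                                       mode="constant", cval=0.0)
        rows[i] = vals.sum(axis=1)
    return rows


def _sinogram_360(image: np.ndarray, angular_step: float) -> np.ndarray:
    half = sinogram(image, angular_step)
    return np.concatenate([half, half[:, ::-1]], axis=0)


def _normalize_rows(sino: np.ndarray) -> np.ndarray:
    x = sino - sino.mean(axis=1, keepdims=True)
    nrm = np.linalg.norm(x, axis=1, keepdims=True)
    nrm[nrm == 0] = 1.0
    return x / nrm


def _bilinear_periodic(c: np.ndarray, a_deg, b_deg, step: float):
    """Bilinearly interpolate the pairwise line-correlation table C (square,
    360-periodic in both axes, sampled every ``step`` degrees)."""
    n = c.shape[0]
    ia = np.asarray(a_deg) / step
    ib = np.asarray(b_deg) / step
    i0, j0 = np.floor(ia).astype(int), np.floor(ib).astype(int)
    fa, fb = ia - i0, ib - j0
    i0, j0 = i0 % n, j0 % n
    i1, j1 = (i0 + 1) % n, (j0 + 1) % n
    return ((1 - fa) * (1 - fb) * c[i0, j0] + fa * (1 - fb) * c[i1, j0]
            + (1 - fa) * fb * c[i0, j1] + fa * fb * c[i1, j1])


def _frame_from_common_line(u: np.ndarray, d: np.ndarray, alpha_deg: float) -> np.ndarray:
    """Rotation matrix R with viewing direction d (rows convention) such that
    the 3-D line u appears in the image at in-plane angle alpha."""
    a = np.radians(alpha_deg)
    e1 = np.cos(a) * u - np.sin(a) * np.cross(d, u)
    e2 = np.cross(d, e1)
    return np.stack([e1, e2, d])  # rows: R^T x = e1 etc.


def _predicted_line_angles(r_i: np.ndarray, r_j: np.ndarray) -> tuple:
    d_i, d_j = r_i[2], r_j[2]
    u = np.cross(d_i, d_j)
    nu = np.linalg.norm(u)
    if nu < 1e-9:
        return None
    u = u / nu
    a_i = np.degrees(np.arctan2(u @ r_i[1], u @ r_i[0])) % 360.0
    a_j = np.degrees(np.arctan2(u @ r_j[1], u @ r_j[0])) % 360.0
    return a_i, a_j


def _pair_score(mats: list, cmats: dict, k: int, others, step: float) -> float:
    total = 0.0
    for m in others:
        pred = _predicted_line_angles(mats[m], mats[k])
        if pred is None:
            continue
        c = cmats[(m, k)] if (m, k) in cmats else cmats[(k, m)].T
        total += float(_bilinear_periodic(c, pred[0], pred[1], step))
    return total


def assign_angles_common_lines(
    class_averages,
    angular_step: float = 2.0,
    search_step: float = 3.0,
    refine_angles: bool = True,
) -> tuple:
    """Assign relative Euler angles to class averages by cross common lines.

    For every image pair the full table of sinogram-line correlations is
    computed; the first image is anchored at the identity (gauge), the second
    and third are found by a joint grid search over their remaining degrees
    of freedom, later images are added sequentially, and a final local
    optimization polishes every orientation against all pairwise tables.
    The solution is defined up to a global rotation and a global hand flip.

    Returns ``(list of OrientationAngles, per-image consistency score)``.
    """
    images = class_averages.images if isinstance(class_averages, ImageStack) else np.asarray(class_averages)
    n_img = len(images)
    if n_img < 3:
        raise ValueError("need at least 3 class averages to fix relative geometry")

    sinos = [_normalize_rows(_sinogram_360(img, angular_step)) for img in images]
    cmats = {}
    peak = np.zeros((n_img, n_img))
    for i in range(n_img):
        for j in range(i + 1, n_img):
            c = sinos[i] @ sinos[j].T
            cmats[(i, j)] = c
            peak[i, j] = peak[j, i] = c.max()
    # a meaningful common-line peak must stand out from the bulk of the line
    # correlations.  Identical (or circularly symmetric) averages produce a
    # flat table (contrast ~1e-3) where every pair of lines "matches";
    # quasi-spherical particles are weak (~0.02-0.1) but still solvable, so
    # the cutoff sits well below them
    contrast = np.mean([c.max() - c.mean() for c in cmats.values()])
    if contrast < 0.005:
        raise ValueError("degenerate class averages: common-line correlation "
                         "is flat across all line pairs")

    step = angular_step

    def peak_angles(i, j):
        c = cmats[(i, j)] if i < j else cmats[(j, i)].T
        a, b = np.unravel_index(np.argmax(c), c.shape)
        return a * step, b * step

    mats = [None] * n_img
    mats[0] = np.eye(3)

    # joint placement of images 1 and 2 against the anchor
    a01, a10 = peak_angles(0, 1)
    a02, a20 = peak_angles(0, 2)
    u01 = np.array([np.cos(np.radians(a01)), np.sin(np.radians(a01)), 0.0])
    u02 = np.array([np.cos(np.radians(a02)), np.sin(np.radians(a02)), 0.0])

    def family(u, alpha, t_deg):
        # viewing directions perpendicular to u, parametrized by t
        a_perp = np.array([0.0, 0.0, 1.0])
        a_perp = a_perp - (a_perp @ u) * u
        if np.linalg.norm(a_perp) < 1e-6:
            a_perp = np.array([0.0, 1.0, 0.0]) - (u[1]) * u
        a_perp /= np.linalg.norm(a_perp)
        b_perp = np.cross(u, a_perp)
        t = np.radians(t_deg)
        d = np.cos(t) * a_perp + np.sin(t) * b_perp
        return _frame_from_common_line(u, d, alpha)

    grid = np.arange(0.0, 360.0, search_step)
    c12 = cmats[(1, 2)]
    best, best_val = None, -np.inf
    mats1 = [family(u01, a10, t) for t in grid]
    mats2 = [family(u02, a20, t) for t in grid]
    for i1, m1 in enumerate(mats1):
        for m2 in mats2:
            pred = _predicted_line_angles(m1, m2)
            if pred is None:
                continue
            v = _bilinear_periodic(c12, pred[0], pred[1], step)
            if v > best_val:
                best_val, best = v, (m1, m2)
    mats[1], mats[2] = best

    # sequential placement of the rest
    for k in range(3, n_img):
        oriented = list(range(k))
        m_star = max(oriented, key=lambda m: peak[m, k])
        a_mk, a_km = peak_angles(m_star, k)
        rm = mats[m_star]
        u3 = np.cos(np.radians(a_mk)) * rm[0] + np.sin(np.radians(a_mk)) * rm[1]
        best, best_val = None, -np.inf
        for t in grid:
            cand = _nonparallel_family(u3, a_km, t)
            v = _pair_score_with(mats, cmats, cand, k, oriented, step)
            if v > best_val:
                best_val, best = v, cand
        mats[k] = best

    if refine_angles:
        for _ in range(2):
            for k in range(1, n_img):
                others = [m for m in range(n_img) if m != k and mats[m] is not None]

                def neg(e):
                    mats_k = euler_to_matrix(*e).T  # rows convention
                    saved, mats[k] = mats[k], mats_k
                    v = _pair_score(mats, cmats, k, others, step)
                    mats[k] = saved
                    return -v

                e0 = np.array(matrix_to_euler(mats[k].T))
                res = optimize.minimize(neg, e0, method="Nelder-Mead",
                                        options={"maxiter": 120, "xatol": 0.05,
                                                 "fatol": 1e-4})
                if -res.fun >= _pair_score(mats, cmats, k, others, step):
                    mats[k] = euler_to_matrix(*res.x).T

    angles, scores = [], []
    for k in range(n_img):
        others = [m for m in range(n_img) if m != k]
        score = _pair_score(mats, cmats, k, others, step) / max(len(others), 1)
        rot, tilt, psi = matrix_to_euler(mats[k].T)
        angles.append(OrientationAngles(rot, tilt, psi, correlation=score))
        scores.append(score)
    return angles, np.array(scores)


def _nonparallel_family(u: np.ndarray, alpha: float, t_deg: float) -> np.ndarray:
    a_perp = np.array([0.0, 0.0, 1.0])
    a_perp = a_perp - (a_perp @ u) * u
    if np.linalg.norm(a_perp) < 1e-6:
        a_perp = np.array([0.0, 1.0, 0.0]) - u[1] * u
    a_perp /= np.linalg.norm(a_perp)
    b_perp = np.cross(u, a_perp)
    t = np.radians(t_deg)
    d = np.cos(t) * a_perp + np.sin(t) * b_perp
    return _frame_from_common_line(u, d, alpha)


def _pair_score_with(mats, cmats, cand, k, others, step):
    saved, mats[k] = mats[k] if mats[k] is not None else None, cand
    v = _pair_score(mats, cmats, k, others, step)
    mats[k] = saved
    return v


# ---------------------------------------------------------------------------
# weighted back-projection

def _ramp_filter(images: np.ndarray) -> np.ndarray:
    n = images.shape[-1]
    fy = np.fft.fftfreq(n)
    fx = np.fft.fftfreq(n)
    w = np.sqrt(fy[:, None] ** 2 + fx[None, :] ** 2)
    return np.fft.ifft2(np.fft.fft2(images, axes=(-2, -1)) * w, axes=(-2, -1)).real


def backproject_weighted(images, angles, pixel_size: float = 1.0) -> VolumeMap:
    """Weighted back-projection: ramp-filter each image in its Fourier plane
    (r* weighting compensating uneven angular sampling), then smear it back
    along its viewing direction.  Output is normalized by the image count,
    so it is linear in the images."""
    images = np.asarray(images, dtype=np.float64)
    if images.ndim == 2:
        images = images[None]
    if len(images) == 0:
        raise ValueError("backproject_weighted needs at least one image")
    if len(angles) != len(images):
        raise ValueError("one angle set per image required")
    filtered = _ramp_filter(images)
    n = images.shape[-1]
    acc = np.zeros((n, n, n), dtype=np.float64)
    for img, ang in zip(filtered, angles):
        acc += backproject_one(img.astype(np.float32), ang)
    return VolumeMap((acc / len(images)).astype(np.float32), pixel_size)


# ---------------------------------------------------------------------------
# FSC

def fsc(volume_a: VolumeMap, volume_b: VolumeMap) -> pd.DataFrame:
    """Fourier shell correlation between two maps on identical grids.

    Returns a DataFrame with columns ``shell`` (integer frequency index),
    ``freq_inv_A`` (1/Å) and ``fsc``.
    """
    if volume_a.shape != volume_b.shape or volume_a.voxel_size != volume_b.voxel_size:
        raise ValueError("fsc requires equal dimensions and voxel size")
    fa = np.fft.fftn(volume_a.data)
    fb = np.fft.fftn(volume_b.data)
    n = volume_a.box_size
    freq = np.fft.fftfreq(n)
    kz, ky, kx = np.meshgrid(freq, freq, freq, indexing="ij")
    shell = np.rint(np.sqrt(kz**2 + ky**2 + kx**2) * n).astype(int)
    n_shells = n // 2 + 1
    sel = shell < n_shells
    cross = np.bincount(shell[sel], (fa * np.conj(fb)).real[sel], minlength=n_shells)
    pa = np.bincount(shell[sel], np.abs(fa[sel]) ** 2, minlength=n_shells)
    pb = np.bincount(shell[sel], np.abs(fb[sel]) ** 2, minlength=n_shells)
    denom = np.sqrt(pa * pb)
    curve = np.where(denom > 0, cross / np.where(denom > 0, denom, 1.0), 0.0)
    freqs = np.arange(n_shells) / (n * volume_a.voxel_size)
    return pd.DataFrame({"shell": np.arange(n_shells), "freq_inv_A": freqs,
                         "fsc": curve})


def resolution_at(curve: pd.DataFrame, cutoff: float = 0.5) -> tuple:
    """Resolution (Å) where the FSC first crosses ``cutoff``.

    Linear interpolation between shells; if the curve never crosses, returns
    the Nyquist resolution with ``crossed=False``.  Returns
    ``(resolution_A, crossed)``.
    """
    f = curve["freq_inv_A"].to_numpy()
    y = curve["fsc"].to_numpy()
    for i in range(1, len(y)):
        if y[i] < cutoff <= y[i - 1]:
            frac = (y[i - 1] - cutoff) / (y[i - 1] - y[i])
            fc = f[i - 1] + frac * (f[i] - f[i - 1])
            return float(1.0 / fc), True
    nyquist = f[-1] if f[-1] > 0 else 1.0
    return float(1.0 / nyquist), False


def low_pass(volume: VolumeMap, resolution_A: float, sharp: bool = False) -> VolumeMap:
    """Low-pass filter a map to ``resolution_A`` (Gaussian falloff reaching
    0.5 at the cutoff frequency, or a hard cutoff if ``sharp``)."""
    n = volume.box_size
    freq = np.fft.fftfreq(n, d=volume.voxel_size)
    kz, ky, kx = np.meshgrid(freq, freq, freq, indexing="ij")
    f = np.sqrt(kz**2 + ky**2 + kx**2)
    fc = 1.0 / resolution_A
    if sharp:
        h = (f <= fc).astype(float)
    else:
        h = np.exp(-np.log(2.0) * (f / fc) ** 2)
    data = np.fft.ifftn(np.fft.fftn(volume.data) * h).real.astype(np.float32)
    return VolumeMap(data, volume.voxel_size)


# ---------------------------------------------------------------------------
# iterative projection-matching refinement

@dataclass
class RefinementState:
    """Bookkeeping for one refinement iteration."""

    iteration: int
    volume: VolumeMap
    angles: pd.DataFrame  # per-image rot/tilt/psi/shift/correlation
    retained: np.ndarray
    retention_fraction: float
    fsc_curve: pd.DataFrame
    resolution_A: float
    resolution_crossed: bool = True


def projection_grid(angular_step: float = 15.0) -> list:
    """Quasi-uniform orientation grid over the sphere (psi = 0)."""
    out = []
    for tilt in np.arange(0.0, 180.0 + 1e-9, angular_step):
        s = np.sin(np.radians(tilt))
        n_rot = max(1, int(round(360.0 * s / angular_step)))
        for rot in np.arange(0.0, 360.0, 360.0 / n_rot):
            out.append(OrientationAngles(float(rot), float(tilt), 0.0))
    return out


def refine(
    stack_nondenoised: ImageStack,
    stack_denoised: ImageStack,
    initial_volume: VolumeMap,
    n_iterations: int = 3,
    retention_fraction: float = 0.75,
    seed: int = 0,
    angular_step: float = 15.0,
    in_plane_n_theta: int = 36,
    estimate_shifts: bool = True,
    max_shift: int = 4,
) -> list:
    """Iterative projection matching with correlation-based retention.

    Per iteration: project the current volume on the angular grid, match each
    *denoised* image to its best projection, keep the top
    ``retention_fraction`` by correlation (stable tie-break by image index),
    and reconstruct from the corresponding *non-denoised* images; even/odd
    halves of the retained set give the FSC.  Returns the list of
    RefinementState, one per iteration.
    """
    if not 0.70 <= retention_fraction <= 0.75:
        warnings.warn(
            f"retention_fraction {retention_fraction} outside [0.70, 0.75] "
            "(allowed, but off the established operating range)", stacklevel=2)
    if len(stack_nondenoised) != len(stack_denoised):
        raise ValueError("denoised and non-denoised stacks must be parallel")
    n_images = len(stack_nondenoised)
    volume = initial_volume
    dirs = projection_grid(angular_step)
    history = []
    for it in range(n_iterations):
        refs = np.stack([project(volume, d) for d in dirs])
        m_idx, delta, corr = match_stack_to_references(
            stack_denoised.images, refs, n_theta=in_plane_n_theta)
        assigned = []
        for i in range(n_images):
            g = dirs[m_idx[i]]
            psi = float(delta[i] % 360.0)
            ang = OrientationAngles(g.rot, g.tilt, psi, correlation=float(corr[i]))
            if estimate_shifts:
                ref_rot = _rotate2d(refs[m_idx[i]], delta[i])
                dx, dy = estimate_shift(stack_denoised.images[i], ref_rot, max_shift)
                # the image is the shifted projection, so the shift is carried
                # forward as-is (backprojection undoes it)
                ang.shift_x, ang.shift_y = dx, dy
            assigned.append(ang)

        n_keep = int(round(retention_fraction * n_images))
        order = np.lexsort((np.arange(n_images), -corr))
        retained = np.sort(order[:n_keep])
        half_a = retained[0::2]
        half_b = retained[1::2]
        vol_a = backproject_weighted(
            stack_nondenoised.images[half_a], [assigned[i] for i in half_a],
            stack_nondenoised.pixel_size)
        vol_b = backproject_weighted(
            stack_nondenoised.images[half_b], [assigned[i] for i in half_b],
            stack_nondenoised.pixel_size)
        full = VolumeMap(
            (len(half_a) * vol_a.data + len(half_b) * vol_b.data) / max(n_keep, 1),
            stack_nondenoised.pixel_size)
        curve = fsc(vol_a, vol_b)
        res, crossed = resolution_at(curve, 0.5)
        table = pd.DataFrame(
            dict(image_index=np.arange(n_images),
                 rot=[a.rot for a in assigned], tilt=[a.tilt for a in assigned],
                 psi=[a.psi for a in assigned],
                 shift_x=[a.shift_x for a in assigned],
                 shift_y=[a.shift_y for a in assigned],
                 correlation=corr, retained=np.isin(np.arange(n_images), retained)))
        history.append(RefinementState(it, full, table, retained,
                                       retention_fraction, curve, res, crossed))
        volume = full
    return history


def tilt_pair_hand_check(
    volume: VolumeMap,
    tilted_images: np.ndarray,
    assigned_angles: list,
    tilt_deg: float,
) -> str:
    """Simulated tilt-pair handedness check.

    Given images of the same particles tilted by a known stage angle about
    the lab y axis, compare their correlation with re-projections of the map
    at +tilt versus -tilt composed with each particle's assigned orientation.
    Returns ``"same"`` if the map's hand is consistent with the tilt sense,
    ``"flipped"`` otherwise.
    """
    from scipy.spatial.transform import Rotation

    t_plus = Rotation.from_euler("y", tilt_deg, degrees=True).as_matrix()
    score_plus = score_minus = 0.0
    for img, ang in zip(tilted_images, assigned_angles):
        m = euler_to_matrix(ang.rot, ang.tilt, ang.psi)
        for sign, tmat in (("+", t_plus), ("-", t_plus.T)):
            pred = project(volume, OrientationAngles(*matrix_to_euler(tmat @ m)))
            p = pred - pred.mean()
            q = img - img.mean()
            denom = np.linalg.norm(p) * np.linalg.norm(q)
            c = float((p * q).sum() / denom) if denom > 0 else 0.0
            if sign == "+":
                score_plus += c
            else:
                score_minus += c
    return "same" if score_plus >= score_minus else "flipped"
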
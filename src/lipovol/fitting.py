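"""Rigid-body docking of an atomic backbone into a density map, and
triangulation of antibody epitopes onto the particle surface.

Docking is an exhaustive rotational search (ZYZ Euler grid) with the best
translation found by FFT cross-correlation at every rotation, followed by
non-maximum suppression in pose space; the surviving top poses provide the
z-score population from which one-sided P-values are computed.  Docking
should be run against both hands of a reconstruction (see
:func:`dock_both_hands`) because single-particle maps carry a mirror
ambiguity.

Epitope triangulation converts (latitude, longitude) surface coordinates to
unit vectors, finds the proper rotation that best aligns three anchor
epitopes with their known 3-D positions (least-squares orthogonal fit), and
applies it to the full table.  A rotation is an isometry of the sphere, so
pairwise great-circle distances between epitopes are preserved exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from scipy.spatial.transform import Rotation

from .core import VolumeMap
from .geometry import euler_to_matrix, rotate_volume

__all__ = [
    "DockPose",
    "model_to_density",
    "read_backbone_coords",
    "prepare_map_for_fitting",
    "dock",
    "dock_both_hands",
    "load_epitope_table",
    "load_synthetic_epitope_table",
    "map_epitopes",
    "latlon_to_unit",
]


@dataclass
class DockPose:
    rank: int
    rot: float
    tilt: float
    psi: float
    x: float
    y: float
    z: float
    correlation: float
    z_score: float = float("nan")
    p_value: float = float("nan")


def read_backbone_coords(pdb_path: str, ca_only: bool = True,
                         max_residue: int | None = None) -> np.ndarray:
    """Read backbone coordinates (Å) from ATOM records of a PDB file."""
    import biotite.structure.io.pdb as pdb

    f = pdb.PDBFile.read(str(pdb_path))
    structure = f.get_structure(model=1)
    mask = structure.hetero == False  # noqa: E712
    if ca_only:
        mask &= structure.atom_name == "CA"
    if max_residue is not None:
        mask &= structure.res_id <= max_residue
    coords = structure.coord[mask]
    if len(coords) == 0:
        raise ValueError("no backbone atoms found in PDB file")
    return np.asarray(coords, dtype=float)


def model_to_density(
    coords: np.ndarray,
    resolution: float,
    voxel_size: float,
    box_size: int | None = None,
    center: bool = True,
) -> VolumeMap:
    """Rasterize atoms as Gaussians whose FWHM equals the target resolution.

    sigma = resolution / (2 sqrt(2 ln 2)).  Total integrated density is
    proportional to the atom count (each atom contributes unit mass).
    """
    coords = np.asarray(coords, dtype=float)
    if coords.size == 0:
        raise ValueError("empty model")
    if resolution < 2 * voxel_size:
        raise ValueError("resolution must be at least 2 x voxel_size")
    if center:
        coords = coords - coords.mean(axis=0)
    if box_size is None:
        extent = np.abs(coords).max() * 2 + 4 * resolution
        box_size = int(np.ceil(extent / voxel_size / 2)) * 2
    c = (box_size - 1) / 2.0
    # histogram atoms onto the grid ((z, y, x) order), then blur once
    idx = coords[:, ::-1] / voxel_size + c
    edges = [np.arange(box_size + 1) - 0.5] * 3
    hist, _ = np.histogramdd(idx, bins=edges)
    sigma_vox = resolution / (2.0 * np.sqrt(2.0 * np.log(2.0))) / voxel_size
    data = ndimage.gaussian_filter(hist, sigma_vox)
    return VolumeMap(data.astype(np.float32), voxel_size)


def prepare_map_for_fitting(
    volume: VolumeMap,
    band_low: float = 80.0,
    band_high: float = 15.0,
    sigma_threshold: float = 1.7,
) -> VolumeMap:
    """Bandpass the map between two spacings (Å), then zero voxels below
    mean + ``sigma_threshold`` standard deviations of the filtered map."""
    if band_high >= band_low:
        raise ValueError("band limits inverted: need band_high < band_low (Å)")
    n = volume.box_size
    freq = np.fft.fftfreq(n, d=volume.voxel_size)
    kz, ky, kx = np.meshgrid(freq, freq, freq, indexing="ij")
    f = np.sqrt(kz**2 + ky**2 + kx**2)
    keep = (f >= 1.0 / band_low) & (f <= 1.0 / band_high)
    data = np.fft.ifftn(np.fft.fftn(volume.data) * keep).real
    sd = data.std()
    if sd == 0:
        return VolumeMap(np.zeros_like(data, dtype=np.float32), volume.voxel_size)
    t = data.mean() + sigma_threshold * sd
    data = np.where(data >= t, data, 0.0)
    return VolumeMap(data.astype(np.float32), volume.voxel_size)


def _rotation_distance_deg(m1: np.ndarray, m2: np.ndarray) -> float:
    r = m1 @ m2.T
    cos = np.clip((np.trace(r) - 1.0) / 2.0, -1.0, 1.0)
    return float(np.degrees(np.arccos(cos)))


def dock(
    model_density: VolumeMap,
    map_density: VolumeMap,
    angular_step: float = 15.0,
    top_n: int = 40,
    report_n: int = 10,
    suppress_rotation_deg: float | None = None,
    suppress_translation_A: float | None = None,
) -> list:
    """Exhaustive rigid docking of a model density into a map.

    At every ZYZ grid rotation the best translation is found by FFT
    correlation; poses then undergo greedy non-maximum suppression in pose
    space, the ``top_n`` survivors define the z-score population
    (z_i = (score_i - mean)/sd over the top_n), and one-sided normal tail
    P-values are attached.  Returns the first ``report_n`` DockPose.
    """
    if abs(model_density.voxel_size - map_density.voxel_size) > 1e-6:
        raise ValueError("model and map must share grid spacing")
    a = map_density.data.astype(np.float64)
    a = a - a.mean()
    fa = np.conj(np.fft.fftn(a))
    na = np.linalg.norm(a)
    nmap = map_density.box_size
    c0 = nmap // 2

    model = model_density.data.astype(np.float64)
    if model.shape != a.shape:  # embed the (smaller) model in the map box
        pad = [(0, max(0, ms - s)) for s, ms in zip(model.shape, a.shape)]
        model = np.pad(model, pad)[: a.shape[0], : a.shape[1], : a.shape[2]]
        shift = [(s - ms) // 2 for s, ms in
                 zip(a.shape, model_density.data.shape)]
        model = np.roll(model, shift, axis=(0, 1, 2))

    raw = []
    for tilt in np.arange(0.0, 180.0 + 1e-9, angular_step):
        s = np.sin(np.radians(tilt))
        n_rot = max(1, int(round(360.0 * s / angular_step)))
        for rot in np.arange(0.0, 360.0, 360.0 / n_rot):
            for psi in np.arange(0.0, 360.0, angular_step):
                m = euler_to_matrix(rot, tilt, psi)
                br = rotate_volume(model, m)
                br = br - br.mean()
                nb = np.linalg.norm(br)
                if nb == 0:
                    continue
                cc = np.fft.fftshift(np.fft.ifftn(np.fft.fftn(br) * fa).real)
                k = np.unravel_index(np.argmax(cc), cc.shape)
                score = float(cc[k] / (na * nb))
                # translation to apply to the rotated model to place it in the map
                dz, dy, dx = (float(c0 - i) for i in k)
                raw.append(((rot, tilt, psi), m,
                            (dx * map_density.voxel_size,
                             dy * map_density.voxel_size,
                             dz * map_density.voxel_size), score))

    raw.sort(key=lambda p: -p[3])
    # suppression radius below the grid step: near-duplicate placements at the
    # same grid rotation collapse, while adjacent-grid refinements of one
    # solution stay visible as separate top ranks
    sup_rot = suppress_rotation_deg if suppress_rotation_deg is not None else 0.9 * angular_step
    sup_tr = suppress_translation_A if suppress_translation_A is not None else 3.0 * map_density.voxel_size
    kept = []
    for pose in raw:
        close = False
        for other in kept:
            if (_rotation_distance_deg(pose[1], other[1]) < sup_rot
                    and np.linalg.norm(np.subtract(pose[2], other[2])) < sup_tr):
                close = True
                break
        if not close:
            kept.append(pose)
        if len(kept) >= top_n:
            break
    if len(kept) < top_n:
        warnings.warn(f"only {len(kept)} poses survived suppression "
                      f"(z-score population smaller than {top_n})", stacklevel=2)

    scores = np.array([p[3] for p in kept])
    sd = scores.std(ddof=0)
    if sd == 0:
        warnings.warn("degenerate docking score distribution: p-values undefined",
                      stacklevel=2)
        zs = np.full(len(scores), np.nan)
        ps = np.full(len(scores), np.nan)
    else:
        zs = (scores - scores.mean()) / sd
        ps = stats.norm.sf(zs)

    poses = []
    for rank, (euler, _m, tr, score) in enumerate(kept[:report_n], start=1):
        poses.append(DockPose(rank, euler[0], euler[1], euler[2],
                              tr[0], tr[1], tr[2], score,
                              float(zs[rank - 1]), float(ps[rank - 1])))
    return poses


def dock_both_hands(model_density: VolumeMap, map_density: VolumeMap, **kwargs) -> tuple:
    """Dock against the map and its mirror; report the better-scoring hand.

    Returns ``(poses, hand)`` with hand in {"same", "flipped"}.
    """
    poses_same = dock(model_density, map_density, **kwargs)
    mirrored = VolumeMap(map_density.data[:, :, ::-1].copy(), map_density.voxel_size)
    poses_flip = dock(model_density, mirrored, **kwargs)
    if poses_same and (not poses_flip or poses_same[0].correlation >= poses_flip[0].correlation):
        return poses_same, "same"
    return poses_flip, "flipped"


# ---------------------------------------------------------------------------
# epitope triangulation

def latlon_to_unit(lat_deg, lon_deg) -> np.ndarray:
    """(latitude, longitude) in degrees -> unit vectors (x, y, z)."""
    lat = np.radians(np.asarray(lat_deg, dtype=float))
    lon = np.radians(np.asarray(lon_deg, dtype=float))
    return np.stack([np.cos(lat) * np.cos(lon),
                     np.cos(lat) * np.sin(lon),
                     np.sin(lat)], axis=-1)


def load_epitope_table(path: str) -> pd.DataFrame:
    """Load an epitope TSV (antibody, residue_range, latitude_deg,
    longitude_deg, is_anchor)."""
    table = pd.read_csv(path, sep="\t")
    required = {"antibody", "residue_range", "latitude_deg", "longitude_deg", "is_anchor"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"epitope table missing columns: {sorted(missing)}")
    if not table["latitude_deg"].between(-90, 90).all():
        raise ValueError("latitude must lie in [-90, 90]")
    if not table["longitude_deg"].between(-180, 180).all():
        raise ValueError("longitude must lie in [-180, 180)")
    return table


def load_synthetic_epitope_table() -> pd.DataFrame:
    """Packaged *synthetic* epitope fixture: real antibody names and apoB-100
    residue ranges with placeholder surface coordinates (for exercising the
    triangulation machinery; substitute measured coordinates via
    :func:`load_epitope_table` for real use)."""
    ref = resources.files("lipovol.data").joinpath("epitopes_synthetic.tsv")
    with resources.as_file(ref) as path:
        return load_epitope_table(path)


def _fit_anchor_rotation(anchors_unit: np.ndarray, targets_unit: np.ndarray,
                         allow_reflection: bool) -> np.ndarray:
    """Least-squares orthogonal fit mapping anchor unit vectors onto target
    unit vectors; proper rotation unless reflection is explicitly allowed."""
    h = targets_unit.T @ anchors_unit
    u, _s, vt = np.linalg.svd(h)
    det = np.linalg.det(u @ vt)
    if det < 0 and not allow_reflection:
        # best proper rotation (Kabsch correction)
        d = np.ones(3)
        d[-1] = -1.0
        r = u @ np.diag(d) @ vt
        r_reflect = u @ vt
        err_proper = np.linalg.norm(r @ anchors_unit.T - targets_unit.T)
        err_reflect = np.linalg.norm(r_reflect @ anchors_unit.T - targets_unit.T)
        if err_reflect < 0.5 * err_proper:
            raise ValueError(
                "anchor geometry requires a reflection; pass allow_reflection=True "
                "if the table's hand is known to be mirrored")
        return r
    return u @ vt


def map_epitopes(
    table: pd.DataFrame,
    anchor_positions_3d: np.ndarray,
    surface_radius: float,
    allow_reflection: bool = False,
) -> pd.DataFrame:
    """Map all epitopes into 3-D map coordinates via three anchors.

    The three rows flagged ``is_anchor`` are matched (in table order) to
    ``anchor_positions_3d``; the best-fitting proper rotation carries every
    epitope's unit vector into map coordinates, scaled to
    ``surface_radius``.  Returns a copy of the table with x/y/z columns.
    """
    anchors = table[table["is_anchor"].astype(bool)]
    if len(anchors) != 3:
        raise ValueError(f"exactly 3 anchors required, got {len(anchors)}")
    anchor_positions_3d = np.asarray(anchor_positions_3d, dtype=float)
    if anchor_positions_3d.shape != (3, 3):
        raise ValueError("anchor_positions_3d must be 3 x 3")

    a_unit = latlon_to_unit(anchors["latitude_deg"].to_numpy(),
                            anchors["longitude_deg"].to_numpy())
    norms = np.linalg.norm(anchor_positions_3d, axis=1)
    if np.any(norms == 0):
        raise ValueError("anchor 3-D positions must be nonzero")
    t_unit = anchor_positions_3d / norms[:, None]
    if np.linalg.norm(np.cross(a_unit[1] - a_unit[0], a_unit[2] - a_unit[0])) < 1e-6:
        raise ValueError("anchors are collinear: rotation is not determined")

    r = _fit_anchor_rotation(a_unit, t_unit, allow_reflection)
    all_unit = latlon_to_unit(table["latitude_deg"].to_numpy(),
                              table["longitude_deg"].to_numpy())
    mapped = (r @ all_unit.T).T * surface_radius
    out = table.copy()
    out["x"] = mapped[:, 0]
    out["y"] = mapped[:, 1]
    out["z"] = mapped[:, 2]
    return out
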
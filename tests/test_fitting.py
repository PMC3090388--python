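"""Model rasterization, map preparation, docking, epitope triangulation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from lipovol.core import VolumeMap
from lipovol.fitting import (dock, dock_both_hands, latlon_to_unit,
                             load_synthetic_epitope_table, map_epitopes,
                             model_to_density, prepare_map_for_fitting)


class TestModelToDensity:
    def test_single_atom_blob_centered_on_atom(self):
        vol = model_to_density(np.array([[3.0, -2.0, 5.0]]), 12.0, 2.0,
                               box_size=32, center=False)
        c = (32 - 1) / 2
        peak = np.unravel_index(np.argmax(vol.data), vol.shape)
        # (z, y, x) indexing: atom at x=3, y=-2, z=5 (half-voxel tolerance)
        expected = (c + 5.0 / 2.0, c - 2.0 / 2.0, c + 3.0 / 2.0)
        assert all(abs(p - e) <= 0.5 for p, e in zip(peak, expected))
        assert vol.data.sum() == pytest.approx(1.0, rel=1e-3)

    def test_translation_equivariance(self):
        rng = np.random.default_rng(0)
        coords = rng.normal(0, 8, (30, 3))
        a = model_to_density(coords, 12.0, 2.0, box_size=32, center=False)
        b = model_to_density(coords + [10.0, 0.0, 0.0], 12.0, 2.0,
                             box_size=32, center=False)
        shifted = np.roll(a.data, 5, axis=2)  # 10 A = 5 voxels along x
        corr = np.corrcoef(shifted.ravel(), b.data.ravel())[0, 1]
        assert corr > 0.999

    def test_two_atoms_resolved_only_at_sufficient_resolution(self):
        """20 A separation: two maxima at 17 A resolution, one at 40 A
        (Gaussian-overlap arithmetic with FWHM = resolution)."""
        coords = np.array([[-10.0, 0.0, 0.0], [10.0, 0.0, 0.0]])

        def n_maxima(resolution):
            vol = model_to_density(coords, resolution, 2.0, box_size=48,
                                   center=False)
            c = 48 // 2 - 1
            line = vol.data[c + 1, c + 1, :]
            interior = (line[1:-1] > line[:-2]) & (line[1:-1] > line[2:])
            return int(interior.sum())

        assert n_maxima(17.0) == 2
        assert n_maxima(40.0) == 1

    def test_density_proportional_to_atom_count(self):
        rng = np.random.default_rng(1)
        c30 = rng.normal(0, 8, (30, 3))
        c60 = np.vstack([c30, rng.normal(0, 8, (30, 3))])
        a = model_to_density(c30, 12.0, 2.0, box_size=32, center=False)
        b = model_to_density(c60, 12.0, 2.0, box_size=32, center=False)
        assert b.data.sum() == pytest.approx(2.0 * a.data.sum(), rel=1e-3)

    def test_empty_model_rejected(self):
        with pytest.raises(ValueError):
            model_to_density(np.zeros((0, 3)), 12.0, 2.0)

    def test_resolution_below_nyquist_rejected(self):
        with pytest.raises(ValueError):
            model_to_density(np.zeros((1, 3)), 3.0, 2.0)


class TestPrepareMap:
    def test_constant_volume_zeroed(self):
        vol = VolumeMap(np.full((32, 32, 32), 5.0, np.float32), 2.8)
        out = prepare_map_for_fitting(vol)
        assert np.all(out.data == 0.0)

    def test_band_edges_pass_and_suppress(self):
        """A 30 A sinusoid is inside the 15-80 A band and survives; a 10 A
        sinusoid is outside and is suppressed by >= 90%."""
        n, vox = 64, 2.5
        z = np.arange(n) * vox

        def sinusoid(period):
            wave = np.sin(2 * np.pi * z / period)
            return VolumeMap(np.broadcast_to(
                wave[:, None, None], (n, n, n)).astype(np.float32).copy(), vox)

        def band_energy(vol):
            f = np.fft.fftn(vol.data)
            freq = np.fft.fftfreq(n, d=vox)
            kz, ky, kx = np.meshgrid(freq, freq, freq, indexing="ij")
            keep = (np.sqrt(kz**2 + ky**2 + kx**2) >= 1 / 80.0) \
                & (np.sqrt(kz**2 + ky**2 + kx**2) <= 1 / 15.0)
            bandpassed = np.fft.ifftn(f * keep).real
            return float((bandpassed**2).sum()), float((vol.data**2).sum())

        kept, total = band_energy(sinusoid(30.0))
        assert kept >= 0.9 * total
        kept, total = band_energy(sinusoid(10.0))
        assert kept <= 0.1 * total

    def test_output_below_threshold_is_exactly_zero(self, ordered_phantom):
        out = prepare_map_for_fitting(ordered_phantom)
        nz = out.data[out.data != 0]
        assert nz.size > 0
        assert nz.min() > 0  # everything below mu + 1.7 sigma was zeroed

    def test_inverted_band_rejected(self, ordered_phantom):
        with pytest.raises(ValueError, match="inverted"):
            prepare_map_for_fitting(ordered_phantom, band_low=15.0,
                                    band_high=80.0)


@pytest.fixture(scope="module")
def dock_fixture():
    """Asymmetric pseudo-atom cluster placed in a map at a known pose
    (15 degrees about z, translation (12, 0, 6) A) next to a weaker decoy."""
    rng = np.random.default_rng(42)
    atoms = rng.normal(0, 25, (60, 3))
    atoms = atoms[np.linalg.norm(atoms, axis=1) < 60]
    r15 = Rotation.from_euler("z", 15, degrees=True).as_matrix()
    placed = atoms @ r15.T + np.array([12.0, 0.0, 6.0])
    n, vox = 40, 6.0
    map_d = model_to_density(placed, 24.0, vox, box_size=n, center=False)
    decoy = rng.normal(0, 15, (30, 3)) + np.array([-80.0, -60.0, -40.0])
    dec_d = model_to_density(decoy, 24.0, vox, box_size=n, center=False)
    map_vol = VolumeMap(map_d.data + 0.6 * dec_d.data, vox)
    model = model_to_density(atoms, 24.0, vox, box_size=n, center=False)
    return model, map_vol


class TestDock:
    def test_self_docking_recovers_identity(self, dock_fixture):
        model, _map_vol = dock_fixture
        poses = dock(model, model, angular_step=30.0, top_n=20, report_n=3)
        p = poses[0]
        assert (p.rot, p.tilt, p.psi) == (0.0, 0.0, 0.0)
        assert (p.x, p.y, p.z) == (0.0, 0.0, 0.0)
        assert p.correlation == pytest.approx(1.0, abs=1e-3)

    def test_known_pose_bracketed_by_top_two(self, dock_fixture):
        """Ground truth 15 degrees off-grid: ranks 1-2 are the two grid
        rotations bracketing it (one step apart), both far more significant
        than rank 3."""
        model, map_vol = dock_fixture
        poses = dock(model, map_vol, angular_step=30.0, top_n=40, report_n=10)
        top2 = {(p.rot, p.tilt, p.psi) for p in poses[:2]}
        assert top2 == {(0.0, 0.0, 0.0), (0.0, 0.0, 30.0)}
        for p in poses[:2]:
            assert (p.x, p.y, p.z) == (12.0, 0.0, 6.0)
            assert p.p_value < 0.05
        assert poses[2].p_value > poses[1].p_value

    def test_z_scores_and_p_values_match_hand_recomputation(self, dock_fixture):
        """Recompute z and one-sided normal p from the returned correlations
        with an explicit error-function formula."""
        from math import erfc, sqrt

        model, map_vol = dock_fixture
        poses = dock(model, map_vol, angular_step=45.0, top_n=15, report_n=15)
        scores = np.array([p.correlation for p in poses])
        mu, sd = scores.mean(), scores.std(ddof=0)
        for p in poses:
            z = (p.correlation - mu) / sd
            assert p.z_score == pytest.approx(z, abs=1e-9)
            assert p.p_value == pytest.approx(0.5 * erfc(z / sqrt(2)), abs=1e-9)

    def test_score_invariant_to_map_offset(self, dock_fixture):
        model, map_vol = dock_fixture
        shifted = VolumeMap(map_vol.data + 7.5, map_vol.voxel_size)
        a = dock(model, map_vol, angular_step=90.0, top_n=5, report_n=1)
        b = dock(model, shifted, angular_step=90.0, top_n=5, report_n=1)
        assert a[0].correlation == pytest.approx(b[0].correlation, abs=1e-5)

    def test_both_hands_identifies_mirrored_map(self, dock_fixture):
        model, map_vol = dock_fixture
        mirrored = VolumeMap(map_vol.data[:, :, ::-1].copy(), map_vol.voxel_size)
        _poses, hand = dock_both_hands(model, mirrored, angular_step=45.0,
                                       top_n=20, report_n=3)
        assert hand == "flipped"

    def test_voxel_size_mismatch_rejected(self, dock_fixture):
        model, map_vol = dock_fixture
        other = VolumeMap(map_vol.data, map_vol.voxel_size * 2)
        with pytest.raises(ValueError):
            dock(model, other)


class TestEpitopeMapping:
    @pytest.fixture()
    def table(self):
        return load_synthetic_epitope_table()

    def test_synthetic_fixture_well_formed(self, table):
        assert len(table) == 11
        assert table["is_anchor"].sum() == 3
        assert set(table[table["is_anchor"]]["antibody"]) == \
            {"MB19", "MB24", "MB11"}

    def test_coincident_anchors_give_identity(self, table):
        anchors = table[table["is_anchor"]]
        units = latlon_to_unit(anchors["latitude_deg"].to_numpy(),
                               anchors["longitude_deg"].to_numpy())
        mapped = map_epitopes(table, units * 115.0, 115.0)
        all_units = latlon_to_unit(table["latitude_deg"].to_numpy(),
                                   table["longitude_deg"].to_numpy())
        got = mapped[["x", "y", "z"]].to_numpy()
        assert np.allclose(got, all_units * 115.0, atol=1e-9)

    def test_known_rotation_recovered(self, table):
        r = Rotation.from_euler("ZYZ", [40, 55, -20], degrees=True).as_matrix()
        anchors = table[table["is_anchor"]]
        units = latlon_to_unit(anchors["latitude_deg"].to_numpy(),
                               anchors["longitude_deg"].to_numpy())
        mapped = map_epitopes(table, (r @ units.T).T * 115.0, 115.0)
        all_units = latlon_to_unit(table["latitude_deg"].to_numpy(),
                                   table["longitude_deg"].to_numpy())
        expected = (r @ all_units.T).T * 115.0
        assert np.allclose(mapped[["x", "y", "z"]].to_numpy(), expected,
                           atol=1e-6 * 115.0)

    def test_noisy_anchors_keep_epitopes_within_ten_degrees(self, table):
        """5 degrees of angular noise on each anchor propagates to < 10
        degrees of great-circle error on the mapped epitopes."""
        rng = np.random.default_rng(3)
        r = Rotation.from_euler("ZYZ", [10, 70, 30], degrees=True).as_matrix()
        anchors = table[table["is_anchor"]]
        units = latlon_to_unit(anchors["latitude_deg"].to_numpy(),
                               anchors["longitude_deg"].to_numpy())
        targets = (r @ units.T).T
        noisy = []
        for t in targets:
            axis = rng.normal(size=3)
            axis -= (axis @ t) * t
            axis /= np.linalg.norm(axis)
            perturb = Rotation.from_rotvec(np.radians(5.0) * axis).as_matrix()
            noisy.append(perturb @ t)
        mapped = map_epitopes(table, np.array(noisy) * 115.0, 115.0)
        all_units = latlon_to_unit(table["latitude_deg"].to_numpy(),
                                   table["longitude_deg"].to_numpy())
        expected = (r @ all_units.T).T
        got = mapped[["x", "y", "z"]].to_numpy() / 115.0
        errs = np.degrees(np.arccos(np.clip((got * expected).sum(axis=1),
                                            -1, 1)))
        assert errs.max() < 10.0

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(rot=st.floats(0, 360), tilt=st.floats(0, 180), psi=st.floats(0, 360))
    def test_mapping_preserves_great_circle_distances(self, rot, tilt, psi):
        """A rotation is an isometry of the sphere: pairwise great-circle
        distances between mapped epitopes equal the originals."""
        table = load_synthetic_epitope_table()
        r = Rotation.from_euler("ZYZ", [rot, tilt, psi], degrees=True).as_matrix()
        anchors = table[table["is_anchor"]]
        units = latlon_to_unit(anchors["latitude_deg"].to_numpy(),
                               anchors["longitude_deg"].to_numpy())
        mapped = map_epitopes(table, (r @ units.T).T * 100.0, 100.0)
        all_units = latlon_to_unit(table["latitude_deg"].to_numpy(),
                                   table["longitude_deg"].to_numpy())
        got = mapped[["x", "y", "z"]].to_numpy() / 100.0
        for i in range(len(table)):
            for j in range(i + 1, len(table)):
                before = np.arccos(np.clip(all_units[i] @ all_units[j], -1, 1))
                after = np.arccos(np.clip(got[i] @ got[j], -1, 1))
                assert after == pytest.approx(before, abs=1e-6)

    def test_collinear_anchors_rejected(self, table):
        bad = table.copy()
        bad["is_anchor"] = False
        bad.loc[:2, "is_anchor"] = True
        bad.loc[:2, "latitude_deg"] = 0.0
        bad.loc[:2, "longitude_deg"] = [0.0, 10.0, 20.0]
        targets = latlon_to_unit(bad.loc[:2, "latitude_deg"],
                                 bad.loc[:2, "longitude_deg"]) * 100.0
        # three points on one great circle are fine; truly collinear unit
        # vectors (all on one axis) are not
        bad.loc[:2, "longitude_deg"] = [0.0, 0.0, 180.0]
        targets = latlon_to_unit(bad.loc[:2, "latitude_deg"],
                                 bad.loc[:2, "longitude_deg"]) * 100.0
        with pytest.raises(ValueError, match="collinear"):
            map_epitopes(bad, targets, 100.0)

    def test_reflection_demanded_but_not_allowed_is_flagged(self, table):
        anchors = table[table["is_anchor"]]
        units = latlon_to_unit(anchors["latitude_deg"].to_numpy(),
                               anchors["longitude_deg"].to_numpy())
        mirrored = units.copy()
        mirrored[:, 0] *= -1.0
        with pytest.raises(ValueError, match="reflection"):
            map_epitopes(table, mirrored * 100.0, 100.0)
        mapped = map_epitopes(table, mirrored * 100.0, 100.0,
                              allow_reflection=True)
        assert len(mapped) == len(table)

    def test_wrong_anchor_count_rejected(self, table):
        bad = table.copy()
        bad["is_anchor"] = False
        with pytest.raises(ValueError, match="3 anchors"):
            map_epitopes(bad, np.eye(3) * 100.0, 100.0)
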
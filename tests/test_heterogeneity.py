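"""Radial-profile filtering and bootstrap 3-D variance."""

import numpy as np
import pytest

from lipovol.classify import ClassSet
from lipovol.core import ImageStack, VolumeMap
from lipovol.geometry import project, uniform_orientations
from lipovol.heterogeneity import (RadialProfile, bootstrap_variance,
                                   filter_classes_by_profile,
                                   profile_correlation, radial_profile_2d)
from lipovol.phantom import default_phantom_spec, make_phantom
from lipovol.reconstruct import backproject_weighted, projection_grid


class TestRadialProfile2D:
    def test_constant_image(self):
        prof = radial_profile_2d(np.full((32, 32), 2.5))
        assert np.allclose(prof.intensity, 2.5)

    def test_single_bright_pixel_localizes(self):
        img = np.zeros((41, 41))
        img[20, 30] = 7.0  # exactly 10 px from the (20, 20) center
        prof = radial_profile_2d(img, center=(20.0, 20.0))
        nonzero = np.flatnonzero(prof.intensity)
        assert nonzero.tolist() == [10]

    def test_unit_disk_step(self):
        n = 64
        yy, xx = np.mgrid[:n, :n]
        c = (n - 1) / 2
        r = np.sqrt((yy - c) ** 2 + (xx - c) ** 2)
        prof = radial_profile_2d((r < 20).astype(float))
        assert np.allclose(prof.intensity[:19], 1.0)
        assert np.allclose(prof.intensity[21:30], 0.0)

    def test_center_outside_rejected(self):
        with pytest.raises(ValueError):
            radial_profile_2d(np.zeros((8, 8)), center=(20.0, 2.0))


class TestProfileCorrelation:
    def test_self_correlation_is_one(self):
        p = RadialProfile(np.arange(10.0), np.arange(10.0) ** 2)
        assert profile_correlation(p, p) == pytest.approx(1.0)

    def test_negation_gives_minus_one(self):
        y = np.sin(np.arange(20.0))
        a = RadialProfile(np.arange(20.0), y)
        b = RadialProfile(np.arange(20.0), 2 * y.mean() - y)
        assert profile_correlation(a, b) == pytest.approx(-1.0)

    def test_matches_independent_pearson_formula(self):
        """Cross-check against a from-scratch Pearson implementation."""
        rng = np.random.default_rng(11)
        ya, yb = rng.normal(size=20), rng.normal(size=20)
        a = RadialProfile(np.arange(20.0), ya)
        b = RadialProfile(np.arange(20.0), yb)
        n = 20
        sx, sy = ya.sum(), yb.sum()
        sxx, syy, sxy = (ya * ya).sum(), (yb * yb).sum(), (ya * yb).sum()
        oracle = (n * sxy - sx * sy) / np.sqrt(
            (n * sxx - sx * sx) * (n * syy - sy * sy))
        assert profile_correlation(a, b) == pytest.approx(oracle, abs=1e-12)

    def test_mixed_binning_resamples_to_coarser(self):
        x_f = np.arange(0.5, 40.0, 1.0)
        x_c = np.arange(1.0, 40.0, 2.0)
        fine = RadialProfile(x_f, np.cos(x_f / 5.0))
        coarse = RadialProfile(x_c, np.cos(x_c / 5.0))
        assert profile_correlation(fine, coarse) > 0.99

    def test_zero_variance_flagged_as_zero(self):
        a = RadialProfile(np.arange(5.0), np.ones(5))
        b = RadialProfile(np.arange(5.0), np.arange(5.0))
        with pytest.warns(UserWarning, match="zero-variance"):
            assert profile_correlation(a, b) == 0.0


def _class_set(images, pixel_size=5.0, members_per_class=3):
    n = len(images)
    assignments = np.repeat(np.arange(n), members_per_class)
    return ClassSet(
        n_classes=n,
        assignments=assignments,
        class_averages=ImageStack(np.stack(images), pixel_size),
        counts=np.full(n, members_per_class),
    )


@pytest.fixture(scope="module")
def model_projections(ordered_phantom):
    return np.stack([project(ordered_phantom, d)
                     for d in projection_grid(45.0)])


class TestProfileFilter:

    def test_projection_as_class_average_is_kept(self, model_projections):
        classes = _class_set([model_projections[0]])
        kept, rejected = filter_classes_by_profile(
            classes, model_projections, threshold=0.99)
        assert kept.n_classes == 1 and rejected == []

    @pytest.mark.parametrize("seed", range(5))
    def test_corrupted_classes_rejected_exactly(self, seed, model_projections):
        """17 genuine class averages + 3 contrast-inverted artifact classes
        (the signature of an uncorrected CTF sign error): exactly the
        corrupted classes fall below the 0.2 profile-correlation threshold."""
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(model_projections), 17, replace=True)
        images = [model_projections[i] + rng.normal(0, 1.0, model_projections[0].shape)
                  for i in idx]
        bad_slots = rng.choice(20, 3, replace=False)
        for slot in sorted(bad_slots):
            j = rng.integers(len(model_projections))
            images.insert(slot, -model_projections[j]
                          + rng.normal(0, 1.0, model_projections[0].shape))
        classes = _class_set(images)
        kept, rejected_images = filter_classes_by_profile(
            classes, model_projections, threshold=0.2)
        assert kept.n_classes == 17
        expected = sorted(i for slot in bad_slots
                          for i in range(3 * slot, 3 * slot + 3))
        assert rejected_images == expected

    def test_pure_noise_classes_mostly_rejected(self, model_projections):
        """Pure-noise class averages carry no consistent radial structure;
        with ~20 profile bins their best correlation is a null draw, so the
        0.2 threshold rejects most (but not provably all) of them while
        never touching genuine classes."""
        rng = np.random.default_rng(0)
        n_noise, rejected_noise = 0, 0
        scale = model_projections.std()
        for _ in range(15):
            images = [model_projections[rng.integers(len(model_projections))]
                      + rng.normal(0, 1.0, model_projections[0].shape)
                      for _ in range(4)]
            images.append(rng.normal(0, scale, model_projections[0].shape))
            kept, rejected_images = filter_classes_by_profile(
                _class_set(images), model_projections, threshold=0.2)
            assert kept.n_classes >= 4  # genuine classes always survive
            n_noise += 1
            rejected_noise += (len(rejected_images) > 0)
        assert rejected_noise >= 0.6 * n_noise

    def test_vacuous_threshold_rejects_nothing(self, model_projections):
        rng = np.random.default_rng(0)
        images = [rng.normal(size=model_projections[0].shape) for _ in range(5)]
        kept, rejected = filter_classes_by_profile(
            _class_set(images), model_projections, threshold=-1.0)
        assert kept.n_classes == 5 and rejected == []

    def test_empty_projection_set_rejected(self):
        with pytest.raises(ValueError):
            filter_classes_by_profile(_class_set([np.zeros((8, 8))]),
                                      np.zeros((0, 8, 8)))


class TestBootstrapVariance:
    def test_identical_images_have_no_resampling_variance(self):
        rng = np.random.default_rng(0)
        img = rng.normal(size=(24, 24)).astype(np.float32)
        angs = [uniform_orientations(1, rng)[0]] * 30
        stack = ImageStack(np.stack([img] * 30), 1.0)
        res = bootstrap_variance(stack, angs, n_bootstrap=20, seed=0)
        scale = np.abs(res.mean_map.data).max()
        assert res.raw_variance_map.data.max() <= 1e-10 * max(scale, 1.0)

    def test_background_only_input_cancels(self):
        """The same background stack passed as both inputs: the paired
        resampling design makes the subtraction exact, so the corrected map
        collapses."""
        rng = np.random.default_rng(1)
        bg = rng.normal(0, 2.0, (60, 24, 24)).astype(np.float32)
        angs = uniform_orientations(60, rng)
        res = bootstrap_variance(ImageStack(bg, 1.0), angs, n_bootstrap=100,
                                 background_stack=ImageStack(bg.copy(), 1.0),
                                 seed=1)
        raw99 = np.percentile(res.raw_variance_map.data, 99)
        corr99 = np.percentile(res.corrected_variance_map.data, 99)
        assert corr99 <= 0.05 * raw99

    def test_corrected_variance_nonnegative(self):
        rng = np.random.default_rng(2)
        imgs = rng.normal(0, 1.0, (20, 16, 16)).astype(np.float32)
        bg = rng.normal(0, 3.0, (20, 16, 16)).astype(np.float32)
        angs = uniform_orientations(20, rng)
        res = bootstrap_variance(ImageStack(imgs, 1.0), angs, n_bootstrap=30,
                                 background_stack=ImageStack(bg, 1.0), seed=2)
        assert res.corrected_variance_map.data.min() >= 0.0

    def test_bootstrap_mean_converges_to_reconstruction(self):
        rng = np.random.default_rng(3)
        spec = default_phantom_spec("disordered", box_size=32, voxel_size=10.0)
        vol = make_phantom(spec)
        angs = uniform_orientations(80, rng)
        imgs = np.stack([project(vol, a) for a in angs])
        stack = ImageStack(imgs, 10.0)
        res = bootstrap_variance(stack, angs, n_bootstrap=200, seed=3)
        plain = backproject_weighted(imgs, angs, 10.0)
        corr = np.corrcoef(res.mean_map.data.ravel(), plain.data.ravel())[0, 1]
        assert corr > 0.99

    @pytest.mark.parametrize("seed", range(3))
    def test_localizes_injected_heterogeneity(self, seed):
        """Mixed stack from two conformations differing in one strong shell
        patch: the top-1% corrected-variance voxels overlap the known
        differing region with Dice >= 0.3."""
        n, vox = 32, 10.0
        base = make_phantom(default_phantom_spec(
            "disordered", box_size=n, voxel_size=vox, knob=False))
        c = (n - 1) / 2
        zz, yy, xx = np.mgrid[:n, :n, :n]
        r = np.sqrt((zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2) * vox
        ux = (xx - c) * vox / np.maximum(r, 1e-9)
        patch = (r > 90) & (r < 115) & (ux > 0.85)
        va = VolumeMap(base.data + 3.0 * patch, vox)
        rng = np.random.default_rng(seed)
        angs = uniform_orientations(200, rng)
        imgs = np.stack([
            project(va if i % 2 == 0 else base, a) + rng.normal(0, 2.0, (n, n))
            for i, a in enumerate(angs)])
        bg = ImageStack(rng.normal(0, 2.0, (200, n, n)).astype(np.float32), vox)
        res = bootstrap_variance(ImageStack(imgs, vox), angs, n_bootstrap=200,
                                 background_stack=bg, seed=seed)
        cv = res.corrected_variance_map.data
        k = max(1, int(0.01 * cv.size))
        top = cv >= np.partition(cv.ravel(), -k)[-k]
        dice = 2 * (top & patch).sum() / (top.sum() + patch.sum())
        assert dice >= 0.3

    def test_ordered_core_less_variable_than_fluid_core(self):
        """Populations with frozen (identical) ordered cores show lower
        median core variance than populations whose disordered cores carry
        per-particle realization noise."""
        n, vox = 32, 10.0
        rng = np.random.default_rng(4)
        c = (n - 1) / 2
        zz, yy, xx = np.mgrid[:n, :n, :n]
        core = (np.sqrt((zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2) * vox) < 75

        def dataset(fluid):
            from scipy import ndimage as ndi
            vols = []
            for _ in range(8):
                spec = default_phantom_spec(
                    "ordered" if not fluid else "disordered",
                    box_size=n, voxel_size=vox)
                data = make_phantom(spec).data.copy()
                if fluid:  # per-particle random core realization
                    bump = ndi.gaussian_filter(rng.normal(0, 1.0, data.shape), 1.5)
                    data[core] += 0.8 * bump[core]
                vols.append(VolumeMap(data, vox))
            angs = uniform_orientations(160, rng)
            imgs = np.stack([project(vols[i % 8], a) + rng.normal(0, 1.0, (n, n))
                             for i, a in enumerate(angs)])
            return ImageStack(imgs, vox), angs

        med = {}
        for fluid in (False, True):
            stack, angs = dataset(fluid)
            res = bootstrap_variance(stack, angs, n_bootstrap=100, seed=4)
            med[fluid] = np.median(res.raw_variance_map.data[core])
        assert med[False] < med[True]

    def test_too_few_bootstraps_rejected(self):
        stack = ImageStack(np.zeros((4, 8, 8)), 1.0)
        angs = uniform_orientations(4, np.random.default_rng(0))
        with pytest.raises(ValueError):
            bootstrap_variance(stack, angs, n_bootstrap=1)
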
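"""Region statistics, cropping, sphere fitting, factory-sphere classification."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from orbct import (
    PhantomSpec,
    RegionMask,
    Sphere,
    VoxelVolume,
    classify_against_factory_sphere,
    crop_dedicated_volume,
    estimate_diameter_mm,
    fit_sphere_least_squares,
    generate_phantom,
    region_statistics,
    sphere_from_three_points,
)
from orbct.region_analysis import DegenerateGeometryError, surface_voxel_centers


def _vol(values, spacing=0.25, origin=(0, 0, 0)):
    return VoxelVolume(values=values, spacing_mm=[spacing] * 3, origin_mm=origin)


class TestRegionStatistics:
    def test_constant_region(self):
        vol = _vol(np.full((5, 5, 5), 7.0))
        mask = np.zeros((5, 5, 5), dtype=bool)
        mask.flat[:10] = True
        st = region_statistics(vol, RegionMask(selector=mask))
        assert (st.mean_hu, st.sd_hu, st.max_hu, st.n_voxels) == (7.0, 0.0, 7.0, 10)
        assert st.volume_mm3 == pytest.approx(10 * 0.25**3)

    def test_two_point_region(self):
        arr = np.zeros((2, 1, 1))
        arr[1] = 1000.0
        st = region_statistics(_vol(arr), RegionMask(selector=np.ones((2, 1, 1), bool)))
        assert (st.mean_hu, st.max_hu) == (500.0, 1000.0)

    def test_single_voxel_sd_defined_as_zero(self):
        mask = np.zeros((3, 3, 3), dtype=bool)
        mask[1, 1, 1] = True
        st = region_statistics(_vol(np.ones((3, 3, 3))), RegionMask(selector=mask))
        assert (st.sd_hu, st.n_voxels) == (0.0, 1)

    def test_value_permutation_within_mask_leaves_stats_unchanged(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(size=(4, 4, 4))
        mask = rng.random((4, 4, 4)) > 0.5
        st1 = region_statistics(_vol(vals), RegionMask(selector=mask))
        shuffled = vals.copy()
        sel = shuffled[mask]
        shuffled[mask] = rng.permutation(sel)
        st2 = region_statistics(_vol(shuffled), RegionMask(selector=mask))
        assert st2.mean_hu == pytest.approx(st1.mean_hu)
        assert st2.sd_hu == pytest.approx(st1.sd_hu)
        assert st2.max_hu == st1.max_hu

    def test_noisy_implant_region_mean_within_clt_bound(self):
        """Simulated implant at 600 HU with 50 HU noise: CLT bound on mean."""
        spec = PhantomSpec(
            implant_true_hu=600.0, pore_fraction=0.0, noise_sd_hu=50.0, seed=21
        )
        truth = generate_phantom(spec)
        st = region_statistics(truth.observed_volume, truth.masks["OI"])
        assert st.mean_hu == pytest.approx(600.0, abs=3 * 50.0 / np.sqrt(st.n_voxels))

    def test_errors(self):
        vol = _vol(np.zeros((3, 3, 3)))
        with pytest.raises(ValueError):
            region_statistics(vol, RegionMask(selector=np.zeros((3, 3, 3), bool)))
        with pytest.raises(ValueError):
            region_statistics(vol, RegionMask(selector=np.zeros((2, 2, 2), bool)))


class TestCrop:
    def test_box_covering_everything_is_identity(self):
        vol = _vol(np.arange(64.0).reshape(4, 4, 4))
        out = crop_dedicated_volume(vol, (-1, 10, -1, 10, -1, 10))
        np.testing.assert_array_equal(out.values, vol.values)
        np.testing.assert_array_equal(out.origin_mm, vol.origin_mm)

    def test_single_voxel_box(self):
        vol = _vol(np.arange(64.0).reshape(4, 4, 4), spacing=1.0)
        out = crop_dedicated_volume(vol, (1.9, 2.1, 0.9, 1.1, 2.9, 3.1))
        assert out.shape == (1, 1, 1)
        assert out.values[0, 0, 0] == vol.values[2, 1, 3]
        np.testing.assert_allclose(out.origin_mm, [2.0, 1.0, 3.0])

    def test_retained_count_matches_exhaustive_center_enumeration(self):
        rng = np.random.default_rng(9)
        vol = _vol(rng.normal(size=(7, 6, 5)), spacing=0.6, origin=(-1.0, 0.3, 2.0))
        lo = vol.origin_mm + rng.uniform(0.0, 1.0, size=3)
        hi = lo + rng.uniform(0.9, 3.0, size=3)
        bounds = np.column_stack([lo, hi]).ravel()
        out = crop_dedicated_volume(vol, bounds)
        centers = vol.all_centers_mm().reshape(-1, 3)
        inside = np.all((centers >= lo) & (centers <= hi), axis=1)
        assert out.values.size == int(inside.sum()) > 0
        # retained voxels keep their world coordinates
        out_centers = out.all_centers_mm().reshape(-1, 3)
        assert set(map(tuple, np.round(out_centers, 9))) <= set(
            map(tuple, np.round(centers, 9))
        )

    def test_empty_intersection_rejected(self):
        vol = _vol(np.zeros((3, 3, 3)))
        with pytest.raises(ValueError):
            crop_dedicated_volume(vol, (10, 11, 10, 11, 10, 11))


class TestThreePointSphere:
    def test_unit_great_circle(self):
        s = sphere_from_three_points((1, 0, 0), (-1, 0, 0), (0, 1, 0))
        np.testing.assert_allclose(s.center_mm, [0, 0, 0], atol=1e-12)
        assert s.radius_mm == pytest.approx(1.0)
        assert s.diameter_mm == pytest.approx(2.0)

    def test_permutation_invariance(self):
        pts = [(1.0, 2.0, 3.0), (4.0, 2.0, -1.0), (0.5, -2.0, 1.0)]
        base = sphere_from_three_points(*pts)
        for perm in [(1, 0, 2), (2, 1, 0), (1, 2, 0)]:
            s = sphere_from_three_points(*(pts[i] for i in perm))
            np.testing.assert_allclose(s.center_mm, base.center_mm, atol=1e-9)
            assert s.radius_mm == pytest.approx(base.radius_mm)

    def test_rigid_motion_equivariance(self):
        """Rotate+translate inputs: center co-transforms, radius invariant."""
        rng = np.random.default_rng(13)
        pts = np.array([[9.0, 0, 0], [-9.0, 0, 0], [0, 9.0, 0]])  # radius-9 circle
        for _ in range(25):
            rot = Rotation.random(rng=rng).as_matrix()
            t = rng.uniform(-50, 50, size=3)
            moved = pts @ rot.T + t
            s = sphere_from_three_points(*moved)
            assert s.radius_mm == pytest.approx(9.0, abs=1e-9)
            np.testing.assert_allclose(s.center_mm, rot @ np.zeros(3) + t, atol=1e-8)

    def test_collinear_and_duplicate_points_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            sphere_from_three_points((0, 0, 0), (1, 0, 0), (2, 0, 0))
        with pytest.raises(DegenerateGeometryError):
            sphere_from_three_points((1, 1, 1), (1, 1, 1), (0, 2, 0))


class TestLeastSquaresSphere:
    def _sphere_points(self, center, radius, n, rng):
        v = rng.normal(size=(n, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        return center + radius * v

    def test_exact_points_recovered_to_machine_precision(self):
        rng = np.random.default_rng(2)
        pts = self._sphere_points(np.array([3.0, -2.0, 7.0]), 9.0, 6, rng)
        s = fit_sphere_least_squares(pts)
        np.testing.assert_allclose(s.center_mm, [3.0, -2.0, 7.0], atol=1e-9)
        assert s.radius_mm == pytest.approx(9.0, abs=1e-9)

    def test_noisy_fit_radius_within_observed_monte_carlo_spread(self):
        radii = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            pts = self._sphere_points(np.zeros(3), 10.0, 500, rng)
            pts += rng.normal(0.0, 0.1, size=pts.shape)
            radii.append(fit_sphere_least_squares(pts).radius_mm)
        assert np.all(np.abs(np.array(radii) - 10.0) < 0.05)

    def test_reduces_to_three_point_sphere_on_great_circle_plus_poles(self):
        three = sphere_from_three_points((9, 0, 0), (-9, 0, 0), (0, 9, 0))
        pts = [(9, 0, 0), (-9, 0, 0), (0, 9, 0), (0, -9, 0), (0, 0, 9), (0, 0, -9)]
        ls = fit_sphere_least_squares(pts)
        np.testing.assert_allclose(ls.center_mm, three.center_mm, atol=1e-9)
        assert ls.radius_mm == pytest.approx(three.radius_mm, abs=1e-9)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            fit_sphere_least_squares([(1, 1, 1)] * 8)
        with pytest.raises(DegenerateGeometryError):
            fit_sphere_least_squares([(0, 0, 0), (1, 0, 0), (0, 1, 0)])


class TestFactoryClassification:
    def test_partition_conserves_voxels_and_inside_when_contained(self, clean_phantom):
        vol = clean_phantom.true_volume
        oi = clean_phantom.masks["OI"]
        big = Sphere(center_mm=clean_phantom.spec.implant_center_mm, radius_mm=50.0)
        inside, beyond = classify_against_factory_sphere(oi, vol, big)
        assert inside.n_voxels == oi.n_voxels and beyond.n_voxels == 0

    def test_counts_match_exhaustive_enumeration(self, clean_phantom):
        vol = clean_phantom.true_volume
        oi = clean_phantom.masks["OI"]
        half = Sphere(
            center_mm=clean_phantom.spec.implant_center_mm,
            radius_mm=clean_phantom.spec.implant_diameter_mm / 4.0,
        )
        inside, beyond = classify_against_factory_sphere(oi, vol, half)
        centers = vol.all_centers_mm().reshape(-1, 3)
        sel = oi.selector.ravel()
        d = np.linalg.norm(centers - np.asarray(half.center_mm), axis=1)
        assert inside.n_voxels == int(np.sum(sel & (d <= half.radius_mm)))
        assert beyond.n_voxels == int(np.sum(sel & (d > half.radius_mm)))
        assert inside.n_voxels + beyond.n_voxels == oi.n_voxels
        assert not np.any(inside.selector & beyond.selector)

    def test_spikes_land_beyond_factory_sphere(self):
        spec = PhantomSpec(
            noise_sd_hu=0.0, pore_fraction=0.0, spike_count=6,
            spike_length_mm=2.0, seed=3,
        )
        truth = generate_phantom(spec)
        factory = Sphere(
            center_mm=spec.implant_center_mm, radius_mm=spec.implant_diameter_mm / 2
        )
        _, beyond = classify_against_factory_sphere(
            truth.masks["OI"], truth.true_volume, factory
        )
        beyond_idx = set(map(tuple, np.argwhere(beyond.selector)))
        assert beyond_idx  # spikes exist
        assert beyond_idx <= truth.spike_voxels  # confined to recorded spike sites


class TestDiameterPipeline:
    @pytest.mark.parametrize("diameter", [16.0, 18.0, 20.0])
    def test_noiseless_estimate_within_one_voxel(self, diameter):
        spec = PhantomSpec(
            implant_diameter_mm=diameter, noise_sd_hu=0.0, pore_fraction=0.0, seed=1
        )
        truth = generate_phantom(spec)
        est = estimate_diameter_mm(truth.masks["OI"], truth.true_volume)
        assert abs(est - diameter) < spec.spacing_mm

    def test_surface_centers_lie_near_sphere_surface(self, clean_phantom):
        spec = clean_phantom.spec
        pts = surface_voxel_centers(clean_phantom.masks["OI"], clean_phantom.true_volume)
        d = np.linalg.norm(pts - np.asarray(spec.implant_center_mm), axis=1)
        assert np.all(d <= spec.implant_diameter_mm / 2 + 1e-9)
        assert np.all(d >= spec.implant_diameter_mm / 2 - 2 * spec.spacing_mm)
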
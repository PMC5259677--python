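"""Ellipse fitting, axis search and the discrete surface model."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from strandroller.barrel_model import (
    EllipseFitError,
    TooShortBarrelError,
    axis_direction_score,
    build_surface,
    center_map,
    ellipse_radius_at,
    find_axis,
    fit_ellipse,
    subsample_points,
    surface_lookup,
)
from strandroller.io_core import DensityMap
from strandroller.pipeline import detect
from strandroller.synthetic import BarrelSpec, generate_ideal_barrel, simulate_density

from conftest import make_ideal_surface


def ellipse_points(a, b, phi, center, n=36, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    psi = np.linspace(0, 2 * np.pi, n, endpoint=False)
    x = a * np.cos(psi)
    y = b * np.sin(psi)
    c, s = np.cos(phi), np.sin(phi)
    pts = np.column_stack([c * x - s * y, s * x + c * y]) + center
    if noise:
        pts += rng.normal(scale=noise, size=pts.shape)
    return pts


class TestFitEllipse:
    def test_exact_circle(self):
        fit = fit_ellipse(ellipse_points(10, 10, 0, (0, 0)))
        assert fit.a == pytest.approx(10, abs=1e-6)
        assert fit.b == pytest.approx(10, abs=1e-6)
        assert fit.residual < 1e-6

    def test_exact_ellipse_recovers_parameters(self):
        phi = np.radians(30)
        fit = fit_ellipse(ellipse_points(12, 8, phi, (3, -2)))
        assert fit.a == pytest.approx(12, abs=1e-6)
        assert fit.b == pytest.approx(8, abs=1e-6)
        assert fit.phi == pytest.approx(phi, abs=1e-6)
        np.testing.assert_allclose(fit.center, (3, -2), atol=1e-6)
        assert fit.residual < 1e-6

    def test_noisy_fit_unbiased_monte_carlo(self):
        # mean recovered semi-major over 100 noise draws stays near truth
        a_vals = [
            fit_ellipse(
                ellipse_points(12, 8, np.radians(30), (0, 0), n=200, noise=0.3, seed=s)
            ).a
            for s in range(100)
        ]
        assert np.mean(a_vals) == pytest.approx(12.0, abs=0.1)

    def test_agrees_with_independent_ellipse_model(self):
        pytest.importorskip("skimage")
        from skimage.measure import EllipseModel

        pts = ellipse_points(12, 8, np.radians(20), (5, 1), n=120, noise=0.1, seed=4)
        fit = fit_ellipse(pts)
        ref = EllipseModel.from_estimate(pts)
        ra, rb = sorted(ref.axis_lengths, reverse=True)
        assert fit.a == pytest.approx(ra, abs=0.05)
        assert fit.b == pytest.approx(rb, abs=0.05)

    def test_degenerate_inputs_rejected(self):
        line = np.column_stack([np.linspace(0, 10, 20), np.linspace(0, 5, 20)])
        with pytest.raises(EllipseFitError):
            fit_ellipse(line)
        with pytest.raises(EllipseFitError):
            fit_ellipse(np.zeros((4, 2)))

    def test_radius_lookup_consistent_with_points(self):
        fit = fit_ellipse(ellipse_points(12, 8, np.radians(30), (3, -2)))
        pts = ellipse_points(12, 8, np.radians(30), (3, -2), n=50)
        rel = pts - fit.center
        r = np.hypot(rel[:, 0], rel[:, 1])
        az = np.arctan2(rel[:, 1], rel[:, 0])
        np.testing.assert_allclose(r, ellipse_radius_at(fit, az), atol=1e-6)


class TestCenterMap:
    def test_already_centered_map_gets_identity_translation(self):
        values = np.zeros((9, 9, 9), np.float32)
        values[4, 4, 4] = 1.0
        dmap = DensityMap(values, 1.0, origin=(-4.5, -4.5, -4.5), threshold=0.5)
        centered, t = center_map(dmap)
        assert np.linalg.norm(t.translation) < 0.5
        np.testing.assert_allclose(centered.occupied_points()[0], 0, atol=1e-9)

    def test_known_shift_recovered(self, barrel8_map):
        shifted = DensityMap(
            barrel8_map.values,
            barrel8_map.voxel_size,
            barrel8_map.origin + np.array([5.0, -3.0, 2.0]),
            threshold=barrel8_map.threshold,
        )
        _, t0 = center_map(barrel8_map)
        _, t1 = center_map(shifted)
        np.testing.assert_allclose(
            t1.translation - t0.translation, [-5.0, 3.0, -2.0], atol=1e-9
        )

    def test_centroid_at_origin_after_centering(self, barrel8_map):
        centered, _ = center_map(barrel8_map)
        pts = centered.occupied_points()
        w = centered.occupied_values()
        centroid = (pts * w[:, None]).sum(axis=0) / w.sum()
        assert np.linalg.norm(centroid) < 0.5


class TestFindAxis:
    def test_z_aligned_barrel(self, barrel8_detection):
        axis = barrel8_detection.axis
        assert np.degrees(np.arccos(abs(axis.direction[2]))) < 5.0
        # the transform maps the direction onto +z
        np.testing.assert_allclose(
            axis.transform.rotation @ axis.direction, [0, 0, 1], atol=1e-6
        )

    def test_rotation_equivariance(self, barrel8_truth):
        R = Rotation.from_euler("zyx", [40, 25, 10], degrees=True).as_matrix()
        rotated = simulate_density(barrel8_truth.all_atoms @ R.T)
        centered, _ = center_map(rotated)
        axis = find_axis(centered)
        expected = R @ np.array([0.0, 0.0, 1.0])
        cosang = abs(np.dot(axis.direction, expected))
        assert np.degrees(np.arccos(np.clip(cosang, -1, 1))) <= 1.5

    def test_found_axis_is_local_optimum(self, barrel8_map, barrel8_detection):
        axis = barrel8_detection.axis
        centered, _ = center_map(barrel8_map)
        pts = centered.occupied_points()
        w = centered.occupied_values()
        pts = pts - (pts * w[:, None]).sum(axis=0) / w.sum()
        pts = subsample_points(pts, 4000)
        best = axis_direction_score(pts, axis.direction)
        u = np.array([1.0, 0.0, 0.0])
        u -= axis.direction * (u @ axis.direction)
        u /= np.linalg.norm(u)
        v = np.cross(axis.direction, u)
        for da in np.radians([-10, -5, -2, 2, 5, 10]):
            for db in np.radians([-10, -5, -2, 2, 5, 10]):
                d = axis.direction + np.tan(da) * u + np.tan(db) * v
                d /= np.linalg.norm(d)
                assert axis_direction_score(pts, d) >= best * (1 - 1e-9)

    def test_recovered_semi_axes_near_truth(self, barrel8_truth, barrel8_detection):
        fit = barrel8_detection.axis.fit
        assert fit.a == pytest.approx(barrel8_truth.spec.a, abs=1.0)
        assert fit.b == pytest.approx(barrel8_truth.spec.b, abs=1.0)


class TestBuildSurface:
    def test_surface_points_hug_slice_ellipses(self, barrel8_detection):
        for sl in barrel8_detection.surface.slices:
            rel = sl.points[:, :2] - sl.fit.center
            r = np.hypot(rel[:, 0], rel[:, 1])
            misfit = np.abs(r - ellipse_radius_at(sl.fit, sl.azimuths))
            assert np.median(misfit) < 1.0  # within one voxel of the ellipse

    def test_surface_points_on_occupied_voxels(self, barrel8_map, barrel8_detection):
        centered, _ = center_map(barrel8_map)
        occ = barrel8_detection.axis.transform.apply(centered.occupied_points())
        for sl in barrel8_detection.surface.slices:
            d = np.linalg.norm(sl.points[:, None, :] - occ[None], axis=-1).min(axis=1)
            assert d.max() < 1e-9  # surface points ARE occupied voxel centers

    def test_morphed_sector_follows_density(self):
        """Where the wall bulges outward, the surface must track the bulge."""
        truth = generate_ideal_barrel(BarrelSpec(n_strands=12, tilt_deg=45.0))
        atoms = truth.all_atoms.copy()
        az = np.arctan2(atoms[:, 1], atoms[:, 0])
        sector = np.abs(az) < np.radians(30)
        r = np.hypot(atoms[:, 0], atoms[:, 1])
        scale = (r + 5.0) / r
        atoms[sector, 0] *= scale[sector]
        atoms[sector, 1] *= scale[sector]
        res = detect(simulate_density(atoms))
        mid = res.surface.mid_slice()
        in_sector = np.abs(mid.azimuths) < np.radians(20)
        out_sector = np.abs(np.abs(mid.azimuths) - np.pi) < np.radians(60)
        assert mid.radii[in_sector].mean() > truth.spec.a + 1.0
        assert abs(mid.radii[out_sector].mean() - truth.spec.a) < 1.5

    def test_too_short_barrel_rejected(self):
        # a flat ring two voxels thick in z: fewer than 3 usable slices
        values = np.zeros((16, 16, 2), np.float32)
        xx, yy = np.meshgrid(np.arange(16), np.arange(16), indexing="ij")
        ring = np.abs(np.hypot(xx - 7.5, yy - 7.5) - 5) < 1
        values[ring, :] = 1.0
        dmap = DensityMap(values, 1.0, (-8, -8, -1), threshold=0.5)
        from strandroller.barrel_model import AxisResult, fit_ellipse as _fe
        from strandroller.io_core import RigidTransform

        xy = dmap.occupied_points()[:, :2]
        axis = AxisResult(
            direction=np.array([0.0, 0.0, 1.0]),
            transform=RigidTransform.identity(),
            fit=_fe(xy),
            score=0.0,
        )
        with pytest.raises(TooShortBarrelError):
            build_surface(dmap, axis)

    def test_density_gap_skips_bins_and_flags_lookup(self):
        truth = generate_ideal_barrel(BarrelSpec(n_strands=12, tilt_deg=45.0))
        az = np.arctan2(truth.all_atoms[:, 1], truth.all_atoms[:, 0])
        kept = truth.all_atoms[np.abs(az) > np.radians(60)]  # 120° gap
        dmap = simulate_density(kept)
        centered, _ = center_map(dmap)
        axis = find_axis(centered)
        surface = build_surface(centered, axis)
        mid = surface.mid_slice()
        assert len(mid.points) < surface.n_angular_bins  # gap bins emit nothing
        _, _, _, fallback = surface_lookup(surface, mid.z, 0.0, with_info=True)
        assert fallback


class TestSurfaceLookup:
    def test_reproduces_knots(self, ideal_surface):
        sl = ideal_surface.slices[3]
        p = surface_lookup(ideal_surface, sl.z, float(sl.azimuths[5]))
        np.testing.assert_allclose(p, sl.points[5], atol=1e-6)

    def test_constant_radius_everywhere(self, ideal_surface):
        rng = np.random.default_rng(0)
        for _ in range(50):
            z = rng.uniform(ideal_surface.z_min, ideal_surface.z_max)
            az = rng.uniform(-np.pi, np.pi)
            p = surface_lookup(ideal_surface, z, az)
            assert np.hypot(p[0], p[1]) == pytest.approx(8.643036635108217, abs=1e-9)

    def test_linear_interpolation_between_slices(self):
        model_lo = make_ideal_surface(9.0, z_min=0.0, z_max=1.0, n_slices=2)
        model_lo.slices[1].radii[:] = 11.0
        model_lo.slices[1].points[:, :2] *= 11.0 / 9.0
        model_lo.slices[1].fit.a = model_lo.slices[1].fit.b = 11.0
        p = surface_lookup(model_lo, 0.5, 0.7)
        assert np.hypot(p[0], p[1]) == pytest.approx(10.0, abs=0.1)

    def test_out_of_range_z_rejected(self, ideal_surface):
        with pytest.raises(ValueError):
            surface_lookup(ideal_surface, ideal_surface.z_max + 1.0, 0.0)

    def test_quantisation_bounded_on_real_barrel(self, barrel8_detection):
        surf = barrel8_detection.surface
        fit = barrel8_detection.axis.fit
        rng = np.random.default_rng(1)
        for _ in range(30):
            z = rng.uniform(surf.z_min, surf.z_max)
            az = rng.uniform(-np.pi, np.pi)
            p = surface_lookup(surf, z, az)
            r = np.hypot(p[0] - fit.center[0], p[1] - fit.center[1])
            assert abs(r - fit.a) < 1.6  # half-voxel quantisation + shell width
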
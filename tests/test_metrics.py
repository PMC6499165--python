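"""COG, peak, surface area, volume integral and peak discretization."""

import numpy as np
import pytest

import tmsmap as tm
from tmsmap.geometry import AngularGrid
from tmsmap.metrics import surface_area, surface_peak, volume_integral
from tmsmap.synthetic import SyntheticMapSpec, field_value


def dataset(points, values):
    return tm.MotorMapDataset(np.asarray(points, float), np.asarray(values, float))


class TestCog:
    def test_equal_values_give_unweighted_centroid(self, rng):
        pts = rng.uniform(-50, 50, (20, 3))
        cog = tm.center_of_gravity(dataset(pts, np.full(20, 7.0)))
        np.testing.assert_allclose(cog.xyz, pts.mean(axis=0), rtol=1e-12)

    def test_single_nonzero_value_pins_cog(self):
        pts = [[0, 0, 0], [10, 20, 30], [5, 5, 5]]
        cog = tm.center_of_gravity(dataset(pts, [0.0, 123.0, 0.0]))
        np.testing.assert_array_equal(cog.xyz, [10, 20, 30])

    def test_matches_naive_weighted_loop(self, rng):
        pts = rng.uniform(-50, 50, (50, 3))
        vals = rng.uniform(0, 1000, 50)
        cog = tm.center_of_gravity(dataset(pts, vals))
        num, den = np.zeros(3), 0.0
        for p, v in zip(pts, vals):
            num += p * v
            den += v
        np.testing.assert_allclose(cog.xyz, num / den, rtol=1e-12)

    def test_all_zero_values_raise(self):
        with pytest.raises(tm.ZeroMassError):
            tm.center_of_gravity(dataset([[1, 2, 3]], [0.0]))

    def test_cog_inside_convex_hull(self, rng):
        from scipy.spatial import Delaunay

        pts = rng.uniform(-50, 50, (30, 3))
        cog = tm.center_of_gravity(dataset(pts, rng.uniform(0, 100, 30)))
        assert Delaunay(pts).find_simplex(cog.xyz) >= 0

    def test_scale_equivariance(self, rng):
        pts = rng.uniform(-50, 50, (20, 3))
        vals = rng.uniform(1, 100, 20)
        a = tm.center_of_gravity(dataset(pts, vals))
        b = tm.center_of_gravity(dataset(pts, 3.7 * vals))
        np.testing.assert_allclose(a.xyz, b.xyz, rtol=1e-12)


class TestPeak:
    def test_strict_maximum(self):
        pos, val = tm.peak(dataset([[0, 0, 0], [1, 1, 1]], [10.0, 90.0]))
        np.testing.assert_array_equal(pos, [1, 1, 1])
        assert val == 90.0

    def test_tie_resolves_to_lowest_index(self):
        pos, _ = tm.peak(dataset([[0, 0, 0], [1, 1, 1]], [90.0, 90.0]))
        np.testing.assert_array_equal(pos, [0, 0, 0])

    def test_surface_peak_equals_exhaustive_scan(self, equator_patch_surface, sphere):
        surface, grid = equator_patch_surface
        pos, val = surface_peak(surface, sphere, grid)
        th, ph = grid.mesh()
        vals = surface(th, ph)
        flat = np.where(np.isfinite(vals), vals, -np.inf)
        best = np.max(flat)
        assert val == pytest.approx(best)
        i, j = np.unravel_index(int(np.argmax(flat)), vals.shape)
        np.testing.assert_allclose(
            pos, sphere.to_cartesian(grid.theta[i], grid.phi[j])
        )


class TestPositionReport:
    def test_zero_offset(self):
        ref = tm.ReferencePoint(1.0, 2.0, 3.0)
        assert tm.position_report([1.0, 2.0, 3.0], ref) == (0.0, 0.0, 0.0, 0.0)

    def test_three_four_five(self):
        ref = tm.ReferencePoint(0.0, 0.0, 0.0)
        dx, dy, dz, euclid = tm.position_report([3.0, 4.0, 0.0], ref)
        assert (dx, dy, dz, euclid) == (3.0, 4.0, 0.0, 5.0)

    def test_components_resum_to_norm(self, rng):
        for _ in range(20):
            p = rng.uniform(-100, 100, 3)
            r = rng.uniform(-100, 100, 3)
            dx, dy, dz, euclid = tm.position_report(p, tm.ReferencePoint(*r))
            assert euclid == pytest.approx(np.sqrt(dx**2 + dy**2 + dz**2), rel=1e-12)

    def test_translation_equivariance(self, rng):
        p = rng.uniform(-50, 50, 3)
        r = rng.uniform(-50, 50, 3)
        shift = rng.uniform(-50, 50, 3)
        a = tm.position_report(p, tm.ReferencePoint(*r))
        b = tm.position_report(p + shift, tm.ReferencePoint(*(r + shift)))
        np.testing.assert_allclose(a, b, atol=1e-9)


class TestSurfaceIntegrals:
    def test_no_cell_above_threshold_gives_zero(self, equator_patch_surface, sphere):
        surface, grid = equator_patch_surface
        assert surface_area(surface, sphere, grid, threshold=1e9) == 0.0
        assert volume_integral(surface, sphere, grid, threshold=1e9) == 0.0

    def test_spherical_cap_area_converges(self, sphere):
        """Discrete patch integration reaches the closed-form cap area
        2πR²(1−cos α) within 1% at 0.005 rad pixel spacing."""
        alpha, radius = 0.5, 100.0
        th_sites = np.linspace(0.0, 0.9, 10)
        ph_sites = np.linspace(-np.pi, np.pi, 25)
        th, ph = np.meshgrid(th_sites, ph_sites, indexing="ij")
        # linear-in-θ map: strictly positive exactly inside the cap θ < α
        surface = tm.fit_surface(
            th.ravel(), ph.ravel(), (alpha - th).ravel(),
            algorithm="piecewise_linear",
        )
        grid = AngularGrid(spacing=0.005, theta_min=0.0, theta_max=0.9,
                           phi_min=-np.pi, phi_max=np.pi)
        sa = surface_area(surface, sphere, grid, threshold=0.0)
        true = 2 * np.pi * radius**2 * (1 - np.cos(alpha))
        assert sa == pytest.approx(true, rel=0.01)

    def test_halving_spacing_changes_sa_under_half_percent(
        self, equator_patch_surface, sphere
    ):
        surface, grid = equator_patch_surface
        fine = AngularGrid(spacing=grid.spacing / 2, theta_min=grid.theta_min,
                           theta_max=grid.theta_max, phi_min=grid.phi_min,
                           phi_max=grid.phi_max)
        sa = surface_area(surface, sphere, grid, threshold=300.0)
        sa_fine = surface_area(surface, sphere, fine, threshold=300.0)
        assert abs(sa_fine - sa) / sa < 0.005

    def test_constant_map_vi_equals_value_times_sa(self, rng, sphere):
        ax = np.linspace(np.pi / 2 - 0.4, np.pi / 2 + 0.4, 9)
        th, ph = np.meshgrid(ax, ax - np.pi / 2, indexing="ij")
        surface = tm.fit_surface(th.ravel(), ph.ravel(), np.full(81, 250.0),
                                 algorithm="piecewise_linear")
        grid = AngularGrid(spacing=0.01, theta_min=ax[0], theta_max=ax[-1],
                           phi_min=-0.4, phi_max=0.4)
        sa = surface_area(surface, sphere, grid)
        vi = volume_integral(surface, sphere, grid)
        assert vi == pytest.approx(250.0 * sa, rel=1e-9)

    def test_doubling_values_doubles_vi_not_cog(self, equator_patch_surface,
                                                sphere, rng):
        surface, grid = equator_patch_surface
        doubled = tm.fit_surface(surface.sites[:, 0], surface.sites[:, 1],
                                 2.0 * surface.values, algorithm="piecewise_cubic")
        vi = volume_integral(surface, sphere, grid)
        vi2 = volume_integral(doubled, sphere, grid)
        assert vi2 == pytest.approx(2.0 * vi, rel=1e-9)
        pts = rng.uniform(-50, 50, (20, 3))
        vals = rng.uniform(1, 100, 20)
        cog = tm.center_of_gravity(dataset(pts, vals))
        cog2 = tm.center_of_gravity(dataset(pts, 2.0 * vals))
        np.testing.assert_allclose(cog.xyz, cog2.xyz, rtol=1e-12)

    def test_matches_independent_riemann_loop(self, sphere):
        """SA and VI equal an explicit per-cell loop over patch cross
        products on a small grid."""
        ax = np.linspace(np.pi / 2 - 0.3, np.pi / 2 + 0.3, 7)
        th, ph = np.meshgrid(ax, ax - np.pi / 2, indexing="ij")
        spec = SyntheticMapSpec(width_rad=0.2)
        values = field_value(spec, th, ph)
        surface = tm.fit_surface(th.ravel(), ph.ravel(), values.ravel(),
                                 algorithm="piecewise_linear")
        grid = AngularGrid(spacing=0.05, theta_min=ax[0], theta_max=ax[-1],
                           phi_min=-0.3, phi_max=0.3)
        threshold = 400.0
        sa_ref, vi_ref = 0.0, 0.0
        for t in grid.theta:
            for p in grid.phi:
                v = surface(np.array(t), np.array(p))
                if np.isnan(v) or v <= threshold:
                    continue
                p0 = np.asarray(sphere.to_cartesian(t, p))
                pq = np.asarray(sphere.to_cartesian(t + grid.spacing, p)) - p0
                qq = np.asarray(sphere.to_cartesian(t, p + grid.spacing)) - p0
                patch = np.linalg.norm(np.cross(pq, qq))
                sa_ref += patch
                vi_ref += patch * v
        assert surface_area(surface, sphere, grid, threshold) == pytest.approx(
            sa_ref, rel=1e-9
        )
        assert volume_integral(surface, sphere, grid, threshold) == pytest.approx(
            vi_ref, rel=1e-9
        )

    def test_sa_vi_non_increasing_in_threshold(self, equator_patch_surface, sphere):
        surface, grid = equator_patch_surface
        thresholds = [0.0, 100.0, 300.0, 600.0, 900.0]
        sas = [surface_area(surface, sphere, grid, t) for t in thresholds]
        vis = [volume_integral(surface, sphere, grid, t) for t in thresholds]
        assert all(b <= a for a, b in zip(sas, sas[1:]))
        assert all(b <= a for a, b in zip(vis, vis[1:]))

    def test_sa_threshold_zero_invariant_under_value_scaling(
        self, equator_patch_surface, sphere
    ):
        surface, grid = equator_patch_surface
        scaled = tm.fit_surface(surface.sites[:, 0], surface.sites[:, 1],
                                5.0 * surface.values, algorithm="piecewise_cubic")
        assert surface_area(scaled, sphere, grid, 0.0) == pytest.approx(
            surface_area(surface, sphere, grid, 0.0), rel=1e-12
        )


def two_bump_surface(separation=0.6, width=0.1, amps=(1000.0, 800.0)):
    ax = np.linspace(np.pi / 2 - 0.6, np.pi / 2 + 0.6, 25)
    th, ph = np.meshgrid(ax, ax - np.pi / 2, indexing="ij")
    centers = [(np.pi / 2, -separation / 2), (np.pi / 2, separation / 2)]
    v = sum(
        a * np.exp(-(((th - ct) ** 2 + (ph - cp) ** 2) / (2 * width**2)))
        for a, (ct, cp) in zip(amps, centers)
    )
    surface = tm.fit_surface(th.ravel(), ph.ravel(), v.ravel(),
                             algorithm="piecewise_cubic")
    grid = AngularGrid(spacing=0.02, theta_min=ax[0], theta_max=ax[-1],
                       phi_min=-0.6, phi_max=0.6)
    return surface, grid, centers


class TestPeakDiscretization:
    def test_two_bumps_give_two_regions_at_their_centers(self, sphere):
        surface, grid, centers = two_bump_surface()
        regions = tm.discretize_peaks(surface, sphere, grid, threshold=50.0)
        assert len(regions) == 2
        got = sorted(
            tm.cartesian_to_angular(r.peak_position, sphere.centroid)[1]
            for r in regions
        )
        for g, (_, cp) in zip(got, centers):
            assert g == pytest.approx(cp, abs=grid.spacing + 1e-9)

    def test_single_bump_single_region_subset_of_total(self, sphere):
        surface, grid, _ = two_bump_surface(amps=(1000.0, 0.0))
        regions = tm.discretize_peaks(surface, sphere, grid, threshold=50.0)
        assert len(regions) == 1
        total_sa = surface_area(surface, sphere, grid, threshold=50.0)
        assert regions[0].surface_area <= total_sa + 1e-9

    def test_region_vi_sums_below_total(self, sphere):
        surface, grid, _ = two_bump_surface()
        threshold = 50.0
        regions = tm.discretize_peaks(surface, sphere, grid, threshold)
        total_vi = volume_integral(surface, sphere, grid, threshold)
        assert sum(r.volume_integral for r in regions) <= total_vi + 1e-6

    def test_no_cell_above_threshold_raises(self, sphere):
        surface, grid, _ = two_bump_surface()
        with pytest.raises(tm.NoPeakError):
            tm.discretize_peaks(surface, sphere, grid, threshold=1e9)


class TestRigidMotionInvariance:
    def test_rotated_inputs_leave_distance_reports_unchanged(self, rng):
        from scipy.spatial.transform import Rotation

        pts = rng.uniform(-50, 50, (25, 3))
        vals = rng.uniform(0, 500, 25)
        ref = rng.uniform(-50, 50, 3)
        rot = Rotation.from_rotvec([0.3, -0.2, 0.5])
        shift = np.array([10.0, -20.0, 5.0])
        pts_r = rot.apply(pts) + shift
        ref_r = rot.apply(ref) + shift
        a = dataset(pts, vals)
        b = dataset(pts_r, vals)
        cog_a = tm.center_of_gravity(a)
        cog_b = tm.center_of_gravity(b)
        da = tm.position_report(cog_a.xyz, tm.ReferencePoint(*ref))
        db = tm.position_report(cog_b.xyz, tm.ReferencePoint(*ref_r))
        assert da[3] == pytest.approx(db[3], abs=1e-6)
        pa = tm.position_report(tm.peak(a)[0], tm.ReferencePoint(*ref))
        pb = tm.position_report(tm.peak(b)[0], tm.ReferencePoint(*ref_r))
        assert pa[3] == pytest.approx(pb[3], abs=1e-6)
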
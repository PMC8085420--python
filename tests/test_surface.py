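"""Surface lattice construction, dose transfer, accumulation, geometry."""

import numpy as np
import pytest

import rectodose as rd
from rectodose.cohort import GridSpec

from conftest import make_cylinder, constant_surface_dose, N_THETA


@pytest.fixture(scope="module")
def cyl():
    contours = make_cylinder(radius=10, length=100, n_slices=11)
    return contours, rd.build_surface_lattice(contours, n_theta=N_THETA)


class TestLattice:
    def test_cylinder_surface_area(self, cyl):
        _, lat = cyl
        assert lat.total_area == pytest.approx(2 * np.pi * 10 * 100, rel=0.02)

    def test_ring_circumference_matches_polygon_perimeter(self, cyl):
        contours, lat = cyl
        from shapely.geometry.polygon import LinearRing
        for poly, circ in zip(contours.polygons, lat.circumferences):
            assert circ == pytest.approx(LinearRing(poly).length, rel=0.01)

    def test_single_slice_rejected(self):
        contours = make_cylinder(n_slices=2)
        short = rd.ContourStack(zs=contours.zs[:1], polygons=contours.polygons[:1])
        with pytest.raises(ValueError):
            rd.build_surface_lattice(short, n_theta=32)

    def test_self_intersecting_polygon_names_slice(self):
        bad = np.array([[0, 0], [10, 10], [10, 0], [0, 10]], float)
        good = make_cylinder(n_slices=2)
        stack = rd.ContourStack(zs=[0.0, 5.0], polygons=[good.polygons[0], bad])
        with pytest.raises(ValueError, match="slice 1"):
            rd.build_surface_lattice(stack, n_theta=32)

    def test_anchor_and_anterior_first_traversal(self, cyl):
        _, lat = cyl
        # v=0 column sits at +x (patient left); first half heads to -y (anterior)
        assert lat.vertices[0, 0, 0] == pytest.approx(10.0, abs=1e-6)
        assert lat.vertices[0, 0, 1] == pytest.approx(0.0, abs=1e-6)
        quarter = N_THETA // 4
        assert lat.vertices[0, quarter, 1] < 0           # anterior = -y
        assert lat.vertices[0, 3 * quarter, 1] > 0       # posterior = +y

    def test_uv_labels_invariant_under_translation(self):
        a = make_cylinder(radius=10, length=50, n_slices=6)
        b = make_cylinder(radius=10, length=50, n_slices=6, center=(5.0, -7.0), z0=30)
        la = rd.build_surface_lattice(a, n_theta=64)
        lb = rd.build_surface_lattice(b, n_theta=64)
        np.testing.assert_allclose(la.u, lb.u)
        np.testing.assert_allclose(
            lb.vertices[:, :, :2] - np.array([5.0, -7.0]),
            la.vertices[:, :, :2], atol=1e-9)


class TestDoseTransfer:
    def test_constant_six_gray_grid_maps_to_eqd2(self, cyl):
        _, lat = cyl
        grid = rd.DoseGrid(np.full((30, 30, 60), 6.0),
                           origin=(-14, -14, -5), spacing=(1, 1, 2))
        sd = rd.map_dose_to_surface(grid, lat)
        np.testing.assert_allclose(sd.dose, 10.8, rtol=1e-12)

    def test_zero_grid_gives_zero(self, cyl):
        _, lat = cyl
        grid = rd.DoseGrid(np.zeros((30, 30, 60)),
                           origin=(-14, -14, -5), spacing=(1, 1, 2))
        assert rd.map_dose_to_surface(grid, lat).dose.max() == 0.0

    def test_grid_scaling_scales_physical_dose(self, cyl):
        _, lat = cyl
        rng = np.random.default_rng(3)
        vals = rng.uniform(0.5, 4.0, (30, 30, 60))
        g1 = rd.DoseGrid(vals, origin=(-14, -14, -5), spacing=(1, 1, 2))
        g2 = rd.DoseGrid(2 * vals, origin=(-14, -14, -5), spacing=(1, 1, 2))
        p1 = rd.sample_trilinear(g1, lat.vertices.reshape(-1, 3))
        p2 = rd.sample_trilinear(g2, lat.vertices.reshape(-1, 3))
        np.testing.assert_allclose(p2, 2 * p1, rtol=1e-12)


class TestAccumulation:
    def test_identical_fractions_double(self, cyl):
        _, lat = cyl
        sd = constant_surface_dose(lat, 3.0)
        out = rd.accumulate_fractions([sd, sd])
        np.testing.assert_allclose(out.dose, 6.0)

    def test_five_uniform_fractions(self, cyl):
        _, lat = cyl
        out = rd.accumulate_fractions([constant_surface_dose(lat, 10.8)] * 5)
        np.testing.assert_allclose(out.dose, 54.0, rtol=1e-12)

    def test_order_invariance_with_fixed_reference(self, cyl):
        _, lat = cyl
        rng = np.random.default_rng(4)
        sds = [rd.SurfaceDose(lat, rng.uniform(0, 5, (lat.rings, lat.n_theta)))
               for _ in range(3)]
        a = rd.accumulate_fractions(sds, reference=0)
        b = rd.accumulate_fractions([sds[0], sds[2], sds[1]], reference=0)
        np.testing.assert_allclose(a.dose, b.dose)

    def test_linearity(self, cyl):
        _, lat = cyl
        rng = np.random.default_rng(5)
        X = rng.uniform(0, 5, (lat.rings, lat.n_theta))
        Y = rng.uniform(0, 5, (lat.rings, lat.n_theta))
        a = rd.accumulate_fractions([rd.SurfaceDose(lat, 2 * X), rd.SurfaceDose(lat, 2 * Y)])
        b = rd.accumulate_fractions([rd.SurfaceDose(lat, X), rd.SurfaceDose(lat, Y)])
        np.testing.assert_allclose(a.dose, 2 * b.dose, rtol=1e-12)

    def test_ring_count_mismatch_resampled_in_u(self):
        c1 = make_cylinder(radius=10, length=100, n_slices=11)
        c2 = make_cylinder(radius=10, length=100, n_slices=6)
        l1 = rd.build_surface_lattice(c1, n_theta=64)
        l2 = rd.build_surface_lattice(c2, n_theta=64)
        out = rd.accumulate_fractions(
            [constant_surface_dose(l1, 1.0), constant_surface_dose(l2, 2.0)])
        assert out.lattice.rings == l1.rings
        np.testing.assert_allclose(out.dose, 3.0, rtol=1e-12)

    def test_errors(self, cyl):
        _, lat = cyl
        with pytest.raises(ValueError):
            rd.accumulate_fractions([])
        other = rd.build_surface_lattice(make_cylinder(n_slices=3), n_theta=32)
        with pytest.raises(ValueError):
            rd.accumulate_fractions([constant_surface_dose(lat, 1),
                                     constant_surface_dose(other, 1)])


class TestGeometryMetrics:
    def test_cylinder_volume(self, cyl):
        contours, _ = cyl
        rep = rd.geometry_metrics(contours)
        assert rep.wall_volume_cm3 == pytest.approx(np.pi * 100 * 100 / 1000, rel=0.02)

    def test_circular_separations_equal_diameter(self, cyl):
        contours, _ = cyl
        rep = rd.geometry_metrics(contours)
        assert rep.ap_separation_mm == pytest.approx(20.0, rel=0.01)
        assert rep.lateral_separation_mm == pytest.approx(20.0, rel=0.01)

    def test_hottest_anterior_vertex_nearest_point_source(self, cyl):
        contours, lat = cyl
        ctv = np.array([0.0, -30.0, 50.0])
        spec = GridSpec(origin=(-15, -15, -5), spacing=(2, 2, 2), shape=(16, 16, 56))
        grid = rd.compute_fraction_dose(np.array([[*ctv, 1.0]]), spec, 100.0)
        sd = rd.map_dose_to_surface(grid, lat)
        rep = rd.geometry_metrics(contours, ctv, sd)
        verts = lat.vertices.reshape(-1, 3)
        ant = sd.region_mask("anterior").ravel()
        dmin = np.linalg.norm(verts[ant] - ctv, axis=1).min()
        assert rep.anterior_extremum_to_ctv_mm == pytest.approx(dmin, abs=1.0)

    def test_missing_ctv_omits_distances(self, cyl):
        contours, _ = cyl
        rep = rd.geometry_metrics(contours)
        assert rep.anterior_extremum_to_ctv_mm is None
        assert rep.posterior_extremum_to_ctv_mm is None


def test_ply_export(tmp_path, cyl=None):
    contours = make_cylinder(radius=5, length=20, n_slices=3, n_points=24)
    lat = rd.build_surface_lattice(contours, n_theta=16)
    sd = constant_surface_dose(lat, 2.0)
    from rectodose.surface import write_ply
    path = tmp_path / "s.ply"
    write_ply(sd, path)
    text = path.read_text().splitlines()
    assert text[0] == "ply"
    assert f"element vertex {3 * 16}" in text
    assert f"element face {2 * 16}" in text
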
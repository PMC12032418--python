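"""Phantom geometry: spheres, nesting, interior grids, centroids, mesh IO."""

import numpy as np
import pytest

from uteroacoustics.media import AIR, get_medium
from uteroacoustics.phantom import (
    MeshFormatError,
    SurfaceMesh,
    icosphere,
    interior_grid,
    nested_sphere_phantom,
    nested_three_region_phantom,
    read_mesh,
    signed_solid_angles,
    subdivisions_for_edge,
    volume_centroid,
    winding_number,
    write_mesh,
)


class TestIcosphere:
    def test_base_icosahedron(self):
        m = icosphere(1.0, 0)
        assert m.triangles.shape == (20, 3)
        assert m.vertices.shape == (12, 3)
        m.validate()

    @pytest.mark.parametrize("n", [0, 1, 2, 3])
    def test_triangle_count(self, n):
        assert icosphere(2.0, n).triangles.shape[0] == 20 * 4 ** n

    def test_area_converges_to_sphere(self):
        m = icosphere(0.25, 4)
        assert m.area == pytest.approx(4 * np.pi * 0.25 ** 2, rel=0.01)
        assert m.volume() == pytest.approx(4 / 3 * np.pi * 0.25 ** 3, rel=0.02)

    def test_watertight_and_oriented(self):
        for n in (0, 2):
            m = icosphere(1.0, n)
            m.validate()
            # flipping one triangle breaks consistency
            bad = SurfaceMesh(m.vertices.copy(), m.triangles.copy())
            bad.triangles[0] = bad.triangles[0][[0, 2, 1]]
            assert not bad.is_watertight()


class TestNestedPhantoms:
    def test_two_sphere_containment_and_media(self):
        topo = nested_sphere_phantom(0.25, 0.15, 5.0, 1000.0)
        assert [s.region_label for s in topo.surfaces] == ["abdomen", "uterus"]
        inner = topo.surfaces[1]
        w = winding_number(topo.surfaces[0], inner.vertices)
        assert np.all(np.abs(w) > 0.5)
        assert topo.medium_outside(0).name == "Air"
        assert topo.medium_inside(1).name == "Amniotic fluid"

    def test_edge_length_follows_wavelength_rule(self):
        f = 1000.0
        topo = nested_sphere_phantom(0.25, 0.15, 5.0, f)
        # outer surface: slower adjacent medium is air
        lam_out = AIR.c0 / f
        assert topo.surfaces[0].mean_edge_length() <= lam_out / 4.0
        lam_in = get_medium("Abdominal tissue").c0 / f
        assert topo.surfaces[1].mean_edge_length() <= lam_in / 4.0

    def test_fig_validation_radii(self):
        """0.5 m outer / 0.3 m inner diameters, i.e. radii 0.25 and 0.15 m."""
        topo = nested_sphere_phantom(0.25, 0.15, 5.0, 500.0)
        r_out = np.linalg.norm(topo.surfaces[0].vertices, axis=1)
        r_in = np.linalg.norm(topo.surfaces[1].vertices, axis=1)
        assert np.allclose(r_out, 0.25) and np.allclose(r_in, 0.15)

    def test_refuses_bad_parameters(self):
        with pytest.raises(ValueError):
            nested_sphere_phantom(0.15, 0.25, 5.0, 1000.0)
        with pytest.raises(ValueError):
            nested_sphere_phantom(0.25, 0.15, -1.0, 1000.0)
        with pytest.raises(ValueError):
            subdivisions_for_edge(0.25, 1e-5)  # beyond desk scale

    def test_three_region_phantom_valid(self):
        topo = nested_three_region_phantom(
            0.25, 0.12, (0.02, 0.02, 0.15), (-0.19, 0.0, 0.0), 5.0, 500.0)
        topo.validate()
        assert {s.region_label for s in topo.surfaces} == {"abdomen", "uterus", "spine"}


class TestInteriorGrid:
    def test_centre_retained_near_surface_excluded(self):
        mesh = icosphere(1.0, 3)
        eg = interior_grid(mesh, spacing=0.2)
        r = np.linalg.norm(eg.points, axis=1)
        assert np.any(r < 0.2)              # centre region retained
        assert np.all(r < 1.0)
        assert eg.excluded_count > 0        # outer shell points dropped
        # every retained point subtends < 0.5 sr from every triangle
        om = np.abs(signed_solid_angles(mesh, eg.points)).max(axis=1)
        assert np.all(om <= 0.5)

    def test_matches_brute_force_filter(self):
        """Retained set equals a per-point, per-triangle brute-force filter."""
        mesh = icosphere(0.5, 1)
        spacing = 0.11
        eg = interior_grid(mesh, spacing=spacing, solid_angle_threshold=0.4)
        lo, hi = mesh.vertices.min(axis=0), mesh.vertices.max(axis=0)
        axes = [np.arange(lo[d] + spacing / 2, hi[d], spacing) for d in range(3)]
        brute = []
        for x in axes[0]:
            for y in axes[1]:
                for z in axes[2]:
                    p = np.array([[x, y, z]])
                    om = signed_solid_angles(mesh, p)[0]
                    inside = abs(om.sum()) / (4 * np.pi) > 0.5
                    if inside and np.abs(om).max() <= 0.4:
                        brute.append((x, y, z))
        np.testing.assert_allclose(eg.points, np.array(brute), atol=1e-12)

    def test_monotone_in_threshold(self):
        mesh = icosphere(1.0, 2)
        counts = [
            len(interior_grid(mesh, spacing=0.15, solid_angle_threshold=t))
            for t in (0.2, 0.5, 1.0, 2.0)
        ]
        assert counts == sorted(counts)

    def test_half_space_limit_discards_touching_points(self):
        """A point epsilon above a triangle face subtends ~2 pi sr."""
        mesh = icosphere(1.0, 1)
        centre_tri = mesh.corners[0].mean(axis=0)
        p = centre_tri * (1.0 - 1e-9)
        om = np.abs(signed_solid_angles(mesh, p[None, :]))[0]
        assert om.max() > np.pi  # far beyond any sane threshold

    def test_errors(self):
        open_mesh = SurfaceMesh(icosphere(1.0, 1).vertices,
                                icosphere(1.0, 1).triangles[:-1])
        with pytest.raises(MeshFormatError):
            interior_grid(open_mesh, spacing=0.3)
        with pytest.raises(ValueError):
            interior_grid(icosphere(1.0, 2), spacing=5.0)


class TestVolumeCentroid:
    def test_sphere_centre_and_translation(self):
        m = icosphere(0.5, 2, center=(0.1, -0.2, 0.3))
        np.testing.assert_allclose(volume_centroid(m), [0.1, -0.2, 0.3], atol=1e-12)
        t = np.array([1.0, 2.0, -3.0])
        np.testing.assert_allclose(
            volume_centroid(m.translated(t)), volume_centroid(m) + t, atol=1e-10)

    def test_tetrahedron_closed_form(self):
        """A tetrahedron's volume centroid is the mean of its vertices."""
        v = np.array([[0.0, 0, 0], [1, 0, 0], [0, 2, 0], [0, 0, 3.0]])
        tris = np.array([[0, 2, 1], [0, 1, 3], [1, 2, 3], [0, 3, 2]])
        mesh = SurfaceMesh(v, tris)
        mesh.validate()
        np.testing.assert_allclose(volume_centroid(mesh), v.mean(axis=0), atol=1e-14)


class TestMeshIO:
    def test_msh_round_trip(self, tmp_path):
        m = icosphere(0.15, 2, region_label="uterus")
        path = tmp_path / "uterus.msh"
        write_mesh(m, path)
        back = read_mesh(path)
        np.testing.assert_array_equal(back.triangles, m.triangles)
        np.testing.assert_allclose(back.vertices, m.vertices, rtol=0, atol=0)
        assert back.region_label == "uterus"

    def test_stl_round_trip_merges_vertices(self, tmp_path):
        m = icosphere(0.25, 2)
        path = tmp_path / "sphere.stl"
        write_mesh(m, path)
        back = read_mesh(path)
        back.validate()  # merged back to watertight
        assert back.triangles.shape == m.triangles.shape
        assert back.vertices.shape == m.vertices.shape
        assert back.area == pytest.approx(m.area, rel=1e-6)

    def test_gmsh_v4_reader(self, tmp_path):
        m = icosphere(1.0, 0)
        path = tmp_path / "v4.msh"
        lines = ["$MeshFormat", "4.1 0 8", "$EndMeshFormat",
                 "$Nodes", f"1 {len(m.vertices)} 1 {len(m.vertices)}",
                 f"2 1 0 {len(m.vertices)}"]
        lines += [str(i + 1) for i in range(len(m.vertices))]
        lines += [f"{v[0]} {v[1]} {v[2]}" for v in m.vertices]
        lines += ["$EndNodes", "$Elements",
                  f"1 {len(m.triangles)} 1 {len(m.triangles)}",
                  f"2 1 2 {len(m.triangles)}"]
        lines += [f"{i + 1} {t[0] + 1} {t[1] + 1} {t[2] + 1}"
                  for i, t in enumerate(m.triangles)]
        lines += ["$EndElements"]
        path.write_text("\n".join(lines))
        back = read_mesh(path)
        np.testing.assert_array_equal(back.triangles, m.triangles)

    def test_rejects_quads_and_unknown_formats(self, tmp_path):
        path = tmp_path / "quad.msh"
        path.write_text("\n".join([
            "$MeshFormat", "2.2 0 8", "$EndMeshFormat",
            "$Nodes", "4", "1 0 0 0", "2 1 0 0", "3 1 1 0", "4 0 1 0",
            "$EndNodes",
            "$Elements", "1", "1 3 2 1 1 1 2 3 4", "$EndElements",
        ]))
        with pytest.raises(MeshFormatError):
            read_mesh(path)
        with pytest.raises(MeshFormatError):
            read_mesh(tmp_path / "mesh.obj")
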
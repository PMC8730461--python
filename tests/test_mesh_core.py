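"""Mesh I/O, validation and exact polyhedral mass properties."""

import numpy as np
import pytest
import trimesh

from bsp3d.mesh import (
    MeshError,
    TriangleMesh,
    merge_close_vertices,
    read_mesh,
    solid_properties,
    validate_mesh,
    write_mesh,
)
from bsp3d.synthetic import PrimitiveSpec, primitive_mesh

from conftest import cylinder_mesh, monte_carlo_solid, random_rotation, two_box_mesh

TETRA_STL = """solid tetra
facet normal 0 0 -1
  outer loop
    vertex 0 0 0
    vertex 0 1 0
    vertex 1 0 0
  endloop
endfacet
facet normal 0 -1 0
  outer loop
    vertex 0 0 0
    vertex 1 0 0
    vertex 0 0 1
  endloop
endfacet
facet normal -1 0 0
  outer loop
    vertex 0 0 0
    vertex 0 0 1
    vertex 0 1 0
  endloop
endfacet
facet normal 1 1 1
  outer loop
    vertex 1 0 0
    vertex 0 1 0
    vertex 0 0 1
  endloop
endfacet
endsolid tetra
"""


class TestIO:
    def test_ascii_stl_tetrahedron_dedup(self, tmp_path):
        """STL facets repeat vertices; reading merges them back to 4."""
        path = tmp_path / "tetra.stl"
        path.write_text(TETRA_STL)
        mesh = read_mesh(path)
        assert mesh.n_vertices == 4
        assert mesh.n_faces == 4
        assert validate_mesh(mesh).is_closed

    @pytest.mark.parametrize("fmt,encoding", [
        ("ply", "ascii"), ("ply", "binary"), ("stl", "ascii"), ("stl", "binary"),
    ])
    def test_round_trip(self, tmp_path, unit_cube, fmt, encoding):
        path = tmp_path / f"cube.{fmt}"
        write_mesh(unit_cube, path, format=fmt, encoding=encoding)
        back = read_mesh(path)
        assert back.n_vertices == unit_cube.n_vertices
        assert back.n_faces == unit_cube.n_faces
        # vertex sets agree within the merge tolerance
        a = np.sort(np.round(unit_cube.vertices, 5), axis=0)
        b = np.sort(np.round(back.vertices, 5), axis=0)
        np.testing.assert_allclose(a, b, atol=1e-5)

    def test_binary_ply_counts(self, tmp_path, unit_cube):
        path = tmp_path / "cube.ply"
        write_mesh(unit_cube, path, encoding="binary")
        back = read_mesh(path, format="ply")
        assert (back.n_vertices, back.n_faces) == (8, 12)

    def test_ply_color_round_trip(self, tmp_path, unit_cube):
        colored = unit_cube.copy()
        colored.colors = np.arange(24, dtype=np.uint8).reshape(8, 3)
        path = tmp_path / "colored.ply"
        write_mesh(colored, path, encoding="binary")
        back = read_mesh(path)
        assert back.colors is not None
        np.testing.assert_array_equal(back.colors, colored.colors)

    def test_unit_scaling(self, tmp_path, unit_cube):
        path = tmp_path / "cube.ply"
        write_mesh(unit_cube, path)
        in_m = read_mesh(path, units="m")
        assert np.isclose(in_m.vertices.max(), 50.0)  # 0.5 m -> 50 cm

    def test_empty_mesh_write_errors(self, tmp_path):
        empty = TriangleMesh(np.zeros((0, 3)), np.zeros((0, 3), dtype=int))
        with pytest.raises(MeshError):
            write_mesh(empty, tmp_path / "empty.ply")

    def test_missing_file_errors(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_mesh(tmp_path / "nope.ply")

    def test_malformed_file_errors(self, tmp_path):
        bad = tmp_path / "bad.ply"
        bad.write_text("ply\nformat ascii 1.0\nelement vertex nonsense\n")
        with pytest.raises(MeshError):
            read_mesh(bad)


class TestValidation:
    def test_closed_cube(self, unit_cube):
        report = validate_mesh(unit_cube)
        assert report.is_closed
        assert report.is_consistently_oriented
        assert report.n_boundary_edges == 0
        assert report.n_components == 1
        assert np.isclose(report.signed_volume, 1.0)

    def test_deleted_triangle_exposes_three_edges(self, unit_cube):
        holed = TriangleMesh(unit_cube.vertices, unit_cube.faces[1:])
        report = validate_mesh(holed)
        assert not report.is_closed
        assert report.n_boundary_edges == 3

    def test_two_disjoint_cubes(self):
        mesh = two_box_mesh()
        assert validate_mesh(mesh).n_components == 2

    def test_flipped_winding_negative_volume(self, unit_cube):
        report = validate_mesh(unit_cube.flipped())
        assert report.signed_volume < 0
        assert report.is_consistently_oriented


class TestSolidProperties:
    def test_unit_cube_closed_form(self, unit_cube):
        props = solid_properties(unit_cube, density=1000.0)
        assert np.isclose(props.volume, 1.0)
        assert np.isclose(props.mass, 0.001)
        np.testing.assert_allclose(props.centroid, 0.0, atol=1e-12)
        np.testing.assert_allclose(
            np.diag(props.inertia_tensor), 0.001 / 6.0, rtol=1e-12
        )
        assert np.allclose(props.inertia_tensor, props.inertia_tensor.T)

    def test_reference_cylinder_printed_values(self, reference_cylinder):
        """Triangulated r=4.1, L=94.0 cylinder reproduces the analytic
        volume and principal moments at integer precision."""
        props = solid_properties(reference_cylinder, density=1000.0)
        moments = np.sort(props.principal_moments)
        assert round(props.volume) == 4964
        assert round(moments[1]) == 3676
        assert round(moments[2]) == 3676
        assert round(moments[0]) == 42

    def test_monte_carlo_oracle_two_boxes(self):
        """Volume/centroid/inertia of an irregular closed mesh agree with a
        ray-parity Monte-Carlo estimate."""
        mesh = two_box_mesh()
        props = solid_properties(mesh, density=1000.0)
        mc_vol, mc_centroid, mc_inertia = monte_carlo_solid(mesh, 400_000, seed=7)
        assert abs(props.volume - mc_vol) / mc_vol < 0.01
        np.testing.assert_allclose(props.centroid, mc_centroid, atol=0.05)
        np.testing.assert_allclose(props.inertia_tensor, mc_inertia, rtol=0.03, atol=2e-5)

    def test_open_mesh_errors_with_count(self, unit_cube):
        # dropping the two coplanar bottom triangles exposes the 4 rim edges
        holed = TriangleMesh(unit_cube.vertices, unit_cube.faces[2:])
        with pytest.raises(MeshError, match="4 boundary edges"):
            solid_properties(holed)

    def test_agrees_with_trimesh(self):
        """Independent library cross-check on a non-symmetric solid."""
        mesh = primitive_mesh(
            PrimitiveSpec(
                kind="frustum",
                dimensions={"r_bottom": 5.0, "r_top": 2.0, "length": 20.0},
                translation=np.array([3.0, -2.0, 7.0]),
            ),
            resolution=128,
        )
        props = solid_properties(mesh, density=1000.0)
        tm = trimesh.Trimesh(mesh.vertices, mesh.faces, process=False)
        assert np.isclose(props.volume, tm.volume, rtol=1e-10)
        np.testing.assert_allclose(props.centroid, tm.center_mass, atol=1e-8)
        # trimesh inertia is about the centroid at density 1: scale to kg.cm^2
        np.testing.assert_allclose(
            props.inertia_tensor, tm.moment_inertia * 1e-3, rtol=1e-8, atol=1e-10
        )


class TestInvariants:
    def test_rotation_equivariance(self):
        rng = np.random.default_rng(11)
        mesh = two_box_mesh()
        props = solid_properties(mesh)
        for _ in range(3):
            rot = random_rotation(rng)
            rotated = mesh.transformed(rot, np.zeros(3))
            props_r = solid_properties(rotated)
            np.testing.assert_allclose(
                props_r.inertia_tensor, rot @ props.inertia_tensor @ rot.T, rtol=1e-8, atol=1e-12
            )

    def test_translation_invariance(self):
        mesh = two_box_mesh()
        props = solid_properties(mesh)
        shift = np.array([123.4, -56.7, 89.0])
        props_t = solid_properties(mesh.transformed(np.eye(3), shift))
        np.testing.assert_allclose(props_t.centroid, props.centroid + shift, rtol=1e-9)
        np.testing.assert_allclose(
            props_t.inertia_tensor, props.inertia_tensor, rtol=1e-9, atol=1e-15
        )

    def test_scaling_law(self):
        mesh = two_box_mesh()
        props = solid_properties(mesh)
        s = 2.5
        scaled = TriangleMesh(mesh.vertices * s, mesh.faces)
        props_s = solid_properties(scaled)
        assert np.isclose(props_s.volume, props.volume * s**3, rtol=1e-9)
        np.testing.assert_allclose(
            props_s.inertia_tensor, props.inertia_tensor * s**5, rtol=1e-9, atol=1e-15
        )

    def test_winding_flip_robustness(self, unit_cube):
        props = solid_properties(unit_cube)
        props_f = solid_properties(unit_cube.flipped())
        assert np.isclose(props_f.volume, props.volume)
        np.testing.assert_allclose(props_f.inertia_tensor, props.inertia_tensor)

    def test_cylinder_resolution_convergence(self):
        truth = np.pi * 4.1**2 * 94.0
        errors = [
            abs(solid_properties(cylinder_mesh(4.1, 94.0, n, n_axial=8)).volume - truth) / truth
            for n in (512, 1024, 2048)
        ]
        assert errors[0] > errors[1] > errors[2]

    def test_principal_moment_triangle_inequality(self):
        props = solid_properties(two_box_mesh())
        a, b, c = np.sort(props.principal_moments)
        assert a >= 0
        assert c <= a + b + 1e-12


def test_merge_close_vertices_drops_degenerate_faces():
    vertices = np.array([[0, 0, 0], [1, 0, 0], [1e-8, 0, 0], [0, 1, 0]], dtype=float)
    faces = np.array([[0, 1, 3], [2, 1, 3], [0, 2, 1]])
    merged = merge_close_vertices(TriangleMesh(vertices, faces))
    assert merged.n_vertices == 3
    assert merged.n_faces == 2  # the face using both duplicates degenerates
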
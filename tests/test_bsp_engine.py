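"""Segment frames, longitudinal length, pCOM, and subject aggregation."""

import numpy as np
import pytest

from bsp3d.bsp import (
    BspError,
    DensityTable,
    compute_segment_bsp,
    compute_subject_bsp,
    longitudinal_extent,
    segment_frame,
)
from bsp3d.mesh import TriangleMesh, solid_properties
from bsp3d.segmentation import AnatomicalFrame, SEGMENT_LABELS
from bsp3d.synthetic import (
    PrimitiveSpec,
    default_phantom_spec,
    phantom_body,
    primitive_mesh,
)

from conftest import cylinder_mesh


def _cone_mesh(base_radius, height, resolution=256):
    """Apex-up cone (numerically a frustum with a vanishing top radius):
    base at z=0, apex at z=height."""
    return primitive_mesh(
        PrimitiveSpec(
            kind="frustum",
            dimensions={"r_bottom": base_radius, "r_top": 0.01, "length": height},
            translation=np.array([0.0, 0.0, height / 2.0]),
        ),
        resolution=resolution,
        n_axial=64,
    )


class TestSegmentFrame:
    def test_non_foot_returns_global(self, unit_cube):
        frame = AnatomicalFrame.identity()
        out = segment_frame("right_thigh", frame, unit_cube)
        assert out is frame

    def test_foot_long_axis_along_largest_horizontal_extent(self):
        """A 25x9x8 box 'foot' lying along global ap gets its longitudinal
        axis re-aligned to the 25 cm (ap) direction."""
        foot = primitive_mesh(
            PrimitiveSpec(kind="box", dimensions={"width": 25.0, "depth": 9.0, "height": 8.0}),
            resolution=16,
        )
        frame = segment_frame("left_foot", AnatomicalFrame.identity(), foot)
        np.testing.assert_allclose(np.abs(frame.long_axis), [1, 0, 0], atol=1e-9)
        assert frame.long_axis[0] > 0  # sign chosen toward +ap
        np.testing.assert_allclose(frame.ap_axis, [0, 0, 1], atol=1e-12)

    def test_cube_foot_tie_breaks_to_ap(self, unit_cube, caplog):
        import logging

        with caplog.at_level(logging.WARNING):
            frame = segment_frame("right_foot", AnatomicalFrame.identity(), unit_cube)
        np.testing.assert_allclose(frame.long_axis, [1, 0, 0], atol=1e-12)
        assert any("degenerate" in rec.message for rec in caplog.records)


class TestLongitudinalExtent:
    def test_cylinder_printed_length(self):
        """The 94.1 cm analytic cylinder returns exactly its length."""
        mesh = cylinder_mesh(4.1, 94.1, resolution=512, n_axial=200)
        props = solid_properties(mesh)
        _, _, length = longitudinal_extent(mesh, props.centroid, [0, 0, 1])
        assert round(length, 1) == 94.1

    def test_sphere_any_axis_gives_diameter(self):
        sphere = primitive_mesh(
            PrimitiveSpec(kind="ellipsoid", dimensions={"a": 3.0, "b": 3.0, "c": 3.0}),
            resolution=256,
            n_axial=128,
        )
        props = solid_properties(sphere)
        for axis in ([0, 0, 1], [1, 0, 0], [0.6, 0.0, 0.8]):
            _, _, length = longitudinal_extent(sphere, props.centroid, axis)
            assert abs(length - 6.0) < 0.01

    def test_cone_endpoints_match_brute_force_sampling(self):
        """Endpoints agree with dense sampling of the axis line against the
        analytic cone surface."""
        mesh = _cone_mesh(5.0, 20.0)
        props = solid_properties(mesh)
        end_plus, end_minus, length = longitudinal_extent(mesh, props.centroid, [0, 0, 1])
        # brute force: walk the vertical line through the COM, find the z
        # range whose points lie inside the analytic cone r(z) = 5(1 - z/20)
        zs = np.linspace(-1.0, 21.0, 200_001)
        r_com = np.hypot(props.centroid[0], props.centroid[1])
        inside = (zs >= 0) & (zs <= 20) & (r_com <= 5.0 * (1 - zs / 20.0))
        z_lo, z_hi = zs[inside][0], zs[inside][-1]
        assert abs(end_minus[2] - z_lo) < 0.05
        assert abs(end_plus[2] - z_hi) < 0.05
        assert abs(length - (z_hi - z_lo)) < 0.05

    def test_com_outside_mesh_errors(self, unit_cube):
        with pytest.raises(BspError, match="no surface intersection"):
            longitudinal_extent(unit_cube, np.array([10.0, 0, 0]), [0, 0, 1])


class TestSegmentBsp:
    def test_uniform_cylinder_pcom_is_50(self):
        mesh = cylinder_mesh(4.1, 94.0, resolution=256, n_axial=64)
        bsp = compute_segment_bsp(mesh, "right_shank", densities=DensityTable.uniform_1000())
        assert abs(bsp.pcom - 50.0) < 0.1

    def test_cone_apex_proximal_pcom_75(self):
        """Uniform cone centroid sits h/4 above the base: with the apex as
        the proximal (superior) end, pCOM = 75%."""
        mesh = _cone_mesh(5.0, 20.0)
        bsp = compute_segment_bsp(mesh, "head", densities=DensityTable.uniform_1000())
        assert abs(bsp.pcom - 75.0) < 0.2

    def test_ellipsoid_inertia_closed_form(self):
        a, b, c = 3.0, 4.0, 5.0
        mesh = primitive_mesh(
            PrimitiveSpec(kind="ellipsoid", dimensions={"a": a, "b": b, "c": c}),
            resolution=256,
            n_axial=128,
        )
        bsp = compute_segment_bsp(mesh, "head", densities=DensityTable.uniform_1000())
        m = bsp.mass
        assert abs(bsp.I_ap - m * (b**2 + c**2) / 5) / (m * (b**2 + c**2) / 5) < 0.005
        assert abs(bsp.I_ml - m * (a**2 + c**2) / 5) / (m * (a**2 + c**2) / 5) < 0.005
        assert abs(bsp.I_long - m * (a**2 + b**2) / 5) / (m * (a**2 + b**2) / 5) < 0.005

    def test_pcom_complement_under_mirroring(self):
        """Mirroring a segment through the transverse plane at the COM maps
        pCOM -> 100 - pCOM."""
        mesh = _cone_mesh(5.0, 20.0)
        bsp = compute_segment_bsp(mesh, "torso", densities=DensityTable.uniform_1000())
        mirrored_vertices = mesh.vertices.copy()
        mirrored_vertices[:, 2] = 2 * bsp.com[2] - mirrored_vertices[:, 2]
        mirrored = TriangleMesh(mirrored_vertices, mesh.faces[:, ::-1].copy())
        bsp_m = compute_segment_bsp(mirrored, "torso", densities=DensityTable.uniform_1000())
        assert abs(bsp.pcom + bsp_m.pcom - 100.0) < 0.1

    def test_inertia_components_invariant_to_repositioning(self):
        """Rotating the whole scan (and its frame) leaves segment-frame
        inertia components unchanged."""
        mesh = cylinder_mesh(3.0, 25.0, resolution=128, n_axial=32)
        bsp0 = compute_segment_bsp(mesh, "left_arm", densities=DensityTable.uniform_1000())
        ang = 0.7
        rot = np.array(
            [[np.cos(ang), 0, np.sin(ang)], [0, 1, 0], [-np.sin(ang), 0, np.cos(ang)]]
        )
        frame = AnatomicalFrame.identity()
        rotated_frame = AnatomicalFrame(
            origin=np.zeros(3),
            ap_axis=rot @ frame.ap_axis,
            ml_axis=rot @ frame.ml_axis,
            long_axis=rot @ frame.long_axis,
        )
        bsp1 = compute_segment_bsp(
            mesh.transformed(rot, np.array([5.0, 6, 7])),
            "left_arm",
            global_frame=rotated_frame,
            densities=DensityTable.uniform_1000(),
        )
        for attr in ("I_ap", "I_ml", "I_long"):
            assert np.isclose(getattr(bsp0, attr), getattr(bsp1, attr), rtol=1e-8)

    def test_parallel_axis_identity(self):
        """Tensor about an endpoint minus tensor about the COM equals
        m (d^2 I - d d^T)."""
        mesh = cylinder_mesh(3.0, 25.0, resolution=128, n_axial=32)
        props = solid_properties(mesh, 1000.0)
        bsp = compute_segment_bsp(mesh, "left_arm", densities=DensityTable.uniform_1000())
        d = bsp.proximal_endpoint - props.centroid
        shift = props.mass * ((d @ d) * np.eye(3) - np.outer(d, d))
        # recompute the tensor about the endpoint directly from the mesh
        shifted = mesh.transformed(np.eye(3), -bsp.proximal_endpoint)
        props_end = solid_properties(shifted, 1000.0)
        second_shift = props_end.centroid
        about_end = props_end.inertia_tensor + props_end.mass * (
            (second_shift @ second_shift) * np.eye(3) - np.outer(second_shift, second_shift)
        )
        np.testing.assert_allclose(
            about_end - props.inertia_tensor, shift, rtol=1e-9, atol=1e-12
        )


@pytest.fixture(scope="module")
def phantom_segments():
    mesh, scheme, truth = phantom_body(default_phantom_spec(resolution=64))
    from bsp3d.segmentation import segment_body

    return segment_body(mesh, scheme), truth


class TestSubjectBsp:
    def test_totals_are_exact_sums(self, phantom_segments):
        segments, _ = phantom_segments
        subject = compute_subject_bsp(segments, densities=DensityTable.literature())
        assert np.isclose(
            subject.total_mass, sum(s.mass for s in subject.segments.values()), rtol=1e-12
        )
        assert np.isclose(
            subject.total_volume, sum(s.volume for s in subject.segments.values()), rtol=1e-12
        )

    def test_phantom_total_volume_matches_truth(self, phantom_segments):
        segments, truth = phantom_segments
        subject = compute_subject_bsp(segments, densities=DensityTable.literature())
        assert abs(subject.total_volume - truth.total_volume) / truth.total_volume < 0.01

    def test_uniform_density_mass_equals_volume(self, phantom_segments):
        segments, _ = phantom_segments
        subject = compute_subject_bsp(segments, densities=DensityTable.uniform_1000())
        assert np.isclose(subject.total_mass, subject.total_volume * 1e-3, rtol=1e-12)

    def test_missing_segment_errors(self, phantom_segments):
        segments, _ = phantom_segments
        partial = {k: v for k, v in segments.items() if k != "head"}
        with pytest.raises(BspError, match="missing segment"):
            compute_subject_bsp(partial)


class TestDensityTable:
    def test_uniform_mode_is_exactly_1000(self):
        table = DensityTable.uniform_1000()
        assert all(table[label] == 1000.0 for label in SEGMENT_LABELS)

    def test_out_of_range_density_rejected(self):
        with pytest.raises(BspError):
            DensityTable({"head": 2000.0})

    def test_sided_label_falls_back_to_base(self):
        table = DensityTable.literature()
        assert table["left_thigh"] == table["thigh"]
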
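import numpy as np
import pytest

from bsp3d.synthetic import PrimitiveSpec, primitive_mesh


@pytest.fixture
def unit_cube():
    """Closed unit cube (1 cm side) centered at the origin."""
    return primitive_mesh(
        PrimitiveSpec(kind="box", dimensions={"width": 1.0, "depth": 1.0, "height": 1.0}),
        resolution=16,
    )


@pytest.fixture
def reference_cylinder():
    """The analytic validation cylinder: r = 4.1 cm, L = 94.0 cm, fine mesh."""
    return primitive_mesh(
        PrimitiveSpec(kind="cylinder", dimensions={"radius": 4.1, "length": 94.0}),
        resolution=512,
        n_axial=200,
    )


def cylinder_mesh(radius, length, resolution=256, n_axial=64):
    return primitive_mesh(
        PrimitiveSpec(kind="cylinder", dimensions={"radius": radius, "length": length}),
        resolution=resolution,
        n_axial=n_axial,
    )


def random_rotation(rng):
    """Uniform-ish random rotation matrix (QR of a Gaussian matrix)."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, [0, 1]] = q[:, [1, 0]]
    return q


def monte_carlo_solid(mesh, n_points, seed, density=1000.0):
    """Independent Monte-Carlo oracle for solid properties.

    Uniform points in the bounding box are classified inside/outside by
    ray-crossing parity along +z (a point is inside iff an odd number of
    triangles lie above it), and volume, centroid and centroid-referenced
    inertia are estimated from the inside sample.  Shares no code with the
    polyhedral integrator.

    Returns (volume_cm3, centroid_cm, inertia_tensor_kgcm2).
    """
    rng = np.random.default_rng(seed)
    lo = mesh.vertices.min(axis=0) - 1e-6
    hi = mesh.vertices.max(axis=0) + 1e-6
    box_volume = float(np.prod(hi - lo))
    tri = mesh.vertices[mesh.faces]  # (m, 3, 3)

    n_inside = 0
    sum_p = np.zeros(3)
    sum_pp = np.zeros((3, 3))
    remaining = n_points
    chunk = 500_000
    while remaining > 0:
        n = min(chunk, remaining)
        remaining -= n
        pts = lo + rng.random((n, 3)) * (hi - lo)
        crossings = np.zeros(n, dtype=np.int64)
        for a, b, c in tri:
            denom = (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])
            if denom == 0.0:  # triangle vertical in the xy projection
                continue
            px = pts[:, 0] - a[0]
            py = pts[:, 1] - a[1]
            wb = (px * (c[1] - a[1]) - py * (c[0] - a[0])) / denom
            wc = ((b[0] - a[0]) * py - (b[1] - a[1]) * px) / denom
            wa = 1.0 - wb - wc
            hit = (wa >= 0) & (wb >= 0) & (wc >= 0)
            if not hit.any():
                continue
            z = wa[hit] * a[2] + wb[hit] * b[2] + wc[hit] * c[2]
            above = z > pts[hit, 2]
            idx = np.flatnonzero(hit)[above]
            crossings[idx] += 1
        inside = pts[crossings % 2 == 1]
        n_inside += len(inside)
        sum_p += inside.sum(axis=0)
        sum_pp += inside.T @ inside
    volume = box_volume * n_inside / n_points
    centroid = sum_p / n_inside
    second = volume * (sum_pp / n_inside - np.outer(centroid, centroid))
    rho_cm = density * 1e-6
    inertia = rho_cm * (np.trace(second) * np.eye(3) - second)
    return volume, centroid, inertia


def two_box_mesh(rotate=True):
    """Irregular closed test solid: two disjoint boxes, one rotated."""
    from bsp3d.mesh import TriangleMesh

    box1 = primitive_mesh(
        PrimitiveSpec(kind="box", dimensions={"width": 4.0, "depth": 3.0, "height": 2.0}),
        resolution=16,
    )
    rot = np.eye(3)
    if rotate:
        ang = 0.6
        rot = np.array(
            [
                [np.cos(ang), -np.sin(ang), 0.0],
                [np.sin(ang), np.cos(ang), 0.0],
                [0.0, 0.0, 1.0],
            ]
        )
    box2 = primitive_mesh(
        PrimitiveSpec(
            kind="box",
            dimensions={"width": 2.0, "depth": 2.5, "height": 3.0},
            rotation=rot,
            translation=np.array([4.5, 1.0, 0.5]),
        ),
        resolution=16,
    )
    vertices = np.concatenate([box1.vertices, box2.vertices])
    faces = np.concatenate([box1.faces, box2.faces + box1.n_vertices])
    return TriangleMesh(vertices, faces, label="two_boxes")
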
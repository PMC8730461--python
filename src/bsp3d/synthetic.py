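"""Synthetic primitives and phantom bodies with analytically known BSPs.

Real scans are not required to exercise the pipeline: this module generates
closed, outward-oriented triangle meshes of geometric primitives (cylinder,
elliptical cylinder, conical frustum, ellipsoid, box) whose volume,
centroid, inertia, length and pCOM have closed forms, and composes 16 of
them into a humanoid "phantom body" whose exact per-segment ground truth
and ready-made segmentation scheme are emitted alongside the mesh.

All primitives are generated with their longitudinal axis along local +z
(except the foot box, whose longitudinal direction is horizontal), then
posed rigidly into the world frame.  Mesh vertices lie exactly on the
analytic surface, so mesh-derived properties converge to the closed forms
with second-order accuracy in the angular resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bsp import SegmentBSP, SubjectBSP, DensityTable
from .mesh import TriangleMesh
from .segmentation import (
    AnatomicalFrame,
    BoundaryPlane,
    SEGMENT_LABELS,
    SegmentationScheme,
    base_label,
)

PRIMITIVE_KINDS = ("cylinder", "elliptical_cylinder", "frustum", "ellipsoid", "box")

MIN_CIRCUMFERENTIAL = 16


class SyntheticError(ValueError):
    """Raised for invalid primitive or phantom specifications."""


@dataclass
class PrimitiveSpec:
    """One primitive solid.

    ``dimensions`` per kind (cm):
      cylinder: radius, length
      elliptical_cylinder: a (x semi-axis), b (y semi-axis), length
      frustum: r_bottom, r_top, length
      ellipsoid: a, b, c (x, y, z semi-axes)
      box: width (x), depth (y), height (z)
    ``rotation``/``translation`` pose the local frame into the world.
    """

    kind: str
    dimensions: dict[str, float]
    label: str = ""
    density: float = 1000.0
    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        if self.kind not in PRIMITIVE_KINDS:
            raise SyntheticError(f"unknown primitive kind {self.kind!r}")
        for name, value in self.dimensions.items():
            if value <= 0:
                raise SyntheticError(f"{self.kind} dimension {name} must be positive")
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if (
            np.abs(self.rotation @ self.rotation.T - np.eye(3)).max() > 1e-9
            or abs(np.linalg.det(self.rotation) - 1.0) > 1e-9
        ):
            raise SyntheticError("pose rotation must be orthonormal with det +1")


@dataclass
class PhantomSpec:
    """Exactly the 16 body-segment labels, one primitive each."""

    primitives: dict[str, PrimitiveSpec]
    resolution: int = 128
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if set(self.primitives) != set(SEGMENT_LABELS):
            raise SyntheticError("phantom needs exactly the 16 segment labels")


@dataclass
class PhantomTruth:
    """Analytic per-segment BSPs and exact totals."""

    segments: dict[str, SegmentBSP]
    total_mass: float = field(init=False)
    total_volume: float = field(init=False)

    def __post_init__(self) -> None:
        self.total_mass = float(sum(s.mass for s in self.segments.values()))
        self.total_volume = float(sum(s.volume for s in self.segments.values()))


# ---------------------------------------------------------------------------
# primitive surface meshes
# ---------------------------------------------------------------------------


def _lathe(radii_x, radii_y, zs, n_theta: int) -> tuple[np.ndarray, np.ndarray]:
    """Closed surface of revolution-like stack: elliptical rings of semi-axes
    (radii_x[i], radii_y[i]) at heights zs[i], with flat caps at both ends."""
    theta = np.linspace(0.0, 2 * np.pi, n_theta, endpoint=False)
    cos_t, sin_t = np.cos(theta), np.sin(theta)
    rings = []
    for rx, ry, z in zip(radii_x, radii_y, zs):
        rings.append(np.column_stack([rx * cos_t, ry * sin_t, np.full(n_theta, z)]))
    vertices = np.concatenate(rings)
    n_rings = len(zs)
    faces = []
    for i in range(n_rings - 1):
        a = i * n_theta + np.arange(n_theta)
        b = i * n_theta + (np.arange(n_theta) + 1) % n_theta
        c = b + n_theta
        d = a + n_theta
        faces.append(np.column_stack([a, b, c]))
        faces.append(np.column_stack([a, c, d]))
    verts = [vertices]
    bottom_center = len(vertices)
    verts.append(np.array([[0.0, 0.0, zs[0]]]))
    top_center = bottom_center + 1
    verts.append(np.array([[0.0, 0.0, zs[-1]]]))
    a = np.arange(n_theta)
    b = (a + 1) % n_theta
    faces.append(np.column_stack([np.full(n_theta, bottom_center), b, a]))
    top = (n_rings - 1) * n_theta
    faces.append(np.column_stack([np.full(n_theta, top_center), top + a, top + b]))
    return np.concatenate(verts), np.concatenate(faces)


def _box_mesh(w: float, d: float, h: float) -> tuple[np.ndarray, np.ndarray]:
    x, y, z = w / 2, d / 2, h / 2
    vertices = np.array(
        [
            [-x, -y, -z], [x, -y, -z], [x, y, -z], [-x, y, -z],
            [-x, -y, z], [x, -y, z], [x, y, z], [-x, y, z],
        ]
    )
    faces = np.array(
        [
            [0, 2, 1], [0, 3, 2],          # bottom (−z)
            [4, 5, 6], [4, 6, 7],          # top (+z)
            [0, 1, 5], [0, 5, 4],          # −y
            [2, 3, 7], [2, 7, 6],          # +y
            [1, 2, 6], [1, 6, 5],          # +x
            [3, 0, 4], [3, 4, 7],          # −x
        ]
    )
    return vertices, faces


def _ellipsoid_mesh(a: float, b: float, c: float, n_theta: int, n_lat: int):
    lat = np.linspace(-np.pi / 2, np.pi / 2, n_lat + 2)[1:-1]
    theta = np.linspace(0.0, 2 * np.pi, n_theta, endpoint=False)
    cos_t, sin_t = np.cos(theta), np.sin(theta)
    rings = [
        np.column_stack(
            [
                a * np.cos(phi) * cos_t,
                b * np.cos(phi) * sin_t,
                np.full(n_theta, c * np.sin(phi)),
            ]
        )
        for phi in lat
    ]
    vertices = np.concatenate(rings)
    faces = []
    for i in range(len(lat) - 1):
        idx_a = i * n_theta + np.arange(n_theta)
        idx_b = i * n_theta + (np.arange(n_theta) + 1) % n_theta
        idx_c = idx_b + n_theta
        idx_d = idx_a + n_theta
        faces.append(np.column_stack([idx_a, idx_b, idx_c]))
        faces.append(np.column_stack([idx_a, idx_c, idx_d]))
    south = len(vertices)
    north = south + 1
    vertices = np.concatenate([vertices, [[0, 0, -c], [0, 0, c]]])
    a_idx = np.arange(n_theta)
    b_idx = (a_idx + 1) % n_theta
    faces.append(np.column_stack([np.full(n_theta, south), b_idx, a_idx]))
    top = (len(lat) - 1) * n_theta
    faces.append(np.column_stack([np.full(n_theta, north), top + a_idx, top + b_idx]))
    return vertices, np.concatenate(faces)


def primitive_mesh(spec: PrimitiveSpec, resolution: int = 128, n_axial: int | None = None) -> TriangleMesh:
    """Closed outward-oriented mesh of a primitive.

    ``resolution`` is the circumferential division count (>=16); ``n_axial``
    controls the axial/latitudinal ring count (defaults chosen per kind).
    """
    if resolution < MIN_CIRCUMFERENTIAL:
        raise SyntheticError(
            f"resolution {resolution} below minimum of {MIN_CIRCUMFERENTIAL}"
        )
    dims = spec.dimensions
    if spec.kind == "cylinder":
        n_ax = n_axial or max(2, resolution // 8)
        zs = np.linspace(-dims["length"] / 2, dims["length"] / 2, n_ax + 1)
        r = np.full(len(zs), dims["radius"])
        vertices, faces = _lathe(r, r, zs, resolution)
    elif spec.kind == "elliptical_cylinder":
        n_ax = n_axial or max(2, resolution // 8)
        zs = np.linspace(-dims["length"] / 2, dims["length"] / 2, n_ax + 1)
        vertices, faces = _lathe(
            np.full(len(zs), dims["a"]), np.full(len(zs), dims["b"]), zs, resolution
        )
    elif spec.kind == "frustum":
        n_ax = n_axial or max(2, resolution // 8)
        zs = np.linspace(-dims["length"] / 2, dims["length"] / 2, n_ax + 1)
        r = np.linspace(dims["r_bottom"], dims["r_top"], len(zs))
        vertices, faces = _lathe(r, r, zs, resolution)
    elif spec.kind == "ellipsoid":
        n_lat = n_axial or max(3, resolution // 2)
        vertices, faces = _ellipsoid_mesh(dims["a"], dims["b"], dims["c"], resolution, n_lat)
    else:  # box
        vertices, faces = _box_mesh(dims["width"], dims["depth"], dims["height"])
    vertices = vertices @ spec.rotation.T + spec.translation
    return TriangleMesh(vertices, faces, label=spec.label)


# ---------------------------------------------------------------------------
# analytic truths
# ---------------------------------------------------------------------------


def _frustum_integrals(r1: float, r2: float, h: float):
    """Exact polynomial integrals of a conical frustum with base radius r1
    at z=0 and top radius r2 at z=h: volume, centroid height, axial and
    transverse (about centroid) second moments per unit density."""
    rpoly = np.polynomial.Polynomial([r1, (r2 - r1) / h])
    r2poly = rpoly**2
    r4poly = rpoly**4
    z = np.polynomial.Polynomial([0.0, 1.0])
    volume = np.pi * r2poly.integ()(h)
    zbar = np.pi * (r2poly * z).integ()(h) / volume
    i_axial = (np.pi / 2.0) * r4poly.integ()(h)
    i_trans_origin = np.pi * (r4poly / 4.0 + r2poly * z**2).integ()(h)
    i_trans = i_trans_origin - volume * zbar**2
    return float(volume), float(zbar), float(i_axial), float(i_trans)


def _local_truth(spec: PrimitiveSpec):
    """(volume, local centroid, diag inertia per axis x/y/z about centroid,
    local long axis unit vector, half-extents along the long axis)."""
    d = spec.dimensions
    rho = spec.density * 1e-6
    if spec.kind == "cylinder":
        r, length = d["radius"], d["length"]
        volume = np.pi * r**2 * length
        m = rho * volume
        i_trans = m * (3 * r**2 + length**2) / 12.0
        return volume, np.zeros(3), np.array([i_trans, i_trans, m * r**2 / 2.0]), \
            np.array([0.0, 0.0, 1.0]), (length / 2, length / 2)
    if spec.kind == "elliptical_cylinder":
        a, b, length = d["a"], d["b"], d["length"]
        volume = np.pi * a * b * length
        m = rho * volume
        ix = m * (3 * b**2 + length**2) / 12.0
        iy = m * (3 * a**2 + length**2) / 12.0
        iz = m * (a**2 + b**2) / 4.0
        return volume, np.zeros(3), np.array([ix, iy, iz]), \
            np.array([0.0, 0.0, 1.0]), (length / 2, length / 2)
    if spec.kind == "frustum":
        r1, r2, length = d["r_bottom"], d["r_top"], d["length"]
        volume, zbar, i_ax, i_tr = _frustum_integrals(r1, r2, length)
        centroid = np.array([0.0, 0.0, zbar - length / 2.0])  # mesh is centered
        return volume, centroid, rho * np.array([i_tr, i_tr, i_ax]), \
            np.array([0.0, 0.0, 1.0]), (length / 2 - centroid[2], length / 2 + centroid[2])
    if spec.kind == "ellipsoid":
        a, b, c = d["a"], d["b"], d["c"]
        volume = 4.0 * np.pi * a * b * c / 3.0
        m = rho * volume
        inertia = m / 5.0 * np.array([b**2 + c**2, a**2 + c**2, a**2 + b**2])
        return volume, np.zeros(3), inertia, np.array([0.0, 0.0, 1.0]), (c, c)
    # box: longitudinal taken along the largest horizontal edge if the box is
    # wider than tall (foot convention), otherwise along z
    w, dd, h = d["width"], d["depth"], d["height"]
    volume = w * dd * h
    m = rho * volume
    inertia = m / 12.0 * np.array([dd**2 + h**2, w**2 + h**2, w**2 + dd**2])
    horizontal = max(w, dd)
    if horizontal > h:
        axis = np.array([1.0, 0.0, 0.0]) if w >= dd else np.array([0.0, 1.0, 0.0])
        half = horizontal / 2.0
    else:
        axis = np.array([0.0, 0.0, 1.0])
        half = h / 2.0
    return volume, np.zeros(3), inertia, axis, (half, half)


def primitive_truth(
    spec: PrimitiveSpec,
    proximal_sign: float = 1.0,
    axes: AnatomicalFrame | None = None,
) -> SegmentBSP:
    """Closed-form BSPs of a primitive, posed into the world frame.

    ``proximal_sign`` selects which end of the local long axis is proximal
    (+1 = the +axis end).  ``axes`` optionally supplies the segment
    ap/ml/long axes (world frame) on which I_ap/I_ml/I_long are read;
    by default the primitive's posed local x/y/z axes are used.
    """
    volume, c_local, i_diag, axis_local, (half_plus, half_minus) = _local_truth(spec)
    rho = spec.density * 1e-6
    mass = rho * volume

    com = spec.rotation @ c_local + spec.translation
    i_local = np.diag(i_diag)
    i_world = spec.rotation @ i_local @ spec.rotation.T
    axis_world = spec.rotation @ axis_local

    end_plus = com + half_plus * axis_world
    end_minus = com - half_minus * axis_world
    length = float(half_plus + half_minus)
    if proximal_sign >= 0:
        proximal, distal = end_plus, end_minus
        pcom = 100.0 * half_plus / length
    else:
        proximal, distal = end_minus, end_plus
        pcom = 100.0 * half_minus / length

    if axes is None:
        rot = spec.rotation.T  # rows are posed local x/y/z axes
    else:
        rot = axes.rotation
    i_axes = rot @ i_world @ rot.T
    return SegmentBSP(
        label=spec.label,
        volume=float(volume),
        mass=float(mass),
        com=com,
        I_ap=float(i_axes[0, 0]),
        I_ml=float(i_axes[1, 1]),
        I_long=float(i_axes[2, 2]),
        inertia_tensor=i_axes,
        proximal_endpoint=proximal,
        distal_endpoint=distal,
        length=length,
        pcom=float(pcom),
    )


# ---------------------------------------------------------------------------
# humanoid phantom
# ---------------------------------------------------------------------------

#: offset (cm) of emitted scheme planes from the exact primitive interfaces,
#: so cut planes never coincide with coplanar cap facets
JUNCTION_OFFSET = 1e-3

_ARM_Y = 24.0      # arm chain centerline |y| (mediolateral offset)
_LEG_Y = 10.0      # leg chain centerline |y|
_ARM_SEP = 19.25   # parasagittal plane separating arm chains from the rest


def default_phantom_spec(resolution: int = 128, noise_sigma: float = 0.0, seed: int = 0) -> PhantomSpec:
    """Reference humanoid phantom: a stacked trunk column (elliptical
    cylinders + ellipsoid head), frustum limbs and box feet, sized to weigh
    about 73 kg at the literature segment densities.

    World frame: ap = +x, ml = +y, long = +z; limbs hang beside the trunk
    at mediolateral offsets, feet point anteriorly (+x).
    """
    prims: dict[str, PrimitiveSpec] = {}

    def place(label, kind, dims, z_lo, z_hi, y=0.0):
        density = DensityTable.literature()[base_label(label)]
        prims[label] = PrimitiveSpec(
            kind=kind,
            dimensions=dims,
            label=label,
            density=density,
            translation=np.array([0.0, y, (z_lo + z_hi) / 2.0]),
        )

    # trunk column: a = anteroposterior (x) semi-axis, b = mediolateral (y)
    place("pelvis", "elliptical_cylinder", {"a": 11.0, "b": 15.5, "length": 18.0}, 90.0, 108.0)
    place("abdomen", "elliptical_cylinder", {"a": 10.5, "b": 14.5, "length": 16.0}, 108.0, 124.0)
    place("torso", "elliptical_cylinder", {"a": 11.5, "b": 17.0, "length": 26.0}, 124.0, 150.0)
    place("head", "ellipsoid", {"a": 10.0, "b": 8.5, "c": 14.0}, 150.0, 178.0)
    for side, sy in (("left", -1.0), ("right", 1.0)):
        # leg chain
        place(f"{side}_thigh", "frustum", {"r_bottom": 7.0, "r_top": 9.0, "length": 44.0},
              46.0, 90.0, y=sy * _LEG_Y)
        place(f"{side}_shank", "frustum", {"r_bottom": 4.0, "r_top": 6.0, "length": 38.0},
              8.0, 46.0, y=sy * _LEG_Y)
        place(f"{side}_foot", "box", {"width": 25.0, "depth": 9.0, "height": 8.0},
              0.0, 8.0, y=sy * _LEG_Y)
        # arm chain (hanging beside the trunk)
        place(f"{side}_arm", "frustum", {"r_bottom": 3.5, "r_top": 4.5, "length": 28.0},
              122.0, 150.0, y=sy * _ARM_Y)
        place(f"{side}_forearm", "frustum", {"r_bottom": 2.8, "r_top": 3.5, "length": 26.0},
              96.0, 122.0, y=sy * _ARM_Y)
        place(f"{side}_hand", "ellipsoid", {"a": 2.2, "b": 4.5, "c": 9.0},
              78.0, 96.0, y=sy * _ARM_Y)
    return PhantomSpec(primitives=prims, resolution=resolution, noise_sigma=noise_sigma, seed=seed)


def _phantom_scheme() -> SegmentationScheme:
    """Boundary planes matching :func:`default_phantom_spec`'s junctions."""
    eps = JUNCTION_OFFSET

    def zplane(name, z):
        return BoundaryPlane(name, point=[0.0, 0.0, z - eps], normal=[0.0, 0.0, 1.0])

    def yplane(name, y):
        return BoundaryPlane(name, point=[0.0, y, 0.0], normal=[0.0, 1.0, 0.0])

    ankle, knee, hip = zplane("ankle", 8.0), zplane("knee", 46.0), zplane("hip", 90.0)
    pelvis_top, abdomen_top = zplane("pelvis_top", 108.0), zplane("abdomen_top", 124.0)
    neck = zplane("neck", 150.0)
    wrist, elbow = zplane("wrist", 96.0), zplane("elbow", 122.0)
    midline = yplane("midline", 0.0)
    arm_r = yplane("right_arm_sep", _ARM_SEP)
    arm_l = yplane("left_arm_sep", -_ARM_SEP)

    inner = [(arm_r, "negative"), (arm_l, "positive")]  # |y| < arm separator
    recipes: list[tuple[str, list[tuple[BoundaryPlane, str]]]] = [
        ("head", [(neck, "positive"), *inner]),
        ("torso", [(abdomen_top, "positive"), (neck, "negative"), *inner]),
        ("abdomen", [(pelvis_top, "positive"), (abdomen_top, "negative"), *inner]),
        ("pelvis", [(hip, "positive"), (pelvis_top, "negative"), *inner]),
    ]
    for side, keep_mid, keep_sep, sep in (
        ("right", "positive", "negative", arm_r),
        ("left", "negative", "positive", arm_l),
    ):
        recipes += [
            (f"{side}_thigh",
             [(midline, keep_mid), (sep, keep_sep), (knee, "positive"), (hip, "negative")]),
            (f"{side}_shank",
             [(midline, keep_mid), (sep, keep_sep), (ankle, "positive"), (knee, "negative")]),
            (f"{side}_foot",
             [(midline, keep_mid), (sep, keep_sep), (ankle, "negative")]),
            (f"{side}_arm",
             [(sep, "negative" if keep_sep == "positive" else "positive"),
              (elbow, "positive")]),
            (f"{side}_forearm",
             [(sep, "negative" if keep_sep == "positive" else "positive"),
              (wrist, "positive"), (elbow, "negative")]),
            (f"{side}_hand",
             [(sep, "negative" if keep_sep == "positive" else "positive"),
              (wrist, "negative")]),
        ]
    return SegmentationScheme(recipes=recipes)


def phantom_body(
    spec: PhantomSpec | None = None,
) -> tuple[TriangleMesh, SegmentationScheme, PhantomTruth]:
    """Whole phantom mesh, its segmentation scheme, and its analytic truth.

    The mesh concatenates the 16 closed primitive meshes (adjacent
    primitives share exact planar interfaces); the scheme's cut planes sit
    :data:`JUNCTION_OFFSET` off those interfaces.  Truth BSPs are composed
    analytically per primitive, with frames matching the pipeline convention
    (global anatomical frame everywhere, foot frames re-aligned heel→toe).
    """
    spec = spec or default_phantom_spec()
    global_frame = AnatomicalFrame.identity()
    vertices = []
    faces = []
    offset = 0
    truths: dict[str, SegmentBSP] = {}
    for label in SEGMENT_LABELS:
        prim = spec.primitives[label]
        mesh = primitive_mesh(prim, resolution=spec.resolution)
        vertices.append(mesh.vertices)
        faces.append(mesh.faces + offset)
        offset += mesh.n_vertices
        if base_label(label) == "foot":
            # foot frame: long = heel→toe (+ap here), ap = vertical,
            # ml completes right-handedness
            long_axis = global_frame.ap_axis
            ap_axis = global_frame.long_axis
            ml_axis = np.cross(long_axis, ap_axis)
            axes = AnatomicalFrame(np.zeros(3), ap_axis, ml_axis, long_axis)
            sign = -1.0  # proximal = heel = −long end
        else:
            axes = global_frame
            sign = 1.0
        truths[label] = primitive_truth(prim, proximal_sign=sign, axes=axes)
    whole = TriangleMesh(np.concatenate(vertices), np.concatenate(faces), label="phantom")
    if spec.noise_sigma > 0:
        whole = perturb_mesh(whole, spec.noise_sigma, spec.seed)
    return whole, _phantom_scheme(), PhantomTruth(segments=truths)


# ---------------------------------------------------------------------------
# perturbation
# ---------------------------------------------------------------------------


def perturb_mesh(mesh: TriangleMesh, sigma: float, seed: int) -> TriangleMesh:
    """Displace every vertex along its (area-weighted) vertex normal by a
    seeded Gaussian of standard deviation ``sigma`` cm; topology (hence
    closure) is preserved."""
    if sigma < 0:
        raise SyntheticError("sigma must be non-negative")
    if sigma == 0:
        return mesh.copy()
    v = mesh.vertices
    f = mesh.faces
    fn = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])  # 2x area * normal
    normals = np.zeros_like(v)
    for k in range(3):
        np.add.at(normals, f[:, k], fn)
    norms = np.linalg.norm(normals, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    normals /= norms
    rng = np.random.default_rng(seed)
    disp = rng.normal(0.0, sigma, size=len(v))
    out = mesh.copy()
    out.vertices = v + disp[:, None] * normals
    return out
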
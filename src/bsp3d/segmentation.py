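"""Whole-body alignment and plane-cut segmentation.

A scan is first rigidly aligned so the global axes coincide with the
anatomical anteroposterior / mediolateral / longitudinal directions, then
partitioned into closed segment meshes by boundary planes.  Each boundary
plane stands in for the taped landmark band used when segmenting scans by
hand: a point on the band and a unit normal oriented proximal→distal.

Cutting keeps the surface watertight: triangles straddling the plane are
split by edge–plane interpolation and every boundary loop opened by the cut
is capped by a fan of triangles from the loop centroid (body cross-sections
are near-convex, so a centroid fan is valid).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .mesh import MeshError, TriangleMesh, signed_volume, validate_mesh

logger = logging.getLogger(__name__)

#: the 16 segment labels of the body model
SEGMENT_LABELS: tuple[str, ...] = (
    "head",
    "torso",
    "abdomen",
    "pelvis",
    "left_hand",
    "right_hand",
    "left_forearm",
    "right_forearm",
    "left_arm",
    "right_arm",
    "left_thigh",
    "right_thigh",
    "left_shank",
    "right_shank",
    "left_foot",
    "right_foot",
)

#: base (side-less) segment names, e.g. for density tables
BASE_LABELS: tuple[str, ...] = (
    "head",
    "torso",
    "abdomen",
    "pelvis",
    "hand",
    "forearm",
    "arm",
    "thigh",
    "shank",
    "foot",
)


def base_label(label: str) -> str:
    """Strip a left_/right_ prefix: ``right_thigh`` -> ``thigh``."""
    for prefix in ("left_", "right_"):
        if label.startswith(prefix):
            return label[len(prefix):]
    return label


class SegmentationError(ValueError):
    """Raised for invalid schemes or degenerate cuts."""


@dataclass
class AnatomicalFrame:
    """Right-handed orthonormal frame: anteroposterior, mediolateral and
    longitudinal unit axes plus an origin, all in cm."""

    origin: np.ndarray
    ap_axis: np.ndarray
    ml_axis: np.ndarray
    long_axis: np.ndarray

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        for name in ("ap_axis", "ml_axis", "long_axis"):
            v = np.asarray(getattr(self, name), dtype=float)
            if abs(np.linalg.norm(v) - 1.0) > 1e-12:
                raise SegmentationError(f"{name} is not unit length")
            setattr(self, name, v)
        if (
            abs(self.ap_axis @ self.ml_axis) > 1e-9
            or abs(self.ap_axis @ self.long_axis) > 1e-9
            or abs(self.ml_axis @ self.long_axis) > 1e-9
        ):
            raise SegmentationError("frame axes are not orthogonal")
        if np.linalg.norm(np.cross(self.ml_axis, self.long_axis) - self.ap_axis) > 1e-9:
            raise SegmentationError("frame is not right-handed (ml x long != ap)")

    @classmethod
    def identity(cls) -> "AnatomicalFrame":
        """Default scan frame: ap = +x, ml = +y, long = +z (superior)."""
        return cls(
            origin=np.zeros(3),
            ap_axis=np.array([1.0, 0.0, 0.0]),
            ml_axis=np.array([0.0, 1.0, 0.0]),
            long_axis=np.array([0.0, 0.0, 1.0]),
        )

    @property
    def rotation(self) -> np.ndarray:
        """Rows are the ap/ml/long axes: maps world vectors to frame coords."""
        return np.vstack([self.ap_axis, self.ml_axis, self.long_axis])


@dataclass
class BoundaryPlane:
    """Segmentation boundary: a point on the plane and a unit normal oriented
    proximal→distal."""

    label: str
    point: np.ndarray
    normal: np.ndarray

    def __post_init__(self) -> None:
        self.point = np.asarray(self.point, dtype=float)
        n = np.asarray(self.normal, dtype=float)
        norm = np.linalg.norm(n)
        if norm == 0:
            raise SegmentationError(f"plane {self.label!r} has zero normal")
        if abs(norm - 1.0) > 1e-12:
            n = n / norm
        self.normal = n

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        return (np.asarray(points, dtype=float) - self.point) @ self.normal


@dataclass
class SegmentationScheme:
    """Ordered recipes mapping each segment label to the half-space
    intersection that isolates it: a list of (plane, keep_side) pairs with
    keep_side in {"positive", "negative"}.

    ``positive`` keeps the half-space the plane normal points into (the
    distal side).
    """

    recipes: list[tuple[str, list[tuple[BoundaryPlane, str]]]]
    frame: AnatomicalFrame = field(default_factory=AnatomicalFrame.identity)

    def __post_init__(self) -> None:
        labels = [label for label, _ in self.recipes]
        if len(set(labels)) != len(labels):
            raise SegmentationError("duplicate segment labels in scheme")
        for label, planes in self.recipes:
            if not planes:
                raise SegmentationError(f"recipe {label!r} has no planes")
            for _, keep in planes:
                if keep not in ("positive", "negative"):
                    raise SegmentationError(f"bad keep side {keep!r} in {label!r}")

    @property
    def labels(self) -> list[str]:
        return [label for label, _ in self.recipes]

    def require_full_body(self) -> None:
        """Raise unless the scheme covers exactly the 16-segment label set."""
        if set(self.labels) != set(SEGMENT_LABELS):
            missing = set(SEGMENT_LABELS) - set(self.labels)
            extra = set(self.labels) - set(SEGMENT_LABELS)
            raise SegmentationError(
                f"scheme is not a 16-segment body model "
                f"(missing={sorted(missing)}, unexpected={sorted(extra)})"
            )

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "frame": {
                "origin": self.frame.origin.tolist(),
                "ap": self.frame.ap_axis.tolist(),
                "ml": self.frame.ml_axis.tolist(),
                "long": self.frame.long_axis.tolist(),
            },
            "segments": [
                {
                    "label": label,
                    "planes": [
                        {
                            "plane": {
                                "point": p.point.tolist(),
                                "normal": p.normal.tolist(),
                            },
                            "keep": keep,
                        }
                        for p, keep in planes
                    ],
                }
                for label, planes in self.recipes
            ],
        }

    @classmethod
    def from_dict(cls, data: dict) -> "SegmentationScheme":
        frame = AnatomicalFrame.identity()
        if "frame" in data:
            fb = data["frame"]
            frame = AnatomicalFrame(
                origin=fb.get("origin", [0, 0, 0]),
                ap_axis=fb["ap"],
                ml_axis=fb["ml"],
                long_axis=fb["long"],
            )
        recipes = []
        for seg in data["segments"]:
            planes = [
                (
                    BoundaryPlane(
                        label=f"{seg['label']}_{i}",
                        point=entry["plane"]["point"],
                        normal=entry["plane"]["normal"],
                    ),
                    entry["keep"],
                )
                for i, entry in enumerate(seg["planes"])
            ]
            recipes.append((seg["label"], planes))
        return cls(recipes=recipes, frame=frame)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        data = self.to_dict()
        with open(path, "w") as fh:
            if path.suffix.lower() in (".yaml", ".yml"):
                yaml.safe_dump(data, fh, sort_keys=False)
            else:
                json.dump(data, fh, indent=1)

    @classmethod
    def load(cls, path: str | Path) -> "SegmentationScheme":
        path = Path(path)
        with open(path) as fh:
            data = yaml.safe_load(fh)  # YAML is a superset of JSON
        return cls.from_dict(data)


# ---------------------------------------------------------------------------
# rigid alignment
# ---------------------------------------------------------------------------


def rigid_fit(source: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid transform (Kabsch): returns ``(R, t, rms)`` with
    ``R @ source + t ≈ target`` and the residual RMS in cm."""
    source = np.asarray(source, dtype=float)
    target = np.asarray(target, dtype=float)
    if source.shape != target.shape or source.ndim != 2 or source.shape[1] != 3:
        raise SegmentationError("landmark arrays must both be (k, 3)")
    if len(source) < 3:
        raise SegmentationError("need at least 3 landmark pairs")
    cs = source.mean(axis=0)
    ct = target.mean(axis=0)
    src = source - cs
    tgt = target - ct
    if np.linalg.matrix_rank(src, tol=1e-9 * max(1.0, np.abs(src).max())) < 2:
        raise SegmentationError("landmarks are collinear")
    h = src.T @ tgt
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rotation = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    translation = ct - rotation @ cs
    residual = source @ rotation.T + translation - target
    rms = float(np.sqrt((residual**2).sum(axis=1).mean()))
    return rotation, translation, rms


def align_scan(
    mesh: TriangleMesh,
    rotation: np.ndarray | None = None,
    translation: np.ndarray | None = None,
    landmarks: tuple[np.ndarray, np.ndarray] | None = None,
) -> TriangleMesh:
    """Apply a rigid transform, given explicitly or fit from >=3 landmark
    point pairs ``(scan_points, anatomical_points)``."""
    if landmarks is not None:
        rotation, translation, rms = rigid_fit(*landmarks)
        logger.info("landmark alignment residual RMS %.4g cm", rms)
    if rotation is None:
        rotation = np.eye(3)
    if translation is None:
        translation = np.zeros(3)
    rotation = np.asarray(rotation, dtype=float)
    if rotation.shape != (3, 3):
        raise SegmentationError("rotation must be 3x3")
    if (
        np.abs(rotation @ rotation.T - np.eye(3)).max() > 1e-6
        or abs(np.linalg.det(rotation) - 1.0) > 1e-6
    ):
        raise SegmentationError("rotation is not a proper orthonormal matrix")
    return mesh.transformed(rotation, np.asarray(translation, dtype=float))


# ---------------------------------------------------------------------------
# plane cut with cap closure
# ---------------------------------------------------------------------------

_ON_PLANE_TOL = 1e-9


def cut_and_cap(
    mesh: TriangleMesh,
    plane: BoundaryPlane,
    keep_side: str = "positive",
    _tol: float = _ON_PLANE_TOL,
) -> TriangleMesh:
    """Cut a closed mesh by a plane, keep one side, and cap the cut.

    ``keep_side="positive"`` keeps the half-space the plane normal points
    into.  Straddling triangles are split by edge–plane interpolation; each
    boundary loop is capped by a centroid fan whose winding keeps the kept
    solid outward-oriented.  Volume is conserved: kept + discarded volumes
    equal the parent volume to well under 0.1%.
    """
    if keep_side not in ("positive", "negative"):
        raise SegmentationError(f"bad keep_side {keep_side!r}")
    d = plane.signed_distance(mesh.vertices)
    if keep_side == "negative":
        d = -d
    d = np.where(np.abs(d) <= _tol, 0.0, d)

    keep_all = d[mesh.faces].min(axis=1) >= 0.0
    drop_all = d[mesh.faces].max(axis=1) <= 0.0
    coplanar = (np.abs(d[mesh.faces]).max(axis=1) == 0.0)
    if coplanar.any():
        # faces lying in the plane belong to the kept solid when their
        # outward normal faces the discarded side
        v = mesh.vertices
        f = mesh.faces[coplanar]
        fn = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
        sign = 1.0 if keep_side == "positive" else -1.0
        facing_out = fn @ (sign * plane.normal) < 0
        keep_all = keep_all.copy()
        drop_all = drop_all.copy()
        idx = np.flatnonzero(coplanar)
        keep_all[idx] = facing_out
        drop_all[idx] = ~facing_out
    straddle = ~(keep_all | drop_all)

    vertices = list(mesh.vertices)
    new_faces: list[tuple[int, int, int]] = [tuple(f) for f in mesh.faces[keep_all & ~straddle]]
    edge_point: dict[tuple[int, int], int] = {}

    def intersection(i: int, j: int) -> int:
        key = (i, j) if i < j else (j, i)
        idx = edge_point.get(key)
        if idx is None:
            di, dj = d[i], d[j]
            t = di / (di - dj)
            vertices.append(mesh.vertices[i] + t * (mesh.vertices[j] - mesh.vertices[i]))
            idx = len(vertices) - 1
            edge_point[key] = idx
        return idx

    for face in mesh.faces[straddle]:
        # clip triangle against half-space d >= 0 (Sutherland–Hodgman)
        poly: list[int] = []
        for k in range(3):
            i, j = face[k], face[(k + 1) % 3]
            if d[i] >= 0:
                poly.append(i)
            if (d[i] > 0 and d[j] < 0) or (d[i] < 0 and d[j] > 0):
                poly.append(intersection(i, j))
        uniq = [p for n, p in enumerate(poly) if p != poly[n - 1]]
        if len(uniq) >= 2 and uniq[0] == uniq[-1]:
            uniq = uniq[:-1]
        if len(uniq) == 3:
            new_faces.append((uniq[0], uniq[1], uniq[2]))
        elif len(uniq) == 4:
            new_faces.append((uniq[0], uniq[1], uniq[2]))
            new_faces.append((uniq[0], uniq[2], uniq[3]))

    if not new_faces:
        raise SegmentationError(f"empty segment: plane {plane.label!r} leaves nothing")

    faces = np.asarray(new_faces, dtype=np.int64)

    # boundary loops: directed edges appearing without their reverse
    de = np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    und = np.sort(de, axis=1)
    _, inv, counts = np.unique(und, axis=0, return_inverse=True, return_counts=True)
    boundary = de[counts[inv] == 1]

    if len(boundary):
        succ = {int(a): int(b) for a, b in boundary}
        verts_arr = np.asarray(vertices)
        visited: set[int] = set()
        cap_faces: list[tuple[int, int, int]] = []
        for start in list(succ):
            if start in visited:
                continue
            loop = [start]
            visited.add(start)
            node = succ[start]
            while node != start:
                loop.append(node)
                visited.add(node)
                node = succ.get(node, start) if node in succ else start
            if len(loop) < 3:
                continue
            centroid = verts_arr[loop].mean(axis=0)
            vertices.append(centroid)
            c = len(vertices) - 1
            for n, a in enumerate(loop):
                b = loop[(n + 1) % len(loop)]
                # reverse traversal closes the surface with outward winding
                cap_faces.append((b, a, c))
        if cap_faces:
            faces = np.concatenate([faces, np.asarray(cap_faces, dtype=np.int64)])

    verts_arr = np.asarray(vertices)
    used = np.unique(faces)
    remap = np.full(len(verts_arr), -1, dtype=np.int64)
    remap[used] = np.arange(len(used))
    out = TriangleMesh(verts_arr[used], remap[faces], label=mesh.label)
    if abs(signed_volume(out)) <= 1e-12:
        raise SegmentationError(f"empty segment: plane {plane.label!r} leaves no volume")
    return out


def segment_body(
    mesh: TriangleMesh,
    scheme: SegmentationScheme,
    volume_tolerance: float = 0.005,
) -> dict[str, TriangleMesh]:
    """Partition an aligned closed mesh into one closed mesh per scheme
    recipe.

    Each recipe's planes are applied in order to a fresh copy of the whole
    mesh.  The summed segment volumes must match the whole-body volume within
    ``volume_tolerance`` (0.5% by default) and every segment must be
    non-empty and closed.
    """
    report = validate_mesh(mesh)
    if not report.is_closed:
        raise MeshError(f"input mesh is not closed: {report.n_boundary_edges} boundary edges")
    parent_volume = abs(report.signed_volume)
    segments: dict[str, TriangleMesh] = {}
    total = 0.0
    for label, planes in scheme.recipes:
        piece = mesh
        try:
            for plane, keep in planes:
                piece = cut_and_cap(piece, plane, keep)
        except SegmentationError as exc:
            raise SegmentationError(f"empty segment: {label}") from exc
        piece = piece.copy()
        piece.label = label
        seg_report = validate_mesh(piece)
        if not seg_report.is_closed:
            raise SegmentationError(
                f"segment {label!r} is not closed ({seg_report.n_boundary_edges} boundary edges)"
            )
        vol = abs(seg_report.signed_volume)
        if vol <= 1e-12:
            raise SegmentationError(f"empty segment: {label}")
        segments[label] = piece
        total += vol
    if total > parent_volume * 1.005:
        raise SegmentationError(
            f"overlapping recipes: segment volumes sum to "
            f"{100 * total / parent_volume:.2f}% of the whole body"
        )
    if abs(total - parent_volume) > volume_tolerance * parent_volume:
        raise SegmentationError(
            f"segment volumes sum to {total:.6g} cm^3 but whole body is "
            f"{parent_volume:.6g} cm^3 (>{100 * volume_tolerance:.2g}% apart)"
        )
    return segments
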
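"""Per-segment body segment parameters and 16-segment subject aggregation.

For each closed segment mesh the pipeline computes, at the segment's uniform
density: volume, mass, volumetric centroid (taken as the center of mass —
the geometric center of the enclosed solid, not a vertex average), the
inertia tensor about the COM expressed on the segment axes (I_ap, I_ml,
I_long, in kg·cm²), the longitudinal length, and the COM position as a
percentage of that length from the proximal endpoint (pCOM).

Length follows the ray construction: a line is projected from the COM along
the segment's longitudinal axis in both directions until it intersects the
segment surface; the farthest intersection on each side is an endpoint and
the length is the endpoint-to-endpoint distance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .mesh import MeshError, TriangleMesh, solid_properties
from .segmentation import (
    AnatomicalFrame,
    BASE_LABELS,
    SEGMENT_LABELS,
    base_label,
)

logger = logging.getLogger(__name__)

#: uniform segment densities (kg/m³) from the cadaver/CT literature.  These
#: are external constants commonly used with 16-segment surface models; the
#: ``uniform_1000`` mode (density of water everywhere) is the assumption-free
#: fallback.
LITERATURE_DENSITIES: dict[str, float] = {
    "head": 1110.0,
    "torso": 920.0,
    "abdomen": 1010.0,
    "pelvis": 1010.0,
    "thigh": 1050.0,
    "shank": 1090.0,
    "foot": 1100.0,
    "arm": 1070.0,
    "forearm": 1130.0,
    "hand": 1160.0,
}

#: proximal endpoint convention: the sign of the segment longitudinal axis
#: that points toward the proximal (body-root-facing) end.  The foot's long
#: axis runs heel→toe, so its proximal (heel) end is the −long end; every
#: other segment's proximal end is the superior (+long) end in a standing
#: scan (head/trunk superior ends; shoulder/elbow/wrist for the arm chain;
#: hip/knee for the leg chain).
PROXIMAL_SIGN: dict[str, float] = {**{name: +1.0 for name in BASE_LABELS}, "foot": -1.0}


class BspError(ValueError):
    """Raised for invalid densities, labels or degenerate geometry."""


@dataclass
class DensityTable:
    """Density (kg/m³) per segment label.

    ``mode="literature"`` uses :data:`LITERATURE_DENSITIES`;
    ``mode="uniform_1000"`` sets every segment to exactly 1000 kg/m³.
    Custom per-segment values may be supplied keyed by base or sided label.
    """

    densities: dict[str, float]
    mode: str = "literature"

    def __post_init__(self) -> None:
        for label, rho in self.densities.items():
            if not 900.0 <= rho <= 1300.0:
                raise BspError(
                    f"density for {label!r} is {rho} kg/m^3, outside [900, 1300]"
                )

    @classmethod
    def literature(cls) -> "DensityTable":
        return cls(dict(LITERATURE_DENSITIES), mode="literature")

    @classmethod
    def uniform_1000(cls) -> "DensityTable":
        return cls({name: 1000.0 for name in BASE_LABELS}, mode="uniform_1000")

    @classmethod
    def from_csv(cls, path) -> "DensityTable":
        import pandas as pd

        df = pd.read_csv(path)
        if not {"label", "density_kgm3"} <= set(df.columns):
            raise BspError("density CSV needs columns label,density_kgm3")
        table = {str(r.label): float(r.density_kgm3) for r in df.itertuples()}
        bases = {base_label(k) for k in table}
        if not set(BASE_LABELS) <= bases:
            raise BspError(f"density CSV missing segments: {sorted(set(BASE_LABELS) - bases)}")
        return cls(table, mode="custom")

    def __getitem__(self, label: str) -> float:
        if label in self.densities:
            return self.densities[label]
        base = base_label(label)
        if base in self.densities:
            return self.densities[base]
        raise BspError(f"no density for segment {label!r}")


@dataclass
class SegmentBSP:
    """Body segment parameters of a single segment.

    ``pcom`` is the COM's distance from the proximal endpoint, as a
    percentage of the longitudinal ``length``; inertia components are about
    the COM on the segment's ap/ml/long axes, in kg·cm².
    """

    label: str
    volume: float
    mass: float
    com: np.ndarray
    I_ap: float
    I_ml: float
    I_long: float
    inertia_tensor: np.ndarray
    proximal_endpoint: np.ndarray
    distal_endpoint: np.ndarray
    length: float
    pcom: float


@dataclass
class SubjectBSP:
    """All 16 segments plus exact totals (mass = Σ segment masses)."""

    segments: dict[str, SegmentBSP]
    total_mass: float = field(init=False)
    total_volume: float = field(init=False)

    def __post_init__(self) -> None:
        self.total_mass = float(sum(s.mass for s in self.segments.values()))
        self.total_volume = float(sum(s.volume for s in self.segments.values()))


# ---------------------------------------------------------------------------
# segment coordinate frames
# ---------------------------------------------------------------------------


def segment_frame(
    label: str, global_frame: AnatomicalFrame, mesh: TriangleMesh
) -> AnatomicalFrame:
    """Segment coordinate frame.

    Every segment uses the global anatomical frame except the feet: the foot
    longitudinal axis is re-aligned with the long (heel→toe) horizontal
    extent of the foot, the anteroposterior axis becomes the former vertical
    (global longitudinal) axis, and the mediolateral axis completes the
    right-handed frame.  Ties in horizontal extent break toward the global
    anteroposterior direction with a warning.
    """
    if base_label(label) != "foot":
        return global_frame

    centered = mesh.vertices - mesh.vertices.mean(axis=0)
    u = centered @ global_frame.ap_axis
    v = centered @ global_frame.ml_axis
    cov = np.cov(np.vstack([u, v]))
    evals, evecs = np.linalg.eigh(cov)
    if abs(evals[1] - evals[0]) <= 1e-6 * max(abs(evals[1]), 1.0):
        logger.warning(
            "foot %r has degenerate horizontal extents; using global ap axis", label
        )
        direction = global_frame.ap_axis
    else:
        a, b = evecs[:, -1]  # dominant horizontal direction (ap, ml) weights
        direction = a * global_frame.ap_axis + b * global_frame.ml_axis
        direction /= np.linalg.norm(direction)
        if direction @ global_frame.ap_axis < 0:
            direction = -direction
    long_axis = direction
    ap_axis = global_frame.long_axis
    ml_axis = np.cross(long_axis, ap_axis)
    ml_axis /= np.linalg.norm(ml_axis)
    return AnatomicalFrame(
        origin=global_frame.origin,
        ap_axis=ap_axis,
        ml_axis=ml_axis,
        long_axis=long_axis,
    )


# ---------------------------------------------------------------------------
# longitudinal extent by ray casting
# ---------------------------------------------------------------------------


def _ray_intersections(mesh: TriangleMesh, origin: np.ndarray, direction: np.ndarray) -> np.ndarray:
    """Signed ray parameters t of all intersections of the line
    ``origin + t * direction`` with the mesh surface (Möller–Trumbore,
    vectorized over faces)."""
    v = mesh.vertices
    v0 = v[mesh.faces[:, 0]]
    e1 = v[mesh.faces[:, 1]] - v0
    e2 = v[mesh.faces[:, 2]] - v0
    pvec = np.cross(direction, e2)
    det = np.einsum("ij,ij->i", e1, pvec)
    ok = np.abs(det) > 1e-14
    inv = np.where(ok, det, 1.0)
    tvec = origin - v0
    uu = np.einsum("ij,ij->i", tvec, pvec) / inv
    qvec = np.cross(tvec, e1)
    vv = (qvec @ direction) / inv
    hit = ok & (uu >= -1e-12) & (vv >= -1e-12) & (uu + vv <= 1 + 1e-12)
    t = np.einsum("ij,ij->i", e2, qvec) / inv
    return t[hit]


def longitudinal_extent(
    mesh: TriangleMesh, com: np.ndarray, long_axis: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Endpoints and length along ``long_axis`` through the COM.

    Rays are cast from the COM in the +axis and −axis directions; the
    farthest surface intersection on each side is an endpoint.  Returns
    ``(end_plus, end_minus, length)`` where ``end_plus`` lies on the +axis
    side.
    """
    com = np.asarray(com, dtype=float)
    axis = np.asarray(long_axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    t = _ray_intersections(mesh, com, axis)
    t_plus = t[t > 1e-12]
    t_minus = t[t < -1e-12]
    if not len(t_plus) or not len(t_minus):
        raise BspError(
            "longitudinal ray found no surface intersection on one side "
            "(is the COM inside the mesh?)"
        )
    end_plus = com + t_plus.max() * axis
    end_minus = com + t_minus.min() * axis
    length = float(np.linalg.norm(end_plus - end_minus))
    return end_plus, end_minus, length


# ---------------------------------------------------------------------------
# per-segment and subject BSPs
# ---------------------------------------------------------------------------


def compute_segment_bsp(
    mesh: TriangleMesh,
    label: str,
    global_frame: AnatomicalFrame | None = None,
    densities: DensityTable | None = None,
    proximal_sign: dict[str, float] | None = None,
) -> SegmentBSP:
    """All BSPs of a single closed segment mesh.

    The inertia tensor from the polyhedral integration (mesh frame, about
    the COM) is rotated into the segment frame; I_ap/I_ml/I_long are its
    diagonal entries on those axes.  pCOM uses the orthogonal projection of
    the COM onto the endpoint–endpoint line (the COM may sit slightly off
    the longitudinal axis for asymmetric segments).
    """
    global_frame = global_frame or AnatomicalFrame.identity()
    densities = densities or DensityTable.literature()
    signs = {**PROXIMAL_SIGN, **(proximal_sign or {})}

    props = solid_properties(mesh, densities[label])
    frame = segment_frame(label, global_frame, mesh)
    rot = frame.rotation  # rows ap, ml, long
    inertia_seg = rot @ props.inertia_tensor @ rot.T

    end_plus, end_minus, length = longitudinal_extent(mesh, props.centroid, frame.long_axis)
    sign = signs.get(base_label(label), 1.0)
    if sign >= 0:
        proximal, distal = end_plus, end_minus
    else:
        proximal, distal = end_minus, end_plus
    u = (distal - proximal) / length
    pcom = 100.0 * float((props.centroid - proximal) @ u) / length

    return SegmentBSP(
        label=label,
        volume=props.volume,
        mass=props.mass,
        com=props.centroid,
        I_ap=float(inertia_seg[0, 0]),
        I_ml=float(inertia_seg[1, 1]),
        I_long=float(inertia_seg[2, 2]),
        inertia_tensor=inertia_seg,
        proximal_endpoint=proximal,
        distal_endpoint=distal,
        length=length,
        pcom=pcom,
    )


def compute_subject_bsp(
    segments: dict[str, TriangleMesh],
    global_frame: AnatomicalFrame | None = None,
    densities: DensityTable | None = None,
) -> SubjectBSP:
    """BSPs for all 16 segments; totals are exact sums of segment masses and
    volumes."""
    missing = set(SEGMENT_LABELS) - set(segments)
    if missing:
        raise BspError(f"missing segment: {sorted(missing)}")
    results = {
        label: compute_segment_bsp(segments[label], label, global_frame, densities)
        for label in SEGMENT_LABELS
    }
    return SubjectBSP(segments=results)


def subject_report(subject: SubjectBSP):
    """Flatten a :class:`SubjectBSP` into the standard report DataFrame."""
    import pandas as pd

    rows = []
    for label, s in subject.segments.items():
        rows.append(
            {
                "label": label,
                "volume_cm3": s.volume,
                "mass_kg": s.mass,
                "com_x": s.com[0],
                "com_y": s.com[1],
                "com_z": s.com[2],
                "I_ap": s.I_ap,
                "I_ml": s.I_ml,
                "I_long": s.I_long,
                "length_cm": s.length,
                "pcom_pct": s.pcom,
            }
        )
    return pd.DataFrame(rows)
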
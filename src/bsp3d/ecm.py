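"""Elliptical cylinder method (ECM).

The ECM models each body segment as a proximal→distal stack of elliptical
cylinders whose semi-axes come from calibrated frontal (width) and sagittal
(depth) photographs.  Each slice of mediolateral semi-axis ``a``,
anteroposterior semi-axis ``b`` and height ``h`` contributes

    V = π a b h,    m = ρ V,
    I_long = m (a² + b²) / 4                (about the stack axis)
    I_ml   = m (3 b² + h²) / 12             (own centroid)
    I_ap   = m (3 a² + h²) / 12

and the composite COM and inertia follow from mass-weighted averaging plus
the parallel-axis theorem along the stack axis.  Segment length is the total
stack height; pCOM is measured from the proximal (first) slice end.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .bsp import SegmentBSP


class EcmError(ValueError):
    """Raised for invalid calibrations or profiles."""


@dataclass
class ViewCalibration:
    """cm-per-pixel scales for the horizontal/vertical directions of the
    frontal and sagittal camera views."""

    frontal_h: float
    frontal_v: float
    sagittal_h: float
    sagittal_v: float

    def __post_init__(self) -> None:
        for name in ("frontal_h", "frontal_v", "sagittal_h", "sagittal_v"):
            if getattr(self, name) <= 0:
                raise EcmError(f"calibration scale {name} must be positive")


@dataclass
class EllipticalSlice:
    """One stacked slice: mediolateral semi-axis ``a``, anteroposterior
    semi-axis ``b`` and height ``h``, all in cm."""

    a: float
    b: float
    h: float

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0 or self.h <= 0:
            raise EcmError("slice dimensions must be positive")


@dataclass
class SegmentProfile:
    """Ordered proximal→distal slices of one segment at a uniform density."""

    label: str
    slices: list[EllipticalSlice]
    density: float = 1000.0

    def __post_init__(self) -> None:
        if not self.slices:
            raise EcmError("profile needs at least one slice")
        if self.density <= 0:
            raise EcmError("density must be positive")

    @property
    def height(self) -> float:
        return float(sum(s.h for s in self.slices))


def calibrate(reference_pixels: float, reference_cm: float) -> float:
    """Scale (cm per pixel) from a reference object of known true length."""
    if reference_pixels <= 0 or reference_cm <= 0:
        raise EcmError("calibration inputs must be positive")
    return reference_cm / reference_pixels


def build_profile(
    frontal_widths,
    sagittal_depths,
    cal: ViewCalibration,
    slice_height: float,
    label: str = "",
    density: float = 1000.0,
) -> SegmentProfile:
    """Digitized pixel widths/depths → calibrated slice stack.

    Semi-axes: a_i = width_i · frontal_h / 2 (mediolateral),
    b_i = depth_i · sagittal_h / 2 (anteroposterior); slices share a uniform
    ``slice_height`` in cm.
    """
    frontal_widths = np.asarray(frontal_widths, dtype=float)
    sagittal_depths = np.asarray(sagittal_depths, dtype=float)
    if frontal_widths.shape != sagittal_depths.shape or frontal_widths.ndim != 1:
        raise EcmError("width and depth lists must have equal length")
    if len(frontal_widths) < 1:
        raise EcmError("need at least one slice")
    if np.any(frontal_widths <= 0) or np.any(sagittal_depths <= 0) or slice_height <= 0:
        raise EcmError("measures must be positive")
    slices = [
        EllipticalSlice(a=w * cal.frontal_h / 2.0, b=d * cal.sagittal_h / 2.0, h=slice_height)
        for w, d in zip(frontal_widths, sagittal_depths)
    ]
    return SegmentProfile(label=label, slices=slices, density=density)


def ecm_properties(profile: SegmentProfile) -> SegmentBSP:
    """Composite segment BSPs of a slice stack.

    The stack runs proximal→distal along the local longitudinal axis; the
    returned COM/endpoints are expressed in stack coordinates with the
    proximal end at the origin and the distal end at (0, 0, length).
    """
    rho_cm = profile.density * 1e-6  # kg per cm^3
    a = np.array([s.a for s in profile.slices])
    b = np.array([s.b for s in profile.slices])
    h = np.array([s.h for s in profile.slices])
    vol = np.pi * a * b * h
    mass = rho_cm * vol
    tops = np.concatenate([[0.0], np.cumsum(h)])
    centers = tops[:-1] + h / 2.0  # distance of slice centroids from proximal end
    length = float(tops[-1])

    m_total = float(mass.sum())
    s_com = float((mass * centers).sum() / m_total)

    i_long = (mass * (a**2 + b**2) / 4.0).sum()
    d2 = (centers - s_com) ** 2
    i_ml = (mass * (3 * b**2 + h**2) / 12.0 + mass * d2).sum()
    i_ap = (mass * (3 * a**2 + h**2) / 12.0 + mass * d2).sum()

    inertia = np.diag([i_ap, i_ml, i_long])
    return SegmentBSP(
        label=profile.label,
        volume=float(vol.sum()),
        mass=m_total,
        com=np.array([0.0, 0.0, s_com]),
        I_ap=float(i_ap),
        I_ml=float(i_ml),
        I_long=float(i_long),
        inertia_tensor=inertia,
        proximal_endpoint=np.zeros(3),
        distal_endpoint=np.array([0.0, 0.0, length]),
        length=length,
        pcom=100.0 * s_com / length,
    )


def profiles_from_csv(path: str | Path, cal: ViewCalibration | None = None) -> list[SegmentProfile]:
    """Load segment profiles from a slice table.

    Columns: ``label, slice_index, width_px, depth_px, height_cm,
    density_kgm3`` (pixel mode, requires ``cal``) or ``label, slice_index,
    width_cm, depth_cm, height_cm, density_kgm3`` (pre-calibrated mode).
    """
    df = pd.read_csv(path)
    pixel_mode = {"width_px", "depth_px"} <= set(df.columns)
    cm_mode = {"width_cm", "depth_cm"} <= set(df.columns)
    if not pixel_mode and not cm_mode:
        raise EcmError("profile CSV needs width_px/depth_px or width_cm/depth_cm columns")
    if pixel_mode and cal is None:
        raise EcmError("pixel-unit profile requires a ViewCalibration")
    profiles = []
    for label, group in df.groupby("label", sort=False):
        group = group.sort_values("slice_index")
        if pixel_mode:
            widths = group["width_px"].to_numpy() * cal.frontal_h
            depths = group["depth_px"].to_numpy() * cal.sagittal_h
        else:
            widths = group["width_cm"].to_numpy()
            depths = group["depth_cm"].to_numpy()
        slices = [
            EllipticalSlice(a=w / 2.0, b=d / 2.0, h=float(hh))
            for w, d, hh in zip(widths, depths, group["height_cm"])
        ]
        density = float(group["density_kgm3"].iloc[0]) if "density_kgm3" in group else 1000.0
        profiles.append(SegmentProfile(label=str(label), slices=slices, density=density))
    return profiles
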
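"""Pelvic Inclination Correction System (PICS) coordinate frame.

The frame standardizes pelvic orientation from four bony landmarks placed on
an MR volume: the pubic symphysis (PS), the sacrococcygeal joint (SCJ) and
the two ischial spines (IS_L, IS_R).  Its axes are

* ``axis_pics``     — the PICS line, the unit vector from PS toward SCJ;
* ``axis_lateral``  — toward the subject's left, the inter-spine vector
  Gram–Schmidt-orthogonalized against the PICS line;
* ``axis_vertical`` — completes a right-handed frame.

All coordinates are world (scanner) millimetres.  PICS coordinates of a point
are ordered ``(lateral, axial, vertical)`` where *axial* is the position along
the PICS line; the origin is at the pubic symphysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "LandmarkSet",
    "PicsFrame",
    "FrameError",
    "validate_landmarks",
    "build_frame",
    "to_pics_coords",
    "project_onto_pics_axis",
]

#: canonical landmark labels used by every I/O dialect
LANDMARK_LABELS = ("PS", "SCJ", "IS_L", "IS_R")

#: minimum angle (degrees) between the inter-spine vector and the PICS line
MIN_LATERAL_ANGLE_DEG = 1.0


class FrameError(ValueError):
    """Raised when a PICS frame cannot be constructed from the landmarks."""


def _point(p) -> np.ndarray:
    a = np.asarray(p, dtype=float).reshape(3)
    return a


@dataclass(frozen=True)
class LandmarkSet:
    """The four anatomical reference points, in world millimetres."""

    pubic_symphysis: np.ndarray
    sacrococcygeal_joint: np.ndarray
    ischial_spine_left: np.ndarray
    ischial_spine_right: np.ndarray

    def __post_init__(self) -> None:
        for name in (
            "pubic_symphysis",
            "sacrococcygeal_joint",
            "ischial_spine_left",
            "ischial_spine_right",
        ):
            object.__setattr__(self, name, _point(getattr(self, name)))

    def transformed(self, rotation: np.ndarray, translation=(0.0, 0.0, 0.0)) -> "LandmarkSet":
        """Apply a rigid transform ``p -> R p + t`` to every landmark."""
        R = np.asarray(rotation, dtype=float).reshape(3, 3)
        t = _point(translation)
        return LandmarkSet(
            R @ self.pubic_symphysis + t,
            R @ self.sacrococcygeal_joint + t,
            R @ self.ischial_spine_left + t,
            R @ self.ischial_spine_right + t,
        )

    def mirrored(self) -> "LandmarkSet":
        """Reflect across the midsagittal plane x=0 (swaps the spines)."""
        M = np.diag([-1.0, 1.0, 1.0])
        return LandmarkSet(
            M @ self.pubic_symphysis,
            M @ self.sacrococcygeal_joint,
            M @ self.ischial_spine_right,
            M @ self.ischial_spine_left,
        )


@dataclass(frozen=True)
class PicsFrame:
    """Orthonormal right-handed anatomical frame anchored at the pubic symphysis."""

    origin: np.ndarray
    axis_pics: np.ndarray
    axis_lateral: np.ndarray
    axis_vertical: np.ndarray

    def __post_init__(self) -> None:
        for name in ("origin", "axis_pics", "axis_lateral", "axis_vertical"):
            object.__setattr__(self, name, _point(getattr(self, name)))

    @property
    def rotation(self) -> np.ndarray:
        """Rows ``(lateral, axial/pics, vertical)``: world -> PICS direction map."""
        return np.vstack([self.axis_lateral, self.axis_pics, self.axis_vertical])


def validate_landmarks(ls: LandmarkSet) -> list[str]:
    """Return the list of violated landmark invariants (empty when valid).

    Diagnostic only; never raises.  Checks finiteness, a non-degenerate PICS
    line (PS != SCJ), distinct ischial spines, and that the inter-spine vector
    is not within ``MIN_LATERAL_ANGLE_DEG`` of parallel to the PICS line.
    """
    report: list[str] = []
    pts = np.vstack(
        [
            ls.pubic_symphysis,
            ls.sacrococcygeal_joint,
            ls.ischial_spine_left,
            ls.ischial_spine_right,
        ]
    )
    if not np.all(np.isfinite(pts)):
        report.append("non-finite landmark coordinate")
        return report

    pics_vec = ls.sacrococcygeal_joint - ls.pubic_symphysis
    lat_vec = ls.ischial_spine_left - ls.ischial_spine_right
    npics = np.linalg.norm(pics_vec)
    nlat = np.linalg.norm(lat_vec)
    if npics == 0.0:
        report.append("degenerate PICS line: pubic symphysis coincides with sacrococcygeal joint")
    if nlat == 0.0:
        report.append("degenerate lateral axis: ischial spines coincide")
    if npics > 0.0 and nlat > 0.0:
        cosang = abs(float(pics_vec @ lat_vec)) / (npics * nlat)
        ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
        if ang <= MIN_LATERAL_ANGLE_DEG:
            report.append(
                "lateral vector nearly parallel to PICS line "
                f"(angle {ang:.3g} deg <= {MIN_LATERAL_ANGLE_DEG} deg)"
            )
    return report


def build_frame(ls: LandmarkSet) -> PicsFrame:
    """Construct the PICS frame from a valid landmark set.

    Raises
    ------
    FrameError
        If any landmark invariant is violated; the message names each one.
    """
    report = validate_landmarks(ls)
    if report:
        raise FrameError("; ".join(report))

    axis_pics = ls.sacrococcygeal_joint - ls.pubic_symphysis
    axis_pics = axis_pics / np.linalg.norm(axis_pics)

    lat = ls.ischial_spine_left - ls.ischial_spine_right
    lat = lat - (lat @ axis_pics) * axis_pics
    axis_lateral = lat / np.linalg.norm(lat)

    # lateral x pics yields det(+1) for row order (lateral, pics, vertical)
    axis_vertical = np.cross(axis_lateral, axis_pics)
    axis_vertical = axis_vertical / np.linalg.norm(axis_vertical)

    return PicsFrame(
        origin=ls.pubic_symphysis,
        axis_pics=axis_pics,
        axis_lateral=axis_lateral,
        axis_vertical=axis_vertical,
    )


def to_pics_coords(points: np.ndarray, frame: PicsFrame) -> np.ndarray:
    """Transform world-mm points into PICS ``(lateral, axial, vertical)`` mm.

    Accepts a single point ``(3,)`` or a stack ``(n, 3)``; an isometry.
    """
    pts = np.asarray(points, dtype=float)
    single = pts.ndim == 1
    pts = np.atleast_2d(pts)
    out = (pts - frame.origin) @ frame.rotation.T
    return out[0] if single else out


def project_onto_pics_axis(point: np.ndarray, frame: PicsFrame) -> float:
    """Signed position of a world point along the PICS line, mm from the pubis."""
    p = _point(point)
    return float((p - frame.origin) @ frame.axis_pics)
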
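"""Iliococcygeus-angle measurement from a levator ani segmentation.

The muscle mask is cut by five planes perpendicular to the PICS line, placed
at k/5 of the pubis-to-right-ischial-spine distance (k = 1..5, plane 1 most
anterior).  Within each plane the foreground voxel centers are split at the
midsagittal PICS plane; a first-degree polynomial fit through each side's
(lateral, vertical) cloud gives that side's inclination to the transverse
plane, and the triangle identity

    total ICA = 180 - left ICA - right ICA

gives the total angle.  A larger total reflects a flatter, more supportive
muscle sheet.  A side with too few voxels (e.g. at an avulsion gap) renders
the plane unmeasurable; that is reported, never fatal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .frame import (
    LandmarkSet,
    PicsFrame,
    build_frame,
    project_onto_pics_axis,
    to_pics_coords,
)
from .io import VolumeMask

__all__ = [
    "PlaneDefinition",
    "PlaneMeasurement",
    "IcaProfile",
    "MeasurementConfig",
    "GeometryError",
    "define_planes",
    "extract_slab",
    "split_sides",
    "fit_side_line",
    "compute_plane_ica",
    "measure_subject",
]

N_PLANES = 5


class GeometryError(ValueError):
    """Raised when the landmark geometry rules out plane placement."""


@dataclass(frozen=True)
class PlaneDefinition:
    """One measurement plane, perpendicular to the PICS line."""

    index: int  # 1..5, anterior to posterior
    axial_position: float  # mm along the PICS axis from the pubic symphysis
    slab_halfwidth: float  # mm; voxels within +/- this of the plane belong to it


@dataclass(frozen=True)
class PlaneMeasurement:
    plane_index: int
    left_angle: float | None
    right_angle: float | None
    total_angle: float | None
    measurable: bool
    left_voxel_count: int = 0
    right_voxel_count: int = 0


@dataclass
class IcaProfile:
    """Per-subject angles for all five planes (indices 1..5, exactly once each)."""

    subject_id: str
    measurements: list[PlaneMeasurement] = field(default_factory=list)

    def __post_init__(self) -> None:
        idx = sorted(m.plane_index for m in self.measurements)
        if idx != list(range(1, N_PLANES + 1)):
            raise ValueError(f"profile needs planes 1..{N_PLANES} exactly once, got {idx}")

    def plane(self, index: int) -> PlaneMeasurement:
        for m in self.measurements:
            if m.plane_index == index:
                return m
        raise KeyError(index)


@dataclass
class MeasurementConfig:
    """Geometry knobs for :func:`measure_subject`.

    slab_halfwidth_mm
        Half-thickness of the voxel slab around each plane.  ``None`` means
        1.5x the in-plane voxel size (~0.74 mm at 0.49 mm isotropic): enough
        voxels for a stable fit without mixing adjacent planes.
    min_points
        Minimum voxels per side for a fit; fewer marks the side unmeasurable.
    plane_scheme
        ``"fifths"`` places plane k at k*D/5 (plane 5 at the spine level);
        ``"midpoints"`` at (k - 0.5)*D/5.
    fit_estimator
        ``"ols"`` — least squares of vertical on lateral (the literal
        first-degree polynomial fit); ``"principal_axis"`` — orthogonal
        (total least squares) fit via the slab's principal component.
    """

    slab_halfwidth_mm: float | None = None
    min_points: int = 10
    plane_scheme: str = "fifths"
    fit_estimator: str = "ols"

    def resolved_halfwidth(self, mask: VolumeMask) -> float:
        if self.slab_halfwidth_mm is not None:
            return float(self.slab_halfwidth_mm)
        return 1.5 * float(np.min(mask.spacing))


def define_planes(ls: LandmarkSet, frame: PicsFrame, slab_halfwidth: float,
                  scheme: str = "fifths") -> list[PlaneDefinition]:
    """Place the five measurement planes along the PICS axis.

    The span D is the axial projection of the right ischial spine; plane k
    sits at ``k*D/5`` (``"fifths"``) or ``(k-0.5)*D/5`` (``"midpoints"``).
    """
    if slab_halfwidth <= 0:
        raise ValueError("slab_halfwidth must be positive")
    D = project_onto_pics_axis(ls.ischial_spine_right, frame)
    if D <= 0:
        raise GeometryError(
            f"ischial spine not posterior to pubic symphysis along the PICS axis (D={D:.2f} mm)"
        )
    if scheme == "fifths":
        offsets = [k / N_PLANES for k in range(1, N_PLANES + 1)]
    elif scheme == "midpoints":
        offsets = [(k - 0.5) / N_PLANES for k in range(1, N_PLANES + 1)]
    else:
        raise ValueError(f"unknown plane scheme: {scheme!r}")
    return [
        PlaneDefinition(index=k, axial_position=off * D, slab_halfwidth=float(slab_halfwidth))
        for k, off in zip(range(1, N_PLANES + 1), offsets)
    ]


def extract_slab(mask: VolumeMask, frame: PicsFrame, plane: PlaneDefinition,
                 pics_points: np.ndarray | None = None) -> np.ndarray:
    """Foreground voxel centers (PICS coords) whose axial coordinate falls in
    ``[axial_position - halfwidth, axial_position + halfwidth)``.

    ``pics_points`` lets callers pass the precomputed PICS-space cloud for the
    whole mask (one transform per subject instead of one per plane).
    """
    if pics_points is None:
        pics_points = to_pics_coords(mask.foreground_world(), frame)
    pics_points = np.atleast_2d(np.asarray(pics_points, dtype=float))
    lo = plane.axial_position - plane.slab_halfwidth
    hi = plane.axial_position + plane.slab_halfwidth
    ax = pics_points[:, 1]
    return pics_points[(ax >= lo) & (ax < hi)]


def split_sides(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Partition slab points at the midsagittal plane.

    Left = lateral coordinate > 0 (subject's left), right = lateral < 0;
    points exactly on the midline are discarded.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.size == 0:
        empty = np.empty((0, 3))
        return empty, empty
    lat = pts[:, 0]
    return pts[lat > 0], pts[lat < 0]


def fit_side_line(points: np.ndarray, min_points: int = 10,
                  estimator: str = "ols") -> float | None:
    """Angle (degrees, [0, 90)) of one muscle side to the transverse plane.

    ``points`` are (lateral, vertical) mm pairs; a first-degree polynomial
    ``vertical = a*lateral + b`` is fit and ``atan(|a|)`` returned.  Returns
    ``None`` (unmeasurable) for fewer than ``min_points`` points or zero
    lateral spread.  The ``"principal_axis"`` estimator instead takes the
    slope of the cloud's first principal component, which is symmetric in the
    two coordinates.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[0] < max(int(min_points), 2):
        return None
    lat, vert = pts[:, 0], pts[:, 1]
    if np.ptp(lat) == 0.0:
        return None
    if estimator == "ols":
        slope = np.polyfit(lat, vert, 1)[0]
    elif estimator == "principal_axis":
        xy = np.column_stack([lat, vert])
        xy = xy - xy.mean(axis=0)
        _, _, vt = np.linalg.svd(xy, full_matrices=False)
        direction = vt[0]
        if direction[0] == 0.0:  # vertical principal axis: angle undefined at 90
            return None
        slope = direction[1] / direction[0]
    else:
        raise ValueError(f"unknown fit estimator: {estimator!r}")
    return math.degrees(math.atan(abs(float(slope))))


def compute_plane_ica(left_angle: float | None, right_angle: float | None,
                      plane_index: int = 0, left_count: int = 0,
                      right_count: int = 0) -> PlaneMeasurement:
    """Combine side angles into the triangle total: ``180 - left - right``.

    If either side is absent the plane is unmeasurable and the total absent.
    """
    measurable = left_angle is not None and right_angle is not None
    total = 180.0 - left_angle - right_angle if measurable else None
    return PlaneMeasurement(
        plane_index=plane_index,
        left_angle=left_angle,
        right_angle=right_angle,
        total_angle=total,
        measurable=measurable,
        left_voxel_count=left_count,
        right_voxel_count=right_count,
    )


def measure_subject(mask: VolumeMask, ls: LandmarkSet,
                    config: MeasurementConfig | None = None,
                    subject_id: str = "") -> IcaProfile:
    """Full per-subject pipeline: frame, planes, slabs, side fits, totals."""
    config = config or MeasurementConfig()
    if not mask.usable:
        raise GeometryError(f"{subject_id or 'subject'}: mask has no foreground voxels")
    try:
        frame = build_frame(ls)
        planes = define_planes(ls, frame, config.resolved_halfwidth(mask), config.plane_scheme)
    except (ValueError, GeometryError) as exc:
        raise type(exc)(f"{subject_id or 'subject'}: {exc}") from exc

    cloud = to_pics_coords(mask.foreground_world(), frame)
    measurements = []
    for plane in planes:
        slab = extract_slab(mask, frame, plane, pics_points=cloud)
        left, right = split_sides(slab)
        left_angle = fit_side_line(left[:, [0, 2]], config.min_points, config.fit_estimator)
        right_angle = fit_side_line(right[:, [0, 2]], config.min_points, config.fit_estimator)
        measurements.append(
            compute_plane_ica(
                left_angle,
                right_angle,
                plane_index=plane.index,
                left_count=len(left),
                right_count=len(right),
            )
        )
    return IcaProfile(subject_id=subject_id, measurements=measurements)
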
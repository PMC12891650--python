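"""File formats: NIfTI masks, fiducial landmarks, scores, manifests, outputs.

Conventions
-----------
* Voxel centers carry the geometry: 0-based voxel index ``i`` maps to world
  millimetres via ``affine @ (i, 1)``, the usual neuroimaging convention.
* Masks are binarized nonzero -> foreground; segmentation tools disagree on
  label values.
* Landmark files may use a different world convention (RAS vs LPS) than the
  mask affine.  ``read_landmarks(..., convention=...)`` applies the explicit
  sign flips; the default is the file's native coordinates.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .frame import LANDMARK_LABELS, LandmarkSet

__all__ = [
    "VolumeMask",
    "SideScores",
    "SubjectRecord",
    "CohortManifest",
    "FormatError",
    "GROUP_LABELS",
    "read_mask",
    "write_mask",
    "read_landmarks",
    "write_fcsv",
    "read_scores",
    "read_manifest",
    "filter_manifest",
    "write_measurements",
    "read_measurements",
]

GROUP_LABELS = ("Nulli", "Par-pre", "Par-post", "POP")

MEASUREMENT_COLUMNS = [
    "record_type",  # "measurement" | "score"
    "subject_id",
    "group",
    "plane",
    "left_ica_deg",
    "right_ica_deg",
    "total_ica_deg",
    "measurable",
    "muscle",
    "left_score",
    "right_score",
    "total_score",
    "category",
]


class FormatError(ValueError):
    """Raised for unreadable or malformed input files."""


@dataclass
class VolumeMask:
    """Binary segmentation volume with its voxel-index -> world-mm affine."""

    voxels: np.ndarray  # 3D bool
    affine: np.ndarray  # 4x4

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels).astype(bool)
        if self.voxels.ndim != 3 or self.voxels.size == 0:
            raise FormatError("mask must be a non-empty 3D array")
        self.affine = np.asarray(self.affine, dtype=float).reshape(4, 4)
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise FormatError("mask affine is singular")

    @property
    def spacing(self) -> np.ndarray:
        """Voxel size per axis, mm (column norms of the affine)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def usable(self) -> bool:
        return bool(self.voxels.any())

    @property
    def foreground_count(self) -> int:
        return int(self.voxels.sum())

    def foreground_world(self) -> np.ndarray:
        """World-mm coordinates of all foreground voxel centers, shape (n, 3)."""
        idx = np.argwhere(self.voxels)
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]


@dataclass(frozen=True)
class SideScores:
    """Expert per-side defect scores (0-3) for one muscle of one subject."""

    muscle: str  # "PCM" | "ICM"
    left: int
    right: int

    def __post_init__(self) -> None:
        if self.muscle not in ("PCM", "ICM"):
            raise ValueError(f"unknown muscle: {self.muscle!r}")
        for side, v in (("left", self.left), ("right", self.right)):
            if int(v) != v or not 0 <= int(v) <= 3:
                raise ValueError(f"{side} score must be an integer in 0..3, got {v!r}")


@dataclass
class SubjectRecord:
    subject_id: str
    group: str
    excluded: bool = False
    exclusion_reason: str = ""
    mask: str = ""
    landmarks: str = ""
    scores: str = ""


@dataclass
class CohortManifest:
    subjects: list[SubjectRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [s.subject_id for s in self.subjects]
        dup = {i for i in ids if ids.count(i) > 1}
        if dup:
            raise FormatError(f"duplicate subject_id(s): {sorted(dup)}")
        for s in self.subjects:
            if s.group not in GROUP_LABELS:
                raise FormatError(f"{s.subject_id}: unknown group {s.group!r}")
            if s.excluded and not s.exclusion_reason:
                raise FormatError(f"{s.subject_id}: excluded without a reason")


# ---------------------------------------------------------------------------
# volumes


def read_mask(path) -> VolumeMask:
    """Load a NIfTI segmentation; any nonzero voxel becomes foreground."""
    try:
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
        affine = img.affine
    except Exception as exc:  # nibabel raises several unrelated types
        raise FormatError(f"cannot read NIfTI mask {path}: {exc}") from exc
    if affine is None or not np.all(np.isfinite(affine)):
        raise FormatError(f"{path}: missing or non-finite affine")
    return VolumeMask(voxels=data != 0, affine=affine)


def write_mask(mask: VolumeMask, path) -> None:
    img = nib.Nifti1Image(mask.voxels.astype(np.uint8), mask.affine)
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# landmarks

_DEFAULT_ALIASES = {label: label for label in LANDMARK_LABELS}

_FIELD_BY_LABEL = {
    "PS": "pubic_symphysis",
    "SCJ": "sacrococcygeal_joint",
    "IS_L": "ischial_spine_left",
    "IS_R": "ischial_spine_right",
}


def _apply_convention(xyz: np.ndarray, convention: str) -> np.ndarray:
    if convention == "native":
        return xyz
    if convention in ("lps_to_ras", "ras_to_lps"):  # both negate x and y
        return xyz * np.array([-1.0, -1.0, 1.0])
    raise ValueError(f"unknown landmark convention: {convention!r}")


def _landmarks_from_rows(rows: list[tuple[str, float, float, float]], aliases, convention) -> LandmarkSet:
    found: dict[str, np.ndarray] = {}
    for label, x, y, z in rows:
        canon = aliases.get(label)
        if canon is None:
            continue  # extra, non-landmark fiducials are ignored
        if canon in found:
            raise FormatError(f"duplicate landmark: {canon}")
        found[canon] = _apply_convention(np.array([x, y, z], dtype=float), convention)
    missing = [lab for lab in LANDMARK_LABELS if lab not in found]
    if missing:
        raise FormatError("landmark missing: " + ", ".join(missing))
    return LandmarkSet(**{_FIELD_BY_LABEL[lab]: found[lab] for lab in LANDMARK_LABELS})


def _read_fcsv_rows(path) -> list[tuple[str, float, float, float]]:
    rows = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split(",")
        if len(parts) < 12:
            raise FormatError(f"{path}: malformed FCSV row: {line!r}")
        # Slicer FCSV: id,x,y,z,ow,ox,oy,oz,vis,sel,lock,label,...
        rows.append((parts[11].strip(), float(parts[1]), float(parts[2]), float(parts[3])))
    return rows


def _read_csv_rows(path, subject_id) -> list[tuple[str, float, float, float]]:
    df = pd.read_csv(path)
    required = {"label", "x_mm", "y_mm", "z_mm"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: landmark CSV needs columns {sorted(required)}")
    if subject_id is not None and "subject_id" in df.columns:
        df = df[df["subject_id"].astype(str) == str(subject_id)]
    return [
        (str(r.label), float(r.x_mm), float(r.y_mm), float(r.z_mm))
        for r in df.itertuples(index=False)
    ]


def read_landmarks(path, dialect: str = "auto", *, aliases: dict[str, str] | None = None,
                   convention: str = "native", subject_id: str | None = None) -> LandmarkSet:
    """Read the four PICS landmarks from an FCSV or plain-CSV fiducial file.

    Parameters
    ----------
    dialect
        ``"fcsv"`` (3D-Slicer fiducial table), ``"csv"``
        (``subject_id,label,x_mm,y_mm,z_mm``) or ``"auto"`` by file suffix.
    aliases
        Map from file labels to the canonical ``PS/SCJ/IS_L/IS_R``; extra
        fiducials whose label has no mapping are ignored.
    convention
        ``"native"`` keeps file coordinates; ``"lps_to_ras"``/``"ras_to_lps"``
        negate x and y to reconcile the fiducial world frame with the mask's.
    """
    amap = dict(_DEFAULT_ALIASES)
    if aliases:
        amap.update({k: v for k, v in aliases.items()})
        # user maps run file-label -> canonical
        amap = {**{label: label for label in LANDMARK_LABELS}, **aliases}
    if dialect == "auto":
        dialect = "fcsv" if str(path).lower().endswith(".fcsv") else "csv"
    if dialect == "fcsv":
        rows = _read_fcsv_rows(path)
    elif dialect == "csv":
        rows = _read_csv_rows(path, subject_id)
    else:
        raise ValueError(f"unknown landmark dialect: {dialect!r}")
    return _landmarks_from_rows(rows, amap, convention)


def write_fcsv(ls: LandmarkSet, path) -> None:
    """Write the four landmarks as a 3D-Slicer fiducial table."""
    pts = {
        "PS": ls.pubic_symphysis,
        "SCJ": ls.sacrococcygeal_joint,
        "IS_L": ls.ischial_spine_left,
        "IS_R": ls.ischial_spine_right,
    }
    lines = [
        "# Markups fiducial file version = 4.11",
        "# CoordinateSystem = RAS",
        "# columns = id,x,y,z,ow,ox,oy,oz,vis,sel,lock,label,desc,associatedNodeID",
    ]
    for i, (label, p) in enumerate(pts.items(), start=1):
        lines.append(
            f"vtkMRMLMarkupsFiducialNode_{i},{p[0]:.6f},{p[1]:.6f},{p[2]:.6f},"
            f"0,0,0,1,1,1,0,{label},,"
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# scores


def read_scores(path) -> dict[tuple[str, str], SideScores]:
    """Read per-subject per-muscle side scores from CSV.

    Expected columns: ``subject_id,muscle,left,right``.  Returns a mapping
    ``(subject_id, muscle) -> SideScores``.
    """
    df = pd.read_csv(path)
    required = {"subject_id", "muscle", "left", "right"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: score CSV needs columns {sorted(required)}")
    out: dict[tuple[str, str], SideScores] = {}
    for r in df.itertuples(index=False):
        key = (str(r.subject_id), str(r.muscle))
        if key in out:
            raise FormatError(f"{path}: duplicate score row for {key}")
        out[key] = SideScores(muscle=str(r.muscle), left=int(r.left), right=int(r.right))
    return out


# ---------------------------------------------------------------------------
# manifest


def read_manifest(path) -> CohortManifest:
    """Load a YAML or JSON cohort manifest (``subjects:`` list of records)."""
    text = Path(path).read_text()
    data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    if not isinstance(data, dict) or "subjects" not in data:
        raise FormatError(f"{path}: manifest must contain a 'subjects' list")
    subjects = [
        SubjectRecord(
            subject_id=str(rec["subject_id"]),
            group=str(rec["group"]),
            excluded=bool(rec.get("excluded", False)),
            exclusion_reason=str(rec.get("exclusion_reason", "") or ""),
            mask=str(rec.get("mask", "") or ""),
            landmarks=str(rec.get("landmarks", "") or ""),
            scores=str(rec.get("scores", "") or ""),
        )
        for rec in data["subjects"]
    ]
    return CohortManifest(subjects=subjects)


def filter_manifest(m: CohortManifest):
    """Apply the study exclusion flags.

    Returns ``(included, tally, group_counts)`` where *included* is the list of
    non-excluded subjects, *tally* counts excluded subjects by reason and
    *group_counts* gives included subjects per group.  Conservation:
    ``len(included) + sum(tally.values()) == len(m.subjects)``.
    """
    included = [s for s in m.subjects if not s.excluded]
    tally = Counter(s.exclusion_reason for s in m.subjects if s.excluded)
    group_counts = Counter(s.group for s in included)
    return included, dict(tally), dict(group_counts)


# ---------------------------------------------------------------------------
# measurement table


def write_measurements(profiles, categories, path, groups: dict[str, str] | None = None) -> None:
    """Write the combined per-plane measurement / per-muscle score table.

    One ``measurement`` row per subject per plane (angles blank and
    ``measurable=False`` where a plane could not be measured) and one
    ``score`` row per subject per scored muscle.

    Parameters
    ----------
    profiles
        Iterable of :class:`~levator_ica.measure.IcaProfile`.
    categories
        Mapping ``(subject_id, muscle) -> DefectCategory`` (may be empty).
    groups
        Optional ``subject_id -> group`` map for the group column.
    """
    groups = groups or {}
    rows = []
    for prof in profiles:
        for m in prof.measurements:
            rows.append(
                {
                    "record_type": "measurement",
                    "subject_id": prof.subject_id,
                    "group": groups.get(prof.subject_id, ""),
                    "plane": m.plane_index,
                    "left_ica_deg": m.left_angle,
                    "right_ica_deg": m.right_angle,
                    "total_ica_deg": m.total_angle,
                    "measurable": m.measurable,
                    "muscle": "",
                    "left_score": "",
                    "right_score": "",
                    "total_score": "",
                    "category": "",
                }
            )
    for (sid, muscle), cat in sorted(categories.items()):
        rows.append(
            {
                "record_type": "score",
                "subject_id": sid,
                "group": groups.get(sid, ""),
                "plane": "",
                "left_ica_deg": "",
                "right_ica_deg": "",
                "total_ica_deg": "",
                "measurable": "",
                "muscle": muscle,
                "left_score": cat.left,
                "right_score": cat.right,
                "total_score": cat.total,
                "category": cat.category,
            }
        )
    pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS).to_csv(path, index=False)


def read_measurements(path) -> pd.DataFrame:
    """Read a table written by :func:`write_measurements`."""
    df = pd.read_csv(path, dtype={"subject_id": str})
    missing = set(MEASUREMENT_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing measurement columns {sorted(missing)}")
    return df
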
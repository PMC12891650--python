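"""Synthetic levator-ani phantoms and cohort simulation.

No public imaging data exists for this measurement, so validation rests on
two synthetic stand-ins:

* **Voxel phantoms** — two planar muscle sheets descending from lateral
  attachments toward the midline at prescribed per-plane angles, voxelized at
  MR resolution (0.49 mm isotropic by default), with landmarks placed
  analytically in the construction frame.  Ground truth is exact:
  total = 180 - left - right of the prescribed angles.  Optional anterior
  avulsion gaps and boundary-voxel noise emulate the failure modes seen in
  real segmentations.
* **Cohort draws** — per-group per-plane total angles from truncated normal
  distributions and defect categories from categorical distributions, with
  defaults set to the published group means/SDs and prevalence fractions of
  the four study groups (nulliparous, parous pre/post-menopausal, prolapse).

All randomness flows through explicit integer seeds.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy import stats as sps

from .frame import LandmarkSet
from .io import SideScores, VolumeMask
from .measure import IcaProfile, PlaneMeasurement, compute_plane_ica
from .scoring import CATEGORIES, categorize

__all__ = [
    "PhantomSpec",
    "GroupSimSpec",
    "CohortSimSpec",
    "generate_phantom",
    "add_noise",
    "simulate_cohort",
    "transform_scene",
    "default_cohort_spec",
    "RESULTS_PLANE4",
]

N_PLANES = 5

#: plane-4 total-ICA parameters per group: (mean deg, SD deg, n) as published
RESULTS_PLANE4 = {
    "Nulli": (95.2, 14.6, 14),
    "Par-pre": (78.6, 21.3, 13),
    "Par-post": (79.7, 19.3, 12),
    "POP": (53.4, 11.9, 16),
}

#: per-group per-plane (mean, SD) of total ICA, planes 2-5, as published;
#: plane 1 was excluded from the study's analysis and has no printed value
_COHORT_ICA = {
    "Nulli": {2: (65.7, 14.7), 3: (77.8, 12.4), 4: (95.2, 14.6), 5: (103.0, 14.6)},
    "Par-pre": {2: (61.0, 16.0), 3: (68.5, 14.7), 4: (78.6, 21.3), 5: (88.0, 23.0)},
    "Par-post": {2: (52.0, 16.0), 3: (67.2, 7.6), 4: (79.7, 19.3), 5: (88.0, 22.0)},
    "POP": {2: (49.0, 13.7), 3: (48.3, 10.2), 4: (53.4, 11.9), 5: (70.0, 16.0)},
}

#: defect-category probabilities (none, minor, major) from the published counts
_COHORT_DEFECTS = {
    "Nulli": {"PCM": (1.0, 0.0, 0.0), "ICM": (11 / 14, 3 / 14, 0.0)},
    "Par-pre": {"PCM": (6 / 13, 6 / 13, 1 / 13), "ICM": (5 / 13, 8 / 13, 0.0)},
    "Par-post": {"PCM": (2 / 12, 8 / 12, 2 / 12), "ICM": (4 / 12, 8 / 12, 0.0)},
    "POP": {"PCM": (2 / 16, 3 / 16, 11 / 16), "ICM": (0.0, 9 / 16, 7 / 16)},
}

_COHORT_N = {"Nulli": 14, "Par-pre": 13, "Par-post": 12, "POP": 16}


@dataclass
class PhantomSpec:
    """Parametric ground truth for one synthetic muscle.

    ``left_angles``/``right_angles`` prescribe the sheet inclination (degrees,
    [0, 85]) at each of the five plane positions; between planes the angle is
    linearly interpolated.  ``avulsion`` is ``(side, extent_mm)``: the named
    sheet is removed for axial coordinates <= extent, emulating detachment
    from the pubic bone.
    """

    left_angles: tuple = (45.0,) * N_PLANES
    right_angles: tuple = (45.0,) * N_PLANES
    sheet_halfwidth_mm: float = 25.0
    sheet_thickness_mm: float = 2.5
    axial_extent_mm: float = 80.0
    voxel_mm: float = 0.49
    avulsion: tuple | None = None  # (side "left"|"right", extent mm)
    noise_flip_prob: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        for name, angles in (("left_angles", self.left_angles), ("right_angles", self.right_angles)):
            a = np.asarray(angles, dtype=float)
            if a.shape != (N_PLANES,):
                raise ValueError(f"{name} must have {N_PLANES} entries")
            if np.any(a < 0) or np.any(a > 85):
                raise ValueError(f"{name} must lie in [0, 85] degrees")
        if self.sheet_thickness_mm < self.voxel_mm:
            raise ValueError("sheet thickness must be >= voxel size")
        if not 0.0 <= self.noise_flip_prob <= 1.0:
            raise ValueError("noise_flip_prob must be in [0, 1]")
        if self.avulsion is not None and self.avulsion[0] not in ("left", "right"):
            raise ValueError("avulsion side must be 'left' or 'right'")


def generate_phantom(spec: PhantomSpec) -> tuple[VolumeMask, LandmarkSet, IcaProfile]:
    """Voxelize the two-sheet phantom and place consistent landmarks.

    The construction frame doubles as the world frame: x lateral (positive =
    subject's left), y along the pubis-to-spine axis, z vertical.  Each sheet
    is the set of voxel centers with ``|z - tan(angle(y)) * |x|| <= t/2`` over
    lateral extent ``|x| <= halfwidth`` and axial extent ``0 <= y <= D``.
    Landmarks: pubic symphysis at the origin, sacrococcygeal joint further
    along +y, ischial spines lateral at axial position D — so the PICS axis
    is +y, the lateral axis +x, and the plane span D is exact.
    """
    spec.validate()
    s = float(spec.voxel_mm)
    hw = float(spec.sheet_halfwidth_mm)
    D = float(spec.axial_extent_mm)
    t = float(spec.sheet_thickness_mm)
    pad = 3.0 * s

    # voxel centers; lateral centers at +/-(j+1/2)s so none sits on the midline
    mx = int(math.ceil((hw + pad) / s))
    xs = (np.arange(2 * mx) - mx + 0.5) * s
    ny = int(math.ceil((D + 2 * pad) / s))
    ys = np.arange(ny) * s + (s / 2 - pad)
    max_tan = math.tan(math.radians(float(np.max([spec.left_angles, spec.right_angles]))))
    zmax = max_tan * hw + t
    nz = int(math.ceil((zmax + t + pad) / s))
    zs = np.arange(nz) * s + (s / 2 - t)

    plane_pos = np.arange(1, N_PLANES + 1) * D / N_PLANES
    tan_left = np.tan(np.radians(np.interp(ys, plane_pos, spec.left_angles)))
    tan_right = np.tan(np.radians(np.interp(ys, plane_pos, spec.right_angles)))

    X = xs[:, None]  # (nx, 1)
    slope = np.where(X > 0, tan_left[None, :], tan_right[None, :])  # (nx, ny)
    height = np.abs(X) * slope
    in_sheet_xy = (np.abs(X) <= hw) & (ys[None, :] >= 0.0) & (ys[None, :] <= D)
    voxels = np.abs(zs[None, None, :] - height[:, :, None]) <= t / 2
    voxels &= in_sheet_xy[:, :, None]

    if spec.avulsion is not None:
        side, extent = spec.avulsion
        on_side = xs > 0 if side == "left" else xs < 0
        voxels[np.ix_(on_side, ys <= float(extent))] = False

    if not voxels.any():
        raise ValueError("phantom spec produced an empty mask")

    affine = np.diag([s, s, s, 1.0])
    affine[:3, 3] = [xs[0], ys[0], zs[0]]
    mask = VolumeMask(voxels=voxels, affine=affine)

    if spec.noise_flip_prob > 0.0:
        mask = add_noise(mask, spec.noise_flip_prob, spec.seed)

    landmarks = LandmarkSet(
        pubic_symphysis=(0.0, 0.0, 0.0),
        sacrococcygeal_joint=(0.0, D + 30.0, 0.0),
        ischial_spine_left=(hw + 10.0, D, 0.0),
        ischial_spine_right=(-(hw + 10.0), D, 0.0),
    )

    truth = IcaProfile(
        subject_id="phantom",
        measurements=[
            compute_plane_ica(float(l), float(r), plane_index=k)
            for k, l, r in zip(range(1, N_PLANES + 1), spec.left_angles, spec.right_angles)
        ],
    )
    return mask, landmarks, truth


def add_noise(mask: VolumeMask, flip_prob: float, seed: int) -> VolumeMask:
    """Flip boundary voxels independently with probability ``flip_prob``.

    Boundary = foreground voxels with a background 6-neighbour, and background
    voxels with a foreground 6-neighbour.  Deterministic given the seed.
    """
    if not 0.0 <= flip_prob <= 1.0:
        raise ValueError("flip_prob must be in [0, 1]")
    if flip_prob == 0.0:
        return VolumeMask(voxels=mask.voxels.copy(), affine=mask.affine.copy())
    structure = ndimage.generate_binary_structure(3, 1)
    fg = mask.voxels
    boundary = (fg & ~ndimage.binary_erosion(fg, structure)) | (
        ~fg & ndimage.binary_dilation(fg, structure)
    )
    rng = np.random.default_rng(seed)
    flips = boundary & (rng.random(fg.shape) < flip_prob)
    return VolumeMask(voxels=fg ^ flips, affine=mask.affine.copy())


def transform_scene(mask: VolumeMask, ls: LandmarkSet, rotation, translation=(0.0, 0.0, 0.0)):
    """Apply one rigid transform jointly to mask affine and landmarks."""
    R = np.asarray(rotation, dtype=float).reshape(3, 3)
    t = np.asarray(translation, dtype=float).reshape(3)
    M = np.eye(4)
    M[:3, :3] = R
    M[:3, 3] = t
    return VolumeMask(voxels=mask.voxels, affine=M @ mask.affine), ls.transformed(R, t)


# ---------------------------------------------------------------------------
# cohort simulation


@dataclass
class GroupSimSpec:
    """One group's generating parameters: sample size, per-plane total-ICA
    normal parameters, and (none, minor, major) probabilities per muscle."""

    n: int
    ica: dict  # plane -> (mean deg, sd deg)
    defects: dict  # muscle -> (p_none, p_minor, p_major)

    def validate(self) -> None:
        if self.n < 1:
            raise ValueError("group n must be >= 1")
        for plane, (mean, sd) in self.ica.items():
            if sd <= 0:
                raise ValueError(f"plane {plane}: SD must be > 0")
        for muscle, probs in self.defects.items():
            if abs(sum(probs) - 1.0) > 1e-9:
                raise ValueError(f"{muscle}: category probabilities must sum to 1")


@dataclass
class CohortSimSpec:
    groups: dict = field(default_factory=dict)  # group label -> GroupSimSpec
    seed: int = 0

    def validate(self) -> None:
        for g in self.groups.values():
            g.validate()


def default_cohort_spec(seed: int = 0) -> CohortSimSpec:
    """The published study conditions: group sizes, per-plane total-ICA
    means/SDs (planes 2-5) and defect-category prevalences."""
    groups = {
        g: GroupSimSpec(n=_COHORT_N[g], ica=dict(_COHORT_ICA[g]), defects=dict(_COHORT_DEFECTS[g]))
        for g in _COHORT_N
    }
    return CohortSimSpec(groups=groups, seed=seed)


def _pairs_for_category(muscle: str, category: str) -> list[tuple[int, int]]:
    return [
        (l, r)
        for l, r in itertools.product(range(4), repeat=2)
        if categorize(SideScores(muscle, l, r)).category == category
    ]


def simulate_cohort(spec: CohortSimSpec | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a synthetic cohort from the group-level generating distributions.

    Total angles come from normals truncated to (0, 180); defect categories
    from the categorical prevalences, with side scores drawn uniformly over
    the pairs compatible with the category so that score aggregation can be
    round-tripped.

    Returns
    -------
    (ica, scores)
        ``ica``: subject_id, group, plane, total_ica_deg (long format).
        ``scores``: subject_id, group, muscle, left, right, category.
    """
    spec = spec or default_cohort_spec()
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    ica_rows, score_rows = [], []
    for group in sorted(spec.groups):
        gspec = spec.groups[group]
        for i in range(gspec.n):
            sid = f"{group}-{i + 1:03d}"
            for plane in sorted(gspec.ica):
                mean, sd = gspec.ica[plane]
                a, b = (0.0 - mean) / sd, (180.0 - mean) / sd
                val = float(sps.truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))
                ica_rows.append(
                    {"subject_id": sid, "group": group, "plane": plane, "total_ica_deg": val}
                )
            for muscle in sorted(gspec.defects):
                probs = gspec.defects[muscle]
                category = CATEGORIES[int(rng.choice(3, p=probs))]
                pairs = _pairs_for_category(muscle, category)
                l, r = pairs[int(rng.integers(len(pairs)))]
                score_rows.append(
                    {"subject_id": sid, "group": group, "muscle": muscle,
                     "left": l, "right": r, "category": category}
                )
    return pd.DataFrame(ica_rows), pd.DataFrame(score_rows)
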
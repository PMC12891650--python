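"""Aggregation of expert per-side defect scores for PCM and ICM.

Each muscle side gets an ordinal severity score 0-3.  The total is the sum of
the two sides and is categorized as none (0), minor (1-3) or major (4-6);
any single side scoring 3 forces the major category regardless of the total.
For the iliococcygeus a side score of 3 denotes a hernia, which is flagged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .io import SideScores

__all__ = [
    "DefectCategory",
    "CATEGORIES",
    "categorize",
    "prevalence_table",
    "round_half_away",
]

CATEGORIES = ("none", "minor", "major")


@dataclass(frozen=True)
class DefectCategory:
    muscle: str
    left: int
    right: int
    total: int
    category: str
    hernia_flag: bool


def categorize(s: SideScores) -> DefectCategory:
    """Map side scores to total and none/minor/major category.

    The side-3 override: a maximal unilateral score is always major damage
    (a hernia when the muscle is the ICM), even when left + right <= 3.
    """
    total = s.left + s.right
    if s.left == 3 or s.right == 3:
        category = "major"
    elif total == 0:
        category = "none"
    elif total <= 3:
        category = "minor"
    else:
        category = "major"
    hernia = s.muscle == "ICM" and (s.left == 3 or s.right == 3)
    return DefectCategory(
        muscle=s.muscle, left=s.left, right=s.right,
        total=total, category=category, hernia_flag=hernia,
    )


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (0.05 -> 0.1), unlike banker's rounding."""
    scale = 10.0 ** ndigits
    return math.copysign(math.floor(abs(x) * scale + 0.5), x) / scale


def prevalence_table(groups: dict[str, str],
                     categories: dict[tuple[str, str], DefectCategory]):
    """Per-group defect-category prevalence for each muscle.

    Parameters
    ----------
    groups
        ``subject_id -> group`` for every included subject.
    categories
        ``(subject_id, muscle) -> DefectCategory``.

    Returns
    -------
    (table, unscored)
        *table* is a DataFrame with columns
        ``group, muscle, category, count, percent`` where percent is
        100*count/(scored subjects in the group), rounded half away from zero
        to one decimal.  *unscored* lists ``(subject_id, muscle)`` pairs with
        no score; they are excluded from the percentages.
    """
    muscles = sorted({m for (_, m) in categories}) or ["PCM", "ICM"]
    rows = []
    unscored: list[tuple[str, str]] = []
    group_order = sorted(set(groups.values()))
    for muscle in muscles:
        for group in group_order:
            sids = [s for s, g in groups.items() if g == group]
            scored = [s for s in sids if (s, muscle) in categories]
            unscored.extend((s, muscle) for s in sids if (s, muscle) not in categories)
            n = len(scored)
            for cat in CATEGORIES:
                count = sum(1 for s in scored if categories[(s, muscle)].category == cat)
                percent = round_half_away(100.0 * count / n, 1) if n else 0.0
                rows.append(
                    {"group": group, "muscle": muscle, "category": cat,
                     "count": count, "percent": percent}
                )
    return pd.DataFrame(rows), unscored
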
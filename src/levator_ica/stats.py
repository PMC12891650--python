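"""Cohort inference on per-plane total ICA.

Per plane: Shapiro-Wilk normality per group (reported, never gating), one-way
fixed-effects ANOVA across the four groups, and Bonferroni-adjusted pairwise
two-sample t tests (raw p times the number of pairs, capped at 1).  A plane
where the angle could not be measured for more subjects than a threshold
(default: any) is omitted from inference — in practice the most anterior
plane, where avulsion gaps live.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "PairwiseComparison",
    "ComparisonResult",
    "apply_plane_exclusion",
    "shapiro_per_group",
    "anova_oneway",
    "bonferroni_pairwise",
    "compare_groups",
    "summarize_groups",
]


@dataclass(frozen=True)
class PairwiseComparison:
    group_a: str
    group_b: str
    raw_p: float | None
    adjusted_p: float | None
    significant: bool
    testable: bool = True


@dataclass
class ComparisonResult:
    plane_index: int
    anova_F: float
    anova_p: float
    pairwise: list[PairwiseComparison] = field(default_factory=list)


def apply_plane_exclusion(profiles, threshold: int = 0):
    """Planes eligible for inference, given per-subject measurability.

    A plane is excluded when the number of subjects with an unmeasurable
    angle there exceeds ``threshold`` (default 0: any missing subject
    excludes the plane).

    Returns ``(eligible, missing_counts)`` with ``eligible`` a sorted list of
    plane indices and ``missing_counts`` a dict plane -> unmeasurable count.
    """
    profiles = list(profiles)
    missing = {k: 0 for k in range(1, 6)}
    for prof in profiles:
        for m in prof.measurements:
            if not m.measurable:
                missing[m.plane_index] += 1
    eligible = sorted(k for k, n in missing.items() if n <= threshold)
    return eligible, missing


def shapiro_per_group(values_by_group: dict[str, np.ndarray]):
    """Shapiro-Wilk W and p per group; constant samples flagged untestable.

    Normality is reported alongside the ANOVA, not used to gate it.
    """
    out: dict[str, dict] = {}
    for group, vals in values_by_group.items():
        v = np.asarray(vals, dtype=float)
        if v.size < 3 or np.ptp(v) == 0.0:
            out[group] = {"W": None, "p": None, "testable": False}
        else:
            W, p = sps.shapiro(v)
            out[group] = {"W": float(W), "p": float(p), "testable": True}
    return out


def anova_oneway(values_by_group: dict[str, np.ndarray]) -> tuple[float, float]:
    """Classical one-way fixed-effects ANOVA: returns (F, p).

    Degenerate all-identical data yields F=0, p=1 rather than NaN.
    """
    samples = [np.asarray(v, dtype=float) for v in values_by_group.values()]
    if len(samples) < 2 or any(len(s) < 2 for s in samples):
        raise ValueError("ANOVA needs >= 2 groups with n >= 2 each")
    pooled = np.concatenate(samples)
    if np.ptp(pooled) == 0.0:
        return 0.0, 1.0
    F, p = sps.f_oneway(*samples)
    return float(F), float(p)


def bonferroni_pairwise(values_by_group: dict[str, np.ndarray], alpha: float = 0.05,
                        welch: bool = False) -> list[PairwiseComparison]:
    """All pairwise two-sample t tests with Bonferroni adjustment.

    Raw p is multiplied by the number of pairs (6 for four groups) and capped
    at 1.  Pooled-variance t by default; ``welch=True`` drops the equal
    variance assumption.  Pairs with a group of n < 2 are untestable.
    """
    groups = list(values_by_group)
    n_pairs = len(groups) * (len(groups) - 1) // 2
    out = []
    for a, b in itertools.combinations(groups, 2):
        va = np.asarray(values_by_group[a], dtype=float)
        vb = np.asarray(values_by_group[b], dtype=float)
        if len(va) < 2 or len(vb) < 2:
            out.append(PairwiseComparison(a, b, None, None, False, testable=False))
            continue
        if np.ptp(np.concatenate([va, vb])) == 0.0:
            raw = 1.0
        else:
            raw = float(sps.ttest_ind(va, vb, equal_var=not welch).pvalue)
        adj = min(1.0, n_pairs * raw)
        out.append(PairwiseComparison(a, b, raw, adj, adj < alpha))
    return out


def compare_groups(values_by_group: dict[str, np.ndarray], plane_index: int,
                   alpha: float = 0.05, welch: bool = False) -> ComparisonResult:
    F, p = anova_oneway(values_by_group)
    pairwise = bonferroni_pairwise(values_by_group, alpha=alpha, welch=welch)
    return ComparisonResult(plane_index=plane_index, anova_F=F, anova_p=p, pairwise=pairwise)


def summarize_groups(profiles, groups: dict[str, str]) -> pd.DataFrame:
    """Per-plane per-group descriptive table over measurable values only.

    Columns: plane, group, n, mean_total, sd_total, mean_left, mean_right,
    plus a ``single_subject`` flag where SD (reported as 0) is based on n=1.
    Values are kept at full precision; integer rounding for presentation is a
    display concern, not done here.
    """
    rows = []
    group_order = sorted(set(groups.values()))
    by_group: dict[tuple[int, str], list] = {}
    for prof in profiles:
        g = groups.get(prof.subject_id)
        if g is None:
            continue
        for m in prof.measurements:
            if m.measurable:
                by_group.setdefault((m.plane_index, g), []).append(
                    (m.total_angle, m.left_angle, m.right_angle)
                )
    for plane in range(1, 6):
        for g in group_order:
            vals = by_group.get((plane, g), [])
            n = len(vals)
            if n == 0:
                rows.append({"plane": plane, "group": g, "n": 0, "mean_total": None,
                             "sd_total": None, "mean_left": None, "mean_right": None,
                             "single_subject": False})
                continue
            arr = np.asarray(vals, dtype=float)
            rows.append(
                {
                    "plane": plane,
                    "group": g,
                    "n": n,
                    "mean_total": float(arr[:, 0].mean()),
                    "sd_total": float(arr[:, 0].std(ddof=1)) if n > 1 else 0.0,
                    "mean_left": float(arr[:, 1].mean()),
                    "mean_right": float(arr[:, 2].mean()),
                    "single_subject": n == 1,
                }
            )
    return pd.DataFrame(rows)
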
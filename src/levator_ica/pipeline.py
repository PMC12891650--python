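"""End-to-end cohort run: manifest -> measurement -> scoring -> statistics.

Subject-level failures (unreadable mask, degenerate landmarks) are logged and
the subject skipped; the run aborts only on configuration or manifest errors,
mirroring how a cohort study excludes individual subjects rather than
discarding the dataset.  Identical inputs and seed produce byte-identical
outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .io import (
    CohortManifest,
    filter_manifest,
    read_landmarks,
    read_manifest,
    read_mask,
    read_measurements,
    read_scores,
    write_measurements,
)
from .measure import (
    IcaProfile,
    MeasurementConfig,
    compute_plane_ica,
    measure_subject,
)
from .scoring import categorize, prevalence_table
from .stats import apply_plane_exclusion, compare_groups, shapiro_per_group, summarize_groups

__all__ = ["RunConfig", "run_pipeline", "profiles_from_table", "run_stats"]


@dataclass
class RunConfig:
    """Configuration for one cohort run."""

    manifest: str
    out_dir: str
    measurement: MeasurementConfig = field(default_factory=MeasurementConfig)
    landmark_convention: str = "native"
    alpha: float = 0.05
    exclusion_threshold: int = 0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        meas = MeasurementConfig(**data.pop("measurement", {}))
        return cls(measurement=meas, **data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def profiles_from_table(df: pd.DataFrame) -> tuple[list[IcaProfile], dict[str, str]]:
    """Rebuild per-subject profiles and the subject->group map from the
    measurement table written by :func:`levator_ica.io.write_measurements`."""
    meas = df[df["record_type"] == "measurement"]
    profiles = []
    groups: dict[str, str] = {}
    for sid, sub in meas.groupby("subject_id", sort=True):
        measurements = []
        for row in sub.itertuples(index=False):
            left = None if pd.isna(row.left_ica_deg) else float(row.left_ica_deg)
            right = None if pd.isna(row.right_ica_deg) else float(row.right_ica_deg)
            measurements.append(compute_plane_ica(left, right, plane_index=int(row.plane)))
        profiles.append(IcaProfile(subject_id=str(sid), measurements=measurements))
        g = sub["group"].iloc[0]
        groups[str(sid)] = "" if pd.isna(g) else str(g)
    return profiles, groups


def run_stats(profiles, groups, alpha: float = 0.05, exclusion_threshold: int = 0):
    """Inference stage shared by the CLI ``stats`` command and ``run``.

    Returns ``(summary, comparisons, shapiro, eligible, missing)``:
    descriptive per-plane table, long-format test results, per-plane
    per-group normality checks, the planes eligible after the missingness
    rule, and the per-plane unmeasurable counts.
    """
    summary = summarize_groups(profiles, groups)
    eligible, missing = apply_plane_exclusion(profiles, threshold=exclusion_threshold)

    comp_rows, shapiro_rows = [], []
    for plane in eligible:
        values_by_group: dict[str, list[float]] = {}
        for prof in profiles:
            g = groups.get(prof.subject_id)
            m = prof.plane(plane)
            if g and m.measurable:
                values_by_group.setdefault(g, []).append(m.total_angle)
        values_by_group = {g: v for g, v in sorted(values_by_group.items()) if len(v) >= 2}
        if len(values_by_group) < 2:
            continue
        for g, res in shapiro_per_group(values_by_group).items():
            shapiro_rows.append({"plane": plane, "group": g, **res})
        result = compare_groups(values_by_group, plane_index=plane, alpha=alpha)
        for pw in result.pairwise:
            comp_rows.append(
                {
                    "plane": plane,
                    "anova_F": result.anova_F,
                    "anova_p": result.anova_p,
                    "group_a": pw.group_a,
                    "group_b": pw.group_b,
                    "raw_p": pw.raw_p,
                    "adjusted_p": pw.adjusted_p,
                    "significant": pw.significant,
                    "testable": pw.testable,
                }
            )
    comparisons = pd.DataFrame(
        comp_rows,
        columns=["plane", "anova_F", "anova_p", "group_a", "group_b",
                 "raw_p", "adjusted_p", "significant", "testable"],
    )
    shapiro = pd.DataFrame(shapiro_rows, columns=["plane", "group", "W", "p", "testable"])
    return summary, comparisons, shapiro, eligible, missing


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full cohort pipeline; returns a report dict with output
    paths, per-subject status and the inference products."""
    manifest_path = Path(cfg.manifest)
    manifest: CohortManifest = read_manifest(manifest_path)
    if not manifest.subjects:
        raise ValueError(f"{cfg.manifest}: manifest lists no subjects")
    base = manifest_path.parent
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    included, tally, group_counts = filter_manifest(manifest)
    log_records: list[dict] = [
        {"event": "start", "config_hash": cfg.digest(), "version": __version__,
         "seed": cfg.seed, "n_manifest": len(manifest.subjects),
         "n_included": len(included), "excluded_tally": tally,
         "group_counts": group_counts}
    ]

    profiles, failed = [], []
    groups: dict[str, str] = {}
    score_cache: dict[str, dict] = {}
    categories = {}
    for rec in sorted(included, key=lambda r: r.subject_id):
        try:
            mask = read_mask(base / rec.mask)
            ls = read_landmarks(base / rec.landmarks, convention=cfg.landmark_convention,
                                subject_id=rec.subject_id)
            prof = measure_subject(mask, ls, cfg.measurement, subject_id=rec.subject_id)
        except Exception as exc:
            failed.append(rec.subject_id)
            log_records.append({"event": "subject_failed", "subject_id": rec.subject_id,
                                "reason": str(exc)})
            continue
        profiles.append(prof)
        groups[rec.subject_id] = rec.group
        n_unmeasurable = sum(1 for m in prof.measurements if not m.measurable)
        if n_unmeasurable:
            log_records.append({"event": "unmeasurable_planes",
                                "subject_id": rec.subject_id, "count": n_unmeasurable})
        if rec.scores:
            key = str(base / rec.scores)
            if key not in score_cache:
                score_cache[key] = read_scores(key)
            for (sid, muscle), ss in score_cache[key].items():
                if sid == rec.subject_id:
                    categories[(sid, muscle)] = categorize(ss)

    measurements_csv = out / "measurements.csv"
    write_measurements(profiles, categories, measurements_csv, groups)

    prevalence, unscored = prevalence_table(groups, categories) if categories else (
        pd.DataFrame(columns=["group", "muscle", "category", "count", "percent"]), [])
    prevalence_csv = out / "prevalence.csv"
    prevalence.to_csv(prevalence_csv, index=False)

    summary, comparisons, shapiro, eligible, missing = run_stats(
        profiles, groups, alpha=cfg.alpha, exclusion_threshold=cfg.exclusion_threshold
    )
    summary_csv = out / "plane_summary.csv"
    comparisons_csv = out / "comparisons.csv"
    shapiro_csv = out / "shapiro.csv"
    summary.to_csv(summary_csv, index=False)
    comparisons.to_csv(comparisons_csv, index=False)
    shapiro.to_csv(shapiro_csv, index=False)

    log_records.append({"event": "inference", "eligible_planes": eligible,
                        "missing_counts": missing,
                        "unscored": [list(u) for u in unscored]})
    log_records.append({"event": "done", "n_measured": len(profiles),
                        "n_failed": len(failed)})
    log_path = out / "run_log.jsonl"
    log_path.write_text("\n".join(json.dumps(r, sort_keys=True) for r in log_records) + "\n")

    return {
        "measurements_csv": str(measurements_csv),
        "prevalence_csv": str(prevalence_csv),
        "plane_summary_csv": str(summary_csv),
        "comparisons_csv": str(comparisons_csv),
        "shapiro_csv": str(shapiro_csv),
        "log": str(log_path),
        "included": [r.subject_id for r in included],
        "failed": failed,
        "eligible_planes": eligible,
        "summary": summary,
        "comparisons": comparisons,
    }
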
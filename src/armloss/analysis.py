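"""Prognostic cut-off sweep, survival stratification, and the grade-1 co-loss rule.

The headline procedures: (1) sweep candidate loss-percentage cut-offs and
score each, per cohort, by Harrell's c-index of the dichotomized loss call;
(2) stratify recurrence-free survival into loss vs no-loss groups at a
chosen cut-off with Kaplan-Meier curves, a log-rank test, and the median
difference; (3) within CNS WHO grade 1 tumors, compare concurrent 1p and
22q loss (both arms above the cut-off) against cases with no or a single
loss.

The c-index is computed per cohort separately, never pooled: validation
cohorts are independent.  The same cut-off is applied to both arms in the
co-loss rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from armloss.metrics import ArmProfile, apply_cutoff, profiles_to_frame
from armloss.segio import SubjectRecord, clinical_to_frame
from armloss.survival import (
    KmCurve,
    LogrankResult,
    harrell_cindex,
    km_fit,
    km_median_difference,
    logrank_test,
)

__all__ = [
    "SweepResult",
    "StratifiedAnalysis",
    "sweep_cutoffs",
    "stratify_by_cutoff",
    "grade1_co_loss_analysis",
]

DEFAULT_CUTOFF_GRID = tuple(range(0, 31))  # integer percents, covers the debated 5-30% range


def _profiles_frame(profiles) -> pd.DataFrame:
    if isinstance(profiles, pd.DataFrame):
        df = profiles
    else:
        df = profiles_to_frame(list(profiles))
    required = {"sample_id", "loss_percent"}
    missing = sorted(required - set(df.columns))
    if missing:
        raise ValueError(f"profiles table missing column(s) {missing}")
    return df


def _clinical_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        df = clinical_to_frame(list(records))
    required = {"sample_id", "time", "event"}
    missing = sorted(required - set(df.columns))
    if missing:
        raise ValueError(f"clinical table missing column(s) {missing}")
    return df


def _join(profiles_df: pd.DataFrame, clinical_df: pd.DataFrame) -> pd.DataFrame:
    prof_ids = set(profiles_df["sample_id"])
    clin_ids = set(clinical_df["sample_id"])
    missing_prof = sorted(clin_ids - prof_ids)
    missing_clin = sorted(prof_ids - clin_ids)
    if missing_prof or missing_clin:
        raise ValueError(
            "profiles/clinical join failure; samples without profiles: "
            f"{missing_prof[:10]}{'...' if len(missing_prof) > 10 else ''}; "
            f"samples without clinical rows: {missing_clin[:10]}{'...' if len(missing_clin) > 10 else ''}"
        )
    merged = clinical_df.merge(
        profiles_df[["sample_id", "loss_percent"]], on="sample_id", how="inner"
    )
    if "cohort" not in merged.columns:
        merged["cohort"] = "unspecified"
    return merged


@dataclass
class SweepResult:
    """Cut-off -> per-cohort concordance-index table.

    ``table`` has one row per (cutoff, cohort) with columns c_index (NaN
    marks an undefined value: one of the two groups empty), n, n_loss.
    """

    cutoffs: list[int]
    cohorts: list[str]
    table: pd.DataFrame

    def c_index(self, cutoff: int, cohort: str) -> float:
        row = self.table[(self.table["cutoff"] == cutoff) & (self.table["cohort"] == cohort)]
        if row.empty:
            raise KeyError(f"no sweep entry for cutoff {cutoff}, cohort {cohort!r}")
        return float(row["c_index"].iloc[0])

    def mean_c_index(self, cutoff: int) -> float:
        """Mean c-index over cohorts at one cut-off (NaN if any cohort undefined)."""
        rows = self.table[self.table["cutoff"] == cutoff]
        return float(rows["c_index"].mean()) if not rows["c_index"].isna().any() else math.nan

    def to_json_records(self) -> list[dict]:
        recs = self.table.to_dict(orient="records")
        for r in recs:
            if isinstance(r["c_index"], float) and math.isnan(r["c_index"]):
                r["c_index"] = None
        return recs


def sweep_cutoffs(
    profiles: Iterable[ArmProfile] | pd.DataFrame,
    records: Iterable[SubjectRecord] | pd.DataFrame,
    cutoffs: Sequence[int] = DEFAULT_CUTOFF_GRID,
) -> SweepResult:
    """Score each candidate cut-off by per-cohort c-index of the loss call.

    For each cohort and cut-off c, the binary risk score 1{loss_percent > c}
    is evaluated with Harrell's c-index.  Cut-offs where a cohort has zero
    loss-called or zero non-loss subjects get a NaN (undefined) marker.
    """
    cutoffs = sorted(int(c) for c in cutoffs)
    merged = _join(_profiles_frame(profiles), _clinical_frame(records))
    cohorts = sorted(merged["cohort"].unique())
    rows = []
    for cohort in cohorts:
        sub = merged[merged["cohort"] == cohort]
        time = sub["time"].to_numpy(float)
        event = sub["event"].to_numpy(int)
        percent = sub["loss_percent"].to_numpy(int)
        for c in cutoffs:
            call = percent > c
            n_loss = int(call.sum())
            if n_loss == 0 or n_loss == len(sub):
                ci = math.nan
            else:
                ci = harrell_cindex(time, event, call.astype(float)).c_index
            rows.append(
                {"cutoff": c, "cohort": cohort, "c_index": ci, "n": len(sub), "n_loss": n_loss}
            )
    return SweepResult(cutoffs=cutoffs, cohorts=cohorts, table=pd.DataFrame(rows))


@dataclass
class StratifiedAnalysis:
    """Two-group (or k-group) survival comparison at a loss cut-off."""

    rule: str
    curves: dict[str, KmCurve]
    logrank: LogrankResult
    median_difference: float | None
    group_sizes: dict[str, int] = field(default_factory=dict)
    group_of: dict[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "rule": self.rule,
            "groups": {k: int(v) for k, v in self.group_sizes.items()},
            "medians": {k: c.median for k, c in self.curves.items()},
            "median_difference_years": self.median_difference,
            "logrank": self.logrank.to_dict(),
        }


def _two_group_analysis(
    merged: pd.DataFrame, in_high: np.ndarray, high_label: str, low_label: str, rule: str
) -> StratifiedAnalysis:
    if in_high.all() or not in_high.any():
        raise ValueError(
            f"stratification '{rule}' produced an empty group "
            f"({int(in_high.sum())} of {len(in_high)} in {high_label!r})"
        )
    t = merged["time"].to_numpy(float)
    e = merged["event"].to_numpy(int)
    km_high = km_fit(t[in_high], e[in_high])
    km_low = km_fit(t[~in_high], e[~in_high])
    lr = logrank_test(t[in_high], e[in_high], t[~in_high], e[~in_high])
    return StratifiedAnalysis(
        rule=rule,
        curves={high_label: km_high, low_label: km_low},
        logrank=lr,
        median_difference=km_median_difference(km_high, km_low),
        group_sizes={high_label: int(in_high.sum()), low_label: int((~in_high).sum())},
        group_of={
            sid: (high_label if h else low_label)
            for sid, h in zip(merged["sample_id"], in_high)
        },
    )


def stratify_by_cutoff(
    profiles: Iterable[ArmProfile] | pd.DataFrame,
    records: Iterable[SubjectRecord] | pd.DataFrame,
    cutoff_percent: int,
) -> StratifiedAnalysis:
    """Kaplan-Meier / log-rank comparison of loss vs no-loss at a cut-off."""
    merged = _join(_profiles_frame(profiles), _clinical_frame(records))
    in_loss = np.array(
        [apply_cutoff(int(p), cutoff_percent) for p in merged["loss_percent"]], dtype=bool
    )
    return _two_group_analysis(
        merged,
        in_loss,
        high_label="loss",
        low_label="no_loss",
        rule=f"loss_percent > {cutoff_percent}",
    )


def grade1_co_loss_analysis(
    profiles_1p: Iterable[ArmProfile] | pd.DataFrame,
    profiles_22q: Iterable[ArmProfile] | pd.DataFrame,
    records: Iterable[SubjectRecord] | pd.DataFrame,
    cutoff_percent: int = 5,
    four_groups: bool = False,
) -> StratifiedAnalysis:
    """Within CNS WHO grade 1: concurrent 1p and 22q loss vs no or single loss.

    Both arms use the same cut-off (default 5%, i.e. >=6% counted as loss).
    With ``four_groups=True`` the breakdown {none, 1p only, 22q only, both}
    is returned instead of the pooled two-group comparison (KM curves only;
    the log-rank still compares co-loss vs the rest).
    """
    p1 = _profiles_frame(profiles_1p).rename(columns={"loss_percent": "loss_percent_1p"})
    p22 = _profiles_frame(profiles_22q).rename(columns={"loss_percent": "loss_percent_22q"})
    clin = _clinical_frame(records)
    if "who_grade" not in clin.columns or clin["who_grade"].isna().all():
        raise ValueError("grade-1 analysis requires a who_grade column")
    merged = clin.merge(p1[["sample_id", "loss_percent_1p"]], on="sample_id").merge(
        p22[["sample_id", "loss_percent_22q"]], on="sample_id"
    )
    if len(merged) < len(clin):
        missing = sorted(set(clin["sample_id"]) - set(merged["sample_id"]))
        raise ValueError(f"samples missing arm profiles: {missing[:10]}")
    grade1 = merged[merged["who_grade"] == 1].reset_index(drop=True)
    if grade1.empty:
        raise ValueError("no CNS WHO grade 1 subjects in the clinical table")

    loss_1p = np.array(
        [apply_cutoff(int(p), cutoff_percent) for p in grade1["loss_percent_1p"]], dtype=bool
    )
    loss_22q = np.array(
        [apply_cutoff(int(p), cutoff_percent) for p in grade1["loss_percent_22q"]], dtype=bool
    )
    co_loss = loss_1p & loss_22q
    rule = f"grade 1: 1p and 22q loss_percent > {cutoff_percent} vs no or single loss"
    result = _two_group_analysis(
        grade1, co_loss, high_label="co_loss", low_label="no_or_single_loss", rule=rule
    )
    if four_groups:
        t = grade1["time"].to_numpy(float)
        e = grade1["event"].to_numpy(int)
        curves: dict[str, KmCurve] = {}
        sizes: dict[str, int] = {}
        for label, mask in (
            ("none", ~loss_1p & ~loss_22q),
            ("1p_only", loss_1p & ~loss_22q),
            ("22q_only", ~loss_1p & loss_22q),
            ("co_loss", co_loss),
        ):
            sizes[label] = int(mask.sum())
            if mask.any():
                curves[label] = km_fit(t[mask], e[mask])
        result.curves = curves
        result.group_sizes = sizes
    return result
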
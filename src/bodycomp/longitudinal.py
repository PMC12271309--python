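"""Per-patient longitudinal change analysis against repeatability limits.

Percent change is measured from the *average of the two pre-treatment
baselines* to the follow-up visit.  A change is called real (increase or
decrease) only when it exceeds the 95% repeatability-coefficient limits of
agreement for that tissue class — strictly: a change exactly on a limit is
``no_change``.  Cohort-level trend uses a two-sided paired t-test of
follow-up vs baseline-mean volumes; gender group differences use Welch's
unequal-variance t-test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

CATEGORIES = ("increase", "decrease", "no_change")


def percent_change(baseline1: float, baseline2: float, followup: float) -> float:
    """Percent change of follow-up vs the mean of the two baselines."""
    for v in (baseline1, baseline2, followup):
        if v is None or not np.isfinite(v) or v <= 0:
            raise ValueError("volumes must be positive and present")
    base = 0.5 * (baseline1 + baseline2)
    return float(100.0 * (followup - base) / base)


def classify_change(change_pct: float, limits: tuple[float, float]) -> str:
    """Classify a percent change against (lower, upper) repeatability limits.

    Strict exceedance: ``increase`` iff change > upper, ``decrease`` iff
    change < lower, boundary values are ``no_change``.
    """
    lower, upper = limits
    if not lower < 0 < upper:
        raise ValueError(f"limits must straddle zero, got {limits}")
    if change_pct > upper:
        return "increase"
    if change_pct < lower:
        return "decrease"
    return "no_change"


@dataclass(frozen=True)
class ChangeRecord:
    """One patient/tissue longitudinal classification."""

    patient: str
    tissue: str
    baseline_ml: float
    followup_ml: float
    change_pct: float
    category: str
    limits_pct: tuple[float, float]


def _paired_records(table: pd.DataFrame, tissue: str) -> pd.DataFrame:
    sub = table[table["tissue"] == tissue]
    wide = sub.pivot(index="patient", columns="visit", values="volume_ml")
    needed = {"baseline1", "baseline2", "day180"}
    if not needed <= set(wide.columns):
        return pd.DataFrame()
    return wide.dropna(subset=list(needed))


def change_records(
    table: pd.DataFrame, limits: dict[str, tuple[float, float]]
) -> list[ChangeRecord]:
    """Per-patient change classification for every tissue with limits given."""
    records: list[ChangeRecord] = []
    for tissue, lim in limits.items():
        wide = _paired_records(table, tissue)
        for patient, row in wide.iterrows():
            chg = percent_change(row["baseline1"], row["baseline2"], row["day180"])
            records.append(
                ChangeRecord(
                    patient=str(patient),
                    tissue=tissue,
                    baseline_ml=0.5 * (row["baseline1"] + row["baseline2"]),
                    followup_ml=row["day180"],
                    change_pct=chg,
                    category=classify_change(chg, lim),
                    limits_pct=lim,
                )
            )
    return records


def cohort_change_analysis(
    table: pd.DataFrame, limits: dict[str, tuple[float, float]]
) -> pd.DataFrame:
    """Cohort summary per tissue: category counts/percentages + paired t-test.

    Percentages are rounded to one decimal.  The paired t-test compares
    day-180 volumes against the baseline means (two-sided, raw volume
    scale); ``p_paired_t`` is NaN when fewer than 2 complete patients exist.
    """
    rows = []
    recs = change_records(table, limits)
    df = pd.DataFrame([r.__dict__ for r in recs])
    if df.empty:
        raise ValueError("no patients with both baselines and follow-up")
    for tissue, sub in df.groupby("tissue"):
        n = len(sub)
        row = {"tissue": tissue, "n": n}
        for cat in CATEGORIES:
            cnt = int((sub["category"] == cat).sum())
            row[f"n_{cat}"] = cnt
            row[f"pct_{cat}"] = round(100.0 * cnt / n, 1)
        if n >= 2:
            t = stats.ttest_rel(sub["followup_ml"], sub["baseline_ml"])
            row["p_paired_t"] = float(t.pvalue)
        else:
            row["p_paired_t"] = float("nan")
        rows.append(row)
    return pd.DataFrame(rows)


def compare_group_volumes(
    table: pd.DataFrame, group: str = "gender", visit: str = "baseline1"
) -> pd.DataFrame:
    """Welch two-sample test of volumes between two groups, per tissue class.

    Derived classes TF = SF+VF and TM = PM+EM are added when their
    constituents are present.  Returns per-tissue group means and the
    two-sided p-value.
    """
    sub = table[table["visit"] == visit].copy()
    groups = sorted(sub[group].unique())
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 groups in {group!r}, got {groups}")

    wide = sub.pivot_table(
        index=["patient", group], columns="tissue", values="volume_ml"
    ).reset_index()
    for derived, parts in (("TF", ("SF", "VF")), ("TM", ("PM", "EM"))):
        if all(p in wide.columns for p in parts) and derived not in wide.columns:
            wide[derived] = wide[list(parts)].sum(axis=1)

    tissues = [c for c in wide.columns if c not in ("patient", group)]
    rows = []
    for tissue in tissues:
        g0 = wide.loc[wide[group] == groups[0], tissue].dropna()
        g1 = wide.loc[wide[group] == groups[1], tissue].dropna()
        if len(g0) < 2 or len(g1) < 2:
            raise ValueError(f"degenerate group for tissue {tissue!r}")
        t = stats.ttest_ind(g0, g1, equal_var=False)
        rows.append(
            {
                "tissue": tissue,
                f"mean_{groups[0]}": float(g0.mean()),
                f"mean_{groups[1]}": float(g1.mean()),
                "t_stat": float(t.statistic),
                "p_value": float(t.pvalue),
            }
        )
    return pd.DataFrame(rows)
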
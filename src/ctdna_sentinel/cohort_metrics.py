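"""Cohort bookkeeping and statistics: tumor-plasma concordance, diagnostic
performance with exact binomial confidence intervals, gene spectra,
per-stage sensitivity and clinicopathological association screens.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

SIGNIFICANCE_LEVEL = 0.05


@dataclass(frozen=True, slots=True)
class ConfusionCounts:
    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n_cases(self) -> int:
        return self.tp + self.fn

    @property
    def n_controls(self) -> int:
        return self.fp + self.tn


def concordance_summary(rows: pd.DataFrame) -> dict:
    """Tumor->plasma concordance bookkeeping over tumor-mutation rows.

    Expects boolean caller_detected / manually_detected columns (the
    tumor-plasma fixture dialect). Reports the caller-path fraction, the
    overall (caller OR manual) fraction, and the manual-rescue accounting:
    how many mutations only manual inspection recovered, in how many
    distinct patients.
    """
    n = len(rows)
    if n == 0:
        return {
            "n": 0,
            "caller_detected": 0,
            "caller_fraction": None,
            "overall_detected": 0,
            "overall_fraction": None,
            "rescued_mutations": 0,
            "rescued_patients": 0,
        }
    caller = rows["caller_detected"].astype(bool)
    manual = rows["manually_detected"].astype(bool)
    rescued = manual & ~caller
    return {
        "n": n,
        "caller_detected": int(caller.sum()),
        "caller_fraction": float(caller.mean()),
        "overall_detected": int((caller | manual).sum()),
        "overall_fraction": float((caller | manual).mean()),
        "rescued_mutations": int(rescued.sum()),
        "rescued_patients": int(rows.loc[rescued, "sample"].nunique()),
    }


def positivity_table(
    detections_by_sample: Mapping[str, Sequence],
    sample_sheet: pd.DataFrame,
) -> tuple[pd.DataFrame, ConfusionCounts]:
    """Per-sample ctDNA positivity plus case/control confusion counts.

    detections_by_sample maps sample_id to its passing detections (objects
    with a ``vaf`` attribute and optionally flags/gene for TP53 tracking,
    or plain dicts with those keys). Samples present in the detections but
    absent from the sheet are an error; sheet samples without detections
    are negative.
    """
    known = set(sample_sheet["sample_id"])
    unknown = set(detections_by_sample) - known
    if unknown:
        raise ValueError(f"samples not in sheet: {sorted(unknown)}")

    def _vaf(d):
        return d.get("vaf") if isinstance(d, dict) else getattr(d, "vaf", None)

    def _gene(d):
        if isinstance(d, dict):
            return d.get("gene", "")
        gene = getattr(d, "gene", "")
        if not gene:
            var = getattr(d, "variant", None)
            gene = getattr(var, "gene", "") if var is not None else ""
        return gene

    rows = []
    for rec in sample_sheet.itertuples(index=False):
        if getattr(rec, "has_plasma", "Y") == "N":
            continue
        dets = list(detections_by_sample.get(rec.sample_id, ()))
        vafs = [v for v in (_vaf(d) for d in dets) if v is not None]
        rows.append(
            {
                "sample_id": rec.sample_id,
                "role": rec.role,
                "ctdna_positive": bool(dets),
                "n_plasma_mutations": len(dets),
                "median_vaf": float(np.median(vafs)) if vafs else None,
                "tp53_in_plasma": any(_gene(d) == "TP53" for d in dets),
            }
        )
    table = pd.DataFrame(rows)
    cases = table[table["role"] == "plasma_case"]
    controls = table[table["role"] == "plasma_control"]
    counts = ConfusionCounts(
        tp=int(cases["ctdna_positive"].sum()),
        fn=int((~cases["ctdna_positive"]).sum()),
        fp=int(controls["ctdna_positive"].sum()),
        tn=int((~controls["ctdna_positive"]).sum()),
    )
    return table, counts


def clopper_pearson_ci(
    k: int, n: int, level: float = 0.95
) -> tuple[float, float]:
    """Exact binomial CI via beta quantiles; k=0 -> lower 0, k=n -> upper 1."""
    if not 0 <= k <= n or n < 1:
        raise ValueError(f"need 0 <= k <= n with n >= 1, got k={k}, n={n}")
    alpha = 1.0 - level
    lower = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    upper = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lower, upper


def _metric(k: int, n: int, level: float) -> dict:
    if n == 0:
        return {"value": None, "ci": None, "k": k, "n": n}
    return {"value": k / n, "ci": clopper_pearson_ci(k, n, level), "k": k, "n": n}


def diagnostic_metrics(counts: ConfusionCounts, ci_level: float = 0.95) -> dict:
    """Sensitivity, specificity and PPV, each with an exact Clopper-Pearson CI.

    Zero-denominator metrics come back as undefined (value None) rather
    than raising.
    """
    return {
        "sensitivity": _metric(counts.tp, counts.tp + counts.fn, ci_level),
        "specificity": _metric(counts.tn, counts.tn + counts.fp, ci_level),
        "ppv": _metric(counts.tp, counts.tp + counts.fp, ci_level),
    }


def per_stage_sensitivity(
    cohort: pd.DataFrame,
    stage_col: str = "stage_group",
    positive_col: str = "ctdna_positive",
    ci_level: float = 0.95,
) -> pd.DataFrame:
    """Sensitivity per disease-stage group with exact CIs.

    Only case rows enter; groups with zero cases are skipped.
    """
    rows = []
    for stage, group in cohort.groupby(stage_col, dropna=True, sort=True):
        n = len(group)
        if n == 0:
            continue
        k = int(group[positive_col].astype(bool).sum())
        lo, hi = clopper_pearson_ci(k, n, ci_level)
        rows.append(
            {"stage": stage, "n": n, "positive": k,
             "sensitivity": k / n, "ci_low": lo, "ci_high": hi}
        )
    return pd.DataFrame(rows)


def _contingency_test(sub: pd.DataFrame, a: str, b: str) -> tuple[str, float]:
    table = pd.crosstab(sub[a], sub[b])
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("constant")
    expected = stats.contingency.expected_freq(table.values)
    # small-sample rule: exact test unless every expected cell exceeds 5
    if (expected <= 5).any():
        if table.shape != (2, 2):
            # exact test only defined here for 2x2; collapse is caller's job
            _, p, _, _ = stats.chi2_contingency(table.values)
            return "chi-square", float(p)
        _, p = stats.fisher_exact(table.values)
        return "fisher", float(p)
    _, p, _, _ = stats.chi2_contingency(table.values, correction=False)
    return "chi-square", float(p)


def association_screen(
    cohort: pd.DataFrame,
    pairs: Sequence[tuple[str, str, str]],
) -> pd.DataFrame:
    """Screen metric x covariate associations.

    pairs are (metric, covariate, kind) with kind "categorical"
    (Fisher exact when any expected cell < 5, chi-square otherwise) or
    "continuous" (Wilcoxon rank-sum between the two covariate groups).
    Constant columns are skipped with a reason. A BH-adjusted column is
    supplementary output; significance is judged at p < 0.05 unadjusted.
    """
    rows = []
    for metric, covariate, kind in pairs:
        sub = cohort[[metric, covariate]].dropna()
        rec = {"metric": metric, "covariate": covariate, "kind": kind,
               "test": None, "p_value": None, "direction": None, "skipped": None}
        if sub[covariate].nunique() < 2 or sub[metric].nunique() < 2:
            rec["skipped"] = "constant column"
            rows.append(rec)
            continue
        if kind == "categorical":
            try:
                rec["test"], rec["p_value"] = _contingency_test(sub, metric, covariate)
            except ValueError:
                rec["skipped"] = "constant column"
                rows.append(rec)
                continue
            rec["direction"] = None
        elif kind == "continuous":
            levels = sorted(sub[covariate].unique())
            if len(levels) != 2:
                rec["skipped"] = f"need 2 covariate groups, got {len(levels)}"
                rows.append(rec)
                continue
            x = sub.loc[sub[covariate] == levels[0], metric].astype(float)
            y = sub.loc[sub[covariate] == levels[1], metric].astype(float)
            stat_res = stats.mannwhitneyu(x, y, alternative="two-sided")
            rec["test"] = "wilcoxon_rank_sum"
            rec["p_value"] = float(stat_res.pvalue)
            rec["direction"] = (
                f"{levels[1]}>{levels[0]}" if y.median() > x.median()
                else f"{levels[0]}>{levels[1]}"
            )
        else:
            raise ValueError(f"unknown pair kind {kind!r}")
        rows.append(rec)
    out = pd.DataFrame(rows)
    tested = out["p_value"].notna()
    out["significant"] = False
    out.loc[tested, "significant"] = out.loc[tested, "p_value"] < SIGNIFICANCE_LEVEL
    if tested.any():
        _, qvals, _, _ = multipletests(out.loc[tested, "p_value"], method="fdr_bh")
        out.loc[tested, "bh_q"] = qvals
    else:
        out["bh_q"] = np.nan
    return out


def gene_spectrum(genes: Iterable[str]) -> pd.DataFrame:
    """Descending per-gene mutation counts with fraction of total."""
    series = pd.Series(list(genes), dtype=str)
    if series.empty:
        return pd.DataFrame(columns=["gene", "count", "fraction"])
    counts = series.value_counts()
    return pd.DataFrame(
        {"gene": counts.index, "count": counts.values,
         "fraction": counts.values / counts.values.sum()}
    )
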
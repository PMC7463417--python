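"""End-to-end cohort analysis: the machine twin of the clinical workflow.

``analyze_cohort`` takes validated patient records and produces one report
dict containing (i) CR-rate contingency analyses over the clinical
covariates, (ii) the per-feature two-group test table, (iii) the two-step
feature selection, (iv) ROC rows for SUVmax, MTV, the selected features and
the combined prediction probability, (v) the logistic coefficients with
Hosmer-Lemeshow calibration, (vi) the MTV-vs-volume consistency analyses,
and (vii) the interobserver ICC table. The report is deterministic given
the cohort and configuration.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np

from pettex import stats_core
from pettex.imaging_io import PatientRecord
from pettex.selection_modeling import (
    default_category_map,
    delong_compare,
    fit_prediction_probability,
    hosmer_lemeshow,
    roc_analysis,
    select_per_category,
    univariate_filter,
)
from pettex.texture_features import DiscretizationSpec, extract_feature_table

__all__ = ["contingency_tables", "analyze_cohort", "report_to_json", "format_report"]


def contingency_tables(records: Sequence[PatientRecord]) -> dict[str, list[list[int]]]:
    """Table-2-style 2x2 counts (rows: subgroup, cols: CR / non-CR)."""
    def count(pred):
        a = sum(1 for r in records if pred(r) and r.response == "CR")
        b = sum(1 for r in records if pred(r) and r.response != "CR")
        c = sum(1 for r in records if not pred(r) and r.response == "CR")
        d = sum(1 for r in records if not pred(r) and r.response != "CR")
        return [[a, b], [c, d]]

    return {
        "stage_I_vs_II_IV": count(lambda r: r.stage == "I"),
        "ipi_0_2_vs_3_5": count(lambda r: r.ipi <= 2),
        "subtype_gcb_vs_nongcb": count(lambda r: r.subtype == "GCB"),
        "intestinal_involved_vs_not": count(lambda r: r.intestinal_involvement),
        "ki67_lt80_vs_ge80": count(lambda r: r.ki67_percent < 80),
    }


def analyze_cohort(
    records: Sequence[PatientRecord],
    disc: DiscretizationSpec | None = None,
    alpha: float = 0.05,
    fisher_sidedness: str = "one",
) -> dict:
    """Run the full analysis on a cohort of patient records."""
    for rec in records:
        if rec.response is None:
            rec.classify()
    labels = [r.response for r in records]

    # clinicopathological contingency analysis
    contingency = {}
    for name, table in contingency_tables(records).items():
        res = stats_core.fisher_exact(table, sidedness=fisher_sidedness)
        (a, b), (c, d) = table
        contingency[name] = {
            "table": table,
            "cr_rate_row1_pct": round(100.0 * a / (a + b), 1) if a + b else float("nan"),
            "cr_rate_row2_pct": round(100.0 * c / (c + d), 1) if c + d else float("nan"),
            "p_value": res.p_value,
            "sidedness": res.sidedness,
        }

    # features, both readers
    feats1 = extract_feature_table(records, disc, reader=1)
    feats2 = extract_feature_table(records, disc, reader=2)

    # two-step selection on texture features (SUVmax/MTV bypass the filter)
    texture = feats1.drop(columns=["suvmax", "mtv_mm3"])
    survivors, filter_table = univariate_filter(texture, labels, alpha=alpha)
    normality = {}
    for name in survivors:
        try:
            normality[name] = stats_core.shapiro_wilk(texture[name].to_numpy()).p_value
        except ValueError:
            normality[name] = float("nan")
    categories = default_category_map(feats1.columns)
    selected = select_per_category(
        {f: float(filter_table.loc[f, "p_value"]) for f in survivors},
        categories,
        normality,
    )

    # ROC for SUVmax, MTV, and each selected feature
    roc = {}
    for name in ["suvmax", "mtv_mm3"] + sorted(set(selected.values())):
        roc[name] = roc_analysis(feats1[name].to_numpy(), labels).to_dict()

    # combined logistic prediction probability
    covar = feats1.copy()
    covar["intestinal_involvement"] = [float(r.intestinal_involvement) for r in records]
    predictors = ["suvmax", "entropy", "volume_mm3", "intestinal_involvement"]
    model = fit_prediction_probability(covar, labels, predictors=predictors)
    hl = hosmer_lemeshow(model.probabilities, labels)
    roc["prediction_probability"] = roc_analysis(model.probabilities, labels).to_dict()

    # MTV vs volume: paired difference and AUC comparison
    wil = stats_core.wilcoxon_signed_rank(
        feats1["mtv_mm3"].to_numpy(), feats1["volume_mm3"].to_numpy()
    )
    dl = delong_compare(feats1["mtv_mm3"].to_numpy(), feats1["volume_mm3"].to_numpy(), labels)

    # interobserver agreement per feature
    icc_rows = {}
    for name in feats1.columns:
        pair = np.column_stack([feats1[name].to_numpy(), feats2[name].to_numpy()])
        try:
            res = stats_core.icc_two_way(pair)
            icc_rows[name] = {"icc": res.icc, "band": res.band}
        except ValueError as exc:
            icc_rows[name] = {"icc": float("nan"), "band": f"undefined ({exc})"}

    return {
        "n_patients": len(records),
        "n_cr": int(sum(1 for l in labels if l == "CR")),
        "n_noncr": int(sum(1 for l in labels if l != "CR")),
        "contingency": contingency,
        "filter_table": filter_table["p_value"].to_dict(),
        "survivors": survivors,
        "selected_features": selected,
        "roc": roc,
        "logistic": {
            "predictors": model.predictors,
            "coefficients": [float(c) for c in model.coefficients],
            "intercept": model.intercept,
            "converged": model.converged,
            "log_likelihood": model.log_likelihood,
            "warning": model.warning,
            "probabilities": [float(p) for p in model.probabilities],
        },
        "hosmer_lemeshow": hl.to_dict(),
        "mtv_vs_volume_wilcoxon": wil.to_dict(),
        "mtv_vs_volume_delong": dl.to_dict(),
        "icc": icc_rows,
        "feature_table": feats1.to_dict(orient="index"),
    }


def report_to_json(report: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, default=float)


def format_report(report: dict) -> str:
    """Human-readable summary of an analysis report."""
    lines = []
    lines.append(
        f"Cohort: {report['n_patients']} patients "
        f"({report['n_cr']} CR, {report['n_noncr']} non-CR)"
    )
    lines.append("\nCR rates by clinicopathological subgroup (Fisher exact):")
    for name, row in report["contingency"].items():
        star = " *" if row["p_value"] < 0.05 else ""
        lines.append(
            f"  {name:<28s} CR {row['cr_rate_row1_pct']:5.1f}% vs "
            f"{row['cr_rate_row2_pct']:5.1f}%   p={row['p_value']:.3f}{star}"
        )
    lines.append("\nSelected features per category:")
    for cat, feat in report["selected_features"].items():
        lines.append(f"  {cat:<24s} -> {feat} (p={report['filter_table'][feat]:.3f})")
    lines.append("\nROC analysis (positive class: non-CR):")
    lines.append(f"  {'marker':<24s} {'cutoff':>10s} {'sens':>6s} {'spec':>6s} {'acc':>6s} {'AUC':>6s}")
    for name, row in report["roc"].items():
        lines.append(
            f"  {name:<24s} {row['cutoff']:>10.3g} {row['sensitivity']:>6.2f} "
            f"{row['specificity']:>6.2f} {row['accuracy']:>6.2f} {row['auc']:>6.3f}"
        )
    hl = report["hosmer_lemeshow"]
    lines.append(
        f"\nHosmer-Lemeshow: chi2={hl['statistic']:.3f}, df={hl['df']}, p={hl['p_value']:.3f}"
    )
    wil = report["mtv_vs_volume_wilcoxon"]
    dl = report["mtv_vs_volume_delong"]
    lines.append(
        f"MTV vs volume: Wilcoxon Z={wil['statistic']:.3f} (p={wil['p_value']:.3g}); "
        f"DeLong Z={dl['statistic']:.3f} (p={dl['p_value']:.3f})"
    )
    key_icc = {k: v for k, v in report["icc"].items() if k in ("suvmax", "entropy", "volume_mm3")}
    lines.append("\nInterobserver ICC (key features):")
    for name, row in key_icc.items():
        lines.append(f"  {name:<24s} ICC={row['icc']:.3f} ({row['band']})")
    return "\n".join(lines)
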
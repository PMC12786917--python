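"""Cohort-level report tables mirroring the published analysis layout.

Given a labeled cohort this module builds: per-item group counts with
Fisher exact p-values, NRS means/SDs with Mann-Whitney p-values, the
score summaries (sum VAS, SP sum) with their cut-off tables, and the
full accuracy panel of the SP-sum cut-off and of a decision tree.  All
numbers come from :mod:`endoquest.scoring` and
:mod:`endoquest.diagnostics`; this module only arranges them.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .diagnostics import (
    ContingencyTable, DiagnosticSummary, contingency_from_indicator,
    diagnostic_summary, fisher_exact, mann_whitney,
)
from .model import Label, PatientRecord
from .scoring import (
    DEFAULT_SP_REGISTRY, SpRegistry, VasVariant, score_record,
)
from .tree import DecisionTree, evaluate_tree

__all__ = ["item_table", "nrs_table", "score_table", "panel_row",
           "panel_frame", "write_report"]

_NRS_ITEMS = [
    "dysmenorrhea_nrs", "cpp_nrs", "dysuria_nrs", "dyschezia_nrs",
    "dyspareunia_nrs", "pain_now_nrs", "strongest_4wks_nrs",
    "average_4wks_nrs",
]


def _split(cohort):
    ems = [r for r in cohort if r.label is Label.EMS]
    no = [r for r in cohort if r.label is Label.NO_EMS]
    if not ems or not no:
        raise ValueError("cohort must contain both labeled groups")
    return ems, no


def item_table(cohort: list[PatientRecord],
               registry: Optional[SpRegistry] = None) -> pd.DataFrame:
    """Per-SP group counts, missing-data counts and Fisher exact p."""
    registry = registry or DEFAULT_SP_REGISTRY
    _split(cohort)  # validates labels present
    rows = []
    for rule in registry:
        ic = contingency_from_indicator(cohort, rule.sp_id)
        t = ic.table
        p = fisher_exact(t).p_value
        rows.append({
            "sp_id": rule.sp_id, "item": rule.name,
            "no_ems_no": t.tn, "no_ems_yes": t.fp,
            "ems_no": t.fn, "ems_yes": t.tp,
            "md_no_ems": ic.missing_no_ems, "md_ems": ic.missing_ems,
            "fisher_p": p,
        })
    return pd.DataFrame(rows)


def nrs_table(cohort: list[PatientRecord]) -> pd.DataFrame:
    """Group NRS means (SD) and Mann-Whitney p per pain scale."""
    ems, no = _split(cohort)
    rows = []
    for item in _NRS_ITEMS:
        a = [getattr(r, item) for r in ems if getattr(r, item) is not None]
        b = [getattr(r, item) for r in no if getattr(r, item) is not None]
        p = mann_whitney(a, b).p_value if a and b else float("nan")
        rows.append({
            "item": item,
            "ems_mean": float(np.mean(a)) if a else float("nan"),
            "ems_sd": float(np.std(a, ddof=1)) if len(a) > 1 else float("nan"),
            "no_ems_mean": float(np.mean(b)) if b else float("nan"),
            "no_ems_sd": float(np.std(b, ddof=1)) if len(b) > 1 else float("nan"),
            "mw_p": p,
        })
    return pd.DataFrame(rows)


def score_table(cohort: list[PatientRecord],
                variant: VasVariant = VasVariant.EIGHT_ITEM,
                tree: Optional[DecisionTree] = None) -> dict:
    """Score summaries, cut-off tables and accuracy panels.

    Returns a JSON-serializable dict with sum-VAS and SP-sum group
    moments, their > 8.5 cut-off tables with Fisher p, the SP-cut-off
    accuracy panel, and (when a tree is given) the tree's confusion
    table and panel.
    """
    ems, no = _split(cohort)
    scores = {r.patient_id: score_record(r, variant) for r in cohort}

    def moments(group, attr):
        vals = [getattr(scores[r.patient_id], attr) for r in group]
        return {"mean": float(np.mean(vals)),
                "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else None}

    def cutoff_table(attr, cut):
        tp = sum(getattr(scores[r.patient_id], attr) > cut for r in ems)
        fp = sum(getattr(scores[r.patient_id], attr) > cut for r in no)
        return ContingencyTable(tn=len(no) - fp, fp=fp,
                                fn=len(ems) - tp, tp=tp)

    vas_cut = cutoff_table("sum_vas", 8.5)
    sp_cut = cutoff_table("sum_sp", 8.5)
    out = {
        "sum_vas": {"variant": variant.value,
                    "EMS": moments(ems, "sum_vas"),
                    "NO_EMS": moments(no, "sum_vas"),
                    "cutoff_8_5": _table_dict(vas_cut),
                    "fisher_p": fisher_exact(vas_cut).p_value},
        "sum_sp": {"EMS": moments(ems, "sum_sp"),
                   "NO_EMS": moments(no, "sum_sp"),
                   "cutoff_8_5": _table_dict(sp_cut),
                   "fisher_p": fisher_exact(sp_cut).p_value,
                   "panel": panel_row(diagnostic_summary(sp_cut))},
    }
    if tree is not None:
        t = evaluate_tree(cohort, tree, variant)
        out["decision_tree"] = {"table": _table_dict(t),
                                "fisher_p": fisher_exact(t).p_value,
                                "panel": panel_row(diagnostic_summary(t))}
    return out


def _table_dict(t: ContingencyTable) -> dict:
    return {"tn": t.tn, "fp": t.fp, "fn": t.fn, "tp": t.tp}


def panel_row(summary: DiagnosticSummary) -> dict:
    """Flatten a DiagnosticSummary into estimate/CI triples."""
    out = {}
    for name in ("sensitivity", "specificity", "ppv", "npv", "accuracy",
                 "odds_ratio", "relative_risk", "lr_pos", "lr_neg"):
        m = getattr(summary, name)
        out[name] = {"estimate": m.estimate, "ci95": [m.ci_low, m.ci_high]}
    out["continuity_corrected"] = summary.continuity_corrected
    return out


def panel_frame(summary: DiagnosticSummary) -> pd.DataFrame:
    row = panel_row(summary)
    rows = [{"metric": k, "estimate": v["estimate"],
             "ci_low": v["ci95"][0], "ci_high": v["ci95"][1]}
            for k, v in row.items() if isinstance(v, dict)]
    return pd.DataFrame(rows)


def write_report(outdir, cohort: list[PatientRecord],
                 variant: VasVariant = VasVariant.EIGHT_ITEM,
                 tree: Optional[DecisionTree] = None,
                 manifest: Optional[dict] = None) -> dict:
    """Write item/NRS/score tables as CSV + a combined JSON report.

    The CSV and JSON files carry the same values; a manifest records the
    configuration that produced them.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    items = item_table(cohort)
    nrs = nrs_table(cohort)
    scores = score_table(cohort, variant, tree)
    items.to_csv(outdir / "items.csv", index=False)
    nrs.to_csv(outdir / "nrs.csv", index=False)
    report = {"items": items.to_dict(orient="records"),
              "nrs": nrs.to_dict(orient="records"),
              "scores": scores}
    (outdir / "report.json").write_text(json.dumps(report, indent=1),
                                        encoding="utf-8")
    if manifest is not None:
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1),
                                              encoding="utf-8")
    return report
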
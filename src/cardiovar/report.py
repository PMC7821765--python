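"""End-to-end pipeline driver and structured report assembly."""

from __future__ import annotations

import json
from dataclasses import asdict
from typing import Optional

from . import __version__
from .burden import burden_table, category_distribution, hgmd_carrier_table
from .filters import run_cascade
from .io import default_gene_categories
from .model import Cohort, GeneCategoryMap
from .pathogenicity import (
    acmg_combine,
    acmg_distribution,
    class_counts,
    classify_all,
    mean_maf_by_class,
    resolve_verdict,
)

__all__ = ["run_pipeline", "build_report", "report_to_json"]


class AssemblyError(RuntimeError):
    """A report was requested before all pipeline stages ran."""


def run_pipeline(
    cohort: Cohort,
    control_ids: Optional[set] = None,
    curation_exclusions: Optional[set] = None,
    category_map: Optional[GeneCategoryMap] = None,
    maf_cutoff: float = 0.005,
) -> dict:
    """Filter, classify and summarize one cohort; returns stage outputs."""
    category_map = category_map or default_gene_categories()
    kept, trace = run_cascade(
        cohort.variants,
        control_ids=control_ids,
        curation_exclusions=curation_exclusions,
        maf_cutoff=maf_cutoff,
    )
    classified = classify_all(kept)
    carried_ids = {vid for p in cohort.patients for vid in p.carried}
    carried_classified = [cv for cv in classified if cv.variant_id in carried_ids]
    # burden needs a class for every *carried* variant; restrict the
    # patient view to carried variants that survived filtering
    analysis_ids = {cv.variant_id for cv in classified}
    patient_view = []
    for p in cohort.patients:
        q = PatientView(p, {v: z for v, z in p.carried.items() if v in analysis_ids})
        patient_view.append(q)
    analysis_cohort = Cohort(variants=kept, patients=[pv.record for pv in patient_view])
    verdicts = [
        resolve_verdict(cv.variant, acmg_combine(set())) for cv in classified
    ]
    return {
        "trace": trace,
        "classified": classified,
        "analysis_cohort": analysis_cohort,
        "class_counts": class_counts(classified),
        "mean_maf": mean_maf_by_class(classified),
        "burden": burden_table(analysis_cohort, classified),
        "hgmd": hgmd_carrier_table(analysis_cohort, classified),
        "categories": category_distribution(classified, category_map, scope="pooled"),
        "acmg": acmg_distribution(verdicts),
    }


class PatientView:
    """A patient with carriage restricted to the analysis set."""

    def __init__(self, patient, carried):
        import copy

        self.record = copy.copy(patient)
        self.record.carried = carried


def build_report(pipeline_out: dict, config: Optional[dict] = None, seed: Optional[int] = None) -> dict:
    """Self-contained, deterministic report of every stage output."""
    required = ("trace", "class_counts", "mean_maf", "burden", "hgmd", "categories", "acmg")
    missing = [k for k in required if k not in pipeline_out]
    if missing:
        raise AssemblyError(f"missing stage outputs: {missing}")
    trace = pipeline_out["trace"]
    return {
        "meta": {
            "software": "cardiovar",
            "version": __version__,
            "seed": seed,
            "config": config or {},
        },
        "filter_trace": trace.to_rows(),
        "class_counts": pipeline_out["class_counts"],
        "mean_maf_by_class": pipeline_out["mean_maf"],
        "burden": [asdict(row) for row in pipeline_out["burden"]],
        "hgmd": pipeline_out["hgmd"],
        "category_distribution": pipeline_out["categories"],
        "acmg_distribution": {
            tier: {"n": n, "pct": pct} for tier, (n, pct) in pipeline_out["acmg"].items()
        },
    }


def report_to_json(report: dict) -> str:
    return json.dumps(report, indent=2, sort_keys=True)
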
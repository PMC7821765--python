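"""Molecular-burden tables and functional-category distributions.

Burden is counted over *carried instances*: a variant carried by two
patients contributes two instances.  A patient is "positive" at a class
threshold when they carry at least one variant at-or-above that
severity; the cumulative variant count is the number of carried
instances at-or-above the threshold summed over the whole subgroup.
``pct_of_all_variants`` is taken against the subgroup's total carried
instances across all classes.

Functional-category tables pool *unique* variants across arms by
default; per-subgroup views count the instances carried by that arm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

from .model import CATEGORIES, Cohort, GeneCategoryMap, PATIENT_SUBGROUPS
from .pathogenicity import CLASS_ORDER, ClassifiedVariant
from .stats import percent, round_half_up

__all__ = [
    "THRESHOLDS",
    "BurdenRow",
    "burden_table",
    "hgmd_carrier_table",
    "category_distribution",
    "gene_frequency_table",
]

#: Cumulative class thresholds, narrowest first.
THRESHOLDS = ("I", "I/II", "I/II/III")

_THRESHOLD_CLASSES = {"I": {"I"}, "I/II": {"I", "II"}, "I/II/III": {"I", "II", "III"}}


@dataclass(frozen=True)
class BurdenRow:
    subgroup: str
    class_threshold: str
    n_patients: int
    n_positive: int
    pct_positive: Optional[float]
    cumulative_variants: int
    pct_of_all_variants: Optional[float]
    variants_per_positive: Optional[float]


def _class_by_id(classified: Sequence[ClassifiedVariant]) -> Dict[str, str]:
    return {cv.variant_id: cv.pclass.value for cv in classified}


def burden_table(
    cohort: Cohort,
    classified: Sequence[ClassifiedVariant],
    subgroups: Sequence[str] = PATIENT_SUBGROUPS,
) -> List[BurdenRow]:
    """One row per subgroup x cumulative class threshold.

    Every carried variant must be classed; carried variants missing from
    ``classified`` raise KeyError.
    """
    cls = _class_by_id(classified)
    rows = []
    for sg in subgroups:
        patients = cohort.patients_in(sg)
        if not patients:
            warnings.warn(f"subgroup {sg!r} has no patients; rows omitted", stacklevel=2)
            continue
        total_instances = sum(len(p.carried) for p in patients)
        for threshold in THRESHOLDS:
            qualifying = _THRESHOLD_CLASSES[threshold]
            n_positive = 0
            cumulative = 0
            for p in patients:
                k = sum(1 for vid in p.carried if cls[vid] in qualifying)
                cumulative += k
                if k > 0:
                    n_positive += 1
            rows.append(
                BurdenRow(
                    subgroup=sg,
                    class_threshold=threshold,
                    n_patients=len(patients),
                    n_positive=n_positive,
                    pct_positive=percent(n_positive, len(patients)),
                    cumulative_variants=cumulative,
                    pct_of_all_variants=percent(cumulative, total_instances),
                    variants_per_positive=(
                        round_half_up(cumulative / n_positive, 2) if n_positive else None
                    ),
                )
            )
    return rows


def hgmd_carrier_table(
    cohort: Cohort,
    classified: Sequence[ClassifiedVariant],
    subgroups: Sequence[str] = PATIENT_SUBGROUPS,
) -> dict:
    """Disease-mutation (HGMD-listed) carrier fractions per subgroup and
    the class distribution of the flagged variants themselves."""
    flagged_ids = {cv.variant_id for cv in classified if cv.variant.hgmd_id}
    carrier = {}
    for sg in subgroups:
        patients = cohort.patients_in(sg)
        if not patients:
            continue
        n_pos = sum(1 for p in patients if any(vid in flagged_ids for vid in p.carried))
        carrier[sg] = {
            "n_patients": len(patients),
            "n_carriers": n_pos,
            "pct_carriers": percent(n_pos, len(patients)),
        }
    by_class = {c: 0 for c in CLASS_ORDER}
    for cv in classified:
        if cv.variant.hgmd_id:
            by_class[cv.pclass.value] += 1
    total = sum(by_class.values())
    return {
        "carriers": carrier,
        "flagged_by_class": {
            c: {"n": n, "pct": percent(n, total) if total else None} for c, n in by_class.items()
        },
    }


def category_distribution(
    classified: Sequence[ClassifiedVariant],
    category_map: GeneCategoryMap,
    scope: str = "pooled",
    cohort: Optional[Cohort] = None,
    classes: Sequence[str] = CLASS_ORDER,
) -> dict:
    """Category x class count table with row-wise percentages.

    ``scope="pooled"`` counts unique variants over the whole analysis
    set; ``scope="per_subgroup"`` restricts, per arm, to the variants
    carried by that arm's patients (instance counting).  ``classes``
    filters the columns (e.g. only the two most severe classes).
    """
    category_map.check_covers(cv.variant.gene for cv in classified)
    classes = tuple(classes)
    if scope == "pooled":
        return {"pooled": _one_distribution(classified, category_map, classes)}
    if scope != "per_subgroup":
        raise ValueError(f"scope must be 'pooled' or 'per_subgroup', got {scope!r}")
    if cohort is None:
        raise ValueError("per_subgroup scope requires the cohort")
    cls_by_id = {cv.variant_id: cv for cv in classified}
    out = {}
    for sg in PATIENT_SUBGROUPS:
        patients = cohort.patients_in(sg)
        if not patients:
            continue
        instances: List[ClassifiedVariant] = []
        for p in patients:
            for vid in p.carried:
                if vid in cls_by_id:
                    instances.append(cls_by_id[vid])
        out[sg] = _one_distribution(instances, category_map, classes)
    return out


def _one_distribution(
    items: Sequence[ClassifiedVariant], category_map: GeneCategoryMap, classes: Sequence[str]
) -> dict:
    table = {cat: {c: 0 for c in classes} for cat in CATEGORIES}
    for cv in items:
        if cv.pclass.value in classes:
            table[category_map.category(cv.variant.gene)][cv.pclass.value] += 1
    out = {}
    for cat in CATEGORIES:
        row_total = sum(table[cat].values())
        out[cat] = {
            c: {"n": table[cat][c], "pct": percent(table[cat][c], row_total) if row_total else None}
            for c in classes
        }
        out[cat]["row_total"] = row_total
    return out


def gene_frequency_table(
    cohort: Cohort,
    classified: Sequence[ClassifiedVariant],
    mode: str = "hgmd_plus_rare",
    subgroups: Sequence[str] = PATIENT_SUBGROUPS,
) -> List[dict]:
    """Per-gene, per-subgroup carrier fractions, sorted by max frequency.

    ``mode`` selects the qualifying variants: ``"hgmd"`` counts only
    disease-mutation-flagged variants, ``"hgmd_plus_rare"`` counts every
    classed variant (the flagged plus the rare/novel ones).
    """
    if mode == "hgmd":
        qualifying = {cv.variant_id: cv for cv in classified if cv.variant.hgmd_id}
    elif mode == "hgmd_plus_rare":
        qualifying = {cv.variant_id: cv for cv in classified}
    else:
        raise ValueError(f"mode must be 'hgmd' or 'hgmd_plus_rare', got {mode!r}")
    genes = sorted({cv.variant.gene for cv in qualifying.values()})
    rows = []
    for gene in genes:
        row = {"gene": gene}
        for sg in subgroups:
            patients = cohort.patients_in(sg)
            if not patients:
                row[sg] = None
                continue
            n_pos = sum(
                1
                for p in patients
                if any(vid in qualifying and qualifying[vid].variant.gene == gene for vid in p.carried)
            )
            row[sg] = percent(n_pos, len(patients))
        rows.append(row)
    rows.sort(key=lambda r: max((r[sg] or 0.0) for sg in subgroups), reverse=True)
    return rows
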
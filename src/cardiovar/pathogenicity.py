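"""Consensus pathogenicity classes and ACMG/AMP five-tier verdicts.

Two orthogonal classifications are attached to each variant:

* the ordinal *consensus class* I-IV, defined by how many of the ten
  in-silico predictors call the variant damaging (>= 7 -> I, 4-6 -> II,
  1-3 -> III, 0 -> IV; I is the highest pathogenic potential);
* the *ACMG/AMP verdict* (pathogenic, likely pathogenic, VUS, likely
  benign, benign), obtained by combining weighted evidence codes
  according to the 2015 guideline's combining rules.

Missing predictor calls count as not-damaging; the number of available
calls is surfaced so users can gate on predictor coverage.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

from .model import PREDICTOR_TOOLS, SchemaError, Variant, PredictorPanel
from .stats import percent

__all__ = [
    "CLASS_ORDER",
    "ACMG_CODES",
    "PathogenicityClass",
    "AcmgVerdict",
    "consensus_class",
    "classify_all",
    "ClassifiedVariant",
    "class_counts",
    "mean_maf_by_class",
    "acmg_combine",
    "acmg_distribution",
]

#: Severity order, most severe first.
CLASS_ORDER = ("I", "II", "III", "IV")

_SEVERITY = {c: i for i, c in enumerate(CLASS_ORDER)}  # lower = more severe

ACMG_CODES = frozenset(
    ["PVS1"]
    + [f"PS{i}" for i in range(1, 5)]
    + [f"PM{i}" for i in range(1, 7)]
    + [f"PP{i}" for i in range(1, 6)]
    + ["BA1"]
    + [f"BS{i}" for i in range(1, 5)]
    + [f"BP{i}" for i in range(1, 7)]
)


@dataclass(frozen=True)
class PathogenicityClass:
    """Ordinal consensus class with its defining damaging count."""

    value: str
    damaging_count: int
    n_available: int

    def __post_init__(self) -> None:
        assert self.value in CLASS_ORDER

    def at_least(self, threshold: str) -> bool:
        """True iff this class is at least as severe as ``threshold``."""
        return _SEVERITY[self.value] <= _SEVERITY[threshold]

    def __lt__(self, other: "PathogenicityClass") -> bool:
        # "less than" = less severe
        return _SEVERITY[self.value] > _SEVERITY[other.value]


def _band(damaging_count: int) -> str:
    if damaging_count >= 7:
        return "I"
    if damaging_count >= 4:
        return "II"
    if damaging_count >= 1:
        return "III"
    return "IV"


def consensus_class(panel: PredictorPanel) -> PathogenicityClass:
    """Class I-IV from the panel's damaging count (missing = not damaging)."""
    dc = panel.damaging_count
    return PathogenicityClass(value=_band(dc), damaging_count=dc, n_available=panel.n_available)


@dataclass(frozen=True)
class ClassifiedVariant:
    variant: Variant
    pclass: PathogenicityClass

    @property
    def variant_id(self) -> str:
        return self.variant.variant_id


def classify_all(variants: Iterable[Variant]) -> List[ClassifiedVariant]:
    """Attach a consensus class to every variant.

    Variants with no predictor panel at all are treated as having ten
    missing calls (damaging count 0, class IV, n_available 0).
    """
    out = []
    empty = PredictorPanel(calls={t: "missing" for t in PREDICTOR_TOOLS})
    for v in variants:
        panel = v.predictor_calls if v.predictor_calls is not None else empty
        out.append(ClassifiedVariant(variant=v, pclass=consensus_class(panel)))
    return out


def class_counts(classified: Sequence[ClassifiedVariant]) -> Dict[str, int]:
    counts = {c: 0 for c in CLASS_ORDER}
    for cv in classified:
        counts[cv.pclass.value] += 1
    return counts


def class_hgmd_split(classified: Sequence[ClassifiedVariant]) -> Dict[str, Dict[str, int]]:
    """Per class, how many variants carry a disease-mutation accession."""
    split = {c: {"hgmd": 0, "other": 0} for c in CLASS_ORDER}
    for cv in classified:
        key = "hgmd" if cv.variant.hgmd_id else "other"
        split[cv.pclass.value][key] += 1
    return split


def mean_maf_by_class(
    classified: Sequence[ClassifiedVariant],
    dbs: Sequence[str] = ("ESP6500", "1000G", "ExAC"),
) -> Dict[str, Optional[float]]:
    """Per-class arithmetic mean of the per-variant mean reference frequency.

    Each variant contributes the mean over the listed databases in which
    it was observed; a variant absent from all of them contributes 0 (it
    has no measured population frequency).  Classes with no variants are
    reported as None, not 0.
    """
    sums = {c: 0.0 for c in CLASS_ORDER}
    ns = {c: 0 for c in CLASS_ORDER}
    for cv in classified:
        freqs = [cv.variant.freq(db) for db in dbs]
        freqs = [f for f in freqs if f is not None]
        value = sum(freqs) / len(freqs) if freqs else 0.0
        sums[cv.pclass.value] += value
        ns[cv.pclass.value] += 1
    return {c: (sums[c] / ns[c] if ns[c] else None) for c in CLASS_ORDER}


@dataclass(frozen=True)
class AcmgVerdict:
    value: str  # pathogenic / likely_pathogenic / VUS / likely_benign / benign
    rule: str  # identifier of the combining rule satisfied


def _count_codes(evidence: Set[str]) -> Dict[str, int]:
    counts = {"PVS": 0, "PS": 0, "PM": 0, "PP": 0, "BA": 0, "BS": 0, "BP": 0}
    for code in evidence:
        prefix = re.match(r"[A-Z]+", code).group(0)
        counts[prefix] += 1
    return counts


def acmg_combine(evidence: Iterable[str]) -> AcmgVerdict:
    """Combine evidence codes into a five-tier verdict.

    Implements the 2015 combining rules.  When both a pathogenic-side
    and a benign-side rule are satisfied the evidence is contradictory
    and the verdict is VUS.
    """
    ev = set(evidence)
    unknown = ev - ACMG_CODES
    if unknown:
        raise SchemaError(f"unknown ACMG codes: {sorted(unknown)}")
    c = _count_codes(ev)
    pvs, ps, pm, pp = c["PVS"], c["PS"], c["PM"], c["PP"]
    ba, bs, bp = c["BA"], c["BS"], c["BP"]

    pathogenic_rule = None
    if pvs >= 1 and (ps >= 1 or pm >= 2 or (pm == 1 and pp == 1) or pp >= 2):
        pathogenic_rule = "pathogenic.ia" if ps >= 1 else "pathogenic.ib-id"
    elif ps >= 2:
        pathogenic_rule = "pathogenic.ii"
    elif ps == 1 and (pm >= 3 or (pm == 2 and pp >= 2) or (pm == 1 and pp >= 4)):
        pathogenic_rule = "pathogenic.iii"

    likely_pathogenic_rule = None
    if pvs >= 1 and pm == 1:
        likely_pathogenic_rule = "likely_pathogenic.i"
    elif ps == 1 and 1 <= pm <= 2:
        likely_pathogenic_rule = "likely_pathogenic.ii"
    elif ps == 1 and pp >= 2:
        likely_pathogenic_rule = "likely_pathogenic.iii"
    elif pm >= 3:
        likely_pathogenic_rule = "likely_pathogenic.iv"
    elif pm == 2 and pp >= 2:
        likely_pathogenic_rule = "likely_pathogenic.v"
    elif pm == 1 and pp >= 4:
        likely_pathogenic_rule = "likely_pathogenic.vi"

    benign_rule = None
    if ba >= 1:
        benign_rule = "benign.i"
    elif bs >= 2:
        benign_rule = "benign.ii"

    likely_benign_rule = None
    if bs == 1 and bp == 1:
        likely_benign_rule = "likely_benign.i"
    elif bp >= 2:
        likely_benign_rule = "likely_benign.ii"

    path_side = pathogenic_rule or likely_pathogenic_rule
    benign_side = benign_rule or likely_benign_rule
    if path_side and benign_side:
        return AcmgVerdict("VUS", rule=f"conflict({path_side},{benign_side})")
    if pathogenic_rule:
        return AcmgVerdict("pathogenic", rule=pathogenic_rule)
    if likely_pathogenic_rule:
        return AcmgVerdict("likely_pathogenic", rule=likely_pathogenic_rule)
    if benign_rule:
        return AcmgVerdict("benign", rule=benign_rule)
    if likely_benign_rule:
        return AcmgVerdict("likely_benign", rule=likely_benign_rule)
    return AcmgVerdict("VUS", rule="no_rule")


TIERS = ("pathogenic", "likely_pathogenic", "VUS", "likely_benign", "benign")


def resolve_verdict(
    variant: Variant, local: Optional[AcmgVerdict], prefer_ingested: bool = True
) -> str:
    """Reported tier when an ingested assertion and the local combination
    coexist: the ingested assertion wins by default (it is the curated
    final verdict); both remain available to callers."""
    if prefer_ingested and variant.clinvar_assertion:
        return variant.clinvar_assertion
    if local is not None:
        return local.value
    if variant.clinvar_assertion:
        return variant.clinvar_assertion
    return "VUS"


def acmg_distribution(verdicts: Iterable[str]) -> Dict[str, Tuple[int, Optional[float]]]:
    """Five-tier counts and half-up one-decimal percentages."""
    verdicts = list(verdicts)
    unknown = set(verdicts) - set(TIERS)
    if unknown:
        raise SchemaError(f"unknown verdict tiers: {sorted(unknown)}")
    total = len(verdicts)
    out = {}
    for tier in TIERS:
        n = verdicts.count(tier)
        out[tier] = (n, percent(n, total) if total else None)
    return out
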
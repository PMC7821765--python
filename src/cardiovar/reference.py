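"""Published summary counts of the emulated cohort study, as inputs.

The original three-arm ventricular-tachycardia cohort (23 + 32 + 37
patients, 60 unaffected controls, 96-gene panel) is not redistributable
at the read level, but its printed integer summaries are pure inputs:
tier counts, per-arm burden integers, category-by-class cell counts and
the control-group filtering composition.  This module rebuilds minimal
in-memory cohorts and variant sets that *realize* those integers, so
the pipeline's arithmetic can be exercised against the printed
percentages end to end.

Everything here is synthetic reconstruction: variants get placeholder
coordinates; only the counted structure is faithful.
"""

from __future__ import annotations

import zlib
from typing import Dict, List, Tuple

from .model import Cohort, PatientRecord, PredictorPanel, Variant

__all__ = [
    "ACMG_TIER_COUNTS",
    "BURDEN_INTEGERS",
    "CATEGORY_CLASS_COUNTS",
    "KCG_COMPOSITION",
    "HGMD_CARRIERS",
    "reference_burden_cohort",
    "reference_category_variants",
    "reference_kcg_pool",
    "reference_kcg_rare_exonic",
]

#: Five-tier verdict counts over the 307 analyzed unique variants.
ACMG_TIER_COUNTS: Dict[str, int] = {
    "pathogenic": 9,
    "likely_pathogenic": 9,
    "VUS": 98,
    "likely_benign": 73,
    "benign": 118,
}

#: Per-arm burden integers: arm size; patients positive at the three
#: cumulative class thresholds (I, I/II, I/II/III); cumulative carried
#: instances at those thresholds; and total carried instances.
BURDEN_INTEGERS: Dict[str, dict] = {
    "CHD_VT": {"n": 23, "positive": (10, 16, 22), "cumulative": (13, 31, 89), "total": 110},
    "DCM_VT": {"n": 32, "positive": (10, 24, 31), "cumulative": (13, 49, 131), "total": 159},
    "iVT": {"n": 37, "positive": (20, 30, 36), "cumulative": (26, 70, 160), "total": 187},
}

#: Unique-variant counts per functional category x consensus class
#: (pooled over arms; cells sum to 307).
CATEGORY_CLASS_COUNTS: Dict[str, Tuple[int, int, int, int]] = {
    "cell_membrane": (0, 7, 8, 2),
    "cytoskeleton": (5, 12, 22, 12),
    "sarcomere": (14, 34, 62, 10),
    "metabolism": (4, 2, 10, 1),
    "intercalated_disc": (6, 5, 15, 4),
    "ion_flux": (12, 7, 18, 2),
    "nucleus": (7, 3, 21, 2),
}

#: Control-group (60 unaffected subjects) filtering composition:
#: 2,150 called variants, 475 common; the remainder includes 68 exonic
#: variants (37 synonymous, 3 frameshift, 3 non-frameshift, 25
#: non-synonymous); a further frequency exclusion leaves 58 rare exonic
#: variants whose consensus classes count 3 / 11 / 36 / 8.
KCG_COMPOSITION = {
    "n_total": 2150,
    "n_common": 475,
    "exonic_effects": {
        "synonymous_snv": 37,
        "frameshift_indel": 3,
        "nonframeshift_indel": 3,
        "nonsynonymous_snv": 25,
    },
    "n_rare_exonic": 58,
    "rare_exonic_classes": (3, 11, 36, 8),
}

#: Patients carrying at least one disease-mutation-flagged variant.
HGMD_CARRIERS = {"CHD_VT": (20, 23), "DCM_VT": (25, 32), "iVT": (30, 37)}

_CLASS_REP_DAMAGING = {"I": 8, "II": 5, "III": 2, "IV": 0}

# genes guaranteed to be on the packaged panel, one per category cycle
_FILLER_GENES = ("TTN", "MYBPC3", "LAMA2", "GAA", "DSG2", "KCNQ1", "LMNA")


def _make_variant(vid: str, cls: str, gene: str = "TTN", effect: str = "nonsynonymous_snv") -> Variant:
    return Variant(
        variant_id=vid,
        chrom="chr1",
        pos=1000 + zlib.crc32(vid.encode()) % 100000,
        ref="A",
        alt="G",
        gene=gene,
        effect=effect,
        predictor_calls=PredictorPanel.from_damaging(_CLASS_REP_DAMAGING[cls]),
    )


def reference_burden_cohort() -> Cohort:
    """A cohort whose per-arm carriage realizes the printed burden integers.

    Per arm, the first ``positive[0]`` patients carry a class-I variant,
    the next block newly turns positive at threshold I/II, and so on;
    instance surpluses are parked on the first patient, which leaves
    every positivity count untouched.  Each carried instance is its own
    unique variant, so instance counting is exercised directly.
    """
    variants: List[Variant] = []
    patients: List[PatientRecord] = []
    serial = 0
    for arm, row in BURDEN_INTEGERS.items():
        n = row["n"]
        p1, p2, p3 = row["positive"]
        c1, c2, c3 = row["cumulative"]
        per_class = {
            "I": c1,
            "II": c2 - c1,
            "III": c3 - c2,
            "IV": row["total"] - c3,
        }
        newly_positive = {"I": (0, p1), "II": (p1, p2), "III": (p2, p3)}
        carried: List[Dict[str, str]] = [dict() for _ in range(n)]

        def give(patient_idx: int, cls: str) -> None:
            nonlocal serial
            vid = f"ref{serial:05d}"
            serial += 1
            variants.append(_make_variant(vid, cls, gene=_FILLER_GENES[serial % len(_FILLER_GENES)]))
            carried[patient_idx][vid] = "het"

        for cls in ("I", "II", "III"):
            lo, hi = newly_positive[cls]
            remaining = per_class[cls]
            for idx in range(lo, hi):  # one each to the newly positive block
                give(idx, cls)
                remaining -= 1
            for _ in range(remaining):  # surplus parked on the first patient
                give(0, cls)
        for _ in range(per_class["IV"]):
            give(0, "IV")

        for j in range(n):
            patients.append(
                PatientRecord(patient_id=f"{arm}_{j:03d}", subgroup=arm, carried=carried[j])
            )
    return Cohort(variants=variants, patients=patients)


def reference_category_variants() -> List[Variant]:
    """307 unique variants realizing the category-by-class cell counts."""
    gene_for = {
        "cell_membrane": "LAMA2",
        "cytoskeleton": "DES",
        "sarcomere": "MYBPC3",
        "metabolism": "GAA",
        "intercalated_disc": "DSG2",
        "ion_flux": "KCNQ1",
        "nucleus": "LMNA",
    }
    variants = []
    serial = 0
    for category, counts in CATEGORY_CLASS_COUNTS.items():
        for cls, n in zip(("I", "II", "III", "IV"), counts):
            for _ in range(n):
                variants.append(_make_variant(f"cat{serial:05d}", cls, gene=gene_for[category]))
                serial += 1
    return variants


def reference_kcg_pool() -> List[Variant]:
    """2,150 control-group calls of which exactly 475 satisfy the common
    rule (frequency above 0.5% in a removal database or dbSNP130
    membership); the rest are rare."""
    pool = []
    comp = KCG_COMPOSITION
    for i in range(comp["n_common"]):
        pool.append(
            Variant(
                variant_id=f"kcgC{i:04d}",
                chrom="chr2",
                pos=1 + i,
                ref="A",
                alt="C",
                gene="TTN",
                effect="nonsynonymous_snv",
                ref_freqs={"ESP6500": 0.02},
                dbsnp130=(i % 2 == 0),
            )
        )
    n_rare = comp["n_total"] - comp["n_common"]
    serial = 0
    # the rare remainder: the printed exonic composition, padded with
    # synonymous filler standing in for non-exonic calls
    effects = []
    for effect, n in comp["exonic_effects"].items():
        effects.extend([effect] * n)
    effects.extend(["synonymous_snv"] * (n_rare - len(effects)))
    for effect in effects:
        pool.append(
            Variant(
                variant_id=f"kcgR{serial:04d}",
                chrom="chr2",
                pos=10_000 + serial,
                ref="A",
                alt="G" if "indel" not in effect else "AG",
                gene="TTN",
                effect=effect,
                ref_freqs={},
            )
        )
        serial += 1
    return pool


def reference_kcg_rare_exonic() -> List[Variant]:
    """The 58 rare exonic control-group variants with their printed
    consensus-class composition (damaging counts placed mid-band)."""
    variants = []
    serial = 0
    for cls, n in zip(("I", "II", "III", "IV"), KCG_COMPOSITION["rare_exonic_classes"]):
        for _ in range(n):
            variants.append(_make_variant(f"kcgX{serial:03d}", cls))
            serial += 1
    return variants
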
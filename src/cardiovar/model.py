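"""Domain types for annotated panel variants, patients and cohorts.

The unit of analysis is the *unique variant* (one genomic alteration with
its annotations) and the *carried instance* (one patient carrying one
variant).  Annotation absence is a first-class state throughout: a variant
that was never observed in a reference database has no frequency for that
database, which is different from a frequency of 0.0.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional

__all__ = [
    "EFFECTS",
    "PREDICTOR_TOOLS",
    "FREQ_DBS",
    "SUBGROUPS",
    "PATIENT_SUBGROUPS",
    "CATEGORIES",
    "SchemaError",
    "IntegrityError",
    "ConfigError",
    "PredictorPanel",
    "Variant",
    "PatientRecord",
    "Cohort",
    "GeneCategoryMap",
    "Violation",
    "validate_cohort",
]

#: Closed vocabulary of coding-effect labels.
EFFECTS = (
    "nonsynonymous_snv",
    "synonymous_snv",
    "stopgain",
    "frameshift_indel",
    "nonframeshift_indel",
    "splice_site",
)

#: The ten in-silico predictors whose calls feed the consensus class,
#: in fixed column order (dbNSFP naming).
PREDICTOR_TOOLS = (
    "SIFT",
    "Polyphen2_HDIV",
    "Polyphen2_HVAR",
    "LRT",
    "MutationTaster",
    "MutationAssessor",
    "FATHMM",
    "RadialSVM",
    "LR",
    "MetaSVM",
)

#: Reference population-frequency databases.
FREQ_DBS = ("ESP6500", "1000G", "ExAC")

#: Clinical arms.  CONTROL is the unaffected comparison group whose
#: observed variants are subtracted during filtering.
PATIENT_SUBGROUPS = ("CHD_VT", "DCM_VT", "iVT")
SUBGROUPS = PATIENT_SUBGROUPS + ("CONTROL",)

#: The seven molecular function / subcellular-association categories
#: used to stratify variant distributions.
CATEGORIES = (
    "cell_membrane",
    "cytoskeleton",
    "sarcomere",
    "metabolism",
    "intercalated_disc",
    "ion_flux",
    "nucleus",
)

ZYGOSITIES = ("het", "hom")
ACMG_TIERS = ("pathogenic", "likely_pathogenic", "VUS", "likely_benign", "benign")
NYHA_CLASSES = ("I", "II", "III", "IV")
FAMILIAL_STATES = ("familial", "sporadic", "unknown")


class SchemaError(ValueError):
    """A table is missing a required column or uses an unknown label."""


class IntegrityError(ValueError):
    """Cross-table references or uniqueness constraints are violated."""


class ConfigError(ValueError):
    """An invalid configuration value."""


@dataclass(frozen=True)
class PredictorPanel:
    """Verdicts of the ten predictors for one variant.

    ``calls`` maps every tool in :data:`PREDICTOR_TOOLS` to one of
    ``"damaging"``, ``"tolerated"`` or ``"missing"`` (no dbNSFP entry).
    """

    calls: Mapping[str, str]

    def __post_init__(self) -> None:
        if tuple(self.calls) != PREDICTOR_TOOLS:
            missing = set(PREDICTOR_TOOLS) - set(self.calls)
            extra = set(self.calls) - set(PREDICTOR_TOOLS)
            raise SchemaError(
                f"predictor panel must have exactly the 10 known tools in "
                f"fixed order (missing={sorted(missing)}, extra={sorted(extra)})"
            )
        bad = {t: v for t, v in self.calls.items() if v not in ("damaging", "tolerated", "missing")}
        if bad:
            raise SchemaError(f"unknown predictor verdicts: {bad}")

    @property
    def damaging_count(self) -> int:
        return sum(1 for v in self.calls.values() if v == "damaging")

    @property
    def n_available(self) -> int:
        return sum(1 for v in self.calls.values() if v != "missing")

    def to_string(self) -> str:
        """Encode as a 10-character string over ``{D, T, .}`` in tool order."""
        code = {"damaging": "D", "tolerated": "T", "missing": "."}
        return "".join(code[self.calls[t]] for t in PREDICTOR_TOOLS)

    @classmethod
    def from_string(cls, s: str) -> "PredictorPanel":
        if len(s) != 10 or any(c not in "DT." for c in s):
            raise SchemaError(f"PRED string must be 10 characters over D/T/., got {s!r}")
        decode = {"D": "damaging", "T": "tolerated", ".": "missing"}
        return cls(calls={t: decode[c] for t, c in zip(PREDICTOR_TOOLS, s)})

    @classmethod
    def from_damaging(cls, n_damaging: int, damaging_slots: Optional[Iterable[int]] = None) -> "PredictorPanel":
        """Panel with ``n_damaging`` damaging calls (first slots by default)."""
        if not 0 <= n_damaging <= 10:
            raise ConfigError(f"damaging count must be 0-10, got {n_damaging}")
        slots = set(range(n_damaging)) if damaging_slots is None else set(damaging_slots)
        return cls(
            calls={
                t: ("damaging" if i in slots else "tolerated")
                for i, t in enumerate(PREDICTOR_TOOLS)
            }
        )


@dataclass(frozen=True)
class Variant:
    """One unique genomic alteration with its annotations.

    Coordinates are 1-based VCF convention.  ``ref_freqs`` holds allele
    frequencies only for databases in which the variant was observed;
    ``dbsnp130`` is membership, not a frequency.
    """

    variant_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    effect: str
    ref_freqs: Mapping[str, float] = field(default_factory=dict)
    dbsnp130: bool = False
    hgmd_id: Optional[str] = None
    clinvar_assertion: Optional[str] = None
    predictor_calls: Optional[PredictorPanel] = None
    phylop100: Optional[float] = None
    siphy29: Optional[float] = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise SchemaError(f"{self.variant_id}: position must be >= 1, got {self.pos}")
        if self.effect not in EFFECTS:
            raise SchemaError(f"{self.variant_id}: unknown effect {self.effect!r}")
        unknown = set(self.ref_freqs) - set(FREQ_DBS)
        if unknown:
            raise SchemaError(f"{self.variant_id}: unknown frequency dbs {sorted(unknown)}")
        # frequency *range* is checked by validate_cohort, so that faulty
        # tables can be ingested and reported rather than half-read
        if self.clinvar_assertion is not None and self.clinvar_assertion not in ACMG_TIERS:
            raise SchemaError(
                f"{self.variant_id}: unknown clinvar assertion {self.clinvar_assertion!r}"
            )

    def freq(self, db: str) -> Optional[float]:
        """Frequency in ``db``, or None when the variant is absent from it."""
        return self.ref_freqs.get(db)

    def with_(self, **changes) -> "Variant":
        return replace(self, **changes)


@dataclass
class PatientRecord:
    """One subject: clinical arm, covariates and carried-variant set.

    Clinical covariates are None when not recorded (the control arm has
    no cardiology work-up).  ``carried`` maps variant_id to zygosity;
    burden statistics count carriers, zygosity is retained for
    extensibility only.
    """

    patient_id: str
    subgroup: str
    age: Optional[float] = None
    sex: Optional[str] = None
    bmi: Optional[float] = None
    nyha: Optional[str] = None
    lvef: Optional[float] = None
    la: Optional[float] = None
    lv_edd: Optional[float] = None
    lv_esd: Optional[float] = None
    qrs: Optional[float] = None
    qt: Optional[float] = None
    familial: Optional[str] = None
    carried: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.subgroup not in SUBGROUPS:
            raise SchemaError(f"{self.patient_id}: unknown subgroup {self.subgroup!r}")
        if self.sex is not None and self.sex not in ("F", "M"):
            raise SchemaError(f"{self.patient_id}: sex must be F or M, got {self.sex!r}")
        if self.nyha is not None and self.nyha not in NYHA_CLASSES:
            raise SchemaError(f"{self.patient_id}: unknown NYHA class {self.nyha!r}")
        if self.familial is not None and self.familial not in FAMILIAL_STATES:
            raise SchemaError(f"{self.patient_id}: unknown familial state {self.familial!r}")

    CLINICAL_FIELDS = ("age", "bmi", "lvef", "la", "lv_edd", "lv_esd", "qrs", "qt")


@dataclass
class Cohort:
    """Cross-linked variant table + patient table."""

    variants: list
    patients: list

    def __post_init__(self) -> None:
        ids = [v.variant_id for v in self.variants]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise IntegrityError(f"duplicate variant_ids: {dupes[:10]}")
        self._by_id = {v.variant_id: v for v in self.variants}

    def variant(self, variant_id: str) -> Variant:
        return self._by_id[variant_id]

    @property
    def variant_ids(self) -> set:
        return set(self._by_id)

    def subgroup_counts(self) -> dict:
        counts: dict = {}
        for p in self.patients:
            counts[p.subgroup] = counts.get(p.subgroup, 0) + 1
        return counts

    def patients_in(self, subgroup: str) -> list:
        return [p for p in self.patients if p.subgroup == subgroup]

    def n_carried_instances(self) -> int:
        return sum(len(p.carried) for p in self.patients)


@dataclass(frozen=True)
class GeneCategoryMap:
    """Gene symbol -> one of the seven molecular-function categories."""

    mapping: Mapping[str, str]

    def __post_init__(self) -> None:
        bad = {g: c for g, c in self.mapping.items() if c not in CATEGORIES}
        if bad:
            raise SchemaError(f"unknown categories: {bad}")

    def category(self, gene: str) -> str:
        try:
            return self.mapping[gene]
        except KeyError:
            raise SchemaError(f"gene {gene!r} has no functional category") from None

    def check_covers(self, genes: Iterable[str]) -> None:
        missing = sorted(set(genes) - set(self.mapping))
        if missing:
            raise SchemaError(f"genes without functional category: {missing}")

    @property
    def genes(self) -> set:
        return set(self.mapping)


@dataclass(frozen=True)
class Violation:
    subject: str  # patient_id or variant_id
    field: str
    message: str


def validate_cohort(cohort: Cohort) -> list:
    """Report every invariant violation in a cohort; empty iff consistent.

    This is a reporting operation: inconsistencies that the constructors
    cannot see (cross-table links, sign constraints on covariates that
    are stored but implausible) are collected rather than raised.
    """
    violations: list = []
    known_ids = cohort.variant_ids
    seen_patients: set = set()
    for p in cohort.patients:
        if p.patient_id in seen_patients:
            violations.append(Violation(p.patient_id, "patient_id", "duplicate patient_id"))
        seen_patients.add(p.patient_id)
        for fname in PatientRecord.CLINICAL_FIELDS:
            value = getattr(p, fname)
            if value is not None and value < 0:
                violations.append(
                    Violation(p.patient_id, fname, f"negative clinical value {value}")
                )
        dangling = sorted(set(p.carried) - known_ids)
        for vid in dangling:
            violations.append(
                Violation(p.patient_id, "carried", f"carried variant_id {vid} not in variant table")
            )
        for vid, zyg in p.carried.items():
            if zyg not in ZYGOSITIES:
                violations.append(Violation(p.patient_id, "carried", f"unknown zygosity {zyg!r}"))
    for v in cohort.variants:
        for db, f in v.ref_freqs.items():
            if not 0.0 <= f <= 1.0:
                violations.append(
                    Violation(v.variant_id, "ref_freqs", f"{db} frequency {f} outside [0, 1]")
                )
    return violations
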
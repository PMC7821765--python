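"""Stepwise rare-variant filtering cascade.

Raw panel calls are reduced to the analysis set in four ordered stages:

1. common-variant removal — frequency strictly above the MAF cutoff
   (default 0.5%) in *any* of the listed reference databases, or
   membership in dbSNP130 when that database is listed;
2. synonymous removal — ``synonymous_snv`` effects are dropped, every
   other coding effect (stop-gain, indels, splice) is kept;
3. control subtraction — variants observed in the unaffected comparison
   group are dropped by variant_id;
4. curation — a reproducible, user-supplied exclusion list (empty by
   default).

A variant absent from every reference database cannot exceed the cutoff
and is therefore rare.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Set, Tuple

from .model import ConfigError, FREQ_DBS, Variant

__all__ = [
    "DEFAULT_MAF_CUTOFF",
    "DEFAULT_REMOVAL_DBS",
    "FilterStage",
    "FilterTrace",
    "flag_common",
    "flag_synonymous",
    "subtract_control",
    "run_cascade",
]

DEFAULT_MAF_CUTOFF = 0.005

#: Databases consulted for common-variant removal.  ExAC is annotated and
#: used for frequency averaging but is not a removal database by default.
DEFAULT_REMOVAL_DBS = ("ESP6500", "1000G", "dbSNP130")

_KNOWN_DBS = set(FREQ_DBS) | {"dbSNP130"}


@dataclass(frozen=True)
class FilterStage:
    name: str
    n_input: int
    n_removed: int
    n_kept: int
    removed_ids: Tuple[str, ...]

    def __post_init__(self) -> None:
        assert self.n_input == self.n_removed + self.n_kept


@dataclass
class FilterTrace:
    """Per-stage accounting: input, removed and kept counts plus ids."""

    stages: List[FilterStage] = field(default_factory=list)

    def add(self, name: str, n_input: int, removed_ids: Sequence[str]) -> None:
        self.stages.append(
            FilterStage(
                name=name,
                n_input=n_input,
                n_removed=len(removed_ids),
                n_kept=n_input - len(removed_ids),
                removed_ids=tuple(removed_ids),
            )
        )

    def check(self) -> None:
        """Assert stage chaining: each stage's kept is the next one's input."""
        for prev, nxt in zip(self.stages, self.stages[1:]):
            if prev.n_kept != nxt.n_input:
                raise AssertionError(
                    f"trace broken between {prev.name!r} ({prev.n_kept} kept) "
                    f"and {nxt.name!r} ({nxt.n_input} input)"
                )

    def stage(self, name: str) -> FilterStage:
        for s in self.stages:
            if s.name == name:
                return s
        raise KeyError(name)

    def to_rows(self) -> List[dict]:
        return [
            {
                "stage": s.name,
                "n_input": s.n_input,
                "n_removed": s.n_removed,
                "n_kept": s.n_kept,
            }
            for s in self.stages
        ]


def is_common(
    variant: Variant,
    maf_cutoff: float = DEFAULT_MAF_CUTOFF,
    dbs: Sequence[str] = DEFAULT_REMOVAL_DBS,
) -> bool:
    """Common iff frequency strictly exceeds the cutoff in any listed
    frequency database, or the variant is a dbSNP130 member when listed."""
    for db in dbs:
        if db == "dbSNP130":
            if variant.dbsnp130:
                return True
        else:
            f = variant.freq(db)
            if f is not None and f > maf_cutoff:
                return True
    return False


def _check_filter_args(maf_cutoff: float, dbs: Sequence[str]) -> None:
    if not 0.0 < maf_cutoff < 1.0:
        raise ConfigError(f"maf_cutoff must be in (0, 1), got {maf_cutoff}")
    if not dbs:
        raise ConfigError("at least one removal database must be listed")
    unknown = set(dbs) - _KNOWN_DBS
    if unknown:
        raise ConfigError(f"unknown reference dbs: {sorted(unknown)}")


def flag_common(
    variants: Iterable[Variant],
    maf_cutoff: float = DEFAULT_MAF_CUTOFF,
    dbs: Sequence[str] = DEFAULT_REMOVAL_DBS,
) -> Tuple[List[Variant], List[Variant]]:
    """Partition into (common, rare)."""
    _check_filter_args(maf_cutoff, dbs)
    common, rare = [], []
    for v in variants:
        (common if is_common(v, maf_cutoff, dbs) else rare).append(v)
    return common, rare


def flag_synonymous(variants: Iterable[Variant]) -> Tuple[List[Variant], List[Variant]]:
    """Partition into (synonymous, non_synonymous)."""
    synonymous, non_synonymous = [], []
    for v in variants:
        (synonymous if v.effect == "synonymous_snv" else non_synonymous).append(v)
    return synonymous, non_synonymous


def subtract_control(
    variants: Iterable[Variant], control_observed_ids: Set[str]
) -> Tuple[List[Variant], List[Variant]]:
    """Partition into (shared-with-control, patient_only) by variant_id."""
    shared, patient_only = [], []
    for v in variants:
        (shared if v.variant_id in control_observed_ids else patient_only).append(v)
    return shared, patient_only


def run_cascade(
    variants: Sequence[Variant],
    control_ids: Optional[Set[str]] = None,
    curation_exclusions: Optional[Set[str]] = None,
    maf_cutoff: float = DEFAULT_MAF_CUTOFF,
    dbs: Sequence[str] = DEFAULT_REMOVAL_DBS,
) -> Tuple[List[Variant], FilterTrace]:
    """Run the full four-stage cascade; returns (analysis set, trace)."""
    control_ids = control_ids or set()
    curation_exclusions = set(curation_exclusions or set())
    trace = FilterTrace()

    common, kept = flag_common(variants, maf_cutoff, dbs)
    trace.add("common_removal", len(variants), [v.variant_id for v in common])

    synonymous, kept = flag_synonymous(kept)
    trace.add("synonymous_removal", len(kept) + len(synonymous), [v.variant_id for v in synonymous])

    shared, kept = subtract_control(kept, control_ids)
    trace.add("control_subtraction", len(kept) + len(shared), [v.variant_id for v in shared])

    surviving_ids = {v.variant_id for v in kept}
    stale = curation_exclusions - surviving_ids
    if stale:
        warnings.warn(
            f"curation exclusions not in surviving set (ignored): {sorted(stale)[:10]}",
            stacklevel=2,
        )
    excluded = [v for v in kept if v.variant_id in curation_exclusions]
    kept = [v for v in kept if v.variant_id not in curation_exclusions]
    trace.add("curation", len(kept) + len(excluded), [v.variant_id for v in excluded])

    trace.check()
    return kept, trace
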
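"""Synthetic cohort generator.

Emulates the statistical structure the downstream analysis assumes: a
96-gene panel yielding ~2,400 raw called variants that collapse to ~340
rare unique non-synonymous variants after filtering; ten predictor
calls whose damaging count is tied to a latent pathogenicity class;
a reference-frequency spectrum in which severer classes are rarer; and
per-arm carriage rates and clinical covariates shaped like a
three-arm ventricular-tachycardia cohort with an unaffected control
group.

The latent class is simulated *first* and predictor calls second — the
inverse of the analysis direction — so that ground truth exists for
recovery tests.  Every piece of randomness flows from a single seed;
runs are bit-identical for a fixed configuration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Tuple

import numpy as np
import yaml

from .model import (
    Cohort,
    ConfigError,
    PatientRecord,
    PredictorPanel,
    PREDICTOR_TOOLS,
    PATIENT_SUBGROUPS,
    Variant,
)

__all__ = [
    "SimConfig",
    "GroundTruth",
    "simulate_predictor_calls",
    "simulate_variant_pool",
    "simulate_cohort",
]

#: damaging-count band per latent class
CLASS_BANDS = {"I": (7, 10), "II": (4, 6), "III": (1, 3), "IV": (0, 0)}
LATENT_CLASSES = ("I", "II", "III", "IV")

# Location/scale defaults per clinical arm.  Symmetric covariates are
# normal (mean, sd); echocardiographic covariates are logistic
# (median, 25th, 75th percentile), which matches a median/IQR
# parameterization while allowing light tails.
_NORMAL_COVARIATES = {
    #          CHD_VT          DCM_VT          iVT             CONTROL
    "age": ((62.3, 8.8), (43.0, 13.3), (37.1, 19.2), (37.5, 10.9)),
    "bmi": ((27.9, 5.5), (27.0, 7.2), (24.9, 5.6), (25.0, 4.0)),
    "qrs": ((112.4, 29.7), (117.4, 27.3), (89.9, 15.4), None),
    "qt": ((401.5, 72.0), (389.0, 38.0), (400.5, 44.8), None),
}
_LOGISTIC_COVARIATES = {
    "lvef": ((35.0, 26.13, 45.0), (24.5, 18.25, 30.0), (61.29, 57.13, 67.48), None),
    "la": ((44.0, 37.0, 46.0), (45.5, 42.0, 49.75), (31.0, 26.6, 35.0), None),
    "lv_edd": ((6.1, 5.7, 6.6), (6.87, 6.33, 7.45), (4.7, 4.22, 4.97), None),
    "lv_esd": ((4.8, 4.0, 5.9), (5.92, 5.63, 6.5), (3.2, 2.63, 3.5), None),
}
_COVARIATE_BOUNDS = {
    "age": (18.0, 95.0),
    "bmi": (14.0, 55.0),
    "qrs": (50.0, 250.0),
    "qt": (250.0, 650.0),
    "lvef": (5.0, 85.0),
    "la": (15.0, 75.0),
    "lv_edd": (2.5, 10.0),
    "lv_esd": (1.5, 9.0),
}
_SEX_MALE_P = {"CHD_VT": 22 / 23, "DCM_VT": 21 / 32, "iVT": 16 / 37, "CONTROL": 0.63}
_NYHA_P = {
    "CHD_VT": (1 / 23, 6 / 23, 16 / 23, 0.0),
    "DCM_VT": (1 / 32, 1 / 32, 20 / 32, 10 / 32),
    "iVT": (25 / 37, 11 / 37, 1 / 37, 0.0),
}
_FAMILIAL_P = {
    "CHD_VT": (6 / 23, 17 / 23, 0.0),
    "DCM_VT": (8 / 32, 24 / 32, 0.0),
    "iVT": (11 / 37, 24 / 37, 2 / 37),
}


def _default_n_per_subgroup() -> Dict[str, int]:
    return {"CHD_VT": 23, "DCM_VT": 32, "iVT": 37, "CONTROL": 60}


def _default_class_mix() -> Tuple[float, ...]:
    # unique-variant class proportions of the analysis set (48/70/156/33 of 307)
    return (48 / 307, 70 / 307, 156 / 307, 33 / 307)


def _default_carrier_rate() -> Dict[str, Tuple[float, ...]]:
    # expected carried variants per patient, per latent class I..IV,
    # chosen so the cumulative per-arm burden matches a 92-patient VT
    # cohort (class-specific instance totals / arm size)
    return {
        "CHD_VT": (13 / 23, 18 / 23, 58 / 23, 21 / 23),
        "DCM_VT": (13 / 32, 36 / 32, 82 / 32, 28 / 32),
        "iVT": (26 / 37, 44 / 37, 90 / 37, 27 / 37),
    }


def _default_maf_mean_by_class() -> Tuple[float, ...]:
    # target mean reference frequency per class; severer classes rarer
    return (0.000279, 0.00267, 0.00372, 0.0192)


@dataclass
class SimConfig:
    """Generator configuration; defaults are the emulated study conditions."""

    n_per_subgroup: Dict[str, int] = field(default_factory=_default_n_per_subgroup)
    n_genes: int = 96
    n_raw_variants: int = 2403
    frac_common: float = 0.63
    frac_synonymous: float = 0.53  # among non-common calls
    control_overlap: float = 0.19  # rare non-synonymous variants also seen in controls
    class_mix: Tuple[float, ...] = field(default_factory=_default_class_mix)
    maf_mean_by_class: Tuple[float, ...] = field(default_factory=_default_maf_mean_by_class)
    p_absent_by_class: Tuple[float, ...] = (0.70, 0.40, 0.30, 0.05)
    maf_sigma: float = 1.0
    hgmd_rate: float = 0.20
    missing_call_rate: float = 0.0
    effect_mix: Dict[str, float] = field(
        default_factory=lambda: {
            "nonsynonymous_snv": 0.961,
            "stopgain": 0.023,
            "splice_site": 0.013,
            "frameshift_indel": 0.003,
        }
    )
    carrier_rate: Dict[str, Tuple[float, ...]] = field(default_factory=_default_carrier_rate)
    control_carried_rate: float = 2.0  # carried control-pool variants per control subject
    gene_weights: Optional[List[float]] = None  # per-gene variant density; uniform if None
    seed: int = 0

    def validate(self) -> None:
        if any(n < 1 for n in self.n_per_subgroup.values()):
            raise ConfigError("every subgroup needs n >= 1")
        for name, p in [
            ("frac_common", self.frac_common),
            ("frac_synonymous", self.frac_synonymous),
            ("control_overlap", self.control_overlap),
            ("hgmd_rate", self.hgmd_rate),
            ("missing_call_rate", self.missing_call_rate),
        ]:
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {p}")
        if len(self.class_mix) != 4 or any(w < 0 for w in self.class_mix):
            raise ConfigError("class_mix must be 4 nonnegative weights")
        if not math.isclose(sum(self.class_mix), 1.0, abs_tol=1e-6):
            raise ConfigError(f"class_mix must sum to 1, got {sum(self.class_mix)}")
        if self.n_raw_variants < 1 and any(w > 0 for w in self.class_mix):
            raise ConfigError("zero variants cannot satisfy a nonzero class demand")
        if not math.isclose(sum(self.effect_mix.values()), 1.0, abs_tol=1e-6):
            raise ConfigError("effect_mix must sum to 1")

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        for key in ("class_mix", "maf_mean_by_class", "p_absent_by_class"):
            setattr(cfg, key, tuple(getattr(cfg, key)))
        cfg.carrier_rate = {k: tuple(v) for k, v in cfg.carrier_rate.items()}
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


@dataclass
class GroundTruth:
    """The generator's ledger: what was simulated, per variant and carriage."""

    variants: "object"  # pandas.DataFrame: variant-level truth
    carriage: "object"  # pandas.DataFrame: (patient_id, variant_id, latent_class)

    def control_observed_ids(self) -> set:
        df = self.variants
        return set(df.loc[df["in_control"], "variant_id"])

    def analysis_ids(self) -> set:
        df = self.variants
        keep = (~df["is_common"]) & (~df["is_synonymous"]) & (~df["in_control"])
        return set(df.loc[keep, "variant_id"])


def simulate_predictor_calls(
    latent_class: str, rng: np.random.Generator, missing_call_rate: float = 0.0
) -> PredictorPanel:
    """Draw a 10-tool panel whose damaging count falls in the latent
    class's defining band (uniform within band); each call is then
    independently replaced by ``missing`` at ``missing_call_rate``."""
    if latent_class not in CLASS_BANDS:
        raise ConfigError(f"unknown latent class {latent_class!r}")
    lo, hi = CLASS_BANDS[latent_class]
    n_damaging = int(rng.integers(lo, hi + 1))
    slots = rng.choice(10, size=n_damaging, replace=False) if n_damaging else []
    calls = {}
    for i, tool in enumerate(PREDICTOR_TOOLS):
        if missing_call_rate > 0 and rng.random() < missing_call_rate:
            calls[tool] = "missing"
        elif i in set(int(s) for s in slots):
            calls[tool] = "damaging"
        else:
            calls[tool] = "tolerated"
    return PredictorPanel(calls=calls)


def _panel_genes(n_genes: int) -> List[str]:
    from .io import default_gene_categories

    genes = sorted(default_gene_categories().genes)
    if n_genes <= len(genes):
        return genes[:n_genes]
    return genes + [f"GENE{i}" for i in range(len(genes), n_genes)]


def _draw_freqs(
    mean_target: float, p_absent: float, sigma: float, rng: np.random.Generator,
    cutoff: float = 0.005,
) -> Dict[str, float]:
    """Reference-db frequencies for one rare variant.

    With probability ``p_absent`` the variant is unobserved everywhere.
    Otherwise the per-variant mean frequency is lognormal with mean
    ``mean_target / (1 - p_absent)`` (so the class mean, zeros
    included, lands on target); the two removal databases are capped at
    the rarity cutoff and the balance is pushed into ExAC, which does
    not participate in removal.
    """
    if rng.random() < p_absent:
        return {}
    mu = math.log(mean_target / (1.0 - p_absent)) - sigma**2 / 2.0
    m_v = min(float(rng.lognormal(mu, sigma)), 0.3)
    present = {"ExAC"}
    if rng.random() < 0.7:
        present.add("ESP6500")
    if rng.random() < 0.7:
        present.add("1000G")
    freqs = {}
    for db in ("ESP6500", "1000G"):
        if db in present:
            freqs[db] = min(m_v * float(rng.uniform(0.3, 1.2)), cutoff)
    # ExAC balances so the mean over present dbs equals m_v exactly
    freqs["ExAC"] = min(max(len(present) * m_v - sum(freqs.values()), 0.0), 1.0)
    return freqs


def simulate_variant_pool(config: SimConfig, rng: Optional[np.random.Generator] = None):
    """Draw the raw called-variant pool plus its ground-truth table.

    Returns ``(variants, truth_df)`` where ``truth_df`` has one row per
    variant with its latent class and the flags (is_common,
    is_synonymous, in_control) that determine its fate in the cascade.
    """
    import pandas as pd

    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    genes = _panel_genes(config.n_genes)
    weights = None
    if config.gene_weights is not None:
        w = np.asarray(config.gene_weights, dtype=float)
        if w.size != len(genes) or (w < 0).any() or w.sum() == 0:
            raise ConfigError("gene_weights must be nonnegative, one per gene, not all zero")
        weights = w / w.sum()

    n = config.n_raw_variants
    n_common = int(round(config.frac_common * n))
    n_rest = n - n_common
    n_syn = int(round(config.frac_synonymous * n_rest))

    kinds = ["common"] * n_common + ["synonymous"] * n_syn + ["rare_nonsyn"] * (n_rest - n_syn)
    gene_idx = rng.choice(len(genes), size=n, p=weights)
    latent = rng.choice(LATENT_CLASSES, size=n, p=np.asarray(config.class_mix))
    class_idx = {c: i for i, c in enumerate(LATENT_CLASSES)}

    variants: List[Variant] = []
    rows = []
    effects, effect_ps = zip(*config.effect_mix.items())
    for i, kind in enumerate(kinds):
        vid = f"var{i:05d}"
        cls = str(latent[i])
        gene = genes[int(gene_idx[i])]
        panel = simulate_predictor_calls(cls, rng, config.missing_call_rate)
        in_control = False
        if kind == "common":
            effect = "synonymous_snv" if rng.random() < 0.5 else "nonsynonymous_snv"
            dbsnp = bool(rng.random() < 0.8)
            f = float(rng.uniform(0.01, 0.30))
            freqs = {
                "ESP6500": f * float(rng.uniform(0.8, 1.2)),
                "1000G": f * float(rng.uniform(0.8, 1.2)),
                "ExAC": f * float(rng.uniform(0.8, 1.2)),
            }
            freqs = {db: min(x, 0.5) for db, x in freqs.items()}
            if not dbsnp and max(freqs.values()) <= 0.005:
                freqs["ESP6500"] = 0.02  # guarantee the common rule fires
        elif kind == "synonymous":
            effect = "synonymous_snv"
            dbsnp = False
            k = class_idx[cls]
            freqs = _draw_freqs(
                config.maf_mean_by_class[k], config.p_absent_by_class[k], config.maf_sigma, rng
            )
        else:
            effect = str(rng.choice(effects, p=np.asarray(effect_ps)))
            dbsnp = False
            k = class_idx[cls]
            freqs = _draw_freqs(
                config.maf_mean_by_class[k], config.p_absent_by_class[k], config.maf_sigma, rng
            )
            in_control = bool(rng.random() < config.control_overlap)
        if effect in ("frameshift_indel", "nonframeshift_indel"):
            ref, alt = "AT", "A"
        else:
            ref, alt = "A", "G"
        variants.append(
            Variant(
                variant_id=vid,
                chrom=f"chr{1 + int(gene_idx[i]) % 22}",
                pos=int(rng.integers(1, 2_000_000)),
                ref=ref,
                alt=alt,
                gene=gene,
                effect=effect,
                ref_freqs=freqs,
                dbsnp130=dbsnp,
                hgmd_id=(
                    f"CM{int(rng.integers(100000, 999999))}"
                    if kind == "rare_nonsyn" and rng.random() < config.hgmd_rate
                    else None
                ),
                predictor_calls=panel,
            )
        )
        rows.append(
            {
                "variant_id": vid,
                "gene": gene,
                "latent_class": cls,
                "damaging_count": panel.damaging_count,
                "is_common": kind == "common",
                "is_synonymous": effect == "synonymous_snv",
                "in_control": in_control,
                "hgmd": variants[-1].hgmd_id is not None,
            }
        )
    return variants, pd.DataFrame(rows)


def _draw_clinical(subgroup: str, rng: np.random.Generator) -> dict:
    col = {"CHD_VT": 0, "DCM_VT": 1, "iVT": 2, "CONTROL": 3}[subgroup]
    values: dict = {}
    for name, params in _NORMAL_COVARIATES.items():
        p = params[col]
        if p is None:
            values[name] = None
            continue
        lo, hi = _COVARIATE_BOUNDS[name]
        values[name] = float(np.clip(rng.normal(p[0], p[1]), lo, hi))
    for name, params in _LOGISTIC_COVARIATES.items():
        p = params[col]
        if p is None:
            values[name] = None
            continue
        median, q25, q75 = p
        scale = (q75 - q25) / (2.0 * math.log(3.0))
        lo, hi = _COVARIATE_BOUNDS[name]
        values[name] = float(np.clip(rng.logistic(median, scale), lo, hi))
    values["sex"] = "M" if rng.random() < _SEX_MALE_P[subgroup] else "F"
    if subgroup in _NYHA_P:
        values["nyha"] = str(rng.choice(["I", "II", "III", "IV"], p=np.asarray(_NYHA_P[subgroup])))
        values["familial"] = str(
            rng.choice(["familial", "sporadic", "unknown"], p=np.asarray(_FAMILIAL_P[subgroup]))
        )
    else:
        values["nyha"] = None
        values["familial"] = None
    return values


def simulate_cohort(config: SimConfig):
    """Simulate the full cohort.

    Returns ``(cohort, truth)``.  Patient carriage is drawn per latent
    class as Poisson counts with the configured per-arm rates, sampling
    distinct variants from the class's analysis-set pool; control
    subjects carry variants from the control-observed pool.
    """
    import pandas as pd

    config.validate()
    rng = np.random.default_rng(config.seed)
    variants, truth_df = simulate_variant_pool(config, rng)

    analysis = truth_df[
        ~truth_df["is_common"] & ~truth_df["is_synonymous"] & ~truth_df["in_control"]
    ]
    pools = {
        c: list(analysis.loc[analysis["latent_class"] == c, "variant_id"])
        for c in LATENT_CLASSES
    }
    control_pool = list(truth_df.loc[truth_df["in_control"], "variant_id"])

    patients: List[PatientRecord] = []
    carriage_rows = []
    class_of = dict(zip(truth_df["variant_id"], truth_df["latent_class"]))
    for subgroup in PATIENT_SUBGROUPS + ("CONTROL",):
        n_subjects = config.n_per_subgroup.get(subgroup, 0)
        for j in range(n_subjects):
            pid = f"{subgroup}_{j:03d}"
            clin = _draw_clinical(subgroup, rng)
            carried: Dict[str, str] = {}
            if subgroup == "CONTROL":
                if control_pool:
                    k = min(int(rng.poisson(config.control_carried_rate)), len(control_pool))
                    for vid in rng.choice(control_pool, size=k, replace=False):
                        carried[str(vid)] = "het"
            else:
                rates = config.carrier_rate[subgroup]
                for c, rate in zip(LATENT_CLASSES, rates):
                    pool = pools[c]
                    if not pool or rate <= 0:
                        continue
                    k = min(int(rng.poisson(rate)), len(pool))
                    for vid in rng.choice(pool, size=k, replace=False):
                        carried[str(vid)] = "hom" if rng.random() < 0.05 else "het"
            for vid in carried:
                carriage_rows.append(
                    {"patient_id": pid, "variant_id": vid, "latent_class": class_of[vid]}
                )
            patients.append(
                PatientRecord(
                    patient_id=pid,
                    subgroup=subgroup,
                    age=clin["age"],
                    sex=clin["sex"],
                    bmi=clin["bmi"],
                    nyha=clin["nyha"],
                    lvef=clin["lvef"],
                    la=clin["la"],
                    lv_edd=clin["lv_edd"],
                    lv_esd=clin["lv_esd"],
                    qrs=clin["qrs"],
                    qt=clin["qt"],
                    familial=clin["familial"],
                    carried=carried,
                )
            )
    cohort = Cohort(variants=variants, patients=patients)
    truth = GroundTruth(
        variants=truth_df,
        carriage=pd.DataFrame(carriage_rows, columns=["patient_id", "variant_id", "latent_class"]),
    )
    return cohort, truth
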
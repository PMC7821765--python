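"""Readers and writers for the pipeline's tabular interchange formats.

Four on-disk artifacts:

* variant table — tab-delimited with a fixed header (or VCF 4.2 with the
  equivalent INFO keys); one row per unique variant;
* patient metadata — CSV, one row per subject;
* genotype table — CSV triples (patient_id, variant_id, zygosity);
* gene-category map — two-column TSV.

Empty cells round-trip to explicit absence, never to 0.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, List, Optional

from .model import (
    FREQ_DBS,
    Cohort,
    GeneCategoryMap,
    IntegrityError,
    PatientRecord,
    PredictorPanel,
    SchemaError,
    Variant,
)

VARIANT_COLUMNS = [
    "variant_id",
    "chrom",
    "pos",
    "ref",
    "alt",
    "gene",
    "effect",
    "af_esp6500",
    "af_1000g",
    "af_exac",
    "dbsnp130",
    "hgmd_id",
    "clinvar",
    "pred",
    "phylop100",
    "siphy29",
]

_FREQ_COLS = {"ESP6500": "af_esp6500", "1000G": "af_1000g", "ExAC": "af_exac"}

PATIENT_COLUMNS = [
    "patient_id",
    "subgroup",
    "age",
    "sex",
    "bmi",
    "nyha",
    "lvef",
    "la",
    "lv_edd",
    "lv_esd",
    "qrs",
    "qt",
    "familial",
]

GENOTYPE_COLUMNS = ["patient_id", "variant_id", "zygosity"]

#: INFO keys of the VCF dialect, mirroring the TSV columns.
VCF_INFO_KEYS = (
    "GENE",
    "EFFECT",
    "AF_ESP6500",
    "AF_1000G",
    "AF_EXAC",
    "DBSNP130",
    "HGMD",
    "CLINVAR",
    "PRED",
)


def _parse_float(cell: str, line_no: int, column: str) -> Optional[float]:
    cell = cell.strip()
    if cell == "":
        return None
    try:
        return float(cell)
    except ValueError:
        raise SchemaError(f"line {line_no}: unparsable {column} value {cell!r}") from None


def _left_normalize(pos: int, ref: str, alt: str) -> tuple:
    """Trim the shared suffix then shared prefix of an indel allele pair."""
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def _row_to_variant(row: dict, line_no: int) -> Variant:
    freqs = {}
    for db, col in _FREQ_COLS.items():
        f = _parse_float(row[col], line_no, col)
        if f is not None:
            freqs[db] = f
    pos_raw = row["pos"].strip()
    try:
        pos = int(pos_raw)
    except ValueError:
        raise SchemaError(f"line {line_no}: unparsable pos value {pos_raw!r}") from None
    pos, ref, alt = _left_normalize(pos, row["ref"].strip(), row["alt"].strip())
    pred = row["pred"].strip()
    return Variant(
        variant_id=row["variant_id"].strip(),
        chrom=row["chrom"].strip(),
        pos=pos,
        ref=ref,
        alt=alt,
        gene=row["gene"].strip(),
        effect=row["effect"].strip(),
        ref_freqs=freqs,
        dbsnp130=row["dbsnp130"].strip() in ("1", "yes", "true"),
        hgmd_id=row["hgmd_id"].strip() or None,
        clinvar_assertion=row["clinvar"].strip() or None,
        predictor_calls=PredictorPanel.from_string(pred) if pred else None,
        phylop100=_parse_float(row["phylop100"], line_no, "phylop100"),
        siphy29=_parse_float(row["siphy29"], line_no, "siphy29"),
    )


def read_variant_table(path, dialect: str = "tsv") -> List[Variant]:
    """Read an annotated variant table (``tsv`` or ``vcf`` dialect).

    Row order is preserved; absent annotations stay absent.  Raises
    :class:`SchemaError` for missing columns and :class:`IntegrityError`
    for duplicate variant ids.
    """
    if dialect == "tsv":
        variants = _read_variant_tsv(path)
    elif dialect == "vcf":
        variants = _read_variant_vcf(path)
    else:
        raise SchemaError(f"unknown dialect {dialect!r}; expected 'tsv' or 'vcf'")
    ids = [v.variant_id for v in variants]
    if len(ids) != len(set(ids)):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise IntegrityError(f"duplicate variant_ids in {path}: {dupes[:10]}")
    return variants


def _read_variant_tsv(path) -> List[Variant]:
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        header = reader.fieldnames or []
        missing = [c for c in VARIANT_COLUMNS if c not in header]
        if missing:
            raise SchemaError(f"variant table {path} missing columns: {missing}")
        return [_row_to_variant(row, line_no) for line_no, row in enumerate(reader, start=2)]


def _read_variant_vcf(path) -> List[Variant]:
    from cyvcf2 import VCF

    # float INFO fields are re-parsed from the raw lines: htslib hands
    # back float32, which would break exact write/read round-trips
    raw_infos = []
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#") and line.strip():
                raw_infos.append(line.rstrip("\n").split("\t")[7])

    variants = []
    for rec, raw_info in zip(VCF(str(path)), raw_infos):
        raw = dict(
            kv.split("=", 1) if "=" in kv else (kv, True) for kv in raw_info.split(";")
        )
        freqs = {}
        for db, key in (("ESP6500", "AF_ESP6500"), ("1000G", "AF_1000G"), ("ExAC", "AF_EXAC")):
            if key in raw:
                freqs[db] = float(raw[key])
        pred = rec.INFO.get("PRED")
        alt = rec.ALT[0] if rec.ALT else "."
        pos, ref, alt = _left_normalize(rec.POS, rec.REF, alt)
        variants.append(
            Variant(
                variant_id=rec.ID,
                chrom=rec.CHROM,
                pos=pos,
                ref=ref,
                alt=alt,
                gene=rec.INFO.get("GENE"),
                effect=rec.INFO.get("EFFECT"),
                ref_freqs=freqs,
                dbsnp130=bool(rec.INFO.get("DBSNP130")),
                hgmd_id=rec.INFO.get("HGMD"),
                clinvar_assertion=rec.INFO.get("CLINVAR"),
                predictor_calls=PredictorPanel.from_string(pred) if pred else None,
                phylop100=_maybe_float(raw.get("PHYLOP100")),
                siphy29=_maybe_float(raw.get("SIPHY29")),
            )
        )
    return variants


def _maybe_float(x):
    return None if x is None else float(x)


def _fmt(x) -> str:
    if x is None:
        return ""
    return repr(x) if isinstance(x, float) else str(x)


def write_variant_table(variants: Iterable[Variant], path, dialect: str = "tsv") -> None:
    if dialect == "tsv":
        _write_variant_tsv(variants, path)
    elif dialect == "vcf":
        _write_variant_vcf(variants, path)
    else:
        raise SchemaError(f"unknown dialect {dialect!r}; expected 'tsv' or 'vcf'")


def _write_variant_tsv(variants: Iterable[Variant], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(VARIANT_COLUMNS)
        for v in variants:
            writer.writerow(
                [
                    v.variant_id,
                    v.chrom,
                    v.pos,
                    v.ref,
                    v.alt,
                    v.gene,
                    v.effect,
                    _fmt(v.freq("ESP6500")),
                    _fmt(v.freq("1000G")),
                    _fmt(v.freq("ExAC")),
                    "1" if v.dbsnp130 else "0",
                    v.hgmd_id or "",
                    v.clinvar_assertion or "",
                    v.predictor_calls.to_string() if v.predictor_calls else "",
                    _fmt(v.phylop100),
                    _fmt(v.siphy29),
                ]
            )


_VCF_HEADER = """##fileformat=VCFv4.2
##INFO=<ID=GENE,Number=1,Type=String,Description="HGNC gene symbol">
##INFO=<ID=EFFECT,Number=1,Type=String,Description="Coding effect">
##INFO=<ID=AF_ESP6500,Number=1,Type=Float,Description="ESP6500 allele frequency">
##INFO=<ID=AF_1000G,Number=1,Type=Float,Description="1000 Genomes allele frequency">
##INFO=<ID=AF_EXAC,Number=1,Type=Float,Description="ExAC allele frequency">
##INFO=<ID=DBSNP130,Number=0,Type=Flag,Description="Member of dbSNP build 130">
##INFO=<ID=HGMD,Number=1,Type=String,Description="HGMD accession">
##INFO=<ID=CLINVAR,Number=1,Type=String,Description="ClinVar five-tier assertion">
##INFO=<ID=PRED,Number=1,Type=String,Description="10 predictor calls over D/T/. in fixed tool order">
##INFO=<ID=PHYLOP100,Number=1,Type=Float,Description="PhyloP 100-way conservation score">
##INFO=<ID=SIPHY29,Number=1,Type=Float,Description="SiPhy 29-way conservation score">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def _write_variant_vcf(variants: Iterable[Variant], path) -> None:
    variants = list(variants)
    with open(path, "w") as fh:
        chroms = []
        for v in variants:
            if v.chrom not in chroms:
                chroms.append(v.chrom)
        fh.write("##fileformat=VCFv4.2\n")
        for line in _VCF_HEADER.splitlines()[1:-1]:
            fh.write(line + "\n")
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(_VCF_HEADER.splitlines()[-1] + "\n")
        for v in variants:
            info = [f"GENE={v.gene}", f"EFFECT={v.effect}"]
            for db, key in (("ESP6500", "AF_ESP6500"), ("1000G", "AF_1000G"), ("ExAC", "AF_EXAC")):
                f = v.freq(db)
                if f is not None:
                    info.append(f"{key}={f!r}")
            if v.dbsnp130:
                info.append("DBSNP130")
            if v.hgmd_id:
                info.append(f"HGMD={v.hgmd_id}")
            if v.clinvar_assertion:
                info.append(f"CLINVAR={v.clinvar_assertion}")
            if v.predictor_calls:
                info.append(f"PRED={v.predictor_calls.to_string()}")
            if v.phylop100 is not None:
                info.append(f"PHYLOP100={v.phylop100!r}")
            if v.siphy29 is not None:
                info.append(f"SIPHY29={v.siphy29!r}")
            fh.write(
                f"{v.chrom}\t{v.pos}\t{v.variant_id}\t{v.ref}\t{v.alt}\t.\t.\t"
                + ";".join(info)
                + "\n"
            )


def _opt_float_cell(cell: str) -> Optional[float]:
    cell = cell.strip()
    return float(cell) if cell else None


def read_patient_table(path) -> List[PatientRecord]:
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in PATIENT_COLUMNS if c not in header]
        if missing:
            raise SchemaError(f"patient table {path} missing columns: {missing}")
        patients = []
        for row in reader:
            patients.append(
                PatientRecord(
                    patient_id=row["patient_id"].strip(),
                    subgroup=row["subgroup"].strip(),
                    age=_opt_float_cell(row["age"]),
                    sex=row["sex"].strip() or None,
                    bmi=_opt_float_cell(row["bmi"]),
                    nyha=row["nyha"].strip() or None,
                    lvef=_opt_float_cell(row["lvef"]),
                    la=_opt_float_cell(row["la"]),
                    lv_edd=_opt_float_cell(row["lv_edd"]),
                    lv_esd=_opt_float_cell(row["lv_esd"]),
                    qrs=_opt_float_cell(row["qrs"]),
                    qt=_opt_float_cell(row["qt"]),
                    familial=row["familial"].strip() or None,
                )
            )
    return patients


def write_patient_table(patients: Iterable[PatientRecord], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(PATIENT_COLUMNS)
        for p in patients:
            writer.writerow(
                [
                    p.patient_id,
                    p.subgroup,
                    _fmt(p.age),
                    p.sex or "",
                    _fmt(p.bmi),
                    p.nyha or "",
                    _fmt(p.lvef),
                    _fmt(p.la),
                    _fmt(p.lv_edd),
                    _fmt(p.lv_esd),
                    _fmt(p.qrs),
                    _fmt(p.qt),
                    p.familial or "",
                ]
            )


def read_genotype_table(path) -> List[tuple]:
    """Carriage triples (patient_id, variant_id, zygosity), order preserved."""
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in GENOTYPE_COLUMNS if c not in header]
        if missing:
            raise SchemaError(f"genotype table {path} missing columns: {missing}")
        return [
            (row["patient_id"].strip(), row["variant_id"].strip(), row["zygosity"].strip())
            for row in reader
        ]


def write_genotype_table(cohort: Cohort, path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(GENOTYPE_COLUMNS)
        for p in cohort.patients:
            for vid, zyg in p.carried.items():
                writer.writerow([p.patient_id, vid, zyg])


def read_cohort(variants_path, patients_path, genotypes_path, dialect: str = "tsv") -> Cohort:
    """Assemble a cross-linked cohort from the three tables.

    Every genotype row must reference a known patient and variant;
    dangling ids raise :class:`IntegrityError` listing the offenders.
    """
    variants = read_variant_table(variants_path, dialect=dialect)
    patients = read_patient_table(patients_path)
    carriage = read_genotype_table(genotypes_path)
    by_patient = {p.patient_id: p for p in patients}
    known_variants = {v.variant_id for v in variants}
    dangling_v = sorted({vid for _, vid, _ in carriage if vid not in known_variants})
    dangling_p = sorted({pid for pid, _, _ in carriage if pid not in by_patient})
    if dangling_v or dangling_p:
        raise IntegrityError(
            f"genotype table references unknown variant_ids {dangling_v[:10]} "
            f"and unknown patient_ids {dangling_p[:10]}"
        )
    for pid, vid, zyg in carriage:
        by_patient[pid].carried[vid] = zyg
    return Cohort(variants=variants, patients=patients)


def write_cohort(cohort: Cohort, out_dir, dialect: str = "tsv") -> dict:
    """Write the three cohort tables into ``out_dir``; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ext = "vcf" if dialect == "vcf" else "tsv"
    paths = {
        "variants": out_dir / f"variants.{ext}",
        "patients": out_dir / "patients.csv",
        "genotypes": out_dir / "genotypes.csv",
    }
    write_variant_table(cohort.variants, paths["variants"], dialect=dialect)
    write_patient_table(cohort.patients, paths["patients"])
    write_genotype_table(cohort, paths["genotypes"])
    return paths


def read_gene_categories(path) -> GeneCategoryMap:
    mapping = {}
    with open(path, newline="") as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise SchemaError(f"{path} line {line_no}: expected 2 tab-separated fields")
            gene, category = parts[0].strip(), parts[1].strip()
            if gene == "gene" and category == "category":
                continue  # optional header
            mapping[gene] = category
    return GeneCategoryMap(mapping=mapping)


def write_gene_categories(cat_map: GeneCategoryMap, path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tcategory\n")
        for gene in sorted(cat_map.mapping):
            fh.write(f"{gene}\t{cat_map.mapping[gene]}\n")


def default_gene_categories() -> GeneCategoryMap:
    """The packaged 96-gene panel category map."""
    from importlib.resources import files

    path = files("cardiovar").joinpath("data/gene_categories.tsv")
    mapping = {}
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("gene\t"):
            continue
        gene, category = line.split("\t")
        mapping[gene] = category
    return GeneCategoryMap(mapping=mapping)
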
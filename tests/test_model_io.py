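"""Domain types, table readers/writers and cohort validation."""

import pytest

from cardiovar.io import (
    VARIANT_COLUMNS,
    read_cohort,
    read_gene_categories,
    read_variant_table,
    write_cohort,
    write_gene_categories,
    write_variant_table,
    default_gene_categories,
)
from cardiovar.model import (
    Cohort,
    GeneCategoryMap,
    IntegrityError,
    PatientRecord,
    PredictorPanel,
    SchemaError,
    validate_cohort,
)
from cardiovar.sim import SimConfig, simulate_cohort, simulate_variant_pool


class TestPredictorPanel:
    def test_string_round_trip(self):
        s = "DDTT.DDDTT"
        panel = PredictorPanel.from_string(s)
        assert panel.to_string() == s
        assert panel.damaging_count == 5
        assert panel.n_available == 9

    @pytest.mark.parametrize("bad", ["DDT", "X" * 10, "D" * 11])
    def test_malformed_string_rejected(self, bad):
        with pytest.raises(SchemaError):
            PredictorPanel.from_string(bad)

    def test_panel_requires_all_ten_tools(self):
        with pytest.raises(SchemaError):
            PredictorPanel(calls={"SIFT": "damaging"})


class TestVariantTableIO:
    @pytest.mark.parametrize("dialect", ["tsv", "vcf"])
    def test_generated_pool_round_trips(self, tmp_path, dialect):
        """A written 500-variant table re-reads to the identical list,
        including the absent-vs-zero distinction on every field."""
        pool, _ = simulate_variant_pool(SimConfig(seed=3, n_raw_variants=500))
        path = tmp_path / f"pool.{dialect}"
        write_variant_table(pool, path, dialect=dialect)
        back = read_variant_table(path, dialect=dialect)
        assert back == pool

    def test_reading_is_idempotent_and_order_stable(self, tmp_path):
        pool, _ = simulate_variant_pool(SimConfig(seed=3, n_raw_variants=50))
        path = tmp_path / "pool.tsv"
        write_variant_table(pool, path)
        first = read_variant_table(path)
        second = read_variant_table(path)
        assert first == second
        assert [v.variant_id for v in first] == [v.variant_id for v in pool]

    def test_empty_frequency_cell_means_absent(self, tmp_path, make_var):
        v = make_var("v1", ref_freqs={"1000G": 0.001})
        path = tmp_path / "t.tsv"
        write_variant_table([v], path)
        (back,) = read_variant_table(path)
        assert "ESP6500" not in back.ref_freqs  # absent, not 0.0
        assert back.freq("1000G") == 0.001

    def test_missing_column_names_the_column(self, tmp_path):
        path = tmp_path / "t.tsv"
        cols = [c for c in VARIANT_COLUMNS if c != "effect"]
        path.write_text("\t".join(cols) + "\n")
        with pytest.raises(SchemaError, match="effect"):
            read_variant_table(path)

    def test_unparsable_frequency_reports_line(self, tmp_path, make_var):
        path = tmp_path / "t.tsv"
        write_variant_table([make_var("v1"), make_var("v2")], path)
        text = path.read_text().replace("v2\tchr1\t100", "v2\tchr1\t100").splitlines()
        row = text[2].split("\t")
        row[VARIANT_COLUMNS.index("af_exac")] = "oops"
        text[2] = "\t".join(row)
        path.write_text("\n".join(text) + "\n")
        with pytest.raises(SchemaError, match="line 3"):
            read_variant_table(path)

    def test_duplicate_variant_id_rejected(self, tmp_path, make_var):
        path = tmp_path / "t.tsv"
        write_variant_table([make_var("dup"), make_var("dup")], path)
        with pytest.raises(IntegrityError, match="dup"):
            read_variant_table(path)

    def test_indels_left_normalized_on_ingest(self, tmp_path, make_var):
        v = make_var("v1", pos=100, ref="CAG", alt="CG", effect="frameshift_indel")
        path = tmp_path / "t.tsv"
        write_variant_table([v], path)
        (back,) = read_variant_table(path)
        assert (back.pos, back.ref, back.alt) == (100, "CA", "C")


class TestCohortIO:
    def test_carriage_counting(self, tmp_path, tiny_cohort):
        paths = write_cohort(tiny_cohort, tmp_path)
        back = read_cohort(paths["variants"], paths["patients"], paths["genotypes"])
        assert back.n_carried_instances() == tiny_cohort.n_carried_instances() == 6
        assert back.subgroup_counts() == {"CHD_VT": 2, "DCM_VT": 1, "iVT": 1, "CONTROL": 1}

    def test_empty_genotype_table(self, tmp_path, tiny_cohort):
        paths = write_cohort(tiny_cohort, tmp_path)
        paths["genotypes"].write_text("patient_id,variant_id,zygosity\n")
        back = read_cohort(paths["variants"], paths["patients"], paths["genotypes"])
        assert all(not p.carried for p in back.patients)

    def test_dangling_variant_id_lists_offenders(self, tmp_path, tiny_cohort):
        paths = write_cohort(tiny_cohort, tmp_path)
        with open(paths["genotypes"], "a") as fh:
            fh.write("p0,ghost1,het\n")
        with pytest.raises(IntegrityError, match="ghost1"):
            read_cohort(paths["variants"], paths["patients"], paths["genotypes"])

    def test_unknown_subgroup_is_schema_error(self, tmp_path, tiny_cohort):
        paths = write_cohort(tiny_cohort, tmp_path)
        text = paths["patients"].read_text().replace("CHD_VT", "MYSTERY_ARM")
        paths["patients"].write_text(text)
        with pytest.raises(SchemaError, match="MYSTERY_ARM"):
            read_cohort(paths["variants"], paths["patients"], paths["genotypes"])

    def test_simulated_cohort_burden_survives_round_trip(self, tmp_path, small_sim):
        """Writing and re-reading a cohort leaves the burden table identical."""
        from cardiovar.burden import burden_table
        from cardiovar.pathogenicity import classify_all

        cohort, _ = small_sim
        classified = classify_all(cohort.variants)
        before = burden_table(cohort, classified)
        paths = write_cohort(cohort, tmp_path)
        back = read_cohort(paths["variants"], paths["patients"], paths["genotypes"])
        after = burden_table(back, classify_all(back.variants))
        assert before == after


class TestValidation:
    def test_consistent_cohort_is_clean(self, tiny_cohort):
        assert validate_cohort(tiny_cohort) == []

    def test_negative_lvef_flagged_once(self, tiny_cohort):
        tiny_cohort.patients[0].lvef = -5.0
        violations = validate_cohort(tiny_cohort)
        assert len(violations) == 1
        assert violations[0].subject == "p0" and violations[0].field == "lvef"

    def test_out_of_range_frequency_flagged(self, make_var):
        cohort = Cohort(variants=[make_var("v1", ref_freqs={"ExAC": 1.5})], patients=[])
        violations = validate_cohort(cohort)
        assert len(violations) == 1 and violations[0].field == "ref_freqs"

    def test_fault_injection_recovers_exact_violation_set(self, tiny_cohort, make_var):
        """The validator finds exactly the faults the injector planted."""
        injected = set()
        tiny_cohort.patients[0].qrs = -10.0
        injected.add(("p0", "qrs"))
        tiny_cohort.patients[2].carried["ghost"] = "het"
        injected.add(("p2", "carried"))
        tiny_cohort.patients[1].carried["v5"] = "triploid"
        injected.add(("p1", "carried"))
        found = {(v.subject, v.field) for v in validate_cohort(tiny_cohort)}
        assert found == injected


class TestGeneCategories:
    def test_packaged_panel_covers_96_genes_in_7_categories(self):
        cmap = default_gene_categories()
        assert len(cmap.genes) == 96
        assert len(set(cmap.mapping.values())) == 7

    def test_round_trip(self, tmp_path):
        cmap = GeneCategoryMap({"TTN": "sarcomere", "GAA": "metabolism"})
        path = tmp_path / "cats.tsv"
        write_gene_categories(cmap, path)
        assert read_gene_categories(path).mapping == cmap.mapping

    def test_unknown_category_rejected(self):
        with pytest.raises(SchemaError):
            GeneCategoryMap({"TTN": "mitochondrion"})
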
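"""Burden tables, HGMD carrier summaries and category distributions."""

import pytest

from cardiovar.burden import (
    THRESHOLDS,
    burden_table,
    category_distribution,
    gene_frequency_table,
    hgmd_carrier_table,
)
from cardiovar.io import default_gene_categories
from cardiovar.model import Cohort, GeneCategoryMap, PatientRecord, PredictorPanel, SchemaError
from cardiovar.pathogenicity import classify_all
from cardiovar.reference import reference_burden_cohort

THRESHOLD_CLASSES = {"I": {"I"}, "I/II": {"I", "II"}, "I/II/III": {"I", "II", "III"}}


def brute_force_burden(cohort, classified):
    """Naive per-patient double loop, independent of burden_table."""
    cls = {cv.variant_id: cv.pclass.value for cv in classified}
    out = {}
    for sg in ("CHD_VT", "DCM_VT", "iVT"):
        patients = [p for p in cohort.patients if p.subgroup == sg]
        total = sum(len(p.carried) for p in patients)
        for thr, ok in THRESHOLD_CLASSES.items():
            pos, cum = 0, 0
            for p in patients:
                k = len([v for v in p.carried if cls[v] in ok])
                cum += k
                pos += k > 0
            out[(sg, thr)] = (len(patients), pos, cum, total)
    return out


@pytest.fixture(scope="module")
def analysis(default_sim):
    """Simulated cohort restricted to its analysis set, plus classes."""
    from cardiovar.report import run_pipeline

    cohort, truth = default_sim
    out = run_pipeline(cohort, control_ids=truth.control_observed_ids())
    return out["analysis_cohort"], out["classified"]


class TestBurdenTable:
    def test_matches_brute_force_recount(self, analysis):
        cohort, classified = analysis
        rows = {(r.subgroup, r.class_threshold): r for r in burden_table(cohort, classified)}
        oracle = brute_force_burden(cohort, classified)
        assert set(rows) == set(oracle)
        for key, (n, pos, cum, total) in oracle.items():
            r = rows[key]
            assert (r.n_patients, r.n_positive, r.cumulative_variants) == (n, pos, cum)

    def test_threshold_widening_is_monotone(self, analysis):
        cohort, classified = analysis
        rows = {(r.subgroup, r.class_threshold): r for r in burden_table(cohort, classified)}
        for sg in ("CHD_VT", "DCM_VT", "iVT"):
            seq = [rows[(sg, t)] for t in THRESHOLDS]
            for narrow, wide in zip(seq, seq[1:]):
                assert narrow.n_positive <= wide.n_positive
                assert narrow.cumulative_variants <= wide.cumulative_variants

    def test_published_integer_cell(self):
        """23 patients, 10 positives holding 13 severe instances ->
        43.5% positive, 1.3 variants per positive."""
        rows = burden_table(
            reference_burden_cohort(), classify_all(reference_burden_cohort().variants)
        )
        chd = {r.class_threshold: r for r in rows if r.subgroup == "CHD_VT"}
        assert chd["I"].n_positive == 10
        assert chd["I"].pct_positive == 43.5
        assert chd["I"].cumulative_variants == 13
        assert chd["I"].pct_of_all_variants == 11.8
        assert chd["I"].variants_per_positive == 1.3

    def test_no_carriers_gives_undefined_rate(self, make_var):
        v = make_var("v1", predictor_calls=PredictorPanel.from_damaging(8))
        cohort = Cohort(
            variants=[v],
            patients=[PatientRecord(f"p{i}", "iVT", carried={}) for i in range(5)],
        )
        rows = burden_table(cohort, classify_all([v]), subgroups=("iVT",))
        for r in rows:
            assert r.n_positive == 0
            assert r.variants_per_positive is None
            assert r.pct_positive == 0.0

    def test_empty_subgroup_omitted_with_warning(self, make_var):
        v = make_var("v1", predictor_calls=PredictorPanel.from_damaging(8))
        cohort = Cohort(variants=[v], patients=[PatientRecord("p0", "iVT", carried={})])
        with pytest.warns(UserWarning, match="CHD_VT"):
            rows = burden_table(cohort, classify_all([v]))
        assert {r.subgroup for r in rows} == {"iVT"}


class TestHgmdCarrierTable:
    def test_all_flagged_all_carriers_gives_100(self, make_var):
        vs = [
            make_var(f"v{i}", hgmd_id=f"CM{i}", predictor_calls=PredictorPanel.from_damaging(8))
            for i in range(3)
        ]
        patients = [
            PatientRecord(f"p{i}", "iVT", carried={"v0": "het"}) for i in range(4)
        ]
        table = hgmd_carrier_table(Cohort(variants=vs, patients=patients), classify_all(vs))
        assert table["carriers"]["iVT"]["pct_carriers"] == 100.0

    def test_matches_brute_force_recount(self, analysis):
        cohort, classified = analysis
        table = hgmd_carrier_table(cohort, classified)
        flagged = {cv.variant_id for cv in classified if cv.variant.hgmd_id}
        for sg, cell in table["carriers"].items():
            patients = [p for p in cohort.patients if p.subgroup == sg]
            expected = sum(1 for p in patients if flagged & set(p.carried))
            assert cell["n_carriers"] == expected


class TestCategoryDistribution:
    def test_published_ion_flux_row_percentages(self, make_var):
        damaging = {"I": 8, "II": 5, "III": 2, "IV": 0}
        variants = []
        i = 0
        for cls, n in zip(("I", "II", "III", "IV"), (12, 7, 18, 2)):
            for _ in range(n):
                variants.append(
                    make_var(
                        f"v{i}", gene="KCNQ1",
                        predictor_calls=PredictorPanel.from_damaging(damaging[cls]),
                    )
                )
                i += 1
        dist = category_distribution(classify_all(variants), default_gene_categories())
        row = dist["pooled"]["ion_flux"]
        assert [row[c]["pct"] for c in ("I", "II", "III", "IV")] == [30.8, 17.9, 46.2, 5.1]

    def test_single_category_single_class_is_100(self, make_var):
        v = make_var("v1", gene="GAA", predictor_calls=PredictorPanel.from_damaging(9))
        dist = category_distribution(classify_all([v]), default_gene_categories())
        assert dist["pooled"]["metabolism"]["I"] == {"n": 1, "pct": 100.0}

    def test_cell_totals_conserve_variant_count(self, analysis):
        cohort, classified = analysis
        dist = category_distribution(classified, default_gene_categories())
        total = sum(row["row_total"] for row in dist["pooled"].values())
        assert total == len(classified)

    def test_matches_brute_force_group_by(self, analysis):
        cohort, classified = analysis
        cmap = default_gene_categories()
        dist = category_distribution(classified, cmap)["pooled"]
        from collections import Counter

        oracle = Counter((cmap.category(cv.variant.gene), cv.pclass.value) for cv in classified)
        for cat, row in dist.items():
            for cls in ("I", "II", "III", "IV"):
                assert row[cls]["n"] == oracle.get((cat, cls), 0)

    def test_unmapped_gene_error_lists_gene(self, make_var):
        v = make_var("v1", gene="NOTAGENE", predictor_calls=PredictorPanel.from_damaging(1))
        with pytest.raises(SchemaError, match="NOTAGENE"):
            category_distribution(classify_all([v]), default_gene_categories())

    def test_per_subgroup_scope_counts_carried_instances(self, analysis):
        cohort, classified = analysis
        dist = category_distribution(
            classified, default_gene_categories(), scope="per_subgroup", cohort=cohort
        )
        for sg in ("CHD_VT", "DCM_VT", "iVT"):
            total = sum(row["row_total"] for row in dist[sg].values())
            carried = sum(len(p.carried) for p in cohort.patients if p.subgroup == sg)
            assert total == carried


class TestGeneFrequency:
    def test_known_fraction(self, make_var):
        v = make_var("v1", gene="LAMA2", hgmd_id="CM1",
                     predictor_calls=PredictorPanel.from_damaging(8))
        patients = [
            PatientRecord(f"p{i}", "DCM_VT", carried={"v1": "het"} if i < 11 else {})
            for i in range(32)
        ]
        rows = gene_frequency_table(
            Cohort(variants=[v], patients=patients), classify_all([v]), mode="hgmd"
        )
        assert rows[0]["gene"] == "LAMA2" and rows[0]["DCM_VT"] == 34.4

    def test_gene_without_carriers_is_zero_everywhere(self, make_var):
        v = make_var("v1", gene="GAA", predictor_calls=PredictorPanel.from_damaging(8))
        patients = [PatientRecord("p0", "iVT", carried={})]
        rows = gene_frequency_table(Cohort(variants=[v], patients=patients), classify_all([v]))
        assert rows[0]["iVT"] == 0.0

    def test_matches_brute_force_recount(self, analysis):
        cohort, classified = analysis
        rows = gene_frequency_table(cohort, classified, mode="hgmd")
        flagged = {cv.variant_id: cv.variant.gene for cv in classified if cv.variant.hgmd_id}
        by_gene = {r["gene"]: r for r in rows}
        for gene in set(flagged.values()):
            for sg in ("CHD_VT", "DCM_VT", "iVT"):
                patients = [p for p in cohort.patients if p.subgroup == sg]
                n = sum(
                    1 for p in patients
                    if any(flagged.get(v) == gene for v in p.carried)
                )
                from cardiovar.stats import percent

                assert by_gene[gene][sg] == percent(n, len(patients))
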
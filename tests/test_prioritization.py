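"""nRPK computation, the expression cutoff and the three-filter prioritization."""

import io

import numpy as np
import pandas as pd
import pytest

from cnvrecur.errors import ValidationError
from cnvrecur.genome import CNVRecord, GeneModel
from cnvrecur.prioritization import (
    ExpressionRecord,
    PrioritizationConfig,
    compute_nrpk,
    expression_cutoff,
    gene_patient_counts,
    prioritize,
    read_expression,
)


def rec(gene, stage, count, kb=1.0, tid=None):
    return ExpressionRecord(gene, tid or gene + ".t1", stage, count, kb)


class TestNrpk:
    def test_arithmetic(self):
        assert rec("G", "E10", 118.0, kb=2.0).nrpk == pytest.approx(59.0)

    def test_zero_count_zero_nrpk(self):
        assert rec("G", "E10", 0.0).nrpk == 0.0

    def test_gene_level_is_max_over_transcripts(self):
        records = [
            rec("G", "E10", 10, kb=1.0, tid="t1"),
            rec("G", "E10", 30, kb=2.0, tid="t2"),  # nrpk 15
        ]
        df = compute_nrpk(records)
        assert df.loc[0, "nrpk"] == pytest.approx(15.0)

    @pytest.mark.parametrize("seed", range(2))
    def test_matches_one_line_oracle(self, seed):
        rng = np.random.default_rng(seed)
        records = [
            rec(f"G{i % 7}", f"E{10 + i % 5}", float(rng.uniform(0, 100)),
                kb=float(rng.uniform(0.5, 5)), tid=f"t{i}")
            for i in range(60)
        ]
        df = compute_nrpk(records).set_index(["gene", "stage"])["nrpk"]
        oracle = {}
        for r in records:
            key = (r.gene, r.stage)
            oracle[key] = max(oracle.get(key, 0.0), r.normalized_count / r.length_kb)
        for key, v in oracle.items():
            assert df[key] == pytest.approx(v)

    def test_missing_transcript_length_listed(self):
        tsv = "gene\ttranscript_id\tlength_kb\tstage\tnormalized_count\nG\tt1\t0\tE10\t5\n"
        with pytest.raises(ValidationError, match="G"):
            read_expression(io.StringIO(tsv))


class TestExpressionCutoff:
    def test_zeros_excluded_from_mean(self):
        records = [rec("A", "E10", 10), rec("B", "E10", 20), rec("C", "E10", 30),
                   rec("D", "E10", 0)]
        assert expression_cutoff(records) == pytest.approx(20.0)

    def test_constant_records(self):
        records = [rec(f"G{i}", "E10", 7.0) for i in range(5)]
        assert expression_cutoff(records) == pytest.approx(7.0)

    def test_all_zero_is_an_error(self):
        with pytest.raises(ValidationError):
            expression_cutoff([rec("A", "E10", 0.0)])


GENES = [
    GeneModel("G1", "c", 100, 200),
    GeneModel("G2", "c", 300, 400),
    GeneModel("G3", "c", 500, 600),
]


def cnv(pid, s, e, t="deletion"):
    return CNVRecord("c", s, e, pid, t)


class TestGenePatientCounts:
    def test_distinct_patients_counted(self):
        cnvs = [cnv("P1", 0, 250), cnv("P2", 150, 350), cnv("P2", 90, 110)]
        counts = gene_patient_counts(cnvs, GENES, "deletion")
        assert counts == {"G1": 2, "G2": 1, "G3": 0}

    def test_empty_cohort_all_zero(self):
        assert set(gene_patient_counts([], GENES, "deletion").values()) == {0}


class TestPrioritize:
    def expression_for(self, high_genes, low_genes, high=70.0, low=5.0):
        records = [rec(g, "E12", high) for g in high_genes]
        records += [rec(g, "E12", low) for g in low_genes]
        return records

    def test_only_high_expression_gene_selected(self):
        # region [100,600) shared by 2 patients, 3 genes, one above cutoff
        cnvs = [cnv("P1", 50, 650), cnv("P2", 80, 700)]
        expr = self.expression_for(["G2"], ["G1", "G3"])
        cfg = PrioritizationConfig(nrpk_cutoff=59.0)
        out = prioritize(cnvs, GENES, expr, cfg)
        assert [c.gene for c in out if c.is_candidate] == ["G2"]
        flags = {c.gene: (c.passed_recurrence, c.passed_gene_count, c.passed_expression)
                 for c in out}
        assert flags["G1"] == (True, True, False)

    def test_gene_count_filter_blocks_crowded_region(self):
        genes = [GeneModel(f"X{i}", "c", 100 * i, 100 * i + 50) for i in range(1, 7)]
        cnvs = [cnv("P1", 0, 1000), cnv("P2", 0, 1000), cnv("P3", 0, 1000)]
        expr = self.expression_for([g.symbol for g in genes], [])
        out = prioritize(cnvs, genes, expr, PrioritizationConfig(nrpk_cutoff=59.0))
        assert not any(c.is_candidate for c in out)
        assert all(c.min_region_gene_count == 6 for c in out)

    def test_monotone_in_thresholds(self, bundle, bundle_expression):
        base = prioritize(bundle.records, bundle.annotation, bundle_expression,
                          PrioritizationConfig(), "deletion")
        selected = {c.gene for c in base if c.is_candidate}
        relaxed_cfgs = [
            PrioritizationConfig(min_patients=2, max_genes_per_region=10),
            PrioritizationConfig(min_patients=2, max_genes_per_region=5, nrpk_cutoff=1.0),
        ]
        for cfg in relaxed_cfgs:
            relaxed = {c.gene for c in
                       prioritize(bundle.records, bundle.annotation, bundle_expression,
                                  cfg, "deletion") if c.is_candidate}
            assert selected <= relaxed

    def test_invariant_under_patient_relabeling(self):
        cnvs = [cnv("P1", 50, 650), cnv("P2", 80, 700)]
        relabeled = [CNVRecord(r.chrom, r.start, r.end, {"P1": "Q9", "P2": "Q1"}[r.patient_id],
                               r.cnv_type) for r in cnvs]
        expr = self.expression_for(["G2"], ["G1", "G3"])
        cfg = PrioritizationConfig(nrpk_cutoff=59.0)
        a = [c.gene for c in prioritize(cnvs, GENES, expr, cfg) if c.is_candidate]
        b = [c.gene for c in prioritize(relabeled, GENES, expr, cfg) if c.is_candidate]
        assert a == b

    def test_attrition_is_monotone(self, bundle, bundle_expression):
        out = prioritize(bundle.records, bundle.annotation, bundle_expression,
                         PrioritizationConfig(), "deletion")
        n_touched = len(out)
        n_rec = sum(c.passed_recurrence for c in out)
        n_rc = sum(c.passed_recurrence and c.passed_gene_count for c in out)
        n_cand = sum(c.is_candidate for c in out)
        assert n_touched >= n_rec >= n_rc >= n_cand
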
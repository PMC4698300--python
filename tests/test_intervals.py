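"""Interval arithmetic against per-base brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cnvrecur.errors import ValidationError
from cnvrecur.genome import CNVRecord, GeneModel, GenomeBuild
from cnvrecur.intervals import (
    Window,
    collapse_contributors,
    count_overlaps,
    coverage_segments,
    genes_in_interval,
    make_windows,
)

CHROM_LEN = 10_000


def random_cnvs(rng, n, chrom="chrT", n_patients=None):
    n_patients = n_patients or n
    out = []
    for i in range(n):
        s = int(rng.integers(0, CHROM_LEN - 1))
        e = int(rng.integers(s + 1, CHROM_LEN + 1))
        out.append(CNVRecord(chrom, s, e, f"P{rng.integers(n_patients)}", "deletion"))
    return out


def depth_oracle(intervals):
    """Per-base depth array on the toy chromosome."""
    depth = np.zeros(CHROM_LEN, dtype=int)
    for r in intervals:
        depth[r.start:r.end] += 1
    return depth


class TestCoverageSegments:
    def test_textbook_two_intervals(self):
        regs = coverage_segments(
            [CNVRecord("c", 0, 10, "P1", "deletion"), CNVRecord("c", 5, 15, "P2", "deletion")]
        )
        assert [(r.start, r.end, r.depth) for r in regs] == [(0, 5, 1), (5, 10, 2), (10, 15, 1)]

    def test_single_interval_identity(self):
        (r,) = coverage_segments([CNVRecord("c", 3, 9, "P1", "deletion")])
        assert (r.start, r.end, r.depth) == (3, 9, 1)
        assert r.patient_ids == frozenset({"P1"})

    @pytest.mark.parametrize("seed", range(5))
    def test_depths_match_per_base_oracle(self, seed):
        rng = np.random.default_rng(seed)
        cnvs = random_cnvs(rng, 50)
        regs = coverage_segments(cnvs)
        depth = depth_oracle(cnvs)
        rebuilt = np.zeros(CHROM_LEN, dtype=int)
        for r in regs:
            assert np.all(depth[r.start:r.end] == r.depth), "segment depth not constant"
            rebuilt[r.start:r.end] = r.depth
        assert np.array_equal(rebuilt, depth)

    @pytest.mark.parametrize("seed", range(3))
    def test_conservation_of_covered_mass(self, seed):
        rng = np.random.default_rng(100 + seed)
        cnvs = random_cnvs(rng, 30)
        regs = coverage_segments(cnvs)
        assert sum(r.depth * r.length for r in regs) == sum(r.length for r in cnvs)

    def test_disjoint_intervals_returned_verbatim_depth_one(self):
        cnvs = [CNVRecord("c", 10 * i, 10 * i + 5, f"P{i}", "deletion") for i in range(8)]
        regs = coverage_segments(cnvs)
        assert [(r.start, r.end, r.depth) for r in regs] == [
            (r.start, r.end, 1) for r in cnvs
        ]

    def test_unknown_chromosome_rejected_with_genome(self, toy_genome):
        with pytest.raises(ValidationError):
            coverage_segments([CNVRecord("chrZ", 0, 5, "P", "deletion")], toy_genome)


class TestCollapseContributors:
    def test_two_patients_listed(self):
        cnvs = [CNVRecord("c", 0, 10, "P1", "deletion"), CNVRecord("c", 5, 15, "P2", "deletion")]
        regs = collapse_contributors(coverage_segments(cnvs), cnvs)
        mid = [r for r in regs if r.depth == 2][0]
        assert mid.patient_ids == frozenset({"P1", "P2"})

    def test_tandem_cnvs_of_one_patient_count_twice_in_depth_once_in_ids(self):
        cnvs = [
            CNVRecord("c", 0, 10, "P1", "deletion"),
            CNVRecord("c", 2, 8, "P1", "deletion"),
        ]
        regs = collapse_contributors(coverage_segments(cnvs), cnvs)
        mid = [r for r in regs if (r.start, r.end) == (2, 8)][0]
        assert mid.depth == 2 and mid.patient_ids == frozenset({"P1"})

    @pytest.mark.parametrize("seed", range(3))
    def test_membership_matches_all_pairs_oracle(self, seed):
        rng = np.random.default_rng(200 + seed)
        cnvs = random_cnvs(rng, 40, n_patients=15)
        regs = collapse_contributors(coverage_segments(cnvs), cnvs)
        for r in regs:
            expected = {
                c.patient_id for c in cnvs if c.start < r.end and c.end > r.start
            }
            assert r.patient_ids == expected


class TestMakeWindows:
    def test_exact_tiling(self):
        g = GenomeBuild("g", (("c", 10_000_000),))
        assert len(make_windows(g, 1_000_000)) == 10

    def test_window_touching_exclusion_removed(self):
        g = GenomeBuild("g", (("c", 10_000_000),), (("c", 2_500_000, 2_600_000),))
        ws = make_windows(g, 1_000_000)
        assert len(ws) == 9
        assert all(not (w.start < 2_600_000 and w.end > 2_500_000) for w in ws)

    def test_remainder_window_kept(self):
        g = GenomeBuild("g", (("c", 10_500_000),))
        ws = make_windows(g, 1_000_000)
        assert len(ws) == 11 and ws[-1].end - ws[-1].start == 500_000


class TestCountOverlaps:
    def test_feature_equal_to_window(self):
        g = GenomeBuild("g", (("c", 3000),))
        ws = make_windows(g, 1000)
        counts = count_overlaps(ws, [("c", 1000, 2000)])
        assert [counts[w] for w in ws] == [0, 1, 0]

    def test_spanning_feature_increments_both(self):
        g = GenomeBuild("g", (("c", 3000),))
        ws = make_windows(g, 1000)
        counts = count_overlaps(ws, [("c", 1500, 2500)])
        assert [counts[w] for w in ws] == [0, 1, 1]

    @pytest.mark.parametrize("seed", range(3))
    def test_counts_match_double_loop_oracle(self, seed):
        rng = np.random.default_rng(300 + seed)
        g = GenomeBuild("g", (("c1", CHROM_LEN), ("c2", CHROM_LEN)))
        ws = make_windows(g, 700)
        feats = []
        for _ in range(60):
            chrom = "c1" if rng.random() < 0.5 else "c2"
            s = int(rng.integers(0, CHROM_LEN - 1))
            e = int(rng.integers(s + 1, CHROM_LEN + 1))
            feats.append((chrom, s, e))
        counts = count_overlaps(ws, feats)
        for w in ws:
            oracle = sum(
                1 for c, s, e in feats if c == w.chrom and s < w.end and e > w.start
            )
            assert counts[w] == oracle


class TestGenesInInterval:
    GENES = [
        GeneModel("A", "c", 100, 200),
        GeneModel("B", "c", 300, 400),
        GeneModel("C", "c", 399, 500),
    ]

    def test_contained_gene_returned(self):
        assert [g.symbol for g in genes_in_interval(("c", 50, 250), self.GENES)] == ["A"]

    def test_one_base_overlap_counts(self):
        assert [g.symbol for g in genes_in_interval(("c", 399, 401), self.GENES)] == ["B", "C"]

    def test_gene_desert_empty(self):
        assert genes_in_interval(("c", 600, 700), self.GENES) == []


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    st.lists(
        st.tuples(st.integers(0, 9_000), st.integers(1, 1_000)),
        min_size=1,
        max_size=25,
    )
)
def test_coverage_property_random_instances(pairs):
    """Segmentation equals the per-base oracle for arbitrary interval sets."""
    cnvs = [
        CNVRecord("c", s, s + l, f"P{i}", "deletion") for i, (s, l) in enumerate(pairs)
    ]
    regs = coverage_segments(cnvs)
    depth = depth_oracle(cnvs)
    rebuilt = np.zeros(CHROM_LEN, dtype=int)
    for r in regs:
        rebuilt[r.start:r.end] = r.depth
    assert np.array_equal(rebuilt, depth)
    # maximality: adjacent segments differ in depth or contributor set
    for a, b in zip(regs, regs[1:]):
        if a.end == b.start:
            assert a.depth != b.depth or a.patient_ids != b.patient_ids
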
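"""Overlap partitioning, nearest-TSS assignment and gene-window membership
against brute-force oracles."""

from __future__ import annotations

import numpy as np
import pytest

import chipcompare as cc
from chipcompare.annotation import Gene, GeneModel
from chipcompare.formats_io import BedInterval


def iv(contig, start, end, name="."):
    return BedInterval(contig, start, end, name=name)


def random_intervals(rng, n, contigs=("c1", "c2"), span=10_000, width=200):
    out = []
    for i in range(n):
        contig = contigs[rng.integers(len(contigs))]
        start = int(rng.integers(0, span))
        out.append(iv(contig, start, start + 1 + int(rng.integers(width)),
                      name=f"p{i}"))
    return out


class TestOverlapPartition:
    def test_identical_sets_have_no_specific_peaks(self):
        a = [iv("c1", 0, 10), iv("c1", 50, 80)]
        part = cc.overlap_partition(a, list(a))
        assert part.specific_a == [] and part.specific_b == []
        assert len(part.shared_a) == len(a)

    def test_disjoint_contigs_share_nothing(self):
        part = cc.overlap_partition([iv("c1", 0, 10)], [iv("c2", 0, 10)])
        assert part.shared_a == [] and part.shared_b == []

    def test_half_open_boundary_semantics(self):
        # one shared base counts; abutment does not
        one_bp = cc.overlap_partition([iv("c1", 0, 10)], [iv("c1", 9, 20)])
        assert len(one_bp.shared_a) == 1
        abut = cc.overlap_partition([iv("c1", 0, 10)], [iv("c1", 10, 20)])
        assert len(abut.shared_a) == 0 and len(abut.specific_a) == 1

    def test_partition_is_exact(self):
        rng = np.random.default_rng(21)
        a = random_intervals(rng, 500)
        b = random_intervals(rng, 500)
        part = cc.overlap_partition(a, b)
        assert len(part.shared_a) + len(part.specific_a) == len(a)
        assert len(part.shared_b) + len(part.specific_b) == len(b)
        assert {id(p) for p in part.shared_a} | {id(p) for p in part.specific_a} == {
            id(p) for p in a
        }

    def test_matches_brute_force_all_pairs(self):
        rng = np.random.default_rng(22)
        a = random_intervals(rng, 1000)
        b = random_intervals(rng, 1000)
        part = cc.overlap_partition(a, b)

        def overlaps(x, y):
            return x.contig == y.contig and max(x.start, y.start) < min(x.end, y.end)

        expected_shared_a = {p.name for p in a if any(overlaps(p, q) for q in b)}
        expected_shared_b = {q.name for q in b if any(overlaps(q, p) for p in a)}
        assert {p.name for p in part.shared_a} == expected_shared_a
        assert {q.name for q in part.shared_b} == expected_shared_b


class TestNearestTss:
    GENES = GeneModel([Gene("g1", "c1", "+", 1000)])

    def test_signed_distance_upstream_is_negative(self):
        (a,) = cc.nearest_tss([iv("c1", 900, 980)], self.GENES)
        assert a.gene_id == "g1"
        assert a.signed_distance == -60.0  # midpoint 940, TSS 1000
        assert a.border_distance == 21  # nearest covered base 979

    def test_orientation_flips_for_minus_strand_gene(self):
        genes = GeneModel([Gene("g1", "c1", "-", 1000)])
        (a,) = cc.nearest_tss([iv("c1", 900, 980)], genes)
        assert a.signed_distance == 60.0

    def test_tie_broken_by_smaller_gene_id(self):
        genes = GeneModel([
            Gene("gB", "c1", "+", 900), Gene("gA", "c1", "+", 1100),
        ])
        (a,) = cc.nearest_tss([iv("c1", 990, 1010)], genes)  # midpoint 1000
        assert a.gene_id == "gA"

    def test_contig_without_genes_marked_absent(self):
        (a,) = cc.nearest_tss([iv("c9", 0, 10)], self.GENES)
        assert a.gene_id is None and a.signed_distance is None

    def test_matches_brute_force_search(self):
        rng = np.random.default_rng(23)
        genes = GeneModel([
            Gene(f"g{i:03d}", ("c1", "c2")[rng.integers(2)],
                 "+-"[rng.integers(2)], int(rng.integers(0, 50_000)))
            for i in range(60)
        ])
        peaks = random_intervals(rng, 200, span=50_000)
        result = cc.nearest_tss(peaks, genes)
        for p, a in zip(peaks, result):
            mid = (p.start + p.end) / 2
            cands = [g for g in genes.genes if g.contig == p.contig]
            dmin = min(abs(mid - g.tss) for g in cands)
            best = min(
                (g for g in cands if abs(mid - g.tss) == dmin),
                key=lambda g: g.gene_id,
            )
            assert a.gene_id == best.gene_id
            expected_signed = mid - best.tss if best.strand == "+" else best.tss - mid
            assert a.signed_distance == expected_signed


class TestTssHistogram:
    def test_point_mass_at_zero(self):
        genes = GeneModel([Gene("g1", "c1", "+", 500)])
        peaks = [iv("c1", 450, 550)] * 4
        counts, fracs, n_out = cc.tss_distance_histogram(
            cc.nearest_tss(peaks, genes), [-1000, 0, 1000]
        )
        assert counts.tolist() == [0, 4]
        assert fracs.tolist() == [0.0, 1.0]
        assert n_out == 0

    def test_empty_assignments(self):
        counts, fracs, n_out = cc.tss_distance_histogram([], [-1000, 0, 1000])
        assert counts.tolist() == [0, 0] and n_out == 0

    def test_uniform_placement_within_multinomial_bounds(self):
        from scipy import stats

        rng = np.random.default_rng(24)
        genes = GeneModel([Gene("g1", "c1", "+", 50_000)])
        n = 4000
        mids = 50_000 + rng.integers(-10_000, 10_000, size=n)
        peaks = [iv("c1", int(m) - 10, int(m) + 10) for m in mids]
        counts, fracs, _ = cc.tss_distance_histogram(
            cc.nearest_tss(peaks, genes), list(range(-10_000, 10_001, 1000))
        )
        # per-bin binomial 99% band, Bonferroni-corrected over 20 bins
        lo, hi = stats.binom.interval(1 - 0.01 / 20, n, 1 / 20)
        assert ((counts >= lo) & (counts <= hi)).all()

    def test_rejects_unsorted_edges(self):
        with pytest.raises(ValueError):
            cc.tss_distance_histogram([], [0, -1000, 1000])


class TestGenesWithinWindow:
    def test_tss_inside_peak_always_counts(self):
        genes = GeneModel([Gene("g1", "c1", "+", 100)])
        hits, n = cc.genes_within_window([iv("c1", 50, 150)], genes, 1)
        assert hits == {"g1"} and n == 1

    def test_threshold_is_inclusive(self):
        genes = GeneModel([
            Gene("at_window", "c1", "+", 1150),  # border 999 -> distance 151
            Gene("beyond", "c1", "+", 1151),
        ])
        hits, _ = cc.genes_within_window([iv("c1", 500, 1000)], genes, 151)
        assert hits == {"at_window"}

    def test_monotone_in_window(self):
        rng = np.random.default_rng(25)
        genes = GeneModel([
            Gene(f"g{i}", "c1", "+", int(rng.integers(0, 100_000)))
            for i in range(100)
        ])
        peaks = random_intervals(rng, 50, contigs=("c1",), span=100_000)
        small, _ = cc.genes_within_window(peaks, genes, 10_000)
        large, _ = cc.genes_within_window(peaks, genes, 50_000)
        assert small <= large

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(26)
        genes = GeneModel([
            Gene(f"g{i}", ("c1", "c2")[rng.integers(2)], "+",
                 int(rng.integers(0, 30_000)))
            for i in range(80)
        ])
        peaks = random_intervals(rng, 60, span=30_000)
        for window in (500, 2000, 10_000):
            hits, _ = cc.genes_within_window(peaks, genes, window)
            expected = set()
            for g in genes.genes:
                for p in peaks:
                    if p.contig != g.contig:
                        continue
                    border = max(0, p.start - g.tss, g.tss - (p.end - 1))
                    if border <= window:
                        expected.add(g.gene_id)
                        break
            assert hits == expected


def test_gene_window_table_reports_common_genes():
    genes = GeneModel([
        Gene("g1", "c1", "+", 1000),
        Gene("g2", "c1", "+", 5000),
        Gene("g3", "c1", "+", 9000),
    ])
    a = [iv("c1", 900, 1100), iv("c1", 4900, 5100)]
    b = [iv("c1", 4900, 5100), iv("c1", 8900, 9100)]
    table = cc.gene_window_table(a, b, genes, windows=(1000,))
    col = "within_1kb_of_TSS"
    assert table.loc["A", col] == 2
    assert table.loc["B", col] == 2
    assert table.loc["Common", col] == 1
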
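"""Degenerate-motif scanning vs enumeration oracle, RPKM arithmetic and
invariances, signal curves and quantile summaries."""

from __future__ import annotations

import numpy as np
import pytest

import chipcompare as cc
from chipcompare.characterization import IUPAC_CODES
from chipcompare.formats_io import BedInterval, GenomeSequence

WGATAR_WORDS = {"AGATAA", "AGATAG", "TGATAA", "TGATAG"}
_RC = str.maketrans("ACGT", "TGCA")
WGATAR_BOTH = WGATAR_WORDS | {w.translate(_RC)[::-1] for w in WGATAR_WORDS}


class TestMotifMatcher:
    def test_forward_match(self):
        m = cc.compile_motif(cc.MotifSpec("WGATAR"))
        assert m.find("AGATAA").tolist() == [0]

    def test_reverse_strand_match(self):
        # CTATCA is the reverse complement of TGATAG
        m = cc.compile_motif(cc.MotifSpec("WGATAR"))
        assert m.find("CTATCA").tolist() == [0]
        single = cc.compile_motif(cc.MotifSpec("WGATAR"), both_strands=False)
        assert single.find("CTATCA").tolist() == []

    def test_reverse_complement_of_spec(self):
        assert cc.MotifSpec("WGATAR").reverse_complement() == "YTATCW"

    def test_invalid_code_names_character(self):
        with pytest.raises(ValueError, match="'X'"):
            cc.MotifSpec("WGAXAR")

    def test_n_in_genome_matches_nothing(self):
        m = cc.compile_motif(cc.MotifSpec("WGATAR"))
        assert m.find("NGATAA").tolist() == []
        n_code = cc.compile_motif(cc.MotifSpec("NGATAR"), both_strands=False)
        assert n_code.find("CGATAA").tolist() == [0]
        assert n_code.find("NGATAA").tolist() == []

    def test_matches_enumeration_oracle_on_random_sequence(self):
        rng = np.random.default_rng(31)
        seq = "".join(rng.choice(list("ACGT"), size=10_000))
        m = cc.compile_motif(cc.MotifSpec("WGATAR"))
        found = set(m.find(seq).tolist())
        expected = {
            i for i in range(len(seq) - 5) if seq[i: i + 6] in WGATAR_BOTH
        }
        assert found == expected

    def test_overlapping_matches_are_all_reported(self):
        # TGATAA at 0 and AGATAA... construct overlap via "TGATAGATAA"
        m = cc.compile_motif(cc.MotifSpec("WGATAR"), both_strands=False)
        hits = set(m.find("TGATAGATAA").tolist())
        assert hits == {0, 4}


class TestPeakMotifFraction:
    def test_all_c_genome_has_no_matches(self):
        genome = GenomeSequence({"c1": "C" * 1000})
        peaks = [BedInterval("c1", 0, 180), BedInterval("c1", 200, 380)]
        n, frac = cc.peak_motif_fraction(peaks, genome)
        assert n == 0 and frac == 0.0

    def test_match_must_lie_inside_peak(self):
        genome = GenomeSequence({"c1": "C" * 100 + "AGATAA" + "C" * 100})
        inside = [BedInterval("c1", 95, 115)]
        straddling = [BedInterval("c1", 0, 103)]  # match start 100, end 106
        assert cc.peak_motif_fraction(inside, genome)[0] == 1
        assert cc.peak_motif_fraction(straddling, genome)[0] == 0

    def test_peak_beyond_contig_raises(self):
        genome = GenomeSequence({"c1": "ACGT" * 10})
        with pytest.raises(ValueError, match="exceeds"):
            cc.peak_motif_fraction([BedInterval("c1", 30, 60)], genome)

    def test_planted_sites_are_detected(self):
        cfg = cc.SimulationConfig(
            n_contigs=1, contig_length=200_000, n_shared_sites=20,
            n_specific_sites_a=0, n_specific_sites_b=0, p_motif_plant=1.0,
            seed=33,
        )
        genome = cc.generate_genome(cfg)
        genome, manifest = cc.plant_sites(genome, cfg)
        peaks = [
            BedInterval(s.contig, s.position - 90, s.position + 90)
            for s in manifest.sites
        ]
        n, frac = cc.peak_motif_fraction(peaks, genome)
        assert frac == 1.0


def test_stratified_table_consistent_with_whole_set():
    cfg = cc.SimulationConfig(
        n_contigs=1, contig_length=200_000, n_shared_sites=30,
        n_specific_sites_a=0, n_specific_sites_b=0, seed=34,
    )
    genome = cc.generate_genome(cfg)
    genome, manifest = cc.plant_sites(genome, cfg)
    peaks = [
        BedInterval(s.contig, s.position - 90, s.position + 90, name=f"p{i}")
        for i, s in enumerate(manifest.sites)
    ]
    table = cc.stratified_motif_table(
        {"all": peaks, "first_half": peaks[:15], "empty": []}, genome
    )
    table = table.set_index("group")
    n_all, frac_all = cc.peak_motif_fraction(peaks, genome)
    assert table.loc["all", "n_with_motif"] == n_all
    assert table.loc["all", "percent"] == round(100 * frac_all, 1)
    assert table.loc["empty", "n_peaks"] == 0
    assert table.loc["empty", "percent"] is pd_na()
    # group counts reconstruct the whole-set count when groups partition it
    half2 = cc.peak_motif_fraction(peaks[15:], genome)[0]
    assert table.loc["first_half", "n_with_motif"] + half2 == n_all


def pd_na():
    import pandas as pd

    return pd.NA


class TestRpkm:
    def frag(self, start, end, contig="c1"):
        return cc.FragmentInterval(contig, start, end, "+")

    def test_unit_arithmetic(self):
        peak = BedInterval("c1", 0, 1000, name="p")
        frags = [self.frag(400, 600)] * 1000  # midpoints at 500
        (sig,) = cc.rpkm_scores([peak], frags, library_depth=1_000_000)
        assert sig.fragment_count == 1000
        assert sig.rpkm == pytest.approx(1000.0)

    def test_zero_fragments(self):
        (sig,) = cc.rpkm_scores(
            [BedInterval("c1", 0, 500)], [], library_depth=1000
        )
        assert sig.rpkm == 0.0

    def test_invariant_under_library_duplication(self):
        rng = np.random.default_rng(35)
        frags = [
            self.frag(int(s), int(s) + 180) for s in rng.integers(0, 9_000, 300)
        ]
        peaks = [BedInterval("c1", i * 1000, i * 1000 + 500, name=f"p{i}")
                 for i in range(9)]
        base = cc.rpkm_scores(peaks, frags, library_depth=len(frags))
        doubled = cc.rpkm_scores(peaks, frags * 2, library_depth=2 * len(frags))
        for a, b in zip(base, doubled):
            assert b.rpkm == pytest.approx(a.rpkm, rel=1e-12)

    def test_membership_is_by_midpoint(self):
        peak = BedInterval("c1", 100, 200)
        inside = self.frag(20, 190)  # midpoint 105
        outside = self.frag(150, 420)  # midpoint 285
        sigs = cc.rpkm_scores([peak], [inside, outside], library_depth=2)
        assert sigs[0].fragment_count == 1


class TestSignalCurve:
    def sig(self, values):
        return [cc.PeakSignal(f"p{i}", 0, v) for i, v in enumerate(values)]

    def test_constant_signals_flat_at_100(self):
        _, y = cc.sorted_signal_curve(self.sig([5.0, 5.0, 5.0]))
        assert y.tolist() == [100.0, 100.0, 100.0]

    def test_simple_values(self):
        x, y = cc.sorted_signal_curve(self.sig([1.0, 2.0, 4.0]))
        assert y.tolist() == [25.0, 50.0, 100.0]
        assert x.tolist() == [0.0, 0.5, 1.0]

    def test_curve_non_decreasing_and_ends_at_100(self):
        rng = np.random.default_rng(36)
        x, y = cc.sorted_signal_curve(self.sig(rng.exponential(3, 500)))
        assert (np.diff(y) >= 0).all()
        assert y[-1] == 100.0
        assert x[0] == 0.0 and x[-1] == 1.0


class TestSignalSummary:
    def test_linear_interpolation_quantiles(self):
        sigs = [cc.PeakSignal(f"p{i}", 0, float(i)) for i in range(1, 101)]
        s = cc.signal_summary(sigs)
        assert s.median == pytest.approx(50.5)
        assert s.p25 == pytest.approx(25.75)
        assert s.p75 == pytest.approx(75.25)
        assert s.mean == pytest.approx(50.5)

    def test_constant_signals_collapse(self):
        s = cc.signal_summary([cc.PeakSignal("p", 0, 2.5)] * 10)
        assert s.p5 == s.p25 == s.median == s.p75 == s.p95 == s.mean == 2.5

    def test_quantile_ordering_invariant(self):
        rng = np.random.default_rng(37)
        s = cc.signal_summary(
            [cc.PeakSignal(f"p{i}", 0, v) for i, v in
             enumerate(rng.lognormal(0, 1, 200))]
        )
        assert s.p5 <= s.p25 <= s.median <= s.p75 <= s.p95
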
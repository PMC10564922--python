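"""Dual-caller consensus, support filtering, annotation and summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cernaforge.circ_consensus import (
    CircRecord,
    ConsensusConfig,
    annotate_circ,
    characterize,
    counts_frame,
    filter_by_support,
    intersect_callers,
    per_sample_report,
)
from cernaforge.io_formats import BSJCall, GeneModel


def mk_calls(junctions, caller, samples=("s1",), reads=5, strand="+"):
    return [
        BSJCall(chrom, start, end, strand, reads, caller, smp)
        for chrom, start, end in junctions
        for smp in samples
    ]


class TestIntersectCallers:
    def test_identical_call_sets_fully_retained(self):
        juncs = [("chr1", 10, 500), ("chr2", 30, 900)]
        a = mk_calls(juncs, "find_circ")
        b = mk_calls(juncs, "circexplorer2")
        out = intersect_callers(a, b)
        assert [c.circ_id for c in out] == ["chr1_10_500", "chr2_30_900"]

    def test_disjoint_call_sets_give_empty_consensus(self):
        a = mk_calls([("chr1", 10, 500)], "find_circ")
        b = mk_calls([("chr1", 11, 500)], "circexplorer2")
        assert intersect_callers(a, b) == []

    def test_count_is_per_sample_maximum(self):
        a = mk_calls([("chr1", 10, 500)], "find_circ", reads=3)
        b = mk_calls([("chr1", 10, 500)], "circexplorer2", reads=9)
        (rec,) = intersect_callers(a, b)
        assert rec.counts.tolist() == [9]

    def test_tolerance_matches_wobbled_junctions(self):
        a = mk_calls([("chr1", 100, 500)], "find_circ")
        b = mk_calls([("chr1", 102, 499)], "circexplorer2")
        assert intersect_callers(a, b, tolerance=0) == []
        (rec,) = intersect_callers(a, b, tolerance=2)
        assert rec.circ_id == "chr1_100_500"  # caller A coordinates kept

    def test_unstranded_call_matches_either_strand(self):
        a = mk_calls([("chr1", 10, 500)], "find_circ", strand=".")
        b = mk_calls([("chr1", 10, 500)], "circexplorer2", strand="-")
        (rec,) = intersect_callers(a, b)
        assert rec.strand == "-"
        a = mk_calls([("chr1", 10, 500)], "find_circ", strand="+")
        assert intersect_callers(a, b) == []

    def test_matches_bruteforce_set_intersection_on_bundle(self, bundle):
        out = intersect_callers(bundle.calls_a, bundle.calls_b)
        # independent oracle: plain set intersection of junction keys that
        # share at least one co-observed sample
        by_key_a, by_key_b = {}, {}
        for c in bundle.calls_a:
            by_key_a.setdefault((c.chrom, c.start, c.end), set()).add(c.sample_id)
        for c in bundle.calls_b:
            by_key_b.setdefault((c.chrom, c.start, c.end), set()).add(c.sample_id)
        expected = {
            f"{k[0]}_{k[1]}_{k[2]}"
            for k in set(by_key_a) & set(by_key_b)
            if by_key_a[k] & by_key_b[k]
        }
        assert {c.circ_id for c in out} == expected
        assert expected == set(bundle.truth.consensus_circ_ids)

    def test_symmetry_of_consensus_ids(self, bundle):
        ab = {c.circ_id for c in intersect_callers(bundle.calls_a, bundle.calls_b)}
        ba = {c.circ_id for c in intersect_callers(bundle.calls_b, bundle.calls_a)}
        assert ab == ba


class TestFilterBySupport:
    def rec(self, counts):
        return CircRecord("chr1_1_2", "chr1", 1, 2, "+",
                          [f"s{i}" for i in range(len(counts))], np.array(counts))

    def test_strict_majority_of_18_samples(self):
        cfg = ConsensusConfig(min_reads=2)
        ten = self.rec([2] * 10 + [0] * 8)
        nine = self.rec([2] * 9 + [0] * 9)
        assert filter_by_support([ten], cfg, 18) == [ten]
        assert filter_by_support([nine], cfg, 18) == []

    def test_all_zero_row_removed(self):
        assert filter_by_support([self.rec([0] * 6)], ConsensusConfig(), 6) == []

    @given(st.lists(st.integers(0, 20), min_size=4, max_size=12),
           st.integers(1, 5))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_raising_min_reads_never_grows_retained_set(self, counts, min_reads):
        rec = self.rec(counts)
        n = len(counts)
        lo = filter_by_support([rec], ConsensusConfig(min_reads=min_reads), n)
        hi = filter_by_support([rec], ConsensusConfig(min_reads=min_reads + 1), n)
        assert set(c.circ_id for c in hi) <= set(c.circ_id for c in lo)


GENES = [
    GeneModel("HOST1", "protein_coding", "TX1", "chr1", "+",
              [(0, 100), (500, 620), (1000, 1090), (1500, 1650), (2000, 2100)]),
    GeneModel("LNC1", "lncRNA", "TX2", "chr1", "+", [(5000, 5400)]),
]


class TestAnnotation:
    def circ(self, start, end, strand="+", chrom="chr1"):
        return CircRecord(f"{chrom}_{start}_{end}", chrom, start, end, strand,
                          ["s1"], np.array([5]))

    def test_exonic_circ_is_protein_coding_with_summed_exons(self):
        c = annotate_circ(self.circ(500, 1650), GENES)  # spans exons 2-4
        assert c.annotation_class == "protein_coding"
        assert c.host_gene_id == "HOST1"
        assert c.exon_count == 3
        assert c.spliced_length == 120 + 90 + 150

    def test_intronic_same_strand_circ(self):
        c = annotate_circ(self.circ(150, 400), GENES)
        assert c.annotation_class == "sense_intronic"
        # opposite strand does not qualify as sense-intronic
        c2 = annotate_circ(self.circ(150, 400, strand="-"), GENES)
        assert c2.annotation_class == "intergenic"

    def test_lncrna_overlap(self):
        c = annotate_circ(self.circ(5100, 5300), GENES)
        assert c.annotation_class == "lncRNA"

    def test_unannotatable_is_intergenic(self):
        c = annotate_circ(self.circ(100, 300, chrom="chr9"), GENES)
        assert c.annotation_class == "intergenic"

    def test_every_class_assigned_exactly_once_on_bundle(self, bundle):
        from cernaforge.circ_consensus import annotate_all, intersect_callers

        circs = annotate_all(intersect_callers(bundle.calls_a, bundle.calls_b),
                             bundle.gene_models)
        for c in circs:
            assert c.annotation_class in (
                "protein_coding", "sense_intronic", "lncRNA", "intergenic")
            assert c.annotation_class == bundle.truth.annotation_classes[c.circ_id]


class TestCharacterize:
    def test_gene_with_eleven_isoforms_lands_in_open_bin(self):
        circs = [
            CircRecord(f"chr1_{i}_{i + 300}", "chr1", i, i + 300, "+", ["s"],
                       np.array([3]), "protein_coding", "G1", 2, 300)
            for i in range(0, 11000, 1000)
        ]
        hists = characterize(circs)
        assert hists["isoforms_per_gene"][">10"] == 1

    def test_histograms_count_planted_values(self):
        circs = [
            CircRecord("chr1_0_100", "chr1", 0, 100, "+", ["s"], np.array([1]),
                       "protein_coding", "G1", 2, 250),
            CircRecord("chr1_5_105", "chr1", 5, 105, "+", ["s"], np.array([1]),
                       "protein_coding", "G1", 3, 700),
            CircRecord("chr2_0_99", "chr2", 0, 99, "+", ["s"], np.array([1]),
                       "protein_coding", "G2", 12, 2500),
        ]
        hists = characterize(circs)
        assert hists["isoforms_per_gene"]["2"] == 1
        assert hists["isoforms_per_gene"]["1"] == 1
        assert hists["spliced_length"]["200-400"] == 1
        assert hists["spliced_length"]["600-800"] == 1
        assert hists["spliced_length"]["2000+"] == 1
        assert hists["exon_count"]["2"] == 1 and hists["exon_count"][">10"] == 1

    def test_empty_input_gives_empty_histograms(self):
        hists = characterize([])
        assert all(h.empty for h in hists.values())


def test_per_sample_report_counts_overlap(bundle):
    report = per_sample_report(bundle.calls_a, bundle.calls_b)
    assert set(report["sample_id"]) == set(bundle.groups.index)
    assert (report["overlap"] <= report[["find_circ", "circexplorer2"]].min(axis=1)).all()


def test_counts_frame_shape(bundle):
    recs = intersect_callers(bundle.calls_a, bundle.calls_b)
    frame = counts_frame(recs)
    assert frame.shape == (len(recs), len(bundle.groups))
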
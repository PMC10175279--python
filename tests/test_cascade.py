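import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from altprom.cascade import (
    DirectionalityScore,
    PooledCtss,
    classify_erna,
    cluster_novel,
    directionality_score,
    filter_exonic_gg,
    initiator_dinucleotide,
    overlap_filter,
    transcript_5p_support,
)
from altprom.clustering import ConsensusCluster
from altprom.ctss import CtssRecord
from altprom.intervals import GenomicInterval


def _cluster(cid, start, end, strand="+", dominant=None, chrom="chr1", expr=(1.0,)):
    dominant = dominant if dominant is not None else start
    return ConsensusCluster(
        cluster_id=cid, chrom=chrom, strand=strand, start=start, end=end,
        dominant_pos=dominant, iq_start=dominant, iq_end=dominant + 1,
        expr=np.asarray(expr, dtype=float), samples=["s"],
    )


def test_overlap_filter_half_open_boundary():
    clusters = [_cluster("a", 100, 120), _cluster("b", 200, 220)]
    removed = overlap_filter(clusters, [GenomicInterval("chr1", 110, 130)])
    assert [c.cluster_id for c in removed] == ["b"]
    kept = overlap_filter(clusters, [GenomicInterval("chr1", 120, 130)])
    assert [c.cluster_id for c in kept] == ["a", "b"]  # touching [120,130) kept
    assert overlap_filter(clusters, []) == clusters


class TestInitiator:
    # positions:      0123456789
    genome = {"chr1": "AACAGGTTCC"}

    def test_yr_pyrimidine_purine(self):
        # -1 base C (pos 2), TSS base A (pos 3)
        assert initiator_dinucleotide(3, "+", self.genome, "chr1") == "YR"

    def test_gg_takes_priority(self):
        # -1 G (pos 4), TSS G (pos 5)
        assert initiator_dinucleotide(5, "+", self.genome, "chr1") == "GG"

    def test_minus_strand_reverse_complement(self):
        # plus-strand "CC" at (pos, pos+1) reads GG on the minus strand
        assert initiator_dinucleotide(8, "-", self.genome, "chr1") == "GG"

    def test_yc_class(self):
        # -1 T (pos 7), TSS C (pos 8)
        assert initiator_dinucleotide(8, "+", self.genome, "chr1") == "YC"

    def test_contig_edge_is_other(self):
        assert initiator_dinucleotide(0, "+", self.genome, "chr1") == "other"
        assert initiator_dinucleotide(9, "-", self.genome, "chr1") == "other"


def test_filter_exonic_gg_removes_exonic_and_gg():
    genome = {"chr1": "AACAGGTTCC" * 100}
    exons = [GenomicInterval("chr1", 0, 50)]
    exonic_yr = _cluster("exonic", 10, 20, dominant=13)       # YR but on exon
    intronic_gg = _cluster("gg", 100, 120, dominant=105)      # GG initiator
    intronic_yr = _cluster("ok", 200, 220, dominant=203)      # YR, intronic
    kept = filter_exonic_gg([exonic_yr, intronic_gg, intronic_yr], exons, genome)
    assert [c.cluster_id for c in kept] == ["ok"]


def test_directionality_score_formula():
    assert DirectionalityScore(3.0, 1.0).ds == pytest.approx(0.5)
    assert DirectionalityScore(10.0, 0.0).ds == pytest.approx(1.0)
    assert DirectionalityScore(2.0, 6.0).ds == pytest.approx(-0.5)
    assert DirectionalityScore(0.0, 0.0).ds is None


def test_directionality_score_window_sums():
    records = [
        CtssRecord("chr1", 1000, "+", 3, 3.0),
        CtssRecord("chr1", 1100, "-", 1, 1.0),
        CtssRecord("chr1", 5000, "+", 50, 50.0),  # outside the window
    ]
    pooled = PooledCtss(records)
    score = directionality_score(pooled, GenomicInterval("chr1", 1000, 1101), flank=200)
    assert score.forward_tpm == 3.0 and score.reverse_tpm == 1.0
    assert score.ds == pytest.approx(0.5)


@settings(derandomize=True, max_examples=50)
@given(fwd=st.floats(0, 1e6), rev=st.floats(0, 1e6))
def test_ds_antisymmetric_under_strand_swap(fwd, rev):
    a, b = DirectionalityScore(fwd, rev).ds, DirectionalityScore(rev, fwd).ds
    if a is None:
        assert b is None
    else:
        assert a == pytest.approx(-b)
        assert -1.0 <= a <= 1.0


def test_classify_erna_band_inclusive():
    assert classify_erna(0.0) is True
    assert classify_erna(0.5) is True
    assert classify_erna(-0.5) is True
    assert classify_erna(0.8) is False
    assert classify_erna(None) is False


def test_cluster_novel_single_linkage_300b():
    a = _cluster("a", 1000, 1010, dominant=1000)
    b = _cluster("b", 1250, 1260, dominant=1250, expr=(5.0,))
    c = _cluster("c", 1600, 1610, dominant=1600)
    novel = cluster_novel([a, b, c], max_span=300)
    # 250 <= 300 merges a+b (b dominates by TPM); 350 > 300 keeps c apart
    assert len(novel) == 2
    assert novel[0].member_cluster_ids == ["a", "b"]
    assert novel[0].dominant_pos == 1250
    assert novel[1].member_cluster_ids == ["c"]


def test_cluster_novel_strand_separation():
    a = _cluster("a", 1000, 1010, dominant=1000, strand="+")
    b = _cluster("b", 1100, 1110, dominant=1100, strand="-")
    assert len(cluster_novel([a, b])) == 2


class TestSupport:
    def _novel(self, pos=10000, strand="+"):
        from altprom.cascade import NovelTss
        return NovelTss("N1", "chr1", strand, pos, ["c1"])

    def test_supported_by_distal_5p_end(self):
        ok = transcript_5p_support(
            self._novel(), [("chr1", 10120, "+")], [("chr1", 15000, "+")])
        assert ok is True

    def test_annotation_proximal_ends_discarded(self):
        # the supporting end is 120 b from the novel TSS but 200 b from an
        # annotated TSS, so it is discarded first -> unsupported
        ok = transcript_5p_support(
            self._novel(), [("chr1", 10120, "+")], [("chr1", 10320, "+")])
        assert ok is False

    def test_no_supporting_ends(self):
        assert transcript_5p_support(self._novel(), [], []) is False

    def test_strand_must_match(self):
        ok = transcript_5p_support(
            self._novel(), [("chr1", 10120, "-")], [])
        assert ok is False

    def test_window_boundary(self):
        assert transcript_5p_support(self._novel(), [("chr1", 10300, "+")], [])
        assert not transcript_5p_support(self._novel(), [("chr1", 10301, "+")], [])


def test_cascade_monotone_and_audited(sim_default, pipeline_result):
    """Each stage only removes clusters; audit rows reconcile with input."""
    records = pipeline_result.cascade_records
    assert len(records) == pipeline_result.counts["intragenic"]
    stages = ["small_rna", "exonic_gg", "enhancer_overlap", "erna_ds", "initiator"]
    survivors = len(records)
    for i, stage in enumerate(stages):
        passed = sum(1 for r in records if r.stage_flags.get(stage, False))
        assert passed <= survivors
        # a cluster evaluated at stage i passed all earlier stages
        for r in records:
            if stage in r.stage_flags:
                assert all(r.stage_flags.get(s, False) for s in stages[:i])
        survivors = passed
    for r in records:
        if r.final_novel_tss_id is not None:
            assert r.passed_all
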
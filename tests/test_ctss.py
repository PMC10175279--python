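import pysam
import pytest

from altprom.ctss import (
    CtssRecord,
    apply_g_correction,
    extract_ctss,
    filter_blacklist,
    tpm_normalize,
)
from altprom.intervals import GenomicInterval

SAM_HEADER = "@HD\tVN:1.6\tSO:coordinate\n@SQ\tSN:chr1\tLN:1000\n"


def _sam(tmp_path, lines):
    path = tmp_path / "reads.sam"
    path.write_text(SAM_HEADER + "".join(lines))
    return path


def _read(name, flag, pos1, mapq, cigar, seq):
    qual = "I" * len(seq)
    return f"{name}\t{flag}\tchr1\t{pos1}\t{mapq}\t{cigar}\t*\t0\t0\t{seq}\t{qual}\n"


def test_extract_ctss_strand_and_mapq(tmp_path):
    """5' ends are strand-aware and MAPQ<20 reads contribute nothing."""
    lines = [
        _read("fwd", 0, 101, 30, "26M", "A" * 26),     # + read at 0-based 100
        _read("rev", 16, 101, 30, "26M", "A" * 26),    # - read: 5' end at 125
        _read("lowq", 0, 101, 19, "26M", "A" * 26),    # dropped
        _read("unmapped", 4, 0, 0, "*", "A" * 26),     # skipped, no exception
    ]
    with pysam.AlignmentFile(_sam(tmp_path, lines), "r") as af:
        records = extract_ctss(af, genome=None, mapq_min=20)
    assert [(r.chrom, r.pos, r.strand, r.count) for r in records] == [
        ("chr1", 100, "+", 1),
        ("chr1", 125, "-", 1),
    ]


def test_extract_ctss_counts_aggregate_per_position(tmp_path):
    lines = [_read(f"r{i}", 0, 101, 30, "10M", "A" * 10) for i in range(3)]
    with pysam.AlignmentFile(_sam(tmp_path, lines), "r") as af:
        records = extract_ctss(af)
    assert records == [CtssRecord("chr1", 100, "+", 3)]


class TestGCorrection:
    genome = {"chr1": "A" * 1000}

    def test_softclipped_cap_g_consumed_no_shift(self):
        # the clip is already excluded from the alignment: position unchanged
        assert apply_g_correction(100, "+", "G", "A", self.genome, "chr1") == 100

    def test_mismatching_first_g_shifts_downstream(self):
        # mis-incorporated cap G occupies the first aligned column
        assert apply_g_correction(100, "+", "", "G", self.genome, "chr1") == 101

    def test_matching_first_g_is_genomic_no_shift(self):
        genome = {"chr1": "A" * 100 + "G" + "A" * 899}
        assert apply_g_correction(100, "+", "", "G", genome, "chr1") == 100

    def test_minus_strand_shift_mirrored(self):
        # on '-', moving into the read body decreases the coordinate
        assert apply_g_correction(125, "-", "", "G", self.genome, "chr1") == 124

    def test_non_g_first_base_untouched(self):
        assert apply_g_correction(100, "+", "", "A", self.genome, "chr1") == 100

    def test_out_of_bounds_position_left_unshifted(self):
        assert apply_g_correction(5000, "+", "", "G", self.genome, "chr1") == 5000

    def test_never_moves_more_than_one_base(self):
        for strand in "+-":
            for first in "ACGT":
                pos = apply_g_correction(50, strand, "", first, self.genome, "chr1")
                assert abs(pos - 50) <= 1


def test_extract_ctss_applies_g_correction_from_sam(tmp_path):
    genome = {"chr1": "A" * 1000}
    lines = [
        # + read whose first aligned base is an unmapped cap G -> shift to 101
        _read("g_mis", 0, 101, 30, "10M", "G" + "A" * 9),
        # + read with the G soft-clipped -> 5' stays at first aligned base 100
        _read("g_clip", 0, 101, 30, "1S9M", "G" + "A" * 9),
        # - read whose biological first base is G (stored seq ends with C)
        _read("g_rev", 16, 101, 30, "10M", "A" * 9 + "C"),
    ]
    with pysam.AlignmentFile(_sam(tmp_path, lines), "r") as af:
        records = extract_ctss(af, genome=genome)
    got = {(r.pos, r.strand): r.count for r in records}
    assert got == {(101, "+"): 1, (100, "+"): 1, (108, "-"): 1}


def test_filter_blacklist_half_open_boundary():
    ctss = [CtssRecord("chr1", 150, "+", 1), CtssRecord("chr1", 99, "+", 1),
            CtssRecord("chr1", 200, "+", 1)]
    blk = [GenomicInterval("chr1", 100, 200)]
    kept = filter_blacklist(ctss, blk)
    assert [r.pos for r in kept] == [99, 200]
    assert filter_blacklist(ctss, []) == ctss


def test_tpm_normalize_proportions_and_conservation():
    recs = tpm_normalize([CtssRecord("c", 1, "+", 1), CtssRecord("c", 2, "+", 3)])
    assert [r.tpm for r in recs] == [250000.0, 750000.0]
    assert abs(sum(r.tpm for r in recs) - 1e6) < 1e-6


def test_tpm_normalize_empty_library_errors():
    with pytest.raises(ValueError, match="empty library"):
        tpm_normalize([])
    with pytest.raises(ValueError, match="empty library"):
        tpm_normalize([CtssRecord("c", 1, "+", 0)])


def test_extract_total_counts_equal_retained_reads(tmp_path):
    lines = [_read(f"r{i}", 0, 101 + 7 * i, 30, "10M", "A" * 10) for i in range(5)]
    lines += [_read("low", 0, 300, 5, "10M", "A" * 10)]
    with pysam.AlignmentFile(_sam(tmp_path, lines), "r") as af:
        records = extract_ctss(af)
    assert sum(r.count for r in records) == 5
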
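"""CTSS extraction: aligned CAGE reads → filtered, G-corrected, TPM-normalized
per-sample CTSS tables.

A CTSS (CAGE transcription start site) is the strand-aware 5'-most aligned
base of a CAGE read.  The CAGE protocol frequently adds an extra template-free
G to the capped 5' end; when that G is absorbed into the alignment as a
mismatch the reported TSS is off by one base, so positions are corrected by
shifting one base into the read body whenever the first aligned base is a G
that mismatches the reference.  Soft-clipped leading bases are already
excluded from the alignment and need no shift.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Mapping

from .intervals import GenomicInterval, RegionIndex

log = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class CtssRecord:
    """One strand-specific single-base 5' end with a per-sample tag count."""

    chrom: str
    pos: int
    strand: str
    count: int
    tpm: float = float("nan")


def _ref_base(genome: Mapping[str, object], chrom: str, pos: int) -> str | None:
    """Uppercase reference base at pos, or None when out of bounds."""
    try:
        seq = genome[chrom]
    except KeyError:
        return None
    if pos < 0 or pos >= len(seq):
        return None
    return str(seq[pos]).upper()


def apply_g_correction(
    five_prime_pos: int,
    strand: str,
    leading_softclip_seq: str,
    first_aligned_base: str,
    genome: Mapping[str, object],
    chrom: str,
) -> int:
    """Return the cap-corrected CTSS position for one read.

    ``leading_softclip_seq`` is the soft-clipped prefix at the read's 5' end
    in read orientation ('' if none); ``first_aligned_base`` is the first
    aligned base of the read, also in read orientation.  If the read starts
    with a soft clip, the extra cap G (if any) was already excluded from the
    alignment and the position is unchanged.  Otherwise, a first aligned base
    that is a G mismatching the reference is taken to be the mis-incorporated
    cap G, and the reported TSS moves one base into the read body (downstream
    on '+', the mirrored direction on '-').  Positions never move by more
    than 1 nt.
    """
    if leading_softclip_seq:
        return five_prime_pos
    if first_aligned_base.upper() != "G":
        return five_prime_pos
    ref = _ref_base(genome, chrom, five_prime_pos)
    if ref is None:
        log.warning("g-correction: %s:%d out of genome bounds; skipped", chrom, five_prime_pos)
        return five_prime_pos
    if strand == "-":
        ref = ref.translate(_COMPLEMENT)
    if ref == "G":
        return five_prime_pos
    return five_prime_pos + 1 if strand == "+" else five_prime_pos - 1


def extract_ctss(
    alignments: Iterable,
    genome: Mapping[str, object] | None = None,
    mapq_min: int = 20,
    g_correction: bool = True,
) -> list[CtssRecord]:
    """Aggregate strand-aware read 5' ends into per-position tag counts.

    ``alignments`` is any iterable of :class:`pysam.AlignedSegment` (e.g. a
    :class:`pysam.AlignmentFile`).  Unmapped reads are skipped (counted in the
    log, never an exception); reads with MAPQ below ``mapq_min`` are
    discarded.  When ``genome`` is given and ``g_correction`` is on, the
    unmapped-cap-G shift is applied per read.
    """
    counts: dict[tuple[str, int, str], int] = {}
    n_unmapped = n_lowq = n_kept = 0
    for read in alignments:
        if read.is_unmapped:
            n_unmapped += 1
            continue
        if read.mapping_quality < mapq_min:
            n_lowq += 1
            continue
        chrom = read.reference_name
        if read.is_reverse:
            strand = "-"
            pos = read.reference_end - 1
        else:
            strand = "+"
            pos = read.reference_start
        seq = read.query_sequence or ""
        if g_correction and genome is not None and seq:
            if read.is_reverse:
                # stored sequence is the reverse complement of the read;
                # the read's 5' clip/base sit at the stored 3' end
                clip = revcomp(seq[read.query_alignment_end:])
                first = revcomp(seq[read.query_alignment_end - 1])
            else:
                clip = seq[: read.query_alignment_start]
                first = seq[read.query_alignment_start]
            pos = apply_g_correction(pos, strand, clip, first, genome, chrom)
        counts[(chrom, pos, strand)] = counts.get((chrom, pos, strand), 0) + 1
        n_kept += 1
    log.info(
        "extract_ctss: kept %d reads (%d unmapped, %d MAPQ<%d discarded), %d CTSS positions",
        n_kept, n_unmapped, n_lowq, mapq_min, len(counts),
    )
    return [
        CtssRecord(chrom, pos, strand, n)
        for (chrom, pos, strand), n in sorted(counts.items())
    ]


def filter_blacklist(
    ctss: list[CtssRecord], blacklist: list[GenomicInterval] | RegionIndex
) -> list[CtssRecord]:
    """Drop CTSSs whose base overlaps any blacklist interval (order preserved)."""
    index = blacklist if isinstance(blacklist, RegionIndex) else RegionIndex(blacklist)
    kept = [r for r in ctss if not index.overlaps(r.chrom, r.pos, r.pos + 1)]
    log.info("filter_blacklist: %d -> %d CTSSs", len(ctss), len(kept))
    return kept


def tpm_normalize(ctss: list[CtssRecord], scale: float = 1e6) -> list[CtssRecord]:
    """Set tpm = count * scale / library total; the totals sum to ``scale``."""
    total = sum(r.count for r in ctss)
    if total <= 0:
        raise ValueError("empty library: no CTSS counts to normalize")
    return [replace(r, tpm=r.count * scale / total) for r in ctss]
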
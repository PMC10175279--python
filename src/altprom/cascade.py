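"""Filtering cascade promoting intragenic clusters to novel alternative TSSs.

Intragenic CAGE clusters are a mix of genuine alternative promoters and
non-promoter signal: small-RNA processing products (drosha sites of
pre-miRNAs, snoRNA 5'-end capping), post-transcriptionally recapped exonic
tags (GG initiation on coding exons), and enhancer RNAs (balanced
bidirectional transcription).  The cascade removes each class in a fixed
order, retains only clusters with a canonical YR or YC transcription
initiator, merges survivors within 300 b into novel alternative TSSs, and
finally checks for independent transcript 5'-end support (RNA-seq/EST),
ignoring supporting ends that sit within 300 b of an annotated TSS.

Stage order: small RNA → coding exon / GG initiation → annotated enhancer →
eRNA directionality → initiator motif → 300-b clustering → 5'-end support.
Each stage's survivor set is a subset of the previous one and every input
cluster receives a per-stage audit record.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .clustering import ConsensusCluster
from .ctss import CtssRecord
from .intervals import GenomicInterval, RegionIndex

log = logging.getLogger(__name__)

STAGES = ["small_rna", "exonic_gg", "enhancer_overlap", "erna_ds", "initiator"]


@dataclass
class DirectionalityScore:
    """DS = (forward - reverse) / (forward + reverse) TPM in a window.

    DS is in [-1, 1]; near +1/-1 means unidirectional (promoter-like)
    transcription, while |DS| <= 0.5 is the balanced bidirectional signature
    of enhancer RNAs.  Undefined (ds=None) when the window has no signal.
    """

    forward_tpm: float
    reverse_tpm: float

    @property
    def ds(self) -> float | None:
        total = self.forward_tpm + self.reverse_tpm
        if total <= 0:
            return None
        return (self.forward_tpm - self.reverse_tpm) / total


@dataclass
class CascadeRecord:
    cluster_id: str
    stage_flags: dict[str, bool] = field(default_factory=dict)
    ds: float | None = None
    initiator_class: str = "other"
    final_novel_tss_id: str | None = None
    support: bool = False

    @property
    def passed_all(self) -> bool:
        return all(self.stage_flags.get(s, False) for s in STAGES)


@dataclass
class NovelTss:
    novel_id: str
    chrom: str
    strand: str
    dominant_pos: int
    member_cluster_ids: list[str]
    support: bool = False


class PooledCtss:
    """Cohort-pooled per-strand CTSS TPM, indexable by genomic window."""

    def __init__(self, records: Sequence[CtssRecord]):
        acc: dict[tuple[str, str], dict[int, float]] = {}
        for r in records:
            acc.setdefault((r.chrom, r.strand), {})
            tpm = r.tpm if r.tpm == r.tpm else float(r.count)  # NaN tpm -> counts
            acc[(r.chrom, r.strand)][r.pos] = acc[(r.chrom, r.strand)].get(r.pos, 0.0) + tpm
        self._pos: dict[tuple[str, str], np.ndarray] = {}
        self._tpm: dict[tuple[str, str], np.ndarray] = {}
        for key, d in acc.items():
            pos = np.array(sorted(d))
            self._pos[key] = pos
            self._tpm[key] = np.array([d[p] for p in pos]).cumsum()

    def window_tpm(self, chrom: str, strand: str, start: int, end: int) -> float:
        """Total TPM on one strand in [start, end)."""
        pos = self._pos.get((chrom, strand))
        if pos is None:
            return 0.0
        cum = self._tpm[(chrom, strand)]
        i, j = np.searchsorted(pos, start), np.searchsorted(pos, end)
        if j == 0:
            return 0.0
        return float(cum[j - 1] - (cum[i - 1] if i > 0 else 0.0))


def overlap_filter(
    clusters: Sequence[ConsensusCluster],
    regions: Sequence[GenomicInterval] | RegionIndex,
) -> list[ConsensusCluster]:
    """Drop clusters whose envelope overlaps >=1 bp of any region."""
    index = regions if isinstance(regions, RegionIndex) else RegionIndex(list(regions))
    kept = [c for c in clusters if not index.overlaps(c.chrom, c.start, c.end)]
    log.info("overlap_filter: %d -> %d clusters", len(clusters), len(kept))
    return kept


def initiator_dinucleotide(dominant_pos: int, strand: str, genome: Mapping[str, object],
                           chrom: str) -> str:
    """Classify the (-1, +1) initiator dinucleotide on the cluster strand.

    GG marks recapping artifacts and takes priority; YR (pyrimidine-purine)
    is the canonical initiator; YC is the weaker pyrimidine-C variant.
    Contig-edge positions classify as 'other'.
    """
    try:
        seq = genome[chrom]
    except KeyError:
        log.warning("initiator: unknown contig %s", chrom)
        return "other"
    if strand == "-":
        lo, hi = dominant_pos, dominant_pos + 1
    else:
        lo, hi = dominant_pos - 1, dominant_pos
    if lo < 0 or hi >= len(seq):
        log.warning("initiator: %s:%d at contig edge", chrom, dominant_pos)
        return "other"
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    if strand == "-":
        minus1 = comp.get(str(seq[dominant_pos + 1]).upper(), "N")
        tss = comp.get(str(seq[dominant_pos]).upper(), "N")
    else:
        minus1 = str(seq[dominant_pos - 1]).upper()
        tss = str(seq[dominant_pos]).upper()
    if minus1 == "G" and tss == "G":
        return "GG"
    if minus1 in "CT" and tss in "AG":
        return "YR"
    if minus1 in "CT" and tss == "C":
        return "YC"
    return "other"


def filter_exonic_gg(
    clusters: Sequence[ConsensusCluster],
    coding_exons: Sequence[GenomicInterval] | RegionIndex,
    genome: Mapping[str, object],
) -> list[ConsensusCluster]:
    """Remove clusters on coding exons OR with a GG (recapping) initiator."""
    index = coding_exons if isinstance(coding_exons, RegionIndex) else RegionIndex(list(coding_exons))
    kept = []
    for c in clusters:
        if index.overlaps(c.chrom, c.start, c.end):
            continue
        if initiator_dinucleotide(c.dominant_pos, c.strand, genome, c.chrom) == "GG":
            continue
        kept.append(c)
    log.info("filter_exonic_gg: %d -> %d clusters", len(clusters), len(kept))
    return kept


def directionality_score(
    pooled: PooledCtss,
    region: GenomicInterval,
    flank: int = 200,
) -> DirectionalityScore:
    """DS over the region envelope ± flank, from cohort-pooled TPM."""
    start, end = max(0, region.start - flank), region.end + flank
    return DirectionalityScore(
        forward_tpm=pooled.window_tpm(region.chrom, "+", start, end),
        reverse_tpm=pooled.window_tpm(region.chrom, "-", start, end),
    )


def classify_erna(ds: float | None) -> bool:
    """eRNA iff -0.5 <= DS <= 0.5 (inclusive); undefined DS is not eRNA."""
    if ds is None:
        log.info("classify_erna: undefined DS treated as not-eRNA")
        return False
    return -0.5 <= ds <= 0.5


def cluster_novel(
    clusters: Sequence[ConsensusCluster],
    max_span: int = 300,
) -> list[NovelTss]:
    """Single-linkage merge of surviving clusters whose dominant CTSSs lie
    within ``max_span`` b on the same strand; the merged novel TSS takes the
    dominant position of its highest-TPM member."""
    items = sorted(clusters, key=lambda c: (c.chrom, c.strand, c.dominant_pos))
    groups: list[list[ConsensusCluster]] = []
    for c in items:
        if (
            groups
            and groups[-1][-1].chrom == c.chrom
            and groups[-1][-1].strand == c.strand
            and c.dominant_pos - groups[-1][-1].dominant_pos <= max_span
        ):
            groups[-1].append(c)
        else:
            groups.append([c])
    novel = []
    width = max(4, len(str(len(groups))))
    for i, g in enumerate(groups, 1):
        top = max(g, key=lambda c: (float(c.expr.sum()), -c.dominant_pos))
        novel.append(
            NovelTss(
                novel_id=f"NOVEL{i:0{width}d}",
                chrom=top.chrom,
                strand=top.strand,
                dominant_pos=top.dominant_pos,
                member_cluster_ids=[c.cluster_id for c in g],
            )
        )
    log.info("cluster_novel: %d clusters -> %d novel TSSs", len(items), len(novel))
    return novel


def transcript_5p_support(
    novel_tss: NovelTss,
    supporting_5p: Sequence[tuple[str, int, str]],
    annotated_5p: Sequence[tuple[str, int, str]],
    window: int = 300,
) -> bool:
    """Supported iff >=1 independent transcript 5' end lies within ±window of
    the novel TSS on the same strand, after discarding supporting ends within
    ±window of any annotated transcript 5' end."""
    annotated = [
        (c, p) for c, p, s in annotated_5p if s == novel_tss.strand
    ]
    for chrom, pos, strand in supporting_5p:
        if strand != novel_tss.strand or chrom != novel_tss.chrom:
            continue
        if abs(pos - novel_tss.dominant_pos) > window:
            continue
        if any(c == chrom and abs(pos - ap) <= window for c, ap in annotated):
            continue
        return True
    return False


def run_cascade(
    intragenic: Sequence[ConsensusCluster],
    small_rna_regions: Sequence[GenomicInterval],
    coding_exons: Sequence[GenomicInterval],
    enhancers: Sequence[GenomicInterval],
    pooled: PooledCtss,
    genome: Mapping[str, object],
    annotated_5p: Sequence[tuple[str, int, str]],
    supporting_5p: Sequence[tuple[str, int, str]],
    ds_flank: int = 200,
    novel_span: int = 300,
    support_window: int = 300,
) -> tuple[list[NovelTss], list[CascadeRecord]]:
    """Run the full cascade and return (novel TSSs, per-cluster audit).

    Monotone by construction: each stage only removes clusters.  Logged
    counts reconcile (input = survivors + removed at every stage).
    """
    records = {c.cluster_id: CascadeRecord(c.cluster_id) for c in intragenic}
    small_idx = RegionIndex(list(small_rna_regions))
    exon_idx = RegionIndex(list(coding_exons))
    enh_idx = RegionIndex(list(enhancers))

    surviving = []
    for c in intragenic:
        rec = records[c.cluster_id]
        rec.initiator_class = initiator_dinucleotide(c.dominant_pos, c.strand, genome, c.chrom)
        rec.stage_flags["small_rna"] = not small_idx.overlaps(c.chrom, c.start, c.end)
        if not rec.stage_flags["small_rna"]:
            continue
        rec.stage_flags["exonic_gg"] = (
            not exon_idx.overlaps(c.chrom, c.start, c.end)
            and rec.initiator_class != "GG"
        )
        if not rec.stage_flags["exonic_gg"]:
            continue
        rec.stage_flags["enhancer_overlap"] = not enh_idx.overlaps(c.chrom, c.start, c.end)
        if not rec.stage_flags["enhancer_overlap"]:
            continue
        score = directionality_score(
            pooled, GenomicInterval(c.chrom, c.start, c.end, c.strand), ds_flank
        )
        rec.ds = score.ds
        rec.stage_flags["erna_ds"] = not classify_erna(score.ds)
        if not rec.stage_flags["erna_ds"]:
            continue
        rec.stage_flags["initiator"] = rec.initiator_class in ("YR", "YC")
        if not rec.stage_flags["initiator"]:
            continue
        surviving.append(c)

    novel = cluster_novel(surviving, novel_span)
    for n in novel:
        n.support = transcript_5p_support(n, supporting_5p, annotated_5p, support_window)
        for cid in n.member_cluster_ids:
            records[cid].final_novel_tss_id = n.novel_id
            records[cid].support = n.support
    n_pass = sum(1 for r in records.values() if r.passed_all)
    log.info(
        "cascade: %d intragenic -> %d surviving -> %d novel TSSs (%d supported)",
        len(intragenic), n_pass, len(novel), sum(1 for n in novel if n.support),
    )
    return novel, sorted(records.values(), key=lambda r: r.cluster_id)
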
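"""Assignment of consensus clusters to transcripts/genes and the
reference/alternative promoter designation.

A consensus cluster becomes a gene promoter when its dominant CTSS lies
within ±window (default 300 b) of an annotated transcript TSS on the same
strand; otherwise it is intragenic when inside a same-strand gene body, else
intergenic.  Genes are single-promoter (SP) or multi-promoter (MP) by
promoter count.  Within an MP gene the promoter with the highest cohort-mean
expression that is also expressed in normal liver is the reference promoter;
all others are alternatives, each labelled upstream/downstream of the
reference strand-awarely.  Gene-level expression is the element-wise sum of
its promoters' TPM vectors.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .clustering import ConsensusCluster
from .intervals import TranscriptModel

log = logging.getLogger(__name__)


@dataclass
class ClusterAssignment:
    cluster_id: str
    category: str  # promoter | intragenic | intergenic
    gene_id: str | None = None
    transcript_id: str | None = None
    distance_to_tss: int | None = None


@dataclass
class PromoterAnnotation:
    cluster_id: str
    gene_id: str
    transcript_id: str | None
    promoter_class: str  # reference | alternative_annotated | alternative_novel
    relative_position: str  # upstream | downstream | NA
    expressed_in_normal: bool


@dataclass
class GeneSummary:
    gene_id: str
    promoter_ids: list[str]
    gene_class: str  # SP | MP
    gene_expr: np.ndarray

    @property
    def n_promoters(self) -> int:
        return len(self.promoter_ids)


def _gene_bodies(transcripts: Sequence[TranscriptModel]) -> dict[str, tuple[str, str, int, int]]:
    bodies: dict[str, tuple[str, str, int, int]] = {}
    for t in transcripts:
        cur = bodies.get(t.gene_id)
        if cur is None:
            bodies[t.gene_id] = (t.chrom, t.strand, t.start, t.end)
        else:
            chrom, strand, s, e = cur
            bodies[t.gene_id] = (chrom, strand, min(s, t.start), max(e, t.end))
    return bodies


def assign_clusters_to_tss(
    consensus: Sequence[ConsensusCluster],
    transcripts: Sequence[TranscriptModel],
    window: int = 300,
) -> list[ClusterAssignment]:
    """Label each cluster promoter / intragenic / intergenic.

    A cluster whose dominant CTSS is within ±window of >=1 same-strand
    transcript TSS is promoter-assigned to the nearest TSS (ambiguity across
    genes is resolved to the nearest and logged).  The remaining clusters are
    intragenic when the dominant CTSS falls inside a same-strand gene body,
    else intergenic.  Every cluster receives exactly one label.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    by_loc: dict[tuple[str, str], list[TranscriptModel]] = {}
    for t in transcripts:
        by_loc.setdefault((t.chrom, t.strand), []).append(t)
    tss_sorted = {
        key: sorted(ts, key=lambda t: t.tss) for key, ts in by_loc.items()
    }
    bodies = _gene_bodies(transcripts)

    out: list[ClusterAssignment] = []
    n_promoter = n_intra = n_inter = n_ambiguous = 0
    for c in consensus:
        candidates = tss_sorted.get((c.chrom, c.strand), [])
        hits = [
            (abs(c.dominant_pos - t.tss), t)
            for t in candidates
            if abs(c.dominant_pos - t.tss) <= window
        ]
        if hits:
            hits.sort(key=lambda h: (h[0], h[1].transcript_id))
            genes_hit = {t.gene_id for _, t in hits}
            if len(genes_hit) > 1:
                n_ambiguous += 1
                log.info("cluster %s within %d b of TSSs of %d genes; nearest wins",
                         c.cluster_id, window, len(genes_hit))
            d, t = hits[0]
            out.append(ClusterAssignment(c.cluster_id, "promoter", t.gene_id,
                                         t.transcript_id, d))
            n_promoter += 1
            continue
        host = None
        for gid, (chrom, strand, s, e) in bodies.items():
            if chrom == c.chrom and strand == c.strand and s <= c.dominant_pos < e:
                host = gid
                break
        if host is not None:
            out.append(ClusterAssignment(c.cluster_id, "intragenic", host))
            n_intra += 1
        else:
            out.append(ClusterAssignment(c.cluster_id, "intergenic"))
            n_inter += 1
    log.info(
        "assign_clusters_to_tss: %d promoter, %d intragenic, %d intergenic (%d ambiguous)",
        n_promoter, n_intra, n_inter, n_ambiguous,
    )
    return out


def normal_expression_flag(
    normal_tpms: Sequence[float], min_tpm: float = 3.0, min_samples: int = 1
) -> bool:
    """True iff >= min_samples normal-tissue samples show TPM >= min_tpm."""
    values = np.asarray(list(normal_tpms), dtype=float)
    if values.size == 0:
        warnings.warn("normal_expression_flag: no normal samples supplied; returning False")
        return False
    return int((values >= min_tpm).sum()) >= min_samples


def pick_reference(
    promoters: Sequence[str],
    mean_expr: Mapping[str, float],
    expressed_in_normal: Mapping[str, bool],
    is_novel: Mapping[str, bool] | None = None,
    dominant_pos: Mapping[str, int] | None = None,
    strand: str = "+",
) -> str:
    """Reference promoter = argmax cohort-mean expression among promoters
    expressed in normal tissue; if none is, argmax over all promoters.

    Ties break toward annotated (non-novel) promoters, then toward the
    5'-most dominant position, for determinism.
    """
    if not promoters:
        raise ValueError("pick_reference: gene has no promoters")
    pool = [p for p in promoters if expressed_in_normal.get(p, False)] or list(promoters)

    def sort_key(p: str):
        novel = bool(is_novel.get(p, False)) if is_novel else False
        pos = dominant_pos.get(p, 0) if dominant_pos else 0
        five_prime = -pos if strand == "-" else pos
        return (-float(mean_expr[p]), novel, five_prime)

    return min(pool, key=sort_key)


def relative_position(alt_dominant: int, ref_dominant: int, strand: str) -> str:
    """Strand-aware position of an alternative promoter vs its reference."""
    if alt_dominant == ref_dominant:
        raise ValueError("alternative and reference promoters share a dominant CTSS")
    downstream = alt_dominant > ref_dominant
    if strand == "-":
        downstream = not downstream
    return "downstream" if downstream else "upstream"


def classify_gene_promoters(
    gene_promoters: Mapping[str, Sequence[ConsensusCluster]],
) -> list[GeneSummary]:
    """SP/MP classification with gene expression = sum of promoter TPM vectors."""
    out = []
    for gid in sorted(gene_promoters):
        clusters = list(gene_promoters[gid])
        if not clusters:
            continue
        expr = np.sum([c.expr for c in clusters], axis=0)
        out.append(
            GeneSummary(
                gene_id=gid,
                promoter_ids=[c.cluster_id for c in clusters],
                gene_class="SP" if len(clusters) == 1 else "MP",
                gene_expr=expr,
            )
        )
    return out


def annotate_promoters(
    gene_promoters: Mapping[str, Sequence[ConsensusCluster]],
    assignments: Mapping[str, ClusterAssignment],
    normal_flags: Mapping[str, bool],
    novel_ids: set[str] | None = None,
) -> list[PromoterAnnotation]:
    """Full reference/alternative annotation for every promoter of every gene."""
    novel_ids = novel_ids or set()
    annotations: list[PromoterAnnotation] = []
    for gid in sorted(gene_promoters):
        clusters = list(gene_promoters[gid])
        if not clusters:
            continue
        strand = clusters[0].strand
        mean_expr = {c.cluster_id: c.mean_expr() for c in clusters}
        dom = {c.cluster_id: c.dominant_pos for c in clusters}
        flags = {c.cluster_id: normal_flags.get(c.cluster_id, False) for c in clusters}
        is_novel = {c.cluster_id: c.cluster_id in novel_ids for c in clusters}
        ref = pick_reference([c.cluster_id for c in clusters], mean_expr, flags,
                             is_novel, dom, strand)
        for c in clusters:
            cid = c.cluster_id
            if cid == ref:
                cls, rel = "reference", "NA"
            else:
                cls = "alternative_novel" if is_novel[cid] else "alternative_annotated"
                rel = relative_position(dom[cid], dom[ref], strand)
            assignment = assignments.get(cid)
            annotations.append(
                PromoterAnnotation(
                    cluster_id=cid,
                    gene_id=gid,
                    transcript_id=assignment.transcript_id if assignment else None,
                    promoter_class=cls,
                    relative_position=rel,
                    expressed_in_normal=flags[cid],
                )
            )
    return annotations
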
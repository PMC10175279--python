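"""End-to-end orchestration: per-sample CTSS tables → consensus clusters →
promoter annotation → novel-promoter cascade → features, plus recovery
scoring against a simulation truth table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from . import annotation as ann
from . import cascade as casc
from . import clustering as clus
from . import features as feat
from .ctss import CtssRecord, filter_blacklist, tpm_normalize
from .intervals import RegionIndex
from .simulate import SimData

log = logging.getLogger(__name__)


def pct(part: float, whole: float) -> float:
    """Percentage helper used in all pipeline summaries."""
    if whole == 0:
        return float("nan")
    return 100.0 * part / whole


@dataclass
class PipelineParams:
    max_gap: int = 20
    q_low: float = 0.1
    q_high: float = 0.9
    merge_gap: int = 0
    min_tpm_a: float = 1.0
    min_samples: int | None = None  # None -> ceil(0.15 * cohort)
    min_tpm_b: float = 3.0
    min_samples_b: int = 1
    tss_window: int = 300
    normal_min_tpm: float = 3.0
    normal_min_samples: int = 1
    ds_flank: int = 200
    novel_span: int = 300
    support_window: int = 300
    shape_threshold: int = 10
    oe_cg_flank: int = 100  # dominant CTSS ± flank window for O/E CG


@dataclass
class PipelineResult:
    consensus: list[clus.ConsensusCluster]
    cohort_samples: list[str]
    assignments: dict[str, ann.ClusterAssignment]
    annotations: list[ann.PromoterAnnotation]
    gene_summaries: list[ann.GeneSummary]
    novel: list[casc.NovelTss]
    cascade_records: list[casc.CascadeRecord]
    features: list[feat.PromoterFeatures]
    counts: dict[str, int] = field(default_factory=dict)

    def annotation_by_cluster(self) -> dict[str, ann.PromoterAnnotation]:
        return {a.cluster_id: a for a in self.annotations}


def _normal_tpm_matrix(
    consensus: Sequence[clus.ConsensusCluster],
    normal_ctss: Mapping[str, Sequence[CtssRecord]],
) -> dict[str, list[float]]:
    """Per-cluster TPM in each normal sample, summed over the cluster envelope."""
    pooled = {s: casc.PooledCtss(records) for s, records in normal_ctss.items()}
    out: dict[str, list[float]] = {}
    for c in consensus:
        out[c.cluster_id] = [
            pooled[s].window_tpm(c.chrom, c.strand, c.start, c.end)
            for s in sorted(pooled)
        ]
    return out


def run_pipeline(sim: SimData, params: PipelineParams | None = None) -> PipelineResult:
    """Run the whole analysis on a simulated (or equivalently structured) cohort.

    The consensus cohort is tumor + adjacent samples; normal samples are used
    only for the expressed-in-normal flag that anchors reference-promoter
    designation.
    """
    p = params or PipelineParams()
    blacklist_idx = RegionIndex(sim.blacklist)

    normalized: dict[str, list[CtssRecord]] = {}
    for sample, records in sim.ctss.items():
        normalized[sample] = tpm_normalize(filter_blacklist(records, blacklist_idx))

    cohort = sorted(s for s, g in sim.groups.items() if g in ("tumor", "adjacent"))
    normals = {s: normalized[s] for s, g in sim.groups.items() if g == "normal"}

    per_sample_clusters = {
        s: clus.cluster_ctss(normalized[s], p.max_gap, p.q_low, p.q_high, sample=s)
        for s in cohort
    }
    consensus = clus.build_consensus(
        per_sample_clusters, p.merge_gap, p.q_low, p.q_high, sample_order=cohort
    )
    consensus = clus.filter_consensus(
        consensus, p.min_tpm_a, p.min_samples, p.min_tpm_b, p.min_samples_b
    )

    assignments = {
        a.cluster_id: a
        for a in ann.assign_clusters_to_tss(consensus, sim.transcripts, p.tss_window)
    }
    by_id = {c.cluster_id: c for c in consensus}

    normal_tpm = _normal_tpm_matrix(consensus, normals)
    normal_flags = {
        cid: ann.normal_expression_flag(vals, p.normal_min_tpm, p.normal_min_samples)
        if vals else False
        for cid, vals in normal_tpm.items()
    }

    # cascade over intragenic clusters
    intragenic = [by_id[cid] for cid, a in assignments.items() if a.category == "intragenic"]
    intragenic.sort(key=lambda c: (c.chrom, c.start))
    pooled_all = casc.PooledCtss([r for s in cohort for r in normalized[s]])
    annotated_5p = [(t.chrom, t.tss, t.strand) for t in sim.transcripts]
    novel, cascade_records = casc.run_cascade(
        intragenic,
        sim.smallrna_regions,
        sim.coding_exons,
        sim.enhancers,
        pooled_all,
        sim.genome,
        annotated_5p,
        sim.supporting_5p,
        p.ds_flank,
        p.novel_span,
        p.support_window,
    )

    # supported novel TSSs become alternative promoters of their host genes
    gene_promoters: dict[str, list[clus.ConsensusCluster]] = {}
    for cid, a in assignments.items():
        if a.category == "promoter":
            gene_promoters.setdefault(a.gene_id, []).append(by_id[cid])
    novel_ids: set[str] = set()
    for n in novel:
        if not n.support:
            continue
        top_cid = max(
            n.member_cluster_ids, key=lambda cid: float(by_id[cid].expr.sum())
        )
        host = assignments[top_cid].gene_id
        if host is None:
            continue
        gene_promoters.setdefault(host, []).append(by_id[top_cid])
        novel_ids.add(top_cid)
    for gid in gene_promoters:
        gene_promoters[gid].sort(key=lambda c: c.start)

    annotations = ann.annotate_promoters(gene_promoters, assignments, normal_flags, novel_ids)
    gene_summaries = ann.classify_gene_promoters(gene_promoters)

    cgi_idx = RegionIndex(sim.cgis)
    chrom_seqs = sim.genome
    features: list[feat.PromoterFeatures] = []
    for a in annotations:
        c = by_id[a.cluster_id]
        seq = str(chrom_seqs[c.chrom][
            max(0, c.dominant_pos - p.oe_cg_flank): c.dominant_pos + p.oe_cg_flank + 1
        ])
        features.append(
            feat.PromoterFeatures(
                cluster_id=c.cluster_id,
                cgi_overlap=cgi_idx.overlaps(c.chrom, c.start, c.end),
                oe_cg=feat.oe_cg(seq),
                shape=feat.promoter_shape(c.iq_width, p.shape_threshold),
                iq_width=c.iq_width,
            )
        )

    counts = {
        "consensus_clusters": len(consensus),
        "promoter_assigned": sum(1 for a in assignments.values() if a.category == "promoter"),
        "intragenic": sum(1 for a in assignments.values() if a.category == "intragenic"),
        "intergenic": sum(1 for a in assignments.values() if a.category == "intergenic"),
        "novel_tss": len(novel),
        "novel_supported": sum(1 for n in novel if n.support),
        "sp_genes": sum(1 for g in gene_summaries if g.gene_class == "SP"),
        "mp_genes": sum(1 for g in gene_summaries if g.gene_class == "MP"),
    }
    log.info("pipeline counts: %s", counts)
    return PipelineResult(
        consensus=consensus,
        cohort_samples=cohort,
        assignments=assignments,
        annotations=annotations,
        gene_summaries=gene_summaries,
        novel=novel,
        cascade_records=cascade_records,
        features=features,
        counts=counts,
    )


# ----------------------------------------------------------------- scoring


def evaluate_recovery(
    truth: pd.DataFrame,
    result: PipelineResult,
    match_tol: int = 100,
) -> dict[str, float]:
    """Score pipeline output against the simulation truth table.

    A planted reference/alternative is recovered when a promoter annotation
    of the right class exists for its gene with a dominant CTSS within
    ``match_tol`` b; planted eRNA and exonic-artifact clusters are excluded
    when no final (supported) novel alternative promoter lies within
    ``match_tol`` b on the same strand.
    """
    by_id = {c.cluster_id: c for c in result.consensus}
    per_gene: dict[str, list[tuple[str, int, str]]] = {}
    for a in result.annotations:
        c = by_id[a.cluster_id]
        per_gene.setdefault(a.gene_id, []).append(
            (a.promoter_class, c.dominant_pos, c.strand)
        )

    def matched(row, classes: set[str]) -> bool:
        for cls, dom, strand in per_gene.get(row.gene_id, []):
            if cls in classes and strand == row.strand and abs(dom - row.dominant_pos) <= match_tol:
                return True
        return False

    refs = truth[truth["kind"] == "reference"]
    alts = truth[truth["kind"].isin(["alternative_annotated", "alternative_novel"])]
    ref_ok = sum(matched(r, {"reference"}) for r in refs.itertuples())
    alt_ok = sum(
        matched(r, {"alternative_annotated", "alternative_novel"})
        for r in alts.itertuples()
    )

    final_novel = [
        (by_id[cid].dominant_pos, by_id[cid].strand)
        for a in result.annotations
        if a.promoter_class == "alternative_novel"
        for cid in [a.cluster_id]
    ]

    def leaked(row) -> bool:
        return any(
            strand == row.strand and abs(dom - row.dominant_pos) <= match_tol
            for dom, strand in final_novel
        )

    ernas = truth[truth["kind"] == "erna"]
    artifacts = truth[truth["kind"] == "exonic_gg"]
    erna_excluded = sum(not leaked(r) for r in ernas.itertuples())
    gg_excluded = sum(not leaked(r) for r in artifacts.itertuples())

    n_alt_down = sum(
        1 for a in result.annotations
        if a.promoter_class.startswith("alternative") and a.relative_position == "downstream"
    )
    n_alt = sum(1 for a in result.annotations if a.promoter_class.startswith("alternative"))

    return {
        "n_planted_ref": len(refs),
        "n_planted_alt": len(alts),
        "n_planted_erna": len(ernas),
        "n_planted_gg": len(artifacts),
        "ref_recovery_pct": pct(ref_ok, len(refs)),
        "alt_detection_pct": pct(alt_ok, len(alts)),
        "erna_exclusion_pct": pct(erna_excluded, len(ernas)) if len(ernas) else float("nan"),
        "exonic_gg_exclusion_pct": pct(gg_excluded, len(artifacts)) if len(artifacts) else float("nan"),
        "alt_downstream_pct": pct(n_alt_down, n_alt) if n_alt else float("nan"),
    }


def summarize(result: PipelineResult) -> dict[str, float]:
    """Headline proportions of the annotation (percent scale)."""
    c = result.counts
    total = c["consensus_clusters"]
    n_genes = c["sp_genes"] + c["mp_genes"]
    return {
        "consensus_clusters": total,
        "intragenic_pct": pct(c["intragenic"], total),
        "sp_gene_pct": pct(c["sp_genes"], n_genes),
        "mp_gene_pct": pct(c["mp_genes"], n_genes),
        "novel_tss": c["novel_tss"],
        "novel_supported": c["novel_supported"],
    }
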
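"""Per-sample tag clusters and cohort consensus clusters.

CTSSs on the same strand within ``max_gap`` (default 20 nt) of each other are
merged single-linkage into tag clusters (TCs).  Each TC carries its dominant
(highest-count) CTSS and an interquantile envelope obtained by trimming the
0.1–0.9 cumulative tag mass from the edges; the interquantile width is the
standard sharp/broad promoter shape proxy.  Per-sample TCs are then merged
across the cohort into consensus clusters with a samples × TPM expression
vector, and consensus clusters are retained only when expressed above
1 TPM in >=15% of the cohort and at >=3 TPM in at least one sample.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Sequence

import numpy as np

from .ctss import CtssRecord

log = logging.getLogger(__name__)


def _dominant(positions: np.ndarray, counts: np.ndarray, strand: str) -> tuple[int, int]:
    """Highest-count position; ties broken toward the 5'-most position."""
    best = counts.max()
    tied = positions[counts == best]
    pos = int(tied.max()) if strand == "-" else int(tied.min())
    return pos, int(best)


def interquantile_bounds(
    positions: Sequence[int],
    counts: Sequence[int | float],
    q_low: float = 0.1,
    q_high: float = 0.9,
) -> tuple[int, int]:
    """Interquantile envelope [iq_start, iq_end) of a tag distribution.

    Edge positions are trimmed from the left while their cumulative tag mass
    is <= q_low * total, and from the right while the remaining suffix mass
    is <= (1 - q_high) * total.  Equivalently, the envelope runs from the tag
    of rank floor(q_low*total)+1 to the tag of rank ceil(q_high*total) when
    tags are enumerated in position order.  Quantiles are treated as exact
    decimals (threshold comparisons in rational arithmetic, so e.g.
    q_high=0.9 with 10 tags trims exactly one trailing tag).  At least one
    position is always retained.
    """
    if q_low >= q_high:
        raise ValueError(f"q_low ({q_low}) must be < q_high ({q_high})")
    pos = np.asarray(positions)
    cnt = np.asarray(counts, dtype=float)
    order = np.argsort(pos)
    pos, cnt = pos[order], cnt[order]
    total = cnt.sum()
    if total <= 0:
        raise ValueError("interquantile_bounds: cluster has no tag mass")
    cum = np.cumsum(cnt)
    suffix = total - np.concatenate(([0.0], cum[:-1]))
    ql = Fraction(str(q_low))
    qr = 1 - Fraction(str(q_high))
    keep = (cum * ql.denominator > ql.numerator * total) & (
        suffix * qr.denominator > qr.numerator * total
    )
    if not keep.any():  # pathological q choices: keep the median tag position
        mid = int(np.searchsorted(cum, total / 2))
        return int(pos[mid]), int(pos[mid]) + 1
    idx = np.flatnonzero(keep)
    return int(pos[idx[0]]), int(pos[idx[-1]]) + 1


@dataclass
class TagCluster:
    """A run of proximal same-strand CTSSs from one sample."""

    chrom: str
    strand: str
    start: int
    end: int
    dominant_pos: int
    dominant_count: int
    total_count: float
    total_tpm: float
    iq_start: int
    iq_end: int
    positions: np.ndarray = field(repr=False)
    counts: np.ndarray = field(repr=False)
    tpms: np.ndarray = field(repr=False)
    sample: str | None = None

    @property
    def iq_width(self) -> int:
        return self.iq_end - self.iq_start


def _make_cluster(
    chrom: str,
    strand: str,
    positions: np.ndarray,
    counts: np.ndarray,
    tpms: np.ndarray,
    q_low: float,
    q_high: float,
    sample: str | None,
) -> TagCluster:
    dom_pos, dom_count = _dominant(positions, counts, strand)
    iq_start, iq_end = interquantile_bounds(positions, counts, q_low, q_high)
    # the dominant CTSS always stays inside the interquantile envelope
    iq_start = min(iq_start, dom_pos)
    iq_end = max(iq_end, dom_pos + 1)
    return TagCluster(
        chrom=chrom,
        strand=strand,
        start=int(positions[0]),
        end=int(positions[-1]) + 1,
        dominant_pos=dom_pos,
        dominant_count=dom_count,
        total_count=float(counts.sum()),
        total_tpm=float(tpms.sum()),
        iq_start=iq_start,
        iq_end=iq_end,
        positions=positions,
        counts=counts,
        tpms=tpms,
        sample=sample,
    )


def cluster_ctss(
    ctss: Sequence[CtssRecord],
    max_gap: int = 20,
    q_low: float = 0.1,
    q_high: float = 0.9,
    sample: str | None = None,
) -> list[TagCluster]:
    """Single-linkage clustering of sorted CTSSs within ``max_gap`` nt.

    Input must be sorted by (chrom, strand, pos); consecutive same-strand
    CTSSs at distance <= max_gap join the same cluster.  Every CTSS ends up
    in exactly one cluster.
    """
    keys = [(r.chrom, r.strand, r.pos) for r in ctss]
    if keys != sorted(keys):
        raise ValueError("cluster_ctss requires input sorted by (chrom, strand, pos)")
    clusters: list[TagCluster] = []
    run: list[CtssRecord] = []

    def flush() -> None:
        if not run:
            return
        clusters.append(
            _make_cluster(
                run[0].chrom,
                run[0].strand,
                np.array([r.pos for r in run]),
                np.array([r.count for r in run], dtype=float),
                np.array([r.tpm for r in run], dtype=float),
                q_low,
                q_high,
                sample,
            )
        )

    for rec in ctss:
        if run and (
            rec.chrom != run[-1].chrom
            or rec.strand != run[-1].strand
            or rec.pos - run[-1].pos > max_gap
        ):
            flush()
            run = []
        run.append(rec)
    flush()
    return clusters


@dataclass
class ConsensusCluster:
    """Cohort-level merge of per-sample TCs with a per-sample TPM vector."""

    cluster_id: str
    chrom: str
    strand: str
    start: int
    end: int
    dominant_pos: int
    iq_start: int
    iq_end: int
    expr: np.ndarray  # per-sample TPM, aligned with the sample order
    samples: list[str] = field(repr=False)
    pooled_positions: np.ndarray = field(repr=False, default=None)
    pooled_counts: np.ndarray = field(repr=False, default=None)

    @property
    def iq_width(self) -> int:
        return self.iq_end - self.iq_start

    def mean_expr(self) -> float:
        return float(self.expr.mean())


def build_consensus(
    per_sample_clusters: dict[str, list[TagCluster]],
    merge_gap: int = 0,
    q_low: float = 0.1,
    q_high: float = 0.9,
    sample_order: Sequence[str] | None = None,
) -> list[ConsensusCluster]:
    """Merge overlapping same-strand TCs across samples into consensus clusters.

    ``merge_gap`` is the minimum separation keeping two clusters apart:
    clusters merge when ``next.start - current.end < merge_gap``, so the
    default 0 requires genuine base overlap.  Per-sample TPM of a consensus
    cluster is the summed member-CTSS TPM of that sample inside the merged
    envelope; samples without signal get 0.  The consensus dominant CTSS and
    interquantile envelope come from counts pooled over all samples.
    """
    samples = list(sample_order) if sample_order is not None else sorted(per_sample_clusters)
    sample_idx = {s: i for i, s in enumerate(samples)}
    flat: list[tuple[str, str, TagCluster, str]] = []
    for s, tcs in per_sample_clusters.items():
        if s not in sample_idx:
            continue
        for tc in tcs:
            flat.append((tc.chrom, tc.strand, tc, s))
    flat.sort(key=lambda t: (t[0], t[1], t[2].start, t[2].end))

    consensus: list[ConsensusCluster] = []
    group: list[tuple[TagCluster, str]] = []
    group_key: tuple[str, str] | None = None
    group_end = -1

    def flush() -> None:
        nonlocal group
        if not group:
            return
        chrom, strand = group_key
        expr = np.zeros(len(samples))
        pooled: dict[int, float] = {}
        for tc, s in group:
            expr[sample_idx[s]] += tc.total_tpm
            for p, c in zip(tc.positions, tc.counts):
                pooled[int(p)] = pooled.get(int(p), 0.0) + float(c)
        positions = np.array(sorted(pooled))
        counts = np.array([pooled[p] for p in positions])
        dom_pos, _ = _dominant(positions, counts, strand)
        iq_s, iq_e = interquantile_bounds(positions, counts, q_low, q_high)
        iq_s, iq_e = min(iq_s, dom_pos), max(iq_e, dom_pos + 1)
        consensus.append(
            ConsensusCluster(
                cluster_id="",
                chrom=chrom,
                strand=strand,
                start=min(tc.start for tc, _ in group),
                end=max(tc.end for tc, _ in group),
                dominant_pos=dom_pos,
                iq_start=iq_s,
                iq_end=iq_e,
                expr=expr,
                samples=samples,
                pooled_positions=positions,
                pooled_counts=counts,
            )
        )

    for chrom, strand, tc, s in flat:
        key = (chrom, strand)
        if group and (key != group_key or tc.start >= group_end + merge_gap):
            flush()
            group = []
        group_key = key
        group_end = tc.end if not group else max(group_end, tc.end)
        group.append((tc, s))
    flush()

    consensus.sort(key=lambda c: (c.chrom, c.start, c.end, c.strand))
    width = max(4, len(str(len(consensus))))
    for i, c in enumerate(consensus, 1):
        c.cluster_id = f"TC{i:0{width}d}"
    log.info("build_consensus: %d per-sample TCs -> %d consensus clusters",
             len(flat), len(consensus))
    return consensus


def filter_consensus(
    clusters: Iterable[ConsensusCluster],
    min_tpm_a: float = 1.0,
    min_samples: int | None = None,
    min_tpm_b: float = 3.0,
    min_samples_b: int = 1,
) -> list[ConsensusCluster]:
    """Expression filter: > min_tpm_a TPM (strict) in >= min_samples samples
    AND >= min_tpm_b TPM in >= min_samples_b samples.

    ``min_samples=None`` uses ceil(0.15 * cohort size), i.e. 15% of the
    cohort (15 samples in a cohort of 100).
    """
    clusters = list(clusters)
    kept = []
    for c in clusters:
        n = math.ceil(0.15 * len(c.expr)) if min_samples is None else min_samples
        cond_a = int((c.expr > min_tpm_a).sum()) >= n
        cond_b = int((c.expr >= min_tpm_b).sum()) >= min_samples_b
        if cond_a and cond_b:
            kept.append(c)
    log.info("filter_consensus: %d -> %d clusters", len(clusters), len(kept))
    return kept
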
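"""Promoter sequence/shape features: CpG-island classes, observed/expected
CG ratio, sharp vs broad promoter shape, and CGI/nonCGI enhancer splitting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

from .intervals import GenomicInterval, RegionIndex

log = logging.getLogger(__name__)


@dataclass
class CgiRecord:
    interval: GenomicInterval
    cgi_class: str  # promoter | intragenic | intergenic


@dataclass
class PromoterFeatures:
    cluster_id: str
    cgi_overlap: bool
    oe_cg: float
    shape: str  # sharp | broad
    iq_width: int


def oe_cg(sequence: str) -> float:
    """Observed/expected CG dinucleotide ratio of a genomic window.

    O/E CG = (#CG dinucleotides × window length) / (#C × #G).  CG-rich
    islands score near or above 1; the bulk genome, where CpG is depleted by
    methyl-C deamination, scores well below.  N bases are excluded from the
    window and base counts and break dinucleotides; windows without any CG
    return 0.
    """
    if len(sequence) < 2:
        raise ValueError("oe_cg requires a sequence of length >= 2")
    seq = sequence.upper()
    n_c = seq.count("C")
    n_g = seq.count("G")
    n_cg = seq.count("CG")
    if n_cg == 0 or n_c == 0 or n_g == 0:
        return 0.0
    window = sum(1 for b in seq if b != "N")
    return n_cg * window / (n_c * n_g)


def classify_cgi(
    cgis: Sequence[GenomicInterval],
    promoter_regions: Sequence[GenomicInterval],
    gene_bodies: Sequence[GenomicInterval],
) -> list[CgiRecord]:
    """Priority classification of CpG islands: promoter > intragenic > intergenic.

    >=1 bp overlap with a promoter region makes a promoter CGI; otherwise
    >=1 bp overlap with a gene body makes an intragenic CGI; the rest are
    intergenic.  Output is a partition of the input.
    """
    prom_idx = RegionIndex(list(promoter_regions))
    body_idx = RegionIndex(list(gene_bodies))
    out = []
    for cgi in cgis:
        if prom_idx.overlaps(cgi.chrom, cgi.start, cgi.end):
            cls = "promoter"
        elif body_idx.overlaps(cgi.chrom, cgi.start, cgi.end):
            cls = "intragenic"
        else:
            cls = "intergenic"
        out.append(CgiRecord(cgi, cls))
    counts = {k: sum(1 for r in out if r.cgi_class == k)
              for k in ("promoter", "intragenic", "intergenic")}
    log.info("classify_cgi: %s", counts)
    return out


def promoter_shape(iq_width: int, threshold: int = 10) -> str:
    """Sharp (single dominant TSS) iff interquantile width <= threshold bases."""
    if iq_width < 1:
        raise ValueError("iq_width must be >= 1")
    return "sharp" if iq_width <= threshold else "broad"


def split_enhancers_by_cgi(
    enhancers: Sequence[GenomicInterval],
    cgis: Sequence[GenomicInterval],
    min_frac: float = 0.10,
) -> tuple[list[GenomicInterval], list[GenomicInterval]]:
    """Split enhancers into (CGI, nonCGI) at >= min_frac CGI length overlap.

    Overlap from multiple CGI fragments is unioned before the fraction test.
    """
    cgi_idx = RegionIndex(list(cgis))
    cgi_enh, noncgi_enh = [], []
    for e in enhancers:
        covered = cgi_idx.overlap_length(e.chrom, e.start, e.end)
        (cgi_enh if covered >= min_frac * len(e) else noncgi_enh).append(e)
    log.info("split_enhancers_by_cgi: %d CGI / %d nonCGI of %d enhancers",
             len(cgi_enh), len(noncgi_enh), len(enhancers))
    return cgi_enh, noncgi_enh
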
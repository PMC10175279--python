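"""Synthetic CAGE cohort generator with ground-truth labels.

Emulates the study conditions the pipeline is built for: a cohort of tumor
and matched tumor-adjacent CAGE libraries plus a small panel of normal-liver
libraries, over a single synthetic contig carrying:

* genes with a broad, CGI-embedded reference promoter expressed in every
  sample (including normals);
* multi-promoter genes with a sharp, CG-poor alternative promoter that is
  active only in a Bernoulli(prevalence) subset of tumor samples (and, with
  lower probability, in tumor-adjacent samples), absent from normal livers —
  either carried by an annotated second transcript or entirely novel
  (intronic, YR-initiated, with an independent supporting transcript 5' end);
* planted bidirectional eRNA tag pairs (balanced ± strand signal, DS ≈ 0);
* exonic GG-initiated recapping artifacts on coding exons;
* small-RNA 5'-end tags inside annotated small-RNA regions;
* a blacklisted region with decoy tags;
* CpG islands with elevated O/E CG (CG-poor elsewhere), intergenic
  enhancers (some CGI-overlapping), and a beta-value matrix with
  CG-density-dependent methylation and planted tumor hypomethylation at
  CG-poor alternative promoters.

Everything is deterministic given the seed; truth tables are first-class
outputs so recovery can be scored mechanically.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .ctss import CtssRecord
from .intervals import GenomicInterval, TranscriptModel
from . import io as aio

log = logging.getLogger(__name__)

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

# relative (strand-oriented) gene layout, positions from the reference TSS
GENE_SPAN = 6000
GENE_PITCH = 12000
EXONS_REL = [(0, 200), (4200, 4500), (5700, 6000)]  # exon1 is 5' non-coding
ALT_ANNOT_REL = 2500       # annotated downstream alternative TSS (intron 1)
ALT_UPSTREAM_REL = -1500   # annotated upstream alternative TSS
ALT_NOVEL_REL = 3000       # novel alternative TSS (intron 1)
ERNA_REL = 3000            # eRNA pair midpoint (intron 1)
SMALLRNA_REL = 2500        # small-RNA 5' end (intron 1)
EXONIC_GG_REL = 4350       # recapping artifact (inside coding exon 2)
CGI_REL = (-250, 350)      # reference-promoter CGI
INTRAGENIC_CGI_REL = (4600, 5200)


@dataclass
class SimConfig:
    """All knobs of the synthetic cohort; defaults are the study conditions."""

    seed: int = 0
    n_tumor: int = 20
    n_adjacent: int = 20
    n_normal: int = 4
    contig: str = "chrS"
    n_genes: int = 60
    n_mp_annotated: int = 10
    n_mp_novel: int = 10
    n_ernas: int = 10
    n_exonic_gg: int = 10
    n_smallrna: int = 5
    alt_prevalence: float = 0.6       # per-tumor-sample activation probability
    alt_adjacent_prob: float = 0.3
    alt_normal_prob: float = 0.0      # tumor-specific alternatives by default
    alt_downstream_frac: float = 0.65  # annotated alternatives placed downstream
    ref_mean_tags: float = 150.0
    alt_mean_tags: float = 60.0
    erna_mean_tags: float = 25.0      # per strand of the pair
    artifact_mean_tags: float = 40.0
    smallrna_mean_tags: float = 40.0
    noise_tags_per_sample: int = 200
    broad_width_range: tuple[int, int] = (30, 80)
    # methylation block
    probe_sigma: float = 0.05
    beta_cgi_promoter: float = 0.10
    beta_alt_promoter: float = 0.70
    beta_gene_body: float = 0.80
    planted_delta_beta: float = -0.30  # tumor hypomethylation at CG-poor alt promoters

    @property
    def genome_length(self) -> int:
        return 5000 + self.n_genes * GENE_PITCH + 20000

    def sample_names(self) -> tuple[list[str], list[str], list[str]]:
        tumors = [f"T{i + 1:02d}" for i in range(self.n_tumor)]
        adjacent = [f"A{i + 1:02d}" for i in range(self.n_adjacent)]
        normal = [f"N{i + 1:02d}" for i in range(self.n_normal)]
        return tumors, adjacent, normal


@dataclass
class SimData:
    """In-memory result of a simulation (everything the pipeline consumes)."""

    config: SimConfig
    genome: dict[str, str]
    transcripts: list[TranscriptModel]
    cgis: list[GenomicInterval]
    blacklist: list[GenomicInterval]
    enhancers: list[GenomicInterval]
    smallrna_regions: list[GenomicInterval]
    coding_exons: list[GenomicInterval]
    supporting_5p: list[tuple[str, int, str]]
    ctss: dict[str, list[CtssRecord]]
    groups: dict[str, str]
    truth: pd.DataFrame
    beta: pd.DataFrame = field(default=None)
    probe_coords: pd.DataFrame = field(default=None)
    probe_truth: pd.DataFrame = field(default=None)


@dataclass
class _Gene:
    gene_id: str
    index: int
    strand: str
    start: int  # genomic start of the gene body
    role: str   # sp | mp_annotated | mp_novel | erna_host | gg_host | smallrna_host
    alt_rel: int | None = None

    @property
    def end(self) -> int:
        return self.start + GENE_SPAN

    def rel(self, x: int) -> int:
        """Map a strand-oriented offset from the reference TSS to genomic."""
        return self.start + x if self.strand == "+" else self.end - 1 - x

    def rel_interval(self, a: int, b: int) -> tuple[int, int]:
        """Map a strand-oriented [a, b) span to a genomic half-open interval."""
        if self.strand == "+":
            return self.start + a, self.start + b
        return self.end - b, self.end - a


def _gene_roles(cfg: SimConfig) -> list[str]:
    roles = (
        ["mp_annotated"] * cfg.n_mp_annotated
        + ["mp_novel"] * cfg.n_mp_novel
        + ["gg_host"] * cfg.n_exonic_gg
        + ["erna_host"] * cfg.n_ernas
        + ["smallrna_host"] * cfg.n_smallrna
    )
    if len(roles) > cfg.n_genes:
        raise ValueError("n_genes too small for the requested planted features")
    roles += ["sp"] * (cfg.n_genes - len(roles))
    return roles


def _layout_genes(cfg: SimConfig, rng: np.random.Generator) -> list[_Gene]:
    roles = _gene_roles(cfg)
    genes = []
    for i, role in enumerate(roles):
        strand = "+" if i % 2 == 0 else "-"
        g = _Gene(f"G{i + 1:03d}", i, strand, 5000 + i * GENE_PITCH, role)
        if role == "mp_annotated":
            downstream = rng.random() < cfg.alt_downstream_frac
            g.alt_rel = ALT_ANNOT_REL if downstream else ALT_UPSTREAM_REL
        elif role == "mp_novel":
            g.alt_rel = ALT_NOVEL_REL
        genes.append(g)
    return genes


def _synth_background(length: int, rng: np.random.Generator) -> np.ndarray:
    """CG-depleted background: iid draw, then 90% of CpG dinucleotides broken."""
    bases = np.array(list("ACGT"))
    seq = rng.choice(bases, size=length, p=[0.3, 0.2, 0.2, 0.3])
    cg = np.flatnonzero((seq[:-1] == "C") & (seq[1:] == "G"))
    broken = cg[rng.random(cg.size) < 0.9]
    seq[broken + 1] = "A"
    return seq


def _synth_cgi(length: int, rng: np.random.Generator) -> np.ndarray:
    """CG-rich island: ~25% of emitted tokens are literal CpG dinucleotides."""
    out: list[str] = []
    bases = "ACGT"
    while len(out) < length:
        if rng.random() < 0.25:
            out.extend("CG")
        else:
            out.append(bases[rng.integers(4)])
    return np.array(out[:length])


def _plant_dinucleotide(seq: np.ndarray, tss: int, strand: str, dinuc: str) -> None:
    """Write the (-1, +1) initiator bases around a TSS on the given strand."""
    if strand == "+":
        seq[tss - 1] = dinuc[0]
        seq[tss] = dinuc[1]
    else:
        seq[tss] = _COMP[dinuc[1]]
        seq[tss + 1] = _COMP[dinuc[0]]


def _sharp_support(center: int) -> tuple[np.ndarray, np.ndarray]:
    offsets = np.array([-2, -1, 0, 1, 2])
    weights = np.array([0.03, 0.12, 0.70, 0.12, 0.03])
    return center + offsets, weights


def _broad_support(
    tss: int, strand: str, cfg: SimConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    lo, hi = cfg.broad_width_range
    w = int(rng.integers(lo, hi + 1))
    weights = rng.dirichlet(np.full(w, 0.8))
    if strand == "+":
        positions = tss + np.arange(w)
    else:
        positions = tss - np.arange(w)
        order = np.argsort(positions)
        positions, weights = positions[order], weights[order]
    return positions, weights


def simulate_genome(cfg: SimConfig) -> SimData:
    """Build the genome FASTA-equivalent, transcript models and region sets.

    Deterministic given ``cfg.seed``; CGI sequences are CG-rich by
    construction (O/E CG well above 0.8), the background is CG-depleted
    (O/E CG well below 0.4).
    """
    rng = np.random.default_rng(cfg.seed)
    genes = _layout_genes(cfg, rng)
    length = cfg.genome_length
    if genes and genes[-1].end + 2000 > length:
        raise ValueError("contig too short for the requested gene count")
    seq = _synth_background(length, rng)

    cgis: list[GenomicInterval] = []
    transcripts: list[TranscriptModel] = []
    coding_exons: list[GenomicInterval] = []
    smallrna_regions: list[GenomicInterval] = []
    supporting_5p: list[tuple[str, int, str]] = []
    enhancers: list[GenomicInterval] = []
    chrom = cfg.contig

    for g in genes:
        # reference-promoter CGI
        a, b = g.rel_interval(*CGI_REL)
        seq[a:b] = _synth_cgi(b - a, rng)
        cgis.append(GenomicInterval(chrom, a, b))
        if g.index % 3 == 0:  # silent intragenic CGI
            a, b = g.rel_interval(*INTRAGENIC_CGI_REL)
            seq[a:b] = _synth_cgi(b - a, rng)
            cgis.append(GenomicInterval(chrom, a, b))

        exons = [GenomicInterval(chrom, *g.rel_interval(x0, x1), strand=g.strand)
                 for x0, x1 in EXONS_REL]
        exons.sort(key=lambda e: e.start)
        tss = g.rel(0)
        ref_exons = exons if g.strand == "+" else exons[::-1]
        transcripts.append(
            TranscriptModel(f"{g.gene_id}.t1", g.gene_id, chrom, g.strand, tss, ref_exons)
        )
        coding_exons.extend(sorted(exons, key=lambda e: e.start)[1:] if g.strand == "+"
                            else sorted(exons, key=lambda e: e.start)[:-1])
        _plant_dinucleotide(seq, tss, g.strand, "CA")

        if g.role == "mp_annotated":
            alt_tss = g.rel(g.alt_rel)
            if g.alt_rel >= 0:  # downstream: first exon inside intron 1
                e0 = GenomicInterval(chrom, *g.rel_interval(g.alt_rel, g.alt_rel + 150),
                                     strand=g.strand)
                e1 = GenomicInterval(chrom, *g.rel_interval(*EXONS_REL[1]), strand=g.strand)
            else:  # upstream of the gene
                e0 = GenomicInterval(chrom, *g.rel_interval(g.alt_rel, g.alt_rel + 150),
                                     strand=g.strand)
                e1 = GenomicInterval(chrom, *g.rel_interval(*EXONS_REL[0]), strand=g.strand)
            alt_exons = [e0, e1] if g.strand == "+" else [e0, e1]
            alt_exons_sorted = sorted(alt_exons, key=lambda e: e.start)
            ordered = alt_exons_sorted if g.strand == "+" else alt_exons_sorted[::-1]
            transcripts.append(
                TranscriptModel(f"{g.gene_id}.t2", g.gene_id, chrom, g.strand,
                                alt_tss, ordered)
            )
            _plant_dinucleotide(seq, alt_tss, g.strand, "CA")
        elif g.role == "mp_novel":
            alt_tss = g.rel(g.alt_rel)
            _plant_dinucleotide(seq, alt_tss, g.strand, "CA")
            jitter = int(rng.integers(-30, 31))
            supporting_5p.append((chrom, alt_tss + jitter, g.strand))
        elif g.role == "gg_host":
            _plant_dinucleotide(seq, g.rel(EXONIC_GG_REL), g.strand, "GG")
        elif g.role == "erna_host":
            center = g.rel(ERNA_REL)
            _plant_dinucleotide(seq, center + 90, "+", "CA")
            _plant_dinucleotide(seq, center - 90, "-", "CA")
        elif g.role == "smallrna_host":
            p = g.rel(SMALLRNA_REL)
            smallrna_regions.append(GenomicInterval(chrom, p - 50, p + 51, g.strand))
            _plant_dinucleotide(seq, p, g.strand, "CA")

    # intergenic enhancers in the tail gap; every third one CGI-overlapping
    tail = genes[-1].end + 2000 if genes else 2000
    for i in range(6):
        s = tail + i * 2000
        if s + 1000 >= length:
            break
        enhancers.append(GenomicInterval(chrom, s, s + 1000))
        if i % 3 == 0:
            seq[s + 100:s + 400] = _synth_cgi(300, rng)
            cgis.append(GenomicInterval(chrom, s + 100, s + 400))

    blacklist = [GenomicInterval(chrom, length - 4000, length - 3800)]

    return SimData(
        config=cfg,
        genome={chrom: "".join(seq)},
        transcripts=transcripts,
        cgis=sorted(cgis, key=lambda r: r.start),
        blacklist=blacklist,
        enhancers=enhancers,
        smallrna_regions=smallrna_regions,
        coding_exons=sorted(coding_exons, key=lambda r: r.start),
        supporting_5p=sorted(supporting_5p, key=lambda t: t[1]),
        ctss={},
        groups={},
        truth=pd.DataFrame(),
    )


def simulate_ctss_cohort(cfg: SimConfig, sim: SimData) -> SimData:
    """Fill ``sim`` with per-sample CTSS tables and the cluster truth table."""
    rng = np.random.default_rng(cfg.seed + 1)
    genes = _layout_genes(cfg, np.random.default_rng(cfg.seed))  # same layout draw
    tumors, adjacent, normals = cfg.sample_names()
    groups = {s: "tumor" for s in tumors}
    groups.update({s: "adjacent" for s in adjacent})
    groups.update({s: "normal" for s in normals})
    chrom = cfg.contig

    # fixed per-promoter supports (shared across samples)
    sources = []  # (truth_row, strand, positions, weights, activity_fn)
    truth_rows = []

    def add_source(tid, kind, gene, strand, dom, shape, prevalence, in_normal,
                   positions, weights, mean_tags, probs):
        truth_rows.append(
            dict(truth_id=tid, kind=kind, gene_id=gene, chrom=chrom, strand=strand,
                 dominant_pos=int(dom), shape=shape, prevalence=prevalence,
                 expressed_in_normal=in_normal)
        )
        sources.append((tid, strand, positions, weights, mean_tags, probs))

    for g in genes:
        tss = g.rel(0)
        pos, wts = _broad_support(tss, g.strand, cfg, rng)
        dom = pos[np.argmax(wts)]
        add_source(f"{g.gene_id}:ref", "reference", g.gene_id, g.strand, dom,
                   "broad", 1.0, True, pos, wts, cfg.ref_mean_tags,
                   {"tumor": 1.0, "adjacent": 1.0, "normal": 1.0})
        if g.role in ("mp_annotated", "mp_novel"):
            alt = g.rel(g.alt_rel)
            pos, wts = _sharp_support(alt)
            kind = "alternative_annotated" if g.role == "mp_annotated" else "alternative_novel"
            add_source(f"{g.gene_id}:alt", kind, g.gene_id, g.strand, alt,
                       "sharp", cfg.alt_prevalence, cfg.alt_normal_prob > 0,
                       pos, wts, cfg.alt_mean_tags,
                       {"tumor": cfg.alt_prevalence,
                        "adjacent": cfg.alt_adjacent_prob,
                        "normal": cfg.alt_normal_prob})
        elif g.role == "erna_host":
            center = g.rel(ERNA_REL)
            for tag, strand, c in (("fwd", "+", center + 90), ("rev", "-", center - 90)):
                pos, wts = _sharp_support(c)
                add_source(f"{g.gene_id}:erna_{tag}", "erna", g.gene_id, strand, c,
                           "sharp", 0.8, False, pos, wts, cfg.erna_mean_tags,
                           {"tumor": 0.8, "adjacent": 0.8, "normal": 0.0})
        elif g.role == "gg_host":
            p = g.rel(EXONIC_GG_REL)
            pos, wts = _sharp_support(p)
            add_source(f"{g.gene_id}:gg", "exonic_gg", g.gene_id, g.strand, p,
                       "sharp", 0.9, False, pos, wts, cfg.artifact_mean_tags,
                       {"tumor": 0.9, "adjacent": 0.9, "normal": 0.0})
        elif g.role == "smallrna_host":
            p = g.rel(SMALLRNA_REL)
            pos, wts = _sharp_support(p)
            add_source(f"{g.gene_id}:smallrna", "smallrna", g.gene_id, g.strand, p,
                       "sharp", 0.9, False, pos, wts, cfg.smallrna_mean_tags,
                       {"tumor": 0.9, "adjacent": 0.9, "normal": 0.0})

    blk = sim.blacklist[0]
    genome_len = len(sim.genome[chrom])
    ctss: dict[str, list[CtssRecord]] = {}
    for sample in tumors + adjacent + normals:
        grp = groups[sample]
        acc: dict[tuple[str, int], int] = {}

        def deposit(strand, positions, n, weights):
            if n <= 0:
                return
            draws = rng.multinomial(n, weights)
            for p, k in zip(positions, draws):
                if k:
                    acc[(strand, int(p))] = acc.get((strand, int(p)), 0) + int(k)

        for tid, strand, positions, weights, mean_tags, probs in sources:
            if rng.random() < probs[grp]:
                deposit(strand, positions, rng.poisson(mean_tags), weights)
        # blacklist decoy + unstructured noise
        deposit("+", np.array([blk.start + 100]), rng.poisson(30), np.array([1.0]))
        noise_pos = rng.integers(100, genome_len - 100, size=cfg.noise_tags_per_sample)
        noise_strand = rng.random(cfg.noise_tags_per_sample) < 0.5
        for p, minus in zip(noise_pos, noise_strand):
            strand = "-" if minus else "+"
            acc[(strand, int(p))] = acc.get((strand, int(p)), 0) + 1

        records = [CtssRecord(chrom, p, s, c) for (s, p), c in sorted(acc.items())]
        records.sort(key=lambda r: (r.chrom, r.strand, r.pos))
        ctss[sample] = records

    sim.ctss = ctss
    sim.groups = groups
    sim.truth = pd.DataFrame(truth_rows)
    log.info("simulate_ctss_cohort: %d samples, %d planted sources",
             len(ctss), len(truth_rows))
    return sim


def simulate_beta_matrix(cfg: SimConfig, sim: SimData) -> SimData:
    """Beta matrix with CG-density-dependent baselines and planted tumor
    hypomethylation at CG-poor alternative promoters."""
    rng = np.random.default_rng(cfg.seed + 2)
    genes = _layout_genes(cfg, np.random.default_rng(cfg.seed))
    tumors, adjacent, _ = cfg.sample_names()
    samples = tumors + adjacent
    is_tumor = np.array([s in set(tumors) for s in samples])

    probes, base, delta = [], [], []
    for g in genes:
        for off in (-200, -100, 50, 150):
            probes.append((f"{g.gene_id}:cgi{off}", g.rel(0) + off,
                           cfg.beta_cgi_promoter, 0.0))
        if g.role in ("mp_annotated", "mp_novel"):
            alt = g.rel(g.alt_rel)
            for off in (-150, -50, 50, 150):
                probes.append((f"{g.gene_id}:alt{off}", alt + off,
                               cfg.beta_alt_promoter, cfg.planted_delta_beta))
        for off in (4800, 5000):
            probes.append((f"{g.gene_id}:body{off}", g.rel(off),
                           cfg.beta_gene_body, 0.0))
    probe_ids = [p[0] for p in probes]
    pos = np.array([p[1] for p in probes])
    base = np.array([p[2] for p in probes])
    delta = np.array([p[3] for p in probes])

    noise = rng.normal(0.0, cfg.probe_sigma, size=(len(probes), len(samples)))
    values = base[:, None] + delta[:, None] * is_tumor[None, :] + noise
    values = np.clip(values, 0.0, 1.0)

    sim.beta = pd.DataFrame(values, index=probe_ids, columns=samples)
    sim.probe_coords = pd.DataFrame(
        {"probe_id": probe_ids, "chrom": cfg.contig, "pos": pos}
    )
    sim.probe_truth = pd.DataFrame(
        {"probe_id": probe_ids, "differential": delta != 0.0, "delta_beta": delta}
    )
    return sim


def simulate_cohort(cfg: SimConfig) -> SimData:
    """Full simulation: genome + regions, CTSS cohort, beta matrix."""
    sim = simulate_genome(cfg)
    sim = simulate_ctss_cohort(cfg, sim)
    sim = simulate_beta_matrix(cfg, sim)
    return sim


# ----------------------------------------------------------------- output


def write_sim(sim: SimData, out_dir: str | Path) -> None:
    """Write the full simulated file tree (deterministic, byte-stable)."""
    out = Path(out_dir)
    (out / "ctss").mkdir(parents=True, exist_ok=True)
    chrom = sim.config.contig
    with open(out / "genome.fa", "w") as fh:
        fh.write(f">{chrom}\n")
        s = sim.genome[chrom]
        for i in range(0, len(s), 60):
            fh.write(s[i:i + 60] + "\n")
    aio.write_transcripts(sim.transcripts, out / "genes.gtf")
    aio.write_regions(sim.cgis, out / "cgi.bed")
    aio.write_regions(sim.blacklist, out / "blacklist.bed")
    aio.write_regions(sim.enhancers, out / "enhancers.bed")
    aio.write_regions(sim.smallrna_regions, out / "smallrna.bed")
    aio.write_regions(sim.coding_exons, out / "coding_exons.bed")
    aio.write_regions(
        [GenomicInterval(c, p, p + 1, s) for c, p, s in sim.supporting_5p],
        out / "support_5p.bed",
    )
    with open(out / "samples.tsv", "w") as fh:
        fh.write("sample\tgroup\n")
        for s in sorted(sim.groups):
            fh.write(f"{s}\t{sim.groups[s]}\n")
    for sample, records in sorted(sim.ctss.items()):
        df = pd.DataFrame(
            [(r.chrom, r.pos, r.strand, r.count) for r in records],
            columns=["chrom", "pos", "strand", "count"],
        )
        aio.write_ctss_table(df, out / "ctss" / f"{sample}.ctss.tsv")
    sim.truth.to_csv(out / "truth_clusters.tsv", sep="\t", index=False)
    if sim.beta is not None:
        aio.write_matrix(sim.beta, out / "beta.tsv", index_label="probe_id")
        sim.probe_coords.to_csv(out / "probes.tsv", sep="\t", index=False)
        sim.probe_truth.to_csv(out / "truth_probes.tsv", sep="\t", index=False)
    cfg_dict = dataclasses.asdict(sim.config)
    with open(out / "sim_config.yaml", "w") as fh:
        for k in sorted(cfg_dict):
            fh.write(f"{k}: {cfg_dict[k]}\n")


def load_sim(sim_dir: str | Path) -> SimData:
    """Re-load a written simulation directory into memory (pipeline input)."""
    from pyfaidx import Fasta

    d = Path(sim_dir)
    genome = {rec.name: str(rec[:]) for rec in Fasta(str(d / "genome.fa"))}
    ctss = {}
    for path in sorted((d / "ctss").glob("*.ctss.tsv")):
        df = aio.read_ctss_table(path)
        ctss[path.name.removesuffix(".ctss.tsv")] = [
            CtssRecord(r.chrom, int(r.pos), r.strand, int(r.count))
            for r in df.itertuples(index=False)
        ]
    beta_path = d / "beta.tsv"
    return SimData(
        config=SimConfig(),
        genome=genome,
        transcripts=aio.read_transcripts(d / "genes.gtf"),
        cgis=aio.read_regions(d / "cgi.bed"),
        blacklist=aio.read_regions(d / "blacklist.bed"),
        enhancers=aio.read_regions(d / "enhancers.bed"),
        smallrna_regions=aio.read_regions(d / "smallrna.bed"),
        coding_exons=aio.read_regions(d / "coding_exons.bed"),
        supporting_5p=[(r.chrom, r.start, r.strand)
                       for r in aio.read_regions(d / "support_5p.bed")],
        ctss=ctss,
        groups=aio.read_group_file(d / "samples.tsv"),
        truth=pd.read_csv(d / "truth_clusters.tsv", sep="\t"),
        beta=aio.read_matrix(beta_path) if beta_path.exists() else None,
        probe_coords=pd.read_csv(d / "probes.tsv", sep="\t")
        if (d / "probes.tsv").exists() else None,
        probe_truth=pd.read_csv(d / "truth_probes.tsv", sep="\t")
        if (d / "truth_probes.tsv").exists() else None,
    )
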
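# Methods

This note documents the models and procedures implemented in `altprom`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic cohort does and does not emulate.

## Coordinates and formats

All internal coordinates are 0-based half-open; a CTSS at position *p* is
the base interval [*p*, *p*+1). BED input/output round-trips
bit-identically. GTF attributes are parsed permissively (`key "value"`
pairs, trailing semicolon optional); a transcript's TSS is derived
strand-aware from its exons (start of the genomic-first exon on `+`,
end−1 of the genomic-last exon on `-`). The canonical per-sample CTSS
table is a TSV of `chrom, pos, strand, count[, tpm]`. SAM/BAM is read
through pysam, FASTA through pyfaidx, matrices through pandas, interval
overlap through intervaltree.

## CTSS extraction

Each retained read contributes one tag at its strand-aware 5′-most aligned
base. Reads with MAPQ < 20 (default, configurable) are discarded; unmapped
reads are skipped and counted, never raised. Tags overlapping blacklist
regions are removed. TPM = count × 10⁶ / library total, so per-sample TPMs
sum to 10⁶.

**Cap-G correction.** The CAGE protocol frequently adds a template-free G
to the capped end. Two cases arise at the alignment level: (a) the extra G
was soft-clipped — it is already outside the alignment, and the first
aligned base is the true TSS (no shift); (b) the extra G was absorbed as a
mismatch — detected as a first aligned base that is `G` on the read strand
while the reference base is not, in which case the TSS shifts one base
into the read body (coordinate +1 on `+`, −1 on `-`). A position never
moves by more than 1 nt. The minus-strand rule is the exact strand mirror
of the plus-strand rule.

## Tag clusters and the interquantile envelope

Same-strand CTSSs at consecutive distance ≤ 20 nt merge single-linkage;
clustering partitions the input. The dominant CTSS is the highest-count
position, ties broken to the 5′-most position (strand-aware) for
determinism. The "within 20 nt" rule is read as gap ≤ 20 (the ≤/<
ambiguity is a config knob).

The interquantile envelope trims edge positions from the left while their
cumulative tag mass is ≤ q_low·total and from the right while the
remaining suffix mass is ≤ (1−q_high)·total (defaults 0.1/0.9).
Equivalently it runs from the tag of rank ⌊q_low·total⌋+1 to the tag of
rank ⌈q_high·total⌉ in position order. Quantile thresholds are compared in
exact rational arithmetic so that decimal quantiles behave exactly (e.g.
q_high = 0.9 with 10 uniform tags trims exactly one trailing position;
naive float comparison gets boundary cases wrong in both directions). The
dominant CTSS is always kept inside the envelope, which matters only for
pathological tie cases. iq_width = iq_end − iq_start is non-increasing in
q_low and non-decreasing in q_high.

## Consensus clusters

Per-sample TCs merge across the cohort when their envelopes genuinely
overlap (`merge_gap = 0`; a positive value lets clusters separated by less
than `merge_gap` bases merge). Per-sample expression of a consensus
cluster is the summed member-CTSS TPM of that sample; the consensus
dominant CTSS and interquantile envelope are computed from counts pooled
over all samples. The expression filter retains a cluster iff
(#samples with TPM **>** 1) ≥ ⌈0.15 × cohort⌉ **and**
(#samples with TPM **≥** 3) ≥ 1 — strict for the 1-TPM condition
("higher than"), inclusive for the 3-TPM condition ("a minimum of"). With
a 100-sample cohort the first condition is 15 samples.

## Reference vs alternative promoters

A cluster whose dominant CTSS lies within ±300 b of a same-strand
annotated transcript TSS is promoter-assigned (nearest TSS wins when two
genes' windows overlap; ambiguity is logged). Remaining clusters are
intragenic if inside a same-strand gene body, else intergenic; the three
labels partition the cluster set. The ±300 b window is a package choice —
consistent with the 300-b rules used elsewhere (novel-TSS merging, 5′-end
support) — and configurable.

Within a gene, the reference promoter is the argmax of cohort-mean
expression **among promoters expressed in normal tissue** (≥ 3 TPM in ≥ 1
normal sample); if none qualifies, the global argmax. Ties break toward
annotated (non-novel) promoters, then 5′-most. All other promoters are
alternatives, positioned upstream/downstream of the reference by dominant
CTSS, mirrored on `-`. Genes are SP with exactly one promoter, otherwise
MP; gene expression is the element-wise sum of promoter TPM vectors.

## Novel-promoter cascade

Stages run in a fixed order, each only removing clusters, with a
per-cluster audit row: small-RNA overlap (≥ 1 bp of the supplied
small-RNA/drosha/snoRNA region set) → coding-exon overlap **or** GG
initiation → annotated-enhancer overlap → eRNA directionality → initiator
retention (YR or YC only) → 300-b single-linkage merging of surviving
dominants into novel TSSs → transcript 5′-end support.

* **Directionality.** DS = (forward − reverse)/(forward + reverse) TPM in
  the cluster envelope ± 200 b, pooled over the cohort. The ±200 b flank
  (≈400-b window, the common eRNA convention) is a package choice; no
  canonical value exists. |DS| ≤ 0.5 classifies the cluster as an eRNA;
  the band is closed at ±0.5 for determinism at the boundary, and an
  undefined DS (no signal) is conservatively not-eRNA.
* **Initiator.** The dinucleotide at (−1, +1) of the pooled dominant CTSS
  on the cluster strand; `GG` is classified first (recapping artifact),
  then YR (Y ∈ {C,T}, R ∈ {A,G}), then YC (taken literally: pyrimidine
  followed by C), else `other`. Contig-edge positions are `other`.
* **Support.** A novel TSS is supported iff ≥ 1 independent transcript 5′
  end (RNA-seq/EST) lies within ±300 b on the same strand, after first
  discarding supporting ends within ±300 b of any annotated transcript
  TSS. Only supported novel TSSs become `alternative_novel` promoters of
  their host gene.

## Sequence features

O/E CG = (#CG dinucleotides × window length)/(#C × #G); this is
algebraically the conventional (CG/L)/((C/L)(G/L)). N bases are excluded
from the window and counts and break dinucleotides; a window without CG
returns 0. The statistic is invariant under reverse complement.

CGIs are classified by overlap priority promoter > intragenic >
intergenic, with ≥ 1 bp sufficing and the promoter region taken as the
consensus-cluster envelope. Promoter shape is sharp iff pooled iq_width ≤
10 b (no published threshold exists; 10 b is the standard sharp/broad
convention and is reported in output). Enhancers are CGI-class when
unioned CGI overlap covers ≥ 10 % of their length. Per-promoter O/E CG is
measured on the dominant CTSS ± 100 b, a fixed window that is comparable
across sharp and broad promoters (envelopes of sharp promoters are too
short for a stable dinucleotide ratio).

## Differential methylation

Per probe, a two-tailed Welch (unequal-variance) t-test between the two
groups on beta values in [0,1]; missing betas are dropped per probe;
probes with < 2 usable values in either group are reported untested.
The degenerate both-groups-constant case is handled explicitly (equal
means → p = 1; unequal → p = 0). Adjustment is Benjamini–Hochberg across
all tested probes (bonferroni available); `significant` means adjusted
p < α (default 0.05). Probes are assigned to every TSS within ±500 b
(strand-agnostic distance). Mean-beta profiles bin probe group-means by
anchor-relative distance (mirrored for `-` anchors); empty bins are NaN.
Group files are plain two-column TSVs, so a mutant-vs-wild-type comparison
is the same code path with a different grouping file.

## Synthetic cohort

Defaults: 20 tumor + 20 matched adjacent + 4 normal libraries; one
~745-kb contig with 60 genes (12-kb pitch, 6-kb bodies, 3 exons of which
exon 1 is non-coding); 10 MP genes with an annotated alternative
transcript (65 % placed 2.5 kb downstream in intron 1, the rest 1.5 kb
upstream), 10 MP genes with a novel intronic alternative TSS (YR
initiator, an independent supporting 5′ end within ±30 b, ≥ 3 kb from any
annotated TSS); 10 bidirectional eRNA pairs (±-strand sharp clusters 180 b
apart, balanced Poisson(25) tags per strand ⇒ pooled DS ≈ 0); 10
GG-initiated artifacts on coding exons; 5 small-RNA tags inside annotated
small-RNA regions; a blacklisted region with decoy tags; 200 unstructured
noise tags per sample.

Reference promoters are broad (30–80 b Dirichlet-weighted supports,
Poisson(150) tags, active in every sample including normals); alternatives
are sharp (5-b support, 70 % mass on the dominant base, Poisson(60) tags),
active per tumor sample with probability 0.6, per adjacent sample 0.3,
and absent from normals — the tumor-enriched, cohort-variable regime the
reference/alternative designation is designed around. CGI sequences are
generated CG-rich (O/E ≥ 0.8 by construction, verified against the O/E
oracle), the background CG-depleted (O/E ≪ 0.4). The beta matrix plants
Δβ = −0.30 (tumor hypomethylation) at σ = 0.05 on probes around the
CG-poor alternative promoters, low baselines (0.10) on CGI reference
promoters and high baselines (0.70–0.80) elsewhere.

What the generator does **not** emulate: read-level sequencing error and
mappability, realistic sequence composition beyond CG density, expression
covariance between genes, promoter-switching dose effects on gene totals,
and array-specific probe biases. Passing recovery tests therefore
demonstrates the correctness and calibration of the pipeline's logic
under its stated model, not performance on real libraries, where mapping
artefacts and annotation incompleteness dominate the error budget.

Everything is deterministic given the seed (byte-identical file trees);
seeds for the genome, tag, and methylation layers are derived as seed,
seed+1, seed+2.

## Problem sizes and numerical choices

The default simulation (44 libraries × ~2.7 k CTSS positions, 440 probes)
runs the whole pipeline in a few seconds, which is the scale used by the
test suite and the acceptance script; all thresholds above are config
fields, and none is tuned per dataset. Tie-breaks (dominant CTSS,
reference choice) are fully deterministic. Degenerate inputs (empty
libraries, zero-variance probes, contig edges, windows without signal)
raise or fall back as documented per function rather than propagating
NaNs silently.

## Known limitations

* Read alignment itself is out of scope; the extractor consumes any
  coordinate-sorted SAM/BAM.
* Consensus merging requires genuine envelope overlap by default; cohorts
  with very sparse per-sample coverage may prefer a positive `merge_gap`.
* A cluster overlapping two genes' TSS windows is assigned to the nearest
  TSS only (flagged in the log), not duplicated.
* Differential expression (e.g. DESeq2-style shrinkage), survival
  association, and motif discovery are deliberately outside the package.
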
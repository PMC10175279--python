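"""Readers/writers for the external formats the pipeline touches.

BED3/BED6 and a permissive GTF dialect (``key "value"`` attribute pairs,
trailing semicolon optional) are parsed directly so malformed records can be
reported with their line number and BED round-trips stay bit-identical.
SAM/BAM goes through pysam (see :mod:`altprom.ctss`), FASTA through pyfaidx,
and matrices through pandas.

Canonical on-disk formats defined here:

* CTSS table — TSV with columns ``chrom, pos, strand, count[, tpm]``,
  one file per sample.
* expression matrix — TSV, first column feature id, header = sample ids.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable

import pandas as pd

from .intervals import GenomicInterval, TranscriptModel


class ParseError(ValueError):
    """Raised for malformed records; message names the file and line."""


# -------------------------------------------------------------- BED


def read_regions(bed_path: str | Path) -> list[GenomicInterval]:
    """Read BED3/BED6 into 0-based half-open intervals (strand '.' if absent)."""
    regions: list[GenomicInterval] = []
    with open(bed_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{bed_path}:{lineno}: expected >=3 BED fields")
            chrom, start_s, end_s = fields[0], fields[1], fields[2]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ParseError(f"{bed_path}:{lineno}: non-integer coordinate") from exc
            strand = fields[5] if len(fields) >= 6 else "."
            try:
                regions.append(GenomicInterval(chrom, start, end, strand))
            except ValueError as exc:
                raise ParseError(f"{bed_path}:{lineno}: {exc}") from exc
    return regions


def write_regions(regions: Iterable[GenomicInterval], bed_path: str | Path,
                  names: Iterable[str] | None = None) -> None:
    """Write BED6 (name '.', score 0); BED3 round-trips stay coordinate-identical."""
    names = list(names) if names is not None else None
    with open(bed_path, "w") as fh:
        for i, r in enumerate(regions):
            name = names[i] if names else "."
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{name}\t0\t{r.strand}\n")


# -------------------------------------------------------------- GTF

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_attributes(attr_block: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(attr_block))


def read_transcripts(gtf_path: str | Path) -> list[TranscriptModel]:
    """Parse exon features of a GTF into :class:`TranscriptModel` objects.

    TSS is derived strand-aware (start of the genomic-first exon on ``+``,
    end−1 of the genomic-last exon on ``-``); exons are returned in 5'→3'
    order.
    """
    exons: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str, str]] = {}  # tid -> (gene_id, chrom, strand)
    with open(gtf_path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ParseError(f"{gtf_path}:{lineno}: expected 9 GTF fields")
            chrom, _src, feature, start_s, end_s, _score, strand, _frame, attrs = fields[:9]
            if feature != "exon":
                continue
            attr = _parse_attributes(attrs)
            tid = attr.get("transcript_id")
            gid = attr.get("gene_id")
            if not tid or not gid:
                raise ParseError(
                    f"{gtf_path}:{lineno}: exon lacks transcript_id/gene_id attributes"
                )
            start, end = int(start_s) - 1, int(end_s)  # GTF is 1-based inclusive
            exons.setdefault(tid, []).append((start, end))
            prev = meta.setdefault(tid, (gid, chrom, strand))
            if prev != (gid, chrom, strand):
                raise ParseError(f"{gtf_path}:{lineno}: inconsistent metadata for {tid}")
    transcripts: list[TranscriptModel] = []
    for tid in sorted(exons):
        gid, chrom, strand = meta[tid]
        ivs = sorted(exons[tid])
        g_ivs = [GenomicInterval(chrom, s, e, strand) for s, e in ivs]
        for a, b in zip(g_ivs, g_ivs[1:]):
            if a.end > b.start:
                raise ParseError(f"{gtf_path}: overlapping exons in transcript {tid}")
        if strand == "-":
            tss = g_ivs[-1].end - 1
            g_ivs = g_ivs[::-1]  # 5'->3'
        else:
            tss = g_ivs[0].start
        transcripts.append(TranscriptModel(tid, gid, chrom, strand, tss, g_ivs))
    return transcripts


def write_transcripts(transcripts: Iterable[TranscriptModel],
                      gtf_path: str | Path, source: str = "altprom") -> None:
    with open(gtf_path, "w") as fh:
        for t in transcripts:
            for exon in sorted(t.exons, key=lambda e: e.start):
                attrs = f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'
                fh.write(
                    f"{t.chrom}\t{source}\texon\t{exon.start + 1}\t{exon.end}\t."
                    f"\t{t.strand}\t.\t{attrs}\n"
                )


# -------------------------------------------------------------- CTSS tables

CTSS_COLUMNS = ["chrom", "pos", "strand", "count", "tpm"]


def read_ctss_table(path: str | Path) -> pd.DataFrame:
    """Read a canonical CTSS TSV (``chrom pos strand count [tpm]``)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "strand": str})
    required = {"chrom", "pos", "strand", "count"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing CTSS columns {sorted(missing)}")
    if "tpm" not in df.columns:
        df["tpm"] = float("nan")
    return df[CTSS_COLUMNS]


def write_ctss_table(df: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in CTSS_COLUMNS if c in df.columns]
    df.to_csv(path, sep="\t", index=False, columns=cols)


# -------------------------------------------------------------- matrices


def read_matrix(path: str | Path) -> pd.DataFrame:
    """TSV matrix: first column = feature id (index), header = sample ids."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix(df: pd.DataFrame, path: str | Path, index_label: str = "feature_id") -> None:
    df.to_csv(path, sep="\t", index_label=index_label)


# -------------------------------------------------------------- misc


def read_group_file(path: str | Path) -> dict[str, str]:
    """Two-column sample→group TSV (with or without a header line)."""
    groups: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 2:
                raise ParseError(f"{path}:{lineno}: expected 2 columns")
            if lineno == 1 and fields[0].lower() in {"sample", "sample_id"}:
                continue
            groups[fields[0]] = fields[1]
    return groups
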
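"""Group-wise differential CpG methylation around promoters.

Beta values (per-probe methylation fractions in [0,1]) are compared between
two sample groups (tumor vs tumor-adjacent, or mutant vs wild-type) with a
two-tailed Welch t-test per probe, followed by Benjamini–Hochberg adjustment
across all tested probes.  Probes with fewer than two usable values in
either group are reported untested.  Mean beta profiles around anchor
positions (TSSs, CGI edges) are computed in fixed-width bins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)


@dataclass
class DiffMethResult:
    probe_id: str
    mean_group1: float
    mean_group2: float
    delta: float  # mean_group2 - mean_group1
    t_stat: float
    p: float
    p_adj: float
    significant: bool
    tested: bool = True


def probes_near_tss(
    probe_coords: pd.DataFrame,
    tss_list: Sequence[tuple[str, int]],
    flank: int = 500,
) -> pd.DataFrame:
    """Assign probes to every TSS within ±flank bases (strand-agnostic).

    ``probe_coords`` needs columns probe_id, chrom, pos.  A probe close to
    two TSSs appears once per TSS.  Returns columns probe_id, chrom, pos,
    tss, distance (signed pos - tss).
    """
    by_chrom: dict[str, list[int]] = {}
    for chrom, t in tss_list:
        by_chrom.setdefault(chrom, []).append(t)
    rows = []
    for rec in probe_coords.itertuples(index=False):
        for t in by_chrom.get(rec.chrom, []):
            if abs(rec.pos - t) <= flank:
                rows.append((rec.probe_id, rec.chrom, rec.pos, t, rec.pos - t))
    return pd.DataFrame(rows, columns=["probe_id", "chrom", "pos", "tss", "distance"])


def _welch(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Welch t-test robust to the zero-variance degenerate case."""
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return np.inf if b.mean() > a.mean() else -np.inf, 0.0
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def differential_beta(
    beta: pd.DataFrame,
    group_labels: Mapping[str, str] | pd.Series,
    alpha: float = 0.05,
    method: str = "fdr_bh",
) -> list[DiffMethResult]:
    """Per-probe two-group Welch t-test on beta values with multiple-testing
    adjustment ('fdr_bh' or 'bonferroni') across all tested probes.

    ``beta`` is probes × samples; ``group_labels`` maps sample id → group.
    delta = mean(group2) - mean(group1) with groups in sorted label order;
    missing betas are dropped per probe.  Probes with <2 usable values in a
    group are returned untested (p = NaN, significant = False).
    """
    labels = pd.Series(dict(group_labels))
    labels = labels[labels.index.intersection(beta.columns)]
    groups = sorted(labels.unique())
    if len(groups) != 2:
        raise ValueError(f"differential_beta needs exactly 2 groups, got {groups}")
    g1 = labels.index[labels == groups[0]]
    g2 = labels.index[labels == groups[1]]

    results: list[DiffMethResult] = []
    tested_idx: list[int] = []
    pvals: list[float] = []
    for i, (probe_id, row) in enumerate(beta.iterrows()):
        a = row[g1].dropna().to_numpy(dtype=float)
        b = row[g2].dropna().to_numpy(dtype=float)
        if len(a) < 2 or len(b) < 2:
            results.append(
                DiffMethResult(str(probe_id), float(np.mean(a)) if len(a) else np.nan,
                               float(np.mean(b)) if len(b) else np.nan,
                               np.nan, np.nan, np.nan, np.nan, False, tested=False)
            )
            continue
        t, p = _welch(a, b)
        results.append(
            DiffMethResult(str(probe_id), float(a.mean()), float(b.mean()),
                           float(b.mean() - a.mean()), t, p, np.nan, False)
        )
        tested_idx.append(i)
        pvals.append(p)
    if pvals:
        reject, p_adj, _, _ = multipletests(pvals, alpha=alpha, method=method)
        for i, padj, rej in zip(tested_idx, p_adj, reject):
            results[i].p_adj = float(padj)
            results[i].significant = bool(rej)
    n_sig = sum(r.significant for r in results)
    log.info("differential_beta: %d probes tested, %d significant at alpha=%g (%s)",
             len(pvals), n_sig, alpha, method)
    return results


def mean_beta_profile(
    beta: pd.DataFrame,
    probe_coords: pd.DataFrame,
    samples: Sequence[str],
    anchors: Sequence[tuple[str, int] | tuple[str, int, str]],
    flank: int = 2000,
    bin_size: int = 100,
) -> np.ndarray:
    """Binned mean beta around anchor positions for one sample group.

    Distances are anchor-relative (flipped for '-' strand anchors when a
    strand is given); bins cover [-flank, flank) and bin_size must divide
    2*flank.  Each (probe, anchor) pair contributes the probe's group-mean
    beta to its bin; empty bins are NaN.
    """
    if (2 * flank) % bin_size != 0:
        raise ValueError("bin_size must divide 2*flank")
    n_bins = (2 * flank) // bin_size
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=int)
    group_mean = beta[list(samples)].mean(axis=1)
    coord = probe_coords.set_index("probe_id")
    for anchor in anchors:
        chrom, pos = anchor[0], anchor[1]
        strand = anchor[2] if len(anchor) > 2 else "+"
        near = coord[(coord["chrom"] == chrom)
                     & (coord["pos"] >= pos - flank)
                     & (coord["pos"] < pos + flank)]
        for probe_id, row in near.iterrows():
            d = int(row["pos"]) - pos
            if strand == "-":
                d = -d - 1  # mirror so downstream-of-TSS stays downstream
            if not (-flank <= d < flank):
                continue
            b = (d + flank) // bin_size
            val = group_mean.get(probe_id, np.nan)
            if val == val:
                sums[b] += val
                counts[b] += 1
    with np.errstate(invalid="ignore"):
        profile = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return profile
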
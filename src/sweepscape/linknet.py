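"""Long-range linkage-network scoring around a sweep locus.

Partial sweeps can carry distant interacting loci to high frequency along
with the swept haplotype.  The network statistic screens for this: within
one background's carriers, every SNP at least 50 Mb from the sweep locus
(or on another chromosome) is tested for strong genotype LD (r^2 above a
cutoff, default 0.6) against the SNPs within 1 Mb of the locus, is scored
once per qualifying interaction, and the scores are accumulated into
half-open 500-kb bins.  Peaks in the histogram are then annotated with
overlapping genes.

The standard 100-kb LD distance cap deliberately does not apply here: the
statistic targets exactly the long-range pairs that cap excludes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genodata import ConfigurationError, InputError, IntervalSet, VariantMatrix
from .popstats import _masked_r2_matrix, _subset_rows

logger = logging.getLogger("sweepscape")

__all__ = ["LinkageHistogram", "linkage_network", "annotate_histogram"]


@dataclass
class LinkageHistogram:
    """500-kb-binned counts of strong long-range interactions with a locus."""

    background_label: str
    bins: pd.DataFrame  # chrom, bin_start, count
    snp_ledger: pd.DataFrame  # chrom, pos, count (per qualifying SNP)
    params: dict = field(default_factory=dict)
    n_skipped: int = 0  # zero-variance SNPs

    @property
    def total_interactions(self) -> int:
        return int(self.bins["count"].sum())

    def to_tsv(self, path, annotations=None):
        df = annotations if annotations is not None else self.bins
        df = df.rename(
            columns={"chrom": "CHROM", "bin_start": "BIN_START", "count": "COUNT",
                     "genes": "GENES"}
        )
        df.to_csv(path, sep="\t", index=False)


def linkage_network(
    vm: VariantMatrix,
    subset,
    locus,
    r2_min: float = 0.6,
    near_bp: float = 1e6,
    far_bp: float = 5e7,
    bin_bp: float = 5e5,
    background_label: str = "",
) -> LinkageHistogram:
    """Score distant SNPs for strong LD with the sweep-locus neighbourhood.

    Parameters
    ----------
    subset : sample ids
        Background members over which LD is computed (>= 4).
    locus : (chrom, start, end, name)
        Sweep locus interval, half-open 0-based.

    The *near* set is every SNP within ``near_bp`` of the locus interval;
    the *candidate* set is every SNP at least ``far_bp`` from the interval
    on the locus chromosome plus all SNPs on other chromosomes.  A
    candidate's score is its number of near-SNPs with r^2 > ``r2_min``
    (pairwise-complete dosage correlation, no distance cap).
    """
    rows = _subset_rows(vm, subset)
    if len(rows) < 4:
        raise ConfigurationError("linkage_network requires >= 4 samples")
    lchrom, lstart, lend, _ = locus
    if lchrom not in set(vm.chrom):
        raise ConfigurationError(f"locus chromosome {lchrom} absent from matrix")

    pos0 = vm.pos - 1
    on_chrom = vm.chrom == lchrom
    # distance from the nearest edge of the locus interval (0 inside)
    dist = np.where(pos0 < lstart, lstart - pos0, np.where(pos0 >= lend, pos0 - lend + 1, 0))
    near_idx = np.flatnonzero(on_chrom & (dist <= near_bp))
    if near_idx.size == 0:
        raise InputError("locus has no flanking SNPs within the near window")
    cand_idx = np.flatnonzero((~on_chrom) | (dist >= far_bp))

    hist_counts: dict = {}
    ledger = []
    n_skipped = 0
    g = vm.genotypes[rows]
    g_near = g[:, near_idx]
    # process candidates in blocks to bound the r^2 matrix size
    block = max(1, int(2_000_000 / max(len(near_idx), 1)))
    for lo in range(0, len(cand_idx), block):
        ci = cand_idx[lo : lo + block]
        r2, valid = _masked_r2_matrix(g[:, ci], g_near)
        strong = valid & (r2 > r2_min)
        scores = strong.sum(axis=1)
        n_skipped += int((~valid).sum())
        for k in np.flatnonzero(scores > 0):
            j = ci[k]
            ledger.append((vm.chrom[j], int(vm.pos[j]), int(scores[k])))
            key = (vm.chrom[j], int((vm.pos[j] - 1) // bin_bp * bin_bp))
            hist_counts[key] = hist_counts.get(key, 0) + int(scores[k])

    bins = pd.DataFrame(
        [(c, s, n) for (c, s), n in sorted(hist_counts.items())],
        columns=["chrom", "bin_start", "count"],
    )
    snp_ledger = pd.DataFrame(ledger, columns=["chrom", "pos", "count"])
    return LinkageHistogram(
        background_label=background_label,
        bins=bins,
        snp_ledger=snp_ledger,
        params={
            "r2_min": r2_min,
            "near_bp": near_bp,
            "far_bp": far_bp,
            "bin_bp": bin_bp,
        },
        n_skipped=n_skipped,
    )


def top_contigs(hist: LinkageHistogram, n: int = 5) -> LinkageHistogram:
    """Restrict a histogram to the n contigs with most interactions (ties by name)."""
    totals = hist.bins.groupby("chrom")["count"].sum().sort_index()
    keep = set(totals.sort_values(ascending=False, kind="stable").head(n).index)
    return LinkageHistogram(
        hist.background_label,
        hist.bins[hist.bins["chrom"].isin(keep)].reset_index(drop=True),
        hist.snp_ledger[hist.snp_ledger["chrom"].isin(keep)].reset_index(drop=True),
        hist.params,
        hist.n_skipped,
    )


def annotate_histogram(hist: LinkageHistogram, genes: IntervalSet) -> pd.DataFrame:
    """Attach overlapping gene names to each nonzero histogram bin.

    Bins are half-open ``[bin_start, bin_start + bin_bp)``; a gene interval
    overlapping a bin (half-open overlap) is listed in that bin, so a gene
    straddling a boundary annotates both bins.  Gene chromosomes absent
    from the histogram trigger a warning.
    """
    bin_bp = int(hist.params.get("bin_bp", 5e5))
    hist_chroms = set(hist.bins["chrom"])
    unmatched = sorted({g[0] for g in genes} - hist_chroms)
    if unmatched and len(hist.bins):
        warnings.warn(f"gene chromosomes not in histogram: {unmatched}")

    annotated = hist.bins.copy()
    names = []
    for _, row in annotated.iterrows():
        b0, b1 = row["bin_start"], row["bin_start"] + bin_bp
        hits = [
            name
            for chrom, start, end, name in genes
            if chrom == row["chrom"] and start < b1 and end > b0
        ]
        names.append(",".join(hits))
    annotated["genes"] = names
    return annotated
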
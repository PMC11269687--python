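"""Sweep-background identification and characterisation.

A *sweep background* is the set of individuals sharing the extended
haplotype that carries a selected allele.  Backgrounds are identified from
the outlier SNPs of the association scan in two ways:

* PCA of the outlier-SNP dosages of focal-mutation homozygotes followed by
  seeded k-means on the first two components (the study assigned clusters
  visually; the seeded clustering adds an explicit uncertainty flag);
* direct haplotype screening: individuals homozygous and non-missing at
  every screen SNP share a multilocus haplotype string (strict members);
  individuals with at most one heterozygous-or-missing screen site attach
  to the unique strict haplotype consistent with them (relaxed members).

Each background is then contrasted against a wild-type cohort via
Delta-statistics — differences of binned Tajima's D, nucleotide diversity
and moving-averaged LD — and against other backgrounds via windowed
Weir–Cockerham FST.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genodata import MISSING, ConfigurationError, IntervalSet, VariantMatrix
from .popstats import (
    TRACK_COLUMNS,
    WindowedStatTrack,
    genotype_r2,
    moving_average,
    site_pi,
    tajimas_d,
    wc_fst,
)

__all__ = [
    "SweepBackground",
    "DeltaProfile",
    "pca_cluster_homozygotes",
    "haplotype_screen",
    "delta_stats",
    "pairwise_background_fst",
]


@dataclass
class SweepBackground:
    """A labelled set of individuals sharing a swept haplotype."""

    label: str
    strict_members: list
    relaxed_members: list = field(default_factory=list)
    locus: tuple | None = None  # (chrom, start, end, name)
    comparison_populations: list | None = None
    haplotype: str = ""

    @property
    def members(self) -> list:
        return list(self.strict_members) + list(self.relaxed_members)

    def __post_init__(self):
        if not self.strict_members:
            raise ConfigurationError("a background needs at least one strict member")


@dataclass
class DeltaProfile:
    """Delta-D, Delta-pi and Delta-LD tracks for one background vs wild type."""

    background_label: str
    delta_d: WindowedStatTrack
    delta_pi: WindowedStatTrack
    delta_ld: WindowedStatTrack


def pca_cluster_homozygotes(
    vm: VariantMatrix,
    outlier_snps,
    k_clusters: int,
    seed: int = 0,
    homozygote_state: str = "hom-alt",
    uncertainty_quantile: float = 0.9,
):
    """PCA + seeded k-means clustering of focal homozygotes at outlier SNPs.

    Individuals whose distance to their centroid exceeds the given quantile
    of within-cluster distances are flagged uncertain (individuals spread
    toward the centre of the PCA, e.g. from missing data or recombination).

    Returns a DataFrame (sample, cluster, pc1, pc2, uncertain).
    """
    outlier_snps = np.asarray(outlier_snps)
    if outlier_snps.size == 0:
        raise ConfigurationError("outlier SNP set is empty")
    homs = [s for s in vm.samples if vm.focal_genotype.get(s) == homozygote_state]
    if len(homs) < k_clusters:
        raise ConfigurationError(
            f"only {len(homs)} homozygotes for {k_clusters} clusters"
        )
    rows = vm.sample_indices(homs)
    g = vm.genotypes[np.ix_(rows, outlier_snps)].astype(float)
    g[g == MISSING] = np.nan
    means = np.nanmean(g, axis=0)
    means = np.where(np.isnan(means), 0.0, means)
    idx = np.where(np.isnan(g))
    g[idx] = means[idx[1]]
    g -= g.mean(axis=0)

    if np.allclose(g, 0):  # degenerate: identical individuals
        coords = np.zeros((len(homs), 2))
        labels = np.zeros(len(homs), dtype=int)
        return pd.DataFrame(
            {"sample": homs, "cluster": labels, "pc1": 0.0, "pc2": 0.0,
             "uncertain": False}
        )

    u, s, vt = np.linalg.svd(g, full_matrices=False)
    n_pc = min(2, len(s))
    coords = u[:, :n_pc] * s[:n_pc]
    if n_pc == 1:
        coords = np.column_stack([coords, np.zeros(len(homs))])

    from sklearn.cluster import KMeans

    km = KMeans(n_clusters=k_clusters, n_init=50, random_state=seed)
    labels = km.fit_predict(coords)
    dist = np.linalg.norm(coords - km.cluster_centers_[labels], axis=1)
    cutoff = np.quantile(dist, uncertainty_quantile) if len(dist) > 1 else np.inf
    uncertain = dist > cutoff
    return pd.DataFrame(
        {
            "sample": homs,
            "cluster": labels,
            "pc1": coords[:, 0],
            "pc2": coords[:, 1],
            "uncertain": uncertain,
        }
    )


def haplotype_screen(
    vm: VariantMatrix,
    screen_snps,
    max_deviation: int = 1,
    min_strict: int = 1,
) -> list:
    """Group individuals by homozygous haplotype at the screen SNPs.

    Strict members are homozygous and non-missing at every screen SNP;
    their haplotype string (one allele per screen SNP) defines the
    background.  Relaxed members have at most ``max_deviation``
    heterozygous-or-missing screen sites and match exactly one strict
    haplotype at all their remaining sites; ambiguity leaves an individual
    unassigned.  Backgrounds with fewer than ``min_strict`` strict members
    are dropped.

    Returns a list of :class:`SweepBackground`, largest strict group first,
    labelled H1, H2, ...
    """
    screen_snps = np.asarray(screen_snps)
    if screen_snps.size == 0:
        raise ConfigurationError("screen SNP set is empty")
    g = vm.genotypes[:, screen_snps]
    strict_haps: dict[str, list] = {}
    pending = []  # (sample, hap template with None at deviations, n_dev)
    for i, sample in enumerate(vm.samples):
        row = g[i]
        deviant = (row == 1) | (row == MISSING)
        n_dev = int(deviant.sum())
        if n_dev == 0:
            hap = "".join("01"[int(x) // 2] for x in row)
            strict_haps.setdefault(hap, []).append(sample)
        elif n_dev <= max_deviation:
            pending.append((sample, row, deviant))

    relaxed: dict[str, list] = {h: [] for h in strict_haps}
    for sample, row, deviant in pending:
        matches = [
            h
            for h in strict_haps
            if all(
                deviant[j] or h[j] == "01"[int(row[j]) // 2]
                for j in range(len(row))
            )
        ]
        if len(matches) == 1:
            relaxed[matches[0]].append(sample)
        # ambiguous or unmatched -> unassigned

    order = sorted(strict_haps, key=lambda h: (-len(strict_haps[h]), h))
    backgrounds = []
    for k, hap in enumerate(order):
        if len(strict_haps[hap]) < min_strict:
            continue
        backgrounds.append(
            SweepBackground(
                label=f"H{k + 1}",
                strict_members=strict_haps[hap],
                relaxed_members=relaxed[hap],
                haplotype=hap,
            )
        )
    return backgrounds


def _binned_pi_track(vm, subset, bin_size):
    """Mean site-pi per half-open bin, emitted for bins containing SNPs."""
    pi = site_pi(vm, subset)
    df = pd.DataFrame(
        {
            "chrom": pi["chrom"],
            "bin": (pi["pos"] - 1) // bin_size,
            "pi": pi["pi"],
        }
    )
    recs = []
    for (chrom, b), grp in df.groupby(["chrom", "bin"], sort=True):
        vals = grp["pi"].dropna()
        value = float(vals.mean()) if len(vals) else np.nan
        recs.append(
            (chrom, int(b) * bin_size, (int(b) + 1) * bin_size, value, len(vals), 0)
        )
    return WindowedStatTrack("pi", pd.DataFrame(recs, columns=TRACK_COLUMNS))


def _binned_ld_track(vm, subset, bin_size, min_bp, max_bp):
    """Mean pairwise r^2 per bin, pairs assigned to their midpoint's bin."""
    ld = genotype_r2(vm, subset, min_bp=min_bp, max_bp=max_bp)
    df = ld.records
    recs = []
    if len(df):
        mid = (df["pos_i"] + df["pos_j"]) // 2
        tmp = pd.DataFrame(
            {"chrom": df["chrom_i"], "bin": (mid - 1) // bin_size, "r2": df["r2"]}
        )
        for (chrom, b), grp in tmp.groupby(["chrom", "bin"], sort=True):
            recs.append(
                (
                    chrom, int(b) * bin_size, (int(b) + 1) * bin_size,
                    float(grp["r2"].mean()), len(grp), 0,
                )
            )
    return WindowedStatTrack("ld", pd.DataFrame(recs, columns=TRACK_COLUMNS))


def _align_delta(track_a: WindowedStatTrack, track_b: WindowedStatTrack, name):
    a = track_a.records.set_index(["chrom", "win_start"])
    b = track_b.records.set_index(["chrom", "win_start"])
    idx = a.index.union(b.index).sort_values()
    va = a["value"].reindex(idx)
    vb = b["value"].reindex(idx)
    out = pd.DataFrame(
        {
            "chrom": [i[0] for i in idx],
            "win_start": [i[1] for i in idx],
            "win_end": [
                int(
                    a["win_end"].reindex(idx).fillna(b["win_end"].reindex(idx)).loc[i]
                )
                for i in idx
            ],
            "value": (va - vb).to_numpy(),
            "n_sites": a["n_sites"]
            .reindex(idx)
            .fillna(0)
            .add(b["n_sites"].reindex(idx).fillna(0))
            .astype(int)
            .to_numpy(),
            "n_samples_used": 0,
        }
    )
    return WindowedStatTrack(name, out.reset_index(drop=True))


def delta_stats(
    vm: VariantMatrix,
    background,
    wildtype,
    chrom: str | None = None,
    bin_size: int = 5000,
    ld_min_bp: int = 500,
    ld_max_bp: int | None = 100_000,
    ma_span: int = 100,
) -> DeltaProfile:
    """Delta-D, Delta-pi and Delta-LD between a background and a wild-type cohort.

    Delta-X(window) = X_background(window) - X_wildtype(window).  D and pi
    are binned; LD is the difference of moving-averaged binned r^2 profiles
    under the standard pair-distance bounds.  Windows undefined in either
    cohort are undefined in the difference.
    """
    members = background.members if isinstance(background, SweepBackground) else list(background)
    wt = list(wildtype)
    label = background.label if isinstance(background, SweepBackground) else "background"
    if set(members) & set(wt):
        raise ConfigurationError("background and wild-type sets overlap")
    if len(members) < 4 or len(wt) < 4:
        raise ConfigurationError("each cohort needs at least 4 samples")
    sub = vm if chrom is None else vm.take_snps(vm.chrom == chrom)

    d_bg = tajimas_d(sub, members, bin_size)
    d_wt = tajimas_d(sub, wt, bin_size)
    pi_bg = _binned_pi_track(sub, members, bin_size)
    pi_wt = _binned_pi_track(sub, wt, bin_size)
    ld_bg = moving_average(_binned_ld_track(sub, members, bin_size, ld_min_bp, ld_max_bp), ma_span)
    ld_wt = moving_average(_binned_ld_track(sub, wt, bin_size, ld_min_bp, ld_max_bp), ma_span)

    return DeltaProfile(
        background_label=label,
        delta_d=_align_delta(d_bg, d_wt, "delta_D"),
        delta_pi=_align_delta(pi_bg, pi_wt, "delta_pi"),
        delta_ld=_align_delta(ld_bg, ld_wt, "delta_ld"),
    )


def pairwise_background_fst(
    vm: VariantMatrix,
    background_a,
    background_b,
    window: int = 5000,
    step: int = 1000,
    highlight: float = 0.25,
):
    """Windowed Weir–Cockerham FST between two backgrounds plus highlights.

    Returns ``(track, highlighted, maxima)``: the sliding-window track, the
    per-SNP records with FST above ``highlight``, and per-chromosome window
    maxima (with the genome-wide maximum under key ``"genome"``).
    """
    mem_a = background_a.members if isinstance(background_a, SweepBackground) else list(background_a)
    mem_b = background_b.members if isinstance(background_b, SweepBackground) else list(background_b)
    per_snp, track = wc_fst(vm, mem_a, mem_b, window=window, step=step)
    highlighted = per_snp[per_snp["fst"] > highlight].reset_index(drop=True)

    maxima = {}
    rec = track.records.dropna(subset=["value"])
    if len(rec):
        gi = rec["value"].idxmax()
        maxima["genome"] = rec.loc[gi, ["chrom", "win_start", "win_end", "value"]].to_dict()
        for chrom, grp in rec.groupby("chrom"):
            ci = grp["value"].idxmax()
            maxima[chrom] = grp.loc[ci, ["win_start", "win_end", "value"]].to_dict()
    return track, highlighted, maxima
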
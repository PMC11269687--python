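"""Windowed population-genetic statistics with fixed window conventions.

Implements the statistics used to characterise partial sweeps, with the
exact conventions of the upstream study pipeline:

* per-site nucleotide diversity (pi), missing calls excluded per site;
* Tajima's D in non-overlapping 5-kb bins (half-open, 0-based grid per
  chromosome);
* genotype linkage disequilibrium r^2 — the squared Pearson correlation of
  unphased dosage vectors — with a 500 bp minimum and 100 kb maximum
  pair distance by default (interchromosomal mode lifts the bounds);
* Weir–Cockerham FST from variance components, per SNP and in 5-kb
  sliding windows stepped by 1 kb using the ratio-of-sums form;
* simple (unweighted) trailing moving averages for visualisation.

All statistics operate on un-imputed matrices: missing calls are handled
per site / per pair, never filled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genodata import MISSING, ConfigurationError, VariantMatrix

__all__ = [
    "WindowedStatTrack",
    "PairwiseLD",
    "site_pi",
    "tajimas_d",
    "tajima_constants",
    "genotype_r2",
    "wc_fst",
    "moving_average",
]

TRACK_COLUMNS = ["chrom", "win_start", "win_end", "value", "n_sites", "n_samples_used"]


@dataclass
class WindowedStatTrack:
    """Per-window records of one statistic (undefined values are NaN)."""

    statistic: str
    records: pd.DataFrame  # columns TRACK_COLUMNS

    def __post_init__(self):
        missing = [c for c in TRACK_COLUMNS if c not in self.records.columns]
        if missing:
            raise ConfigurationError(f"track lacks columns {missing}")

    def __len__(self):
        return len(self.records)

    def to_tsv(self, path):
        self.records.to_csv(path, sep="\t", index=False)


@dataclass
class PairwiseLD:
    """Pairwise r^2 records (chrom_i, pos_i, chrom_j, pos_j, r2)."""

    records: pd.DataFrame
    n_skipped: int = 0  # zero-variance pairs


def _subset_rows(vm: VariantMatrix, subset):
    if subset is None:
        return np.arange(vm.n_samples)
    rows = vm.sample_indices(subset)
    if len(rows) != len(set(map(int, rows))):
        raise ConfigurationError("duplicate samples in subset")
    return rows


def _site_counts(g: np.ndarray):
    """(alt allele count, called allele count) per site for a dosage block."""
    called = g != MISSING
    alt = np.where(called, g, 0).sum(axis=0)
    n_al = 2 * called.sum(axis=0)
    return alt, n_al


def site_pi(vm: VariantMatrix, subset=None) -> pd.DataFrame:
    """Per-site nucleotide diversity over a sample subset.

    pi = 2 p (1-p) n/(n-1) with p the alternate-allele frequency and n the
    called allele count — identical to the fraction of mismatching pairs
    among the C(n,2) pairs of called alleles.  Sites called in fewer than
    two samples are skipped (NaN) and counted in ``attrs['n_skipped']``.
    """
    rows = _subset_rows(vm, subset)
    if len(rows) < 2:
        raise ConfigurationError("site_pi requires at least 2 samples")
    g = vm.genotypes[rows]
    alt, n_al = _site_counts(g)
    n_called = (g != MISSING).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = alt / n_al
        pi = 2.0 * p * (1.0 - p) * n_al / (n_al - 1.0)
    pi = np.where(n_called >= 2, pi, np.nan)
    out = pd.DataFrame({"chrom": vm.chrom, "pos": vm.pos, "pi": pi, "n_alleles": n_al})
    out.attrs["n_skipped"] = int((n_called < 2).sum())
    return out


def tajima_constants(n: int):
    """Tajima's a1, a2, b1, b2, c1, c2, e1, e2 for n sequences."""
    if n < 2:
        raise ConfigurationError("Tajima constants need n >= 2")
    i = np.arange(1, n)
    a1 = np.sum(1.0 / i)
    a2 = np.sum(1.0 / i**2)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return a1, a2, b1, b2, c1, c2, e1, e2


def tajimas_d(vm: VariantMatrix, subset=None, bin_size: int = 5000) -> WindowedStatTrack:
    """Tajima's D in non-overlapping bins of ``bin_size`` bp.

    Per bin: S = number of segregating sites, k-hat = sum of per-site mean
    pairwise differences, and the allele count n entering the constants is
    the modal per-site called-allele count in the bin (with low missingness
    this equals the complete-data 2 x sample count).  Bins containing SNPs
    but no segregating site are emitted with value NaN.
    """
    if bin_size <= 0:
        raise ConfigurationError("bin_size must be positive")
    rows = _subset_rows(vm, subset)
    if len(rows) < 4:
        raise ConfigurationError("tajimas_d requires at least 4 samples")
    alt, n_al = _site_counts(vm.genotypes[rows])
    seg = (alt > 0) & (alt < n_al) & (n_al >= 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = alt / n_al
        khat_site = np.where(seg, 2.0 * p * (1.0 - p) * n_al / (n_al - 1.0), 0.0)

    df = pd.DataFrame(
        {
            "chrom": vm.chrom,
            "bin": (vm.pos - 1) // bin_size,
            "seg": seg.astype(int),
            "khat": khat_site,
            "n_al": np.where(n_al >= 2, n_al, 0),
            "usable": (n_al >= 2).astype(int),
        }
    )

    recs = []
    for (chrom, b), grp in df.groupby(["chrom", "bin"], sort=True):
        S = int(grp["seg"].sum())
        n_sites = int(grp["usable"].sum())
        counts = grp.loc[grp["n_al"] > 0, "n_al"]
        if S == 0 or len(counts) == 0:
            value, n_used = np.nan, 0
        else:
            n = int(counts.mode().min())  # modal called-allele count, ties low
            if n < 2:
                value, n_used = np.nan, n
            else:
                a1, _, _, _, _, _, e1, e2 = tajima_constants(n)
                var = e1 * S + e2 * S * (S - 1)
                khat = float(grp["khat"].sum())
                value = (khat - S / a1) / np.sqrt(var) if var > 0 else np.nan
                n_used = n
        recs.append((chrom, int(b) * bin_size, (int(b) + 1) * bin_size, value, n_sites, n_used))
    return WindowedStatTrack("D", pd.DataFrame(recs, columns=TRACK_COLUMNS))


def _masked_r2_matrix(g_left: np.ndarray, g_right: np.ndarray):
    """Pairwise-complete squared Pearson correlation between dosage columns.

    ``g_left``: samples x p, ``g_right``: samples x q, entries in
    {0,1,2,MISSING}.  Returns (r2 matrix p x q, valid mask) where invalid
    entries (zero variance or < 2 complete samples) are NaN.
    """
    v_l = (g_left != MISSING).astype(np.float64)
    v_r = (g_right != MISSING).astype(np.float64)
    x_l = np.where(g_left != MISSING, g_left, 0).astype(np.float64)
    x_r = np.where(g_right != MISSING, g_right, 0).astype(np.float64)

    n = v_l.T @ v_r
    sx = x_l.T @ v_r
    sy = v_l.T @ x_r
    sxy = x_l.T @ x_r
    sxx = (x_l**2).T @ v_r
    syy = v_l.T @ (x_r**2)

    with np.errstate(divide="ignore", invalid="ignore"):
        cov = sxy - sx * sy / n
        var_x = sxx - sx**2 / n
        var_y = syy - sy**2 / n
        r2 = cov**2 / (var_x * var_y)
    valid = (n >= 2) & (var_x > 1e-12) & (var_y > 1e-12)
    r2 = np.where(valid, np.clip(r2, 0.0, 1.0), np.nan)
    return r2, valid


def genotype_r2(
    vm: VariantMatrix,
    subset=None,
    min_bp: int = 500,
    max_bp: int | None = 100_000,
    interchrom: bool = False,
) -> PairwiseLD:
    """Genotype LD as squared dosage correlation over pairwise-complete samples.

    Same-chromosome pairs closer than ``min_bp`` or farther than ``max_bp``
    are excluded (``max_bp=None`` lifts the cap — used by the long-range
    linkage network).  With ``interchrom=True`` cross-chromosome pairs are
    included and distance bounds do not apply to them.  Zero-variance pairs
    are skipped and counted.
    """
    rows = _subset_rows(vm, subset)
    if len(rows) < 2:
        raise ConfigurationError("genotype_r2 requires at least 2 samples")
    g = vm.genotypes[rows]

    recs = []
    n_skipped = 0
    chrom_ids = pd.unique(vm.chrom)
    for chrom in chrom_ids:
        idx = np.flatnonzero(vm.chrom == chrom)
        pos = vm.pos[idx]
        block = g[:, idx]
        r2_all, valid = _masked_r2_matrix(block, block)
        for a in range(len(idx)):
            dist = pos[a + 1:] - pos[a]
            sel = dist >= min_bp
            if max_bp is not None:
                sel &= dist <= max_bp
            for off in np.flatnonzero(sel):
                b = a + 1 + off
                if not valid[a, b]:
                    n_skipped += 1
                    continue
                recs.append((chrom, int(pos[a]), chrom, int(pos[b]), float(r2_all[a, b])))

    if interchrom:
        for ci in range(len(chrom_ids)):
            for cj in range(ci + 1, len(chrom_ids)):
                ii = np.flatnonzero(vm.chrom == chrom_ids[ci])
                jj = np.flatnonzero(vm.chrom == chrom_ids[cj])
                r2_ab, valid = _masked_r2_matrix(g[:, ii], g[:, jj])
                for a in range(len(ii)):
                    for b in range(len(jj)):
                        if not valid[a, b]:
                            n_skipped += 1
                            continue
                        recs.append(
                            (
                                chrom_ids[ci], int(vm.pos[ii[a]]),
                                chrom_ids[cj], int(vm.pos[jj[b]]),
                                float(r2_ab[a, b]),
                            )
                        )
    df = pd.DataFrame(recs, columns=["chrom_i", "pos_i", "chrom_j", "pos_j", "r2"])
    return PairwiseLD(df, n_skipped=n_skipped)


def _wc_components(vm: VariantMatrix, rows_a, rows_b):
    """Weir–Cockerham (1984) per-SNP variance components a, b, c for two groups."""
    comps = []
    for rows in (rows_a, rows_b):
        g = vm.genotypes[rows]
        called = g != MISSING
        n_i = called.sum(axis=0).astype(float)  # diploid individuals called
        alt = np.where(called, g, 0).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            p_i = alt / (2.0 * n_i)
        h_i = np.where(n_i > 0, (g == 1).sum(axis=0) / np.maximum(n_i, 1), 0.0)
        comps.append((n_i, np.nan_to_num(p_i), h_i))
    (n1, p1, h1), (n2, p2, h2) = comps

    r = 2.0
    usable = (n1 > 0) & (n2 > 0) & (n1 + n2 > 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        nbar = (n1 + n2) / r
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1.0)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        inner = pbar * (1 - pbar) - (r - 1.0) / r * s2
        a = nbar / nc * (s2 - (inner - hbar / 4.0) / (nbar - 1.0))
        b = nbar / (nbar - 1.0) * (inner - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar)
        c = hbar / 2.0
    for arr in (a, b, c):
        arr[~usable] = np.nan
    return a, b, c, usable


def wc_fst(
    vm: VariantMatrix,
    group_a,
    group_b,
    window: int = 5000,
    step: int = 1000,
):
    """Weir–Cockerham FST between two sample groups.

    Returns ``(per_snp, track)``: a per-SNP DataFrame with theta = a/(a+b+c)
    (negative estimates retained, not clipped) and a sliding-window
    :class:`WindowedStatTrack` whose value is the ratio of summed components
    sum(a)/sum(a+b+c) over the SNPs in each half-open window; windows
    without usable SNPs are omitted.
    """
    rows_a = _subset_rows(vm, group_a)
    rows_b = _subset_rows(vm, group_b)
    if len(rows_a) < 2 or len(rows_b) < 2:
        raise ConfigurationError("each group needs at least 2 samples")
    if set(map(int, rows_a)) & set(map(int, rows_b)):
        raise ConfigurationError("groups overlap")
    if window <= 0 or step <= 0:
        raise ConfigurationError("window and step must be positive")

    a, b, c, usable = _wc_components(vm, rows_a, rows_b)
    denom = a + b + c
    with np.errstate(divide="ignore", invalid="ignore"):
        theta = np.where(usable & (np.abs(denom) > 0), a / denom, np.nan)
    per_snp = pd.DataFrame({"chrom": vm.chrom, "pos": vm.pos, "fst": theta})

    recs = []
    n_used = len(rows_a) + len(rows_b)
    for chrom in pd.unique(vm.chrom):
        idx = np.flatnonzero((vm.chrom == chrom) & usable & ~np.isnan(denom))
        if len(idx) == 0:
            continue
        pos0 = vm.pos[idx] - 1  # 0-based
        ca = np.concatenate([[0.0], np.cumsum(a[idx])])
        cd = np.concatenate([[0.0], np.cumsum(denom[idx])])
        last_start = (int(pos0.max()) // step) * step
        for start in range(0, last_start + 1, step):
            lo = np.searchsorted(pos0, start, side="left")
            hi = np.searchsorted(pos0, start + window, side="left")
            if hi <= lo:
                continue
            num = ca[hi] - ca[lo]
            den = cd[hi] - cd[lo]
            val = num / den if abs(den) > 0 else np.nan
            recs.append((chrom, start, start + window, val, hi - lo, n_used))
    track = WindowedStatTrack("fst", pd.DataFrame(recs, columns=TRACK_COLUMNS))
    return per_snp, track


def global_wc_fst(vm: VariantMatrix, group_a, group_b) -> float:
    """Genome-wide weighted Weir–Cockerham FST: sum(a) / sum(a+b+c) over SNPs."""
    rows_a = _subset_rows(vm, group_a)
    rows_b = _subset_rows(vm, group_b)
    a, b, c, usable = _wc_components(vm, rows_a, rows_b)
    denom = a + b + c
    ok = usable & np.isfinite(denom)
    return float(np.nansum(a[ok]) / np.nansum(denom[ok]))


def moving_average(track: WindowedStatTrack, span: int) -> WindowedStatTrack:
    """Simple trailing moving average over the preceding ``span`` records.

    Computed within each chromosome in record order; the first ``span - 1``
    records of each chromosome are undefined.  NaN (undefined) input
    records are skipped by the average (min_periods = span over defined
    values would discard long runs; instead the mean ignores NaN but the
    positional warm-up rule is kept).
    """
    if span < 1:
        raise ConfigurationError("span must be >= 1")
    df = track.records.reset_index(drop=True)
    out = np.full(len(df), np.nan)
    for chrom, grp in df.groupby("chrom", sort=False):
        vals = grp["value"].to_numpy(dtype=float)
        finite = np.isfinite(vals)
        csum = np.concatenate([[0.0], np.cumsum(np.where(finite, vals, 0.0))])
        ccnt = np.concatenate([[0], np.cumsum(finite.astype(int))])
        ma = np.full(len(vals), np.nan)
        for i in range(span - 1, len(vals)):
            cnt = ccnt[i + 1] - ccnt[i + 1 - span]
            if cnt > 0:
                ma[i] = (csum[i + 1] - csum[i + 1 - span]) / cnt
        out[grp.index.to_numpy()] = ma
    df = df.copy()
    df["value"] = out
    return WindowedStatTrack(track.statistic + "_ma", df)
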
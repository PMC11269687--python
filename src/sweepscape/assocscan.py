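"""Structure-conditioned genome scan for SNPs tracking a focal genotype.

The scan asks, SNP by SNP, whether genetic variation is structured in line
with the genotype at a focal resistance mutation (e.g. a sodium-channel
*kdr* substitution) beyond what genome-wide population structure explains.
Structure is captured by K latent factors — here the leading principal
components of the centred dosage matrix — and each SNP's dosage is
regressed on (intercept, focal dosage, factors).  The focal-coefficient
z-scores are recalibrated by the genomic inflation factor
lambda_GC = median(z^2) / 0.4549 before two-sided normal p-values, which
are then Benjamini–Hochberg adjusted.  Outliers are SNPs whose adjusted
p-value falls below the inverse of the number of SNPs scanned.

This is a deterministic least-squares counterpart of the MCMC latent
factor mixed model: same test target (structure-adjusted association),
no sampler nondeterminism, a single z per SNP.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genodata import MISSING, ConfigurationError, InputError, IntervalSet, VariantMatrix

logger = logging.getLogger("sweepscape")

__all__ = [
    "AssociationScanResult",
    "latent_factors",
    "lfmm_scan",
    "adjust_pvalues_bh",
    "outlier_threshold",
    "select_outliers",
]

#: median of the chi-square(1) distribution, the null median of z^2
CHI2_MEDIAN_1DF = float(stats.chi2.ppf(0.5, 1))


@dataclass
class AssociationScanResult:
    """Per-SNP scan output plus the scan's calibration metadata."""

    records: pd.DataFrame  # chrom, pos, z, p, p_adj, tested
    K: int
    maf_cutoff: float
    lambda_gc: float
    samples_used: list = field(default_factory=list)

    @property
    def n_tested(self) -> int:
        return int(self.records["tested"].sum())

    def to_tsv(self, path, threshold=None):
        df = self.records.rename(
            columns={"chrom": "CHROM", "pos": "POS", "z": "Z", "p": "P", "p_adj": "P_ADJ"}
        )
        if threshold is not None:
            df["OUTLIER"] = (df["P_ADJ"] < threshold).fillna(False)
        df.to_csv(path, sep="\t", index=False)


def _mean_filled_dosage(vm: VariantMatrix, rows) -> np.ndarray:
    g = vm.genotypes[rows].astype(float)
    g[g == MISSING] = np.nan
    means = np.nanmean(g, axis=0)
    means = np.where(np.isnan(means), 0.0, means)
    idx = np.where(np.isnan(g))
    g[idx] = means[idx[1]]
    return g


def latent_factors(vm: VariantMatrix, K: int, seed: int = 0, subset=None):
    """Leading K principal-component scores of the centred dosage matrix.

    Missing entries are mean-filled for factor estimation only.  Returns
    ``(scores, variance_explained)`` where the variance profile (all
    components up to min(n, p)) aids manual choice of K; the sign of each
    component is fixed so its largest-magnitude loading is positive.
    """
    rows = np.arange(vm.n_samples) if subset is None else vm.sample_indices(subset)
    if not 1 <= K < len(rows):
        raise ConfigurationError(f"K must satisfy 1 <= K < {len(rows)} samples")
    g = _mean_filled_dosage(vm, rows)
    g -= g.mean(axis=0)
    u, s, vt = np.linalg.svd(g, full_matrices=False)
    # deterministic sign: largest-|loading| entry of each right vector positive
    for k in range(len(s)):
        j = int(np.argmax(np.abs(vt[k])))
        if vt[k, j] < 0:
            u[:, k] *= -1
            vt[k] *= -1
    scores = u[:, :K] * s[:K]
    var = s**2
    variance_explained = var / var.sum() if var.sum() > 0 else var
    return scores, variance_explained


def lfmm_scan(
    vm: VariantMatrix,
    focal,
    K: int,
    maf: float = 0.05,
    seed: int = 0,
    subset=None,
) -> AssociationScanResult:
    """Latent-factor-adjusted association scan of every SNP against ``focal``.

    Parameters
    ----------
    focal : array-like
        Per-sample dosage of the focal mutation in {0, 1, 2}; NaN entries
        (unknown genotype) drop the sample from the scan.
    K : int
        Number of latent structure factors (0 reduces to simple regression).
    maf : float
        SNPs with minor allele frequency below this are flagged untested.
    """
    rows = np.arange(vm.n_samples) if subset is None else vm.sample_indices(subset)
    focal = np.asarray(focal, dtype=float)
    if len(focal) != len(rows):
        raise ConfigurationError("focal vector length must match the sample set")
    keep = ~np.isnan(focal)
    rows, focal = rows[keep], focal[keep]
    n = len(rows)
    if n < K + 3:
        raise ConfigurationError("too few samples with known focal genotype")
    if np.all(focal == focal[0]):
        raise InputError("focal genotype is constant: no contrast to test")

    g = _mean_filled_dosage(vm, rows)
    p_hat = g.mean(axis=0) / 2.0
    maf_vec = np.minimum(p_hat, 1.0 - p_hat)
    tested = maf_vec >= maf

    if K > 0:
        sub_vm = type(vm)(
            [vm.samples[i] for i in rows], vm.chrom, vm.pos, vm.genotypes[rows],
        )
        factors, _ = latent_factors(sub_vm, K, seed=seed)
        # drop factors collinear with the focal contrast
        fc = focal - focal.mean()
        keep_f = []
        for k in range(factors.shape[1]):
            col = factors[:, k]
            denom = np.linalg.norm(fc) * np.linalg.norm(col - col.mean())
            corr = 0.0 if denom == 0 else abs(np.dot(fc, col - col.mean()) / denom)
            if corr > 0.999:
                warnings.warn(f"latent factor {k + 1} collinear with focal; dropped")
            else:
                keep_f.append(k)
        factors = factors[:, keep_f]
        X = np.column_stack([np.ones(n), focal, factors])
    else:
        X = np.column_stack([np.ones(n), focal])

    q = X.shape[1]
    xtx_inv = np.linalg.pinv(X.T @ X)
    beta = xtx_inv @ X.T @ g  # q x p
    resid = g - X @ beta
    dof = n - q
    if dof < 1:
        raise ConfigurationError("not enough residual degrees of freedom")
    sigma2 = (resid**2).sum(axis=0) / dof
    se = np.sqrt(np.maximum(sigma2 * xtx_inv[1, 1], 1e-300))
    z = beta[1] / se

    z_tested = z[tested]
    if len(z_tested) == 0:
        raise InputError("no SNPs pass the MAF cutoff")
    lambda_gc = float(np.median(z_tested**2) / CHI2_MEDIAN_1DF)
    if lambda_gc <= 0:
        lambda_gc = 1.0
    z_cal = z / np.sqrt(lambda_gc)
    p = 2.0 * stats.norm.sf(np.abs(z_cal))

    p_adj = np.full(vm.n_snps, np.nan)
    p_adj[tested] = adjust_pvalues_bh(p[tested])[0]

    records = pd.DataFrame(
        {
            "chrom": vm.chrom,
            "pos": vm.pos,
            "z": np.where(tested, z_cal, np.nan),
            "p": np.where(tested, p, np.nan),
            "p_adj": p_adj,
            "tested": tested,
        }
    )
    if lambda_gc > 1.5:
        logger.info("lfmm_scan: genomic inflation lambda_gc = %.2f", lambda_gc)
    return AssociationScanResult(
        records, K=K, maf_cutoff=maf, lambda_gc=lambda_gc,
        samples_used=[vm.samples[i] for i in rows],
    )


def adjust_pvalues_bh(p, fdr: float = 0.01):
    """Benjamini–Hochberg step-up adjustment.

    Returns ``(adjusted p, flags)`` where flags mark adjusted p < ``fdr``.
    """
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise InputError("p-values must lie in [0, 1]")
    from statsmodels.stats.multitest import multipletests

    if len(p) == 0:
        return p.copy(), np.zeros(0, dtype=bool)
    _, p_adj, _, _ = multipletests(p, alpha=fdr, method="fdr_bh")
    return p_adj, p_adj < fdr


def outlier_threshold(n_snps: int) -> float:
    """Outlier significance threshold: the inverse of the number of SNPs."""
    if n_snps < 1:
        raise ConfigurationError("n_snps must be >= 1")
    return 1.0 / n_snps


@dataclass
class OutlierSelection:
    """Outlier SNP index sets from one or two scans sharing a SNP frame."""

    outliers_a: np.ndarray
    outliers_b: np.ndarray | None
    intersection: np.ndarray | None
    partitions: dict  # name -> {"inside", "near", "elsewhere"} index arrays


def select_outliers(
    result_a: AssociationScanResult,
    result_b: AssociationScanResult | None = None,
    threshold: float = None,
    locus_window: IntervalSet | None = None,
    near_bp: float = 1e6,
) -> OutlierSelection:
    """Outlier sets per scan, their intersection, and near-locus partitions.

    An outlier is a tested SNP with adjusted p below ``threshold`` (default:
    1 / number of SNPs in the frame).  With a locus interval set, each
    outlier set is partitioned into inside-interval / within ``near_bp`` of
    an interval / elsewhere.
    """
    frame = result_a.records
    if threshold is None:
        threshold = outlier_threshold(len(frame))
    if result_b is not None:
        fb = result_b.records
        if not (
            np.array_equal(frame["pos"].to_numpy(), fb["pos"].to_numpy())
            and np.array_equal(frame["chrom"].to_numpy(), fb["chrom"].to_numpy())
        ):
            raise InputError("scans do not share a SNP frame")

    def outlier_idx(res):
        padj = res.records["p_adj"].to_numpy()
        return np.flatnonzero(res.records["tested"].to_numpy() & (padj < threshold))

    out_a = outlier_idx(result_a)
    out_b = outlier_idx(result_b) if result_b is not None else None
    inter = (
        np.intersect1d(out_a, out_b) if out_b is not None else None
    )

    partitions = {}
    if locus_window is not None:
        chrom = frame["chrom"].to_numpy()
        pos0 = frame["pos"].to_numpy() - 1
        inside = np.zeros(len(frame), dtype=bool)
        near = np.zeros(len(frame), dtype=bool)
        for ichrom, start, end, _name in locus_window:
            on = chrom == ichrom
            inside |= on & (pos0 >= start) & (pos0 < end)
            near |= on & (pos0 >= start - near_bp) & (pos0 < end + near_bp)
        for name, idx in (
            ("scan_a", out_a),
            ("scan_b", out_b),
            ("intersection", inter),
        ):
            if idx is None:
                continue
            partitions[name] = {
                "inside": idx[inside[idx]],
                "near": idx[near[idx] & ~inside[idx]],
                "elsewhere": idx[~near[idx]],
            }
    return OutlierSelection(out_a, out_b, inter, partitions)
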
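"""f3 admixture tests and PCA-projection admixture proportions.

The three-population statistic f3(C; A, B) = E[(c - a)(c - b)] over SNPs,
with the Patterson-style correction - c(1 - c)/(n_C - 1) removing the bias
from estimating the target frequency c with n_C sampled alleles, is
significantly negative when population C derives from admixture of sources
related to A and B.  Standard errors come from a delete-one block
jackknife over consecutive SNP blocks; significance is one-sided for
f3 < 0 with Bonferroni control over the triads tested in a run.

Admixture proportions are estimated geometrically: a single principal
component is built from the pooled source-population dosages, query
individuals are projected with the same centring and loadings, and the
relative position between the source means gives alpha-hat in [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genodata import MISSING, ConfigurationError, InputError, VariantMatrix

__all__ = ["F3Result", "ProjectionResult", "f3_test", "f3_tests", "pca_projection"]


@dataclass
class F3Result:
    """One f3 test: value, jackknife SE, Z, p, Bonferroni-adjusted p."""

    target: str
    source_a: str
    source_b: str
    f3: float
    se: float
    z: float
    p: float
    p_bonferroni: float
    n_snps: int
    n_blocks: int
    block_size: int


@dataclass
class ProjectionResult:
    """Source-pair PC1 projection with per-sample admixture estimates."""

    loadings: np.ndarray
    coordinates: pd.DataFrame  # sample, coordinate, alpha_hat, role
    mean_a: float
    mean_b: float


def _pop_freqs(vm: VariantMatrix, pop):
    rows = vm.sample_indices(vm.pop_members(pop))
    if len(rows) < 2:
        raise ConfigurationError(f"population {pop} needs >= 2 samples")
    g = vm.genotypes[rows]
    called = g != MISSING
    alt = np.where(called, g, 0).sum(axis=0)
    n_al = 2 * called.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = alt / n_al
    return p, n_al


def f3_test(
    vm: VariantMatrix,
    target: str,
    source_a: str,
    source_b: str,
    block_size: int = 500,
    n_triads: int = 1,
) -> F3Result:
    """f3(target; A, B) with block-jackknife significance.

    Per SNP, f3 = (c - a)(c - b) - c(1 - c)/(n_C - 1) with a, b, c the
    sample alternate-allele frequencies and n_C the target's called allele
    count.  SNPs with any of the three frequencies undefined, or n_C < 2,
    are dropped.  ``n_triads`` scales the Bonferroni adjustment when the
    test is part of a batch.
    """
    a, _ = _pop_freqs(vm, source_a)
    b, _ = _pop_freqs(vm, source_b)
    c, n_c = _pop_freqs(vm, target)
    ok = np.isfinite(a) & np.isfinite(b) & np.isfinite(c) & (n_c >= 2)
    # drop sites monomorphic across all three groups: uninformative
    poly = ~((a == b) & (b == c) & ((c == 0) | (c == 1)))
    ok &= poly
    if not ok.any():
        raise InputError("no informative SNP for the f3 test")
    f3_snp = ((c - a) * (c - b) - c * (1 - c) / (n_c - 1))[ok]

    n = len(f3_snp)
    n_blocks = int(np.ceil(n / block_size))
    if n_blocks < 2:
        raise ConfigurationError("need at least 2 SNP blocks for the jackknife")
    if n_blocks < 20:
        warnings.warn(
            f"only {n_blocks} jackknife blocks: f3 may be underpowered "
            "(reduced-representation data caveat)"
        )
    total = f3_snp.sum()
    f3_hat = total / n
    loo = np.empty(n_blocks)
    for i in range(n_blocks):
        sl = slice(i * block_size, min((i + 1) * block_size, n))
        m = sl.stop - sl.start
        loo[i] = (total - f3_snp[sl].sum()) / (n - m)
    se = float(np.sqrt((n_blocks - 1) / n_blocks * ((loo - loo.mean()) ** 2).sum()))
    if se <= 0:
        raise InputError("degenerate jackknife (zero variance)")
    z = float(f3_hat / se)
    from scipy.stats import norm

    p = float(norm.cdf(z))  # one-sided: admixture signal is f3 < 0
    return F3Result(
        target, source_a, source_b,
        float(f3_hat), se, z, p, min(1.0, p * n_triads),
        n_snps=n, n_blocks=n_blocks, block_size=block_size,
    )


def f3_tests(vm: VariantMatrix, triads, block_size: int = 500) -> pd.DataFrame:
    """Run f3 for a list of (target, sourceA, sourceB) triads, Bonferroni over all."""
    results = [
        f3_test(vm, t, a, b, block_size=block_size, n_triads=len(triads))
        for t, a, b in triads
    ]
    return pd.DataFrame(
        [
            (r.target, r.source_a, r.source_b, r.f3, r.se, r.z, r.p, r.p_bonferroni)
            for r in results
        ],
        columns=["TARGET", "A", "B", "F3", "SE", "Z", "P", "P_BONF"],
    )


def pca_projection(
    vm: VariantMatrix,
    source_a: str,
    source_b: str,
    query_samples,
) -> ProjectionResult:
    """Project query samples onto the PC1 of two source populations.

    The axis is the leading principal component of the centred,
    frequency-standardised dosages of the pooled source samples, restricted
    to SNPs polymorphic in that pool.  Queries are projected with the same
    centring and loadings (missing entries contribute zero after centring).
    alpha-hat = (mean_B - x) / (mean_B - mean_A), clipped to [0, 1]; the
    axis is oriented with source A at the negative end, so alpha-hat is the
    source-A ancestry fraction.
    """
    mem_a = vm.pop_members(source_a)
    mem_b = vm.pop_members(source_b)
    if set(mem_a) & set(mem_b):
        raise ConfigurationError("source populations overlap")
    if len(mem_a) < 3 or len(mem_b) < 3:
        raise ConfigurationError("each source population needs >= 3 samples")
    pool = mem_a + mem_b
    rows = vm.sample_indices(pool)
    g = vm.genotypes[rows].astype(float)
    g[g == MISSING] = np.nan

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        p = np.nanmean(g, axis=0) / 2.0
    poly = np.isfinite(p) & (p > 0) & (p < 1)
    if not poly.any():
        raise InputError("no SNP polymorphic in the source pool")
    g = g[:, poly]
    p = p[poly]
    centre = 2.0 * p
    scale = np.sqrt(2.0 * p * (1.0 - p))

    z = (g - centre) / scale
    z[~np.isfinite(z)] = 0.0  # missing entries: no deviation from the pool mean
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    loadings = vt[0] / s[0] * np.sqrt(len(pool)) if s[0] > 0 else vt[0]
    if s[0] <= 1e-10:
        raise InputError("degenerate axis: source populations indistinguishable")

    def project(sample_ids):
        r = vm.sample_indices(sample_ids)
        q = vm.genotypes[r].astype(float)
        q[q == MISSING] = np.nan
        zq = (q[:, poly] - centre) / scale
        zq[~np.isfinite(zq)] = 0.0
        return zq @ loadings

    x_a = project(mem_a)
    x_b = project(mem_b)
    mean_a, mean_b = float(x_a.mean()), float(x_b.mean())
    if abs(mean_a - mean_b) < 1e-10:
        raise InputError("degenerate axis: source means coincide")
    sign = -1.0 if mean_a > mean_b else 1.0  # orient source A negative
    loadings_o = loadings * sign
    x_a, x_b, mean_a, mean_b = sign * x_a, sign * x_b, sign * mean_a, sign * mean_b

    query_samples = list(query_samples)
    x_q = sign * project(query_samples) if query_samples else np.array([])

    def alpha(x):
        return float(np.clip((mean_b - x) / (mean_b - mean_a), 0.0, 1.0))

    rows_out = (
        [(s, float(x), alpha(x), "source_a") for s, x in zip(mem_a, x_a)]
        + [(s, float(x), alpha(x), "source_b") for s, x in zip(mem_b, x_b)]
        + [(s, float(x), alpha(x), "query") for s, x in zip(query_samples, x_q)]
    )
    coords = pd.DataFrame(rows_out, columns=["sample", "coordinate", "alpha_hat", "role"])
    return ProjectionResult(loadings_o, coords, mean_a, mean_b)
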
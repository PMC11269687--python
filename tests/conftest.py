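import numpy as np
import pytest

from sweepscape import VariantMatrix


def make_vm(genotypes, chrom=None, pos=None, populations=None, focal=None):
    """Small VariantMatrix from a genotype list-of-rows (samples x SNPs)."""
    g = np.asarray(genotypes, dtype=np.int8)
    n_samples, n_snps = g.shape
    samples = [f"s{i + 1}" for i in range(n_samples)]
    chrom = np.asarray(chrom, dtype=object) if chrom is not None else np.full(
        n_snps, "chr1", dtype=object
    )
    pos = np.asarray(pos, dtype=np.int64) if pos is not None else np.arange(
        1, n_snps + 1
    ) * 1000
    pops = populations or {s: "pop1" for s in samples}
    focal_map = focal or {}
    return VariantMatrix(samples, chrom, pos, g, pops, {}, focal_map)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def random_vm(rng, n_samples, n_snps, missing_rate=0.1, n_pops=1):
    """Random small matrix for oracle comparisons (may contain missing)."""
    g = rng.integers(0, 3, size=(n_samples, n_snps)).astype(np.int8)
    if missing_rate > 0:
        g[rng.random(g.shape) < missing_rate] = -1
    samples = [f"s{i + 1}" for i in range(n_samples)]
    pops = {s: f"pop{(i % n_pops) + 1}" for i, s in enumerate(samples)}
    pos = np.sort(rng.choice(np.arange(1, 10_000_000), size=n_snps, replace=False))
    return VariantMatrix(
        samples, np.full(n_snps, "chr1", dtype=object), pos, g, pops, {}, {}
    )
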
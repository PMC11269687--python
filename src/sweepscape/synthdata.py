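"""Structured genotype/depth simulator with embedded partial sweeps.

The generator produces the statistical structure that partial selective
sweeps leave in population SNP data, by forward construction rather than
coalescent simulation, so that every downstream stage has exact ground
truth:

* multi-population differentiation under the Balding–Nichols model
  (per-population allele frequencies drawn from a Beta distribution around a
  shared ancestral frequency, dispersion set by a drift parameter F);
* one or more sweep *backgrounds*: sets of carrier individuals whose
  chromosomes are overwritten by a shared haplotype around a focal locus,
  with per-chromosome tract lengths decaying exponentially away from the
  locus (recombination erosion) and an always-swept core, plus an explicit
  excess of private singleton variants on swept chromosomes (the
  rare-allele signature, injected so a negative Tajima's D contrast is not
  an artifact of the overwrite);
* per-individual read depths: a Gamma-distributed sequencing-effort scalar
  per individual and Poisson site depths proportional to local copy number,
  giving the read-depth-ratio signal used for copy-number inference;
* optional admixed individuals whose alleles are drawn from a mixture of
  two source populations' empirical frequencies, optionally with
  post-admixture binomial drift.

All generators are bit-for-bit reproducible under a fixed seed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genodata import (
    MISSING,
    ConfigurationError,
    DepthMatrix,
    IntervalSet,
    VariantMatrix,
)

__all__ = [
    "SweepSpec",
    "CnvSpec",
    "AdmixtureSpec",
    "SimulationConfig",
    "simulate_neutral",
    "overlay_sweep",
    "simulate_depth",
    "simulate_admixture",
]


@dataclass
class SweepSpec:
    """One sweep background at a focal locus.

    ``carrier_fraction`` / ``het_fraction`` give the fraction of each
    population's individuals made homozygous / heterozygous carriers; a
    scalar applies to every population, a dict maps population label to
    fraction.  ``mean_tract`` is the expected one-sided swept tract length
    (exponential decay), ``core_halfwidth`` the always-swept core around the
    locus, and ``rare_mut_rate`` the expected number of private singleton
    variants per swept chromosome.
    """

    chrom: str
    locus_pos: int
    background_label: str
    carrier_fraction: object = 0.3
    het_fraction: object = 0.0
    mean_tract: float = 2e6
    core_halfwidth: float = 1e6
    rare_mut_rate: float = 2.0

    def __post_init__(self):
        if not self.mean_tract > self.core_halfwidth >= 0:
            raise ConfigurationError("require mean_tract > core_halfwidth >= 0")

    def fraction_for(self, pop, het=False):
        f = self.het_fraction if het else self.carrier_fraction
        f = f.get(pop, 0.0) if isinstance(f, dict) else float(f)
        if not 0 <= f <= 1:
            raise ConfigurationError("carrier fractions must lie in [0, 1]")
        return f


@dataclass
class CnvSpec:
    """Copy-number multiplier for one genomic region.

    ``copy_number`` is a scalar, a per-population dict, or a per-sample
    dict; the diploid baseline elsewhere is 2.
    """

    region: tuple  # (chrom, start, end, name), half-open 0-based
    copy_number: object = 2

    def copy_for(self, sample, population):
        cn = self.copy_number
        if isinstance(cn, dict):
            cn = cn.get(sample, cn.get(population, 2))
        if cn < 0:
            raise ConfigurationError("copy_number must be >= 0")
        return float(cn)


@dataclass
class AdmixtureSpec:
    """Two-source admixture: alpha from source_a, (1 - alpha) from source_b."""

    source_a: str
    source_b: str
    alpha: float = 0.5
    n_admixed: int = 10
    drift_generations: int = 0
    drift_pop_size: int = 200

    def __post_init__(self):
        if not 0 <= self.alpha <= 1:
            raise ConfigurationError("alpha must lie in [0, 1]")


@dataclass
class SimulationConfig:
    """Study-condition defaults for the simulator.

    The defaults emulate a two-population reduced-representation SNP study:
    50 diploids per population, 5,000 SNPs over two 20-Mb chromosomes,
    Balding–Nichols drift F = 0.1, 2.5% missing calls, and mean read depth
    20x.
    """

    seed: int = 0
    n_chrom: int = 2
    chrom_length: int = 20_000_000
    n_snps: int = 5000
    n_pops: int = 2
    n_per_pop: int = 50
    drift_F: object = 0.1  # scalar or per-population list
    missing_rate: float = 0.025
    sweeps: list = field(default_factory=list)
    cnv: CnvSpec | None = None
    depth_mean: float = 20.0
    admixture: AdmixtureSpec | None = None

    def __post_init__(self):
        for name in ("n_chrom", "chrom_length", "n_snps", "n_pops", "n_per_pop"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        if not 0 <= self.missing_rate < 1:
            raise ConfigurationError("missing_rate must lie in [0, 1)")
        for f in self.drift_values():
            if not 0 < f < 1:
                raise ConfigurationError("drift_F must lie in (0, 1)")

    def drift_values(self):
        f = self.drift_F
        if np.isscalar(f):
            return [float(f)] * self.n_pops
        if len(f) != self.n_pops:
            raise ConfigurationError("drift_F list length must equal n_pops")
        return [float(x) for x in f]

    def chrom_names(self):
        return [f"chr{i + 1}" for i in range(self.n_chrom)]

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "sweeps" in raw:
            raw["sweeps"] = [SweepSpec(**s) for s in raw["sweeps"]]
        if raw.get("cnv"):
            c = raw["cnv"]
            c["region"] = tuple(c["region"])
            raw["cnv"] = CnvSpec(**c)
        if raw.get("admixture"):
            raw["admixture"] = AdmixtureSpec(**raw["admixture"])
        return cls(**raw)


def simulate_neutral(config: SimulationConfig) -> VariantMatrix:
    """Balding–Nichols multi-population genotypes without selection.

    SNP positions are uniform without replacement per chromosome (sorted);
    the ancestral frequency of each SNP is Uniform(0.05, 0.95); population
    frequencies are Beta(p(1-F)/F, (1-p)(1-F)/F); genotypes are
    Binomial(2, p_pop), then masked missing at ``missing_rate``.
    """
    rng = np.random.default_rng(config.seed)
    per_chrom = np.full(config.n_chrom, config.n_snps // config.n_chrom)
    per_chrom[: config.n_snps % config.n_chrom] += 1
    if per_chrom.max() > config.chrom_length:
        raise ConfigurationError("n_snps exceeds chromosome capacity")

    chroms, poss = [], []
    for name, k in zip(config.chrom_names(), per_chrom):
        pos = np.sort(rng.choice(config.chrom_length, size=int(k), replace=False)) + 1
        chroms.append(np.full(int(k), name, dtype=object))
        poss.append(pos)
    chrom = np.concatenate(chroms)
    pos = np.concatenate(poss)
    p_anc = rng.uniform(0.05, 0.95, size=config.n_snps)

    samples, pops = [], {}
    geno_blocks = []
    for j, F in enumerate(config.drift_values()):
        pop = f"pop{j + 1}"
        ids = [f"{pop}_ind{i + 1}" for i in range(config.n_per_pop)]
        samples.extend(ids)
        pops.update({s: pop for s in ids})
        a = p_anc * (1 - F) / F
        b = (1 - p_anc) * (1 - F) / F
        p_pop = rng.beta(a, b)
        geno_blocks.append(
            rng.binomial(2, p_pop, size=(config.n_per_pop, config.n_snps)).astype(np.int8)
        )
    geno = np.vstack(geno_blocks)
    if config.missing_rate > 0:
        mask = rng.random(geno.shape) < config.missing_rate
        geno[mask] = MISSING

    regions = {s: pops[s] for s in samples}
    focal = {s: "wild-type" for s in samples}
    return VariantMatrix(samples, chrom, pos, geno, pops, regions, focal)


def _background_haplotype(label: str, n_snps: int) -> np.ndarray:
    # one fixed random allele per SNP, a function of the label alone so the
    # same background reuses its haplotype across calls
    rng = np.random.default_rng(zlib.crc32(label.encode()) & 0x7FFFFFFF)
    return rng.integers(0, 2, size=n_snps).astype(np.int8)


def overlay_sweep(vm: VariantMatrix, spec: SweepSpec, seed: int, exclude=()):
    """Overwrite carrier chromosomes with a shared swept haplotype.

    Returns ``(new_vm, carrier_table)`` where the table records ground-truth
    membership (columns: sample, background, zygosity).  Non-carrier
    genotypes are never altered; missing calls stay missing (dropout is an
    observation-level artifact).  ``exclude`` lists samples that must not be
    chosen as carriers (used when layering several backgrounds).
    """
    if spec.chrom not in set(vm.chrom):
        raise ConfigurationError(f"chromosome {spec.chrom} absent from matrix")
    rng = np.random.default_rng(seed)
    on_chrom = np.flatnonzero(vm.chrom == spec.chrom)
    pos_c = vm.pos[on_chrom]

    pops = sorted({vm.populations[s] for s in vm.samples}) if vm.populations else [None]
    carriers = []  # (sample, n_copies)
    for pop in pops:
        members = [s for s in vm.samples if pop is None or vm.populations[s] == pop]
        eligible = [s for s in members if s not in exclude]
        # fractions refer to the population size; carriers drawn from the
        # samples not already claimed by another background
        n_hom = int(round(spec.fraction_for(pop, het=False) * len(members)))
        n_het = int(round(spec.fraction_for(pop, het=True) * len(members)))
        if n_hom + n_het > len(eligible):
            raise ConfigurationError("carrier fractions exceed available samples")
        chosen = rng.choice(len(eligible), size=n_hom + n_het, replace=False)
        carriers += [(eligible[i], 2) for i in chosen[:n_hom]]
        carriers += [(eligible[i], 1) for i in chosen[n_hom:]]

    if not carriers:
        import warnings

        warnings.warn(f"sweep {spec.background_label}: zero carriers; identity output")
        return replace(vm, genotypes=vm.genotypes.copy()), pd.DataFrame(
            columns=["sample", "background", "zygosity"]
        )

    hap = _background_haplotype(spec.background_label, len(on_chrom))
    geno = vm.genotypes.copy()
    focal = dict(vm.focal_genotype) if vm.focal_genotype else {}
    idx_of = {s: i for i, s in enumerate(vm.samples)}

    for sample, copies in carriers:
        row = idx_of[sample]
        g = geno[row, on_chrom].astype(np.int16)
        swept = np.zeros((copies, len(on_chrom)), dtype=bool)
        for c in range(copies):
            left = max(spec.core_halfwidth, rng.exponential(spec.mean_tract))
            right = max(spec.core_halfwidth, rng.exponential(spec.mean_tract))
            swept[c] = (pos_c >= spec.locus_pos - left) & (pos_c <= spec.locus_pos + right)
        n_swept = swept.sum(axis=0)
        # residual allele for the unswept chromosome of a het carrier; a
        # missing call on a part-swept site resolves to a random residual
        residual = np.where(
            g == 2, 1, np.where(g == 0, 0, rng.integers(0, 2, len(g)))
        )
        # the overwrite yields observed calls: the swept tract is the
        # ground-truth construction the screening stage is tested against
        new = np.where(n_swept == 2, 2 * hap, np.where(n_swept == 1, hap + residual, g))
        # private singletons on each swept chromosome: flip that chromosome's
        # allele away from the background haplotype
        for c in range(copies):
            tract = np.flatnonzero(swept[c])
            k = rng.poisson(spec.rare_mut_rate)
            if k and len(tract):
                hit = rng.choice(tract, size=min(k, len(tract)), replace=False)
                new[hit] = np.clip(new[hit] + (1 - 2 * hap[hit]), 0, 2)
        geno[row, on_chrom] = new.astype(np.int8)
        if focal:
            focal[sample] = "hom-alt" if copies == 2 else "het"

    table = pd.DataFrame(
        {
            "sample": [s for s, _ in carriers],
            "background": spec.background_label,
            "zygosity": ["hom" if c == 2 else "het" for s, c in carriers],
        }
    )
    out = replace(vm, genotypes=geno, focal_genotype=focal)
    return out, table


def depth_site_grid(config: SimulationConfig, spacing: int = 5000):
    """A uniform site grid (chrom, pos arrays) for depth simulation."""
    chroms, poss = [], []
    for name in config.chrom_names():
        pos = np.arange(1, config.chrom_length + 1, spacing, dtype=np.int64)
        chroms.append(np.full(len(pos), name, dtype=object))
        poss.append(pos)
    return np.concatenate(chroms), np.concatenate(poss)


def simulate_depth(
    config: SimulationConfig,
    samples,
    populations: dict,
    chrom,
    pos,
    seed: int | None = None,
) -> DepthMatrix:
    """Poisson read depths with per-individual effort and regional copy number.

    Effort s_i ~ Gamma(shape 10, mean ``depth_mean``); depth at site r ~
    Poisson(s_i * c_ir / 2) with c_ir the copy number from ``config.cnv``
    inside its region and 2 elsewhere.
    """
    if config.depth_mean <= 0:
        raise ConfigurationError("depth_mean must be positive")
    chrom = np.asarray(chrom, dtype=object)
    pos = np.asarray(pos, dtype=np.int64)
    rng = np.random.default_rng(config.seed + 7_001 if seed is None else seed)
    effort = rng.gamma(shape=10.0, scale=config.depth_mean / 10.0, size=len(samples))

    in_region = np.zeros(len(pos), dtype=bool)
    if config.cnv is not None:
        rchrom, start, end, _ = config.cnv.region
        in_region = (chrom == rchrom) & (pos - 1 >= start) & (pos - 1 < end)

    depth = np.empty((len(samples), len(pos)), dtype=np.int64)
    for i, s in enumerate(samples):
        copy = np.full(len(pos), 2.0)
        if config.cnv is not None:
            copy[in_region] = config.cnv.copy_for(s, populations.get(s))
        depth[i] = rng.poisson(effort[i] * copy / 2.0)
    return DepthMatrix(list(samples), chrom, pos, depth, dict(populations))


def simulate_admixture(
    vm: VariantMatrix,
    pop_a: str,
    pop_b: str,
    alpha: float,
    n: int,
    seed: int,
    drift_generations: int = 0,
    drift_pop_size: int = 200,
) -> VariantMatrix:
    """Append ``n`` admixed individuals drawn from a two-source frequency mixture.

    Each allele comes from population A's empirical alternate-allele
    frequency with probability ``alpha``, else from population B's.  With
    ``drift_generations`` > 0, the mixed frequency vector first undergoes
    binomial resampling (2N draws per generation) to emulate post-admixture
    drift, which is what makes the f3 statistic robustly negative.
    """
    if not 0 <= alpha <= 1:
        raise ConfigurationError("alpha must lie in [0, 1]")
    for p in (pop_a, pop_b):
        if not vm.pop_members(p):
            raise ConfigurationError(f"population {p} absent")
    if n == 0:
        return vm
    rng = np.random.default_rng(seed)

    def freqs(pop):
        rows = vm.sample_indices(vm.pop_members(pop))
        g = vm.genotypes[rows]
        called = g != MISSING
        alt = np.where(called, g, 0).sum(axis=0)
        tot = 2 * called.sum(axis=0)
        return np.where(tot > 0, alt / np.maximum(tot, 1), 0.5)

    p_mix = alpha * freqs(pop_a) + (1 - alpha) * freqs(pop_b)
    for _ in range(drift_generations):
        p_mix = rng.binomial(2 * drift_pop_size, p_mix) / (2 * drift_pop_size)

    geno = rng.binomial(2, p_mix, size=(n, vm.n_snps)).astype(np.int8)
    ids = [f"admix_ind{i + 1}" for i in range(n)]
    samples = list(vm.samples) + ids
    new_geno = np.vstack([vm.genotypes, geno])
    pops = dict(vm.populations)
    regions = dict(vm.regions)
    focal = dict(vm.focal_genotype)
    for s in ids:
        if pops:
            pops[s] = "admixed"
        if regions:
            regions[s] = "admixed"
        if focal:
            focal[s] = "unknown"
    return VariantMatrix(samples, vm.chrom, vm.pos, new_geno, pops, regions, focal)


def simulate_study(config: SimulationConfig):
    """Full generator: neutral matrix + sweeps + depth + admixture.

    Returns ``(vm, depth_matrix_or_None, carrier_table)``.
    """
    vm = simulate_neutral(config)
    tables = []
    taken: set = set()
    for i, spec in enumerate(config.sweeps):
        vm, tab = overlay_sweep(vm, spec, seed=config.seed + 101 + i, exclude=taken)
        taken |= set(tab["sample"])
        tables.append(tab)
    carrier_table = (
        pd.concat(tables, ignore_index=True)
        if tables
        else pd.DataFrame(columns=["sample", "background", "zygosity"])
    )
    if config.admixture is not None:
        a = config.admixture
        vm = simulate_admixture(
            vm, a.source_a, a.source_b, a.alpha, a.n_admixed,
            seed=config.seed + 977,
            drift_generations=a.drift_generations,
            drift_pop_size=a.drift_pop_size,
        )
    dm = None
    if config.cnv is not None:
        chrom, pos = depth_site_grid(config)
        dm = simulate_depth(config, vm.samples, vm.populations, chrom, pos)
    return vm, dm, carrier_table
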
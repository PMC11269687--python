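"""Genotype data model, VCF/BED/TSV ingestion, variant filters and imputation.

The central container is :class:`VariantMatrix`: an individuals x SNPs matrix
of alternate-allele dosages (0/1/2, with -1 encoding a missing call) plus
genomic coordinates and per-sample metadata (population, geographic region,
and the genotype state at a named focal resistance mutation such as a
voltage-sensitive sodium channel *kdr* substitution).  A parallel
:class:`DepthMatrix` holds per-sample per-site read depths on the same
coordinate frame; depth sites need not be polymorphic.

Coordinate conventions: VCF positions are 1-based; interval files (BED) are
half-open 0-based.  Conversion happens only at the I/O boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger("sweepscape")

#: Sentinel for a missing genotype call.
MISSING = -1

FOCAL_STATES = ("wild-type", "het", "hom-alt", "unknown")


class InputError(ValueError):
    """Unreadable or malformed input data."""


class ConfigurationError(ValueError):
    """Invalid parameter value or inconsistent configuration."""


def _check_coordinates(chrom: np.ndarray, pos: np.ndarray) -> None:
    if len(chrom) != len(pos):
        raise ConfigurationError("chrom and pos must have equal length")
    # positions strictly increasing within each chromosome block
    same = chrom[1:] == chrom[:-1]
    if np.any(same & (np.diff(pos) <= 0)):
        raise ConfigurationError("positions must be strictly increasing within chromosomes")


@dataclass
class VariantMatrix:
    """Diploid biallelic genotype matrix with sample metadata.

    Attributes
    ----------
    samples : list of str
        Ordered sample identifiers; rows of ``genotypes``.
    chrom, pos : ndarray
        Per-SNP chromosome id and 1-based position, sorted with positions
        strictly increasing within each chromosome.
    genotypes : ndarray of int8, shape (n_samples, n_snps)
        Alternate-allele dosage in {0, 1, 2} or ``MISSING`` (-1).
    populations, regions, focal_genotype : dict
        Per-sample labels; ``focal_genotype`` takes values in
        ``{"wild-type", "het", "hom-alt", "unknown"}``.
    """

    samples: list
    chrom: np.ndarray
    pos: np.ndarray
    genotypes: np.ndarray
    populations: dict = field(default_factory=dict)
    regions: dict = field(default_factory=dict)
    focal_genotype: dict = field(default_factory=dict)

    def __post_init__(self):
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if len(self.samples) < 1:
            raise ConfigurationError("VariantMatrix needs at least one sample")
        if self.genotypes.ndim != 2 or self.genotypes.shape != (len(self.samples), len(self.pos)):
            raise ConfigurationError(
                f"genotype matrix shape {self.genotypes.shape} does not match "
                f"{len(self.samples)} samples x {len(self.pos)} SNPs"
            )
        if self.n_snps < 1:
            raise ConfigurationError("VariantMatrix needs at least one SNP")
        _check_coordinates(self.chrom, self.pos)
        bad = ~np.isin(self.genotypes, (0, 1, 2, MISSING))
        if bad.any():
            raise ConfigurationError("genotypes must be 0, 1, 2 or missing (-1)")
        sset = set(self.samples)
        if len(sset) != len(self.samples):
            raise ConfigurationError("duplicate sample ids")
        for name, mapping in (
            ("populations", self.populations),
            ("regions", self.regions),
            ("focal_genotype", self.focal_genotype),
        ):
            if mapping and set(mapping) != sset:
                missing = sset - set(mapping)
                extra = set(mapping) - sset
                raise ConfigurationError(
                    f"{name} keys must be exactly the sample set "
                    f"(missing: {sorted(missing)[:5]}, extra: {sorted(extra)[:5]})"
                )

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.pos)

    def sample_indices(self, subset) -> np.ndarray:
        """Row indices for an iterable of sample ids (order preserved)."""
        lookup = {s: i for i, s in enumerate(self.samples)}
        try:
            return np.array([lookup[s] for s in subset], dtype=np.intp)
        except KeyError as exc:
            raise ConfigurationError(f"unknown sample id: {exc.args[0]}") from None

    def pop_members(self, population) -> list:
        return [s for s in self.samples if self.populations.get(s) == population]

    def take_snps(self, index) -> "VariantMatrix":
        """New matrix restricted to the given SNP indices (kept sorted)."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return replace(
            self,
            chrom=self.chrom[index],
            pos=self.pos[index],
            genotypes=self.genotypes[:, index],
        )

    def called_mask(self) -> np.ndarray:
        return self.genotypes != MISSING


@dataclass
class DepthMatrix:
    """Per-sample per-site read depth on a sorted coordinate frame.

    Sites need not be polymorphic; the copy-number pipeline deliberately
    retains monomorphic sites.
    """

    samples: list
    chrom: np.ndarray
    pos: np.ndarray
    depth: np.ndarray  # (n_samples, n_sites), non-negative int
    populations: dict = field(default_factory=dict)
    regions: dict = field(default_factory=dict)

    def __post_init__(self):
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.depth = np.asarray(self.depth)
        if self.depth.shape != (len(self.samples), len(self.pos)):
            raise ConfigurationError("depth matrix shape mismatch")
        _check_coordinates(self.chrom, self.pos)
        if (self.depth < 0).any():
            raise ConfigurationError("depths must be non-negative")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_indices(self, subset) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        return np.array([lookup[s] for s in subset], dtype=np.intp)


@dataclass
class IntervalSet:
    """Named genomic intervals, half-open zero-based (BED convention)."""

    records: list  # of (chrom, start, end, name)

    def __post_init__(self):
        names = [r[3] for r in self.records]
        if len(set(names)) != len(names):
            raise ConfigurationError("interval names must be unique within a set")
        for chrom, start, end, name in self.records:
            if not start < end:
                raise ConfigurationError(f"interval {name}: start must be < end")

    def __iter__(self):
        return iter(self.records)

    def __len__(self):
        return len(self.records)

    @classmethod
    def from_bed(cls, path) -> "IntervalSet":
        recs = []
        with open(path) as fh:
            for i, line in enumerate(fh):
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise InputError(f"{path}: BED line {i + 1} has fewer than 3 columns")
                name = parts[3] if len(parts) > 3 else f"interval_{i + 1}"
                recs.append((parts[0], int(parts[1]), int(parts[2]), name))
        return cls(recs)

    def to_bed(self, path) -> None:
        with open(path, "w") as fh:
            for chrom, start, end, name in self.records:
                fh.write(f"{chrom}\t{start}\t{end}\t{name}\n")

    def span(self):
        """(chrom, min start, max end) — all records must share one chromosome."""
        chroms = {r[0] for r in self.records}
        if len(chroms) != 1:
            raise ConfigurationError("span() requires a single-chromosome interval set")
        return (
            next(iter(chroms)),
            min(r[1] for r in self.records),
            max(r[2] for r in self.records),
        )


# ---------------------------------------------------------------------------
# metadata and VCF I/O
# ---------------------------------------------------------------------------

METADATA_COLUMNS = ["sample", "population", "region", "focal_genotype"]


def read_metadata(path) -> pd.DataFrame:
    """Read the sample metadata TSV (sample, population, region, focal_genotype)."""
    try:
        meta = pd.read_csv(path, sep="\t", dtype=str)
    except OSError as exc:
        raise InputError(f"cannot read metadata table {path}: {exc}") from exc
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise ConfigurationError(f"metadata table lacks columns: {missing}")
    bad = set(meta["focal_genotype"].fillna("unknown")) - set(FOCAL_STATES)
    if bad:
        raise ConfigurationError(f"unrecognised focal_genotype values: {sorted(bad)}")
    return meta


def read_vcf(path, metadata=None):
    """Read a VCF into a :class:`VariantMatrix` (and :class:`DepthMatrix` if DP present).

    Only biallelic SNP rows are retained; multi-allelic rows and indels are
    dropped with a logged count.  Genotypes are mapped to alternate-allele
    dosage; missing calls to ``MISSING``.

    Parameters
    ----------
    path : str
        VCF (optionally bgzipped) file path.
    metadata : DataFrame or str, optional
        Sample metadata table (or path to its TSV) covering all VCF samples.

    Returns
    -------
    (VariantMatrix, DepthMatrix or None)
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare exceptions on bad files
        raise InputError(f"cannot read VCF {path}: {exc}") from exc

    samples = list(vcf.samples)
    if metadata is not None:
        if not isinstance(metadata, pd.DataFrame):
            metadata = read_metadata(metadata)
        known = set(metadata["sample"])
        unknown = [s for s in samples if s not in known]
        if unknown:
            raise ConfigurationError(f"metadata lacks VCF samples: {unknown}")

    chroms, poss, rows, depth_rows = [], [], [], []
    n_dropped = 0
    has_depth = True
    for v in vcf:
        if len(v.ALT) != 1 or not v.is_snp:
            n_dropped += 1
            continue
        gts = np.array(v.genotypes, dtype=object)
        dosage = np.empty(len(samples), dtype=np.int8)
        for i, g in enumerate(v.genotypes):
            a, b = g[0], g[1]
            if a < 0 or b < 0:
                dosage[i] = MISSING
            else:
                dosage[i] = int(a > 0) + int(b > 0)
        chroms.append(v.CHROM)
        poss.append(v.POS)
        rows.append(dosage)
        try:
            dp = v.format("DP")
        except KeyError:
            dp = None
        if dp is None:
            has_depth = False
        elif has_depth:
            depth_rows.append(np.where(dp[:, 0] < 0, 0, dp[:, 0]).astype(np.int64))
    if n_dropped:
        logger.info("read_vcf: dropped %d non-biallelic-SNP rows", n_dropped)
    if not rows:
        raise InputError(f"{path}: no biallelic SNP records")

    chrom = np.array(chroms, dtype=object)
    pos = np.array(poss, dtype=np.int64)
    geno = np.vstack(rows).T  # samples x snps

    pops, regions, focal = {}, {}, {}
    if metadata is not None:
        m = metadata.set_index("sample")
        pops = {s: m.at[s, "population"] for s in samples}
        regions = {s: m.at[s, "region"] for s in samples}
        focal = {s: m.at[s, "focal_genotype"] for s in samples}

    vm = VariantMatrix(samples, chrom, pos, geno, pops, regions, focal)
    vm.n_dropped_multiallelic = n_dropped

    dm = None
    if has_depth and depth_rows:
        dm = DepthMatrix(samples, chrom, pos, np.vstack(depth_rows).T, pops, regions)
    return vm, dm


_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(vm: VariantMatrix, path, depth: DepthMatrix | None = None) -> None:
    """Write a minimal VCF 4.2 with GT (and DP when a depth matrix is given).

    ``read_vcf(write_vcf(vm))`` is the identity on genotypes.  REF/ALT are
    written as placeholder A/T alleles: the pipeline operates on dosages only.
    """
    if depth is not None and not np.array_equal(depth.pos, vm.pos):
        raise ConfigurationError("depth matrix coordinate frame differs from variant matrix")
    fmt = "GT:DP" if depth is not None else "GT"
    try:
        fh = open(path, "w")
    except OSError as exc:
        raise InputError(f"cannot write VCF {path}: {exc}") from exc
    with fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if depth is not None:
            fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        for c in pd.unique(vm.chrom):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(vm.samples) + "\n")
        for j in range(vm.n_snps):
            cells = []
            for i in range(vm.n_samples):
                gt = _GT_STRINGS[int(vm.genotypes[i, j])]
                if depth is not None:
                    gt = f"{gt}:{int(depth.depth[i, j])}"
                cells.append(gt)
            fh.write(
                f"{vm.chrom[j]}\t{vm.pos[j]}\t.\tA\tT\t.\tPASS\t.\t{fmt}\t"
                + "\t".join(cells)
                + "\n"
            )


# ---------------------------------------------------------------------------
# filters, imputation, allele frequency
# ---------------------------------------------------------------------------


def filter_variants(
    vm: VariantMatrix,
    min_pop_call: float = 0.5,
    min_total_call: float = 0.9,
    min_mac: int = 3,
) -> VariantMatrix:
    """Apply the study's SNP retention rules.

    A SNP is retained when it is called in at least ``min_pop_call`` of the
    individuals of *every* population, in at least ``min_total_call`` of all
    individuals, and its minor allele count is at least ``min_mac``.  The
    per-population rule is evaluated literally on the metadata populations
    column, including very small populations.
    """
    if not (0 <= min_pop_call <= 1 and 0 <= min_total_call <= 1):
        raise ConfigurationError("call-rate thresholds must lie in [0, 1]")
    if min_mac < 0:
        raise ConfigurationError("min_mac must be non-negative")
    if not vm.populations:
        raise ConfigurationError("filter_variants requires population labels")

    called = vm.called_mask()
    keep = called.mean(axis=0) >= min_total_call
    n_total = int((~keep).sum())

    pop_labels = np.array([vm.populations[s] for s in vm.samples], dtype=object)
    keep_pop = np.ones(vm.n_snps, dtype=bool)
    for pop in pd.unique(pop_labels):
        rows = pop_labels == pop
        keep_pop &= called[rows].mean(axis=0) >= min_pop_call
    n_pop = int((keep & ~keep_pop).sum())
    keep &= keep_pop

    g = vm.genotypes
    alt = np.where(called, g, 0).sum(axis=0)
    n_alleles = 2 * called.sum(axis=0)
    mac = np.minimum(alt, n_alleles - alt)
    keep_mac = mac >= min_mac
    n_mac = int((keep & ~keep_mac).sum())
    keep &= keep_mac

    logger.info(
        "filter_variants: removed %d (total call), %d (pop call), %d (MAC); kept %d/%d",
        n_total, n_pop, n_mac, int(keep.sum()), vm.n_snps,
    )
    if not keep.any():
        raise InputError("no SNPs survive filtering")
    out = vm.take_snps(keep)
    out.removal_counts = {"total_call": n_total, "pop_call": n_pop, "mac": n_mac}
    return out


def impute_missing(vm: VariantMatrix) -> VariantMatrix:
    """Fill missing calls with the per-SNP modal genotype (ties toward lower dosage).

    A deliberately simple, declared rule: haplotype-aware imputation is out of
    scope, and the sweep statistics downstream run on un-imputed data anyway.
    """
    g = vm.genotypes.copy()
    miss = g == MISSING
    if not miss.any():
        return replace(vm, genotypes=g)
    fully = miss.all(axis=0)
    if fully.any():
        j = int(np.flatnonzero(fully)[0])
        raise InputError(f"SNP {vm.chrom[j]}:{vm.pos[j]} is missing in all samples")
    counts = np.stack([(g == k).sum(axis=0) for k in (0, 1, 2)])  # 3 x n_snps
    modal = counts.argmax(axis=0)  # argmax takes the first max => ties to lower dosage
    g[miss] = np.broadcast_to(modal, g.shape).astype(np.int8)[miss]
    return replace(vm, genotypes=g)


def allele_frequency(vm: VariantMatrix, snp: int, subset=None) -> float:
    """Alternate-allele frequency at one SNP over a sample subset.

    Missing calls are excluded from both numerator and denominator.  Raises
    ``InputError`` when every call in the subset is missing.
    """
    if subset is None:
        rows = np.arange(vm.n_samples)
    else:
        rows = vm.sample_indices(subset)
        if len(rows) == 0:
            raise ConfigurationError("sample subset is empty")
    g = vm.genotypes[rows, snp]
    called = g != MISSING
    n_alleles = 2 * int(called.sum())
    if n_alleles == 0:
        raise InputError(f"all calls missing at SNP index {snp} in subset")
    return float(g[called].sum()) / n_alleles
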
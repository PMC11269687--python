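"""End-to-end study pipelines on simulated data.

Each function here wires the library stages together under fixed study
conditions — the sample sizes, marker densities and sweep parameters the
synthetic generator treats as its defaults — and returns plain dictionaries
of summary numbers.  They are what the verification suite and the
reproduction script run.

The two-background experiment mirrors the core analysis: simulate two
partial sweep backgrounds segregating at one locus in two populations,
scan for SNPs structured by carrier state, screen near-locus outliers for
shared homozygous haplotypes, and contrast carriers against wild types
with Delta-statistics and between-background FST.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .assocscan import lfmm_scan, outlier_threshold, select_outliers
from .genodata import IntervalSet, VariantMatrix
from .linknet import linkage_network
from .popstats import _masked_r2_matrix, moving_average
from .sweeps import delta_stats, haplotype_screen, pairwise_background_fst
from .synthdata import SimulationConfig, SweepSpec, simulate_neutral, simulate_study

#: focal locus position used by the simulated experiments (mid-chromosome)
LOCUS_POS = 10_000_000
#: screen size mirroring the study's multilocus haplotype screens
N_SCREEN_SNPS = 32
#: smoothing span (occupied 5-kb bins) for locus-scale Delta profiles
DELTA_MA_SPAN = 20


def two_background_config(seed: int) -> SimulationConfig:
    """Two partial sweep backgrounds (30% / 20% homozygous carriers) at one locus."""
    return SimulationConfig(
        seed=seed,
        sweeps=[
            SweepSpec("chr1", LOCUS_POS, "bgA", carrier_fraction=0.3),
            SweepSpec("chr1", LOCUS_POS, "bgB", carrier_fraction=0.2),
        ],
    )


def _carrier_focal(vm: VariantMatrix, hom_samples) -> np.ndarray:
    hom = set(hom_samples)
    return np.array([2.0 if s in hom else 0.0 for s in vm.samples])


def screen_snp_set(vm, scan_result, locus_chrom="chr1", locus_pos=LOCUS_POS,
                   near_bp=1e6, n_screen=N_SCREEN_SNPS):
    """Near-locus outlier SNPs, strongest first, capped at ``n_screen``."""
    sel = select_outliers(
        scan_result,
        threshold=outlier_threshold(vm.n_snps),
        locus_window=IntervalSet([(locus_chrom, locus_pos - 1, locus_pos, "locus")]),
        near_bp=near_bp,
    )
    part = sel.partitions["scan_a"]
    near = np.concatenate([part["inside"], part["near"]])
    padj = scan_result.records["p_adj"].to_numpy()[near]
    return near[np.argsort(padj, kind="stable")[:n_screen]], sel


def sweep_recovery_experiment(seed: int, K: int = 2) -> dict:
    """Scan + screen one simulated two-background dataset.

    Returns ground-truth recovery of homozygous carriers (strict or relaxed
    members of the majority-matching screen group) and the number of
    wild-type individuals contaminating strict membership.
    """
    vm, _, carriers = simulate_study(two_background_config(seed))
    hom = carriers[carriers["zygosity"] == "hom"]
    truth = hom.set_index("sample")["background"]

    scan = lfmm_scan(vm, _carrier_focal(vm, hom["sample"]), K=K)
    screen, _ = screen_snp_set(vm, scan)
    backgrounds = haplotype_screen(vm, screen, max_deviation=1)

    recovered = 0
    contamination = 0
    for bg in backgrounds:
        labels = [truth.get(s, "WT") for s in bg.strict_members]
        majority = max(set(labels), key=labels.count)
        if majority == "WT":
            continue
        contamination += sum(1 for s in bg.strict_members if truth.get(s, "WT") == "WT")
        recovered += sum(1 for s in bg.members if truth.get(s, "WT") == majority)
    return {
        "n_hom_carriers": int(len(hom)),
        "n_recovered": int(recovered),
        "recovery": recovered / len(hom),
        "strict_contamination": int(contamination),
        "n_screen_snps": int(len(screen)),
        "n_outliers": int(np.sum(scan.records["p_adj"] < outlier_threshold(vm.n_snps))),
    }


def delta_localization_experiment(seed: int) -> dict:
    """Locate the smoothed Delta-D / Delta-pi minima, Delta-LD maximum and
    the between-background FST maximum on one simulated dataset.

    Distances are from window start to the true locus, in bp.
    """
    vm, _, carriers = simulate_study(two_background_config(seed))
    hom = carriers[carriers["zygosity"] == "hom"]
    bg_a = hom.loc[hom["background"] == "bgA", "sample"].tolist()
    bg_b = hom.loc[hom["background"] == "bgB", "sample"].tolist()
    wildtype = [s for s in vm.samples if s not in set(hom["sample"])]

    profile = delta_stats(vm, bg_a, wildtype, chrom="chr1", ma_span=DELTA_MA_SPAN)

    def extremum(track, smooth, minimum=True):
        rec = track.records
        if smooth:
            rec = moving_average(track, DELTA_MA_SPAN).records
        rec = rec.dropna(subset=["value"])
        row = rec.loc[rec["value"].idxmin() if minimum else rec["value"].idxmax()]
        return abs(float(row["win_start"]) - LOCUS_POS)

    chr1 = vm.take_snps(vm.chrom == "chr1")
    _, _, maxima = pairwise_background_fst(chr1, bg_a, bg_b)
    return {
        "delta_d_min_dist": extremum(profile.delta_d, smooth=True),
        "delta_pi_min_dist": extremum(profile.delta_pi, smooth=True),
        "delta_ld_max_dist": extremum(profile.delta_ld, smooth=False, minimum=False),
        "fst_max_dist": abs(float(maxima["genome"]["win_start"]) - LOCUS_POS),
    }


def null_fdr_experiment(seeds, K: int = 2, n_snps: int = 5000) -> dict:
    """Realized FDR at the 1/n-SNP threshold for focal-independent scans."""
    n_false = 0
    n_runs_with_discovery = 0
    for seed in seeds:
        vm = simulate_neutral(SimulationConfig(seed=seed, n_snps=n_snps))
        rng = np.random.default_rng(10_000 + seed)
        focal = rng.choice([0.0, 1.0, 2.0], size=vm.n_samples, p=[0.5, 0.3, 0.2])
        scan = lfmm_scan(vm, focal, K=K)
        padj = scan.records["p_adj"].to_numpy()
        R = int(np.nansum(padj < outlier_threshold(vm.n_snps)))
        n_false += R
        n_runs_with_discovery += int(R > 0)
    # every discovery under the null is false: realized FDR = mean V/max(R,1)
    return {
        "realized_fdr": n_runs_with_discovery / len(list(seeds)),
        "total_false_discoveries": n_false,
    }


def planted_linknet_config(seed: int) -> SimulationConfig:
    """One ~100-member background on a 120-Mb chromosome pair.

    The small always-swept core leaves partial tract coverage (hence LD
    structure) in the locus neighbourhood, and the subset size matches the
    largest background cohorts the network analysis is designed for.
    """
    return SimulationConfig(
        seed=seed,
        n_chrom=2,
        chrom_length=120_000_000,
        n_per_pop=165,
        sweeps=[
            SweepSpec(
                "chr1", LOCUS_POS, "bgA", carrier_fraction=0.3,
                core_halfwidth=2e5, mean_tract=2e6,
            )
        ],
    )


def planted_linknet_experiment(seed: int, plant_pos_min: float = 7e7) -> dict:
    """Plant a distant copy of the best-tagging locus SNP and score the network.

    The planted column duplicates the near-locus SNP with the most strong-LD
    partners among carriers (the dosage pattern that tags the swept tract) at
    the first SNP beyond ``plant_pos_min`` on the locus chromosome — over
    60 Mb from the locus, inside the far candidate zone.
    """
    vm, _, carriers = simulate_study(planted_linknet_config(seed))
    members = carriers.loc[carriers["zygosity"] == "hom", "sample"].tolist()
    rows = vm.sample_indices(members)
    near = np.flatnonzero((vm.chrom == "chr1") & (np.abs(vm.pos - LOCUS_POS) < 1e6))
    g_near = vm.genotypes[rows][:, near]
    r2, valid = _masked_r2_matrix(g_near, g_near)
    partners = ((r2 > 0.6) & valid).sum(axis=1)
    src = near[int(np.argmax(partners))]
    far = int(np.flatnonzero((vm.chrom == "chr1") & (vm.pos > plant_pos_min))[0])
    vm.genotypes[:, far] = vm.genotypes[:, src]

    hist = linkage_network(vm, members, ("chr1", LOCUS_POS - 1, LOCUS_POS, "locus"))
    planted_bin = int((vm.pos[far] - 1) // 500_000 * 500_000)
    top = hist.bins.sort_values(
        ["count", "chrom", "bin_start"], ascending=[False, True, True]
    ).iloc[0]
    planted_count = int(
        hist.bins.loc[
            (hist.bins["chrom"] == "chr1") & (hist.bins["bin_start"] == planted_bin),
            "count",
        ].sum()
    )
    return {
        "argmax_is_planted": bool(
            top["chrom"] == "chr1" and int(top["bin_start"]) == planted_bin
        ),
        "planted_count": planted_count,
        "total_interactions": hist.total_interactions,
        "ledger_total": int(hist.snp_ledger["count"].sum()),
    }


def cnv_experiment(seed: int, copy_number: float = 5.0, n_samples: int = 30) -> dict:
    """Depth-ratio recovery for a region at elevated copy number.

    2,000 coding sites at 100-bp spacing against diploid flanks; expectation
    for copy 5 vs 2 is a ratio of 2.5.
    """
    from .cnv import depth_ratio, flank_consistency
    from .genodata import DepthMatrix, IntervalSet
    from .synthdata import CnvSpec, simulate_depth

    region = ("chr1", 60_000_000, 60_200_000, "target_genes")
    cfg = SimulationConfig(
        seed=seed, n_chrom=1, chrom_length=120_000_000, n_pops=1,
        n_per_pop=n_samples, cnv=CnvSpec(region=region, copy_number=copy_number),
    )
    samples = [f"pop1_ind{i + 1}" for i in range(n_samples)]
    pops = {s: "pop1" for s in samples}
    pos_coding = np.arange(region[1], region[2], 100, dtype=np.int64) + 1
    pos_flank = np.concatenate(
        [
            np.arange(region[1] - 10_000_000, region[1], 5000, dtype=np.int64),
            np.arange(region[2], region[2] + 10_000_000, 5000, dtype=np.int64),
        ]
    ) + 1
    pos = np.sort(np.concatenate([pos_coding, pos_flank]))
    chrom = np.full(len(pos), "chr1", dtype=object)
    dm = simulate_depth(cfg, samples, pops, chrom, pos, seed=seed + 40_000)
    result = depth_ratio(dm, IntervalSet([region]))
    included = result.included()
    return {
        "mean_ratio": float(included["ratio"].mean()),
        "n_included": int(len(included)),
        "flank_r2": flank_consistency(result),
    }


def admixture_experiments(seed: int) -> dict:
    """f3 and PCA-projection checks on simulated admixture.

    alpha = 0.5 with 20 generations of post-admixture drift at N = 200 for
    the f3 test (10,000 SNPs, source drift F = 0.2); an unadmixed third
    population for the positive control; alpha = 0.25 for the projection.
    """
    from .admixture import f3_test, pca_projection
    from .synthdata import simulate_admixture, simulate_neutral

    vm = simulate_neutral(SimulationConfig(seed=seed, n_snps=10_000, drift_F=0.2))
    vm_adm = simulate_admixture(
        vm, "pop1", "pop2", alpha=0.5, n=20, seed=seed + 500,
        drift_generations=20, drift_pop_size=200,
    )
    f3_adm = f3_test(vm_adm, "admixed", "pop1", "pop2")

    vm3 = simulate_neutral(
        SimulationConfig(seed=seed + 1, n_snps=10_000, n_pops=3, drift_F=0.2)
    )
    f3_null = f3_test(vm3, "pop3", "pop1", "pop2")

    vm_q = simulate_admixture(
        simulate_neutral(SimulationConfig(seed=seed + 2, n_snps=5000, drift_F=0.2)),
        "pop1", "pop2", alpha=0.25, n=20, seed=seed + 600,
    )
    proj = pca_projection(vm_q, "pop1", "pop2", vm_q.pop_members("admixed"))
    alpha_hat = float(
        proj.coordinates.loc[proj.coordinates["role"] == "query", "alpha_hat"].mean()
    )
    return {
        "f3_admixed": f3_adm.f3,
        "f3_admixed_z": f3_adm.z,
        "f3_unadmixed": f3_null.f3,
        "alpha_hat_mean": alpha_hat,
    }
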
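"""Background identification (PCA clusters, haplotype screen) and contrasts."""

import numpy as np
import pandas as pd
import pytest

import sweepscape as ss
from sweepscape import ConfigurationError

from conftest import make_vm


# ---------------------------------------------------------------------------
# haplotype_screen
# ---------------------------------------------------------------------------


def _screen_vm():
    # screen SNPs at indices 0..3; haplotypes: A = 0101, B = 1010
    rows = [
        [0, 2, 0, 2, 1],   # strict A
        [0, 2, 0, 2, 0],   # strict A (non-screen SNP differs: irrelevant)
        [2, 0, 2, 0, 1],   # strict B
        [0, 2, 1, 2, 1],   # one het site -> relaxed A
        [2, 0, -1, 0, 1],  # one missing -> relaxed B
        [0, -1, -1, 2, 1],  # two deviations -> unassigned
        [2, 2, 2, 2, 1],   # all hom but matches neither -> own background
    ]
    return make_vm(rows)


def test_haplotype_screen_strict_relaxed_unassigned():
    vm = _screen_vm()
    bgs = ss.haplotype_screen(vm, [0, 1, 2, 3], max_deviation=1)
    by_hap = {b.haplotype: b for b in bgs}
    a = by_hap["0101"]
    b = by_hap["1010"]
    assert set(a.strict_members) == {"s1", "s2"}
    assert a.relaxed_members == ["s4"]
    assert b.strict_members == ["s3"]
    assert b.relaxed_members == ["s5"]
    assigned = {m for bg in bgs for m in bg.members}
    assert "s6" not in assigned  # two deviations
    assert "s7" in {m for bg in bgs for m in bg.strict_members}  # own haplotype


def test_haplotype_screen_ambiguous_relaxed_left_unassigned():
    rows = [
        [0, 2, 2],  # strict 011
        [2, 2, 2],  # strict 111
        [1, 2, 2],  # het at SNP 0: consistent with both -> unassigned
    ]
    vm = make_vm(rows)
    bgs = ss.haplotype_screen(vm, [0, 1, 2])
    assert all("s3" not in bg.members for bg in bgs)


def test_haplotype_screen_invariances():
    vm = _screen_vm()
    base = {
        b.haplotype: set(b.strict_members)
        for b in ss.haplotype_screen(vm, [0, 1, 2, 3])
    }
    # sample order permutation
    order = [3, 0, 6, 2, 5, 1, 4]
    vm_perm = ss.VariantMatrix(
        [vm.samples[i] for i in order],
        vm.chrom, vm.pos, vm.genotypes[order],
        {vm.samples[i]: "pop1" for i in order},
    )
    perm = {
        b.haplotype: set(b.strict_members)
        for b in ss.haplotype_screen(vm_perm, [0, 1, 2, 3])
    }
    assert base == perm
    # adding non-screen SNPs
    extra = np.hstack([vm.genotypes, np.ones((7, 3), dtype=np.int8)])
    vm_extra = make_vm(extra)
    more = {
        b.haplotype: set(b.strict_members)
        for b in ss.haplotype_screen(vm_extra, [0, 1, 2, 3])
    }
    assert base == more
    with pytest.raises(ConfigurationError):
        ss.haplotype_screen(vm, [])


# ---------------------------------------------------------------------------
# pca_cluster_homozygotes
# ---------------------------------------------------------------------------


def test_pca_clusters_recover_two_simulated_backgrounds():
    from sweepscape.pipeline import two_background_config

    for seed in (1, 5, 9):
        vm, _, carriers = ss.simulate_study(two_background_config(seed))
        hom = carriers[carriers["zygosity"] == "hom"]
        truth = hom.set_index("sample")["background"]
        core = np.flatnonzero(
            (vm.chrom == "chr1") & (np.abs(vm.pos - 10_000_000) < 9e5)
        )
        out = ss.pca_cluster_homozygotes(vm, core, k_clusters=2, seed=seed)
        table = out.assign(truth=out["sample"].map(truth))
        purity = (
            table.groupby("cluster")["truth"]
            .agg(lambda x: x.value_counts().iloc[0] / len(x))
            .min()
        )
        assert purity == 1.0


def test_pca_cluster_degenerate_and_single_cluster():
    rows = [[0, 2, 0]] * 5
    vm = make_vm(rows, focal={f"s{i + 1}": "hom-alt" for i in range(5)})
    out = ss.pca_cluster_homozygotes(vm, [0, 1, 2], k_clusters=1, seed=0)
    assert (out["cluster"] == 0).all()
    assert np.allclose(out[["pc1", "pc2"]], 0.0)
    with pytest.raises(ConfigurationError):
        ss.pca_cluster_homozygotes(vm, [0, 1, 2], k_clusters=6, seed=0)


# ---------------------------------------------------------------------------
# delta_stats
# ---------------------------------------------------------------------------


def _twin_cohort_vm(rng):
    """Two disjoint cohorts with identical genotype rows."""
    block = rng.integers(0, 3, size=(6, 30)).astype(np.int8)
    g = np.vstack([block, block])
    samples = [f"a{i}" for i in range(6)] + [f"b{i}" for i in range(6)]
    pos = np.sort(rng.choice(np.arange(1, 200_000), 30, replace=False))
    return ss.VariantMatrix(
        samples, np.full(30, "chr1", dtype=object), pos, g,
        {s: "pop1" for s in samples},
    ), samples[:6], samples[6:]


def test_delta_zero_for_identical_cohorts(rng):
    vm, a, b = _twin_cohort_vm(rng)
    prof = ss.delta_stats(vm, a, b, ma_span=1)
    for track in (prof.delta_d, prof.delta_pi, prof.delta_ld):
        defined = track.records["value"].dropna()
        np.testing.assert_allclose(defined, 0.0, atol=1e-12)


def test_delta_antisymmetry(rng):
    vm = ss.simulate_neutral(ss.SimulationConfig(seed=21, n_snps=600))
    a = vm.samples[:20]
    b = vm.samples[50:70]
    fwd = ss.delta_stats(vm, a, b, ma_span=5)
    rev = ss.delta_stats(vm, b, a, ma_span=5)
    for t1, t2 in (
        (fwd.delta_d, rev.delta_d),
        (fwd.delta_pi, rev.delta_pi),
        (fwd.delta_ld, rev.delta_ld),
    ):
        v1 = t1.records["value"].to_numpy()
        v2 = t2.records["value"].to_numpy()
        np.testing.assert_allclose(v1, -v2, atol=1e-12, equal_nan=True)


def test_delta_rejects_overlap_and_small_cohorts():
    vm = make_vm(np.zeros((8, 4), dtype=np.int8))
    with pytest.raises(ConfigurationError):
        ss.delta_stats(vm, vm.samples[:4], vm.samples[3:])
    with pytest.raises(ConfigurationError):
        ss.delta_stats(vm, vm.samples[:2], vm.samples[4:])


def test_simulated_sweep_delta_minima_localise():
    from sweepscape.pipeline import delta_localization_experiment

    res = delta_localization_experiment(seed=3)
    assert res["delta_d_min_dist"] < 1e6
    assert res["delta_pi_min_dist"] < 1e6
    assert res["delta_ld_max_dist"] < 2e6
    assert res["fst_max_dist"] < 1e6


def test_neutral_split_shows_no_localised_extreme():
    """Random halves of a neutral population: the locus bin is not an
    outlier of the smoothed Delta profile."""
    ranks = []
    for seed in (31, 32, 33, 34, 35):
        vm = ss.simulate_neutral(ss.SimulationConfig(seed=seed))
        rng = np.random.default_rng(seed)
        order = rng.permutation(vm.samples)
        prof = ss.delta_stats(
            vm, list(order[:30]), list(order[30:60]), chrom="chr1", ma_span=20
        )
        rec = (
            ss.moving_average(prof.delta_d, 20)
            .records.dropna(subset=["value"])
            .reset_index(drop=True)
        )
        # rank of the window nearest the (meaningless) locus position
        target = (rec["win_start"] - 10_000_000).abs().idxmin()
        ranks.append(sps_rank(rec["value"], target))
    assert np.mean([r < 0.05 for r in ranks]) <= 0.2


def sps_rank(values, idx):
    v = values.to_numpy()
    return float((v <= v[idx]).mean())


# ---------------------------------------------------------------------------
# pairwise_background_fst
# ---------------------------------------------------------------------------


def test_fixed_difference_is_sole_highlight():
    g = np.array(
        [[0, 1], [0, 1], [0, 1], [2, 1], [2, 1], [2, 1]], dtype=np.int8
    )
    vm = make_vm(g, pos=[1000, 2000])
    track, highlighted, maxima = ss.pairwise_background_fst(
        vm, vm.samples[:3], vm.samples[3:]
    )
    assert list(highlighted["pos"]) == [1000]
    # the 5-kb window pools both SNPs: sum(a)/sum(a+b+c) over a fixed
    # difference and an invariant site
    assert maxima["genome"]["value"] > 0.25
    per_snp, _ = ss.wc_fst(vm, vm.samples[:3], vm.samples[3:])
    assert per_snp["fst"][0] == pytest.approx(1.0)


def test_same_background_split_rarely_exceeds_highlight():
    from sweepscape.pipeline import two_background_config

    rates = []
    for seed in (1, 2):
        vm, _, carriers = ss.simulate_study(two_background_config(seed))
        hom = carriers[carriers["zygosity"] == "hom"]
        bg_a = hom.loc[hom["background"] == "bgA", "sample"].tolist()
        rng = np.random.default_rng(seed)
        order = rng.permutation(bg_a)
        half = len(order) // 2
        track, _, _ = ss.pairwise_background_fst(
            vm.take_snps(vm.chrom == "chr1"), list(order[:half]), list(order[half:])
        )
        vals = track.records["value"].dropna()
        rates.append(np.mean(vals > 0.25))
    assert np.mean(rates) <= 0.01
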
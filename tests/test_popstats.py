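"""Windowed statistics vs independent brute-force oracles.

The oracles enumerate allele pairs / transcribe the textbook formulas
directly and stay independent of the vectorised implementations they
check.
"""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

import sweepscape as ss
from sweepscape import ConfigurationError
from sweepscape.popstats import tajima_constants

from conftest import make_vm, random_vm


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------


def alleles_at_site(genotypes_column):
    """Expand called diploid dosages into a list of 0/1 alleles."""
    out = []
    for g in genotypes_column:
        if g >= 0:
            out.extend([1] * g + [0] * (2 - g))
    return out


def oracle_site_pi(genotypes_column):
    """Fraction of mismatching allele pairs among all C(n,2) pairs.

    Undefined (None) when fewer than two samples are called at the site.
    """
    if sum(1 for g in genotypes_column if g >= 0) < 2:
        return None
    alleles = alleles_at_site(genotypes_column)
    pairs = list(itertools.combinations(alleles, 2))
    return sum(a != b for a, b in pairs) / len(pairs)


def oracle_tajimas_d(genotype_matrix):
    """Tajima's D for one bin by direct enumeration.

    S counts segregating sites; k-hat sums per-site mismatching-pair
    fractions; n is the modal per-site called-allele count.
    """
    cols = [genotype_matrix[:, j] for j in range(genotype_matrix.shape[1])]
    usable = []
    for c in cols:
        al = alleles_at_site(c)
        if len(al) >= 2:
            usable.append(al)
    if not usable:
        return None
    S = sum(1 for al in usable if 0 < sum(al) < len(al))
    if S == 0:
        return None
    khat = 0.0
    for al in usable:
        if 0 < sum(al) < len(al):
            pairs = list(itertools.combinations(al, 2))
            khat += sum(a != b for a, b in pairs) / len(pairs)
    counts = sorted(len(al) for al in usable)
    from collections import Counter

    freq = Counter(counts)
    top = max(freq.values())
    n = min(k for k, v in freq.items() if v == top)
    if n < 2:
        return None
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * S + e2 * S * (S - 1)
    if var <= 0:
        return None
    return (khat - S / a1) / np.sqrt(var)


def oracle_r2(col_i, col_j):
    """Squared Pearson correlation over pairwise-complete samples."""
    mask = (col_i >= 0) & (col_j >= 0)
    x, y = col_i[mask].astype(float), col_j[mask].astype(float)
    if len(x) < 2 or np.var(x) == 0 or np.var(y) == 0:
        return None
    return sps.pearsonr(x, y).statistic ** 2


def oracle_wc_theta(col_a, col_b):
    """Weir & Cockerham (1984) theta for one SNP, two groups, transcribed
    component by component."""
    def summarize(col):
        called = col[col >= 0]
        n = len(called)
        if n == 0:
            return None
        p = called.sum() / (2 * n)
        h = np.mean(called == 1)
        return n, p, h

    sa, sb = summarize(col_a), summarize(col_b)
    if sa is None or sb is None:
        return None
    (n1, p1, h1), (n2, p2, h2) = sa, sb
    if n1 + n2 <= 2:
        return None
    r = 2
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (1 / (nbar - 1)) * (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - ((r - 1) / r) * s2 - ((2 * nbar - 1) / (4 * nbar)) * hbar
    )
    c = hbar / 2
    denom = a + b + c
    if denom == 0:
        return None
    return a / denom


# ---------------------------------------------------------------------------
# worked examples
# ---------------------------------------------------------------------------


def test_site_pi_worked_example():
    # genotypes {0,1,1,2}: 8 alleles, p = 0.5 -> 16 mismatching pairs / 28
    vm = make_vm([[0], [1], [1], [2]])
    out = ss.site_pi(vm)
    assert out["pi"][0] == pytest.approx(16 / 28)
    assert out["pi"][0] == pytest.approx(oracle_site_pi(vm.genotypes[:, 0]))


def test_site_pi_monomorphic_and_skipped_sites():
    vm = make_vm([[0, 2, -1], [0, 2, -1], [0, 2, 1]])
    out = ss.site_pi(vm)
    assert out["pi"][0] == 0.0
    assert out["pi"][1] == 0.0
    assert np.isnan(out["pi"][2])  # one called sample -> skipped
    assert out.attrs["n_skipped"] == 1


def test_tajimas_d_zero_segregating_bin_undefined():
    vm = make_vm([[0, 0], [0, 0], [0, 0], [0, 0]], pos=[100, 200])
    track = ss.tajimas_d(vm)
    assert len(track.records) == 1
    assert np.isnan(track.records["value"][0])


def test_tajimas_d_six_diploids_single_bin_matches_oracle():
    g = np.array(
        [
            [0, 1, 0, 2],
            [1, 0, 0, 2],
            [0, 0, 1, 1],
            [2, 1, 0, 2],
            [0, 0, 0, 2],
            [1, 2, 0, 2],
        ],
        dtype=np.int8,
    )
    vm = make_vm(g, pos=[500, 1500, 2500, 4500])
    track = ss.tajimas_d(vm, bin_size=5000)
    expected = oracle_tajimas_d(g)
    assert track.records["value"][0] == pytest.approx(expected, abs=1e-12)


def test_genotype_r2_examples():
    # identical dosage vectors 10 kb apart -> r2 = 1; 300 bp pair excluded
    g = np.array([[0, 0, 0], [1, 1, 0], [2, 2, 2], [0, 0, 2]], dtype=np.int8)
    vm = make_vm(g, pos=[1000, 11000, 11300])
    ld = ss.genotype_r2(vm)
    pairs = {(r.pos_i, r.pos_j): r.r2 for r in ld.records.itertuples()}
    assert pairs[(1000, 11000)] == pytest.approx(1.0)
    assert (11000, 11300) not in pairs  # 300 bp < 500 bp minimum
    assert pairs[(1000, 11300)] == pytest.approx(
        oracle_r2(g[:, 0], g[:, 2]), abs=1e-12
    )


def test_genotype_r2_textbook_vectors():
    g = np.array([[0, 0], [1, 0], [2, 2], [0, 2]], dtype=np.int8)
    vm = make_vm(g, pos=[1000, 2000])
    ld = ss.genotype_r2(vm)
    assert ld.records["r2"][0] == pytest.approx(oracle_r2(g[:, 0], g[:, 1]), abs=1e-12)


def test_wc_fst_fixed_difference_is_one():
    g = np.vstack([np.zeros((10, 3)), np.full((10, 3), 2)]).astype(np.int8)
    vm = make_vm(g)
    a = vm.samples[:10]
    b = vm.samples[10:]
    per_snp, track = ss.wc_fst(vm, a, b)
    assert np.allclose(per_snp["fst"], 1.0)
    assert np.allclose(track.records["value"].dropna(), 1.0)


def test_wc_fst_identical_groups_near_zero():
    block = np.array([[0], [1], [1], [2], [0]], dtype=np.int8)
    g = np.vstack([block, block])
    vm = make_vm(g)
    per_snp, track = ss.wc_fst(vm, vm.samples[:5], vm.samples[5:])
    assert per_snp["fst"][0] <= 0  # estimator may be slightly negative
    assert abs(track.records["value"].dropna().iloc[0]) < 0.15


def test_wc_fst_overlapping_groups_rejected():
    vm = make_vm([[0], [1], [2], [0]])
    with pytest.raises(ConfigurationError):
        ss.wc_fst(vm, vm.samples[:3], vm.samples[2:])


# ---------------------------------------------------------------------------
# 200 random instances per statistic vs oracle
# ---------------------------------------------------------------------------


def test_statistics_match_oracles_on_random_instances(rng):
    n_checked = {"pi": 0, "d": 0, "r2": 0, "fst": 0}
    for _ in range(200):
        n_samples = int(rng.integers(4, 7))
        n_snps = int(rng.integers(2, 11))
        vm = random_vm(rng, n_samples, n_snps, missing_rate=0.15)

        out = ss.site_pi(vm)
        for j in range(n_snps):
            exp = oracle_site_pi(vm.genotypes[:, j])
            if exp is None:
                assert np.isnan(out["pi"][j])
            else:
                assert out["pi"][j] == pytest.approx(exp, abs=1e-10)
                n_checked["pi"] += 1

        # one bin spanning all SNPs
        track = ss.tajimas_d(vm, bin_size=20_000_000)
        exp_d = oracle_tajimas_d(vm.genotypes)
        got = track.records["value"][0]
        if exp_d is None:
            assert np.isnan(got)
        else:
            assert got == pytest.approx(exp_d, abs=1e-10)
            n_checked["d"] += 1

        ld = ss.genotype_r2(vm, min_bp=0, max_bp=None)
        pairs = {(r.pos_i, r.pos_j): r.r2 for r in ld.records.itertuples()}
        for i, j in itertools.combinations(range(n_snps), 2):
            exp = oracle_r2(vm.genotypes[:, i], vm.genotypes[:, j])
            key = (int(vm.pos[i]), int(vm.pos[j]))
            if exp is None:
                assert key not in pairs
            else:
                assert pairs[key] == pytest.approx(exp, abs=1e-10)
                n_checked["r2"] += 1

        half = n_samples // 2
        ga, gb = vm.samples[:half], vm.samples[half:]
        if half >= 2 and n_samples - half >= 2:
            per_snp, _ = ss.wc_fst(vm, ga, gb)
            rows_a = vm.sample_indices(ga)
            rows_b = vm.sample_indices(gb)
            for j in range(n_snps):
                exp = oracle_wc_theta(
                    vm.genotypes[rows_a, j], vm.genotypes[rows_b, j]
                )
                got = per_snp["fst"][j]
                if exp is None:
                    assert np.isnan(got)
                else:
                    assert got == pytest.approx(exp, abs=1e-10)
                    n_checked["fst"] += 1
    # the comparison actually exercised every statistic
    assert all(v >= 150 for v in n_checked.values()), n_checked


# ---------------------------------------------------------------------------
# invariants
# ---------------------------------------------------------------------------


def test_statistics_invariant_under_sample_permutation(rng):
    for _ in range(10):
        vm = random_vm(rng, 6, 8, missing_rate=0.1)
        perm = list(vm.samples)
        rng.shuffle(perm)
        pi_a = ss.site_pi(vm, vm.samples)["pi"]
        pi_b = ss.site_pi(vm, perm)["pi"]
        np.testing.assert_allclose(pi_a, pi_b, equal_nan=True)
        d_a = ss.tajimas_d(vm, vm.samples).records["value"]
        d_b = ss.tajimas_d(vm, perm).records["value"]
        np.testing.assert_allclose(d_a, d_b, equal_nan=True)


def test_value_ranges(rng):
    for _ in range(20):
        vm = random_vm(rng, 6, 10, missing_rate=0.1)
        out = ss.site_pi(vm)
        ok = out["pi"].notna()
        n_al = out.loc[ok, "n_alleles"]
        cap = 2 * n_al / (n_al - 1) * 0.25
        assert ((out.loc[ok, "pi"] >= 0) & (out.loc[ok, "pi"] <= cap + 1e-12)).all()
        ld = ss.genotype_r2(vm, min_bp=0, max_bp=None)
        assert ((ld.records["r2"] >= 0) & (ld.records["r2"] <= 1)).all()
        half = vm.samples[:3], vm.samples[3:]
        _, track = ss.wc_fst(vm, *half)
        vals = track.records["value"].dropna()
        assert (vals <= 1 + 1e-12).all()


def test_tajima_constants_reference_n10():
    # closed-form check at n = 10 against direct summation
    a1, a2, *_ = tajima_constants(10)
    assert a1 == pytest.approx(sum(1 / i for i in range(1, 10)))
    assert a2 == pytest.approx(sum(1 / i**2 for i in range(1, 10)))


# ---------------------------------------------------------------------------
# moving average
# ---------------------------------------------------------------------------


def _track(values, chrom="chr1"):
    import pandas as pd

    n = len(values)
    return ss.WindowedStatTrack(
        "x",
        pd.DataFrame(
            {
                "chrom": chrom,
                "win_start": np.arange(n) * 5000,
                "win_end": (np.arange(n) + 1) * 5000,
                "value": values,
                "n_sites": 1,
                "n_samples_used": 0,
            }
        ),
    )


def test_moving_average_hand_example():
    ma = ss.moving_average(_track([1, 2, 3, 4]), span=3)
    vals = ma.records["value"].to_numpy()
    assert np.isnan(vals[0]) and np.isnan(vals[1])
    assert vals[2] == pytest.approx(2.0)
    assert vals[3] == pytest.approx(3.0)


def test_moving_average_span_one_identity_and_constant_series():
    vals = [2.5, 2.5, 2.5, 2.5]
    assert np.allclose(
        ss.moving_average(_track(vals), 1).records["value"], vals
    )
    ma = ss.moving_average(_track(vals), 3).records["value"].dropna()
    assert np.allclose(ma, 2.5)
    with pytest.raises(ConfigurationError):
        ss.moving_average(_track(vals), 0)


def test_moving_average_restarts_per_chromosome():
    import pandas as pd

    t1 = _track([1, 1], "chr1").records
    t2 = _track([5, 5], "chr2").records
    track = ss.WindowedStatTrack("x", pd.concat([t1, t2], ignore_index=True))
    ma = ss.moving_average(track, 2).records
    by = ma.set_index(["chrom", "win_start"])["value"]
    assert np.isnan(by[("chr2", 0)])  # warm-up restarts on the new chromosome
    assert by[("chr2", 5000)] == pytest.approx(5.0)
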
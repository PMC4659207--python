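import numpy as np
import pytest
from hypothesis import given, strategies as st

import flockdiv as fd
from flockdiv.ld import (_em_batch, _ld_stats_arrays, genotype_pair_table,
                         DEFAULT_BIN_EDGES_BP)

from conftest import make_gm, make_map


# ---------------------------------------------------------------------------
# EM haplotype frequencies
# ---------------------------------------------------------------------------

def _panel_from_haplotypes(hap_counts, rng=None):
    """Individuals built from an explicit haplotype multiset (known phase).

    hap_counts: dict {(a1, a2): count} of haplotypes; individuals are formed
    by pairing consecutive haplotypes after a fixed shuffle.
    """
    haps = [h for h, c in hap_counts.items() for _ in range(c)]
    rng = rng or np.random.default_rng(5)
    haps = [haps[i] for i in rng.permutation(len(haps))]
    gx = np.array([haps[2 * i][0] + haps[2 * i + 1][0] for i in range(len(haps) // 2)])
    gy = np.array([haps[2 * i][1] + haps[2 * i + 1][1] for i in range(len(haps) // 2)])
    return gx, gy, haps


def _counting_oracle(haps):
    f = {k: 0 for k in [(1, 1), (1, 0), (0, 1), (0, 0)]}
    for h in haps:
        f[h] += 1
    tot = len(haps)
    return {k: v / tot for k, v in f.items()}


def test_em_equals_phased_counting_when_resolvable():
    """Drop the double heterozygotes: phase is then fully resolved and the
    EM estimate must equal direct haplotype counting exactly."""
    rng = np.random.default_rng(11)
    gx, gy, haps = _panel_from_haplotypes(
        {(1, 1): 30, (1, 0): 14, (0, 1): 22, (0, 0): 34}, rng)
    keep = ~((gx == 1) & (gy == 1))
    gx, gy = gx[keep], gy[keep]
    resolved = []
    for i in np.flatnonzero(keep):
        resolved += [haps[2 * i], haps[2 * i + 1]]
    want = _counting_oracle(resolved)
    hf = fd.em_haplotype_freqs(gx, gy)
    assert hf.f_AB == pytest.approx(want[(1, 1)], abs=1e-12)
    assert hf.f_Ab == pytest.approx(want[(1, 0)], abs=1e-12)
    assert hf.f_aB == pytest.approx(want[(0, 1)], abs=1e-12)
    assert hf.f_ab == pytest.approx(want[(0, 0)], abs=1e-12)


def test_em_duplicated_snp_perfect_coupling():
    rng = np.random.default_rng(0)
    gx = rng.binomial(2, 0.3, 150)
    hf = fd.em_haplotype_freqs(gx, gx)
    p = gx.mean() / 2
    assert hf.f_AB == pytest.approx(p, abs=1e-9)
    assert hf.f_ab == pytest.approx(1 - p, abs=1e-9)
    assert hf.f_Ab == pytest.approx(0, abs=1e-9)
    assert fd.ld_stats(hf) == (pytest.approx(1.0), pytest.approx(1.0))


def test_em_equilibrium_fixed_point():
    # genotype table consistent with independent loci at HWE margins
    gx = np.repeat([0, 1, 2], [16, 48, 36])          # p = 0.6
    gy = np.tile(np.repeat([0, 1, 2], [25, 50, 25]), 1)  # p = 0.5 within each class
    # build exact product table: counts n_ij = 100 * P(i)P(j)
    counts = np.outer([16, 48, 36], [25, 50, 25]) / 100.0
    res = _em_batch(counts[None])
    assert res["f11"][0] == pytest.approx(0.6 * 0.5, abs=1e-9)
    r2, dp = _ld_stats_arrays(res["f11"], res["f10"], res["f01"], res["f00"])
    assert r2[0] == pytest.approx(0.0, abs=1e-9)
    assert dp[0] == pytest.approx(0.0, abs=1e-9)


def test_em_marginals_preserved_and_loglik_monotone():
    rng = np.random.default_rng(2)
    for _ in range(20):
        n = rng.integers(0, 12, size=(1, 3, 3)).astype(float)
        S = n.sum()
        if S < 2:
            continue
        res = _em_batch(n)
        if not res["valid"][0]:
            continue
        f = [res[k][0] for k in ("f11", "f10", "f01", "f00")]
        assert sum(f) == pytest.approx(1.0, abs=1e-9)
        assert f[0] + f[1] == pytest.approx(res["p1"][0], abs=1e-6)
        assert f[0] + f[2] == pytest.approx(res["p2"][0], abs=1e-6)
        # log-likelihood is non-decreasing along the EM path
        lls = [_em_batch(n, max_iter=k)["loglik"][0] for k in range(1, 12)]
        assert all(b >= a - 1e-9 for a, b in zip(lls, lls[1:]))


def test_ld_stats_hand_worked():
    hf = fd.HaplotypeFreqs(f_AB=0.5, f_Ab=0.2, f_aB=0.2, f_ab=0.1,
                           loglik=0.0, em_iterations=1)
    r2, dp = fd.ld_stats(hf)
    assert r2 == pytest.approx(0.01 ** 2 / (0.7 * 0.3) ** 2, rel=1e-9)
    assert dp == pytest.approx(0.01 / 0.21, rel=1e-9)


@given(st.integers(0, 2 ** 31 - 1))
def test_ld_invariant_to_allele_relabeling(seed):
    rng = np.random.default_rng(seed)
    gx = rng.integers(0, 3, 60)
    gy = rng.integers(0, 3, 60)
    try:
        a = fd.ld_stats(fd.em_haplotype_freqs(gx, gy))
    except ValueError:
        return
    b = fd.ld_stats(fd.em_haplotype_freqs(2 - gx, gy))
    c = fd.ld_stats(fd.em_haplotype_freqs(gx, 2 - gy))
    assert a[0] == pytest.approx(b[0], abs=1e-9) and a[1] == pytest.approx(b[1], abs=1e-9)
    assert a[0] == pytest.approx(c[0], abs=1e-9) and a[1] == pytest.approx(c[1], abs=1e-9)


# ---------------------------------------------------------------------------
# D' confidence bounds
# ---------------------------------------------------------------------------

def test_dprime_ci_perfect_coupling_large_sample():
    rng = np.random.default_rng(1)
    gx = rng.binomial(2, 0.4, 200)
    lo, hi = fd.dprime_confidence_bounds(gx, gx)
    assert hi >= 0.98 and lo > 0.7


def test_dprime_ci_tiny_sample_uninformative():
    gx = np.array([0, 1, 2, 1])
    lo, hi = fd.dprime_confidence_bounds(gx, gx)
    assert hi - lo > 0.5


def test_dprime_ci_low_monotone_in_sample_size():
    rng = np.random.default_rng(3)
    base = rng.binomial(2, 0.5, 400)
    prev = -1.0
    for n in (8, 25, 80, 250):
        lo, hi = fd.dprime_confidence_bounds(base[:n], base[:n])
        assert lo >= prev - 1e-12
        prev = lo


# ---------------------------------------------------------------------------
# decay / adjacent / non-syntenic tables
# ---------------------------------------------------------------------------

def test_decay_bin_conventions():
    rng = np.random.default_rng(4)
    d = rng.binomial(2, 0.5, size=(40, 2)).astype(np.int8)
    # pair at exactly 10,000 bp falls in the 10-20 kb bin (half-open bins)
    smap = make_map([1000, 11000])
    res = fd.ld_decay(make_gm(d), smap)
    assert res.table.loc[res.table["bin"] == "10-20 kb", "n_pairs"].iloc[0] == 1
    assert res.table["n_pairs"].sum() == 1


def test_decay_counts_all_syntenic_pairs(sheep_panel):
    gm, smap, _ = sheep_panel
    res = fd.ld_decay(gm, smap, "MER")
    expect = sum(len(smap.chrom_indices(c)) * (len(smap.chrom_indices(c)) - 1) // 2
                 for c in smap.chromosomes())
    assert res.n_pairs + res.n_skipped == expect


def test_decay_small_ne_has_more_short_range_ld(sheep_panel):
    gm, smap, _ = sheep_panel
    bl = fd.ld_decay(gm, smap, "BL").table
    mer = fd.ld_decay(gm, smap, "MER").table
    assert bl["mean_r2"].iloc[0] > mer["mean_r2"].iloc[0]
    # decay: r2 decreases with distance (Spearman over populated bins)
    from scipy.stats import spearmanr
    for t in (bl, mer):
        tt = t[t["n_pairs"] > 10]
        rho, _ = spearmanr(np.arange(len(tt)), tt["mean_r2"])
        assert rho < 0


def test_adjacent_ld_counting_and_perfect_ld():
    rng = np.random.default_rng(8)
    col = rng.binomial(2, 0.5, size=(60, 1)).astype(np.int8)
    gm = make_gm(np.tile(col, (1, 4)))  # 4 duplicated columns
    adj = fd.adjacent_ld(gm, make_map([1000, 2000, 3000, 4000]))
    assert adj["n_pairs"].iloc[0] == 3
    assert adj["mean_r2"].iloc[0] == pytest.approx(1.0)
    # single-SNP chromosome -> NA
    sm2 = fd.SNPMap(["a", "b"], ["1", "2"], [100, 100], ["A", "A"], ["B", "B"])
    adj2 = fd.adjacent_ld(make_gm(col[:, :1].repeat(2, axis=1)), sm2)
    assert np.isnan(adj2["mean_r2"]).all()


def test_adjacent_ld_unlinked_floor():
    rng = np.random.default_rng(9)
    S, m = 100, 600
    d = rng.binomial(2, rng.uniform(0.2, 0.8, m), size=(S, m)).astype(np.int8)
    adj = fd.adjacent_ld(make_gm(d), make_map(np.arange(1, m + 1) * 1000))
    floor = 1 / S + 3.19 / S ** 2
    assert adj["mean_r2"].iloc[0] == pytest.approx(floor, rel=0.2)


def test_nonsyntenic_deterministic_and_floor():
    rng = np.random.default_rng(10)
    S, m = 100, 300
    d = rng.binomial(2, rng.uniform(0.2, 0.8, m), size=(S, m)).astype(np.int8)
    sm = fd.SNPMap([f"s{i}" for i in range(m)],
                   ["1"] * 100 + ["2"] * 100 + ["3"] * 100,
                   list(np.arange(1, 101) * 1000) * 3, ["A"] * m, ["B"] * m)
    gm = make_gm(d)
    a = fd.nonsyntenic_ld(gm, sm, fraction=0.5, seed=7)
    b = fd.nonsyntenic_ld(gm, sm, fraction=0.5, seed=7)
    assert a.mean_r2 == b.mean_r2 and list(a.snp_indices) == list(b.snp_indices)
    # panmictic sample: mean r2 at the sampling floor (Waples expectation)
    full = fd.nonsyntenic_ld(gm, sm, fraction=1.0, seed=7)
    assert full.n_pairs == 3 * 100 * 100
    assert full.mean_r2 == pytest.approx(1 / S + 3.19 / S ** 2, rel=0.2)
    with pytest.raises(ValueError, match="2 chromosomes"):
        fd.nonsyntenic_ld(gm, make_map(np.arange(1, m + 1) * 1000), seed=1)


def test_nonsyntenic_counting_small():
    rng = np.random.default_rng(12)
    d = rng.binomial(2, 0.5, size=(50, 4)).astype(np.int8)
    sm = fd.SNPMap(list("abcd"), ["1", "1", "2", "2"], [100, 200, 100, 200],
                   ["A"] * 4, ["B"] * 4)
    res = fd.nonsyntenic_ld(make_gm(d), sm, fraction=1.0, seed=0)
    assert res.n_pairs == 4
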
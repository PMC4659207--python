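import numpy as np
import pytest
from hypothesis import given, strategies as st

import flockdiv as fd
from flockdiv.genotype_io import MISSING

from conftest import make_gm


def test_expected_het_values():
    assert fd.expected_het(0.5) == 0.5
    assert fd.expected_het(0.0) == 0.0
    assert fd.expected_het(0.2) == pytest.approx(0.32)


def test_population_diversity_degenerate_cases():
    # fixed population: He = Ho = 0, nothing polymorphic
    gm = make_gm(np.zeros((5, 4)), populations=["P"] * 5)
    row = fd.population_diversity(gm).iloc[0]
    assert row.He == 0 and row.Ho == 0 and row.pct_polymorphic == 0
    # all-heterozygote SNP: p = 0.5 -> He = 0.5, Ho = 1
    gm = make_gm(np.ones((6, 1)), populations=["P"] * 6)
    row = fd.population_diversity(gm).iloc[0]
    assert row.He == pytest.approx(0.5) and row.Ho == pytest.approx(1.0)


def test_bottleneck_population_less_diverse(sheep_panel):
    gm, _, _ = sheep_panel
    div = fd.population_diversity(gm).set_index("population")
    assert div.loc["BL", "He"] < div.loc["MER", "He"]
    assert div.loc["PD", "He"] < div.loc["MER", "He"]


def _two_pop_single_snp(da, db):
    d = np.concatenate([da, db])[:, None]
    pops = ["A"] * len(da) + ["B"] * len(db)
    return make_gm(d, populations=pops)


def test_fst_identical_populations_zero():
    rng = np.random.default_rng(0)
    d = rng.binomial(2, 0.4, size=(40, 50)).astype(np.int8)
    gm = make_gm(np.vstack([d, d]), populations=["A"] * 40 + ["B"] * 40)
    assert fd.pairwise_fst(gm, "A", "B") == pytest.approx(0.0, abs=1e-12)


def test_fst_opposite_fixation_is_one():
    gm = _two_pop_single_snp(np.full(10, 2), np.zeros(10))
    assert fd.pairwise_fst(gm, "A", "B") == pytest.approx(1.0)


def test_fst_hand_worked_case():
    # pA=0.2 (nA=100), pB=0.4 (nB=300): FST = 0.015/0.455
    da = np.array([1] * 40 + [0] * 60)
    db = np.array([1] * 240 + [0] * 60)
    gm = _two_pop_single_snp(da, db)
    assert fd.pairwise_fst(gm, "A", "B") == pytest.approx(0.015 / 0.455, abs=1e-9)


@given(st.integers(0, 2 ** 31 - 1))
def test_fst_symmetric_and_label_swap_invariant(seed):
    rng = np.random.default_rng(seed)
    d = rng.integers(0, 3, size=(30, 20)).astype(np.int8)
    gm = make_gm(d, populations=["A"] * 15 + ["B"] * 15)
    f_ab = fd.pairwise_fst(gm, "A", "B")
    f_ba = fd.pairwise_fst(gm, "B", "A")
    assert f_ab == pytest.approx(f_ba, abs=1e-12)
    # swap allele labels at every SNP
    sw = d.copy()
    ok = sw != MISSING
    sw[ok] = 2 - sw[ok]
    f_sw = fd.pairwise_fst(make_gm(sw, populations=["A"] * 15 + ["B"] * 15), "A", "B")
    assert f_ab == pytest.approx(f_sw, abs=1e-12)


def test_fst_increases_with_divergence_time():
    """Two populations drifting independently from one founder pool."""
    def panel(gens, seed):
        scn = fd.SimScenario(
            chromosome_lengths_mb=(20.0,), snp_density_per_mb=10.0,
            founder_size=80, split_generations=gens,
            breeds={"A": fd.BreedConfig(ne=40), "B": fd.BreedConfig(ne=40)},
            crosses={}, sample_sizes={"A": 40, "B": 40}, seed=seed,
            missing_rate=0.0, genotype_error_rate=0.0)
        gm, _, _ = fd.simulate_panel(scn)
        return fd.pairwise_fst(gm, "A", "B")
    for seed in range(5):
        assert panel(4, seed) < panel(40, seed)


def test_grm_duplicate_individual_and_symmetry(hwe_panel):
    d = hwe_panel.dosages[:50]
    d = np.vstack([d, d[0:1]])  # duplicate individual 0
    gm = make_gm(d)
    G = fd.grm(gm)
    np.testing.assert_allclose(G, G.T)
    assert G[0, -1] == pytest.approx(G[0, 0])


def test_grm_mean_diagonal_near_one_at_hwe(hwe_panel):
    G = fd.grm(hwe_panel)
    assert np.mean(np.diag(G)) == pytest.approx(1.0, abs=0.05)


def test_grm_all_monomorphic_errors():
    gm = make_gm(np.zeros((5, 3)))
    with pytest.raises(ValueError, match="monomorphic"):
        fd.grm(gm)


def test_pca_rank_one_structure():
    # two populations fixed for opposite alleles at every SNP
    d = np.vstack([np.zeros((10, 30)), np.full((10, 30), 2)])
    gm = make_gm(d, populations=["A"] * 10 + ["B"] * 10)
    res = fd.pca(fd.grm(gm), k=3)
    assert res.variance_fraction[0] > 0.99
    pc1 = res.scores[:, 0]
    assert (np.sign(pc1[:10]) == np.sign(pc1[0])).all()
    assert (np.sign(pc1[10:]) != np.sign(pc1[0])).all()


def test_pca_identity_grm_equal_fractions():
    res = fd.pca(np.eye(6), k=6)
    np.testing.assert_allclose(res.variance_fraction, np.full(6, 1 / 6), atol=1e-12)


def test_pca_crosses_between_parents(sheep_panel):
    gm, _, _ = sheep_panel
    res = fd.pca(fd.grm(gm), k=2)
    pc1 = res.scores[:, 0]
    cent = {p: pc1[gm.population == p].mean() for p in ("MER", "BL", "MxB")}
    lo, hi = sorted([cent["MER"], cent["BL"]])
    assert lo < cent["MxB"] < hi  # sign-invariant: ordering of centroids


def test_pca_scores_invariant_to_sample_order(hwe_panel):
    G = fd.grm(hwe_panel.subset_samples(np.arange(40)))
    perm = np.random.default_rng(0).permutation(40)
    r1 = fd.pca(G, k=2)
    r2 = fd.pca(G[np.ix_(perm, perm)], k=2)
    for k in range(2):
        a, b = r1.scores[perm, k], r2.scores[:, k]
        assert np.allclose(a, b, atol=1e-8) or np.allclose(a, -b, atol=1e-8)
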
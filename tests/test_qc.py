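from fractions import Fraction
from math import comb

import numpy as np
import pytest
from hypothesis import given, strategies as st

import flockdiv as fd
from flockdiv.genotype_io import MISSING, QualityAnnotations
from flockdiv.qc import QCConfig, apply_qc, hwe_pvalues

from conftest import make_gm, make_map


def test_snp_call_rate_counts_missing():
    d = np.zeros((100, 1), dtype=np.int8)
    d[:3, 0] = MISSING
    assert fd.snp_call_rate(make_gm(d))[0] == pytest.approx(0.97)
    assert fd.snp_call_rate(make_gm(np.zeros((10, 1))))[0] == 1.0
    assert fd.snp_call_rate(make_gm(np.full((10, 1), MISSING)))[0] == 0.0


def test_minor_allele_frequency_cases():
    gm = make_gm(np.array([[0], [1], [2], [2]]))
    assert fd.minor_allele_frequency(gm)[0] == pytest.approx(0.375)  # p=0.625
    assert fd.minor_allele_frequency(make_gm(np.zeros((4, 1))))[0] == 0.0
    assert fd.minor_allele_frequency(make_gm(np.ones((4, 1))))[0] == 0.5


def hwe_oracle(n_AA, n_Aa, n_aa):
    """Exact-rational enumeration over all heterozygote configurations."""
    n = n_AA + n_Aa + n_aa
    na = 2 * n_aa + n_Aa
    rare = min(na, 2 * n - na)
    if rare == 0:
        return Fraction(1)
    probs = {}
    for h in range(rare % 2, rare + 1, 2):
        hr = (rare - h) // 2
        hc = n - h - hr
        probs[h] = Fraction(2 ** h) * Fraction(
            comb(n, hr) * comb(n - hr, h), 1)
    total = sum(probs.values())
    obs = probs[min(n_Aa, rare)]
    return sum(p for p in probs.values() if p <= obs) / total


@pytest.mark.parametrize("counts,expected", [
    ((1, 2, 1), 1.0),       # observed het count is modal
    ((25, 50, 25), 1.0),
])
def test_hwe_exact_known_values(counts, expected):
    assert fd.hwe_exact_test(*counts) == pytest.approx(expected, abs=1e-12)


def test_hwe_extreme_deficit_fails_cutoff():
    assert fd.hwe_exact_test(50, 0, 50) < 1e-15


def test_hwe_monomorphic_is_one():
    assert fd.hwe_exact_test(10, 0, 0) == 1.0


@given(st.integers(0, 70), st.integers(0, 70), st.integers(0, 60))
def test_hwe_matches_enumeration_oracle(a, b, c):
    if a + b + c == 0:
        return
    p = fd.hwe_exact_test(a, b, c)
    assert abs(p - float(hwe_oracle(a, b, c))) < 1e-12


def test_het_outlier_flags():
    rng = np.random.default_rng(0)
    d = rng.binomial(2, 0.5, size=(200, 1000)).astype(np.int8)
    gm = make_gm(d)
    assert not fd.het_outlier_flags(gm, 3.0).any() or \
        fd.het_outlier_flags(gm, 3.0).mean() < 0.01
    # one fully heterozygous SNP among ordinary ones is flagged (z >> 3)
    d2 = d.copy()
    d2[:, 0] = 1
    assert fd.het_outlier_flags(make_gm(d2), 3.0)[0]
    # infinite limit -> no flags
    assert not fd.het_outlier_flags(make_gm(d2), np.inf).any()
    # zero variance -> no flags
    same = np.tile(d[:, :1], (1, 5))
    assert not fd.het_outlier_flags(make_gm(same), 3.0).any()


def test_apply_qc_reason_attribution_and_order():
    rng = np.random.default_rng(1)
    d = rng.binomial(2, 0.4, size=(50, 6)).astype(np.int8)
    d[:, 2] = 0           # monomorphic -> low MAF
    d[:30, 3] = MISSING   # call rate 0.4
    sm = fd.SNPMap([f"s{i}" for i in range(6)],
                   ["1", "X", "1", "1", "0", "1"],
                   [100, 200, 300, 400, 500, 600],
                   ["A"] * 6, ["B"] * 6)
    gm = make_gm(d)
    gm2, sm2, rep = apply_qc(gm, sm, None, QCConfig())
    assert rep.removed["non_autosomal"] == 1      # chromosome X
    assert rep.removed["unmapped"] == 1           # chromosome 0
    assert rep.removed["low_call_rate"] == 1
    assert rep.removed["low_maf"] == 1
    assert sum(rep.removed.values()) + rep.n_surviving == 6
    assert gm2.n_snps == sm2.n_snps == rep.n_surviving


def test_apply_qc_clean_panel_is_identity(hwe_panel):
    sm = make_map(np.arange(1, hwe_panel.n_snps + 1) * 1000)
    gm2, sm2, rep = apply_qc(hwe_panel, sm, QualityAnnotations.from_matrix(hwe_panel))
    assert all(v == 0 for v in rep.removed.values())
    np.testing.assert_array_equal(gm2.dosages, hwe_panel.dosages)


def test_apply_qc_idempotent(sheep_panel):
    gm, smap, _ = sheep_panel
    gm1, sm1, rep1 = apply_qc(gm, smap)
    gm2, sm2, rep2 = apply_qc(gm1, sm1)
    assert list(sm1.snp_id) == list(sm2.snp_id)


def test_apply_qc_all_removed_errors():
    d = np.zeros((10, 2), dtype=np.int8)  # all monomorphic
    sm = make_map([100, 200])
    with pytest.raises(ValueError, match="review"):
        apply_qc(make_gm(d), sm)


@given(st.integers(0, 2 ** 32 - 1))
def test_qc_counting_identity_fuzzed(seed):
    rng = np.random.default_rng(seed)
    n, m = 30, 25
    d = rng.integers(0, 3, size=(n, m)).astype(np.int8)
    d[rng.random(size=d.shape) < 0.2] = MISSING
    chroms = rng.choice(["1", "2", "X", "0"], size=m)
    sm = fd.SNPMap([f"s{i}" for i in range(m)], chroms,
                   np.arange(1, m + 1) * 1000, ["A"] * m, ["B"] * m)
    try:
        _, _, rep = apply_qc(make_gm(d), sm)
    except ValueError:
        return  # everything removed is a legal outcome for random panels
    assert sum(rep.removed.values()) + rep.n_surviving == m
    # a SNP is attributed to exactly one reason
    all_ids = [x for ids in rep.removed_ids.values() for x in ids]
    assert len(all_ids) == len(set(all_ids))
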
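import numpy as np
import pandas as pd
import pytest

import flockdiv as fd
from flockdiv.genotype_io import MISSING
from flockdiv.roh import ROHParams, roh_length_categories

from conftest import make_gm, make_map


def test_min_roh_snps_formula():
    # direct evaluation: ln(0.05/(48599*1273)) / ln(0.65) = 48.60 -> 49
    assert fd.min_roh_snps(48599, 1273, 0.05, 0.35) == 49
    # vacuous bound when alpha >= n_s * n_i (numerator log(>=1))
    with pytest.warns(UserWarning):
        assert fd.min_roh_snps(1, 1, 1.0, 0.35) == 0
    # het -> 1 limit: denominator -> -inf, l -> 1
    assert fd.min_roh_snps(1000, 100, 0.05, 1 - 1e-12) == 1
    with pytest.raises(ValueError):
        fd.min_roh_snps(1000, 100, 0.05, 0.0)


def _window_params(**kw):
    base = dict(window_span_kb=200.0, max_missing_per_window=2,
                max_het_per_window=1, min_length_kb=500.0, max_gap_kb=250.0)
    base.update(kw)
    return ROHParams(**base)


def _het_background(m):
    return np.ones(m, dtype=np.int8)  # heterozygous everywhere


def test_planted_600kb_run_recovered():
    # SNPs every 10 kb; plant 61 homozygous SNPs spanning 600 kb
    pos = np.arange(1, 301) * 10_000
    smap = make_map(pos)
    row = _het_background(300)
    row = fd.plant_roh(row, "1", pos[100], pos[160], smap)
    seg = fd.detect_roh(row, smap, _window_params(), l=40)
    assert len(seg) == 1
    s = seg.iloc[0]
    # recovered within a couple of SNPs of the planted boundaries
    assert abs(s.start_bp - pos[100]) <= 2 * 10_000
    assert abs(s.end_bp - pos[160]) <= 2 * 10_000
    assert s.n_snps >= 40 and s.length_bp >= 500_000


def test_planted_400kb_run_rejected_by_length_filter():
    pos = np.arange(1, 301) * 10_000
    smap = make_map(pos)
    row = fd.plant_roh(_het_background(300), "1", pos[100], pos[140], smap)
    seg = fd.detect_roh(row, smap, _window_params(), l=20)
    assert len(seg) == 0


def test_gap_over_250kb_splits_run():
    # homozygous chromosome with one 300-kb inter-SNP gap in the middle
    pos = np.concatenate([np.arange(1, 101) * 10_000,
                          1_000_000 + 300_000 + np.arange(1, 101) * 10_000])
    smap = make_map(pos)
    row = np.zeros(200, dtype=np.int8)
    seg = fd.detect_roh(row, smap, _window_params(), l=40)
    assert len(seg) == 2
    assert (seg["length_bp"] < 1_300_000).all()


def test_fully_heterozygous_yields_nothing():
    pos = np.arange(1, 201) * 10_000
    seg = fd.detect_roh(_het_background(200), make_map(pos), _window_params(), l=10)
    assert len(seg) == 0


def test_fully_homozygous_tiles_chromosomes():
    sm = fd.SNPMap([f"s{i}" for i in range(200)],
                   ["1"] * 100 + ["2"] * 100,
                   list(np.arange(1, 101) * 10_000) * 2,
                   ["A"] * 200, ["B"] * 200)
    seg = fd.detect_roh(np.zeros(200, dtype=np.int8), sm, _window_params(), l=10)
    assert set(seg["chrom"]) == {"1", "2"}
    for c in ("1", "2"):
        s = seg[seg["chrom"] == c]
        assert len(s) == 1
        assert s.iloc[0]["n_snps"] == 100


def test_emitted_segments_satisfy_all_filters(sheep_panel):
    gm, smap, _ = sheep_panel
    params = ROHParams()
    segs, l = fd.roh_cohort(gm, smap, params)
    assert len(segs) > 0
    assert (segs["n_snps"] >= l).all()
    assert (segs["length_bp"] >= params.min_length_kb * 1000).all()
    # no internal gap above the cap
    for r in segs.sample(min(len(segs), 50), random_state=0).itertuples():
        idx = smap.chrom_indices(r.chrom)
        pos = smap.pos_bp[idx]
        inside = pos[(pos >= r.start_bp) & (pos <= r.end_bp)]
        assert np.max(np.diff(inside)) <= params.max_gap_kb * 1000


def test_crossbreds_nearly_roh_free(sheep_panel):
    gm, smap, _ = sheep_panel
    segs, _ = fd.roh_cohort(gm, smap)
    per_pop = segs.groupby("population").size().reindex(gm.populations(), fill_value=0)
    assert per_pop["BL"] > per_pop["MER"]
    assert per_pop["MxB"] < 0.1 * per_pop["BL"]


def test_length_categories_boundaries():
    segs = pd.DataFrame({
        "sample_id": ["a", "a", "a", "b"],
        "chrom": "1", "start_bp": 0,
        "end_bp": [3_000_000, 6_000_000, 5_000_000, 700_000],
        "n_snps": 10,
        "length_bp": [3_000_000, 6_000_000, 5_000_000, 700_000],
    })
    out = roh_length_categories(segs).set_index("sample_id")
    assert out.loc["a", "1-5 Mb"] == pytest.approx(3.0)
    # 6 Mb and the exactly-5-Mb segment both land in 5-10 Mb (half-open bins)
    assert out.loc["a", "5-10 Mb"] == pytest.approx(11.0)
    assert out.loc["a", "total_mb"] == pytest.approx(14.0)
    # a 0.7 Mb segment counts in the total but in no >=1 Mb category
    assert out.loc["b", "total_mb"] == pytest.approx(0.7)
    assert out.loc["b", "1-5 Mb"] == 0.0


def test_roh_incidence_counts_individuals():
    pos = np.arange(1, 31) * 10_000
    smap = make_map(pos)
    segs = pd.DataFrame([
        {"sample_id": "a", "chrom": "1", "start_bp": pos[9], "end_bp": pos[19],
         "n_snps": 11, "length_bp": pos[19] - pos[9]},
    ])
    inc = fd.roh_incidence(segs, smap)
    assert inc[9] == 1 and inc[19] == 1 and inc[15] == 1
    assert inc[8] == 0 and inc[20] == 0
    assert fd.roh_incidence(segs.iloc[:0], smap).sum() == 0


def test_roh_incidence_peaks_at_planted_region(sheep_panel):
    gm, smap, _ = sheep_panel
    chrom = "1"
    idx = smap.chrom_indices(chrom)
    pos = smap.pos_bp[idx]
    start, end = int(pos[100]), int(pos[100] + 2_500_000)
    d = gm.dosages.copy()
    for i in range(gm.n_samples):
        d[i] = fd.plant_roh(d[i], chrom, start, end, smap)
    gm2 = fd.GenotypeMatrix(d, gm.sample_ids, gm.population)
    segs, _ = fd.roh_cohort(gm2, smap, ROHParams())
    inc = fd.roh_incidence(segs, smap)
    in_region = (smap.chrom == chrom) & (smap.pos_bp >= start) & (smap.pos_bp <= end)
    assert inc[in_region].mean() > 5 * max(inc[~in_region].mean(), 1e-9)
    assert np.argmax(inc) in np.flatnonzero(in_region)


def test_chromosome_summary_arithmetic():
    smap = make_map(np.arange(1, 101) * 1_000_000)  # 100 Mb extent
    segs = pd.DataFrame([
        {"sample_id": "a", "chrom": "1", "start_bp": 1, "end_bp": 10_000_001,
         "n_snps": 10, "length_bp": 10_000_000},
        {"sample_id": "b", "chrom": "1", "start_bp": 1, "end_bp": 20_000_001,
         "n_snps": 20, "length_bp": 20_000_000},
    ])
    out = fd.roh_chromosome_summary(segs, smap)
    row = out.iloc[0]
    assert row.n_roh == 2 and row.n_animals == 2
    assert row.mean_mb_per_animal == pytest.approx(15.0)
    assert row.pct_coverage == pytest.approx(15.0)
    empty = fd.roh_chromosome_summary(segs.iloc[:0], smap)
    assert empty.iloc[0]["pct_coverage"] == 0.0 and empty.iloc[0]["no_roh"]
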
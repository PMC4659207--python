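"""Gabriel-style haplotype block partitioning from D' confidence bounds.

A pair of SNPs is in "strong LD" when the one-sided 95% likelihood bounds on
D' satisfy upper >= 0.98 and lower >= 0.70; it shows "strong evidence of
historical recombination" when the upper bound is < 0.90; otherwise it is
uninformative.  A candidate block is a map interval whose outermost pair is
strong, whose span does not exceed a cap (default 500 kb, which is why
maximum observed block lengths cluster just under 500 kb), and in which at
least 95% of the informative pairs are strong.  Uninformative pairs are
excluded from the 95% denominator, so a 2-SNP candidate requires its single
pair to be strong.  Candidates are accepted greedily by decreasing length;
overlapping candidates are discarded, so blocks never overlap.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .genotype_io import GenotypeMatrix, SNPMap
from .ld import _counts_allpairs_blocks, _dprime_ci_batch


class PairClass(Enum):
    STRONG_LD = "STRONG_LD"
    RECOMBINATION = "RECOMBINATION"
    UNINFORMATIVE = "UNINFORMATIVE"


STRONG_CI_HIGH = 0.98
STRONG_CI_LOW = 0.70
RECOMB_CI_HIGH = 0.90
STRONG_FRACTION = 0.95


def classify_pair(ci_low: float, ci_high: float) -> PairClass:
    """Classify one pair from its D' confidence bounds (Gabriel rule)."""
    if ci_high >= STRONG_CI_HIGH and ci_low >= STRONG_CI_LOW:
        return PairClass.STRONG_LD
    if ci_high < RECOMB_CI_HIGH:
        return PairClass.RECOMBINATION
    return PairClass.UNINFORMATIVE


def _classify_arrays(ci_low: np.ndarray, ci_high: np.ndarray) -> np.ndarray:
    """Vectorised classification: 1 strong, -1 recombination, 0 uninformative."""
    out = np.zeros(len(ci_low), dtype=np.int8)
    out[(ci_high >= STRONG_CI_HIGH) & (ci_low >= STRONG_CI_LOW)] = 1
    out[(out == 0) & (ci_high < RECOMB_CI_HIGH)] = -1
    return out


def classify_pairs(gm: GenotypeMatrix, smap: SNPMap, population: str | None = None,
                   max_span_kb: float = 500.0) -> pd.DataFrame:
    """D' CI classification for every syntenic pair within the span cap.

    Returns a DataFrame with global SNP indices ``i < j``, the CI bounds and
    the class code (1 strong, -1 recombination, 0 uninformative).
    """
    X = gm.dosages if population is None else gm.dosages[gm.population_mask(population)]
    max_dist = int(max_span_kb * 1000)
    recs = []
    for c in smap.chromosomes():
        idx = smap.chrom_indices(c)
        if len(idx) < 2:
            continue
        Xc = X[:, idx]
        pos = smap.pos_bp[idx]
        for ii, jj, n in _counts_allpairs_blocks(Xc, pos, max_dist=max_dist):
            lo, hi, ok = _dprime_ci_batch(n)
            cls = _classify_arrays(lo, hi)
            cls[~ok] = 0  # degenerate pairs are uninformative
            recs.append(pd.DataFrame({"i": idx[ii], "j": idx[jj],
                                      "ci_low": lo, "ci_high": hi, "cls": cls}))
    if not recs:
        return pd.DataFrame(columns=["i", "j", "ci_low", "ci_high", "cls"])
    return pd.concat(recs, ignore_index=True)


def find_blocks(pair_class: pd.DataFrame, smap: SNPMap,
                max_span_kb: float = 500.0) -> pd.DataFrame:
    """Greedy Gabriel block selection from classified pairs.

    ``pair_class`` must hold columns ``i``, ``j`` (global map indices) and
    ``cls`` (1/-1/0) for every pair within the span cap.  Returns a
    BED-like DataFrame of non-overlapping blocks (>= 2 SNPs each).
    """
    max_span = int(max_span_kb * 1000)
    cls_map: dict[tuple[int, int], int] = {
        (int(r.i), int(r.j)): int(r.cls)
        for r in pair_class.itertuples() if r.cls != 0
    }
    candidates = []
    for c in smap.chromosomes():
        idx = smap.chrom_indices(c)
        pos = smap.pos_bp[idx]
        m = len(idx)
        for a in range(m):
            gi = int(idx[a])
            b_max = int(np.searchsorted(pos, pos[a] + max_span, side="right") - 1)
            for b in range(b_max, a, -1):
                gj = int(idx[b])
                if cls_map.get((gi, gj)) != 1:
                    continue
                strong = recomb = 0
                for u in range(a, b + 1):
                    gu = int(idx[u])
                    for v in range(u + 1, b + 1):
                        k = cls_map.get((gu, int(idx[v])), 0)
                        if k == 1:
                            strong += 1
                        elif k == -1:
                            recomb += 1
                informative = strong + recomb
                if informative and strong / informative >= STRONG_FRACTION:
                    candidates.append((int(pos[b] - pos[a]), b - a + 1, c,
                                       gi, gj, int(pos[a]), int(pos[b])))
    candidates.sort(key=lambda t: (-t[0], -t[1], t[2], t[3]))
    taken: set[int] = set()
    rows = []
    for length, nsnp, c, gi, gj, pa, pb in candidates:
        span = range(gi, gj + 1)
        if any(k in taken for k in span):
            continue
        taken.update(span)
        rows.append({"chrom": c, "first_idx": gi, "last_idx": gj,
                     "start_bp": pa, "end_bp": pb, "n_snps": nsnp,
                     "length_bp": length})
    df = pd.DataFrame(rows, columns=["chrom", "first_idx", "last_idx",
                                     "start_bp", "end_bp", "n_snps", "length_bp"])
    if len(df):
        df = df.sort_values(["chrom", "start_bp"]).reset_index(drop=True)
    return df


def haplotype_blocks(gm: GenotypeMatrix, smap: SNPMap, population: str | None = None,
                     max_span_kb: float = 500.0):
    """Full block detection for one population: classify pairs, then partition.

    Returns ``(blocks DataFrame, pair classification DataFrame)``.
    """
    pc = classify_pairs(gm, smap, population, max_span_kb=max_span_kb)
    return find_blocks(pc, smap, max_span_kb=max_span_kb), pc


def block_summary(blocks: pd.DataFrame, smap: SNPMap,
                  chrom_lengths: dict[str, int] | None = None) -> dict:
    """Per-population block summary (counts, coverage, SNP content).

    ``chrom_lengths`` (bp) defaults to the map extent per chromosome.
    Percent of genome is total block length over total chromosome length;
    percent of SNPs counts map SNPs inside blocks.
    """
    lengths = chrom_lengths or smap.chrom_lengths()
    genome = float(sum(lengths.values()))
    total_snps = smap.n_snps
    if len(blocks) == 0:
        return {"n_blocks": 0, "total_length_mb": 0.0, "pct_genome": 0.0,
                "mean_length_kb": 0.0, "median_length_kb": 0.0,
                "max_length_kb": 0.0, "min_length_kb": 0.0,
                "n_snps_in_blocks": 0, "pct_snps_in_blocks": 0.0,
                "min_snps_per_block": 0, "max_snps_per_block": 0}
    lb = blocks["length_bp"].to_numpy(dtype=float)
    nsnps = int(blocks["n_snps"].sum())  # blocks are disjoint
    return {
        "n_blocks": int(len(blocks)),
        "total_length_mb": float(lb.sum() / 1e6),
        "pct_genome": float(100.0 * lb.sum() / genome),
        "mean_length_kb": float(lb.mean() / 1e3),
        "median_length_kb": float(np.median(lb) / 1e3),
        "max_length_kb": float(lb.max() / 1e3),
        "min_length_kb": float(lb.min() / 1e3),
        "n_snps_in_blocks": nsnps,
        "pct_snps_in_blocks": float(100.0 * nsnps / total_snps),
        "min_snps_per_block": int(blocks["n_snps"].min()),
        "max_snps_per_block": int(blocks["n_snps"].max()),
    }
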
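"""Runs of homozygosity: sliding-window detection and summaries.

Detection follows the PLINK sliding-window scheme under a kb-parameterised
window: windows of consecutive SNPs spanning at most ``window_span_kb`` slide
one SNP at a time; a window counts as homozygous when it contains at most
``max_het_per_window`` heterozygotes and ``max_missing_per_window`` missing
calls.  A SNP is ROH-eligible when the fraction of windows containing it that
are homozygous reaches ``window_hit_threshold`` (PLINK's --homozyg-window-
threshold rule; windows anchored near a run's edge inevitably take in flanking
heterozygous tracts, so requiring a high fraction would make any run shorter
than the window span undetectable).  Maximal runs of
eligible SNPs are split wherever two consecutive SNPs are more than
``max_gap_kb`` apart, then filtered to runs of at least ``l`` SNPs (the
false-positive bound below) spanning at least ``min_length_kb``.

The minimum SNP count ``l`` bounds the expected number of chance runs: with
``n_s`` SNPs per individual, ``n_i`` individuals, tolerated false-positive
level ``alpha`` and mean per-SNP heterozygosity ``het``,

    l = ceil( ln(alpha / (n_s * n_i)) / ln(1 - het) ).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix, SNPMap

#: half-open length-category edges in Mb
LENGTH_CATEGORY_EDGES_MB = (1.0, 5.0, 10.0, 15.0, 20.0, 25.0)
LENGTH_CATEGORY_LABELS = ("1-5 Mb", "5-10 Mb", "10-15 Mb", "15-20 Mb",
                          "20-25 Mb", ">25 Mb")


@dataclass
class ROHParams:
    window_span_kb: float = 1000.0
    max_missing_per_window: int = 2
    max_het_per_window: int = 1
    min_length_kb: float = 500.0
    max_gap_kb: float = 250.0
    alpha: float = 0.05
    window_hit_threshold: float = 0.05


def min_roh_snps(n_s: int, n_i: int, alpha: float = 0.05, het: float = 0.35) -> int:
    """Minimum number of SNPs constituting a ROH (false-positive bound).

    ``het`` is the mean observed per-SNP heterozygosity across all SNPs.
    Returns ``ceil(ln(alpha/(n_s*n_i)) / ln(1-het))``; 0 (with a warning)
    when ``alpha >= n_s*n_i`` makes the bound vacuous.
    """
    if n_s < 1 or n_i < 1:
        raise ValueError("n_s and n_i must be >= 1")
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if not (0 < het < 1):
        raise ValueError("het must be in (0,1); formula undefined otherwise")
    ratio = alpha / (n_s * n_i)
    if ratio >= 1:
        warnings.warn("alpha >= n_s*n_i: minimum-SNP bound is vacuous (l=0)")
        return 0
    return int(math.ceil(math.log(ratio) / math.log(1.0 - het)))


def _detect_chrom(g: np.ndarray, pos: np.ndarray, params: ROHParams, l: int):
    """ROH index ranges [(first, last), ...] for one individual/chromosome."""
    m = len(pos)
    if m == 0:
        return []
    span = int(params.window_span_kb * 1000)
    het = (g == 1).astype(np.int32)
    mis = (g == MISSING).astype(np.int32)
    chet = np.concatenate([[0], np.cumsum(het)])
    cmis = np.concatenate([[0], np.cumsum(mis)])
    ends = np.searchsorted(pos, pos + span, side="right") - 1  # window end per start
    nhet = chet[ends + 1] - chet[np.arange(m)]
    nmis = cmis[ends + 1] - cmis[np.arange(m)]
    hom_w = (nhet <= params.max_het_per_window) & (nmis <= params.max_missing_per_window)
    chom = np.concatenate([[0], np.cumsum(hom_w)])
    # windows containing SNP k start at s in [smin(k), k]; ends is non-decreasing
    k = np.arange(m)
    smin = np.searchsorted(ends, k, side="left")
    total = k - smin + 1
    hom_cover = chom[k + 1] - chom[smin]
    eligible = hom_cover / total >= params.window_hit_threshold

    gap_bp = int(params.max_gap_kb * 1000)
    min_len = int(params.min_length_kb * 1000)
    out = []
    s = 0
    while s < m:
        if not eligible[s]:
            s += 1
            continue
        e = s
        while e + 1 < m and eligible[e + 1] and pos[e + 1] - pos[e] <= gap_bp:
            e += 1
        n_snps = e - s + 1
        length = int(pos[e] - pos[s])
        if n_snps >= l and length >= min_len:
            out.append((s, e))
        s = e + 1
    return out


def detect_roh(genotypes: np.ndarray, smap: SNPMap, params: ROHParams | None = None,
               l: int = 1) -> pd.DataFrame:
    """ROH segments for one individual (map-sorted genotype row).

    Returns a DataFrame with chrom, start_bp, end_bp, n_snps and length_bp
    (= end - start); empty when no run passes the filters.
    """
    params = params or ROHParams()
    rows = []
    for c in smap.chromosomes():
        idx = smap.chrom_indices(c)
        pos = smap.pos_bp[idx]
        for s, e in _detect_chrom(np.asarray(genotypes)[idx], pos, params, l):
            rows.append({"chrom": c, "start_bp": int(pos[s]), "end_bp": int(pos[e]),
                         "n_snps": e - s + 1, "length_bp": int(pos[e] - pos[s])})
    return pd.DataFrame(rows, columns=["chrom", "start_bp", "end_bp",
                                       "n_snps", "length_bp"])


def roh_cohort(gm: GenotypeMatrix, smap: SNPMap, params: ROHParams | None = None,
               l: int | None = None) -> tuple[pd.DataFrame, int]:
    """ROH segments for every individual in the cohort.

    When ``l`` is None it is computed from the whole cohort: ``n_s`` = SNP
    count, ``n_i`` = individual count, ``het`` = mean observed per-SNP
    heterozygosity.  Returns ``(segments DataFrame, l)``.
    """
    params = params or ROHParams()
    if l is None:
        het = float(np.nanmean(gm.het_obs()))
        l = min_roh_snps(gm.n_snps, gm.n_samples, params.alpha, het)
    frames = []
    for i in range(gm.n_samples):
        seg = detect_roh(gm.dosages[i], smap, params, l)
        if len(seg):
            seg.insert(0, "sample_id", gm.sample_ids[i])
            seg.insert(1, "population", gm.population[i])
            frames.append(seg)
    cols = ["sample_id", "population", "chrom", "start_bp", "end_bp",
            "n_snps", "length_bp"]
    segs = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=cols)
    return segs, l


def roh_length_categories(segments: pd.DataFrame, sample_ids=None) -> pd.DataFrame:
    """Per-individual summed ROH length (Mb) in the six length categories.

    Categories are half-open [low, high) Mb.  Segments shorter than 1 Mb
    (but >= the minimum length) count toward ``total_mb`` only.
    """
    ids = list(sample_ids) if sample_ids is not None else (
        sorted(segments["sample_id"].unique()) if len(segments) else [])
    out = pd.DataFrame(0.0, index=ids,
                       columns=list(LENGTH_CATEGORY_LABELS) + ["total_mb"])
    out.index.name = "sample_id"
    if len(segments) == 0:
        return out.reset_index()
    mb = segments["length_bp"].to_numpy() / 1e6
    cat = np.searchsorted(LENGTH_CATEGORY_EDGES_MB, mb, side="right") - 1
    for (sid, k), grp in segments.assign(_mb=mb, _cat=cat).groupby(["sample_id", "_cat"]):
        if k >= 0:
            out.loc[sid, LENGTH_CATEGORY_LABELS[int(k)]] += grp["_mb"].sum()
    for sid, grp in segments.assign(_mb=mb).groupby("sample_id"):
        out.loc[sid, "total_mb"] = grp["_mb"].sum()
    return out.reset_index()


def population_mean_categories(per_individual: pd.DataFrame,
                               population: pd.Series | dict) -> pd.DataFrame:
    """Population means of per-individual category sums."""
    df = per_individual.copy()
    pop = pd.Series(population)
    df["population"] = df["sample_id"].map(pop)
    return df.groupby("population", sort=False).mean(numeric_only=True).reset_index()


def roh_incidence(segments: pd.DataFrame, smap: SNPMap) -> np.ndarray:
    """Number of individuals whose ROH cover each SNP position."""
    counts = np.zeros(smap.n_snps, dtype=np.int64)
    if len(segments) == 0:
        return counts
    for c in smap.chromosomes():
        idx = smap.chrom_indices(c)
        pos = smap.pos_bp[idx]
        sub = segments[segments["chrom"] == c]
        for r in sub.itertuples():
            a = np.searchsorted(pos, r.start_bp, side="left")
            b = np.searchsorted(pos, r.end_bp, side="right")
            counts[idx[a:b]] += 1
    return counts


def roh_chromosome_summary(segments: pd.DataFrame, smap: SNPMap,
                           chrom_lengths: dict[str, int] | None = None) -> pd.DataFrame:
    """Per-chromosome ROH count and percent coverage.

    Mean ROH burden per chromosome is the summed ROH length divided by the
    number of animals that have at least one ROH on that chromosome; the
    percentage divides that mean by the chromosome length.  Chromosomes with
    no ROH are reported as 0% and flagged.
    """
    lengths = chrom_lengths or smap.chrom_lengths()
    rows = []
    for c in smap.chromosomes():
        sub = segments[segments["chrom"] == c] if len(segments) else segments
        n = int(len(sub))
        if n == 0:
            rows.append({"chrom": c, "n_roh": 0, "n_animals": 0,
                         "mean_mb_per_animal": 0.0, "pct_coverage": 0.0,
                         "no_roh": True})
            continue
        n_animals = sub["sample_id"].nunique()
        mean_mb = sub["length_bp"].sum() / 1e6 / n_animals
        rows.append({"chrom": c, "n_roh": n, "n_animals": int(n_animals),
                     "mean_mb_per_animal": float(mean_mb),
                     "pct_coverage": float(100.0 * mean_mb / (lengths[c] / 1e6)),
                     "no_roh": False})
    return pd.DataFrame(rows)
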
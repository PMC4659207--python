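"""Per-population gene diversity, pairwise FST, GRM and PCA.

Expected heterozygosity per SNP is 1 minus the sum of squared allele
frequencies (= 2pq for a biallelic locus).  Pairwise FST follows the
Hudson/Nei-style (HT - HS)/HT with HT computed from the size-weighted mean
allele frequency of the pair and HS as the size-weighted mean of the
within-population expected heterozygosities; both are averaged over loci
before the final ratio ("ratio of averages").  Population structure is
summarised by PCA of a VanRaden method-1 genomic relationship matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import eigh

from .genotype_io import MISSING, GenotypeMatrix


def expected_het(p) -> np.ndarray | float:
    """Expected heterozygosity 2p(1-p) for allele frequency p."""
    p = np.asarray(p, dtype=float)
    out = 2.0 * p * (1.0 - p)
    return float(out) if out.ndim == 0 else out


def _pop_freq_counts(gm: GenotypeMatrix, mask: np.ndarray):
    """(freq, n_called) per SNP for the samples selected by mask."""
    d = gm.dosages[mask]
    ok = d != MISSING
    n = ok.sum(axis=0)
    s = np.where(ok, d, 0).sum(axis=0, dtype=np.int64)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, s / (2.0 * n), np.nan)
    return p, n


def population_diversity(gm: GenotypeMatrix, populations=None) -> pd.DataFrame:
    """He, Ho and % polymorphic SNPs per population.

    He and Ho are computed per SNP within the population (complete-case) and
    averaged over SNPs with at least one call.  A SNP is polymorphic in a
    population when both alleles are observed there.
    """
    rows = []
    for pop in (populations or gm.populations()):
        mask = gm.population_mask(pop)
        if mask.sum() < 2:
            raise ValueError(f"population {pop!r} has fewer than 2 individuals")
        p, n = _pop_freq_counts(gm, mask)
        called = n > 0
        he = expected_het(p[called])
        ho = gm.het_obs(rows=mask)[called]
        poly = (p[called] > 0) & (p[called] < 1)
        rows.append({
            "population": pop,
            "n": int(mask.sum()),
            "He": float(np.nanmean(he)),
            "Ho": float(np.nanmean(ho)),
            "pct_polymorphic": float(100.0 * poly.mean()),
        })
    return pd.DataFrame(rows)


def pairwise_fst(gm: GenotypeMatrix, pop_a: str, pop_b: str) -> float:
    """Pairwise FST = (HT - HS)/HT, averaged over loci before the ratio.

    Per SNP, with per-population complete-case frequencies pA, pB and call
    counts nA, nB: HT uses the size-weighted pooled frequency and HS is the
    size-weighted mean of the two within-population 2pq values.  SNPs
    monomorphic in the pooled pair (HT = 0) are excluded from both averages.
    """
    pa, na = _pop_freq_counts(gm, gm.population_mask(pop_a))
    pb, nb = _pop_freq_counts(gm, gm.population_mask(pop_b))
    ok = (na > 0) & (nb > 0)
    pa, pb = pa[ok], pb[ok]
    na, nb = na[ok].astype(float), nb[ok].astype(float)
    pbar = (na * pa + nb * pb) / (na + nb)
    ht = 2.0 * pbar * (1.0 - pbar)
    hs = (na * 2.0 * pa * (1.0 - pa) + nb * 2.0 * pb * (1.0 - pb)) / (na + nb)
    keep = ht > 0
    if not keep.any() or ht[keep].mean() == 0:
        warnings.warn("pair has no polymorphic SNPs; FST defined as 0")
        return 0.0
    HT = ht[keep].mean()
    HS = hs[keep].mean()
    return float((HT - HS) / HT)


def fst_matrix(gm: GenotypeMatrix, populations=None) -> pd.DataFrame:
    """Symmetric population x population FST matrix (diagonal 0)."""
    pops = populations or gm.populations()
    out = pd.DataFrame(0.0, index=pops, columns=pops)
    for i, a in enumerate(pops):
        for b in pops[i + 1:]:
            v = pairwise_fst(gm, a, b)
            out.loc[a, b] = out.loc[b, a] = v
    return out


def grm(gm: GenotypeMatrix, freqs: np.ndarray | None = None) -> np.ndarray:
    """VanRaden method-1 genomic relationship matrix.

    Columns are centred by twice the allele frequency (pooled-cohort
    frequencies by default) and the cross-product is scaled by
    ``sum_k 2 p_k (1 - p_k)``.  Missing dosages are replaced by ``2p``
    (zero after centring).  Monomorphic SNPs are dropped.
    """
    if gm.n_samples < 2:
        raise ValueError("need at least 2 individuals")
    p = gm.allele_freq() if freqs is None else np.asarray(freqs, dtype=float)
    keep = np.isfinite(p) & (p > 0) & (p < 1)
    if not keep.any():
        raise ValueError("all SNPs monomorphic; GRM denominator is zero")
    d = gm.dosages[:, keep].astype(float)
    p = p[keep]
    z = np.where(d == MISSING, 0.0, d - 2.0 * p)
    denom = float(np.sum(2.0 * p * (1.0 - p)))
    return (z @ z.T) / denom


@dataclass
class PCAResult:
    scores: np.ndarray          # n x k, eigenvectors scaled by sqrt(eigenvalue)
    eigenvalues: np.ndarray     # non-increasing
    variance_fraction: np.ndarray

    def to_dataframe(self, sample_ids=None, population=None) -> pd.DataFrame:
        df = pd.DataFrame(self.scores,
                          columns=[f"PC{i + 1}" for i in range(self.scores.shape[1])])
        if sample_ids is not None:
            df.insert(0, "sample_id", sample_ids)
        if population is not None:
            df.insert(1, "population", population)
        return df


def pca(G: np.ndarray, k: int = 10) -> PCAResult:
    """Eigendecomposition of a GRM; scores are sqrt(eigenvalue)-scaled.

    Variance fractions use eigenvalues floored at zero (small negative
    eigenvalues can arise numerically in a near-singular GRM).
    """
    G = np.asarray(G, dtype=float)
    n = G.shape[0]
    if n < 3:
        raise ValueError("PCA needs a GRM from at least 3 individuals")
    k = min(int(k), n)
    w, v = eigh((G + G.T) / 2.0)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    pos = np.maximum(w, 0.0)
    frac = pos / pos.sum() if pos.sum() > 0 else np.zeros_like(pos)
    scores = v[:, :k] * np.sqrt(pos[:k])
    return PCAResult(scores=scores, eigenvalues=w, variance_fraction=frac)
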
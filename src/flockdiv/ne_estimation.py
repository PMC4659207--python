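"""LD-based effective population size (single sample, random mating).

The pairwise statistic is the Burrows composite disequilibrium, which needs
no phase and no HWE assumption: with dosage vectors x, y over the S
complete-case individuals,

    Delta = cov(x, y) / 2
    r^2   = Delta^2 / [(p_x q_x + D_x)(p_y q_y + D_y)]

where ``D`` is each locus's homozygote-excess departure from HWE
(``P(hom_alt) - p^2``).  With all moments taken over the same sample, the
composite denominator equals half the dosage variance, so the composite
correlation reduces exactly to the squared Pearson correlation of the dosage
vectors — which is how it is computed here.

The sampling contribution to mean r^2 among unlinked loci is removed with
the standard bias correction for samples of S >= 30:

    E[r^2 | no drift] = 1/S + 3.19/S^2
    r2_drift = mean r^2 - E[...]
    Ne = (1/3 + sqrt(1/9 - 2.76 * r2_drift)) / (2 * r2_drift)

(r2_drift <= 0 yields an infinite estimate).  For S < 30 the small-sample
constants of the same method (0.0018 + 0.907/S + 4.44/S^2 and the
0.308/2.08 quadratic) are available behind ``allow_small_sample``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix, SNPMap
from .ld import nonsyntenic_ld  # noqa: F401  (re-exported companion baseline)

INFINITE = math.inf


@dataclass
class NeEstimate:
    population: str
    ne_hat: float            # INFINITE when r2_drift <= 0
    mean_r2: float
    r2_drift: float
    n_pairs: int
    harmonic_S: float
    pcrit: float


def burrows_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Composite (Burrows) r^2 for one locus pair from unphased dosages.

    Complete-case; raises when fewer than 2 shared calls or either locus is
    monomorphic in the shared subset.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = (x != MISSING) & (y != MISSING)
    x, y = x[ok], y[ok]
    if len(x) < 2:
        raise ValueError("fewer than 2 complete-case individuals")
    vx = x.var()
    vy = y.var()
    if vx == 0 or vy == 0:
        raise ValueError("monomorphic locus in the complete-case subset")
    delta = np.mean(x * y) - x.mean() * y.mean()  # = 2 * composite Delta
    return float((delta * delta) / (vx * vy))


def _pairwise_r2(X: np.ndarray, ii: np.ndarray, jj: np.ndarray, chunk: int = 200_000):
    """Vectorised composite r^2 and complete-case S for arbitrary pairs."""
    ok = (X != MISSING)
    Xf = np.where(ok, X, 0).astype(np.float64)
    okf = ok.astype(np.float64)
    r2 = np.full(len(ii), np.nan)
    S = np.zeros(len(ii))
    for lo in range(0, len(ii), chunk):
        hi = min(lo + chunk, len(ii))
        xi, yi = Xf[:, ii[lo:hi]], Xf[:, jj[lo:hi]]
        oi, oj = okf[:, ii[lo:hi]], okf[:, jj[lo:hi]]
        both = oi * oj
        n = both.sum(0)
        sx = (xi * both).sum(0)
        sy = (yi * both).sum(0)
        sxx = (xi * xi * both).sum(0)
        syy = (yi * yi * both).sum(0)
        sxy = (xi * yi * both).sum(0)
        with np.errstate(invalid="ignore", divide="ignore"):
            num = (n * sxy - sx * sy) ** 2
            den = (n * sxx - sx * sx) * (n * syy - sy * sy)
            r2[lo:hi] = np.where((n >= 2) & (den > 0), num / np.where(den > 0, den, 1.0),
                                 np.nan)
        S[lo:hi] = n
    return r2, S


def expected_sampling_r2(S: float, small_sample: bool = False) -> float:
    """Expected composite r^2 among unlinked loci from sampling alone."""
    if small_sample:
        return 0.0018 + 0.907 / S + 4.44 / (S * S)
    return 1.0 / S + 3.19 / (S * S)


def ne_from_r2(mean_r2: float, S: float, small_sample: bool = False) -> tuple[float, float]:
    """Bias-corrected Ne from a mean composite r^2 at harmonic sample size S.

    Returns ``(ne_hat, r2_drift)``; ``ne_hat`` is INFINITE when the drift
    signal is non-positive.
    """
    r2d = mean_r2 - expected_sampling_r2(S, small_sample)
    if r2d <= 0:
        return INFINITE, r2d
    if small_sample:
        disc = 0.308 ** 2 - 2.08 * r2d
        ne = (0.308 + math.sqrt(max(disc, 0.0))) / (2.0 * r2d)
    else:
        disc = 1.0 / 9.0 - 2.76 * r2d
        ne = (1.0 / 3.0 + math.sqrt(max(disc, 0.0))) / (2.0 * r2d)
    return ne, r2d


def estimate_ne(gm: GenotypeMatrix, smap: SNPMap, population: str | None = None,
                pcrit: float = 0.05, pairs: str = "nonsyntenic",
                fraction: float = 0.05, seed: int = 0,
                allow_small_sample: bool = False) -> NeEstimate:
    """LD-based Ne for one population.

    SNPs with within-population MAF below ``pcrit`` are screened out.  The
    default pair set is the cross-chromosome (non-syntenic) pairs of a seeded
    per-autosome subsample (``fraction`` of SNPs per chromosome), which
    satisfies the unlinked-loci assumption of the bias correction;
    ``pairs='all'`` uses every pair, syntenic included, for comparability
    with tools that default to that (at the cost of a known downward bias in
    Ne from physical linkage).  Mean r^2 is weighted by per-pair
    complete-case sample size; the correction uses the harmonic mean S.
    """
    rows = np.ones(gm.n_samples, bool) if population is None \
        else gm.population_mask(population)
    S_pop = int(rows.sum())
    if S_pop < 30 and not allow_small_sample:
        raise ValueError("sample size < 30: small-sample bias constants required "
                         "(set allow_small_sample=True)")
    X = gm.dosages[rows]
    p = gm.allele_freq(rows=rows)
    maf = np.minimum(p, 1 - p)
    keep = np.flatnonzero(np.isfinite(maf) & (maf >= pcrit))
    if len(keep) < 2:
        raise ValueError("fewer than 2 SNPs pass the pcrit screen")

    chroms = smap.chromosomes()
    chrom_of = smap.chrom
    if pairs == "nonsyntenic":
        rng = np.random.default_rng(seed)
        picks = []
        for c in chroms:
            idx = keep[chrom_of[keep] == c]
            if len(idx) == 0:
                continue
            k = max(1, math.ceil(fraction * len(idx)))
            picks.append(np.sort(rng.choice(idx, size=min(k, len(idx)), replace=False)))
        if len(picks) < 2:
            raise ValueError("non-syntenic pairs need SNPs on >= 2 chromosomes")
        ii_l, jj_l = [], []
        for a in range(len(picks)):
            for b in range(a + 1, len(picks)):
                gi, gj = np.meshgrid(picks[a], picks[b], indexing="ij")
                ii_l.append(gi.ravel())
                jj_l.append(gj.ravel())
        ii, jj = np.concatenate(ii_l), np.concatenate(jj_l)
    elif pairs == "all":
        iu = np.triu_indices(len(keep), k=1)
        ii, jj = keep[iu[0]], keep[iu[1]]
    else:
        raise ValueError("pairs must be 'nonsyntenic' or 'all'")

    r2, S = _pairwise_r2(X, ii, jj)
    ok = np.isfinite(r2) & (S >= 3)
    if not ok.any():
        raise ValueError("no valid locus pairs")
    r2, S = r2[ok], S[ok]
    # the sampling expectation 1/S + 3.19/S^2 is calibrated for the Burrows
    # estimator carrying the S/(S-1) small-sample correction on Delta; the
    # composite correlation must be put on that scale before the floor is
    # subtracted, or the drift signal of large populations is swamped
    r2 = r2 * (S / (S - 1.0)) ** 2
    mean_r2 = float(np.average(r2, weights=S))
    harm_S = float(len(S) / np.sum(1.0 / S))
    small = harm_S < 30
    ne, r2d = ne_from_r2(mean_r2, harm_S, small_sample=small)
    return NeEstimate(population=population or "ALL", ne_hat=ne, mean_r2=mean_r2,
                      r2_drift=r2d, n_pairs=int(ok.sum()), harmonic_S=harm_S,
                      pcrit=pcrit)


def ne_table(gm: GenotypeMatrix, smap: SNPMap, populations=None, **kwargs) -> pd.DataFrame:
    """Ne estimates for several populations as a tidy table."""
    rows = []
    for pop in (populations or gm.populations()):
        est = estimate_ne(gm, smap, pop, **kwargs)
        rows.append({"population": pop, "Ne": est.ne_hat, "mean_r2": est.mean_r2,
                     "r2_drift": est.r2_drift, "n_pairs": est.n_pairs,
                     "harmonic_S": est.harmonic_S})
    return pd.DataFrame(rows)
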
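"""Pairwise linkage disequilibrium from unphased genotypes.

Haplotype frequencies for a pair of biallelic SNPs are estimated by EM on the
3x3 genotype table: only double heterozygotes are phase-ambiguous, and each
iteration splits them between the coupling (AB/ab) and repulsion (Ab/aB)
phases in the ratio ``f_AB*f_ab : f_Ab*f_aB``.  From the fitted frequencies
the module computes r^2 and D', the likelihood-grid one-sided confidence
bounds on D' used by the Gabriel block definition, distance-binned decay
tables (14 bins, <10 kb to >50 Mb), adjacent-SNP LD per chromosome, and a
non-syntenic (cross-chromosome) baseline from a seeded SNP subsample.

Individuals missing either genotype of a pair are dropped for that pair
(complete-case, as in Haploview); pairs monomorphic in the complete-case
subset are skipped and counted.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import GenotypeMatrix, SNPMap

log = logging.getLogger(__name__)

EM_TOL = 1e-10
EM_MAX_ITER = 1000

#: lower edges (bp) of the 14 half-open [low, high) distance bins
DEFAULT_BIN_EDGES_BP = np.array(
    [0, 10, 20, 40, 60, 100, 200, 500, 1000, 2000, 5000, 10000, 20000, 50000],
    dtype=np.int64) * 1000

BIN_LABELS = ["<10 kb", "10-20 kb", "20-40 kb", "40-60 kb", "60-100 kb",
              "100-200 kb", "200-500 kb", "500 kb-1 Mb", "1-2 Mb", "2-5 Mb",
              "5-10 Mb", "10-20 Mb", "20-50 Mb", ">50 Mb"]


@dataclass
class HaplotypeFreqs:
    """EM-fitted haplotype frequencies for one SNP pair.

    ``A``/``B`` denote the dosage-counted alleles at the first and second
    locus; lowercase the alternatives.  Frequencies sum to 1 and their
    marginals equal the sample allele frequencies.
    """

    f_AB: float
    f_Ab: float
    f_aB: float
    f_ab: float
    loglik: float
    em_iterations: int

    @property
    def p_A(self) -> float:
        return self.f_AB + self.f_Ab

    @property
    def p_B(self) -> float:
        return self.f_AB + self.f_aB


# ---------------------------------------------------------------------------
# genotype-pair tables
# ---------------------------------------------------------------------------

def genotype_pair_table(gx: np.ndarray, gy: np.ndarray) -> np.ndarray:
    """3x3 complete-case genotype count table for one SNP pair."""
    gx = np.asarray(gx)
    gy = np.asarray(gy)
    ok = (gx >= 0) & (gy >= 0)
    n = np.zeros((3, 3), dtype=np.int64)
    np.add.at(n, (gx[ok].astype(int), gy[ok].astype(int)), 1)
    return n


def _counts_for_pairs(X: np.ndarray, ii: np.ndarray, jj: np.ndarray,
                      chunk: int = 200_000):
    """Yield (slice, counts (C,3,3)) for an arbitrary pair list.

    ``X`` is samples x SNPs int8 dosage with -1 missing.
    """
    P = len(ii)
    ind = [(X == a) for a in (0, 1, 2)]
    for lo in range(0, P, chunk):
        hi = min(lo + chunk, P)
        i_c, j_c = ii[lo:hi], jj[lo:hi]
        n = np.empty((hi - lo, 3, 3), dtype=np.float64)
        for a in range(3):
            Ai = ind[a][:, i_c]
            for b in range(3):
                n[:, a, b] = np.einsum("sp,sp->p", Ai, ind[b][:, j_c],
                                       dtype=np.float64)
        yield slice(lo, hi), n


def _counts_allpairs_blocks(X: np.ndarray, pos: np.ndarray,
                            max_dist: int | None = None,
                            block: int = 1200, chunk: int = 300_000):
    """Yield (ii, jj, counts) over all i<j pairs of one chromosome.

    Genotype-class cross-products are computed blockwise with BLAS matmuls;
    pairs farther apart than ``max_dist`` (bp) are omitted when given.
    """
    m = X.shape[1]
    ind = [(X == a).astype(np.float32) for a in (0, 1, 2)]
    for b0 in range(0, m, block):
        b1 = min(b0 + block, m)
        for c0 in range(b0, m, block):
            c1 = min(c0 + block, m)
            if max_dist is not None and pos[c0] - pos[b1 - 1] > max_dist:
                break
            grams = [[ind[a][:, b0:b1].T @ ind[b][:, c0:c1] for b in range(3)]
                     for a in range(3)]
            if b0 == c0:
                iu = np.triu_indices(b1 - b0, k=1)
                ii_loc, jj_loc = iu
            else:
                ii_loc, jj_loc = np.meshgrid(np.arange(b1 - b0), np.arange(c1 - c0),
                                             indexing="ij")
                ii_loc, jj_loc = ii_loc.ravel(), jj_loc.ravel()
            ii = ii_loc + b0
            jj = jj_loc + c0
            if max_dist is not None:
                keep = (pos[jj] - pos[ii]) <= max_dist
                ii, jj, ii_loc, jj_loc = ii[keep], jj[keep], ii_loc[keep], jj_loc[keep]
            for lo in range(0, len(ii), chunk):
                hi = min(lo + chunk, len(ii))
                n = np.empty((hi - lo, 3, 3), dtype=np.float64)
                for a in range(3):
                    for b in range(3):
                        n[:, a, b] = grams[a][b][ii_loc[lo:hi], jj_loc[lo:hi]]
                yield ii[lo:hi], jj[lo:hi], n


# ---------------------------------------------------------------------------
# EM
# ---------------------------------------------------------------------------

def _em_batch(n: np.ndarray, tol: float = EM_TOL, max_iter: int = EM_MAX_ITER):
    """Vectorised EM over a batch of 3x3 genotype tables.

    Returns dict with haplotype frequencies ``f11, f10, f01, f00`` (1 = the
    dosage-counted allele), allele frequencies, sample sizes, per-pair
    iteration counts, log-likelihoods and a validity mask (>=2 complete-case
    individuals, both loci polymorphic).
    """
    n = np.asarray(n, dtype=np.float64)
    c11f = 2 * n[:, 2, 2] + n[:, 2, 1] + n[:, 1, 2]
    c10f = 2 * n[:, 2, 0] + n[:, 2, 1] + n[:, 1, 0]
    c01f = 2 * n[:, 0, 2] + n[:, 0, 1] + n[:, 1, 2]
    c00f = 2 * n[:, 0, 0] + n[:, 0, 1] + n[:, 1, 0]
    dh = n[:, 1, 1]
    S = n.sum(axis=(1, 2))
    twoS = np.where(S > 0, 2.0 * S, 1.0)
    p1 = (c11f + c10f + dh) / twoS
    p2 = (c11f + c01f + dh) / twoS
    valid = (S >= 2) & (p1 > 0) & (p1 < 1) & (p2 > 0) & (p2 < 1)

    # linkage-equilibrium initialisation
    f11 = p1 * p2
    f10 = p1 * (1 - p2)
    f01 = (1 - p1) * p2
    f00 = (1 - p1) * (1 - p2)
    iters = np.zeros(len(n), dtype=np.int32)
    # pairs with no double heterozygote are phase-resolved: EM fixed after one step
    active = np.flatnonzero(valid)
    a11, a10, a01, a00 = (x[active] for x in (f11, f10, f01, f00))
    ac11, ac10, ac01, ac00 = (x[active] for x in (c11f, c10f, c01f, c00f))
    adh, a2S = dh[active], twoS[active]
    for it in range(1, max_iter + 1):
        num = a11 * a00
        den = num + a10 * a01
        w = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.5)
        t = adh * w
        g11 = (ac11 + t) / a2S
        g00 = (ac00 + t) / a2S
        g10 = (ac10 + adh - t) / a2S
        g01 = (ac01 + adh - t) / a2S
        delta = np.maximum(np.maximum(np.abs(g11 - a11), np.abs(g10 - a10)),
                           np.maximum(np.abs(g01 - a01), np.abs(g00 - a00)))
        a11, a10, a01, a00 = g11, g10, g01, g00
        conv = delta < tol
        if conv.any():
            idx = active[conv]
            f11[idx], f10[idx], f01[idx], f00[idx] = \
                a11[conv], a10[conv], a01[conv], a00[conv]
            iters[idx] = it
            keep = ~conv
            if not keep.any():
                active = active[:0]
                break
            active = active[keep]
            a11, a10, a01, a00 = a11[keep], a10[keep], a01[keep], a00[keep]
            ac11, ac10, ac01, ac00 = ac11[keep], ac10[keep], ac01[keep], ac00[keep]
            adh, a2S = adh[keep], a2S[keep]
    if len(active):
        f11[active], f10[active], f01[active], f00[active] = a11, a10, a01, a00
        iters[active] = max_iter

    loglik = _table_loglik(n, f11, f10, f01, f00)
    return {"f11": f11, "f10": f10, "f01": f01, "f00": f00,
            "p1": p1, "p2": p2, "S": S, "iters": iters,
            "loglik": loglik, "valid": valid}


def _table_loglik(n, f11, f10, f01, f00):
    """Multinomial log-likelihood of 3x3 genotype tables given haplotype freqs."""
    probs = _genotype_probs(f11, f10, f01, f00)
    lp = np.log(np.where(probs > 0, probs, 1.0))  # cells with n=0 contribute 0
    bad = (n > 0) & (probs <= 0)
    terms = n * lp
    out = terms.sum(axis=(1, 2))
    out[bad.any(axis=(1, 2))] = -np.inf
    return out


def _genotype_probs(f11, f10, f01, f00):
    """Genotype-pair probabilities (...,3,3) assuming random union of haplotypes."""
    shape = np.broadcast(f11, f10).shape + (3, 3)
    p = np.empty(shape)
    p[..., 0, 0] = f00 ** 2
    p[..., 0, 1] = 2 * f00 * f01
    p[..., 0, 2] = f01 ** 2
    p[..., 1, 0] = 2 * f00 * f10
    p[..., 1, 1] = 2 * (f11 * f00 + f10 * f01)
    p[..., 1, 2] = 2 * f01 * f11
    p[..., 2, 0] = f10 ** 2
    p[..., 2, 1] = 2 * f10 * f11
    p[..., 2, 2] = f11 ** 2
    return p


def em_haplotype_freqs(gx: np.ndarray, gy: np.ndarray,
                       max_iter: int = EM_MAX_ITER) -> HaplotypeFreqs:
    """EM haplotype frequency estimate for one SNP pair (complete-case)."""
    n = genotype_pair_table(gx, gy)
    if n.sum() < 2:
        raise ValueError("fewer than 2 individuals with both genotypes called")
    res = _em_batch(n[None], max_iter=max_iter)
    if not res["valid"][0]:
        raise ValueError("a locus is monomorphic in the complete-case subset; LD undefined")
    return HaplotypeFreqs(
        f_AB=float(res["f11"][0]), f_Ab=float(res["f10"][0]),
        f_aB=float(res["f01"][0]), f_ab=float(res["f00"][0]),
        loglik=float(res["loglik"][0]), em_iterations=int(res["iters"][0]))


# ---------------------------------------------------------------------------
# r^2 and D'
# ---------------------------------------------------------------------------

def _ld_stats_arrays(f11, f10, f01, f00):
    p1 = f11 + f10
    p2 = f11 + f01
    q1 = 1.0 - p1
    q2 = 1.0 - p2
    D = f11 - p1 * p2
    denom = p1 * q1 * p2 * q2
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(denom > 0, D * D / np.where(denom > 0, denom, 1.0), np.nan)
        dmax = np.where(D > 0, np.minimum(p1 * q2, q1 * p2),
                        np.minimum(p1 * p2, q1 * q2))
        dp = np.where(D == 0, 0.0,
                      np.abs(D) / np.where(dmax > 0, dmax, np.nan))
    return np.clip(r2, 0, 1), np.clip(dp, 0, 1)


def ld_stats(hf: HaplotypeFreqs) -> tuple[float, float]:
    """(r^2, D') from haplotype frequencies.

    D = f_AB - p_A p_B; r^2 = D^2 / (p_A q_A p_B q_B); D' = |D| / Dmax with
    the standard convention Dmax = min(p_A q_B, q_A p_B) for D > 0 and
    min(p_A p_B, q_A q_B) for D < 0 (D' = 0 when D = 0).
    """
    r2, dp = _ld_stats_arrays(np.array([hf.f_AB]), np.array([hf.f_Ab]),
                              np.array([hf.f_aB]), np.array([hf.f_ab]))
    if not np.isfinite(r2[0]):
        raise ValueError("a marginal allele frequency is 0; LD undefined")
    return float(r2[0]), float(dp[0])


# ---------------------------------------------------------------------------
# D' confidence bounds (likelihood grid, Gabriel construction)
# ---------------------------------------------------------------------------

def _dprime_ci_batch(n: np.ndarray, grid_step: float = 0.01):
    """One-sided 95% likelihood bounds on D' for a batch of genotype tables.

    The table likelihood is evaluated on a D' grid (step ``grid_step``) with
    allele frequencies held at their MLEs and the sign of D fixed at its EM
    estimate; the normalised likelihood is treated as a discrete distribution
    and the 5th/95th cumulative grid points reported.  Degenerate tables get
    the uninformative bounds (0, 1).
    """
    res = _em_batch(n)
    p1, p2 = res["p1"], res["p2"]
    D = res["f11"] - p1 * p2
    flip = D < 0
    n_use = np.where(flip[:, None, None], n[:, :, ::-1], n)
    p2 = np.where(flip, 1.0 - p2, p2)
    q1, q2 = 1.0 - p1, 1.0 - p2
    dmax = np.minimum(p1 * q2, q1 * p2)
    grid = np.arange(0.0, 1.0 + grid_step / 2, grid_step)
    G = len(grid)
    ci_low = np.zeros(len(n))
    ci_high = np.ones(len(n))
    ok = res["valid"] & (dmax > 0)
    if ok.any():
        d = dmax[ok, None] * grid[None, :]
        P1, P2 = p1[ok, None], p2[ok, None]
        f11 = np.clip(P1 * P2 + d, 1e-12, None)
        f10 = np.clip(P1 * (1 - P2) - d, 1e-12, None)
        f01 = np.clip((1 - P1) * P2 - d, 1e-12, None)
        f00 = np.clip((1 - P1) * (1 - P2) + d, 1e-12, None)
        probs = _genotype_probs(f11, f10, f01, f00)  # (P,G,3,3)
        ll = np.einsum("pab,pgab->pg", n_use[ok],
                       np.log(np.clip(probs, 1e-300, None)))
        ll -= ll.max(axis=1, keepdims=True)
        w = np.exp(ll)
        cum = np.cumsum(w, axis=1) / w.sum(axis=1, keepdims=True)
        ci_low[ok] = grid[np.argmax(cum >= 0.05, axis=1)]
        ci_high[ok] = grid[np.argmax(cum >= 0.95, axis=1)]
    return ci_low, ci_high, ok


def dprime_confidence_bounds(gx: np.ndarray, gy: np.ndarray,
                             grid_step: float = 0.01) -> tuple[float, float]:
    """One-sided 95% D' confidence bounds for a single SNP pair."""
    n = genotype_pair_table(gx, gy)
    lo, hi, ok = _dprime_ci_batch(n[None], grid_step=grid_step)
    return float(lo[0]), float(hi[0])


# ---------------------------------------------------------------------------
# population-level tables
# ---------------------------------------------------------------------------

@dataclass
class LDDecayResult:
    population: str
    table: pd.DataFrame            # 14 distance bins
    per_chromosome: pd.DataFrame   # all-pairs means per chromosome
    n_pairs: int
    n_skipped: int                 # pairs undefined (monomorphic in subset)


def _pop_matrix(gm: GenotypeMatrix, population: str | None):
    if population is None:
        return gm.dosages
    return gm.dosages[gm.population_mask(population)]


def ld_decay(gm: GenotypeMatrix, smap: SNPMap, population: str | None = None,
             bin_edges_bp: np.ndarray = DEFAULT_BIN_EDGES_BP,
             max_distance_bp: int | None = None) -> LDDecayResult:
    """Distance-binned mean r^2 and D' over all syntenic pairs.

    Bins are half-open ``[low, high)`` on |pos_i - pos_j|.  Also returns
    all-pairs means per chromosome.  ``max_distance_bp`` optionally caps the
    evaluated pair distance for large panels (default: exact, all pairs).
    """
    X = _pop_matrix(gm, population)
    nb = len(bin_edges_bp)
    sum_r2 = np.zeros(nb)
    sum_dp = np.zeros(nb)
    cnt = np.zeros(nb, dtype=np.int64)
    chrom_rows = []
    skipped = 0
    for c in smap.chromosomes():
        idx = smap.chrom_indices(c)
        if len(idx) < 2:
            continue
        Xc = X[:, idx]
        pos = smap.pos_bp[idx]
        c_r2_sum = c_dp_sum = 0.0
        c_n = 0
        for ii, jj, n in _counts_allpairs_blocks(Xc, pos, max_dist=max_distance_bp):
            res = _em_batch(n)
            ok = res["valid"]
            skipped += int((~ok).sum())
            if not ok.any():
                continue
            r2, dp = _ld_stats_arrays(res["f11"][ok], res["f10"][ok],
                                      res["f01"][ok], res["f00"][ok])
            dist = pos[jj[ok]] - pos[ii[ok]]
            b = np.searchsorted(bin_edges_bp, dist, side="right") - 1
            np.add.at(sum_r2, b, r2)
            np.add.at(sum_dp, b, dp)
            np.add.at(cnt, b, 1)
            c_r2_sum += r2.sum()
            c_dp_sum += dp.sum()
            c_n += len(r2)
        chrom_rows.append({"chrom": c, "n_pairs": c_n,
                           "mean_r2": c_r2_sum / c_n if c_n else np.nan,
                           "mean_dprime": c_dp_sum / c_n if c_n else np.nan})
    with np.errstate(invalid="ignore", divide="ignore"):
        table = pd.DataFrame({
            "bin": BIN_LABELS[:nb],
            "low_bp": bin_edges_bp,
            "high_bp": np.append(bin_edges_bp[1:], -1),
            "n_pairs": cnt,
            "mean_r2": np.where(cnt > 0, sum_r2 / np.maximum(cnt, 1), np.nan),
            "mean_dprime": np.where(cnt > 0, sum_dp / np.maximum(cnt, 1), np.nan),
        })
    return LDDecayResult(population=population or "ALL", table=table,
                         per_chromosome=pd.DataFrame(chrom_rows),
                         n_pairs=int(cnt.sum()), n_skipped=skipped)


def adjacent_ld(gm: GenotypeMatrix, smap: SNPMap,
                population: str | None = None) -> pd.DataFrame:
    """Mean r^2 over consecutive-SNP pairs, per chromosome."""
    X = _pop_matrix(gm, population)
    rows = []
    for c in smap.chromosomes():
        idx = smap.chrom_indices(c)
        if len(idx) < 2:
            rows.append({"chrom": c, "n_pairs": 0, "mean_r2": np.nan})
            continue
        ii, jj = idx[:-1], idx[1:]
        r2s = []
        for sl, n in _counts_for_pairs(X, ii, jj):
            res = _em_batch(n)
            ok = res["valid"]
            r2, _ = _ld_stats_arrays(res["f11"][ok], res["f10"][ok],
                                     res["f01"][ok], res["f00"][ok])
            r2s.append(r2)
        r2 = np.concatenate(r2s) if r2s else np.array([])
        rows.append({"chrom": c, "n_pairs": len(r2),
                     "mean_r2": float(r2.mean()) if len(r2) else np.nan})
    return pd.DataFrame(rows)


@dataclass
class NonSyntenicLD:
    population: str
    mean_r2: float
    mean_dprime: float
    n_pairs: int
    snp_indices: np.ndarray


def nonsyntenic_ld(gm: GenotypeMatrix, smap: SNPMap, population: str | None = None,
                   fraction: float = 0.05, seed: int = 0) -> NonSyntenicLD:
    """Mean LD among cross-chromosome pairs of a seeded SNP subsample.

    ``ceil(fraction * n_c)`` SNPs are drawn per autosome with a seeded RNG;
    r^2/D' are averaged over every cross-chromosome pair of the sample,
    giving the no-linkage baseline.
    """
    chroms = smap.chromosomes()
    if len(chroms) < 2:
        raise ValueError("non-syntenic LD needs at least 2 chromosomes")
    rng = np.random.default_rng(seed)
    picks = []
    for c in chroms:
        idx = smap.chrom_indices(c)
        k = max(1, math.ceil(fraction * len(idx)))
        picks.append(np.sort(rng.choice(idx, size=min(k, len(idx)), replace=False)))
    X = _pop_matrix(gm, population)
    ii_all, jj_all = [], []
    for a in range(len(picks)):
        for b in range(a + 1, len(picks)):
            i_g, j_g = np.meshgrid(picks[a], picks[b], indexing="ij")
            ii_all.append(i_g.ravel())
            jj_all.append(j_g.ravel())
    ii = np.concatenate(ii_all)
    jj = np.concatenate(jj_all)
    r2s, dps = [], []
    for sl, n in _counts_for_pairs(X, ii, jj):
        res = _em_batch(n)
        ok = res["valid"]
        r2, dp = _ld_stats_arrays(res["f11"][ok], res["f10"][ok],
                                  res["f01"][ok], res["f00"][ok])
        r2s.append(r2)
        dps.append(dp)
    r2 = np.concatenate(r2s) if r2s else np.array([])
    dp = np.concatenate(dps) if dps else np.array([])
    return NonSyntenicLD(population=population or "ALL",
                         mean_r2=float(r2.mean()) if len(r2) else np.nan,
                         mean_dprime=float(dp.mean()) if len(dp) else np.nan,
                         n_pairs=len(r2),
                         snp_indices=np.concatenate(picks))
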
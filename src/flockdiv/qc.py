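"""SNP and sample quality control for array genotype panels.

Filters mirror standard array QC practice: removal of non-autosomal and
unmapped markers, optional GenCall (GC) score screen, SNP call rate, minor
allele frequency, an exact Hardy-Weinberg test with a very stringent cut-off
(appropriate at array scale, where a chi-square approximation would be
meaningless at p ~ 1e-15), and a heterozygosity-outlier screen.  Each removed
SNP is attributed to exactly one reason — the first failing rule in the
documented order — so the per-reason counts are mutually exclusive and sum,
with the survivors, to the input SNP count.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .genotype_io import MISSING, GenotypeMatrix, QualityAnnotations, SNPMap

log = logging.getLogger(__name__)

#: filter order; each SNP is attributed to the first failing rule
FILTER_ORDER = ("non_autosomal", "unmapped", "low_gc", "low_call_rate",
                "low_maf", "hwe", "het_outlier")

_SEX_LABELS = {"X", "Y", "XY", "MT", "M", "W", "Z"}


@dataclass
class QCConfig:
    """Thresholds for :func:`apply_qc`.

    Defaults: SNP call rate >= 0.95, GC score >= 0.6 (only when GC scores are
    supplied), MAF >= 0.01, exact HWE p > 1e-15, heterozygosity within 3 SD of
    the panel mean.  The individual call-rate filter defaults to report-only
    (threshold 0).
    """

    min_snp_call_rate: float = 0.95
    min_gc: float = 0.6
    min_maf: float = 0.01
    hwe_p_cutoff: float = 1e-15
    het_sd_limit: float = 3.0
    min_ind_call_rate: float = 0.0


@dataclass
class QCReport:
    n_input: int
    removed: dict[str, int]
    removed_ids: dict[str, list]
    surviving_idx: np.ndarray
    surviving_ids: list
    low_call_rate_individuals: list = field(default_factory=list)

    @property
    def n_surviving(self) -> int:
        return len(self.surviving_idx)

    def to_dataframe(self) -> pd.DataFrame:
        rows = [{"reason": r, "n_removed": self.removed.get(r, 0)} for r in FILTER_ORDER]
        rows.append({"reason": "surviving", "n_removed": self.n_surviving})
        return pd.DataFrame(rows)


def snp_call_rate(gm: GenotypeMatrix) -> np.ndarray:
    """Fraction of non-missing calls per SNP."""
    if gm.n_samples < 1:
        raise ValueError("need at least one individual")
    return gm.snp_call_rate()


def minor_allele_frequency(gm: GenotypeMatrix, rows: np.ndarray | None = None) -> np.ndarray:
    """MAF per SNP over non-missing calls; NaN for all-missing SNPs."""
    p = gm.allele_freq(rows)
    return np.minimum(p, 1.0 - p)


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided exact Hardy-Weinberg test.

    Conditional on the observed allele counts, sums the probabilities of all
    heterozygote counts (same parity as the observed one) whose conditional
    probability does not exceed that of the observed configuration.
    Monomorphic samples return p = 1 by convention.
    """
    n_AA, n_Aa, n_aa = int(n_AA), int(n_Aa), int(n_aa)
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("negative genotype count")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("no genotypes")
    n_a = 2 * n_aa + n_Aa  # minor-side allele count (symmetry makes choice irrelevant)
    rare = min(n_a, 2 * n - n_a)
    if rare == 0:
        return 1.0
    hets = np.arange(rare % 2, rare + 1, 2)
    # log P(h | n, rare) up to a constant: multinomial over (hom_rare, het, hom_common)
    hom_r = (rare - hets) // 2
    hom_c = n - hets - hom_r
    logp = hets * np.log(2.0) - (gammaln(hom_r + 1) + gammaln(hets + 1) + gammaln(hom_c + 1))
    logp -= logp.max()
    prob = np.exp(logp)
    prob /= prob.sum()
    obs = min(n_Aa, rare)  # observed het count (clipped for safety)
    p_obs = prob[np.searchsorted(hets, obs)]
    return float(min(1.0, prob[prob <= p_obs * (1 + 1e-12)].sum()))


def hwe_pvalues(gm: GenotypeMatrix) -> np.ndarray:
    """Exact HWE p-value per SNP on the pooled cohort (complete-case)."""
    d = gm.dosages
    n2 = (d == 2).sum(axis=0)
    n1 = (d == 1).sum(axis=0)
    n0 = (d == 0).sum(axis=0)
    out = np.ones(gm.n_snps)
    cache: dict[tuple[int, int, int], float] = {}
    for j in range(gm.n_snps):
        key = (int(n2[j]), int(n1[j]), int(n0[j]))
        if key not in cache:
            cache[key] = hwe_exact_test(*key) if sum(key) > 0 else 1.0
        out[j] = cache[key]
    return out


def het_outlier_flags(gm: GenotypeMatrix, het_sd_limit: float = 3.0,
                      snp_mask: np.ndarray | None = None) -> np.ndarray:
    """Flag SNPs whose observed heterozygosity deviates from the panel mean.

    Mean and SD are taken over the SNPs selected by ``snp_mask`` (all SNPs by
    default), pooled across samples.  Zero SD yields no flags.
    """
    if gm.n_snps < 2:
        raise ValueError("need at least two SNPs")
    ho = gm.het_obs()
    mask = np.ones(gm.n_snps, bool) if snp_mask is None else np.asarray(snp_mask, bool)
    vals = ho[mask & ~np.isnan(ho)]
    flags = np.zeros(gm.n_snps, bool)
    if len(vals) < 2 or not np.isfinite(het_sd_limit):
        return flags
    mu, sd = vals.mean(), vals.std(ddof=1)
    if sd == 0:
        return flags
    with np.errstate(invalid="ignore"):
        flags = np.abs(ho - mu) > het_sd_limit * sd
    return np.where(np.isnan(ho), False, flags) & mask


def _is_autosome(chrom: np.ndarray) -> np.ndarray:
    return np.array([str(c).isdigit() and int(c) > 0 for c in chrom])


def apply_qc(gm: GenotypeMatrix, smap: SNPMap,
             annotations: QualityAnnotations | None = None,
             config: QCConfig | None = None):
    """Apply the SNP filters in the documented order and report removals.

    Order: (1) non-autosomal, (2) unmapped, (3) GC score (when supplied),
    (4) SNP call rate, (5) MAF, (6) exact HWE, (7) heterozygosity outlier.
    MAF, HWE and the het screen are computed on the pooled cohort.

    Returns ``(filtered GenotypeMatrix, filtered SNPMap, QCReport)``.
    """
    config = config or QCConfig()
    m = gm.n_snps
    alive = np.ones(m, bool)
    removed: dict[str, int] = {}
    removed_ids: dict[str, list] = {}

    def drop(reason: str, fail: np.ndarray):
        hit = alive & fail
        removed[reason] = int(hit.sum())
        removed_ids[reason] = list(smap.snp_id[hit])
        alive[hit] = False

    auto = _is_autosome(smap.chrom)
    sexchrom = np.array([str(c).upper() in _SEX_LABELS for c in smap.chrom])
    drop("non_autosomal", ~auto & sexchrom)
    drop("unmapped", ~auto | (smap.pos_bp <= 0))

    if annotations is not None and annotations.gc_score is not None:
        drop("low_gc", np.nan_to_num(annotations.gc_score, nan=0.0) < config.min_gc)
    else:
        removed["low_gc"] = 0
        removed_ids["low_gc"] = []

    drop("low_call_rate", snp_call_rate(gm) < config.min_snp_call_rate)

    maf = minor_allele_frequency(gm)
    drop("low_maf", np.isnan(maf) | (maf < config.min_maf))

    pvals = hwe_pvalues(gm)
    drop("hwe", pvals < config.hwe_p_cutoff)

    drop("het_outlier", het_outlier_flags(gm, config.het_sd_limit, snp_mask=alive))

    if not alive.any():
        raise ValueError("all SNPs removed by QC; review thresholds")

    low_ind = gm.ind_call_rate() < config.min_ind_call_rate
    if low_ind.any():
        warnings.warn(f"{int(low_ind.sum())} individuals below call-rate threshold "
                      "(report-only; no individuals removed)")

    idx = np.flatnonzero(alive)
    report = QCReport(
        n_input=m, removed=removed, removed_ids=removed_ids,
        surviving_idx=idx, surviving_ids=list(smap.snp_id[idx]),
        low_call_rate_individuals=list(gm.sample_ids[low_ind]),
    )
    assert sum(removed.values()) + report.n_surviving == m
    return gm.subset_snps(idx), smap.subset(idx), report
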
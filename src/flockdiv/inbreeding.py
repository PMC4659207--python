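"""Marker-based inbreeding coefficients (GCTA-style F1, F2, F3).

With ``x`` the dosage of the counted allele and ``p`` its frequency in the
individual's own population (q = 1 - p), the per-SNP terms are

    t1 = (x - 2p)^2 / (2pq) - 1          variance of the additive genotype
    t2 = 1 - x(2 - x) / (2pq)            excess of homozygotes
    t3 = (x^2 - (1 + 2p)x + 2p^2) / (2pq)  correlation between uniting gametes

and each coefficient is the mean of its term over the individual's
non-missing, within-population-polymorphic SNPs.  Frequencies are computed
within population, which is what yields the negative (outbred) coefficients
of F1 crosses between diverged parental breeds.  All three terms have
expectation 0 under Hardy-Weinberg proportions and are invariant to swapping
the allele labels (x -> 2 - x with p -> 1 - p).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix


def f_coefficients(gm: GenotypeMatrix, populations=None,
                   f2_form: str = "mean_of_ratios") -> pd.DataFrame:
    """Per-individual F1/F2/F3 using within-population allele frequencies.

    SNPs monomorphic within a population are skipped there (counted in the
    ``n_snps_used`` column as excluded).  ``f2_form='ratio_of_sums'``
    switches F2 to the summed-numerator / summed-denominator variant some
    tools use; the default averages per-SNP ratios with equal weights.
    """
    if f2_form not in ("mean_of_ratios", "ratio_of_sums"):
        raise ValueError("f2_form must be 'mean_of_ratios' or 'ratio_of_sums'")
    frames = []
    for pop in (populations or gm.populations()):
        mask = gm.population_mask(pop)
        if mask.sum() < 2:
            raise ValueError(f"population {pop!r} has fewer than 2 individuals")
        d = gm.dosages[mask].astype(float)
        ok = d != MISSING
        n = ok.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n > 0, np.where(ok, d, 0).sum(axis=0) / (2.0 * n), np.nan)
        poly = np.isfinite(p) & (p > 0) & (p < 1)
        x = d[:, poly]
        use = ok[:, poly]
        pp = p[poly]
        two_pq = 2.0 * pp * (1.0 - pp)
        t1 = (x - 2 * pp) ** 2 / two_pq - 1.0
        t2_num = x * (2.0 - x)
        t3 = (x * x - (1.0 + 2.0 * pp) * x + 2.0 * pp * pp) / two_pq
        cnt = use.sum(axis=1)
        f1 = np.where(use, t1, 0.0).sum(axis=1) / cnt
        f3 = np.where(use, t3, 0.0).sum(axis=1) / cnt
        if f2_form == "mean_of_ratios":
            f2 = np.where(use, 1.0 - t2_num / two_pq, 0.0).sum(axis=1) / cnt
        else:
            denom = np.where(use, two_pq, 0.0).sum(axis=1)
            f2 = 1.0 - np.where(use, t2_num, 0.0).sum(axis=1) / denom
        frames.append(pd.DataFrame({
            "sample_id": gm.sample_ids[mask], "population": pop,
            "f1": f1, "f2": f2, "f3": f3, "n_snps_used": cnt,
        }))
    return pd.concat(frames, ignore_index=True)


def critical_percentage(coeffs: pd.DataFrame, threshold: float = 0.065) -> pd.DataFrame:
    """Percentage of individuals with each F metric above ``threshold``, per population."""
    rows = []
    for pop, grp in coeffs.groupby("population", sort=False):
        n = len(grp)
        rows.append({"population": pop, "n": n,
                     **{f"pct_{k}_gt_threshold": float(100.0 * (grp[k] > threshold).mean())
                        for k in ("f1", "f2", "f3")}})
    return pd.DataFrame(rows)


def inbreeding_summary(coeffs: pd.DataFrame, threshold: float = 0.065) -> pd.DataFrame:
    """Population means of F1/F2/F3 plus the critical percentages."""
    means = coeffs.groupby("population", sort=False)[["f1", "f2", "f3"]].mean().reset_index()
    crit = critical_percentage(coeffs, threshold)
    return means.merge(crit, on="population")
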
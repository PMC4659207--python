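# Methods

`flockdiv` implements a complete genome-wide diversity analysis for unphased
diploid biallelic SNP-array panels with population structure: quality
control, heterozygosity and pairwise F<sub>ST</sub>, GRM-based PCA, pairwise
linkage disequilibrium (r² and D′) with decay tables and haplotype blocks,
runs of homozygosity, LD-based effective population size and three
marker-based inbreeding coefficients — all driven, when no real data are at
hand, by a built-in forward simulator of breed formation.  This note records
the models, the defaults and the genuinely open design choices.

## Data model

Genotypes are alternate-allele dosages in {0, 1, 2} with a single missing
sentinel; every statistic is complete-case (missing calls never enter a
numerator or denominator).  Coordinates are 1-based inclusive bp; dosage
orientation (which allele is counted) is recorded in the map but never
normalised, because every statistic computed here is invariant to swapping
allele labels.  Population labels are part of the genotype container: the
PED family-id column or an explicit sample→population table for VCF.

## Quality control

Filters run in a fixed order — non-autosomal, unmapped, GenCall score (only
when scores are supplied), SNP call rate < 0.95, MAF < 0.01, exact
Hardy–Weinberg p < 1e-15, heterozygosity more than 3 SD from the panel mean —
and each removed SNP is attributed to the first failing rule, so per-reason
counts are mutually exclusive and sum to the input count.  The HWE test is
the exact conditional test (enumeration over heterozygote counts with the
allele counts fixed), not a chi-square: at a 1e-15 cut-off the chi-square
approximation error would dominate the decision.  MAF, HWE and the
heterozygosity screen are computed on the pooled cohort, producing one shared
SNP set for all populations.  The individual call-rate filter is report-only
by default.  A 3-SD outlier screen is not strictly idempotent in the
mathematical sense (removing outliers shrinks the SD); in practice a second
pass removes nothing on array-scale panels, and the test suite checks this on
its simulated panels.

## Diversity and structure

Per SNP, expected heterozygosity is 2pq and observed heterozygosity the
fraction of heterozygous calls; both are averaged over SNPs within each
population.  Pairwise F<sub>ST</sub> = (H<sub>T</sub> − H<sub>S</sub>)/H<sub>T</sub>
is a ratio of averages: per SNP, H<sub>T</sub> uses the sample-size-weighted
pooled allele frequency and H<sub>S</sub> the weighted mean of the two
within-population 2pq values; H<sub>T</sub> and H<sub>S</sub> are then averaged
over loci before the ratio.  SNPs monomorphic in the pooled pair are 0/0
terms and are excluded from both averages.  Structure is summarised by
eigendecomposition of a VanRaden method-1 GRM (columns centred at 2p with
pooled-cohort frequencies, cross-products scaled by Σ2pq, missing dosages
centred to zero); small negative eigenvalues that arise numerically are
floored at zero when variance fractions are formed.

## Linkage disequilibrium

Haplotype frequencies for a SNP pair are fitted by EM on the 3×3 genotype
table.  Only double heterozygotes are phase-ambiguous; each iteration splits
them between coupling and repulsion in the ratio f_AB·f_ab : f_Ab·f_aB,
starting from linkage equilibrium, until the largest frequency change is
below 1e-10 (cap 1000 iterations).  Pairs with fewer than two complete-case
individuals or a monomorphic locus in the complete-case subset are skipped
and counted.  From the fitted frequencies, D = f_AB − p_A·p_B,
r² = D²/(p_A q_A p_B q_B), and D′ = |D|/D_max with the standard
sign-dependent D_max.

Confidence bounds on D′ follow the likelihood-grid construction used by the
block definition: the genotype-table likelihood is evaluated on a D′ grid of
step 0.01 with allele frequencies held at their MLEs and the sign of D fixed
at its EM estimate; the normalised likelihood is read as a discrete
distribution and the 5th/95th cumulative points reported as one-sided 95%
bounds.

Decay tables average r² and D′ over all syntenic pairs in 14 half-open
distance bins from <10 kb to >50 Mb; per-chromosome all-pairs means and
adjacent-pair means are emitted alongside.  The non-syntenic baseline draws a
seeded 5% sample of SNPs per autosome and averages LD over every
cross-chromosome pair — for unlinked loci this approaches the pure sampling
floor, ≈1/S + 3.19/S² for S individuals.  All-pairs computation is exact by
default (a `max_distance_bp` cap exists for very large panels); genotype
tables are accumulated blockwise with BLAS matrix products, and the EM is
vectorised with active-set compression, which keeps a ~2-million-pair
chromosome in a few seconds.

## Haplotype blocks

A pair is in strong LD when its D′ bounds satisfy upper ≥ 0.98 and lower
≥ 0.70; it shows strong evidence of historical recombination when the upper
bound is < 0.90; otherwise it is uninformative.  A candidate block is an
interval whose outermost pair is strong, whose span is at most 500 kb
(configurable; the cap is why maximum block lengths cluster just below
500 kb), and in which at least 95% of informative pairs are strong —
uninformative pairs are excluded from the denominator, so a 2-SNP block needs
its single pair strong.  Candidates are accepted greedily by decreasing
length (ties: more SNPs, then leftmost) and overlaps discarded.  No minimum
block length is imposed beyond two SNPs.

## Runs of homozygosity

Windows of consecutive SNPs spanning at most 1000 kb slide one SNP at a
time; a window is homozygous when it has at most 1 heterozygote and 2 missing
calls.  A SNP is ROH-eligible when at least 5% of the windows containing it
are homozygous — the PLINK `--homozyg-window-threshold` rule.  (Requiring a
*high* fraction instead would make every run shorter than the window span
undetectable, because windows anchored near a run edge inevitably take in
flanking heterozygous tract.)  Maximal runs of eligible SNPs are split at
inter-SNP gaps above 250 kb, then filtered to at least `l` SNPs and at least
500 kb, where

    l = ceil( ln(α / (n_s · n_i)) / ln(1 − het) )

bounds the expected number of chance runs (α = 0.05; het = mean observed
per-SNP heterozygosity; `l` is an integer count, hence the ceiling; it is
computed once for the whole cohort by default, per-population on request).
Segment coordinates are the first/last eligible SNP positions, inclusive;
heterozygous calls tolerated inside windows may survive inside a segment, as
in PLINK.  Length categories (1–5, 5–10, 10–15, 15–20, 20–25, >25 Mb) are
half-open; segments of 0.5–1 Mb count toward totals but no category.
Per-chromosome coverage divides the summed ROH length by the number of
animals with at least one ROH on that chromosome, then by the chromosome
length.

## Effective population size

The pair statistic is the Burrows composite disequilibrium, which requires
neither phase nor HWE: Δ = cov(x, y)/2 and r² = Δ²/[(p_x q_x + D_x)(p_y q_y +
D_y)] with D the homozygote-excess departure at each locus.  Taken over the
same sample, the composite denominator is exactly half the dosage variance,
so the statistic reduces to the squared Pearson correlation of dosage
vectors; `burrows_r2` exposes that form (a duplicated locus gives exactly 1).
The sampling floor 1/S + 3.19/S² is calibrated for the Burrows estimator
carrying the S/(S−1) correction on Δ, i.e. for (S/(S−1))² times the plain
correlation, so `estimate_ne` rescales per-pair r² accordingly before
subtracting the floor — without this, the drift signal of large populations
(1/(3Ne) ≈ 0.002 at Ne = 200 against a floor of ≈0.018 at S = 60) is swamped
and Ne is badly overestimated.  Ne is then
(1/3 + sqrt(1/9 − 2.76·r²_drift))/(2·r²_drift); non-positive drift yields an
infinite estimate.  Samples under 30 use the published small-sample constants
(0.0018 + 0.907/S + 4.44/S²; 0.308/2.08 quadratic) behind an explicit flag.
The default pair set is non-syntenic (cross-chromosome) pairs from a seeded
5%-per-autosome subsample, which satisfies the unlinked-loci assumption; an
`all`-pairs mode exists for comparability with tools that default to it, at
the cost of a documented downward bias from physical linkage.  The MAF screen
`pcrit` defaults to 0.05.  Mean r² is weighted by per-pair complete-case
sample size and the correction uses the harmonic mean S.  Confidence
intervals are out of scope (point estimates only).

## Inbreeding coefficients

Per SNP, with within-population frequency p and dosage x: F1 from the
variance of the additive genotype ((x−2p)²/2pq − 1), F2 from homozygote
excess (1 − x(2−x)/2pq), F3 from the correlation between uniting gametes
((x² − (1+2p)x + 2p²)/2pq); each coefficient is the equal-weight mean over
the individual's informative SNPs (a summed-numerator/denominator variant of
F2 is available because tools differ).  Within-population frequencies are
essential: they are what make F1 crosses of diverged breeds come out negative
(excess heterozygosity relative to their own cohort).  The "critical
percentage" is the share of individuals with a coefficient above 0.065.

## The simulator: what it emulates, and what it does not

Discrete-generation Wright–Fisher diploids: a founder pool at linkage
equilibrium with allele frequencies uniform on (0.05, 0.95) (an array-like
common-allele spectrum; LD then builds by drift), per-breed histories of an
optional formation bottleneck followed by a constant size, recombination with
Poisson crossovers on a uniform 1 cM/Mb map, F1 crosses drawing one gamete
from each parental cohort, pooled-MAF ≥ 0.01 ascertainment, then genotype
error (0.1%) and missingness (2%).  Mutation is omitted after founding.

The shipped `sheep_scenario` keeps the study design it emulates — five
populations with sample sizes 253/265/264/260/231, post-split sizes 140
(bottlenecked), 152 (bottlenecked) and 348, and two F1-type crosses — on a
desk-scale genome: 3 chromosomes of 80/60/50 Mb at 18 SNPs/Mb (~55 kb
spacing, the spacing of a 50k ovine array; ~3400 SNPs total).  A split depth
of 25 generations with 4-generation formation bottlenecks (Ne 50 and 80) was
chosen once so that constant-size drift reproduces differentiation of the
observed magnitude (pairwise F<sub>ST</sub> ~0.01–0.08) together with the
rare-allele excess of bottlenecked breeds; real breed histories are longer
with larger historical sizes, which this constant-size approximation trades
away.  Consequences to keep in mind when reading passing tests: simulated
panels have no genotyping batch structure, no map error, uniform
recombination and missingness, and breed differentiation driven by pure
drift — so tests demonstrate correctness of the estimators under the stated
model, not robustness to array artefacts.

## Numerical choices and degenerate inputs

EM tolerance 1e-10, cap 1000 iterations, equilibrium initialisation (the
likelihood is then non-decreasing along the path, which the tests assert).
D′ grid step 0.01; degenerate tables get uninformative bounds (0, 1).
Distance and length bins are half-open [low, high).  Monomorphic SNPs:
p-value 1 in HWE, skipped in LD/Ne/F with counts, dropped from the GRM.
All-missing SNPs yield NaN summaries and are flagged by QC.  Ties in block
selection break by SNP count then left position.  All randomness flows from
explicit seeds (`numpy` `SeedSequence` spawning); identical configuration
and seed reproduce every output byte for byte.

## Problem sizes used by the shipped checks

The test suite and the acceptance script run entirely on simulated panels:
the five-population scenario above (~1273 × 3400 after QC) for the pipeline
and summary statistics, smaller two/three-population scenarios (tens of Mb,
1–2.5k SNPs, 35–60 samples per population) for module-level checks, and
single-population Wright–Fisher panels (4 × 50 Mb chromosomes, ~280 SNPs,
S = 60, 20 generations, 10 seeds per true Ne ∈ {50, 100, 200}) for
effective-size parameter recovery.
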
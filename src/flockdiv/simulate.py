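"""Seeded forward-in-time simulator of breed-structured SNP panels.

Discrete-generation Wright-Fisher diploids with recombination (Poisson
crossovers at a uniform genetic map, default 1 cM/Mb) drift from a common
founder pool through per-breed histories (optional formation bottleneck, then
a constant post-split size).  Crossbred cohorts are produced by drawing one
gamete from each named parental population, so an "F1(A,B)" individual is a
genuine first cross.  Site ascertainment keeps SNPs with pooled MAF above a
floor, mimicking array design; missingness and genotype error are applied
last.  Everything is reproducible from the scenario seed, and the returned
:class:`SimTruth` records the quantities parameter-recovery tests need.

Forward simulation (rather than coalescent) keeps bottlenecks, crosses and
planted autozygous regions scriptable with exact truth bookkeeping; the
default scenarios stay at desk scale (a few chromosomes, a few thousand
SNPs).  Mutation is omitted after founding — adequate over the <= 200
simulated generations used here.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .genotype_io import MISSING, GenotypeMatrix, SNPMap


@dataclass
class BreedConfig:
    """Post-split history of one pure breed."""
    ne: int
    bottleneck_ne: int | None = None
    bottleneck_generations: int = 0


@dataclass
class CrossConfig:
    """F1 cross between two previously defined populations."""
    parent_a: str
    parent_b: str


@dataclass
class SimScenario:
    chromosome_lengths_mb: tuple
    snp_density_per_mb: float
    founder_size: int
    split_generations: int
    breeds: dict
    crosses: dict
    sample_sizes: dict
    seed: int
    founder_freq_range: tuple = (0.05, 0.95)
    cm_per_mb: float = 1.0
    maf_ascertainment: float = 0.01
    missing_rate: float = 0.02
    genotype_error_rate: float = 0.001

    @property
    def n_chromosomes(self) -> int:
        return len(self.chromosome_lengths_mb)

    def validate(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if min(self.chromosome_lengths_mb) <= 0 or self.snp_density_per_mb <= 0:
            raise ValueError("chromosome lengths and SNP density must be positive")
        if self.founder_size < 2 or self.split_generations < 0:
            raise ValueError("invalid founder size or split depth")
        defined = list(self.breeds)
        for name, cr in self.crosses.items():
            if cr.parent_a not in defined or cr.parent_b not in defined:
                raise ValueError(f"cross {name!r} references undefined population")
            defined.append(name)
        for name in self.sample_sizes:
            if name not in defined:
                raise ValueError(f"sample size given for undefined population {name!r}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["breeds"] = {k: asdict(v) for k, v in self.breeds.items()}
        d["crosses"] = {k: asdict(v) for k, v in self.crosses.items()}
        return d


@dataclass
class SimTruth:
    """Ground truth stored alongside a simulated panel."""
    ne: dict                      # configured post-split Ne per population
    founder_freqs: np.ndarray     # per retained SNP
    planted_regions: list = field(default_factory=list)
    scenario: SimScenario | None = None


def sheep_scenario(seed: int = 17) -> SimScenario:
    """Five-population sheep-like default scenario at desk scale.

    Three pure breeds with the study's sample sizes and effective sizes
    (a small bottlenecked meat breed BL, a second meat breed PD, and a large
    diverse wool breed MER) plus the two F1-type crosses MxB = F1(MER, BL)
    and MxBxP = F1(MxB, PD).  The genome is reduced to three chromosomes at
    ~55 kb SNP spacing (the spacing of a 50k ovine array); split depth and
    the formation bottlenecks are set so drift produces breed differentiation
    of the observed magnitude (pairwise FST in the 0.01-0.08 range) and a
    rare-allele excess in the bottlenecked breeds.
    """
    return SimScenario(
        chromosome_lengths_mb=(80.0, 60.0, 50.0),
        snp_density_per_mb=18.0,
        founder_size=400,
        split_generations=25,
        breeds={
            "BL": BreedConfig(ne=140, bottleneck_ne=50, bottleneck_generations=4),
            "PD": BreedConfig(ne=152, bottleneck_ne=80, bottleneck_generations=4),
            "MER": BreedConfig(ne=348),
        },
        crosses={
            "MxB": CrossConfig("MER", "BL"),
            "MxBxP": CrossConfig("MxB", "PD"),
        },
        sample_sizes={"BL": 253, "MER": 265, "PD": 264, "MxB": 260, "MxBxP": 231},
        seed=seed,
    )


# ---------------------------------------------------------------------------
# core machinery
# ---------------------------------------------------------------------------

def _build_map(scn: SimScenario, rng: np.random.Generator):
    ids, chroms, poss = [], [], []
    slices = []
    start = 0
    for k, L in enumerate(scn.chromosome_lengths_mb, start=1):
        n = int(round(L * scn.snp_density_per_mb))
        pos = np.sort(rng.choice(np.arange(1, int(L * 1e6)), size=n, replace=False))
        ids += [f"c{k}_{p}" for p in pos]
        chroms += [str(k)] * n
        poss.append(pos)
        slices.append((start, start + n))
        start += n
    pos_all = np.concatenate(poss)
    smap = SNPMap(np.array(ids, dtype=object), chroms, pos_all,
                  np.full(start, "A", dtype=object), np.full(start, "B", dtype=object))
    return smap, slices


def _gamete(h0: np.ndarray, h1: np.ndarray, pos_by_chrom, len_bp_by_chrom,
            cm_per_mb: float, rng: np.random.Generator) -> np.ndarray:
    """One recombinant gamete from a diploid parent (Haldane crossovers)."""
    out = np.empty_like(h0)
    off = 0
    for pos, L in zip(pos_by_chrom, len_bp_by_chrom):
        m = len(pos)
        lam = (L / 1e6) * cm_per_mb / 100.0  # expected crossovers per meiosis
        k = rng.poisson(lam)
        sl = slice(off, off + m)
        start = rng.integers(2)
        if k == 0:
            src = h0 if start == 0 else h1
            out[sl] = src[sl]
        else:
            xo = np.sort(rng.uniform(0, L, size=k))
            parity = (start + np.searchsorted(xo, pos)) % 2
            out[sl] = np.where(parity == 0, h0[sl], h1[sl])
        off += m
    return out


class _Genome:
    def __init__(self, smap: SNPMap, slices, cm_per_mb: float):
        self.pos_by_chrom = [smap.pos_bp[a:b] for a, b in slices]
        self.len_bp = [int(p.max()) + 1 for p in self.pos_by_chrom]
        self.cm_per_mb = cm_per_mb

    def breed_offspring(self, haps: np.ndarray, n_off: int,
                        rng: np.random.Generator) -> np.ndarray:
        """Random-mating offspring haplotypes (2*n_off, m) from a diploid pool."""
        n_par = haps.shape[0] // 2
        out = np.empty((2 * n_off, haps.shape[1]), dtype=haps.dtype)
        for i in range(n_off):
            pa, pb = _two_distinct(n_par, rng)
            out[2 * i] = _gamete(haps[2 * pa], haps[2 * pa + 1],
                                 self.pos_by_chrom, self.len_bp, self.cm_per_mb, rng)
            out[2 * i + 1] = _gamete(haps[2 * pb], haps[2 * pb + 1],
                                     self.pos_by_chrom, self.len_bp, self.cm_per_mb, rng)
        return out

    def cross_offspring(self, haps_a: np.ndarray, haps_b: np.ndarray, n_off: int,
                        rng: np.random.Generator) -> np.ndarray:
        """F1 offspring: one gamete from each parental pool per individual."""
        na, nb = haps_a.shape[0] // 2, haps_b.shape[0] // 2
        out = np.empty((2 * n_off, haps_a.shape[1]), dtype=haps_a.dtype)
        for i in range(n_off):
            pa = rng.integers(na)
            pb = rng.integers(nb)
            out[2 * i] = _gamete(haps_a[2 * pa], haps_a[2 * pa + 1],
                                 self.pos_by_chrom, self.len_bp, self.cm_per_mb, rng)
            out[2 * i + 1] = _gamete(haps_b[2 * pb], haps_b[2 * pb + 1],
                                     self.pos_by_chrom, self.len_bp, self.cm_per_mb, rng)
        return out


def _two_distinct(n: int, rng: np.random.Generator):
    a = rng.integers(n)
    if n == 1:
        return a, a
    b = rng.integers(n - 1)
    return a, b + (b >= a)


def simulate_panel(scenario: SimScenario):
    """Run a scenario and return ``(GenotypeMatrix, SNPMap, SimTruth)``.

    Deterministic per seed: the same scenario always yields the identical
    panel.
    """
    scenario.validate()
    ss = np.random.SeedSequence(scenario.seed)
    rng_map, rng_founder, rng_pops, rng_noise = \
        [np.random.default_rng(s) for s in ss.spawn(4)]

    smap, slices = _build_map(scenario, rng_map)
    m = smap.n_snps
    lo, hi = scenario.founder_freq_range
    founder_freqs = rng_founder.uniform(lo, hi, size=m)
    founder = (rng_founder.random((2 * scenario.founder_size, m))
               < founder_freqs).astype(np.uint8)
    genome = _Genome(smap, slices, scenario.cm_per_mb)

    pop_rngs = {name: np.random.default_rng(s)
                for name, s in zip(list(scenario.breeds) + list(scenario.crosses),
                                   rng_pops.spawn(len(scenario.breeds)
                                                  + len(scenario.crosses)))}

    pools: dict[str, np.ndarray] = {}   # final-generation haplotypes per population
    cohorts: dict[str, np.ndarray] = {}  # sampled cohort haplotypes

    for name, cfg in scenario.breeds.items():
        rng = pop_rngs[name]
        sizes = ([cfg.bottleneck_ne] * cfg.bottleneck_generations
                 if cfg.bottleneck_ne else [])
        sizes += [cfg.ne] * (scenario.split_generations - len(sizes))
        if not sizes:
            sizes = [cfg.ne]
        first = min(sizes[0], scenario.founder_size)
        pick = rng.choice(scenario.founder_size, size=first, replace=False)
        haps = founder[np.stack([2 * pick, 2 * pick + 1], axis=1).ravel()]
        for N in sizes:
            haps = genome.breed_offspring(haps, N, rng)
        pools[name] = haps
        n_samp = scenario.sample_sizes.get(name, 0)
        if n_samp:
            cohorts[name] = genome.breed_offspring(haps, n_samp, rng)

    for name, cfg in scenario.crosses.items():
        rng = pop_rngs[name]
        pa = cohorts.get(cfg.parent_a, pools.get(cfg.parent_a))
        pb = cohorts.get(cfg.parent_b, pools.get(cfg.parent_b))
        n_samp = scenario.sample_sizes.get(name, 0)
        cohorts[name] = genome.cross_offspring(pa, pb, n_samp, rng)
        pools[name] = cohorts[name]

    names, pops_lab, rows = [], [], []
    for name in scenario.sample_sizes:
        haps = cohorts[name]
        dos = (haps[0::2].astype(np.int8) + haps[1::2].astype(np.int8))
        rows.append(dos)
        names += [f"{name}_{i:04d}" for i in range(dos.shape[0])]
        pops_lab += [name] * dos.shape[0]
    dosages = np.concatenate(rows, axis=0)

    # array-style ascertainment on the pooled sample
    p_pool = dosages.mean(axis=0) / 2.0
    maf = np.minimum(p_pool, 1 - p_pool)
    keep = maf >= scenario.maf_ascertainment
    if keep.sum() < 2:
        raise ValueError("ascertainment left <2 SNPs; increase founder diversity "
                         "or lower maf_ascertainment")
    dosages = dosages[:, keep]
    smap = smap.subset(np.flatnonzero(keep))
    founder_freqs = founder_freqs[keep]
    p_pool = p_pool[keep]

    if scenario.genotype_error_rate > 0:
        err = rng_noise.random(dosages.shape) < scenario.genotype_error_rate
        redraw = rng_noise.binomial(2, np.broadcast_to(p_pool, dosages.shape)
                                    ).astype(np.int8)
        dosages = np.where(err, redraw, dosages)
    if scenario.missing_rate > 0:
        miss = rng_noise.random(dosages.shape) < scenario.missing_rate
        dosages = np.where(miss, np.int8(MISSING), dosages)

    gm = GenotypeMatrix(dosages, np.array(names, dtype=object),
                        np.array(pops_lab, dtype=object))
    truth = SimTruth(ne={k: v.ne for k, v in scenario.breeds.items()},
                     founder_freqs=founder_freqs, scenario=scenario)
    return gm, smap, truth


def plant_roh(genotypes: np.ndarray, chrom: str, start_bp: int, end_bp: int,
              smap: SNPMap) -> np.ndarray:
    """Return a copy of one individual's row made homozygous across a region.

    The region's genotypes are collapsed onto a single haplotype (the allele
    carried where the individual has at least one copy; missing calls become
    homozygous reference).  Raises when the region covers fewer than 2 SNPs.
    """
    g = np.asarray(genotypes).copy()
    idx = smap.chrom_indices(chrom)
    pos = smap.pos_bp[idx]
    sel = idx[(pos >= start_bp) & (pos <= end_bp)]
    if len(sel) < 2:
        raise ValueError("planted region covers fewer than 2 SNPs")
    g[sel] = np.where(g[sel] >= 1, 2, 0).astype(g.dtype)
    return g
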
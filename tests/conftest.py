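import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import flockdiv as fd

settings.register_profile(
    "suite", derandomize=True, max_examples=25, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


def make_gm(dosages, populations=None, sample_ids=None):
    """Small helper: GenotypeMatrix from a plain array."""
    d = np.asarray(dosages, dtype=np.int8)
    n = d.shape[0]
    return fd.GenotypeMatrix(
        d,
        sample_ids if sample_ids is not None else [f"s{i}" for i in range(n)],
        populations if populations is not None else ["POP"] * n)


def make_map(positions, chrom="1"):
    """SNPMap on one chromosome with A/B allele codes."""
    pos = np.asarray(positions, dtype=np.int64)
    m = len(pos)
    return fd.SNPMap([f"snp{i}" for i in range(m)], [chrom] * m, pos,
                     ["A"] * m, ["B"] * m)


@pytest.fixture(scope="session")
def sheep_panel():
    """Desk-scale five-population panel: two bottlenecked meat breeds, one
    large wool breed, and the two F1-type crosses."""
    scn = fd.SimScenario(
        chromosome_lengths_mb=(40.0, 30.0, 25.0),
        snp_density_per_mb=25.0,
        founder_size=150,
        split_generations=20,
        breeds={
            "BL": fd.BreedConfig(ne=60, bottleneck_ne=30, bottleneck_generations=3),
            "PD": fd.BreedConfig(ne=80, bottleneck_ne=40, bottleneck_generations=3),
            "MER": fd.BreedConfig(ne=200),
        },
        crosses={"MxB": fd.CrossConfig("MER", "BL"),
                 "MxBxP": fd.CrossConfig("MxB", "PD")},
        sample_sizes={"BL": 60, "MER": 60, "PD": 60, "MxB": 50, "MxBxP": 40},
        seed=42,
    )
    gm, smap, truth = fd.simulate_panel(scn)
    return gm, smap, truth


@pytest.fixture(scope="session")
def hwe_panel():
    """One random-mating population drawn directly at Hardy-Weinberg
    proportions (the large-Ne limit)."""
    rng = np.random.default_rng(7)
    p = rng.uniform(0.1, 0.9, 800)
    d = rng.binomial(2, p, size=(500, 800)).astype(np.int8)
    return make_gm(d)
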
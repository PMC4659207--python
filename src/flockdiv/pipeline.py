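"""One-call orchestration: QC -> diversity/FST/PCA -> LD -> blocks -> ROH ->
Ne -> inbreeding, written as a reproducible report bundle.

Each stage operates on the QC-passing panel and is independent of the others,
so any stage error aborts with the stage name while earlier outputs are kept.
All randomness (non-syntenic SNP subsampling, Ne pair sampling) derives from
the single run seed, and tables are written with a fixed numeric format, so
an identical configuration produces a byte-identical bundle.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import blocks as blocks_mod
from . import diversity as div_mod
from . import inbreeding as inb_mod
from . import ld as ld_mod
from . import ne_estimation as ne_mod
from . import roh as roh_mod
from .genotype_io import (GenotypeMatrix, QualityAnnotations, SNPMap,
                          read_ped_map, read_vcf, write_reports)
from .qc import QCConfig, apply_qc
from .simulate import SimScenario, simulate_panel

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    out_dir: str
    seed: int = 17
    # input: either a simulation scenario or file paths
    scenario: SimScenario | None = None
    ped_path: str | None = None
    map_path: str | None = None
    vcf_path: str | None = None
    pop_map_path: str | None = None
    # module parameters
    qc: QCConfig = field(default_factory=QCConfig)
    roh: roh_mod.ROHParams = field(default_factory=roh_mod.ROHParams)
    max_span_kb: float = 500.0
    nonsyntenic_fraction: float = 0.05
    ne_pcrit: float = 0.05
    inbreeding_threshold: float = 0.065
    ld_max_distance_kb: float | None = None
    ld_populations: list | None = None  # default: all

    def describe(self) -> dict:
        d = {
            "seed": self.seed, "out_dir": str(self.out_dir),
            "qc": vars(self.qc), "roh": vars(self.roh),
            "max_span_kb": self.max_span_kb,
            "nonsyntenic_fraction": self.nonsyntenic_fraction,
            "ne_pcrit": self.ne_pcrit,
            "inbreeding_threshold": self.inbreeding_threshold,
            "ld_max_distance_kb": self.ld_max_distance_kb,
            "input": {"ped": self.ped_path, "map": self.map_path,
                      "vcf": self.vcf_path, "pop_map": self.pop_map_path},
        }
        if self.scenario is not None:
            d["scenario"] = self.scenario.to_dict()
        return d


def _load(config: RunConfig):
    if config.scenario is not None:
        gm, smap, _ = simulate_panel(config.scenario)
        return gm, smap
    if config.vcf_path:
        return read_vcf(config.vcf_path, config.pop_map_path)
    if config.ped_path and config.map_path:
        return read_ped_map(config.ped_path, config.map_path)
    raise ValueError("RunConfig needs a scenario, a VCF, or a PED/MAP pair")


def run_all(config: RunConfig) -> dict:
    """Execute the full analysis and write the report bundle.

    Returns a dict of the in-memory result tables; files are written under
    ``config.out_dir`` as they are produced.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    tables: dict[str, pd.DataFrame] = {}

    def stage(name):
        log.info("pipeline stage: %s", name)

    try:
        stage("load")
        gm, smap = _load(config)
    except Exception as exc:
        raise PipelineError("load", exc) from exc

    try:
        stage("qc")
        ann = QualityAnnotations.from_matrix(gm)
        gm, smap, qc_report = apply_qc(gm, smap, ann, config.qc)
        results["qc_report"] = qc_report
        tables["qc_report"] = qc_report.to_dataframe()
    except Exception as exc:
        raise PipelineError("qc", exc) from exc

    pops = config.ld_populations or gm.populations()

    try:
        stage("diversity")
        tables["diversity"] = div_mod.population_diversity(gm)
        fst = div_mod.fst_matrix(gm)
        tables["fst"] = fst.reset_index(names="population")
        G = div_mod.grm(gm)
        pc = div_mod.pca(G, k=5)
        tables["pca_scores"] = pc.to_dataframe(gm.sample_ids, gm.population)
        tables["pca_variance"] = pd.DataFrame({
            "component": [f"PC{i+1}" for i in range(5)],
            "variance_fraction": pc.variance_fraction[:5],
        })
        results["pca"] = pc
    except Exception as exc:
        raise PipelineError("diversity", exc) from exc

    try:
        stage("ld")
        max_dist = (None if config.ld_max_distance_kb is None
                    else int(config.ld_max_distance_kb * 1000))
        decay_frames, chrom_frames, adj_frames, ns_rows = [], [], [], []
        for pop in pops:
            dec = ld_mod.ld_decay(gm, smap, pop, max_distance_bp=max_dist)
            decay_frames.append(dec.table.assign(population=pop))
            chrom_frames.append(dec.per_chromosome.assign(population=pop))
            adj_frames.append(ld_mod.adjacent_ld(gm, smap, pop).assign(population=pop))
            ns = ld_mod.nonsyntenic_ld(gm, smap, pop,
                                       fraction=config.nonsyntenic_fraction,
                                       seed=config.seed)
            ns_rows.append({"population": pop, "mean_r2": ns.mean_r2,
                            "mean_dprime": ns.mean_dprime, "n_pairs": ns.n_pairs})
        tables["ld_decay"] = pd.concat(decay_frames, ignore_index=True)
        tables["ld_per_chromosome"] = pd.concat(chrom_frames, ignore_index=True)
        tables["ld_adjacent"] = pd.concat(adj_frames, ignore_index=True)
        tables["ld_nonsyntenic"] = pd.DataFrame(ns_rows)
    except Exception as exc:
        raise PipelineError("ld", exc) from exc

    try:
        stage("blocks")
        blk_frames, summ_rows = [], []
        for pop in pops:
            blk, _ = blocks_mod.haplotype_blocks(gm, smap, pop,
                                                 max_span_kb=config.max_span_kb)
            blk_frames.append(blk.assign(population=pop))
            summ_rows.append({"population": pop,
                              **blocks_mod.block_summary(blk, smap)})
        tables["blocks"] = pd.concat(blk_frames, ignore_index=True)
        tables["block_summary"] = pd.DataFrame(summ_rows)
    except Exception as exc:
        raise PipelineError("blocks", exc) from exc

    try:
        stage("roh")
        segs, l_min = roh_mod.roh_cohort(gm, smap, config.roh)
        tables["roh_segments"] = segs
        per_ind = roh_mod.roh_length_categories(segs, sample_ids=gm.sample_ids)
        pop_map = dict(zip(gm.sample_ids, gm.population))
        tables["roh_categories"] = roh_mod.population_mean_categories(per_ind, pop_map)
        tables["roh_incidence"] = pd.DataFrame({
            "snp_id": smap.snp_id, "chrom": smap.chrom, "pos_bp": smap.pos_bp,
            "n_in_roh": roh_mod.roh_incidence(segs, smap)})
        tables["roh_chromosomes"] = roh_mod.roh_chromosome_summary(segs, smap)
        results["roh_min_snps"] = l_min
    except Exception as exc:
        raise PipelineError("roh", exc) from exc

    try:
        stage("ne")
        tables["ne"] = ne_mod.ne_table(gm, smap, pops, pcrit=config.ne_pcrit,
                                       fraction=config.nonsyntenic_fraction,
                                       seed=config.seed)
    except Exception as exc:
        raise PipelineError("ne", exc) from exc

    try:
        stage("inbreeding")
        coeffs = inb_mod.f_coefficients(gm)
        tables["inbreeding_individual"] = coeffs
        tables["inbreeding_summary"] = inb_mod.inbreeding_summary(
            coeffs, config.inbreeding_threshold)
    except Exception as exc:
        raise PipelineError("inbreeding", exc) from exc

    params = config.describe()
    params["roh_min_snps"] = results["roh_min_snps"]
    write_reports(tables, out, params=params)
    results["tables"] = tables
    results["out_dir"] = out
    return results
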
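"""Genotype containers and readers/writers for PLINK PED/MAP and VCF text.

The package represents a SNP panel as two aligned objects:

* :class:`SNPMap` — per-marker id, chromosome, 1-based bp position and the
  two allele codes, sorted by chromosome and position;
* :class:`GenotypeMatrix` — an ``individuals x SNPs`` matrix of alternate
  (B) allele dosages in ``{0, 1, 2}`` with :data:`MISSING` (= -1) for
  no-calls, plus sample ids and a population label per sample.

Dosage counts the B/ALT allele.  Array data have arbitrary strand, and every
statistic computed downstream is invariant to swapping the allele labels at a
locus, so the orientation is only book-kept (in ``SNPMap.allele_a/allele_b``)
rather than normalised.  Coordinates are 1-based inclusive bp throughout;
lengths are converted to kb/Mb only in report formatting.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

MISSING = -1

log = logging.getLogger(__name__)


def _chrom_key(c: str):
    """Sort key putting numeric chromosome labels first, in numeric order."""
    c = str(c)
    return (0, int(c), "") if c.isdigit() else (1, 0, c)


@dataclass
class SNPMap:
    """Marker map: id, chromosome label, 1-based position, allele codes.

    ``allele_b`` is the dosage-counted allele.  Positions must be strictly
    increasing within each chromosome (checked by :meth:`validate`).
    """

    snp_id: np.ndarray
    chrom: np.ndarray
    pos_bp: np.ndarray
    allele_a: np.ndarray
    allele_b: np.ndarray

    def __post_init__(self):
        self.snp_id = np.asarray(self.snp_id, dtype=object)
        self.chrom = np.asarray([str(c) for c in np.asarray(self.chrom)], dtype=object)
        self.pos_bp = np.asarray(self.pos_bp, dtype=np.int64)
        self.allele_a = np.asarray(self.allele_a, dtype=object)
        self.allele_b = np.asarray(self.allele_b, dtype=object)

    @property
    def n_snps(self) -> int:
        return len(self.snp_id)

    def validate(self) -> None:
        if len(set(self.snp_id)) != self.n_snps:
            raise ValueError("SNP ids are not unique")
        for c in self.chromosomes():
            pos = self.pos_bp[self.chrom == c]
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions not strictly increasing on chromosome {c}")

    def chromosomes(self) -> list[str]:
        """Chromosome labels in map order."""
        seen: dict[str, None] = {}
        for c in self.chrom:
            seen.setdefault(c, None)
        return list(seen)

    def chrom_indices(self, chrom: str) -> np.ndarray:
        return np.flatnonzero(self.chrom == str(chrom))

    def chrom_lengths(self) -> dict[str, int]:
        """Chromosome extent (max mapped position, bp) per chromosome."""
        return {c: int(self.pos_bp[self.chrom == c].max()) for c in self.chromosomes()}

    def subset(self, idx) -> "SNPMap":
        idx = np.asarray(idx)
        return SNPMap(self.snp_id[idx], self.chrom[idx], self.pos_bp[idx],
                      self.allele_a[idx], self.allele_b[idx])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "snp_id": self.snp_id, "chrom": self.chrom, "pos_bp": self.pos_bp,
            "allele_a": self.allele_a, "allele_b": self.allele_b,
        })


@dataclass
class GenotypeMatrix:
    """Dosage matrix (individuals x SNPs) with sample ids and population labels."""

    dosages: np.ndarray
    sample_ids: np.ndarray
    population: np.ndarray

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.population = np.asarray([str(p) for p in np.asarray(self.population)],
                                     dtype=object)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (individuals x SNPs)")
        if len(self.sample_ids) != self.dosages.shape[0]:
            raise ValueError("sample_ids length does not match dosage rows")
        if len(self.population) != self.dosages.shape[0]:
            raise ValueError("population length does not match dosage rows")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.population:
            seen.setdefault(p, None)
        return list(seen)

    def population_mask(self, population: str) -> np.ndarray:
        mask = self.population == str(population)
        if not mask.any():
            raise ValueError(f"unknown population label: {population!r}")
        return mask

    def subset_snps(self, idx) -> "GenotypeMatrix":
        return GenotypeMatrix(self.dosages[:, np.asarray(idx)],
                              self.sample_ids, self.population)

    def subset_samples(self, sel) -> "GenotypeMatrix":
        sel = np.asarray(sel)
        return GenotypeMatrix(self.dosages[sel], self.sample_ids[sel],
                              self.population[sel])

    # --- per-SNP summaries (complete-case: MISSING never enters a statistic) ---

    def allele_freq(self, rows: np.ndarray | None = None) -> np.ndarray:
        """B-allele frequency per SNP over non-missing calls (NaN if no calls)."""
        d = self.dosages if rows is None else self.dosages[rows]
        ok = d != MISSING
        n = ok.sum(axis=0)
        s = np.where(ok, d, 0).sum(axis=0, dtype=np.int64)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n > 0, s / (2.0 * n), np.nan)

    def snp_call_rate(self) -> np.ndarray:
        return (self.dosages != MISSING).mean(axis=0)

    def ind_call_rate(self) -> np.ndarray:
        return (self.dosages != MISSING).mean(axis=1)

    def het_obs(self, rows: np.ndarray | None = None) -> np.ndarray:
        """Observed heterozygote fraction per SNP (non-missing calls; NaN if none)."""
        d = self.dosages if rows is None else self.dosages[rows]
        n = (d != MISSING).sum(axis=0)
        h = (d == 1).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n > 0, h / n, np.nan)


@dataclass
class QualityAnnotations:
    """Optional per-SNP/per-individual quality metrics used by QC."""

    gc_score: np.ndarray | None = None
    snp_call_rate: np.ndarray | None = None
    ind_call_rate: np.ndarray | None = None

    @classmethod
    def from_matrix(cls, gm: GenotypeMatrix, gc_score=None) -> "QualityAnnotations":
        return cls(
            gc_score=None if gc_score is None else np.asarray(gc_score, dtype=float),
            snp_call_rate=gm.snp_call_rate(),
            ind_call_rate=gm.ind_call_rate(),
        )


# ---------------------------------------------------------------------------
# PLINK PED/MAP text dialect
# ---------------------------------------------------------------------------

def _sorted_order(chrom, pos):
    return np.array(sorted(range(len(pos)), key=lambda k: (_chrom_key(chrom[k]), pos[k])))


def read_ped_map(ped_path, map_path, alleles: Mapping[str, tuple[str, str]] | SNPMap | None = None):
    """Read a PLINK text pedigree (PED) and map (MAP) file pair.

    Population labels are taken from the PED family-id column.  Genotypes
    ``0 0`` (or any half-call containing ``0``) become :data:`MISSING`.

    Parameters
    ----------
    alleles
        Optional orientation pin: a mapping ``snp_id -> (allele_a, allele_b)``
        or a :class:`SNPMap`.  When absent, the dosage-counted allele
        (``allele_b``) is the first allele encountered in the file at that SNP.

    Returns
    -------
    (GenotypeMatrix, SNPMap), sorted by chromosome and position.
    """
    map_rows = []
    with open(map_path) as fh:
        for ln, line in enumerate(fh, 1):
            tok = line.split()
            if not tok:
                continue
            if len(tok) != 4:
                raise ValueError(f"{map_path}: line {ln}: expected 4 fields, got {len(tok)}")
            map_rows.append((tok[0], tok[1], int(tok[3])))
    m = len(map_rows)
    snp_ids = [r[1] for r in map_rows]

    if isinstance(alleles, SNPMap):
        alleles = {s: (a, b) for s, a, b in zip(alleles.snp_id, alleles.allele_a, alleles.allele_b)}

    fids, iids, geno_tokens = [], [], []
    with open(ped_path) as fh:
        for ln, line in enumerate(fh, 1):
            tok = line.split()
            if not tok:
                continue
            if len(tok) != 6 + 2 * m:
                raise ValueError(
                    f"{ped_path}: line {ln}: expected {6 + 2 * m} fields, got {len(tok)}")
            fids.append(tok[0])
            iids.append(tok[1])
            geno_tokens.append(tok[6:])

    n = len(iids)
    dos = np.full((n, m), MISSING, dtype=np.int8)
    allele_a = np.empty(m, dtype=object)
    allele_b = np.empty(m, dtype=object)
    for j in range(m):
        sid = snp_ids[j]
        if alleles is not None and sid in alleles:
            a_ref, b_cnt = alleles[sid]
        else:
            a_ref = b_cnt = None
        observed: list[str] = []
        col = [(geno_tokens[i][2 * j], geno_tokens[i][2 * j + 1]) for i in range(n)]
        for a1, a2 in col:
            for a in (a1, a2):
                if a != "0" and a not in observed:
                    observed.append(a)
        if len(observed) > 2:
            raise ValueError(f"SNP {sid}: more than 2 alleles observed: {observed}")
        if b_cnt is None:
            b_cnt = observed[0] if observed else "0"
            a_ref = observed[1] if len(observed) > 1 else "0"
        else:
            bad = [a for a in observed if a not in (a_ref, b_cnt)]
            if bad:
                raise ValueError(f"SNP {sid}: allele {bad[0]} not in supplied pair")
        allele_a[j], allele_b[j] = a_ref, b_cnt
        for i, (a1, a2) in enumerate(col):
            if a1 == "0" or a2 == "0":
                continue
            dos[i, j] = (a1 == b_cnt) + (a2 == b_cnt)

    smap = SNPMap(np.array(snp_ids, dtype=object),
                  [r[0] for r in map_rows], [r[2] for r in map_rows],
                  allele_a, allele_b)
    order = _sorted_order(smap.chrom, smap.pos_bp)
    smap = smap.subset(order)
    smap.validate()
    gm = GenotypeMatrix(dos[:, order], np.array(iids, dtype=object), np.array(fids, dtype=object))
    return gm, smap


def write_ped_map(gm: GenotypeMatrix, smap: SNPMap, ped_path, map_path) -> None:
    """Write PLINK PED/MAP text files (inverse of :func:`read_ped_map`)."""
    with open(map_path, "w") as fh:
        for c, sid, pos in zip(smap.chrom, smap.snp_id, smap.pos_bp):
            fh.write(f"{c}\t{sid}\t0\t{pos}\n")
    a = np.where(smap.allele_a == "0", "A", smap.allele_a)
    b = np.where(smap.allele_b == "0", "B", smap.allele_b)
    with open(ped_path, "w") as fh:
        for i in range(gm.n_samples):
            row = [str(gm.population[i]), str(gm.sample_ids[i]), "0", "0", "0", "-9"]
            d = gm.dosages[i]
            for j in range(gm.n_snps):
                if d[j] == MISSING:
                    row += ["0", "0"]
                elif d[j] == 0:
                    row += [a[j], a[j]]
                elif d[j] == 1:
                    row += [a[j], b[j]]
                else:
                    row += [b[j], b[j]]
            fh.write(" ".join(row) + "\n")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_pop_map(path) -> dict[str, str]:
    """Read a two-column (sample, population) whitespace-separated file."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            tok = line.split()
            if len(tok) >= 2:
                out[tok[0]] = tok[1]
    return out


def read_vcf(vcf_path, pop_map: Mapping[str, str] | str | Path):
    """Read biallelic SNP records from a VCF into (GenotypeMatrix, SNPMap).

    Dosage counts the ALT allele; ``./.`` becomes :data:`MISSING`.
    Multiallelic or non-SNP records are skipped (count logged).  VCF carries
    no population field, so a sample->population mapping is required.
    """
    from cyvcf2 import VCF

    if not isinstance(pop_map, Mapping):
        pop_map = read_pop_map(pop_map)

    vcf = VCF(str(vcf_path), gts012=False)
    samples = list(vcf.samples)
    missing_pop = [s for s in samples if s not in pop_map]
    if missing_pop:
        raise ValueError(f"samples missing from population map: {missing_pop[:5]}")

    rows, ids, chroms, poss, ref, alt = [], [], [], [], [], []
    skipped = 0
    for v in vcf:
        if len(v.ALT) != 1 or not v.is_snp:
            skipped += 1
            continue
        try:
            g = np.array(v.genotypes, dtype=np.int16)[:, :2]
        except Exception as exc:  # pragma: no cover - malformed record
            raise ValueError(f"record {v.CHROM}:{v.POS}: GT field required") from exc
        dos = (g == 1).sum(axis=1).astype(np.int8)
        dos[(g < 0).any(axis=1)] = MISSING
        rows.append(dos)
        ids.append(v.ID if v.ID not in (None, ".") else f"{v.CHROM}_{v.POS}")
        chroms.append(v.CHROM)
        poss.append(v.POS)
        ref.append(v.REF)
        alt.append(v.ALT[0])
    if skipped:
        log.info("read_vcf: skipped %d multiallelic/non-SNP records", skipped)
    if not rows:
        raise ValueError("no biallelic SNP records in VCF")

    smap = SNPMap(ids, chroms, poss, ref, alt)
    order = _sorted_order(smap.chrom, smap.pos_bp)
    smap = smap.subset(order)
    smap.validate()
    dos = np.stack(rows, axis=1)[:, order]
    pops = [pop_map[s] for s in samples]
    gm = GenotypeMatrix(dos, np.array(samples, dtype=object), np.array(pops, dtype=object))
    gm.n_skipped_records = skipped  # type: ignore[attr-defined]
    return gm, smap


# ---------------------------------------------------------------------------
# Result tables
# ---------------------------------------------------------------------------

def write_reports(results: Mapping[str, pd.DataFrame], out_dir, params: dict | None = None):
    """Write result tables as TSV plus a JSON sidecar of run parameters.

    Identical inputs and parameters produce byte-identical files (fixed float
    format, fixed line terminator, sorted JSON keys).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in results.items():
        p = out_dir / f"{name}.tsv"
        df.to_csv(p, sep="\t", index=False, float_format="%.6g", lineterminator="\n")
        paths[name] = p
    if params is not None:
        p = out_dir / "run_params.json"
        p.write_text(json.dumps(params, indent=2, sort_keys=True, default=str) + "\n")
        paths["run_params"] = p
    return paths
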
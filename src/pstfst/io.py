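"""Readers, writers, and site filtering.

The pipeline's entry point is a VCF of diploid genotype calls (GT field)
plus a tab-separated population map and a long-format trait CSV.  Site
filtering reproduces the standard ddRAD quality recipe: drop indels and
non-biallelic records, require a minimum genotyping proportion within every
population, and keep only sites whose global minor allele frequency is
strictly above a floor.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .containers import MISSING, GenotypeMatrix, IntegrityError, PopulationMap, TraitTable

logger = logging.getLogger(__name__)

__all__ = [
    "FilterConfig",
    "read_vcf",
    "write_vcf",
    "read_population_map",
    "write_population_map",
    "read_traits",
    "write_traits",
    "apply_filters",
    "align_datasets",
]


class VcfParseError(ValueError):
    pass


class EmptyResultError(ValueError):
    """All sites (or all individuals) were removed."""


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Parse a VCFv4.x file into a :class:`GenotypeMatrix`.

    Only the GT field is used.  Phased separators are treated as unphased.
    Any genotype containing a missing allele (``.``) is treated as fully
    missing, as is any genotype carrying an allele index above 1 (possible
    at multiallelic records, which are retained but flagged for the filter
    stage rather than dropped here).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        vcf = VCF(str(path), gts012=False)
    except Exception as exc:  # pragma: no cover - cyvcf2 raises various types
        raise VcfParseError(f"cannot open {path}: {exc}") from exc
    samples = list(vcf.samples)
    if not samples:
        raise VcfParseError(f"{path}: no sample columns")
    rows = []
    meta = {"chrom": [], "pos": [], "id": [], "ref": [], "alt": [],
            "multiallelic": [], "is_indel": []}
    for i, rec in enumerate(vcf):
        try:
            alts = list(rec.ALT)
            gts = rec.genotypes
        except Exception as exc:
            raise VcfParseError(f"{path}: malformed record #{i + 1}") from exc
        if not alts:
            alts = ["."]
        alt = alts[0]
        dos = np.empty(len(samples), dtype=np.int8)
        for j, g in enumerate(gts):
            alleles = g[:-1]  # last element is the phase flag
            if any(a is None or a < 0 for a in alleles) or len(alleles) != 2:
                dos[j] = MISSING
            elif any(a > 1 for a in alleles):
                dos[j] = MISSING  # allele from a second ALT; site is flagged
            else:
                dos[j] = alleles[0] + alleles[1]
        rows.append(dos)
        meta["chrom"].append(rec.CHROM)
        meta["pos"].append(rec.POS)
        meta["id"].append(rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}")
        meta["ref"].append(rec.REF)
        meta["alt"].append(alt)
        meta["multiallelic"].append(len(alts) > 1)
        meta["is_indel"].append(
            len(rec.REF) != 1 or any(len(a) != 1 for a in alts if a != ".")
        )
    if not rows:
        raise VcfParseError(f"{path}: no variant records")
    return GenotypeMatrix(
        dosage=np.vstack(rows).T,
        locus_meta=pd.DataFrame(meta),
        sample_ids=samples,
    )


_GT_STRING = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(g: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal VCFv4.2 with GT-only genotype columns."""
    path = Path(path)
    meta = g.locus_meta
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=pstfst\n")
        for chrom in pd.unique(meta["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(g.sample_ids) + "\n")
        for l in range(g.n_loci):
            row = meta.iloc[l]
            gts = "\t".join(_GT_STRING[int(d)] for d in g.dosage[:, l])
            fh.write(f"{row['chrom']}\t{row['pos']}\t{row['id']}\t{row['ref']}\t"
                     f"{row['alt']}\t.\t.\t.\tGT\t{gts}\n")


def read_population_map(path: str | Path) -> PopulationMap:
    """Read a tab-separated map: individual, population, region, range."""
    t = pd.read_csv(path, sep="\t", dtype=str)
    need = ["individual", "population", "region", "range"]
    if list(t.columns[:4]) != need:
        raise IntegrityError(
            f"population map must have columns {need}, got {list(t.columns)}"
        )
    if t["individual"].duplicated().any():
        dups = sorted(t["individual"][t["individual"].duplicated()])
        raise IntegrityError(f"duplicated individual rows: {dups[:5]}")
    return PopulationMap(t.set_index("individual"))


def write_population_map(pmap: PopulationMap, path: str | Path) -> None:
    pmap.table.rename_axis("individual").reset_index().to_csv(
        path, sep="\t", index=False
    )


def read_traits(path: str | Path) -> TraitTable:
    """Read a long-format trait CSV with columns individual, trait, value."""
    t = pd.read_csv(path, dtype={"individual": str, "trait": str})
    if "trait_name" in t.columns:  # accept the alternate header spelling
        t = t.rename(columns={"trait_name": "trait"})
    return TraitTable(t[["individual", "trait", "value"]])


def write_traits(traits: TraitTable, path: str | Path) -> None:
    traits.table.to_csv(path, index=False)


@dataclass
class FilterConfig:
    """Site-filter thresholds.

    ``min_pop_call_rate`` is enforced within every population (call rate
    >= threshold in all of them); ``min_maf`` is a strict floor on the
    minor allele frequency computed over the whole dataset.
    """

    biallelic_only: bool = True
    drop_indels: bool = True
    min_pop_call_rate: float = 0.9
    min_maf: float = 0.05

    def __post_init__(self) -> None:
        for name in ("min_pop_call_rate", "min_maf"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


def apply_filters(
    g: GenotypeMatrix,
    pmap: PopulationMap,
    cfg: FilterConfig | None = None,
) -> tuple[GenotypeMatrix, dict]:
    """Apply the three site filters in fixed order and return a removal log.

    Order: indel/biallelic -> per-population call rate -> global MAF.
    Samples absent from the map are dropped (with a warning) before any
    call-rate computation, mirroring how a keep-file restricts a VCF run.
    The operation is idempotent: re-filtering the output removes nothing.
    """
    cfg = cfg or FilterConfig()
    mapped = [s for s in g.sample_ids if s in pmap.table.index]
    unmapped = [s for s in g.sample_ids if s not in pmap.table.index]
    if unmapped:
        warnings.warn(
            f"dropping {len(unmapped)} genotyped individuals absent from the "
            f"population map: {unmapped[:5]}...",
            stacklevel=2,
        )
        g = g.subset_samples(mapped)
    if g.n_samples == 0:
        raise EmptyResultError("no genotyped individuals present in the map")

    n_input = g.n_loci
    log: dict = {"input_sites": n_input, "removed": {}, "thresholds": {
        "min_pop_call_rate": cfg.min_pop_call_rate, "min_maf": cfg.min_maf}}

    keep = np.ones(g.n_loci, dtype=bool)
    meta = g.locus_meta
    site_type = np.zeros(g.n_loci, dtype=bool)
    if cfg.drop_indels and "is_indel" in meta:
        site_type |= meta["is_indel"].to_numpy(dtype=bool)
    if cfg.biallelic_only and "multiallelic" in meta:
        site_type |= meta["multiallelic"].to_numpy(dtype=bool)
    log["removed"]["indel_or_not_biallelic"] = int(site_type.sum())
    keep &= ~site_type

    pops = pmap.subset(g.sample_ids).group_labels("population")
    called = g.dosage != MISSING
    pop_fail = np.zeros(g.n_loci, dtype=bool)
    for pop in pd.unique(pops):
        rows = [g.sample_ids.index(i) for i in pops.index[pops == pop]]
        rate = called[rows, :].mean(axis=0)
        pop_fail |= rate < cfg.min_pop_call_rate
    log["removed"]["pop_call_rate"] = int((pop_fail & keep).sum())
    keep &= ~pop_fail

    p = g.allele_frequencies()
    with np.errstate(invalid="ignore"):
        maf = np.minimum(p, 1.0 - p)
    maf_fail = ~(maf > cfg.min_maf)  # strict: MAF exactly at the floor fails
    log["removed"]["maf"] = int((maf_fail & keep).sum())
    keep &= ~maf_fail

    log["output_sites"] = int(keep.sum())
    if log["output_sites"] == 0:
        raise EmptyResultError("no sites survive filtering")
    return g.subset_loci(keep), log


def write_filter_log(log: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(log, indent=2))


def align_datasets(
    g: GenotypeMatrix | None,
    pmap: PopulationMap,
    traits: TraitTable | None,
    require_joint: bool = False,
) -> tuple[GenotypeMatrix | None, PopulationMap, TraitTable | None]:
    """Restrict each dataset to individuals present in the map.

    Genotype-only individuals remain available for allele-based statistics
    and trait-only individuals for trait-variance inference: the two sets
    may overlap without being equal.  With ``require_joint`` an empty
    genotype/trait intersection is an error.
    """
    mapped = set(pmap.table.index)
    g_out = g.subset_samples(mapped) if g is not None else None
    t_out = traits.subset(mapped) if traits is not None else None
    if g_out is not None and g_out.n_samples == 0:
        raise IntegrityError("no genotyped individuals appear in the map")
    if t_out is not None and not len(t_out.table):
        raise IntegrityError("no phenotyped individuals appear in the map")
    if require_joint and g_out is not None and t_out is not None:
        joint = set(g_out.sample_ids) & set(t_out.individuals)
        if not joint:
            raise IntegrityError(
                "genotyped and phenotyped individual sets are disjoint but a "
                "joint analysis was requested"
            )
    return g_out, pmap, t_out
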
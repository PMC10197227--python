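"""Shared in-memory containers for the divergence pipeline.

The analysis operates on three linked objects: a diploid genotype matrix
(alternate-allele dosage per individual and locus), a hierarchical sampling
map (individuals nested in populations nested in geographic regions nested
in a native/non-native range), and a long-format table of common-garden
trait measurements.  Genotyped and phenotyped individual sets may overlap
without being equal; alignment is handled explicitly in :mod:`pstfst.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MISSING = -1  # sentinel for a missing diploid dosage

__all__ = ["MISSING", "GenotypeMatrix", "PopulationMap", "TraitTable"]


class IntegrityError(ValueError):
    """Inconsistent identifiers or grouping across linked inputs."""


@dataclass
class GenotypeMatrix:
    """Individuals x loci diploid alternate-allele dosages.

    Parameters
    ----------
    dosage
        Integer matrix of shape ``(n_samples, n_loci)`` with entries in
        ``{0, 1, 2}`` and :data:`MISSING` (= -1) for missing genotypes.
    locus_meta
        One row per locus with at least columns ``chrom``, ``pos`` (1-based),
        ``id``, ``ref``, ``alt``.  Optional boolean columns ``multiallelic``
        and ``is_indel`` flag sites kept for the filter stage.
    sample_ids
        Ordered individual labels matching the rows of ``dosage``.
    """

    dosage: np.ndarray
    locus_meta: pd.DataFrame
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.ndim != 2:
            raise ValueError("dosage must be 2-D (individuals x loci)")
        n, m = self.dosage.shape
        if len(self.sample_ids) != n:
            raise ValueError(
                f"{len(self.sample_ids)} sample ids for {n} dosage rows"
            )
        if len(self.locus_meta) != m:
            raise ValueError(
                f"{len(self.locus_meta)} locus rows for {m} dosage columns"
            )
        if len(set(self.sample_ids)) != n:
            raise IntegrityError("duplicate sample ids")
        bad = ~np.isin(self.dosage, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("dosage entries must be 0, 1, 2 or missing (-1)")
        self.locus_meta = self.locus_meta.reset_index(drop=True)
        if (self.locus_meta["pos"] < 1).any():
            raise ValueError("VCF positions are 1-based; pos must be >= 1")
        if (self.locus_meta["ref"] == self.locus_meta["alt"]).any():
            raise ValueError("ref and alt alleles must differ")

    @property
    def n_samples(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_loci(self) -> int:
        return self.dosage.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        return self.dosage == MISSING

    def subset_loci(self, idx: np.ndarray | Sequence[int]) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            dosage=self.dosage[:, idx],
            locus_meta=self.locus_meta.iloc[idx].reset_index(drop=True),
            sample_ids=list(self.sample_ids),
        )

    def subset_samples(self, ids: Iterable[str]) -> "GenotypeMatrix":
        wanted = [s for s in self.sample_ids if s in set(ids)]
        pos = [self.sample_ids.index(s) for s in wanted]
        return GenotypeMatrix(
            dosage=self.dosage[pos, :],
            locus_meta=self.locus_meta.copy(),
            sample_ids=wanted,
        )

    def allele_frequencies(self) -> np.ndarray:
        """Alternate-allele frequency per locus over non-missing genotypes."""
        called = self.dosage != MISSING
        n = called.sum(axis=0)
        alt = np.where(called, self.dosage, 0).astype(np.int64).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = alt / (2.0 * n)
        return np.where(n > 0, p, np.nan)


@dataclass
class PopulationMap:
    """Three-level grouping: population within region within range.

    Stored as a frame indexed by individual with columns ``population``,
    ``region`` and ``range``.  Nesting is strict: each population belongs
    to exactly one region and each region to exactly one range.
    """

    table: pd.DataFrame

    REQUIRED = ("population", "region", "range")

    def __post_init__(self) -> None:
        t = self.table
        missing_cols = [c for c in self.REQUIRED if c not in t.columns]
        if missing_cols:
            raise IntegrityError(f"population map missing columns {missing_cols}")
        if t.index.has_duplicates:
            dups = sorted(t.index[t.index.duplicated()].unique())
            raise IntegrityError(f"duplicate individuals in map: {dups[:5]}")
        for child, parent in (("population", "region"), ("region", "range")):
            n_parents = t.groupby(child, sort=False)[parent].nunique()
            bad = n_parents[n_parents > 1]
            if len(bad):
                raise IntegrityError(
                    f"{child}(s) {list(bad.index)} assigned to multiple {parent}s"
                )

    @property
    def individuals(self) -> list[str]:
        return list(self.table.index)

    def group_labels(self, level: str) -> pd.Series:
        """Per-individual label at ``level`` in {population, region, range}."""
        if level not in self.REQUIRED:
            raise ValueError(f"unknown grouping level {level!r}")
        return self.table[level]

    def individuals_in(self, level: str, label: str) -> list[str]:
        lab = self.group_labels(level)
        return list(lab.index[lab == label])

    def groups(self, level: str) -> list[str]:
        return list(pd.unique(self.group_labels(level)))

    def subset(self, individuals: Iterable[str]) -> "PopulationMap":
        keep = [i for i in self.table.index if i in set(individuals)]
        return PopulationMap(self.table.loc[keep])


@dataclass
class TraitTable:
    """Long-format individual-level trait values.

    Columns ``individual``, ``trait``, ``value``; one row per measurement.
    """

    table: pd.DataFrame
    covariates: pd.DataFrame | None = field(default=None)

    def __post_init__(self) -> None:
        need = {"individual", "trait", "value"}
        if not need.issubset(self.table.columns):
            raise IntegrityError(f"trait table needs columns {sorted(need)}")
        vals = pd.to_numeric(self.table["value"], errors="coerce")
        if not np.isfinite(vals).all():
            raise IntegrityError("non-finite or non-numeric trait values")
        self.table = self.table.assign(value=vals.astype(float)).reset_index(drop=True)

    @property
    def traits(self) -> list[str]:
        return list(pd.unique(self.table["trait"]))

    @property
    def individuals(self) -> list[str]:
        return list(pd.unique(self.table["individual"]))

    def values_for(self, trait: str) -> pd.Series:
        sub = self.table[self.table["trait"] == trait]
        if sub.empty:
            raise KeyError(f"no measurements for trait {trait!r}")
        return pd.Series(sub["value"].to_numpy(), index=sub["individual"].to_numpy())

    def subset(self, individuals: Iterable[str]) -> "TraitTable":
        keep = self.table["individual"].isin(set(individuals))
        return TraitTable(self.table[keep].reset_index(drop=True))
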
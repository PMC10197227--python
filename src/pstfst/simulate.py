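"""Synthetic genotype and phenotype generators with recorded truth.

Genotypes follow a two-level Balding-Nichols model: regional allele
frequencies are Beta draws around an ancestral frequency with drift
parameter ``F_neutral`` (so the expected Weir-Cockerham theta among regions
equals ``F_neutral``), and populations within a region take a second,
weaker Beta draw (``F_pop``) to mimic the limited within-range substructure
typical of a recent plant invasion.  A configurable minority of loci can be
simulated at an elevated drift parameter to stand in for selected loci.

Traits are Gaussian with region, population, and residual variance
components, exactly the hierarchical linear model the Pst sampler fits, so
the recorded truth includes the exact Pst implied by the configured
variances.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import MISSING, GenotypeMatrix, IntegrityError, PopulationMap, TraitTable
from . import io as _io

logger = logging.getLogger(__name__)

__all__ = [
    "GenoSimConfig",
    "TraitSimConfig",
    "simulate_subpopulation_frequencies",
    "simulate_genotypes",
    "simulate_traits",
    "write_fixture_set",
    "wright_fisher_sample",
]


@dataclass
class GenoSimConfig:
    """Design and drift parameters for the genotype simulator.

    Defaults mirror a six-region sampling design of 24 individuals per
    region (~2000 anonymous biallelic RAD SNPs), with region-level
    differentiation in the low range typical of a recently spread
    outcrossing weed.
    """

    n_units: int = 6
    pops_per_unit: int = 1
    inds_per_pop: int = 24
    n_loci: int = 2000
    ancestral_maf_range: tuple[float, float] = (0.05, 0.5)
    F_neutral: float = 0.05
    F_pop: float = 0.01
    selected_fraction: float = 0.0
    F_selected: float | None = None
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_units", "pops_per_unit", "inds_per_pop", "n_loci"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        lo, hi = self.ancestral_maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("ancestral_maf_range must lie in (0, 0.5]")
        if not 0 < self.F_neutral < 1:
            raise ValueError("F_neutral must be in (0, 1)")
        if not 0 <= self.F_pop < 1:
            raise ValueError("F_pop must be in [0, 1)")
        if not 0 <= self.selected_fraction < 1:
            raise ValueError("selected_fraction must be in [0, 1)")
        if self.F_selected is None:
            self.F_selected = self.F_neutral
        if self.F_selected < self.F_neutral:
            raise ValueError("F_selected must be >= F_neutral")
        if not 0 <= self.missing_rate < 0.5:
            raise ValueError("missing_rate must be in [0, 0.5)")


@dataclass
class TraitSimConfig:
    """Variance components for the Gaussian trait simulator.

    ``true_pst`` below uses sigma2_W = sigma2_pop + sigma2_resid (all
    phenotypic variance within the compared units), the same default
    convention the inference module applies.

    ``range_effect`` adds a fixed mean difference between the native and
    non-native ranges (+-range_effect/2), emulating a trait under divergent
    selection between ranges on top of the region/population drift
    variances.
    """

    sigma2_between: float = 1.0
    sigma2_pop: float = 0.25
    sigma2_resid: float = 1.0
    grand_mean: float = 0.0
    h2: float = 1.0
    range_effect: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sigma2_between", "sigma2_pop", "sigma2_resid"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.sigma2_between + self.sigma2_pop + self.sigma2_resid <= 0:
            raise ValueError("at least one variance component must be > 0")
        if not 0 < self.h2 <= 1:
            raise ValueError("h2 must be in (0, 1]")

    @property
    def true_pst(self) -> float:
        """Pst implied by the configured variances (sigma2_W = pop + resid)."""
        s2w = self.sigma2_pop + self.sigma2_resid
        denom = self.sigma2_between + 2.0 * self.h2 * s2w
        return 0.0 if denom == 0 else self.sigma2_between / denom


def simulate_subpopulation_frequencies(
    ancestral_freq: float,
    F: float,
    n_units: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Balding-Nichols draw of per-unit allele frequencies.

    Each unit's frequency is Beta(p(1-F)/F, (1-p)(1-F)/F), which has mean
    ``ancestral_freq`` and variance F p (1-p) -- i.e. an expected
    Weir-Cockerham theta of F among the units.
    """
    if not 0 < ancestral_freq < 1:
        raise ValueError("ancestral_freq must be in (0, 1)")
    if not 0 < F < 1:
        raise ValueError("drift parameter F must be in (0, 1)")
    scale = (1.0 - F) / F
    return rng.beta(ancestral_freq * scale, (1.0 - ancestral_freq) * scale, size=n_units)


def simulate_genotypes(
    config: GenoSimConfig,
) -> tuple[GenotypeMatrix, PopulationMap, dict]:
    """Draw genotypes and a matching population map; return truth record.

    Truth records the ancestral frequencies, the realized unit frequencies,
    and the indices/drift parameter of loci simulated as selected.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    L, U, P, I = cfg.n_loci, cfg.n_units, cfg.pops_per_unit, cfg.inds_per_pop

    lo, hi = cfg.ancestral_maf_range
    p_anc = rng.uniform(lo, hi, size=L)
    flip = rng.random(L) < 0.5  # randomize which allele is minor
    p_anc = np.where(flip, 1.0 - p_anc, p_anc)

    n_sel = int(round(cfg.selected_fraction * L))
    selected = rng.choice(L, size=n_sel, replace=False) if n_sel else np.empty(0, int)
    F_locus = np.full(L, cfg.F_neutral)
    F_locus[selected] = cfg.F_selected

    # unit-level Balding-Nichols draw, then an optional weaker draw per pop
    scale = (1.0 - F_locus) / F_locus
    unit_freq = rng.beta(p_anc * scale, (1.0 - p_anc) * scale, size=(U, L))
    if cfg.F_pop > 0 and P > 1:
        s2 = (1.0 - cfg.F_pop) / cfg.F_pop
        a = np.clip(unit_freq * s2, 1e-12, None)
        b = np.clip((1.0 - unit_freq) * s2, 1e-12, None)
        pop_freq = rng.beta(a[None, :, :], b[None, :, :], size=(P, U, L))
    else:
        pop_freq = np.broadcast_to(unit_freq, (P, U, L)).copy()

    rows, sample_ids, map_rows = [], [], []
    for u in range(U):
        for p in range(P):
            freqs = pop_freq[p, u]
            dos = rng.binomial(2, freqs, size=(I, L)).astype(np.int8)
            rows.append(dos)
            for i in range(I):
                sid = f"u{u + 1}p{p + 1}i{i + 1}"
                sample_ids.append(sid)
                map_rows.append(
                    (sid, f"pop_u{u + 1}_{p + 1}", f"region{u + 1}",
                     "native" if u < max(1, U // 3) else "non-native")
                )
    dosage = np.vstack(rows)
    if cfg.missing_rate > 0:
        miss = rng.random(dosage.shape) < cfg.missing_rate
        dosage[miss] = MISSING

    locus_meta = pd.DataFrame({
        "chrom": [f"locus{l + 1}" for l in range(L)],
        "pos": np.full(L, 1),
        "id": [f"snp{l + 1}" for l in range(L)],
        "ref": ["A"] * L,
        "alt": ["G"] * L,
        "multiallelic": False,
        "is_indel": False,
    })
    g = GenotypeMatrix(dosage=dosage, locus_meta=locus_meta, sample_ids=sample_ids)
    pmap = PopulationMap(
        pd.DataFrame(map_rows, columns=["individual", "population", "region", "range"])
        .set_index("individual")
    )
    truth = {
        "config": asdict(cfg),
        "selected_loci": sorted(int(i) for i in selected),
        "F_neutral": cfg.F_neutral,
        "F_selected": cfg.F_selected,
        "ancestral_freq": p_anc.tolist(),
    }
    return g, pmap, truth


def simulate_traits(
    pmap: PopulationMap,
    config: TraitSimConfig,
    trait_name: str = "trait",
) -> tuple[TraitTable, dict]:
    """Draw one Gaussian trait per mapped individual under the nested model.

    y_i = mu + a_region(i) + b_pop(i) + e_i with independent normal effects.
    """
    if not len(pmap.table):
        raise IntegrityError("population map is empty")
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    regions = pmap.groups("region")
    pops = pmap.groups("population")
    a = rng.normal(0.0, np.sqrt(cfg.sigma2_between), size=len(regions))
    b = rng.normal(0.0, np.sqrt(cfg.sigma2_pop), size=len(pops))
    a_of = dict(zip(regions, a))
    b_of = dict(zip(pops, b))
    inds = pmap.individuals
    e = rng.normal(0.0, np.sqrt(cfg.sigma2_resid), size=len(inds))
    reg_lab = pmap.group_labels("region")
    pop_lab = pmap.group_labels("population")
    rng_lab = pmap.group_labels("range")
    ranges = sorted(pd.unique(rng_lab))
    shift = {r: (j - (len(ranges) - 1) / 2.0) * cfg.range_effect
             for j, r in enumerate(ranges)}
    values = np.array(
        [cfg.grand_mean + shift.get(rng_lab[i], 0.0)
         + a_of[reg_lab[i]] + b_of[pop_lab[i]] for i in inds]
    ) + e
    traits = TraitTable(pd.DataFrame(
        {"individual": inds, "trait": trait_name, "value": values}
    ))
    truth = {
        "config": asdict(cfg),
        "trait": trait_name,
        "region_effects": {r: float(v) for r, v in a_of.items()},
        "population_effects": {p: float(v) for p, v in b_of.items()},
        "range_shifts": {r: float(v) for r, v in shift.items()},
        "true_pst": cfg.true_pst,
    }
    return traits, truth


def write_fixture_set(
    genotypes: GenotypeMatrix,
    pmap: PopulationMap,
    traits: TraitTable | None,
    out_dir: str | Path,
    truth: dict | None = None,
) -> dict:
    """Write VCF + map TSV + trait CSV + truth JSON; return the manifest.

    Identifiers must be consistent: every genotyped and phenotyped
    individual must appear in the map.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mapped = set(pmap.table.index)
    stray = [s for s in genotypes.sample_ids if s not in mapped]
    if stray:
        raise IntegrityError(f"genotyped individuals missing from map: {stray[:5]}")
    manifest: dict = {}
    _io.write_vcf(genotypes, out / "genotypes.vcf")
    manifest["vcf"] = "genotypes.vcf"
    _io.write_population_map(pmap, out / "popmap.tsv")
    manifest["map"] = "popmap.tsv"
    if traits is not None and len(traits.table):
        stray_t = [i for i in traits.individuals if i not in mapped]
        if stray_t:
            raise IntegrityError(
                f"phenotyped individuals missing from map: {stray_t[:5]}"
            )
        _io.write_traits(traits, out / "traits.csv")
        manifest["traits"] = "traits.csv"
    else:
        warnings.warn("empty trait table: no traits.csv written", stacklevel=2)
    if truth is not None:
        (out / "truth.json").write_text(json.dumps(truth, indent=2))
        manifest["truth"] = "truth.json"
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def wright_fisher_sample(
    true_ne: int,
    n_sampled: int,
    n_loci: int,
    n_generations: int,
    rng: np.random.Generator,
    init_freq_range: tuple[float, float] = (0.2, 0.8),
) -> np.ndarray:
    """Individual-based neutral Wright-Fisher drift at unlinked loci.

    A closed random-mating population of ``true_ne`` diploids is evolved for
    ``n_generations`` (each offspring draws two parents uniformly with
    replacement and one allele per parent per locus), then ``n_sampled``
    individuals are returned as a dosage matrix.  This is the drift oracle
    used to validate the linkage-disequilibrium Ne estimator: finite
    population size generates the inter-locus disequilibrium the estimator
    reads out, with no selection or structure involved.
    """
    p0 = rng.uniform(*init_freq_range, size=n_loci)
    dosage = rng.binomial(2, p0, size=(true_ne, n_loci))
    for _ in range(n_generations):
        parents = rng.integers(0, true_ne, size=(true_ne, 2))
        t1 = rng.binomial(1, dosage[parents[:, 0]] / 2.0)
        t2 = rng.binomial(1, dosage[parents[:, 1]] / 2.0)
        dosage = t1 + t2
    pick = rng.choice(true_ne, size=n_sampled, replace=False)
    return dosage[pick].astype(np.int8)
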
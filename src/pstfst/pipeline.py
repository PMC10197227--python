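"""End-to-end orchestration: simulate/load -> filter -> scan -> stats -> Pst.

The pipeline enforces the neutral-set hand-off: the Fst values supplied to
the Pst comparisons are computed on the loci that survive outlier
exclusion, not on the full SNP panel (an explicit override exists for
sensitivity checks).  Every run writes a manifest with input hashes, the
seed, and per-stage outputs so a bundle can be reproduced bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as _io
from . import outliers, popgen, pst, simulate
from .containers import GenotypeMatrix, PopulationMap, TraitTable

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "make_demo", "derive_stage_seeds"]


@dataclass
class PipelineConfig:
    """Inputs, stage settings and output location for one run."""

    out_dir: str = "pstfst_run"
    vcf: str | None = None
    popmap: str | None = None
    traits: str | None = None
    simulation: dict | None = None          # GenoSimConfig/TraitSimConfig kwargs
    filter: dict = field(default_factory=dict)
    outlier: dict = field(default_factory=dict)
    pst_model: dict = field(default_factory=dict)
    fst_bootstrap_reps: int = 1000
    allow_full_set_fst: bool = False        # override the neutral-set hand-off
    estimate_ne: bool = True
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        has_files = self.vcf is not None and self.popmap is not None
        if not has_files and self.simulation is None:
            raise ValueError("provide input paths (vcf+popmap) or a simulation block")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


def derive_stage_seeds(seed: int) -> dict[str, int]:
    """Fan a single run seed out to fixed per-stage seeds.

    Stages can then be rerun in isolation with the same substream.  Seeds
    stay below 2**31 so they are portable across generators.
    """
    ss = np.random.SeedSequence(seed)
    names = ("simulate", "traits", "scan", "fst", "pst")
    children = ss.spawn(len(names))
    return {n: int(c.generate_state(1)[0] % (2 ** 31)) for n, c in zip(names, children)}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all stages in fixed order; return the report bundle manifest."""
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = derive_stage_seeds(cfg.seed)
    manifest: dict = {"seed": cfg.seed, "stage_seeds": seeds, "stages": {},
                      "config": {k: v for k, v in asdict(cfg).items()}}
    t_start = time.time()

    def stage(name):
        logger.info("stage %s ...", name)
        manifest["stages"][name] = {"t_start": round(time.time() - t_start, 2)}

    try:
        # ---- inputs -------------------------------------------------------
        stage("inputs")
        if cfg.simulation is not None:
            sim = dict(cfg.simulation)
            trait_specs = sim.pop("traits", [{"name": "trait", "config": {}}])
            geno_cfg = simulate.GenoSimConfig(**{**sim, "seed": seeds["simulate"]})
            g, pmap, truth = simulate.simulate_genotypes(geno_cfg)
            frames, truths = [], {"genotypes": truth}
            for k, entry in enumerate(trait_specs):
                t_cfg = simulate.TraitSimConfig(
                    **{**entry.get("config", {}), "seed": seeds["traits"] + k})
                name = entry.get("name", f"trait{k}")
                tt, t_truth = simulate.simulate_traits(pmap, t_cfg, name)
                frames.append(tt.table)
                truths[name] = t_truth
            traits = TraitTable(pd.concat(frames, ignore_index=True))
            simulate.write_fixture_set(g, pmap, traits, out / "inputs", truth=truths)
        else:
            g = _io.read_vcf(cfg.vcf)
            pmap = _io.read_population_map(cfg.popmap)
            traits = _io.read_traits(cfg.traits) if cfg.traits else None
            for key, p in (("vcf", cfg.vcf), ("popmap", cfg.popmap), ("traits", cfg.traits)):
                if p:
                    manifest["stages"]["inputs"][key + "_sha256"] = _sha256(Path(p))
        g, pmap, traits = _io.align_datasets(g, pmap, traits)

        # ---- filtering ----------------------------------------------------
        stage("filter")
        fcfg = _io.FilterConfig(**cfg.filter)
        g_f, flog = _io.apply_filters(g, pmap, fcfg)
        _io.write_filter_log(flog, out / "filter_log.json")

        # ---- outlier scan -------------------------------------------------
        stage("scan")
        report = outliers.build_report(
            g_f, pmap, random_state=seeds["scan"], **cfg.outlier)
        report.table.to_csv(out / "outlier_report.csv")
        (out / "neutral_loci.txt").write_text("\n".join(report.neutral_ids) + "\n")
        g_neutral = g_f.subset_loci(report.neutral_indices(g_f.locus_meta["id"]))
        manifest["stages"]["scan"].update(
            n_outliers=len(report.outlier_ids), n_neutral=len(report.neutral_ids))

        # ---- neutral diversity and Fst ------------------------------------
        stage("stats")
        rng_fst = np.random.default_rng(seeds["fst"])
        div = popgen.diversity_table(g_neutral, pmap, estimate_ne=cfg.estimate_ne)
        div.to_csv(out / "diversity_by_region.csv", index=False)
        fst_cells, fst_results = popgen.pairwise_fst_table(
            g_neutral, pmap, bootstrap_reps=cfg.fst_bootstrap_reps, rng=rng_fst)
        fst_cells.to_csv(out / "pairwise_fst_regions.csv")
        g_for_pst = g_f if cfg.allow_full_set_fst else g_neutral
        ranges = sorted(pmap.groups("range"))
        fst_table: dict[tuple[str, str], float] = {
            tuple(sorted(k)): v.theta for k, v in fst_results.items()}
        if len(ranges) == 2:
            range_res = popgen.wc_fst(
                g_for_pst, pmap, ranges[0], ranges[1], level="range",
                bootstrap_reps=cfg.fst_bootstrap_reps, rng=rng_fst)
            fst_table[tuple(ranges)] = range_res.theta
            manifest["stages"]["stats"]["range_fst"] = range_res.theta

        # ---- Pst inference ------------------------------------------------
        stage("pst")
        results = None
        if traits is not None:
            pcfg = pst.PstModelConfig(**{**cfg.pst_model, "seed": seeds["pst"]})
            results = pst.run_all_comparisons(traits, pmap, fst_table, pcfg)
            results.to_csv(out / "pst_fst_results.csv", index=False)
            pst.format_results_table(results).to_csv(
                out / "pst_fst_table.csv", index=False)
            summaries = results.to_dict(orient="records")
            (out / "pst_fst_results.json").write_text(json.dumps(summaries, indent=2))

        manifest["elapsed_s"] = round(time.time() - t_start, 2)
        (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        bundle = {
            "manifest": manifest,
            "filter_log": flog,
            "diversity": div,
            "pairwise_fst": fst_cells,
            "fst_results": fst_results,
            "outlier_report": report,
            "pst_results": results,
            "out_dir": str(out),
        }
        return bundle
    except Exception as exc:
        failed = [k for k in manifest["stages"]][-1] if manifest["stages"] else "setup"
        raise RuntimeError(f"pipeline failed at stage {failed!r}: {exc}") from exc


DEMO_SIMULATION = {
    "n_units": 6,
    "pops_per_unit": 4,
    "inds_per_pop": 12,
    "n_loci": 500,
    "F_neutral": 0.05,
    "F_pop": 0.01,
    "selected_fraction": 0.02,
    "F_selected": 0.5,
    "missing_rate": 0.02,
    "traits": [
        # drift-consistent: between-region variance implying Pst near Fst
        {"name": "neutral_trait",
         "config": {"sigma2_between": 0.15, "sigma2_pop": 0.25, "sigma2_resid": 1.0}},
        # strong divergence: a large fixed shift between the ranges
        {"name": "divergent_trait",
         "config": {"sigma2_between": 0.1, "sigma2_pop": 0.25, "sigma2_resid": 1.0,
                    "range_effect": 3.0}},
    ],
}


def make_demo(out_dir: str | Path, seed: int = 7, force: bool = False) -> PipelineConfig:
    """Write a small seeded demo fixture and its expected classifications.

    The demo is 6 regions x 4 populations x 12 individuals at 500 loci with
    two traits: one simulated under drift-scale between-region variance and
    one under strong divergent selection.  The expected outcome (only the
    second trait classified divergent in the range comparison) is stored
    next to the fixture.
    """
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(f"{out} exists and is not empty (use force)")
    out.mkdir(parents=True, exist_ok=True)
    cfg = PipelineConfig(
        out_dir=str(out / "results"),
        simulation=DEMO_SIMULATION,
        outlier={},
        pst_model={"n_chains": 3, "n_iter": 3000, "n_burnin": 500},
        fst_bootstrap_reps=200,
        estimate_ne=True,
        seed=seed,
    )
    (out / "demo_config.yaml").write_text(yaml.safe_dump(asdict(cfg)))
    expected = {
        "range_comparison": {
            "neutral_trait": "drift-consistent",
            "divergent_trait": "divergent",
        }
    }
    (out / "expected_results.json").write_text(json.dumps(expected, indent=2))
    return cfg
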
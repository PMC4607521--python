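"""End-to-end pipeline: simulate/load -> QC -> PCA -> admixture CV ->
component FST -> f3 scan -> f3 power -> FST tree -> ancestry maps.

Each stage reads only prior-stage outputs and writes plain files
(PLINK/TSV/Newick/JSON) into the output directory, so any stage can be
rerun in isolation.  A master seed fans out to per-stage seeds through
``numpy.random.SeedSequence([master_seed, stage_index])``, so changing one
stage's seed never perturbs another stage.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import fstats, genio, popdist, qc, simdata, structure

logger = logging.getLogger("afrostruct")

STAGES = (
    "simulate",
    "qc",
    "pca",
    "admixture",
    "component_fst",
    "f3_scan",
    "f3_power",
    "fst_tree",
    "ancestry_map",
)

__all__ = ["PipelineConfig", "run_pipeline", "STAGES", "stage_seed"]


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed."""
    idx = STAGES.index(stage)
    return int(
        np.random.SeedSequence([master_seed, idx]).generate_state(1)[0] % (2**31)
    )


@dataclass
class PipelineConfig:
    """All stage parameters; defaults follow standard array-QC practice."""

    out_dir: str = "afrostruct_out"
    master_seed: int = 1
    scenario_path: str | None = None  # YAML scenario; None -> default scenario
    plink_prefix: str | None = None  # load instead of simulating
    stages: tuple[str, ...] = STAGES

    snp_call_rate: float = 0.9
    sample_call_rate: float = 0.98
    ld_window: int = 200
    ld_step: int = 25
    ld_r2: float = 0.4
    kinship_threshold: float = qc.SECOND_DEGREE_KINSHIP

    pca_components: int = 10

    k_min: int = 2
    k_max: int = 20
    cv_folds: int = 5
    cv_seeds_per_k: int = 3
    em_tol: float = 1e-2
    em_max_iter: int = 300

    f3_block_size: int = 100

    power_donor: str | None = None  # default: first population
    power_pop1: str | None = None  # default: second population
    power_alpha_step: float = 0.05
    power_reps: int = 100

    idw_power: float = 3.0
    idw_step_deg: float = 2.0

    def validate(self) -> None:
        for s in self.stages:
            if s not in STAGES:
                raise ValueError(f"unknown stage {s!r}")
        if not (0 <= self.snp_call_rate <= 1 and 0 <= self.sample_call_rate <= 1):
            raise ValueError("call rates must lie in [0,1]")
        if not 0 < self.ld_r2 <= 1:
            raise ValueError("ld_r2 must lie in (0,1]")
        if self.k_min < 1 or self.k_max < self.k_min:
            raise ValueError("need 1 <= k_min <= k_max")
        if not 0 < self.power_alpha_step < 1:
            raise ValueError("power_alpha_step must lie in (0,1)")

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        if "stages" in doc:
            doc["stages"] = tuple(doc["stages"])
        return cls(**doc)


@dataclass
class StageRecord:
    stage: str
    seed: int | None
    parameters: dict
    outputs: list[str]
    duration_s: float


@dataclass
class PipelineResult:
    manifest: list[StageRecord] = field(default_factory=list)
    summary: dict = field(default_factory=dict)


def _write_manifest(result: PipelineResult, out: Path) -> None:
    with open(out / "manifest.json", "w") as fh:
        json.dump(
            [
                {
                    "stage": r.stage,
                    "seed": r.seed,
                    "parameters": r.parameters,
                    "outputs": r.outputs,
                    "duration_s": round(r.duration_s, 3),
                }
                for r in result.manifest
            ],
            fh,
            indent=2,
        )


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the enabled stages in fixed order; returns manifest + summary."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result = PipelineResult()

    def record(stage: str, seed: int | None, params: dict, outputs: list[Path], t0: float):
        rec = StageRecord(stage, seed, params, [str(p) for p in outputs], time.time() - t0)
        result.manifest.append(rec)
        _write_manifest(result, out)
        logger.info("stage %s done in %.1fs", stage, rec.duration_s)

    G = None
    fit6 = None
    enabled = [s for s in STAGES if s in config.stages]

    for stage in enabled:
        t0 = time.time()
        logger.info("=== stage %s ===", stage)
        if stage != "simulate" and G is None:
            # allow resuming from a previous run's QC output on disk
            prev = out / "genotypes_qc"
            src = prev if prev.with_suffix(".bed").exists() else out / "genotypes"
            if not src.with_suffix(".bed").exists():
                raise RuntimeError(f"stage {stage!r} needs genotypes; run 'simulate' first")
            G = genio.read_plink_binary(f"{src}.bed", f"{src}.bim", f"{src}.fam")
        if stage == "component_fst" and fit6 is None:
            raise RuntimeError("component_fst requires the admixture stage")
        try:
            if stage == "simulate":
                seed = stage_seed(config.master_seed, stage)
                if config.plink_prefix:
                    G = genio.read_plink_binary(
                        f"{config.plink_prefix}.bed",
                        f"{config.plink_prefix}.bim",
                        f"{config.plink_prefix}.fam",
                    )
                    params = {"plink_prefix": config.plink_prefix}
                else:
                    if config.scenario_path:
                        scenario = simdata.scenario_from_yaml(config.scenario_path)
                        scenario.seed = seed
                    else:
                        scenario = simdata.default_scenario(seed=seed)
                    freqs = simdata.draw_component_frequencies(scenario)
                    G = simdata.simulate_genotypes(scenario, freqs)
                    params = {"scenario": config.scenario_path or "default", "seed": seed}
                genio.write_plink_binary(G, str(out / "genotypes"))
                record(stage, seed, params, [out / "genotypes.bed"], t0)

            elif stage == "qc":
                G, rep1 = qc.filter_call_rate(G, config.snp_call_rate, config.sample_call_rate)
                kin = qc.kinship_matrix(G)
                G, rep2 = qc.remove_related(G, kin, config.kinship_threshold)
                G, rep3 = qc.ld_prune(G, config.ld_window, config.ld_step, config.ld_r2)
                report = pd.concat([r.to_frame() for r in (rep1, rep2, rep3)])
                genio.write_table(report, str(out / "qc_report.tsv"))
                genio.write_table(kin, str(out / "kinship.tsv"))
                genio.write_plink_binary(G, str(out / "genotypes_qc"))
                result.summary["post_qc_shape"] = [G.n_samples, G.n_variants]
                record(
                    stage, None,
                    {"snp_call_rate": config.snp_call_rate,
                     "sample_call_rate": config.sample_call_rate,
                     "ld": [config.ld_window, config.ld_step, config.ld_r2],
                     "kinship_threshold": config.kinship_threshold},
                    [out / "qc_report.tsv", out / "genotypes_qc.bed"], t0,
                )

            elif stage == "pca":
                res = structure.pca(G, config.pca_components)
                df = pd.DataFrame(
                    res.coordinates,
                    columns=[f"PC{i+1}" for i in range(res.coordinates.shape[1])],
                )
                df.insert(0, "sample_id", G.samples["sample_id"])
                df.insert(1, "population", G.samples["population"])
                genio.write_table(df, str(out / "pca.tsv"))
                record(stage, None, {"n_components": config.pca_components},
                       [out / "pca.tsv"], t0)

            elif stage == "admixture":
                seed = stage_seed(config.master_seed, stage)
                cv = structure.admixture_cv(
                    G, range(config.k_min, config.k_max + 1),
                    folds=config.cv_folds, seeds_per_K=config.cv_seeds_per_k,
                    seed=seed, tol=config.em_tol, max_iter=config.em_max_iter,
                )
                genio.write_table(
                    pd.DataFrame(
                        {"K": cv.K_values, "cv_error": cv.mean_error, "cv_sd": cv.sd_error}
                    ),
                    str(out / "cv_errors.tsv"),
                )
                fit6 = structure.admixture_fit(
                    G, cv.chosen_K, seed=seed, tol=1e-4,
                    max_iter=max(config.em_max_iter, 500),
                )
                qdf = pd.DataFrame(
                    fit6.Q, columns=[f"comp{k+1}" for k in range(fit6.K)]
                )
                qdf.insert(0, "sample_id", G.samples["sample_id"])
                qdf.insert(1, "population", G.samples["population"])
                genio.write_table(qdf, str(out / "Q.tsv"))
                genio.write_table(
                    pd.DataFrame(fit6.P.T, columns=[f"comp{k+1}" for k in range(fit6.K)]),
                    str(out / "P.tsv"),
                )
                result.summary["chosen_K"] = cv.chosen_K
                record(stage, seed,
                       {"k_range": [config.k_min, config.k_max],
                        "folds": config.cv_folds, "seeds_per_k": config.cv_seeds_per_k},
                       [out / "cv_errors.tsv", out / "Q.tsv", out / "P.tsv"], t0)

            elif stage == "component_fst":
                m = structure.component_fst(fit6.P)
                genio.write_table(
                    m.to_frame().reset_index(names="component"),
                    str(out / "component_fst.tsv"),
                )
                result.summary["component_fst"] = m.to_frame().to_dict()
                record(stage, None, {}, [out / "component_fst.tsv"], t0)

            elif stage == "f3_scan":
                trios = fstats.f3_all_trios(G, config.f3_block_size)
                counts = fstats.significant_counts(trios)
                genio.write_table(trios, str(out / "f3_trios.tsv"))
                genio.write_table(counts, str(out / "f3_counts.tsv"))
                result.summary["f3_significant_per_target"] = dict(
                    zip(counts["target"], counts["n_significant"].astype(int))
                )
                record(stage, None, {"block_size": config.f3_block_size},
                       [out / "f3_trios.tsv", out / "f3_counts.tsv"], t0)

            elif stage == "f3_power":
                seed = stage_seed(config.master_seed, stage)
                pops = G.populations
                donor = config.power_donor or pops[0]
                pop1 = config.power_pop1 or pops[1]
                grid = tuple(
                    np.round(
                        np.arange(config.power_alpha_step, 0.9999, config.power_alpha_step), 6
                    )
                )
                grid = tuple(a for a in grid if 0 < a < 1)
                design = fstats.CVPowerDesign(
                    donor=donor, pop1=pop1, alpha_grid=grid,
                    n_reps=config.power_reps, seed=seed,
                )
                table = fstats.cv_f3_power(G, design, config.f3_block_size)
                genio.write_table(table, str(out / "f3_power.tsv"))
                result.summary["f3_power"] = dict(
                    zip(table["alpha"].astype(float), table["power"].astype(float))
                )
                record(stage, seed,
                       {"donor": donor, "pop1": pop1, "reps": config.power_reps},
                       [out / "f3_power.tsv"], t0)

            elif stage == "fst_tree":
                m = popdist.wc_fst_matrix(G)
                genio.write_table(
                    m.to_frame().reset_index(names="population"),
                    str(out / "fst_matrix.tsv"),
                )
                tree = popdist.complete_linkage_tree(m)
                genio.write_newick(tree, str(out / "fst_tree.nwk"))
                record(stage, None, {}, [out / "fst_matrix.tsv", out / "fst_tree.nwk"], t0)

            elif stage == "ancestry_map":
                if fit6 is None:
                    raise RuntimeError("ancestry_map requires the admixture stage")
                pops = G.populations
                labels = G.samples["population"].to_numpy()
                outputs = []
                lons = G.samples["lon"].to_numpy()
                lats = G.samples["lat"].to_numpy()
                has_geo = [
                    p for p in pops
                    if np.isfinite(lons[labels == p]).all() and np.isfinite(lats[labels == p]).all()
                ]
                if has_geo:
                    pts_lon = {p: float(lons[labels == p][0]) for p in has_geo}
                    pts_lat = {p: float(lats[labels == p][0]) for p in has_geo}
                    lon_rng = (min(pts_lon.values()) - 2, max(pts_lon.values()) + 2)
                    lat_rng = (min(pts_lat.values()) - 2, max(pts_lat.values()) + 2)
                    for k in range(fit6.K):
                        pts = [
                            (pts_lon[p], pts_lat[p], float(fit6.Q[labels == p, k].mean()))
                            for p in has_geo
                        ]
                        grid = popdist.idw_interpolate(
                            pts, lon_rng, lat_rng,
                            step_deg=config.idw_step_deg, power=config.idw_power,
                        )
                        path = out / f"ancestry_map_comp{k+1}.tsv"
                        genio.write_table(grid.to_frame(), str(path))
                        outputs.append(path)
                record(stage, None,
                       {"power": config.idw_power, "step_deg": config.idw_step_deg},
                       outputs, t0)
        except Exception:
            logger.exception("stage %s failed; prior outputs preserved in %s", stage, out)
            raise

    with open(out / "summary.json", "w") as fh:
        json.dump(result.summary, fh, indent=2, default=str)
    return result
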
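"""End-to-end orchestration: QC -> structure -> relatedness/diversity ->
landscape metrics -> diversity models -> surface optimization -> gene-flow
models -> barriers, from one declarative config.

A config describes one or more regions (replicate landscapes).  Each region
either references input files (VCF, coordinate CSV, per-year land-cover
rasters, climate rasters) or asks for a synthetic dataset; all module
parameters live under their stage's key and every stage's seed derives
deterministically from the global seed.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import (barriers, landscape_metrics, model_engine, optimizer,
               popstructure, relatedness, resistance, synthgen, variant_qc)
from .genotypes import read_vcf
from .raster import read_ascii_grid

__all__ = ["Config", "RunReport", "validate_config", "run_pipeline",
           "DEFAULT_CONFIG"]

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "output_dir": "ibrscape_out",
    "regions": {},
    "qc": {"max_missing": 0.30, "min_qual": 50.0, "depth_range": [30.0, 240.0],
           "min_maf": 0.03, "hwe_alpha": 1e-4, "r2_max": 0.6, "fdr_q": 0.05},
    "structure": {"k_range": [1, 6], "alpha": 1.0, "restarts": 3,
                  "holdout_frac": 0.10, "n_folds": 2, "n_boot": 200},
    "relatedness": {"n_perm": 199, "span": 0.75},
    "diversity": {"radii": [2.0, 4.0, 6.0], "target_class": 0},
    "gene_flow": {"ga": {"population": 16, "stagnation": 5,
                         "max_generations": 15},
                  "n_runs": 2, "optimize_climate": False},
    "barriers": {"n_barriers": 1},
}


@dataclass
class Config:
    data: dict

    def __getitem__(self, k):
        return self.data[k]

    def get(self, k, default=None):
        return self.data.get(k, default)


@dataclass
class RunReport:
    sections: dict = field(default_factory=dict)
    timings: dict = field(default_factory=dict)
    seed: int = 0

    def digest(self) -> str:
        blob = json.dumps(_jsonify(self.sections), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            json.dump({"seed": self.seed, "digest": self.digest(),
                       "timings": self.timings,
                       "sections": _jsonify(self.sections)}, fh, indent=2)
        return path


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return np.round(obj.astype(float), 10).tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return round(float(obj), 10)
    if isinstance(obj, float):
        return round(obj, 10)
    if isinstance(obj, pd.DataFrame):
        return _jsonify(obj.to_dict(orient="list"))
    return obj


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def validate_config(source) -> tuple[Config | None, list]:
    """Validate a config file or dict; collect ALL errors before returning."""
    errors: list[str] = []
    if isinstance(source, (str, Path)):
        path = Path(source)
        if not path.exists():
            return None, [f"config file {path} does not exist"]
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    else:
        raw = dict(source)
    data = _merge(DEFAULT_CONFIG, raw)
    if not data.get("regions"):
        errors.append("config must define at least one region")
    for name, region in (data.get("regions") or {}).items():
        has_sim = "simulate" in region
        has_inputs = "inputs" in region
        if not has_sim and not has_inputs:
            errors.append(f"region {name!r}: needs 'simulate' or 'inputs'")
        if has_inputs:
            inp = region["inputs"]
            for key in ("vcf", "coordinates"):
                if key not in inp:
                    errors.append(f"region {name!r}: inputs.{key} missing")
                elif not Path(inp[key]).exists():
                    errors.append(f"region {name!r}: path {inp[key]} not found")
            for year, p in (inp.get("landcover") or {}).items():
                if not Path(p).exists():
                    errors.append(
                        f"region {name!r}: land-cover raster for year {year} "
                        f"not found: {p}")
        if has_sim:
            sim = region["simulate"]
            if sim.get("n_samples", 2) < 2:
                errors.append(f"region {name!r}: n_samples must be >= 2")
    for radius in data["diversity"]["radii"]:
        if radius <= 0:
            errors.append(f"diversity: buffer radius {radius} must be > 0")
    qc = data["qc"]
    for key in ("max_missing", "min_qual", "min_maf"):
        if qc[key] <= 0:
            errors.append(f"qc.{key} must be positive")
    if errors:
        return None, errors
    return Config(data=data), []


def _load_region(name: str, region: dict, seed: int):
    """Return (geno, samples, class_maps, climate) for one region block."""
    if "simulate" in region:
        sim = dict(region["simulate"])
        grid = sim.get("grid_size", 40)
        sched = {int(k): int(v) for k, v in (sim.get("mine_schedule") or {
            1979: 0, 2011: int(0.05 * grid * grid),
            2014: int(0.08 * grid * grid), 2016: int(0.11 * grid * grid),
        }).items()}
        truth = synthgen.make_landscape(
            grid_size=grid, years=tuple(sched), mine_growth_schedule=sched,
            n_climate_fields=sim.get("n_climate_fields", 4), seed=seed,
            cluster_params=sim.get("cluster_params"),
            gp_params=sim.get("gp_params"))
        samples = synthgen.sample_locations(
            truth, n=sim.get("n_samples", 30),
            min_dist=sim.get("min_dist", 2.0), seed=seed + 1, region=name)
        geno, _ = synthgen.simulate_genotypes(
            truth, samples, n_loci=sim.get("n_loci", 500),
            artifact_spec=sim.get("artifacts"), seed=seed + 2)
        return geno, samples, truth.class_maps, truth.climate_fields
    inp = region["inputs"]
    geno = read_vcf(inp["vcf"])
    coords = pd.read_csv(inp["coordinates"])
    samples = synthgen.SampleSet(
        ids=list(coords["id"]),
        coords=coords[["x", "y"]].to_numpy(dtype=float), region=name)
    class_maps = {int(y): read_ascii_grid(p, name="landcover", year=int(y))
                  for y, p in (inp.get("landcover") or {}).items()}
    climate = {nm: read_ascii_grid(p, name=nm)
               for nm, p in (inp.get("climate") or {}).items()}
    return geno, samples, class_maps, climate


def run_pipeline(config: Config | dict, out_dir: str | Path | None = None
                 ) -> RunReport:
    """Execute the full analysis per region; returns (and writes) a report."""
    if isinstance(config, dict):
        config, errors = validate_config(config)
        if errors:
            raise ValueError("invalid config: " + "; ".join(errors))
    cfg = config.data
    seed = int(cfg["seed"])
    out = Path(out_dir or cfg["output_dir"])
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(seed=seed)
    for r_i, (name, region) in enumerate(sorted(cfg["regions"].items())):
        t_region = time.time()
        rseed = seed * 1000 + r_i * 100
        sec: dict = {}
        try:
            sec, stage_timings = _run_region(name, region, cfg, rseed, out,
                                             report)
        except Exception as exc:
            report.sections[name] = sec
            report.to_json(out / "run_report.json")
            raise RuntimeError(f"stage failure in region {name!r}: {exc}") from exc
        report.sections[name] = sec
        stage_timings["total"] = time.time() - t_region
        report.timings[name] = {k: round(v, 2) for k, v in stage_timings.items()}
    report.to_json(out / "run_report.json")
    return report


def _run_region(name, region, cfg, rseed, out, report):
    sec = {}
    timings = {}

    t0 = time.time()
    geno, samples, class_maps, climate = _load_region(name, region, rseed)
    sec["inputs"] = {"n_individuals": geno.n_individuals,
                     "n_loci": geno.n_loci,
                     "years": sorted(class_maps),
                     "climate_layers": sorted(climate)}
    timings["load"] = time.time() - t0

    # --- QC -------------------------------------------------------------
    t0 = time.time()
    qc = cfg["qc"]
    st = cfg["structure"]

    def ancestry_fitter(g):
        k, _ = popstructure.choose_k(
            g, k_range=st["k_range"], holdout_frac=st["holdout_frac"],
            n_folds=st["n_folds"], seed=rseed + 3, alpha=st["alpha"],
            restarts=max(st["restarts"] - 1, 1))
        return popstructure.estimate_ancestry(
            g, K=k, alpha=st["alpha"], seed=rseed + 4, restarts=st["restarts"])

    clean, filter_report = variant_qc.run_qc(
        geno, max_missing=qc["max_missing"], min_qual=qc["min_qual"],
        depth_range=tuple(qc["depth_range"]), min_maf=qc["min_maf"],
        hwe_alpha=qc["hwe_alpha"], r2_max=qc["r2_max"],
        ancestry_fitter=ancestry_fitter, fdr_q=qc["fdr_q"])
    sec["qc"] = filter_report.to_dict()
    timings["qc"] = time.time() - t0

    # --- structure --------------------------------------------------------
    t0 = time.time()
    best_k, curve = popstructure.choose_k(
        clean, k_range=st["k_range"], holdout_frac=st["holdout_frac"],
        n_folds=st["n_folds"], seed=rseed + 5, alpha=st["alpha"],
        restarts=max(st["restarts"] - 1, 1))
    model = popstructure.estimate_ancestry(
        clean, K=best_k, alpha=st["alpha"], seed=rseed + 6,
        restarts=st["restarts"])
    assignments = model.hard_clusters()
    km_labels, bic_curve = popstructure.pc_kmeans_bic(
        clean, k_range=st["k_range"], seed=rseed + 7)
    sizes = np.bincount(assignments, minlength=best_k)
    if best_k > 1 and sizes.min() >= 2:
        summaries = popstructure.cluster_diversity(
            clean, assignments, n_boot=st["n_boot"], seed=rseed + 8)
    else:
        summaries = popstructure.cluster_diversity(
            clean, np.zeros(clean.n_individuals, dtype=int),
            n_boot=st["n_boot"], seed=rseed + 8)
    sec["structure"] = {
        "chosen_k": best_k,
        "cv_curve": curve,
        "kmeans_bic_k": int(bic_curve.dropna(subset=["BIC"])
                            .loc[lambda d: d["BIC"].idxmin(), "K"])
        if not bic_curve.empty else None,
        "cluster_sizes": sizes.tolist(),
        "diversity": [{"cluster": s.cluster, "n": s.n, "He": s.he,
                       "He_ci": list(s.he_ci), "F": s.f, "F_ci": list(s.f_ci)}
                      for s in summaries],
    }
    timings["structure"] = time.time() - t0

    # --- relatedness ------------------------------------------------------
    t0 = time.time()
    rl = cfg["relatedness"]
    rel = relatedness.yang_relatedness(clean)
    div = relatedness.individual_het_inbreeding(clean)
    corr = relatedness.relatedness_correlogram(
        rel, samples.coords, n_perm=rl["n_perm"], span=rl["span"],
        seed=rseed + 9)
    sec["relatedness"] = {
        "mean_offdiag": float(np.nanmean(rel.offdiag())),
        "mean_H": float(np.nanmean(div["H"])),
        "mean_f": float(np.nanmean(div["f"])),
        "correlogram_significant_frac": float(corr.significant().mean()),
    }
    rel_df = rel.to_long()
    rel_df.to_csv(out / f"{name}_relatedness.csv", index=False)
    timings["relatedness"] = time.time() - t0

    # --- landscape metrics + diversity models -----------------------------
    t0 = time.time()
    dv = cfg["diversity"]
    years = sorted(class_maps)
    pre_year = years[0]
    target = dv["target_class"]
    records = {}
    for radius in dv["radii"]:
        records[radius] = landscape_metrics.habitat_records(
            class_maps, samples.coords, radius, target, pre_year=pre_year)
    div_data = div.copy()
    div_data["logit_H"] = np.log(np.clip(div_data["H"], 1e-6, 1 - 1e-6)
                                 / (1 - np.clip(div_data["H"], 1e-6, 1 - 1e-6)))
    div_data["cluster"] = assignments

    amount_col = f"amount_{pre_year}_prop"

    def fit_amount(payload):
        rec = payload
        d = div_data.assign(amount=rec[amount_col].to_numpy())
        return model_engine.fit_gls(d, "logit_H", ["amount"], family="none")

    chosen_radius, aic_table = landscape_metrics.select_buffer_size(
        records, fit_amount)
    rec = records[chosen_radius]
    loss_cols = [c for c in rec.columns if c.startswith("loss_")]
    d = div_data.assign(amount=rec[amount_col].to_numpy(),
                        **{c: rec[c].to_numpy() for c in loss_cols})
    predictors = ["amount"] + loss_cols
    div_tables = {}
    for response in ("logit_H", "f"):
        def fit_fn(data, resp, preds, model_name=""):
            if sizes.min() >= 2 and best_k > 1:
                return model_engine.fit_lmm(data, resp, preds, ["cluster"],
                                            model_name=model_name)
            return model_engine.fit_gls(data, resp, preds, family="none",
                                        model_name=model_name)
        table = model_engine.dredge(d, response, predictors, fit_fn,
                                    collinearity_r=0.6)
        avg = model_engine.average_and_importance(table)
        div_tables[response] = {
            "table": table.table,
            "importance": avg["importance"],
            "best_model": table.best_fit.model_name,
        }
    sec["diversity_models"] = {
        "chosen_radius": chosen_radius,
        "buffer_aic": aic_table,
        "models": {k: {"best_model": v["best_model"],
                       "importance": v["importance"]}
                   for k, v in div_tables.items()},
    }
    timings["diversity"] = time.time() - t0

    # --- resistance optimization ------------------------------------------
    t0 = time.time()
    gf = cfg["gene_flow"]
    ga_cfg = gf["ga"]
    latest = class_maps[years[-1]]
    runs = []
    for run_i in range(gf["n_runs"]):
        ga = optimizer.GAConfig(seed=rseed + 20 + run_i, **ga_cfg)
        runs.append(optimizer.optimize_surface(
            rel, latest, "categorical", ga, coords=samples.coords))
    conv = optimizer.convergence_check(runs) if len(runs) >= 2 else None
    best_run = min(runs, key=lambda r: r.final_objective)
    sec["optimization"] = {
        "best_params": best_run.best_params,
        "final_objective": best_run.final_objective,
        "n_evaluations": sum(r.n_evaluations for r in runs),
        "convergence": None if conv is None else {
            "cv_objective": conv.cv_objective,
            "median_agreement": conv.median_agreement,
            "passed": conv.passed},
    }
    timings["optimize"] = time.time() - t0

    # --- gene-flow model comparison ----------------------------------------
    t0 = time.time()
    ibd = resistance.commute_distance(
        resistance.null_ibd_surface(latest), samples.coords)
    lc_dists = {}
    for y in years:
        surf = resistance.categorical_surface(
            class_maps[y],
            {int(c): best_run.best_params["class_values"].get(
                int(c), 1.0)
             for c in np.unique(class_maps[y].data)})
        lc_dists[f"landcover_{y}"] = resistance.commute_distance(
            surf, samples.coords)
    other = {}
    if gf.get("optimize_climate") and climate:
        chosen, _, _ = landscape_metrics.select_climate_variables(
            climate, samples.coords, n_axes=min(3, len(climate)))
        for nm in chosen:
            ga = optimizer.GAConfig(seed=rseed + 40, **ga_cfg)
            crun = optimizer.optimize_surface(
                rel, climate[nm], "monomolecular", ga, coords=samples.coords)
            other[nm] = crun.best_distance
    comparison = optimizer.compare_gene_flow_models(
        lc_dists, other, rel, ibd,
        assignments=assignments if best_k > 1 else None)
    sec["gene_flow"] = {
        "stage1": comparison["stage1"].table,
        "ibd_parsimonious": comparison["ibd_parsimonious"],
        "landcover_winner": comparison["landcover_winner"],
        "stage2_best": (comparison["stage2"].best_fit.model_name
                        if comparison["stage2"] is not None else None),
        "lrt": comparison["lrt"],
    }
    timings["gene_flow"] = time.time() - t0

    # --- barriers -----------------------------------------------------------
    t0 = time.time()
    graph = barriers.gabriel_graph(samples.coords)
    A = rel.values.copy()
    rng_ = A[np.isfinite(A)].max() - A[np.isfinite(A)].min()
    dis = 1.0 - (A - np.nanmin(A)) / (rng_ if rng_ > 0 else 1.0)
    np.fill_diagonal(dis, 0.0)
    bars = barriers.monmonier_barrier(
        graph, dis, n_barriers=cfg["barriers"]["n_barriers"])
    sec["barriers"] = [{"n_crossed": b.n_crossed,
                        "termination": b.termination,
                        "low_contrast": b.low_contrast} for b in bars]
    timings["barriers"] = time.time() - t0

    return sec, timings
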
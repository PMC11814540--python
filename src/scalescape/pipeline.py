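"""End-to-end orchestration: simulate -> pseudoabs -> features -> model -> screen -> stats.

Each stage is a function that reads its inputs from the output directory
(written by earlier stages), computes, and persists its products as
plain-text files, so any stage can be re-run in isolation with identical
results.  ``run_pipeline`` chains them and writes a machine-readable JSON
run report with per-stage status and the headline results (best scale, top
variable, diversity table, screen flags).
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig, stage_seed
from .features import BufferSpec, build_feature_table, disc_specs
from .io import (
    read_ascii_grid,
    read_feature_table,
    read_points_csv,
    write_ascii_grid,
    write_feature_table,
    write_mask_set,
    write_points_csv,
    write_points_geojson,
)
from .landscape import (
    MaskSet,
    PreferenceSpec,
    generate_landscape,
    generate_sighting_pool,
    make_masks,
    place_presences,
)
from .models import (
    ModelConfig,
    fit_scale_ensemble,
    pearson_matrix,
    summarize_scales,
    variable_importance,
)
from .outliers import DeletionScheduleConfig, deletion_screen, trend_test
from .pseudoabsence import ConstraintSpec, draw_negatives, sample_candidates
from .stats import diversity_table, nmds

log = logging.getLogger(__name__)

STAGES = ("simulate", "pseudoabs", "features", "model", "screen", "stats")


def _read_masks(outdir: Path) -> MaskSet:
    border = read_ascii_grid(outdir / "border_mask.asc").grid.astype(bool)
    town = read_ascii_grid(outdir / "town_mask.asc").grid.astype(bool)
    return MaskSet(border_mask=border, town_mask=town)


def stage_simulate(cfg: PipelineConfig, outdir: Path) -> dict:
    """Generate the landscape, masks, presences and sighting pool."""
    lc = cfg.landscape
    seed = stage_seed(cfg.seed, "simulate")
    raster = generate_landscape(
        lc.n_rows, lc.n_cols, lc.cell_size, lc.class_mix, lc.patchiness, seed
    )
    masks = make_masks(raster, lc.border_band, lc.town_count, lc.town_radius, seed + 1)
    pref = PreferenceSpec(
        focal_class=lc.preference.focal_class,
        focal_radius=lc.preference.focal_radius,
        strength=lc.preference.strength,
    )
    presences = place_presences(
        raster, pref, lc.n_presences, lc.min_spacing, seed + 2, masks=masks
    )
    sightings = generate_sighting_pool(raster, lc.n_sightings, seed + 3)
    write_ascii_grid(raster, outdir / "landscape.asc")
    write_mask_set(masks, raster, outdir / "border_mask.asc", outdir / "town_mask.asc")
    write_points_csv(presences, outdir / "presences.csv")
    write_points_geojson(presences, outdir / "presences.geojson")
    write_points_csv(sightings, outdir / "sightings.csv")
    return {
        "files": [
            "landscape.asc",
            "border_mask.asc",
            "town_mask.asc",
            "presences.csv",
            "presences.geojson",
            "sightings.csv",
        ],
        "n_presences": len(presences),
        "n_sightings": len(sightings),
    }


def stage_pseudoabs(cfg: PipelineConfig, outdir: Path) -> dict:
    """Sample the candidate pool and draw the negative set."""
    raster = read_ascii_grid(outdir / "landscape.asc")
    masks = _read_masks(outdir)
    sightings = read_points_csv(outdir / "sightings.csv")
    pc = cfg.pseudoabsence
    spec = ConstraintSpec(
        min_sighting_dist=pc.min_sighting_dist,
        avoid_towns=pc.avoid_towns,
        n_candidates=pc.n_candidates,
        n_draw=pc.n_draw,
    )
    seed = stage_seed(cfg.seed, "pseudoabs")
    candidates = sample_candidates(raster, sightings, masks, spec, seed)
    negatives = draw_negatives(candidates, pc.n_draw, seed + 1)
    # land-use composition summary around each candidate (smallest model radius)
    summary_radius = min(cfg.model.radii_km) * 1000.0
    comp = build_feature_table(raster, candidates, [BufferSpec(outer=summary_radius)])
    write_points_csv(candidates, outdir / "candidates.csv")
    write_points_csv(negatives, outdir / "negatives.csv")
    write_points_geojson(negatives, outdir / "negatives.geojson")
    write_feature_table(comp, outdir / "candidate_composition.csv")
    return {
        "files": [
            "candidates.csv",
            "negatives.csv",
            "negatives.geojson",
            "candidate_composition.csv",
        ],
        "n_candidates": len(candidates),
        "n_negatives": len(negatives),
    }


def stage_features(cfg: PipelineConfig, outdir: Path) -> dict:
    """Buffer class areas for presences + negatives at all model radii."""
    raster = read_ascii_grid(outdir / "landscape.asc")
    presences = read_points_csv(outdir / "presences.csv")
    negatives = read_points_csv(outdir / "negatives.csv")
    points = pd.concat([presences, negatives], ignore_index=True)
    points["label"] = points["label"].astype(int)
    specs = disc_specs(cfg.model.radii_km)
    features = build_feature_table(raster, points, specs)
    write_feature_table(features, outdir / "features.csv")
    return {"files": ["features.csv"], "n_rows": len(features)}


def stage_model(cfg: PipelineConfig, outdir: Path) -> dict:
    """Per-scale ensembles, accuracy summary, importances, Pearson matrices."""
    features = read_feature_table(outdir / "features.csv")
    seed = stage_seed(cfg.seed, "model")
    mc = cfg.model
    results = []
    for i, spec in enumerate(disc_specs(mc.radii_km)):
        config = ModelConfig(
            n_trees=mc.n_trees,
            n_models=mc.n_models,
            oob_fraction=mc.oob_fraction,
            sampling=mc.sampling,
            seed=seed + i,
        )
        res = fit_scale_ensemble(features, spec, config)
        results.append(res)
        log.info(
            "scale %s: mean acc %.3f +- %.3f",
            spec.label,
            res.mean_accuracy,
            res.accuracies.std(ddof=1) if len(res.accuracies) > 1 else 0.0,
        )
    summary = summarize_scales(results)
    summary.table.to_csv(outdir / "scale_accuracy.csv", index=False, float_format="%.6f")

    imp_frames = []
    for res in results:
        vi = variable_importance(res)
        vi.insert(0, "scale", res.spec.label)
        imp_frames.append(vi)
    pd.concat(imp_frames, ignore_index=True).to_csv(
        outdir / "importances.csv", index=False, float_format="%.6f"
    )
    for res in results:
        pm = pearson_matrix(features, res.spec)
        pm.to_csv(outdir / f"pearson_{res.spec.label.replace('-', '_')}.csv",
                  float_format="%.6f")

    best = summary.best_spec
    best_res = next(r for r in results if r.spec == best)
    vi_best = variable_importance(best_res).sort_values("rank")
    return {
        "files": ["scale_accuracy.csv", "importances.csv"],
        "best_scale": best.label,
        "best_scale_outer_m": best.outer,
        "best_mean_accuracy": best_res.mean_accuracy,
        "best_max_accuracy": best_res.max_accuracy,
        "tied": summary.tied,
        "top_variable": vi_best.iloc[0]["variable"],
        "top_importance": float(vi_best.iloc[0]["importance"]),
    }


def stage_screen(cfg: PipelineConfig, outdir: Path) -> dict:
    """Deletion-based outlier screen on the configured annular scales."""
    raster = read_ascii_grid(outdir / "landscape.asc")
    presences = read_points_csv(outdir / "presences.csv")
    negatives = read_points_csv(outdir / "negatives.csv")
    points = pd.concat([presences, negatives], ignore_index=True)
    points["label"] = points["label"].astype(int)
    sc = cfg.screen
    seed = stage_seed(cfg.seed, "screen")
    rings = [BufferSpec(inner=r[0] * 1000.0, outer=r[1] * 1000.0) for r in sc.rings_km]
    ring_features = build_feature_table(raster, points, rings)
    records = []
    summaries = {}
    for i, ring in enumerate(rings):
        schedule = DeletionScheduleConfig(
            deletion_counts=tuple(sc.deletion_counts),
            reps_per_k=sc.reps_per_k,
            seed=seed + 2 * i,
        )
        model_cfg = ModelConfig(
            n_trees=sc.n_trees, n_models=sc.n_models, seed=seed + 2 * i + 1
        )
        res = deletion_screen(ring_features, ring, schedule, model_cfg)
        trend = trend_test(res)
        rec = res.records.copy()
        rec["deleted_ids"] = rec["deleted_ids"].map(lambda ids: ";".join(map(str, ids)))
        records.append(rec)
        summaries[ring.label] = {
            "baseline_mean": res.baseline_mean,
            "baseline_sd": res.baseline_sd,
            "best_k": res.best_k,
            "best_rep": res.best_rep,
            "delta": res.delta,
            "flagged_ids": list(map(str, res.flagged_ids)),
            "slope": trend.slope,
            "slope_p": trend.p_value,
            "classification": trend.classification,
        }
    pd.concat(records, ignore_index=True).to_csv(
        outdir / "screen_records.csv", index=False, float_format="%.6f"
    )
    (outdir / "screen_summary.json").write_text(json.dumps(summaries, indent=2, sort_keys=True))
    return {"files": ["screen_records.csv", "screen_summary.json"], "rings": summaries}


def stage_stats(cfg: PipelineConfig, outdir: Path) -> dict:
    """Per-scale diversity tests and the NMDS ordination."""
    features = read_feature_table(outdir / "features.csv")
    table, _ = diversity_table(features, alpha_normality=cfg.stats.alpha_normality)
    table.to_csv(outdir / "diversity_tests.csv", index=False, float_format="%.6f")
    scale_m = cfg.stats.nmds_scale_km * 1000.0
    sub = features[(features["inner_m"] == 0) & (features["outer_m"] == scale_m)]
    ord_info: dict = {"stress": None, "converged": None}
    files = ["diversity_tests.csv"]
    if len(sub) >= 4:
        res = nmds(sub, seed=stage_seed(cfg.seed, "stats"), n_init=cfg.stats.nmds_n_init)
        res.coordinates.to_csv(outdir / "nmds_coordinates.csv", index=False,
                               float_format="%.6f")
        ord_info = {"stress": res.stress, "converged": res.converged}
        files.append("nmds_coordinates.csv")
    sig = table[table["p"] < 0.05]
    return {
        "files": files,
        "n_scales_significant": int(len(sig)),
        "n_scales": int(len(table)),
        "min_p": float(table["p"].min()),
        "nmds": ord_info,
    }


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "pseudoabs": stage_pseudoabs,
    "features": stage_features,
    "model": stage_model,
    "screen": stage_screen,
    "stats": stage_stats,
}


def run_stage(name: str, cfg: PipelineConfig, outdir) -> dict:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    return _STAGE_FUNCS[name](cfg, outdir)


def run_pipeline(cfg: PipelineConfig, outdir) -> dict:
    """Run every stage in order and write ``run_report.json``.

    On a stage failure, the report (and a ``FAILED`` marker) is still
    written with the partial results, and the exception re-raised.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    root = logging.getLogger("scalescape")
    root.addHandler(handler)
    if root.level > logging.INFO or root.level == logging.NOTSET:
        root.setLevel(logging.INFO)
    report: dict = {
        "version": __version__,
        "config": cfg.model_dump(),
        "stages": {},
        "headline": {},
    }
    failed = None
    try:
        for name in STAGES:
            t0 = time.perf_counter()
            try:
                info = _STAGE_FUNCS[name](cfg, outdir)
            except Exception as exc:  # noqa: BLE001 - report then re-raise
                report["stages"][name] = {"status": "FAILED", "error": str(exc)}
                failed = (name, exc)
                break
            info["status"] = "ok"
            info["seconds"] = round(time.perf_counter() - t0, 3)
            report["stages"][name] = info
            log.info("stage %s done in %.1fs", name, info["seconds"])
    finally:
        root.removeHandler(handler)
        handler.close()

    if failed is None:
        model_info = report["stages"]["model"]
        stats_info = report["stages"]["stats"]
        screen_info = report["stages"]["screen"]
        report["headline"] = {
            "best_scale": model_info["best_scale"],
            "best_mean_accuracy": model_info["best_mean_accuracy"],
            "top_variable": model_info["top_variable"],
            "diversity_scales_significant": f"{stats_info['n_scales_significant']}"
                                            f"/{stats_info['n_scales']}",
            "nmds_stress": stats_info["nmds"]["stress"],
            "screen": {
                k: {kk: v[kk] for kk in ("delta", "slope", "classification")}
                for k, v in screen_info["rings"].items()
            },
        }
    manifest = sorted(
        str(p.relative_to(outdir)) for p in outdir.glob("*") if p.is_file()
    )
    report["manifest"] = manifest
    (outdir / "run_report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    if failed is not None:
        (outdir / "FAILED").write_text(f"stage {failed[0]}: {failed[1]}\n")
        raise RuntimeError(f"pipeline failed at stage {failed[0]}: {failed[1]}") from failed[1]
    return report
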
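"""End-to-end orchestration: synthetic world -> assemblages -> biomes.

Stages run in the workflow order (tolerance data -> hexagon aggregation ->
block PCAs -> random forests -> fuzzy clustering -> biomes/hotspots ->
characterization), each PFT processed independently.  Every stage writes
its tables under the output directory; a manifest records settings, seeds,
row counts, the selected number of clusters per PFT, and file hashes so a
run can be replayed and verified.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from stressbiomes import io
from stressbiomes.config import (
    CLIMATE_VARS,
    PFTS,
    SOIL_VARS,
    TOPO_VARS,
    TRAITS,
    PipelineConfig,
)
from stressbiomes.characterization import overlap_with_classes, summarize_strategy_space
from stressbiomes.fuzzy_biomes import (
    detect_polytolerance,
    fuzzy_kmeans,
    label_clusters_and_rescale,
    polytolerance_summary,
    select_k_fuzzy_silhouette,
)
from stressbiomes.grid_aggregation import aggregate_assemblages, build_hex_grid, clean_occurrences
from stressbiomes.hotspot_kde import kde_hotspots
from stressbiomes.ortho_spaces import cross_block_correlation, parallel_analysis, pca_varimax
from stressbiomes.synthetic_data import generate_world
from stressbiomes.tolerance_models import (
    ForestParams,
    fit_axis_model,
    importance_ranking,
    partial_dependence,
    permutation_importance,
    spatial_cv_residual_check,
)

log = logging.getLogger("stressbiomes")

HOTSPOT_CLASSES = ("shade_drought", "shade_wc")

_STAGE_SEEDS = {
    "simulate": 11,
    "reduce": 13,
    "model": 17,
    "classify": 19,
}


def _stage_seed(master: int, stage: str) -> int:
    return int(
        np.random.SeedSequence((master, _STAGE_SEEDS[stage])).generate_state(1)[0]
        % (2**31)
    )


def stage_simulate(cfg: PipelineConfig, outdir: Path) -> dict:
    world_cfg = cfg.world
    species, grid, landscape, occurrences, meta = generate_world(world_cfg)
    io.write_csv(species, outdir / "species.csv")
    io.write_csv(landscape, outdir / "landscape.csv")
    io.write_csv(occurrences, outdir / "occurrences.csv")
    io.write_grid_geojson(
        grid, outdir / "landscape.geojson",
        landscape[["hex_id", "pnv_class", "true_group"]],
    )
    return meta


def stage_aggregate(cfg: PipelineConfig, outdir: Path) -> dict:
    if cfg.mode == "synthetic":
        species = pd.read_csv(outdir / "species.csv")
        occurrences = pd.read_csv(outdir / "occurrences.csv")
        landscape = pd.read_csv(outdir / "landscape.csv")
        extent = cfg.world.extent
        cell_area = cfg.world.cell_area_km2
    else:
        species = pd.read_csv(cfg.species_csv)
        occurrences = pd.read_csv(cfg.occurrences_csv)
        landscape = pd.read_csv(cfg.landscape_csv)
        pad = 1.0
        extent = (
            occurrences["x"].min() - pad,
            occurrences["y"].min() - pad,
            occurrences["x"].max() + pad,
            occurrences["y"].max() + pad,
        )
        cell_area = cfg.world.cell_area_km2

    cleaned, report = clean_occurrences(occurrences)
    grid = build_hex_grid(extent, cell_area)
    assemblages = aggregate_assemblages(
        cleaned, species, grid, landscape, min_species=cfg.min_species
    )
    io.write_csv(assemblages, outdir / "assemblages.csv")
    counts = assemblages.groupby("pft", observed=True).size().to_dict()
    return {"cleaning": report, "assemblage_counts": counts}


def _blocks(assemblages: pd.DataFrame) -> dict[str, list[str]]:
    return {
        "Clim": [c for c in CLIMATE_VARS if c in assemblages.columns],
        "Soil": [c for c in SOIL_VARS if c in assemblages.columns],
        "Traits": [f"log10_{t}" for t in TRAITS if f"log10_{t}" in assemblages.columns],
    }


def stage_reduce(cfg: PipelineConfig, outdir: Path) -> dict:
    assemblages = pd.read_csv(outdir / "assemblages.csv")
    seed = _stage_seed(cfg.seed, "reduce")
    info: dict = {}
    for pft in PFTS:
        sub = assemblages[assemblages["pft"] == pft].reset_index(drop=True)
        if len(sub) == 0:
            continue
        spaces = []
        retention = {}
        for block, cols in _blocks(sub).items():
            X = sub[cols].to_numpy(dtype=float)
            k, _ = parallel_analysis(X, n_iter=cfg.paran_iter, seed=seed)
            k = max(k, 1)  # always keep at least one component per block
            space = pca_varimax(X, k, variables=cols, block=block)
            spaces.append(space)
            retention[block] = {
                "k": k,
                "variance_explained": space.variance_explained.tolist(),
            }
            io.write_csv(
                space.loadings_frame().reset_index(names="variable"),
                outdir / f"loadings_{block.lower()}_{pft}.csv",
            )
        topo = sub[list(TOPO_VARS)].reset_index(drop=True)
        corr, max_r = cross_block_correlation(spaces, topo)
        predictors = pd.concat(
            [sub[["hex_id", "center_x", "center_y", "axis1", "axis2"]]]
            + [sp.scores_frame() for sp in spaces]
            + [topo],
            axis=1,
        )
        io.write_csv(predictors, outdir / f"predictors_{pft}.csv")
        io.write_csv(corr.reset_index(names="component"), outdir / f"component_corr_{pft}.csv")
        info[pft] = {"retention": retention, "max_abs_component_r": max_r}
    io.write_json(info, outdir / "retention.json")
    return info


def _predictor_names(frame: pd.DataFrame) -> list[str]:
    skip = {"hex_id", "center_x", "center_y", "axis1", "axis2"}
    return [c for c in frame.columns if c not in skip]


def stage_model(cfg: PipelineConfig, outdir: Path) -> dict:
    seed = _stage_seed(cfg.seed, "model")
    info: dict = {}
    n_models = 0
    for pft in PFTS:
        path = outdir / f"predictors_{pft}.csv"
        if not path.exists():
            continue
        data = pd.read_csv(path)
        predictors = _predictor_names(data)
        params = ForestParams(
            n_trees=cfg.n_trees, min_node_size=cfg.min_node_size, seed=seed
        )
        preds_out = data[["hex_id"]].copy()
        pft_info: dict = {"predictors": predictors}
        pd_frames = []
        for axis in ("axis1", "axis2"):
            model = fit_axis_model(data, axis, predictors, params, pft=pft)
            n_models += 1
            imp = permutation_importance(model, data, n_perm=cfg.n_perm, seed=seed)
            io.write_csv(imp, outdir / f"importance_{pft}_{axis}.csv")
            ranking = importance_ranking(imp)
            for name in ranking["predictor"].head(3):
                curve = partial_dependence(model, data, name)
                curve.insert(0, "axis", axis)
                pd_frames.append(curve)
            cv = spatial_cv_residual_check(
                data, axis, predictors,
                n_folds=cfg.spatial_cv_folds, params=params, seed=seed,
            )
            preds_out[f"pred_{axis}"] = model.predictions
            preds_out[f"sd_{axis}"] = model.prediction_sd
            pft_info[axis] = {
                "oob_rmse": model.oob_rmse,
                "oob_r2": model.oob_r2,
                "top_predictor": importance_ranking(imp).iloc[0]["predictor"],
                "cv_rmse": cv["cv_rmse"],
                "residual_trend_p": cv["p_values"],
            }
        io.write_csv(preds_out, outdir / f"predictions_{pft}.csv")
        io.write_csv(
            pd.concat(pd_frames, ignore_index=True),
            outdir / f"partial_dependence_{pft}.csv",
        )
        info[pft] = pft_info
    info["n_models"] = n_models
    io.write_json(info, outdir / "model_report.json")
    return info


def stage_classify(cfg: PipelineConfig, outdir: Path) -> dict:
    seed = _stage_seed(cfg.seed, "classify")
    info: dict = {}
    for pft in PFTS:
        path = outdir / f"predictions_{pft}.csv"
        if not path.exists():
            continue
        preds = pd.read_csv(path)
        X = preds[["pred_axis1", "pred_axis2"]].to_numpy()
        if len(cfg.k_range) == 1:
            # K fixed by config: best-of-n_rep restarts, no silhouette search
            K = cfg.k_range[0]
            ss = np.random.SeedSequence(seed)
            part = None
            for s_run in ss.generate_state(cfg.n_rep) % (2**31):
                cand = fuzzy_kmeans(X, K, m=cfg.fuzziness, seed=int(s_run))
                if part is None or cand.objective < part.objective:
                    part = cand
            scores, k_fixed = {}, True
        else:
            K, scores, parts = select_k_fuzzy_silhouette(
                X, cfg.k_range, n_rep=cfg.n_rep, m=cfg.fuzziness,
                alpha=cfg.fs_alpha, seed=seed,
            )
            part, k_fixed = parts[K], False

        membership = pd.DataFrame(
            part.U, columns=[f"u_{k}" for k in range(part.K)]
        )
        membership.insert(0, "hex_id", preds["hex_id"])
        io.write_csv(membership, outdir / f"membership_{pft}.csv")

        pft_info = {
            "selected_k": int(K),
            "k_fixed": k_fixed,
            "fuzzy_silhouette": {str(k): v for k, v in scores.items()},
        }
        if part.K == 4:
            ternary, labels = label_clusters_and_rescale(
                part, cfg.world.triangle, index=preds.index
            )
            ternary.insert(0, "hex_id", preds["hex_id"])
            ternary["polytolerance"] = detect_polytolerance(ternary, *cfg.band)
            hard4 = part.hard_labels()
            ternary["hard_cluster"] = [labels[int(c)] for c in hard4]
            io.write_csv(ternary, outdir / f"ternary_{pft}.csv")
            io.write_json(
                {
                    "centroids": part.centroids,
                    "labels": {str(k): v for k, v in labels.items()},
                    "objective": part.objective,
                },
                outdir / f"centroids_{pft}.json",
            )
            pft_info["polytolerance"] = polytolerance_summary(
                ternary["polytolerance"]
            ).to_dict(orient="records")
            landscape_path = outdir / "landscape.csv"
            if landscape_path.exists():
                landscape = pd.read_csv(landscape_path)
                truth = ternary.merge(
                    landscape[["hex_id", "true_group"]], on="hex_id", how="left"
                )
                pft_info["ari_vs_planted"] = float(
                    adjusted_rand_score(truth["true_group"], truth["hard_cluster"])
                )
        info[pft] = pft_info
    io.write_json(info, outdir / "classification_report.json")
    return info


def stage_hotspots(cfg: PipelineConfig, outdir: Path) -> dict:
    info: dict = {}
    for pft in PFTS:
        path = outdir / f"ternary_{pft}.csv"
        if not path.exists():
            continue
        ternary = pd.read_csv(path)
        preds = pd.read_csv(outdir / f"predictors_{pft}.csv")
        merged = ternary.merge(
            preds[["hex_id", "center_x", "center_y"]], on="hex_id", how="left"
        )
        eval_points = merged[["center_x", "center_y"]].to_numpy()
        frames = []
        counts = {}
        for cls in HOTSPOT_CLASSES:
            events = merged.loc[
                merged["polytolerance"] == cls, ["center_x", "center_y"]
            ].to_numpy()
            counts[cls] = len(events)
            import warnings as _warnings

            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore")
                surface = kde_hotspots(
                    events, eval_points, radius=cfg.kde_radius, bands=cfg.kde_bands
                )
            surface.insert(0, "hex_id", merged["hex_id"])
            surface.insert(1, "class", cls)
            frames.append(surface)
        hot = pd.concat(frames, ignore_index=True)
        io.write_csv(hot, outdir / f"hotspots_{pft}.csv")
        if cfg.mode == "synthetic":
            grid = build_hex_grid(cfg.world.extent, cfg.world.cell_area_km2)
            bands = hot.pivot(index="hex_id", columns="class", values="band")
            bands.columns = [f"band_{c}" for c in bands.columns]
            io.write_grid_geojson(
                grid, outdir / f"hotspots_{pft}.geojson",
                bands.reset_index().merge(
                    pd.DataFrame({"hex_id": grid.hex_ids}), on="hex_id", how="right"
                ).fillna("none"),
            )
        info[pft] = {"event_counts": counts}
    return info


def stage_characterize(cfg: PipelineConfig, outdir: Path) -> dict:
    info: dict = {}
    landscape_path = outdir / "landscape.csv"
    landscape = pd.read_csv(landscape_path) if landscape_path.exists() else None
    for pft in PFTS:
        path = outdir / f"ternary_{pft}.csv"
        if not path.exists():
            continue
        ternary = pd.read_csv(path)
        preds = pd.read_csv(outdir / f"predictors_{pft}.csv")
        merged = ternary.merge(preds, on="hex_id", how="left")
        # region label: polytolerance class where present, else the STB
        region = merged["stb"].where(merged["polytolerance"] == "none", merged["polytolerance"])
        score_cols = [c for c in merged.columns if c.split(".")[0] in ("Clim", "Soil", "Traits")]
        summary = summarize_strategy_space(region, merged[score_cols + list(TOPO_VARS)]
                                           if set(TOPO_VARS) <= set(merged.columns)
                                           else merged[score_cols])
        io.write_csv(summary, outdir / f"summary_{pft}.csv")
        if landscape is not None and "pnv_class" in landscape.columns:
            with_pnv = merged.merge(
                landscape[["hex_id", "pnv_class"]], on="hex_id", how="left"
            )
            overlap = overlap_with_classes(region, with_pnv["pnv_class"])
            io.write_csv(overlap, outdir / f"overlap_{pft}.csv")
            info[pft] = {"n_regions": overlap["region"].nunique()}
    return info


STAGES = (
    ("simulate", stage_simulate),
    ("aggregate", stage_aggregate),
    ("reduce", stage_reduce),
    ("model", stage_model),
    ("classify", stage_classify),
    ("hotspots", stage_hotspots),
    ("characterize", stage_characterize),
)


def run_pipeline(cfg: PipelineConfig, outdir: str | Path) -> dict:
    """Run all stages in order and write a replayable manifest."""
    cfg.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": cfg.to_dict(), "seed": cfg.seed, "stages": {}}
    for name, fn in STAGES:
        if name == "simulate" and cfg.mode != "synthetic":
            continue
        log.info("stage %s", name)
        try:
            manifest["stages"][name] = fn(cfg, outdir)
        except Exception as err:
            raise RuntimeError(f"pipeline stage {name!r} failed: {err}") from err
    manifest["n_models"] = manifest["stages"].get("model", {}).get("n_models", 0)
    manifest["selected_k"] = {
        pft: v["selected_k"]
        for pft, v in manifest["stages"].get("classify", {}).items()
        if isinstance(v, dict) and "selected_k" in v
    }
    manifest["output_hashes"] = {
        p.name: io.file_hash(p)
        for p in sorted(outdir.glob("*.csv"))
    }
    io.write_json(manifest, outdir / "manifest.json")
    return manifest
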
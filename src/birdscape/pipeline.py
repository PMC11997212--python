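"""End-to-end orchestration: detections + rasters in, models and maps out.

Stages run in the fixed order metrics → buffers → model fits → buffer
selection → predictor comparison → ordination → prediction → evaluation.
Every stage writes its artefacts into the run directory and nothing
mutates an earlier stage's output; a manifest records seeds, configuration
and input checksums so a rerun with the same config is reproducible.
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

from . import acoustic, models, ordination, prediction, raster

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_all"]


@dataclass
class PipelineConfig:
    """Inputs, thresholds and seeds for a full pipeline run.

    All randomness is surfaced as named per-stage seeds; there is no hidden
    global RNG state.
    """

    detections_csv: str = "detections.csv"
    sites_csv: str = "sites.csv"
    ndvi_grid: str = "ndvi.asc"
    ndsm_grid: str = "ndsm.asc"
    veg_mask_grid: str = "veg_mask.asc"
    centre_xy: tuple[float, float] = (2500.0, 2500.0)
    min_confidence: float = 0.8
    rare_max_total: int = 10
    rare_removals: list[str] = field(default_factory=list)
    buffer_radii_m: tuple[float, ...] = raster.BUFFER_RADII_M
    shannon_log_ndvi: bool = True
    train_fraction: float = 0.8
    n_permutations: int = 999
    nmds_starts: int = 20
    seed_split: int = 0
    seed_nmds: int = 0
    seed_permutations: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "centre_xy" in raw:
            raw["centre_xy"] = tuple(raw["centre_xy"])
        if "buffer_radii_m" in raw:
            raw["buffer_radii_m"] = tuple(raw["buffer_radii_m"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        import yaml

        d = asdict(self)
        d["centre_xy"] = list(d["centre_xy"])
        d["buffer_radii_m"] = list(d["buffer_radii_m"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline failed in stage {stage!r}: {cause}")
        self.stage = stage


def _checksum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(cfg: PipelineConfig, outdir, indir=".") -> Path:
    """Run the full analysis and return the run directory."""
    indir = Path(indir)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages": {}, "inputs": {}, "config": json.loads(json.dumps(asdict(cfg), default=list))}
    inputs = {
        "detections": indir / cfg.detections_csv,
        "sites": indir / cfg.sites_csv,
        "ndvi": indir / cfg.ndvi_grid,
        "ndsm": indir / cfg.ndsm_grid,
        "veg_mask": indir / cfg.veg_mask_grid,
    }
    for name, path in inputs.items():
        if not path.exists():
            raise StageError("inputs", FileNotFoundError(path))
        manifest["inputs"][name] = {"path": str(path), "sha256": _checksum(path)}

    def stage(name):
        def deco(fn):
            t0 = time.perf_counter()
            try:
                result = fn()
            except Exception as err:  # fail loudly with stage context
                raise StageError(name, err) from err
            manifest["stages"][name] = {"seconds": round(time.perf_counter() - t0, 3)}
            log.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
            return result

        return deco

    sites = pd.read_csv(inputs["sites"])

    @stage("metrics")
    def metrics():
        dets = acoustic.read_detections_csv(inputs["detections"])
        dets = acoustic.filter_confidence(dets, cfg.min_confidence)
        dets = acoustic.remove_singletons(dets)
        _, dets = acoustic.rare_species_review(dets, cfg.rare_max_total, cfg.rare_removals)
        effort = sites[["site_id", "days_recorded"]]
        vt = acoustic.var_per_species(dets, effort)
        div = acoustic.site_diversity(vt, site_ids=sites["site_id"])
        vt.to_csv(out / "var_table.csv", index=False)
        div.to_csv(out / "site_metrics.csv", index=False)
        return vt, div

    var_table, site_metrics = metrics

    @stage("buffers")
    def buffers():
        ndvi = raster.read_ascii_grid(inputs["ndvi"])
        ndsm = raster.read_ascii_grid(inputs["ndsm"])
        mask = raster.read_ascii_grid(inputs["veg_mask"])
        vol = raster.veg_volume_layer(ndsm, mask)
        table = raster.site_buffer_table(sites, ndvi, vol, cfg.buffer_radii_m)
        table.to_csv(out / "buffer_table.csv", index=False)
        return ndvi, table

    ndvi_layer, buffer_table = buffers

    data = site_metrics.merge(sites[["site_id", "x", "y", "week"]], on="site_id")
    data["distance_km"] = raster.distance_to_centre(data[["x", "y"]].to_numpy(), cfg.centre_xy) / 1000.0

    @stage("fit")
    def fits():
        table = models.fit_metric_buffer_models(
            data, buffer_table, cfg.buffer_radii_m, cfg.shannon_log_ndvi
        )
        table.drop(columns="fit").to_csv(out / "model_table.csv", index=False)
        return table

    model_table = fits

    @stage("buffer_selection")
    def select():
        best = models.buffer_selection(model_table)
        return best

    best_buffer = select

    @stage("comparison")
    def compare():
        summary = models.compare_predictors(model_table, best_buffer)
        with open(out / "predictor_comparison.json", "w") as fh:
            json.dump(summary, fh, indent=2, default=float)
        return summary

    comparison = compare

    @stage("ordination")
    def ordinate():
        comm = var_table.pivot_table(
            index="site_id", columns="species", values="var", fill_value=0.0
        )
        comm = comm.loc[comm.sum(axis=1) > 0]
        D_bc = ordination.bray_curtis(comm, log1p=True)
        res = ordination.nmds(
            D_bc, k=2, n_starts=cfg.nmds_starts, seed=cfg.seed_nmds, site_labels=comm.index
        )
        res.species_scores = ordination.species_scores(res, comm)
        env = (
            data.set_index("site_id")
            .loc[comm.index, ["week", "distance_km"]]
            .assign(week=lambda d: d["week"].astype(str))
        )
        bb = buffer_table[buffer_table["radius_m"] == best_buffer].set_index("site_id")
        env["mean_ndvi"] = bb.loc[comm.index, "mean_ndvi"]
        env["log_veg_volume"] = bb.loc[comm.index, "log_veg_volume"]
        res = ordination.rotate_to_variable(res, env["mean_ndvi"].to_numpy())
        ef = ordination.envfit(res, env, n_perm=cfg.n_permutations, seed=cfg.seed_permutations)

        comm_pa = ordination.to_presence_absence(comm)
        D_j = ordination.jaccard(comm_pa)
        res_pa = ordination.nmds(
            D_j, k=2, n_starts=cfg.nmds_starts, seed=cfg.seed_nmds + 1, site_labels=comm.index
        )
        m2, t, p_pro = ordination.procrustes_protest(
            res.scores, res_pa.scores, n_perm=cfg.n_permutations, seed=cfg.seed_permutations
        )
        r_mantel, p_mantel = ordination.mantel(
            D_bc, D_j, n_perm=cfg.n_permutations, seed=cfg.seed_permutations
        )
        scores = pd.DataFrame(res.scores, index=comm.index, columns=["nmds1", "nmds2"])
        scores.to_csv(out / "nmds_site_scores.csv")
        res.species_scores.to_csv(out / "nmds_species_scores.csv")
        report = {
            "stress_bray_curtis": res.stress,
            "linear_r2_bray_curtis": res.linear_r2,
            "stress_jaccard": res_pa.stress,
            "envfit_vectors": ef.vectors.to_dict(orient="index"),
            "envfit_factors": {
                k: {"r2": v["r2"], "p": v["p"]} for k, v in ef.factors.items()
            },
            "procrustes": {"m2": m2, "t": t, "p": p_pro},
            "mantel": {"r": r_mantel, "p": p_mantel},
        }
        with open(out / "ordination_report.json", "w") as fh:
            json.dump(report, fh, indent=2, default=float)
        return report

    ordination_report = ordinate

    @stage("predict")
    def predict():
        train, test = prediction.split_data(
            data, prediction.SplitSpec(cfg.train_fraction, cfg.seed_split)
        )
        bb = buffer_table[buffer_table["radius_m"] == best_buffer][
            ["site_id", "mean_ndvi", "log_veg_volume"]
        ]
        train_m = train.merge(bb, on="site_id")
        test_m = test.merge(bb, on="site_id")
        ndvi100 = raster.aggregate(ndvi_layer, 100.0, stat="mean")
        report = {"best_buffer_m": best_buffer, "metrics": {}}
        for response in models.RESPONSES:
            logp = cfg.shannon_log_ndvi and response == "shannon"
            spec = models.ModelSpec(response, "mean_ndvi", best_buffer, log_predictor=logp)
            fit = models.fit_ols(spec, train_m)
            grid, extrap = prediction.predict_grid(fit, ndvi100, cfg.centre_xy)
            grid.to_ascii_grid(out / f"prediction_{response}.asc")
            pred = prediction.predict_rows(fit, test_m)
            obs = test_m[response].to_numpy()
            rmse, mae = prediction.evaluate(pred, obs)
            sma = prediction.sma_regression(obs, pred)
            report["metrics"][response] = {
                "train_r_squared": fit.r_squared,
                "rmse": rmse,
                "mae": mae,
                "sma": sma,
                "extrapolated_cells": int(np.nansum(extrap.values)),
            }
        with open(out / "evaluation.json", "w") as fh:
            json.dump(report, fh, indent=2, default=float)
        return report

    evaluation = predict

    manifest["summary"] = {
        "n_sites": int(len(sites)),
        "best_buffer_m": float(best_buffer),
        "best_predictor": comparison["best_predictor"],
        "nmds_stress": ordination_report["stress_bray_curtis"],
        "rmse": {m: v["rmse"] for m, v in evaluation["metrics"].items()},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    cfg.to_yaml(out / "config.yaml")
    return out
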
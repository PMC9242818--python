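"""One-shot orchestration: segment -> evaluate -> features -> select -> classify.

A run is driven by a single config mapping (YAML/JSON on disk); every stage
writes its artefacts into the output directory and the run manifest records
the materialised config, a config hash, per-stage status and the outputs, so
a saved config re-runs bit-identically for the deterministic stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
import traceback
from dataclasses import asdict
from pathlib import Path

import numpy as np
import yaml

from . import __version__, classify, io, levelset, metrics, phantom, selection, texture
from .segment import segment, triangle_seed
from .tables import FeatureTable

logger = logging.getLogger(__name__)

STAGES = ("inputs", "segment", "evaluate", "features", "select", "classify")


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()


def demo_config(output_dir: str | Path, seed: int = 0) -> dict:
    """A self-contained configuration exercising every stage on phantoms."""
    return {
        "output_dir": str(output_dir),
        "seed": seed,
        "phantom": {"noise_sd": 5.0, "seed": seed},
        "segment": {
            "sigma": 1.0,
            "i0": "auto",
            "i0_window": [38, 54, 50, 74],  # straddles the lesion boundary
            "seed_triangle": {"center": [64, 64], "radius": 8},
            "evolve": {"max_iters": 400},
        },
        "evaluate": {},
        "features": {},
        "feature_table": {"seed": seed},
        "select": {"k": 10},
        "classify": {"nda_scheme": "kfold"},
    }


def _materialise(config: dict) -> dict:
    """Fill defaults so the manifest records the complete effective config."""
    out = {"seed": 0, "log_level": "INFO", **config}
    if "phantom" in out:
        out["phantom"] = asdict(phantom.PhantomSpec(**out["phantom"]))
    if "feature_table" in out:
        out["feature_table"] = asdict(phantom.FeatureTableSpec(**out["feature_table"]))
    seg = dict(out.get("segment", {}))
    seg.setdefault("sigma", 1.0)
    seg.setdefault("i0", "auto")
    seg.setdefault("indicator", "enhanced")
    seg["evolve"] = asdict(levelset.EvolveParams(**seg.get("evolve", {})))
    out["segment"] = seg
    return out


def run_pipeline(config: dict) -> dict:
    """Execute all configured stages; returns (and writes) the run manifest.

    A stage failure is recorded in the manifest and the dependent stages are
    skipped rather than aborting the run.
    """
    config = _materialise(config)
    outdir = Path(config.get("output_dir", "lsradiomics_run"))
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, str(config.get("log_level", "INFO"))))

    manifest: dict = {
        "version": __version__,
        "config": config,
        "config_hash": config_hash(config),
        "stages": {},
    }

    def record(stage: str, status: str, **info) -> None:
        manifest["stages"][stage] = {"status": status, **info}

    state: dict = {}

    def run_stage(stage: str, fn) -> bool:
        upstream_failed = any(
            s["status"] != "ok" for s in manifest["stages"].values()
        )
        if upstream_failed:
            record(stage, "skipped", reason="upstream failure")
            return False
        try:
            info = fn() or {}
            record(stage, "ok", **info)
            return True
        except Exception as exc:
            logger.error("stage %s failed: %s", stage, exc)
            record(stage, "failed", error=str(exc), trace=traceback.format_exc(limit=3))
            return False

    # -- inputs -------------------------------------------------------------
    def _inputs():
        if "phantom" in config:
            spec = phantom.PhantomSpec(**config["phantom"])
            img, truth = phantom.generate_phantom(spec)
            io.write_image(outdir / "phantom.png", img)
            io.write_mask(outdir / "truth.png", truth)
            state["image"], state["truth"] = img, truth
            return {"source": "phantom", "outputs": ["phantom.png", "truth.png"]}
        inputs = config["inputs"]
        state["image"] = io.read_image(inputs["image"])
        if "truth" in inputs:
            state["truth"] = io.read_mask(inputs["truth"])
        return {"source": "files"}

    run_stage("inputs", _inputs)

    # -- segment ------------------------------------------------------------
    def _segment():
        seg = config["segment"]
        if "seed_polygon" in seg:
            poly = np.asarray(seg["seed_polygon"], dtype=float)
        else:
            tri = seg.get("seed_triangle", {"center": [64, 64], "radius": 8})
            poly = triangle_seed(tuple(tri["center"]), tri["radius"])
        result = segment(
            state["image"],
            poly,
            roi=tuple(seg["roi"]) if "roi" in seg else None,
            sigma=seg["sigma"],
            i0=seg["i0"],
            i0_window=tuple(seg["i0_window"]) if seg.get("i0_window") else None,
            indicator=seg["indicator"],
            evolve_params=levelset.EvolveParams(**seg["evolve"]),
        )
        io.write_mask(outdir / "mask.png", result.mask)
        state["mask"] = result.mask
        return {
            "outputs": ["mask.png"],
            "i0": result.i0,
            "iterations": result.iterations,
            "converged": bool(result.converged),
        }

    run_stage("segment", _segment)

    # -- evaluate -----------------------------------------------------------
    def _evaluate():
        if "truth" not in state:
            return {"note": "no reference mask; evaluation skipped"}
        res = metrics.evaluate(state["mask"], state["truth"])
        (outdir / "eval.json").write_text(json.dumps(res.to_dict(), indent=2))
        return {"outputs": ["eval.json"], **res.to_dict()}

    run_stage("evaluate", _evaluate)

    # -- features -----------------------------------------------------------
    def _features():
        cfg = texture.TextureConfig(**config.get("features", {}))
        vec = texture.extract_all(state["image"], state["mask"], cfg)
        vec.to_csv(outdir / "features.csv", header=["value"])
        return {"outputs": ["features.csv"], "n_features": int(len(vec))}

    run_stage("features", _features)

    # -- select + classify (on the cohort-level feature table) ---------------
    def _load_table() -> FeatureTable:
        ft_cfg = config["feature_table"]
        if "path" in ft_cfg:
            return FeatureTable.from_csv(ft_cfg["path"])
        return phantom.generate_feature_table(phantom.FeatureTableSpec(**ft_cfg))

    def _select():
        table = _load_table()
        state["table"] = table
        k = config.get("select", {}).get("k", 10)
        results, combined = selection.select_all_methods(table, k)
        state["selection"] = results
        for method, res in results.items():
            (outdir / f"selected_{method}.csv").write_text(
                "feature\n" + "\n".join(res.selected) + "\n"
            )
        return {
            "outputs": [f"selected_{m}.csv" for m in results],
            "combined_count": len(combined),
        }

    run_stage("select", _select)

    def _classify():
        table: FeatureTable = state["table"]
        cls_cfg = config.get("classify", {})
        scheme = cls_cfg.get("nda_scheme", "loo")
        grid: dict[str, dict[str, classify.ClassifyResult]] = {}
        for sel_method, sel_res in state["selection"].items():
            sub = table.select(sel_res.selected)
            grid[sel_method] = {
                "rda": classify.rda(sub),
                "pca": classify.pca_analysis(sub),
                "lda": classify.lda(sub),
                "nda": classify.nda(
                    sub, seed=int(config.get("seed", 0)), scheme=scheme
                ),
            }
        report = {
            sel: {m: r.cell() for m, r in row.items()} for sel, row in grid.items()
        }
        (outdir / "report.json").write_text(json.dumps(report, indent=2))
        (outdir / "report.txt").write_text(classify.mcr_report(grid) + "\n")
        manifest["mcr_grid"] = report
        return {"outputs": ["report.json", "report.txt"]}

    run_stage("classify", _classify)

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
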
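"""End-to-end orchestration: simulate -> features -> score -> cluster.

Stages communicate only via files (CSV / TIFF / Newick) so any stage can
be re-run or inspected independently, and a machine-readable manifest
records the configuration hash, master seed, per-stage timing, warning
counts and SHA-256 checksums of every data output. Re-running with the
same configuration and seed reproduces identical checksums.
"""

from __future__ import annotations

import hashlib
import json
import re
import time
import warnings
from pathlib import Path

import pandas as pd
import tifffile

from . import __version__
from .cluster import build_profile_matrix, cluster_profiles, export_heatmap
from .morphometry import (
    LabeledImagePair,
    aggregate_cells_frame,
    compute_cell_features,
    records_to_frame,
)
from .screenstats import (
    ScreenConfig,
    call_hits,
    confusion_vs_truth,
    score_screens,
    summarize_screen,
)
from .synth import (
    EffectModel,
    generate_screen_set,
    layouts_to_frame,
    make_layouts,
    write_image_screen,
)


class ConfigError(ValueError):
    """Raised at startup for an invalid pipeline configuration."""


DEFAULT_CONFIG: dict = {
    "seed": 0,
    "tier": "features",  # "features" (fast, statistical) or "images"
    "scale": {
        "n_plates": 2,
        "n_screens": 3,
        "cells_per_well": 50,
        "fields_per_well": 8,
        "image_size": 512,
    },
    "effects": {
        "fraction_hits_decrease": 0.08,
        "fraction_hits_increase": 0.10,
        "effect_magnitude": 0.35,
        "between_screen_sd": 0.03,
        "well_noise_sd": 0.04,
        "cell_cv": 0.30,
    },
    "scoring": {
        "z_threshold": 1.5,
        "min_screens": 2,
        "robust": False,
        "sign_consistency": True,
        "min_cells": 20,
    },
    "cluster": {
        "metric": "euclidean",
        "all_genes": False,
        "render": True,
    },
}


def validate_config(config: dict | None) -> dict:
    """Merge a user config over the defaults, rejecting unknown keys."""
    merged = json.loads(json.dumps(DEFAULT_CONFIG))
    if config is None:
        return merged
    bad: list[str] = []
    for key, val in config.items():
        if key not in merged:
            bad.append(key)
            continue
        if isinstance(merged[key], dict):
            if not isinstance(val, dict):
                raise ConfigError(f"section {key!r} must be a mapping")
            for sub, sval in val.items():
                if sub not in merged[key]:
                    bad.append(f"{key}.{sub}")
                else:
                    merged[key][sub] = sval
        else:
            merged[key] = val
    if bad:
        raise ConfigError(f"unknown configuration key(s): {', '.join(sorted(bad))}")
    if merged["tier"] not in ("features", "images"):
        raise ConfigError(f"unknown tier {merged['tier']!r}")
    return merged


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _screen_config(cfg: dict) -> ScreenConfig:
    sc = cfg["scoring"]
    return ScreenConfig(
        z_threshold=sc["z_threshold"],
        min_screens=sc["min_screens"],
        n_screens=cfg["scale"]["n_screens"],
        z_variant="robust" if sc["robust"] else "classical",
        require_sign_consistency=sc["sign_consistency"],
        min_cells=sc["min_cells"],
    )


MASK_NAME = re.compile(
    r"(?P<plate>[^_]+)_(?P<well>[A-H]\d{2})_S(?P<screen>\d+)_(?P<field>[^_]+)_cell\.tif$"
)


def features_from_masks(mask_dir, *, pixel_size: float = 1.0) -> pd.DataFrame:
    """Measure every `*_cell.tif`/`*_nuc.tif` pair under ``mask_dir``."""
    mask_dir = Path(mask_dir)
    frames = []
    for cell_path in sorted(mask_dir.glob("*_cell.tif")):
        m = MASK_NAME.search(cell_path.name)
        if not m:
            warnings.warn(f"unparseable mask name {cell_path.name} skipped")
            continue
        nuc_path = cell_path.with_name(cell_path.name[: -len("_cell.tif")] + "_nuc.tif")
        pair = LabeledImagePair(
            cell_mask=tifffile.imread(cell_path),
            nucleus_mask=tifffile.imread(nuc_path),
            pixel_size=pixel_size,
            field_id=m["field"],
            well_id=m["well"],
            plate_id=m["plate"],
            screen_id=int(m["screen"]),
        )
        recs = compute_cell_features(pair)
        if recs:
            frames.append(records_to_frame(recs))
    if not frames:
        return pd.DataFrame()
    return pd.concat(frames, ignore_index=True)


def run_pipeline(config: dict | None, out_dir, *, seed: int | None = None) -> dict:
    """Execute the full synthetic-screen pipeline and write a manifest.

    ``seed`` overrides the config's master seed. Returns the manifest
    dict (also written to ``manifest.json``). Any stage error aborts with
    the failure recorded in the manifest before the exception propagates.
    """
    cfg = validate_config(config)
    if seed is not None:
        cfg["seed"] = int(seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    cfg_json = json.dumps(cfg, sort_keys=True)
    manifest: dict = {
        "package_version": __version__,
        "config": cfg,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "master_seed": cfg["seed"],
        "stages": {},
        "outputs": {},
    }

    def run_stage(name, fn):
        t0 = time.perf_counter()
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            try:
                result = fn()
            except Exception as exc:
                manifest["stages"][name] = {
                    "status": "failed",
                    "error": f"{type(exc).__name__}: {exc}",
                    "seconds": round(time.perf_counter() - t0, 3),
                }
                (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
                raise
        manifest["stages"][name] = {
            "status": "ok",
            "seconds": round(time.perf_counter() - t0, 3),
            "n_warnings": len(caught),
            "warnings": [str(w.message) for w in caught[:10]],
        }
        return result

    scale = cfg["scale"]
    layouts = make_layouts(n_plates=scale["n_plates"], n_screens=scale["n_screens"])
    genes = sorted(
        {t for lo in layouts for t in lo.library_wells().values()}
    )
    effects = EffectModel.plant(genes, cfg["seed"], **cfg["effects"])

    # -- simulate ----------------------------------------------------------
    def stage_simulate():
        truth = effects.truth_frame()
        truth.to_csv(out / "truth.csv", index=False)
        layouts_to_frame(layouts).to_csv(out / "layout.csv", index=False)
        if cfg["tier"] == "images":
            mask_dir = out / "masks"
            write_image_screen(
                mask_dir,
                layouts,
                effects,
                cells_per_well=scale["cells_per_well"],
                seed=cfg["seed"],
                fields_per_well=scale["fields_per_well"],
                image_size=scale["image_size"],
            )
            return mask_dir
        cells, _ = generate_screen_set(
            layouts,
            effects,
            cells_per_well=scale["cells_per_well"],
            seed=cfg["seed"],
            fields_per_well=scale["fields_per_well"],
        )
        cells.to_csv(out / "cells.csv", index=False)
        return cells

    sim_result = run_stage("simulate", stage_simulate)

    # -- features ----------------------------------------------------------
    def stage_features():
        layout_df = pd.read_csv(out / "layout.csv")
        if cfg["tier"] == "images":
            cells = features_from_masks(sim_result)
            cells.to_csv(out / "cells.csv", index=False)
        else:
            cells = sim_result
        wells = aggregate_cells_frame(
            cells, layout_df, min_cells=cfg["scoring"]["min_cells"]
        )
        wells.to_csv(out / "wells.csv", index=False)
        return wells

    wells = run_stage("features", stage_features)

    # -- score -------------------------------------------------------------
    def stage_score():
        sc = _screen_config(cfg)
        ztable = score_screens(wells, sc)
        ztable.to_csv(out / "zscores.csv", index=False)
        hits = call_hits(ztable, sc)
        hits.to_csv(out / "hits.csv", index=False)
        summary = summarize_screen(hits)
        truth = pd.read_csv(out / "truth.csv")
        summary["recovery"] = confusion_vs_truth(hits, truth)
        (out / "summary.json").write_text(json.dumps(summary, indent=2))
        return ztable, hits, summary

    ztable, hits, summary = run_stage("score", stage_score)

    # -- cluster -----------------------------------------------------------
    def stage_cluster():
        cl_cfg = cfg["cluster"]
        gene_subset = (
            None if cl_cfg["all_genes"] else hits.loc[hits["hit"], "gene"].tolist()
        )
        if gene_subset is not None and len(gene_subset) < 2:
            warnings.warn("fewer than 2 hit genes; clustering all genes")
            gene_subset = None
        matrix = build_profile_matrix(ztable, gene_subset)
        clustering = cluster_profiles(matrix, metric=cl_cfg["metric"])
        export_heatmap(clustering, out / "profiles", render=cl_cfg["render"])
        return clustering

    run_stage("cluster", stage_cluster)

    manifest["summary"] = summary
    for f in sorted(out.glob("*.csv")) + sorted(out.glob("*.nwk")) + sorted(
        out.glob("*.json")
    ):
        if f.name != "manifest.json":
            manifest["outputs"][f.name] = _sha256(f)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
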
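"""Stage orchestration: each stage reads the CSV artifacts of the previous
ones from the run directory and writes its own atomically, alongside a
manifest (config, seed, package version, input checksums, filter counts).

Stage order: simulate -> evi -> greenup -> nestbox -> prepare -> annual /
lmm / synchrony / mantel / cloudscan; ``all`` runs the full chain.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .breeding import prepare_analysis_table
from .cloudscan import annual_synchrony_series, enumerate_windows, scan_windows
from .config import PipelineConfig
from .errors import PipelineError, UndefinedStatisticError
from .greenup import extract_greenup_map, z_transform_map
from .mantel import mantel_correlogram
from .models import (annual_correlation, annual_phenology_table, fit_breeding_lmm,
                     phenology_residuals)
from .evi2 import aggregate_periods
from .simulate import simulate_dataset, write_dataset
from .synchrony import (compare_species_synchrony, habitat_overlay,
                        habitat_regression_table, pixel_synchrony)
from .weighting import PixelGrid, nestbox_greenup_table

logger = logging.getLogger(__name__)

STAGES = ("simulate", "evi", "greenup", "nestbox", "prepare", "annual", "lmm",
          "synchrony", "mantel", "cloudscan", "all")

#: artifacts each stage needs, mapped to the stage that produces them
_REQUIRES = {
    "evi": {"observations.csv": "simulate"},
    "greenup": {"evi_series.csv": "evi"},
    "nestbox": {"greenup.csv": "greenup", "nestboxes.csv": "simulate",
                "grid.csv": "simulate"},
    "prepare": {"breeding.csv": "simulate", "nestboxes.csv": "simulate",
                "nestbox_greenup.csv": "nestbox"},
    "annual": {"analysis_table.csv": "prepare", "greenup.csv": "greenup",
               "grid.csv": "simulate", "halffall.csv": "simulate"},
    "lmm": {"analysis_table.csv": "prepare"},
    "synchrony": {"analysis_table.csv": "prepare", "greenup.csv": "greenup",
                  "grid.csv": "simulate", "overlaps.csv": "simulate",
                  "compartments.csv": "simulate"},
    "mantel": {"analysis_table.csv": "prepare", "synchrony_map.csv": "synchrony",
               "grid.csv": "simulate", "nestboxes.csv": "simulate"},
    "cloudscan": {"analysis_table.csv": "prepare", "cloud.csv": "simulate"},
}


def _stage_seed(base_seed: int, stage: str) -> int:
    h = hashlib.sha256(f"{base_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _atomic_write_csv(df: pd.DataFrame, path: Path) -> None:
    tmp = path.with_suffix(path.suffix + ".tmp")
    df.to_csv(tmp, index=False)
    os.replace(tmp, path)


def _atomic_write_json(obj, path: Path) -> None:
    tmp = path.with_suffix(path.suffix + ".tmp")
    tmp.write_text(json.dumps(obj, indent=2, default=_json_default))
    os.replace(tmp, path)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        v = float(o)
        return v if np.isfinite(v) else None
    raise TypeError(f"not JSON serializable: {type(o)}")


def _require(outdir: Path, stage: str) -> dict:
    found = {}
    for fname, producer in _REQUIRES.get(stage, {}).items():
        p = outdir / fname
        if not p.exists():
            raise PipelineError(
                f"stage {stage!r} needs {fname}; run stage {producer!r} first")
        found[fname] = p
    return found


def _manifest(outdir: Path, stage: str, config: PipelineConfig, inputs: dict,
              outputs: dict, counts: dict) -> None:
    _atomic_write_json({
        "stage": stage, "version": __version__, "seed": config.seed,
        "config": config.to_dict(),
        "inputs": {k: _checksum(p) for k, p in inputs.items()},
        "outputs": {k: _checksum(Path(p)) for k, p in outputs.items()},
        "counts": counts,
    }, outdir / f"manifest_{stage}.json")


def run_stage(stage: str, config: PipelineConfig) -> dict:
    """Run one pipeline stage; returns {artifact name: path}."""
    if stage not in STAGES:
        raise PipelineError(f"unknown stage {stage!r}; expected one of {STAGES}")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if stage == "all":
        outputs = {}
        for st in STAGES[:-1]:
            outputs.update(run_stage(st, config))
        return outputs
    inputs = _require(outdir, stage)
    fn = globals()[f"_stage_{stage}"]
    outputs, counts = fn(outdir, config, inputs)
    _manifest(outdir, stage, config, inputs, outputs, counts)
    logger.info("stage %s done: %s", stage, {k: str(v) for k, v in outputs.items()})
    return outputs


def _stage_simulate(outdir, config, inputs):
    sim_cfg = config.simulation.replace(seed=_stage_seed(config.seed, "simulate"))
    bundle = simulate_dataset(sim_cfg)
    paths = write_dataset(bundle, outdir)
    counts = {"observations": len(bundle.observations),
              "breeding_records": len(bundle.breeding),
              "nestboxes": len(bundle.landscape.nestboxes)}
    return paths, counts


def _stage_evi(outdir, config, inputs):
    obs = pd.read_csv(inputs["observations.csv"])
    series = aggregate_periods(obs)
    p = outdir / "evi_series.csv"
    _atomic_write_csv(series, p)
    counts = {"observations_in": len(obs),
              "cloudy_excluded": int((obs["cloudy"] == 1).sum()),
              "series_rows": len(series),
              "missing_periods": int(series["evi2"].isna().sum())}
    return {"evi_series.csv": p}, counts


def _stage_greenup(outdir, config, inputs):
    series = pd.read_csv(inputs["evi_series.csv"])
    gmap = extract_greenup_map(series, min_periods=config.min_periods,
                               ci_bootstrap=config.ci_bootstrap,
                               seed=_stage_seed(config.seed, "greenup"))
    gmap = z_transform_map(gmap)
    p = outdir / "greenup.csv"
    _atomic_write_csv(gmap, p)
    counts = {"pixel_years": len(gmap),
              "converged": int(gmap["converged"].sum()),
              "dropped": int((~gmap["converged"]).sum())}
    return {"greenup.csv": p}, counts


def _stage_nestbox(outdir, config, inputs):
    gmap = pd.read_csv(inputs["greenup.csv"])
    grid_df = pd.read_csv(inputs["grid.csv"])
    boxes = pd.read_csv(inputs["nestboxes.csv"])
    grid = PixelGrid.from_dataframe(grid_df, config.simulation.pixel_size)
    table = nestbox_greenup_table(boxes, gmap, grid)
    p = outdir / "nestbox_greenup.csv"
    _atomic_write_csv(table, p)
    counts = {"box_years_assigned": len(table),
              "box_years_possible": len(boxes) * gmap["year"].nunique()}
    return {"nestbox_greenup.csv": p}, counts


def _stage_prepare(outdir, config, inputs):
    records = pd.read_csv(inputs["breeding.csv"])
    boxes = pd.read_csv(inputs["nestboxes.csv"])
    nbg = pd.read_csv(inputs["nestbox_greenup.csv"])
    table, excluded, rejects = prepare_analysis_table(
        records, boxes, nbg, brood_window=config.brood_window_days)
    p1, p2, p3 = (outdir / "analysis_table.csv", outdir / "excluded.csv",
                  outdir / "rejects.csv")
    _atomic_write_csv(table, p1)
    _atomic_write_csv(excluded, p2)
    _atomic_write_csv(rejects, p3)
    counts = {"records_in": len(records), "retained": len(table),
              "excluded_late_broods": len(excluded), "rejected": len(rejects)}
    assert counts["retained"] + counts["excluded_late_broods"] + \
        counts["rejected"] == counts["records_in"]
    return {"analysis_table.csv": p1, "excluded.csv": p2, "rejects.csv": p3}, counts


def _stage_annual(outdir, config, inputs):
    table = pd.read_csv(inputs["analysis_table.csv"])
    gmap = pd.read_csv(inputs["greenup.csv"])
    grid_df = pd.read_csv(inputs["grid.csv"])
    halffall = pd.read_csv(inputs["halffall.csv"])
    annual = annual_phenology_table(gmap, grid_df, table, halffall,
                                    woodland_threshold=config.woodland_threshold)
    p = outdir / "annual_phenology.csv"
    _atomic_write_csv(annual, p)
    correlations = {}
    pairs = [("halffall_day", "greenup_vs_halffall")]
    for sp in config.species:
        pairs += [(f"mean_laying_{sp}", f"greenup_vs_laying_{sp}"),
                  (f"mean_hatch_{sp}", f"greenup_vs_hatch_{sp}")]
    for col, name in pairs:
        if col not in annual.columns:
            continue
        try:
            r, pval, n = annual_correlation(annual["mean_greenup"], annual[col])
            correlations[name] = {"r": r, "p": pval, "n": n}
        except UndefinedStatisticError as err:
            correlations[name] = {"error": str(err)}
    pj = outdir / "annual_correlations.json"
    _atomic_write_json(correlations, pj)
    return {"annual_phenology.csv": p, "annual_correlations.json": pj}, \
        {"years": len(annual)}


def _stage_lmm(outdir, config, inputs):
    table = pd.read_csv(inputs["analysis_table.csv"])
    fits = {}
    for sp in config.species:
        sub = table[table["species"] == sp]
        for response in ("laying_day", "hatch_day"):
            if response not in sub.columns:
                continue
            for cov in ("minimal", "full"):
                fit = fit_breeding_lmm(sub, response=response, covariates=cov,
                                       female_re=config.female_re)
                fits[f"{sp}.{response}.{cov}"] = fit.summary_dict()
    p = outdir / "model_fits.json"
    _atomic_write_json(fits, p)
    return {"model_fits.json": p}, {"models": len(fits)}


def _stage_synchrony(outdir, config, inputs):
    table = pd.read_csv(inputs["analysis_table.csv"])
    gmap = pd.read_csv(inputs["greenup.csv"])
    grid_df = pd.read_csv(inputs["grid.csv"])
    overlaps = pd.read_csv(inputs["overlaps.csv"])
    comp = pd.read_csv(inputs["compartments.csv"])
    habitat = habitat_overlay(overlaps, comp)
    ph = outdir / "pixel_habitat.csv"
    _atomic_write_csv(habitat, ph)

    outputs = {"pixel_habitat.csv": ph}
    counts = {}
    maps = {}
    reg_frames = []
    for sp in config.species:
        sub = table[table["species"] == sp]
        sync = pixel_synchrony(sub, gmap, grid_df, min_years=config.min_years,
                               woodland_threshold=config.woodland_threshold)
        maps[sp] = sync
        p = outdir / f"synchrony_map_{sp}.csv"
        _atomic_write_csv(sync, p)
        outputs[f"synchrony_map_{sp}.csv"] = p
        counts[f"{sp}_pixels_included"] = int(sync["included"].sum())
        reg_frames.append(habitat_regression_table(sync, habitat, species=sp))
    preg = outdir / "habitat_regressions.csv"
    _atomic_write_csv(pd.concat(reg_frames, ignore_index=True), preg)
    outputs["habitat_regressions.csv"] = preg
    # keep a combined map for downstream stages
    combined = pd.concat([m.assign(species=sp) for sp, m in maps.items()],
                         ignore_index=True)
    pc = outdir / "synchrony_map.csv"
    _atomic_write_csv(combined, pc)
    outputs["synchrony_map.csv"] = pc
    if len(maps) == 2:
        sp_a, sp_b = config.species
        comp_res = compare_species_synchrony(maps[sp_a], maps[sp_b])
        comp_res["species_a"], comp_res["species_b"] = sp_a, sp_b
        pj = outdir / "species_comparison.json"
        _atomic_write_json(comp_res, pj)
        outputs["species_comparison.json"] = pj
    return outputs, counts


def _stage_mantel(outdir, config, inputs, min_box_years: int = 7):
    table = pd.read_csv(inputs["analysis_table.csv"])
    sync = pd.read_csv(inputs["synchrony_map.csv"])
    grid_df = pd.read_csv(inputs["grid.csv"])
    boxes = pd.read_csv(inputs["nestboxes.csv"])
    seed = _stage_seed(config.seed, "mantel")
    outputs, counts = {}, {}
    for sp in config.species:
        sub = table[table["species"] == sp].copy()
        resid = phenology_residuals(sub, female_re=config.female_re)
        sub = sub.loc[resid.index]
        sub["resid"] = resid
        per_box = sub.groupby("box_id").agg(value=("resid", "mean"),
                                            n=("resid", "size")).reset_index()
        per_box = per_box[per_box["n"] >= min_box_years]
        per_box = per_box.merge(boxes[["box_id", "x", "y"]], on="box_id")
        if len(per_box) >= 4:
            cg = mantel_correlogram(per_box[["x", "y"]].to_numpy(),
                                    per_box["value"].to_numpy(), seed=seed)
            p = outdir / f"correlogram_laying_{sp}.csv"
            _atomic_write_csv(cg.table, p)
            outputs[f"correlogram_laying_{sp}.csv"] = p
            counts[f"{sp}_boxes_used"] = len(per_box)
        ssub = sync[(sync["species"] == sp) & sync["included"]].merge(
            grid_df[["pixel_id", "x", "y"]], on="pixel_id")
        if len(ssub) >= 4:
            cg = mantel_correlogram(ssub[["x", "y"]].to_numpy(),
                                    ssub["r"].to_numpy(), seed=seed)
            p = outdir / f"correlogram_synchrony_{sp}.csv"
            _atomic_write_csv(cg.table, p)
            outputs[f"correlogram_synchrony_{sp}.csv"] = p
    return outputs, counts


def _stage_cloudscan(outdir, config, inputs):
    table = pd.read_csv(inputs["analysis_table.csv"])
    cloud = pd.read_csv(inputs["cloud.csv"])
    windows = enumerate_windows(config.window_min_len, config.window_max_len,
                                config.window_horizon)
    outputs, counts = {}, {"n_windows": len(windows)}
    sync_frames = []
    for sp in config.species:
        sub = table[table["species"] == sp]
        sync = annual_synchrony_series(sub)
        sync_frames.append(sync.rename(sp))
        scan = scan_windows(windows, cloud, sync)
        p = outdir / f"window_scan_{sp}.csv"
        _atomic_write_csv(scan, p)
        outputs[f"window_scan_{sp}.csv"] = p
        counts[f"{sp}_years_used"] = int(sync.notna().sum())
    ps = outdir / "annual_synchrony.csv"
    _atomic_write_csv(pd.concat(sync_frames, axis=1).reset_index(), ps)
    outputs["annual_synchrony.csv"] = ps
    return outputs, counts
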
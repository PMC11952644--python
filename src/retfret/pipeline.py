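"""Run orchestration: simulate / quantify / typecall / longitudinal / report.

A JSON run configuration names the stages to execute and their parameters;
every stage writes CSV tables (and the report stage PNG figures) into the
output directory, plus a manifest recording the seed, package version and
configuration so runs are reproducible byte for byte.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, movie_io, preprocess, quant, scene, segment, survival
from .histology import assign_types, fit_landmark_warp, iqr_positive

__all__ = ["run_pipeline", "DEFAULT_CONFIG"]

STAGES = ("simulate", "quantify", "typecall", "longitudinal", "report")

DEFAULT_CONFIG: dict = {
    "stages": ["simulate", "quantify", "typecall", "longitudinal", "report"],
    "scene": {"n_cells": 40, "field_shape": [160, 160], "n_frames": 60},
    "acquisitions": [{"id": "baseline"}, {"id": "post", "drug": "ROT"}],
    "baseline_acquisition": "baseline",
    "quant": {"min_pixels": 100, "min_sum_intensity": 50.0, "smooth_window": 20},
    "longitudinal": {"n_cells": 120, "frames_per_day": 40},
}

_FLOAT_FMT = "%.10g"


def run_pipeline(config: dict | str | Path, seed: int = 0,
                 outdir: str | Path = "results/run") -> dict:
    """Execute the configured stages in order; returns a dict of the key
    output paths. Unknown stage names fail fast."""
    if not isinstance(config, dict):
        config = json.loads(Path(config).read_text())
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = config.get("stages", list(STAGES))
    for s in stages:
        if s not in STAGES:
            raise ValueError(f"unknown stage {s!r}; known stages: {STAGES}")
    state: dict = {"outputs": {}}
    for s in stages:
        _STAGE_FNS[s](config, seed, outdir, state)
    manifest = {"seed": seed, "version": __version__, "stages": stages,
                "config": {k: v for k, v in config.items() if k != "stages"},
                "outputs": {k: str(v) for k, v in state["outputs"].items()}}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    state["outputs"]["manifest"] = outdir / "manifest.json"
    return state["outputs"]


def _stage_simulate(config, seed, outdir, state):
    sc_cfg = dict(config.get("scene", {}))
    sc_cfg["field_shape"] = tuple(sc_cfg.get("field_shape", (160, 160)))
    base = scene.make_scene(seed=seed, **sc_cfg)
    state["scenes"] = {}
    for acq in config.get("acquisitions", [{"id": "baseline"}]):
        acq_id = acq["id"]
        sc = scene.apply_perturbation(base, acq["drug"]) if acq.get("drug") else base
        state["scenes"][acq_id] = sc
        movie = scene.render_movie(sc)
        path = outdir / f"{acq_id}.tif"
        movie_io.save_interleaved(movie, path)
        state["outputs"][f"movie_{acq_id}"] = path
    truth_path = outdir / "scene_truth.csv"
    base.truth_table().to_csv(truth_path, index=False, float_format=_FLOAT_FMT)
    state["outputs"]["scene_truth"] = truth_path
    state["base_scene"] = base


def _stage_quantify(config, seed, outdir, state):
    qcfg = config.get("quant", {})
    base_acq = config.get("baseline_acquisition", "baseline")
    tables, roiset = [], None
    for acq in config.get("acquisitions", [{"id": "baseline"}]):
        acq_id = acq["id"]
        movie = movie_io.load_interleaved(outdir / f"{acq_id}.tif")
        movie = preprocess.subtract_background(movie)
        if movie.n_frames >= 2:
            movie, qc = preprocess.motion_correct(movie)
            qc.to_csv(outdir / f"qc_{acq_id}.csv", index=False, float_format=_FLOAT_FMT)
        if roiset is None:  # segment once on the baseline projection
            proj = movie_io.average_projection(movie)
            sc = state.get("base_scene")
            radius = sc.cells[0].radius if sc and sc.cells else 8.0
            roiset = segment.segment_somas(
                proj, soma_radius_px=radius,
                corner_mask=scene.default_corner_mask(proj.shape))
        tables.append(quant.quantify(movie, roiset, acq_id, **qcfg))
    table = pd.concat(tables, ignore_index=True)
    table = quant.zscore_normalize(table, base_acq)
    path = outdir / "cell_table.csv"
    table.to_csv(path, index=False, float_format=_FLOAT_FMT)
    state["outputs"]["cell_table"] = path
    state["cell_table"] = table
    state["roiset"] = roiset


def _stage_typecall(config, seed, outdir, state):
    sc = state.get("base_scene")
    if sc is None:
        raise ValueError("typecall stage needs the simulate stage (or external inputs)")
    warp_truth = scene.SmoothWarp(dy=3.0, dx=-2.0, amp=1.5, period=140.0)
    channels, labels3d, landmarks, conf_truth = scene.render_immunostain(sc, warp_truth)
    warp = fit_landmark_warp(landmarks)
    mapped = warp(conf_truth[["confocal_y", "confocal_x"]].to_numpy())
    calls = conf_truth[["cell_id"]].copy()
    mip = {m: channels[m].max(axis=0) for m in ("spp1", "tbr2", "cart")}
    for m in ("spp1", "tbr2", "cart"):
        vals = np.array([
            mip[m][int(round(y)) - 4:int(round(y)) + 5,
                   int(round(x)) - 4:int(round(x)) + 5].mean()
            for (y, x) in conf_truth[["confocal_y", "confocal_x"]].to_numpy()])
        calls[f"{m}_intensity"] = vals
        calls[f"{m}_pos"], _ = iqr_positive(vals)
    calls["invivo_y"], calls["invivo_x"] = mapped[:, 0], mapped[:, 1]
    calls = assign_types(calls)
    path = outdir / "typecalls.csv"
    calls.to_csv(path, index=False, float_format=_FLOAT_FMT)
    state["outputs"]["typecalls"] = path
    state["typecalls"] = calls


def _stage_longitudinal(config, seed, outdir, state):
    lcfg = dict(config.get("longitudinal", {}))
    tables, truth = scene.simulate_longitudinal_cohort(seed=seed + 11, **lcfg)
    ztabs = _zscore_day_tables(tables)
    records = survival.classify_fates(ztabs)
    ztabs = survival.exclude_cleaved(ztabs, records)
    course = survival.daily_population_course(ztabs, records)
    rpath = outdir / "survival_records.csv"
    records.to_csv(rpath, index=False, float_format=_FLOAT_FMT)
    cpath = outdir / "day_course.csv"
    course.to_csv(cpath, index=False, float_format=_FLOAT_FMT)
    state["outputs"]["survival_records"] = rpath
    state["outputs"]["day_course"] = cpath
    state["survival_records"] = records
    state["day_course"] = course


def _zscore_day_tables(tables: dict[int, pd.DataFrame],
                       pre_day: int = 0) -> dict[int, pd.DataFrame]:
    """Smooth and z-score trace-level day tables against the pre-injury day."""
    combined = pd.concat(
        [t.assign(acquisition_id=f"day{d:02d}") for d, t in tables.items()],
        ignore_index=True)
    combined = quant.apply_filters(combined)
    combined = quant.add_smoothed_ratio(combined, smoothing_domain="ratio")
    combined = quant.zscore_normalize(combined, f"day{pre_day:02d}")
    return {d: g.copy() for d, g in
            combined.groupby(combined["acquisition_id"].str[3:].astype(int))}


def _stage_report(config, seed, outdir, state):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    summary = {}
    if "cell_table" in state:
        t = state["cell_table"]
        keep = quant.retained(t)
        base = config.get("baseline_acquisition", "baseline")
        bz = t[keep & (t["acquisition_id"] == base)]["zscore"]
        summary["n_cells"] = int(t["cell_id"].nunique())
        summary["baseline_z_mean"] = float(bz.mean())
        summary["baseline_z_sd"] = float(bz.std(ddof=0))
        fig, ax = plt.subplots(figsize=(4, 3))
        per_cell = t[keep & (t["acquisition_id"] == base)].groupby("cell_id")["zscore"].mean()
        ax.hist(per_cell, bins=20)
        ax.set_xlabel("baseline ATP z-score")
        ax.set_ylabel("cells")
        fig.tight_layout()
        fig.savefig(outdir / "baseline_histogram.png", dpi=120)
        plt.close(fig)
    if "day_course" in state:
        c = state["day_course"]
        fig, ax = plt.subplots(figsize=(4, 3))
        ax.plot(c["day"], c["mean_z"], "-o")
        ax.fill_between(c["day"], c["mean_z"] - c["sd_z"], c["mean_z"] + c["sd_z"],
                        alpha=0.3)
        ax.set_xlabel("days post injury")
        ax.set_ylabel("population z")
        fig.tight_layout()
        fig.savefig(outdir / "day_course.png", dpi=120)
        plt.close(fig)
        summary["day_course_peak_day"] = int(c.loc[c["mean_z"].idxmax(), "day"])
    if "survival_records" in state:
        r = state["survival_records"]
        for fate in ("survived", "died"):
            sel = r[r["fate"] == fate]
            if len(sel):
                summary[f"mean_baseline_z_{fate}"] = float(sel["baseline_mean_z"].mean())
    spath = outdir / "summary.json"
    spath.write_text(json.dumps(summary, indent=2, sort_keys=True))
    state["outputs"]["summary"] = spath


_STAGE_FNS = {"simulate": _stage_simulate, "quantify": _stage_quantify,
              "typecall": _stage_typecall, "longitudinal": _stage_longitudinal,
              "report": _stage_report}
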
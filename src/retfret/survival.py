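"""Longitudinal fate classification and survival-vs-baseline contrasts.

During apoptosis the sensor's linker is cleaved, collapsing the YFP/CFP
ratio far below physiological values. A tracked cell is called dead on the
first post-injury day its smoothed z-score falls 5 SD below the pre-injury
population mean, or the first day it can no longer be tracked (configurable
to censoring instead). Post-cleavage frames are excluded from all ATP
quantification. The survival contrast compares per-cell baseline mean z
between fates, optionally splitting survivors by post hoc alpha identity.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from . import stats as _stats
from .quant import retained

__all__ = ["classify_fates", "exclude_cleaved", "survival_contrast",
           "daily_population_course"]


def classify_fates(tables: dict[int, pd.DataFrame], pre_day: int = 0,
                   sd_cut: float = 5.0, missing: str = "died") -> pd.DataFrame:
    """Classify each tracked cell's fate from its per-day z traces.

    ``tables`` maps day index -> z-scored per-frame table (shared cell_id
    space; the pre-injury day supplies the baseline). A cell dies on the
    first day its smoothed z dips below ``-sd_cut`` (cleavage signature,
    ``cleaved_flag``) or, if ``missing="died"`` (default), the first day it
    has no trace; ``missing="censor"`` records disappearance without a
    death call. Cells without pre-injury data are skipped with a warning.
    """
    if missing not in ("died", "censor"):
        raise ValueError(f"unknown missing policy {missing!r}")
    days = sorted(tables)
    if pre_day not in tables:
        raise ValueError("pre-injury day missing from tables")
    pre = tables[pre_day]
    pre_keep = retained(pre)
    baseline = (pre[pre_keep].groupby("cell_id")["zscore"].mean()
                .rename("baseline_mean_z"))
    post_days = [d for d in days if d > pre_day]

    all_cells = set()
    for d in days:
        all_cells |= set(tables[d]["cell_id"].unique())

    records = []
    for cid in sorted(all_cells):
        if cid not in baseline.index:
            warnings.warn(f"cell {cid} has no pre-injury data; skipped")
            continue
        fate, death_day, cleaved = "survived", None, False
        for d in post_days:
            g = tables[d]
            z = g.loc[g["cell_id"] == cid, "zscore"]
            if z.empty:
                if missing == "died":
                    fate, death_day = "died", d
                break
            if z.min() < -sd_cut:
                fate, death_day, cleaved = "died", d, True
                break
        records.append({"cell_id": cid,
                        "baseline_mean_z": float(baseline.loc[cid]),
                        "fate": fate, "death_day": death_day,
                        "cleaved_flag": cleaved})
    return pd.DataFrame(records)


def exclude_cleaved(tables: dict[int, pd.DataFrame],
                    records: pd.DataFrame) -> dict[int, pd.DataFrame]:
    """Flag every frame on or after a cell's death day as
    ``excluded_cleaved`` so it drops out of population statistics."""
    death = records.dropna(subset=["death_day"]).set_index("cell_id")["death_day"]
    out = {}
    for d, t in tables.items():
        t = t.copy()
        if "excluded_cleaved" not in t:
            t["excluded_cleaved"] = False
        dying = t["cell_id"].map(death)
        t.loc[dying.notna() & (d >= dying), "excluded_cleaved"] = True
        out[d] = t
    return out


def survival_contrast(records: pd.DataFrame,
                      typecalls: pd.DataFrame | None = None,
                      design: str = "ttest") -> dict:
    """Baseline-ATP contrast between fates.

    Compares ``baseline_mean_z`` of died vs survived cells; with
    ``typecalls`` (cell_id, type_label) the survivors additionally split
    into alpha-family vs non-alpha for a three-group comparison. Returns
    the group means, the survived-minus-died difference, and the test
    results from the stats module.
    """
    for fate in ("survived", "died"):
        if (records["fate"] == fate).sum() < 2:
            raise ValueError(f"fewer than 2 cells in group {fate!r}")
    surv = records.loc[records["fate"] == "survived", "baseline_mean_z"].to_numpy()
    died = records.loc[records["fate"] == "died", "baseline_mean_z"].to_numpy()
    out = {
        "mean_survived": float(surv.mean()), "mean_died": float(died.mean()),
        "difference": float(surv.mean() - died.mean()),
        "test": _stats.compare_groups({"died": died, "survived": surv}, design=design),
    }
    if typecalls is not None:
        merged = records.merge(typecalls[["cell_id", "type_label"]], on="cell_id",
                               how="left")
        is_alpha = merged["type_label"].isin(["alpha", "alpha_on_s"])
        s_alpha = merged.loc[(merged["fate"] == "survived") & is_alpha,
                             "baseline_mean_z"].to_numpy()
        s_non = merged.loc[(merged["fate"] == "survived") & ~is_alpha,
                           "baseline_mean_z"].to_numpy()
        if len(s_alpha) >= 2 and len(s_non) >= 2:
            out["three_group_test"] = _stats.compare_groups(
                {"died": died, "surviving_alpha": s_alpha,
                 "surviving_non_alpha": s_non}, design="anova_tukey")
            out["mean_surviving_alpha"] = float(s_alpha.mean())
            out["mean_surviving_non_alpha"] = float(s_non.mean())
    return out


def daily_population_course(tables: dict[int, pd.DataFrame],
                            records: pd.DataFrame | None = None,
                            pre_day: int = 0,
                            retina_col: str | None = None) -> pd.DataFrame:
    """Per-day population mean +/- SD of z across retained cells, with a
    rank-sum test of each day's per-cell means against the pre-injury day.

    Optionally splits by fate (``records``) and reports per-retina means
    when ``retina_col`` names a column in the tables.
    """
    fates = None
    if records is not None:
        fates = records.set_index("cell_id")["fate"]

    def cell_means(t: pd.DataFrame) -> pd.Series:
        return t[retained(t)].groupby("cell_id")["zscore"].mean()

    pre_means = cell_means(tables[pre_day])
    rows = []
    for d in sorted(tables):
        m = cell_means(tables[d])
        if m.empty:
            continue
        row = {"day": d, "n_cells": int(m.size), "mean_z": float(m.mean()),
               "sd_z": float(m.std(ddof=0))}
        row["p_vs_pre"] = (1.0 if d == pre_day
                           else _stats.ranksum_p(m.to_numpy(), pre_means.to_numpy()))
        if fates is not None:
            for fate in ("survived", "died"):
                sel = m[m.index.map(fates) == fate]
                row[f"mean_z_{fate}"] = float(sel.mean()) if sel.size else np.nan
        if retina_col is not None and retina_col in tables[d]:
            t = tables[d]
            per_ret = (t[retained(t)].groupby([retina_col, "cell_id"])["zscore"].mean()
                       .groupby(level=0).mean())
            for rname, rv in per_ret.items():
                row[f"retina_mean_{rname}"] = float(rv)
        rows.append(row)
    return pd.DataFrame(rows)
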
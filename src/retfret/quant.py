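"""Per-cell FRET ratio quantification: ROI traces, filters, z-scoring and
window summaries.

The measurement contract: per frame and channel, the mean pixel intensity
within each ROI; the FRET ratio is the ratio of those channel means (ratio
of means, never mean of pixel ratios). High-frequency temporal noise is
removed with a 20-frame moving average applied to the per-channel means
before the ratio is formed (ratio-domain smoothing is available as an
option). ROIs under 100 pixels or with time-average YFP+CFP mean intensity
under 50 are discarded. Smoothed ratios are z-scored against the pooled
baseline population (all retained cells, all baseline frames of the same
retina); the same mean/SD then standardise every other acquisition of that
retina. Window summaries integrate the z trace with the composite
trapezoidal rule and divide by the window duration.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .movie_io import TwoChannelMovie
from .preprocess import smooth_trace
from .segment import RoiSet

__all__ = ["extract_traces", "apply_filters", "add_smoothed_ratio",
           "zscore_normalize", "summarize_window", "acute_flux", "quantify"]

TRACE_COLUMNS = ["cell_id", "acquisition_id", "frame", "t_s", "pixel_count",
                 "yfp_mean", "cfp_mean", "ratio"]


def extract_traces(movie: TwoChannelMovie, roiset: RoiSet,
                   acquisition_id: str = "acq") -> pd.DataFrame:
    """Per-frame, per-channel ROI mean intensities and the frame-wise
    YFP/CFP ratio of means.

    The movie must already be background-subtracted and motion-corrected.
    Returns a long table with one row per (roi, frame); ``cell_id`` starts
    out equal to ``roi_id`` and is remapped by tracking when acquisitions
    are combined.
    """
    labels = roiset.label_image
    ids = roiset.rois["roi_id"].to_numpy()
    if len(ids) == 0:
        return pd.DataFrame(columns=TRACE_COLUMNS)
    counts = roiset.rois.set_index("roi_id")["pixel_count"]
    if (counts == 0).any():
        raise ValueError("ROI with zero pixels")
    t_s = movie.times_s
    masks = [labels == i for i in ids]
    pieces = []
    for roi_id, mask in zip(ids, masks):
        npx = int(mask.sum())
        ymeans = movie.yfp[:, mask].mean(axis=1)
        cmeans = movie.cfp[:, mask].mean(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(cmeans > 0, ymeans / cmeans, np.nan)
        pieces.append(pd.DataFrame({
            "cell_id": int(roi_id), "acquisition_id": acquisition_id,
            "frame": np.arange(movie.n_frames), "t_s": t_s,
            "pixel_count": npx, "yfp_mean": ymeans, "cfp_mean": cmeans,
            "ratio": ratio,
        }))
    return pd.concat(pieces, ignore_index=True)


def apply_filters(table: pd.DataFrame, min_pixels: int = 100,
                  min_sum_intensity: float = 50.0) -> pd.DataFrame:
    """Flag ROIs with fewer than ``min_pixels`` pixels (``too_small``) or
    time-average YFP+CFP mean intensity below ``min_sum_intensity``
    (``too_dim``); both boundary values are retained. Flagged rows are
    excluded from all population statistics downstream."""
    out = table.copy()
    grp = out.groupby(["acquisition_id", "cell_id"], sort=False)
    sum_int = grp[["yfp_mean", "cfp_mean"]].transform("mean").sum(axis=1)
    # flags accumulate, so successive filter passes commute
    out["too_small"] = (out["pixel_count"] < min_pixels) \
        | out.get("too_small", pd.Series(False, index=out.index))
    out["too_dim"] = (sum_int < min_sum_intensity) \
        | out.get("too_dim", pd.Series(False, index=out.index))
    if "excluded_cleaved" not in out:
        out["excluded_cleaved"] = False
    return out


def retained(table: pd.DataFrame) -> pd.Series:
    """Boolean mask of rows that enter population statistics."""
    m = pd.Series(True, index=table.index)
    for col in ("too_small", "too_dim", "excluded_cleaved"):
        if col in table:
            m &= ~table[col].astype(bool)
    return m


def add_smoothed_ratio(table: pd.DataFrame, window: int = 20,
                       smoothing_domain: str = "channel") -> pd.DataFrame:
    """Attach ``ratio_smoothed``: moving-average filtered traces.

    ``smoothing_domain="channel"`` (default, the acquisition-order reading)
    smooths each channel's ROI-mean trace then takes the ratio;
    ``"ratio"`` smooths the ratio trace directly.
    """
    if smoothing_domain not in ("channel", "ratio"):
        raise ValueError(f"unknown smoothing_domain {smoothing_domain!r}")
    out = table.sort_values(["acquisition_id", "cell_id", "frame"]).reset_index(drop=True)

    def _smooth(g: pd.DataFrame) -> pd.Series:
        if smoothing_domain == "channel":
            ys = smooth_trace(g["yfp_mean"].to_numpy(), window)
            cs = smooth_trace(g["cfp_mean"].to_numpy(), window)
            with np.errstate(divide="ignore", invalid="ignore"):
                r = np.where(cs > 0, ys / cs, np.nan)
        else:
            r = smooth_trace(g["ratio"].to_numpy(), window)
        return pd.Series(r, index=g.index)

    out["ratio_smoothed"] = (
        out.groupby(["acquisition_id", "cell_id"], sort=False, group_keys=False)
           .apply(_smooth, include_groups=False))
    return out


def zscore_normalize(table: pd.DataFrame, baseline_acquisition: str,
                     sd_mode: str = "population") -> pd.DataFrame:
    """Z-score every acquisition's smoothed ratios against the baseline
    population mean and SD.

    The baseline population pools all retained cells across all frames of
    ``baseline_acquisition``; normalisation is per retina (call once per
    retina's table). ``sd_mode`` selects population (ddof=0, default) or
    sample (ddof=1) SD.
    """
    if "ratio_smoothed" not in table:
        raise ValueError("run add_smoothed_ratio first")
    keep = retained(table)
    base = table[keep & (table["acquisition_id"] == baseline_acquisition)]
    if base["cell_id"].nunique() < 2:
        raise ValueError("baseline acquisition needs >= 2 retained cells")
    vals = base["ratio_smoothed"].dropna().to_numpy()
    mu = float(vals.mean())
    ddof = 0 if sd_mode == "population" else 1
    sigma = float(vals.std(ddof=ddof))
    if sigma == 0:
        raise ValueError("degenerate baseline (sigma = 0)")
    out = table.copy()
    out["zscore"] = (out["ratio_smoothed"] - mu) / sigma
    out.attrs["baseline_mu"] = mu
    out.attrs["baseline_sigma"] = sigma
    return out


def summarize_window(table: pd.DataFrame, window: tuple[float, float],
                     reference_window: tuple[float, float] | None = None,
                     value: str = "zscore",
                     window_label: str = "window") -> pd.DataFrame:
    """Per-cell AUC-over-duration summary of the z trace in a time window.

    ``mean_z_auc`` is the composite-trapezoid integral of the trace over
    the window divided by the window duration; for a constant trace it
    equals that constant. ``delta_vs_reference`` subtracts the same summary
    over ``reference_window`` (the pre-injection contrast).
    """
    start_s, end_s = window
    if end_s <= start_s:
        raise ValueError("window end must exceed start")
    rows = []
    for (acq, cid), g in table.groupby(["acquisition_id", "cell_id"], sort=False):
        rows.append({
            "cell_id": cid, "acquisition_id": acq, "window_label": window_label,
            "start_s": start_s, "end_s": end_s,
            "mean_z_auc": _window_auc(g, start_s, end_s, value),
            "delta_vs_reference": np.nan,
        })
    out = pd.DataFrame(rows)
    if reference_window is not None:
        ref = {(acq, cid): _window_auc(g, *reference_window, value)
               for (acq, cid), g in table.groupby(["acquisition_id", "cell_id"], sort=False)}
        out["delta_vs_reference"] = [
            r["mean_z_auc"] - ref[(r["acquisition_id"], r["cell_id"])]
            for r in out.to_dict("records")]
    return out


def _window_auc(g: pd.DataFrame, start_s: float, end_s: float, value: str) -> float:
    g = g.sort_values("frame")
    sel = (g["t_s"] >= start_s) & (g["t_s"] <= end_s)
    t = g.loc[sel, "t_s"].to_numpy()
    v = g.loc[sel, value].to_numpy()
    if t.size < 2:
        raise ValueError("window covers fewer than 2 frames")
    return float(np.trapezoid(v, t) / (t[-1] - t[0]))


def acute_flux(table: pd.DataFrame, window: tuple[float, float] = (0.0, 10.0),
               value: str = "zscore") -> pd.DataFrame:
    """Absolute maximum change of the smoothed z trace inside a window:
    max - min, a non-negative magnitude (the acute-dynamics statistic for
    scan-onset and scan-restart windows)."""
    start_s, end_s = window
    rows = []
    for (acq, cid), g in table.groupby(["acquisition_id", "cell_id"], sort=False):
        sel = (g["t_s"] >= start_s) & (g["t_s"] <= end_s)
        v = g.loc[sel, value].to_numpy()
        if v.size < 2:
            raise ValueError("acute-flux window covers fewer than 2 frames")
        rows.append({"cell_id": cid, "acquisition_id": acq,
                     "acute_flux": float(v.max() - v.min())})
    return pd.DataFrame(rows)


def quantify(movie: TwoChannelMovie, roiset: RoiSet, acquisition_id: str = "acq",
             min_pixels: int = 100, min_sum_intensity: float = 50.0,
             smooth_window: int = 20, smoothing_domain: str = "channel") -> pd.DataFrame:
    """Extract, filter and smooth ROI traces for one acquisition (z-scoring
    is applied afterwards, once the baseline acquisition is known)."""
    t = extract_traces(movie, roiset, acquisition_id)
    t = apply_filters(t, min_pixels, min_sum_intensity)
    return add_smoothed_ratio(t, smooth_window, smoothing_domain)
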
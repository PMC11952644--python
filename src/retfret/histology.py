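"""Post hoc immunostain registration, marker positivity and type calls.

Confocal volumes of the fixed, immunostained retina are registered onto the
in vivo reference with a landmark thin-plate-spline warp; warped confocal
soma centroids are matched to in vivo ROIs by the same one-to-one
assignment used for tracking. Marker positivity uses the within-image
Q3 + 1.5*IQR rule; the identical rule with discard semantics removes
vascular off-target outliers. Cell types follow the marker logic: SPP1+TBR2
-> alpha-ON-sustained, SPP1 only -> alpha, TBR2 only -> intrinsically
photosensitive, CART only -> ON-OFF direction-selective.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.interpolate import RBFInterpolator

__all__ = ["LandmarkWarp", "fit_landmark_warp", "iqr_positive", "iqr_threshold",
           "assign_types", "quantify_mito_if", "middle_slices"]


class LandmarkWarp:
    """Thin-plate-spline interpolant mapping confocal (y, x) coordinates
    into the in vivo frame. Exact at the control points (no smoothing) and,
    by its degree-1 polynomial part, exactly reproduces any affine
    relation."""

    def __init__(self, invivo_points: np.ndarray, confocal_points: np.ndarray):
        src = np.atleast_2d(np.asarray(confocal_points, dtype=float))
        dst = np.atleast_2d(np.asarray(invivo_points, dtype=float))
        if src.shape[0] < 4:
            raise ValueError("need at least 4 landmark pairs")
        centred = src - src.mean(axis=0)
        if np.linalg.matrix_rank(centred, tol=1e-8 * max(1.0, np.abs(centred).max())) < 2:
            raise ValueError("degenerate (collinear) control points")
        self.control_confocal = src
        self.control_invivo = dst
        self._rbf = RBFInterpolator(src, dst, kernel="thin_plate_spline", degree=1)

    def __call__(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return self._rbf(pts)

    def control_residual(self) -> float:
        """Max |warp(confocal) - invivo| over the control points (px)."""
        return float(np.abs(self(self.control_confocal) - self.control_invivo).max())


def fit_landmark_warp(pairs: pd.DataFrame | np.ndarray,
                      tolerance_px: float = 0.1) -> LandmarkWarp:
    """Fit the landmark warp from a correspondence table.

    ``pairs`` is either a DataFrame with columns invivo_y, invivo_x,
    confocal_y, confocal_x (0-based pixel coordinates) or an (N, 4) array
    in that column order.
    """
    if isinstance(pairs, pd.DataFrame):
        inv = pairs[["invivo_y", "invivo_x"]].to_numpy(dtype=float)
        con = pairs[["confocal_y", "confocal_x"]].to_numpy(dtype=float)
    else:
        arr = np.asarray(pairs, dtype=float)
        inv, con = arr[:, :2], arr[:, 2:4]
    warp = LandmarkWarp(inv, con)
    res = warp.control_residual()
    if res > tolerance_px:
        warnings.warn(f"landmark residual {res:.3g} px exceeds tolerance {tolerance_px}")
    return warp


def iqr_threshold(values: np.ndarray, quantile_method: str = "linear") -> float:
    """Q3 + 1.5*IQR within one image (linear-interpolated quantiles)."""
    v = np.asarray(values, dtype=float)
    if v.size < 4:
        raise ValueError("need at least 4 values for the IQR rule")
    q1, q3 = np.quantile(v, [0.25, 0.75], method=quantile_method)
    return float(q3 + 1.5 * (q3 - q1))


def iqr_positive(values: np.ndarray,
                 quantile_method: str = "linear") -> tuple[np.ndarray, float]:
    """Within-image positivity call: value >= Q3 + 1.5*IQR.

    Used both for SPP1 (and by default TBR2/CART) marker scoring and, with
    discard semantics, for removing vascular off-target outliers. With all
    values equal the IQR is 0 and the >= comparison marks everything
    positive.
    """
    v = np.asarray(values, dtype=float)
    thr = iqr_threshold(v, quantile_method)
    return v >= thr, thr


TYPE_PRECEDENCE = ("alpha_on_s", "alpha", "ip", "oods", "unlabeled")


def assign_types(calls: pd.DataFrame) -> pd.DataFrame:
    """Map per-cell marker positivity to a type label.

    Expects boolean columns spp1_pos, tbr2_pos, cart_pos. SPP1+TBR2 ->
    alpha_on_s; SPP1 only -> alpha; TBR2 only -> ip; CART only -> oods;
    nothing -> unlabeled. CART together with SPP1 or TBR2 is biologically
    inconsistent: unlabeled with a conflict warning.
    """
    out = calls.copy()
    spp1 = out["spp1_pos"].to_numpy(dtype=bool)
    tbr2 = out["tbr2_pos"].to_numpy(dtype=bool)
    cart = out["cart_pos"].to_numpy(dtype=bool)
    conflict = cart & (spp1 | tbr2)
    label = np.full(len(out), "unlabeled", dtype=object)
    label[cart & ~conflict] = "oods"
    label[tbr2 & ~spp1 & ~conflict] = "ip"
    label[spp1 & ~tbr2 & ~conflict] = "alpha"
    label[spp1 & tbr2 & ~conflict] = "alpha_on_s"
    label[conflict] = "unlabeled"
    out["type_label"] = label
    out["marker_conflict"] = conflict
    if conflict.any():
        warnings.warn(f"{int(conflict.sum())} cells with conflicting CART co-labelling")
    return out


def middle_slices(z_indices: np.ndarray, fraction: float = 0.6) -> np.ndarray:
    """The middle ``fraction`` of a cell's occupied z-slices, symmetric:
    k = round(fraction*n) slices starting at floor((n-k)/2). A cell on a
    single slice keeps that slice (with a warning upstream)."""
    z = np.sort(np.unique(np.asarray(z_indices)))
    n = z.size
    k = max(int(round(fraction * n)), 1)
    off = (n - k) // 2
    return z[off:off + k]


def quantify_mito_if(volume: np.ndarray, soma_masks: np.ndarray,
                     fraction: float = 0.6,
                     discard_outliers: bool = True) -> pd.DataFrame:
    """Per-cell mitochondrial-protein immunofluorescence from one
    volumetric field of view.

    For each labelled soma, the marker channel is averaged over the middle
    60% of the cell's occupied z-slices. Vascular off-target outliers
    (raw mean >= Q3 + 1.5*IQR within the image) are discarded before the
    per-field z-scoring so they cannot distort the normalisation.

    Returns columns cell_id, n_slices, mito_mean, outlier, mito_z (NaN for
    discarded cells).
    """
    volume = np.asarray(volume, dtype=float)
    soma_masks = np.asarray(soma_masks)
    if volume.shape != soma_masks.shape:
        raise ValueError("volume and soma masks must share a shape")
    rows = []
    for cid in np.unique(soma_masks):
        if cid == 0:
            continue
        mask = soma_masks == cid
        zs = np.unique(np.nonzero(mask.any(axis=(1, 2)))[0])
        if zs.size < 2:
            warnings.warn(f"cell {cid} spans < 2 z-slices; using all of them")
            use = zs
        else:
            use = middle_slices(zs, fraction)
        sub = np.zeros_like(mask)
        sub[use] = mask[use]
        rows.append({"cell_id": int(cid), "n_slices": int(zs.size),
                     "mito_mean": float(volume[sub].mean())})
    out = pd.DataFrame(rows)
    if out.empty:
        out["outlier"] = out["mito_z"] = np.nan
        return out
    vals = out["mito_mean"].to_numpy()
    if discard_outliers and len(out) >= 4 and np.ptp(vals) > 0:
        pos, _ = iqr_positive(vals)
        out["outlier"] = pos
    else:
        out["outlier"] = False
    keep = ~out["outlier"]
    mu = out.loc[keep, "mito_mean"].mean()
    sd = out.loc[keep, "mito_mean"].std(ddof=0)
    out["mito_z"] = np.where(keep, (out["mito_mean"] - mu) / sd if sd > 0 else 0.0, np.nan)
    return out
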
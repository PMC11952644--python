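"""Soma segmentation on average projections and ROI matching across
acquisitions and days.

Segmentation either ingests an externally produced label image verbatim
(the plugin path — e.g. a neural-network segmenter) or falls back to
Laplacian-of-Gaussian blob detection at the configured soma radius followed
by marker-based watershed. ROIs of the same cell across acquisitions are
matched by exact minimum-total-distance one-to-one assignment on centroid
distance with a gate, the deterministic equivalent of linear-assignment
trackers; day-to-day tracking chains such matches against the day-0
reference, with a manual-override table taking precedence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import linear_sum_assignment
from skimage import feature, filters, measure, segmentation

from .preprocess import RigidTransform, transform_points

__all__ = ["RoiSet", "segment_somas", "match_rois", "track_days"]


@dataclass
class RoiSet:
    """Labelled soma footprints on one reference projection."""

    label_image: np.ndarray           # (H, W) int, 0 = background
    rois: pd.DataFrame                # roi_id, pixel_count, centroid_y/x, bbox_*

    @classmethod
    def from_label_image(cls, labels: np.ndarray) -> "RoiSet":
        labels = np.asarray(labels)
        rows = []
        for p in measure.regionprops(labels):
            rows.append({"roi_id": int(p.label), "pixel_count": int(p.area),
                         "centroid_y": float(p.centroid[0]), "centroid_x": float(p.centroid[1]),
                         "bbox_y0": p.bbox[0], "bbox_x0": p.bbox[1],
                         "bbox_y1": p.bbox[2], "bbox_x1": p.bbox[3]})
        cols = ["roi_id", "pixel_count", "centroid_y", "centroid_x",
                "bbox_y0", "bbox_x0", "bbox_y1", "bbox_x1"]
        df = pd.DataFrame(rows, columns=cols)
        return cls(label_image=labels, rois=df)

    def __len__(self) -> int:
        return len(self.rois)

    def centroids(self) -> np.ndarray:
        return self.rois[["centroid_y", "centroid_x"]].to_numpy(dtype=float)


def segment_somas(projection: np.ndarray,
                  soma_radius_px: float = 8.0,
                  corner_mask: np.ndarray | None = None,
                  labels: np.ndarray | None = None,
                  detect_threshold: float = 0.08,
                  min_pixels: int = 20) -> RoiSet:
    """Produce soma ROIs on a background-subtracted average projection.

    If ``labels`` is given (plugin mode) it is ingested verbatim after a
    shape check. Otherwise LoG blob detection at the soma radius seeds a
    marker-based watershed on the smoothed projection. ROIs touching the
    scan-clipped corner mask are removed in both modes.
    """
    projection = np.asarray(projection, dtype=float)
    if labels is not None:
        labels = np.asarray(labels)
        if labels.shape != projection.shape:
            raise ValueError("plugin label image shape mismatch")
        labels = labels.copy()
        if corner_mask is not None:
            labels = _drop_corner_rois(labels, corner_mask)
        return RoiSet.from_label_image(labels)

    if projection.size == 0 or projection.max() <= projection.min():
        return RoiSet.from_label_image(np.zeros(projection.shape, dtype=np.int32))

    sigma = soma_radius_px / 2.5
    smoothed = filters.gaussian(projection, sigma=sigma / 2.0)
    norm = (smoothed - smoothed.min()) / (smoothed.max() - smoothed.min())
    blobs = feature.blob_log(norm, min_sigma=0.6 * sigma, max_sigma=1.6 * sigma,
                             num_sigma=5, threshold=detect_threshold)
    markers = np.zeros(projection.shape, dtype=np.int32)
    for i, (y, x, _) in enumerate(blobs, start=1):
        markers[int(y), int(x)] = i
    if markers.max() == 0:
        return RoiSet.from_label_image(markers)

    # foreground = pixels meaningfully above the (already subtracted) floor
    thr = 0.25 * np.median([norm[int(y), int(x)] for y, x, _ in blobs])
    mask = norm > thr
    labels = segmentation.watershed(-smoothed, markers, mask=mask)
    # keep footprints compact: clip each ROI at ~1.5 soma radii from its seed
    yy, xx = np.mgrid[0:labels.shape[0], 0:labels.shape[1]]
    for i, (y, x, _) in enumerate(blobs, start=1):
        far = (labels == i) & ((yy - y) ** 2 + (xx - x) ** 2 > (1.5 * soma_radius_px) ** 2)
        labels[far] = 0
    if corner_mask is not None:
        labels = _drop_corner_rois(labels, corner_mask)
    for p in measure.regionprops(labels):
        if p.area < min_pixels:
            labels[labels == p.label] = 0
    labels, _, _ = segmentation.relabel_sequential(labels)
    return RoiSet.from_label_image(labels.astype(np.int32))


def _drop_corner_rois(labels: np.ndarray, corner_mask: np.ndarray) -> np.ndarray:
    corner_mask = np.asarray(corner_mask, dtype=bool)
    bad = np.unique(labels[corner_mask])
    out = labels.copy()
    out[np.isin(out, bad[bad > 0])] = 0
    return out


def match_rois(ref: RoiSet, other: RoiSet, transform: RigidTransform | None = None,
               gate_px: float = 8.0,
               ref_acq: str = "ref", other_acq: str = "other") -> pd.DataFrame:
    """Optimal one-to-one assignment of ``other`` ROIs to ``ref`` ROIs on
    centroid distance, admitting only pairs within ``gate_px``.

    ``transform`` maps the other acquisition's coordinates into the
    reference frame. Returns a track table with one row per ROI per
    acquisition; matched ROIs share ``cell_id`` (the reference roi_id),
    unmatched ROIs carry a null cell_id. Cost ties are broken toward lower
    roi_ids.
    """
    ref_ids = ref.rois["roi_id"].to_numpy()
    oth_ids = other.rois["roi_id"].to_numpy()
    rows = [{"cell_id": int(i), "acquisition_id": ref_acq, "roi_id": int(i)}
            for i in ref_ids]

    if len(ref_ids) and len(oth_ids):
        pts = other.centroids()
        if transform is not None:
            pts = transform_points(pts, transform, other.label_image.shape)
        d = np.linalg.norm(ref.centroids()[:, None, :] - pts[None, :, :], axis=2)
        big = gate_px * 1e6 + 1.0
        cost = np.where(d <= gate_px, d, big)
        # deterministic tie-break: prefer lower roi_ids
        cost = cost + 1e-9 * (ref_ids[:, None] + oth_ids[None, :])
        ri, oi = linear_sum_assignment(cost)
        assigned = {}
        for a, b in zip(ri, oi):
            if d[a, b] <= gate_px:
                assigned[int(oth_ids[b])] = int(ref_ids[a])
        for j in oth_ids:
            rows.append({"cell_id": assigned.get(int(j)), "acquisition_id": other_acq,
                         "roi_id": int(j)})
    else:
        for j in oth_ids:
            rows.append({"cell_id": None, "acquisition_id": other_acq, "roi_id": int(j)})
    out = pd.DataFrame(rows, columns=["cell_id", "acquisition_id", "roi_id"])
    out["cell_id"] = out["cell_id"].astype("Int64")
    return out


def paired_rois(table: pd.DataFrame, acq_a: str, acq_b: str) -> pd.DataFrame:
    """Cells matched in both acquisitions: columns cell_id, roi_id_a, roi_id_b."""
    t = table.dropna(subset=["cell_id", "roi_id"])
    a = t[t["acquisition_id"] == acq_a].set_index("cell_id")["roi_id"]
    b = t[t["acquisition_id"] == acq_b].set_index("cell_id")["roi_id"]
    common = a.index.intersection(b.index)
    return pd.DataFrame({"cell_id": common,
                         "roi_id_a": a.loc[common].to_numpy(),
                         "roi_id_b": b.loc[common].to_numpy()})


def track_days(roisets: list[RoiSet],
               transforms: list[RigidTransform] | None = None,
               gate_px: float = 8.0,
               day_labels: list[str] | None = None,
               overrides: pd.DataFrame | None = None) -> pd.DataFrame:
    """Chain day-by-day ROI matching against the day-0 reference.

    ``transforms[k]`` maps day k coordinates into the day-0 frame (entry 0
    is ignored). An ``overrides`` table with columns (acquisition_id,
    roi_id, cell_id) wins over automatic matches; referencing an unknown
    roi_id is an error. Cells absent on a day keep their id via a gap
    record (roi_id null).
    """
    if day_labels is None:
        day_labels = [f"day{k}" for k in range(len(roisets))]
    if transforms is None:
        transforms = [RigidTransform() for _ in roisets]
    ref = roisets[0]
    pieces = []
    for k, (rs, tf, lab) in enumerate(zip(roisets, transforms, day_labels)):
        if k == 0:
            t = pd.DataFrame({"cell_id": pd.array(ref.rois["roi_id"], dtype="Int64"),
                              "acquisition_id": lab, "roi_id": ref.rois["roi_id"]})
        else:
            t = match_rois(ref, rs, tf, gate_px, ref_acq="__ref__", other_acq=lab)
            t = t[t["acquisition_id"] == lab]
        pieces.append(t)
    table = pd.concat(pieces, ignore_index=True)

    if overrides is not None:
        for _, row in overrides.iterrows():
            sel = ((table["acquisition_id"] == row["acquisition_id"])
                   & (table["roi_id"] == row["roi_id"]))
            if not sel.any():
                raise ValueError(
                    f"override references unknown roi_id {row['roi_id']} on "
                    f"{row['acquisition_id']}")
            # an override steals the cell id from any automatic assignee
            clash = ((table["acquisition_id"] == row["acquisition_id"])
                     & (table["cell_id"] == row["cell_id"]) & ~sel)
            table.loc[clash, "cell_id"] = pd.NA
            table.loc[sel, "cell_id"] = row["cell_id"]

    # gap records: tracked cells missing on a day
    all_cells = table.loc[table["cell_id"].notna(), "cell_id"].unique()
    gaps = []
    for lab in day_labels:
        present = set(table.loc[(table["acquisition_id"] == lab)
                                & table["cell_id"].notna(), "cell_id"])
        for cid in all_cells:
            if cid not in present:
                gaps.append({"cell_id": cid, "acquisition_id": lab, "roi_id": pd.NA})
    if gaps:
        table = pd.concat([table, pd.DataFrame(gaps)], ignore_index=True)
    table["cell_id"] = table["cell_id"].astype("Int64")
    table["roi_id"] = table["roi_id"].astype("Int64")
    return table.sort_values(["acquisition_id", "roi_id"], na_position="last",
                             ignore_index=True)
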
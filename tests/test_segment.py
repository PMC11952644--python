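import itertools

import numpy as np
import pandas as pd
import pytest

from retfret import movie_io
from retfret import preprocess as pp
from retfret import scene as sc
from retfret import segment as seg

from conftest import match_to_truth


def _points_roiset(points, shape=(64, 64), radius=2):
    """RoiSet of small discs at the given (y, x) points, ids 1..n."""
    labels = np.zeros(shape, dtype=np.int32)
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    for i, (y, x) in enumerate(points, start=1):
        labels[(yy - y) ** 2 + (xx - x) ** 2 <= radius ** 2] = i
    return seg.RoiSet.from_label_image(labels)


def _brute_force_assignment(dist, gate):
    """Minimum-total-distance one-to-one matching by full enumeration."""
    n_ref, n_oth = dist.shape
    k = min(n_ref, n_oth)
    best_pairs, best_cost = [], np.inf
    for ref_sub in itertools.combinations(range(n_ref), k):
        for perm in itertools.permutations(range(n_oth), k):
            pairs = [(i, j) for i, j in zip(ref_sub, perm) if dist[i, j] <= gate]
            cost = sum(dist[i, j] for i, j in pairs) - 1e9 * len(pairs)
            if cost < best_cost - 1e-12:
                best_cost, best_pairs = cost, pairs
    return set(best_pairs)


# --- segmentation ----------------------------------------------------------

def test_fallback_segmentation_recall(small_scene, noiseless_movie):
    movie = pp.subtract_background(noiseless_movie)
    proj = movie_io.average_projection(movie)
    rs = seg.segment_somas(proj, soma_radius_px=8, corner_mask=small_scene.corner_mask)
    hits = match_to_truth(rs, small_scene, radius_px=5.0)
    recall = len(set(hits.values())) / len(small_scene.cells)
    assert recall >= 0.95


def test_empty_image_gives_empty_roiset():
    rs = seg.segment_somas(np.zeros((64, 64)))
    assert len(rs) == 0


def test_plugin_labels_pass_through_verbatim(small_scene):
    labels = small_scene.truth_label_image()
    rs = seg.segment_somas(np.zeros_like(labels, dtype=float), labels=labels)
    counts = {int(i): int((labels == i).sum()) for i in np.unique(labels) if i}
    got = dict(zip(rs.rois["roi_id"], rs.rois["pixel_count"]))
    assert got == counts


def test_plugin_label_shape_mismatch_rejected():
    with pytest.raises(ValueError, match="shape mismatch"):
        seg.segment_somas(np.zeros((32, 32)), labels=np.zeros((16, 16), dtype=int))


def test_corner_touching_rois_removed(small_scene):
    labels = small_scene.truth_label_image().copy()
    # paint an extra ROI straddling the corner mask
    labels[0:6, 0:6] = 999
    rs = seg.segment_somas(np.zeros_like(labels, dtype=float), labels=labels,
                           corner_mask=small_scene.corner_mask)
    assert 999 not in set(rs.rois["roi_id"])


# --- matching --------------------------------------------------------------

def test_identical_roisets_self_match():
    rs = _points_roiset([(10, 10), (30, 40), (50, 20)])
    table = seg.match_rois(rs, rs, gate_px=5)
    other = table[table["acquisition_id"] == "other"]
    assert (other["cell_id"].to_numpy() == other["roi_id"].to_numpy()).all()


def test_shifted_roiset_matched_through_transform():
    pts = [(10, 10), (30, 40), (50, 20), (20, 50)]
    ref = _points_roiset(pts)
    moved = _points_roiset([(y + 4, x + 4) for y, x in pts])
    tf = pp.RigidTransform(dy=-4.0, dx=-4.0)
    table = seg.match_rois(ref, moved, tf, gate_px=10)
    other = table[table["acquisition_id"] == "other"]
    assert (other["cell_id"].to_numpy() == other["roi_id"].to_numpy()).all()


def test_equidistant_tie_broken_toward_lower_roi_id():
    ref = _points_roiset([(20, 10), (20, 30)])
    other = _points_roiset([(20, 20)])
    table = seg.match_rois(ref, other, gate_px=15)
    got = table.loc[table["acquisition_id"] == "other", "cell_id"].iloc[0]
    assert got == 1


def test_assignment_matches_brute_force_enumeration():
    rng = np.random.default_rng(0)
    for trial in range(60):
        n_ref, n_oth = rng.integers(1, 7, size=2)
        ref_pts = rng.uniform(5, 59, (n_ref, 2))
        oth_pts = rng.uniform(5, 59, (n_oth, 2))
        gate = rng.uniform(5, 40)
        ref = _points_roiset(ref_pts)
        oth = _points_roiset(oth_pts)
        if len(ref) != n_ref or len(oth) != n_oth:
            continue  # overlapping discs merged; skip degenerate draw
        dist = np.linalg.norm(ref.centroids()[:, None] - oth.centroids()[None], axis=2)
        table = seg.match_rois(ref, oth, gate_px=gate)
        got = {(int(c) - 1, int(r) - 1) for c, r in
               table.loc[(table["acquisition_id"] == "other") & table["cell_id"].notna(),
                         ["cell_id", "roi_id"]].itertuples(index=False)}
        expected = _brute_force_assignment(dist, gate)
        got_cost = sum(dist[i, j] for i, j in got)
        exp_cost = sum(dist[i, j] for i, j in expected)
        assert len(got) == len(expected)
        assert got_cost == pytest.approx(exp_cost, abs=1e-9)


def test_no_match_beyond_gate():
    ref = _points_roiset([(10, 10)])
    other = _points_roiset([(40, 40)])
    table = seg.match_rois(ref, other, gate_px=5)
    assert table.loc[table["acquisition_id"] == "other", "cell_id"].isna().all()


def test_match_symmetric_under_swap():
    rng = np.random.default_rng(3)
    pts_a = rng.uniform(5, 59, (5, 2))
    pts_b = rng.uniform(5, 59, (5, 2))
    a, b = _points_roiset(pts_a), _points_roiset(pts_b)
    t_ab = seg.match_rois(a, b, gate_px=25)
    t_ba = seg.match_rois(b, a, gate_px=25)
    pairs_ab = {(int(c), int(r)) for c, r in
                t_ab.loc[(t_ab["acquisition_id"] == "other") & t_ab["cell_id"].notna(),
                         ["cell_id", "roi_id"]].itertuples(index=False)}
    pairs_ba = {(int(r), int(c)) for c, r in
                t_ba.loc[(t_ba["acquisition_id"] == "other") & t_ba["cell_id"].notna(),
                         ["cell_id", "roi_id"]].itertuples(index=False)}
    assert pairs_ab == pairs_ba


# --- day tracking ----------------------------------------------------------

def test_identical_days_fully_tracked():
    rs = _points_roiset([(10, 10), (30, 40), (50, 20)])
    table = seg.track_days([rs, rs, rs], gate_px=5)
    tracked = table[table["cell_id"].notna() & table["roi_id"].notna()]
    assert len(tracked) == 9


def test_deleted_cell_gets_gap_records_and_keeps_id():
    pts = [(10, 10), (30, 40), (50, 20)]
    full = _points_roiset(pts)
    partial = _points_roiset(pts[:2])
    table = seg.track_days([full, full, partial, partial], gate_px=5)
    gone = table[(table["cell_id"] == 3)]
    assert set(gone["acquisition_id"]) == {"day0", "day1", "day2", "day3"}
    assert gone.loc[gone["acquisition_id"].isin(["day2", "day3"]), "roi_id"].isna().all()
    # the freed id is never re-assigned to another ROI
    assert (table.loc[table["roi_id"].notna() & (table["cell_id"] == 3),
                      "acquisition_id"].isin(["day0", "day1"])).all()


def test_override_wins_and_unknown_roi_rejected():
    pts = [(10, 10), (30, 40)]
    rs = _points_roiset(pts)
    ov = pd.DataFrame([{"acquisition_id": "day1", "roi_id": 1, "cell_id": 2}])
    table = seg.track_days([rs, rs], gate_px=5, overrides=ov)
    got = table.loc[(table["acquisition_id"] == "day1") & (table["roi_id"] == 1),
                    "cell_id"].iloc[0]
    assert got == 2
    bad = pd.DataFrame([{"acquisition_id": "day1", "roi_id": 99, "cell_id": 1}])
    with pytest.raises(ValueError, match="unknown roi_id"):
        seg.track_days([rs, rs], gate_px=5, overrides=bad)


def test_seven_day_series_with_drift_and_dropout():
    """Simulated week of imaging: per-day rigid drift and 20% random cell
    dropout; >= 98% of persisting cells keep their identity."""
    rng = np.random.default_rng(42)
    scene = sc.make_scene(n_cells=60, field_shape=(256, 256), n_frames=2, seed=6)
    truth = scene.truth_table()
    base_pts = truth[["centroid_y", "centroid_x"]].to_numpy()
    roisets, transforms, kept = [], [], []
    for day in range(7):
        drift = np.array([3.0 * day, -2.0 * day])
        keep = np.ones(len(base_pts), dtype=bool)
        if day > 0:
            keep = rng.random(len(base_pts)) > 0.2
        pts = base_pts[keep] + drift + rng.normal(0, 0.4, (keep.sum(), 2))
        labels = np.zeros(scene.field_shape, dtype=np.int32)
        yy, xx = np.mgrid[0:scene.field_shape[0], 0:scene.field_shape[1]]
        ids = truth["cell_id"].to_numpy()[keep]
        for i, (y, x) in zip(ids, pts):
            labels[(yy - y) ** 2 + (xx - x) ** 2 <= 9] = i
        roisets.append(seg.RoiSet.from_label_image(labels))
        transforms.append(pp.RigidTransform(dy=-drift[0], dx=-drift[1]))
        kept.append(dict(zip(ids, range(keep.sum()))))
    table = seg.track_days(roisets, transforms, gate_px=8)
    # score: tracked cell_id equals the truth id used to paint the ROI
    correct = total = 0
    for day in range(1, 7):
        lab = f"day{day}"
        sub = table[(table["acquisition_id"] == lab) & table["roi_id"].notna()]
        for _, row in sub.iterrows():
            total += 1
            if row["cell_id"] is not pd.NA and row["cell_id"] == row["roi_id"]:
                correct += 1
    assert total > 0 and correct / total >= 0.98
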
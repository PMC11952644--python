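import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from retfret import movie_io
from retfret import quant as qt
from retfret import scene as sc
from retfret import segment as seg

from conftest import quantify_scene


def _movie_from_arrays(yfp, cfp, frame_rate=1.0):
    return movie_io.TwoChannelMovie(yfp=np.asarray(yfp, float),
                                    cfp=np.asarray(cfp, float), frame_rate=frame_rate)


def _single_roi(shape=(6, 6), box=(1, 4)):
    labels = np.zeros(shape, dtype=np.int32)
    labels[box[0]:box[1], box[0]:box[1]] = 1
    return seg.RoiSet.from_label_image(labels)


def _trace_table(values, acquisition_id="acq", cell_id=1, frame_rate=1.0,
                 pixel_count=150, intensity=100.0):
    values = np.asarray(values, dtype=float)
    n = values.size
    return pd.DataFrame({
        "cell_id": cell_id, "acquisition_id": acquisition_id,
        "frame": np.arange(n), "t_s": np.arange(n) / frame_rate,
        "pixel_count": pixel_count, "yfp_mean": intensity / 2,
        "cfp_mean": intensity / 2, "ratio": values,
        "ratio_smoothed": values, "zscore": values,
    })


# --- trace extraction ------------------------------------------------------

def test_uniform_roi_ratio():
    rs = _single_roi()
    yfp = np.full((3, 6, 6), 90.0)
    cfp = np.full((3, 6, 6), 60.0)
    t = qt.extract_traces(_movie_from_arrays(yfp, cfp), rs)
    np.testing.assert_allclose(t["ratio"], 1.5)


def test_ratio_of_means_not_mean_of_ratios():
    labels = np.zeros((1, 2), dtype=np.int32)
    labels[:] = 1
    rs = seg.RoiSet.from_label_image(labels)
    yfp = np.array([[[2.0, 4.0]]])
    cfp = np.array([[[1.0, 3.0]]])
    t = qt.extract_traces(_movie_from_arrays(yfp, cfp), rs)
    assert t["ratio"].iloc[0] == pytest.approx(3.0 / 2.0)
    assert t["ratio"].iloc[0] != pytest.approx(np.mean([2.0 / 1.0, 4.0 / 3.0]))


def test_extraction_matches_naive_pixel_loop():
    rng = np.random.default_rng(5)
    labels = (rng.random((8, 8)) < 0.4).astype(np.int32)
    labels[0, 0] = 1  # non-empty
    rs = seg.RoiSet.from_label_image(labels)
    yfp = rng.uniform(1, 100, (4, 8, 8))
    cfp = rng.uniform(1, 100, (4, 8, 8))
    t = qt.extract_traces(_movie_from_arrays(yfp, cfp), rs)
    for frame in range(4):
        ys, cs, n = 0.0, 0.0, 0
        for y in range(8):
            for x in range(8):
                if labels[y, x] == 1:
                    ys += yfp[frame, y, x]
                    cs += cfp[frame, y, x]
                    n += 1
        row = t[t["frame"] == frame].iloc[0]
        assert row["yfp_mean"] == pytest.approx(ys / n, rel=1e-12)
        assert row["ratio"] == pytest.approx(ys / cs, rel=1e-12)


# --- filters ---------------------------------------------------------------

@pytest.mark.parametrize("pixels,intensity,small,dim", [
    (99, 100.0, True, False),    # just under the area cut
    (100, 100.0, False, False),  # boundary retained
    (150, 49.9, False, True),    # just under the intensity cut
    (150, 50.0, False, False),   # boundary retained
    (99, 49.9, True, True),
])
def test_filter_boundaries(pixels, intensity, small, dim):
    t = _trace_table(np.ones(5), pixel_count=pixels, intensity=intensity)
    out = qt.apply_filters(t)
    assert out["too_small"].all() == small
    assert out["too_dim"].all() == dim
    assert qt.retained(out).all() == (not small and not dim)


def test_filters_order_independent():
    rng = np.random.default_rng(1)
    t = pd.concat([_trace_table(rng.random(5), cell_id=i,
                                pixel_count=rng.integers(50, 200),
                                intensity=rng.uniform(10, 90))
                   for i in range(1, 9)], ignore_index=True)
    a = qt.apply_filters(qt.apply_filters(t, min_pixels=100, min_sum_intensity=0),
                         min_pixels=0, min_sum_intensity=50)
    b = qt.apply_filters(qt.apply_filters(t, min_pixels=0, min_sum_intensity=50),
                         min_pixels=100, min_sum_intensity=0)
    merged_a = a["too_small"] | a["too_dim"]
    merged_b = b["too_small"] | b["too_dim"]
    pd.testing.assert_series_equal(merged_a, merged_b)


# --- z-scoring -------------------------------------------------------------

def test_zscore_uses_population_sd():
    t = pd.concat([_trace_table([1.0, 1.0], cell_id=1),
                   _trace_table([3.0, 3.0], cell_id=2)], ignore_index=True)
    t = qt.apply_filters(t)
    out = qt.zscore_normalize(t, "acq")
    assert out.attrs["baseline_mu"] == 2.0
    assert out.attrs["baseline_sigma"] == 1.0  # population SD of {1,1,3,3}
    assert out.loc[out["ratio_smoothed"] == 1.0, "zscore"].iloc[0] == -1.0


def test_post_injection_value_at_mu_maps_to_zero():
    base = pd.concat([_trace_table([1.0, 3.0], cell_id=1),
                      _trace_table([2.0, 2.0], cell_id=2)], ignore_index=True)
    post = _trace_table([2.0, 2.0], acquisition_id="post", cell_id=1)
    t = qt.apply_filters(pd.concat([base, post], ignore_index=True))
    out = qt.zscore_normalize(t, "acq")
    np.testing.assert_allclose(out.loc[out["acquisition_id"] == "post", "zscore"], 0.0)


def test_baseline_population_normalizes_to_unit(small_scene):
    table, _ = quantify_scene(small_scene, noise=sc.NoiseModel())
    keep = qt.retained(table)
    z = table.loc[keep & (table["acquisition_id"] == "baseline"), "zscore"]
    assert abs(z.mean()) < 1e-9
    assert abs(z.std(ddof=0) - 1.0) < 1e-9


def test_degenerate_baseline_rejected():
    t = qt.apply_filters(pd.concat([_trace_table([2.0, 2.0], cell_id=1),
                                    _trace_table([2.0, 2.0], cell_id=2)],
                                   ignore_index=True))
    with pytest.raises(ValueError, match="degenerate baseline"):
        qt.zscore_normalize(t, "acq")


def test_zscore_invariant_to_common_channel_rescale(small_scene):
    """Scaling both channels by one factor leaves the ratio, hence every
    z-score, unchanged."""
    movie = sc.render_movie(small_scene, noise=None)
    rs = seg.RoiSet.from_label_image(small_scene.truth_label_image())
    t1 = qt.quantify(movie, rs, "baseline", min_pixels=20, min_sum_intensity=0)
    scaled = movie_io.TwoChannelMovie(yfp=movie.yfp * 3.7, cfp=movie.cfp * 3.7,
                                      frame_rate=movie.frame_rate)
    t2 = qt.quantify(scaled, rs, "baseline", min_pixels=20, min_sum_intensity=0)
    z1 = qt.zscore_normalize(t1, "baseline")["zscore"]
    z2 = qt.zscore_normalize(t2, "baseline")["zscore"]
    np.testing.assert_allclose(z1, z2, atol=1e-9)


# --- window summaries ------------------------------------------------------

def test_constant_z_window_auc_is_constant():
    t = _trace_table(np.ones(30))
    s = qt.summarize_window(t, window=(0.0, 20.0))
    assert s["mean_z_auc"].iloc[0] == pytest.approx(1.0, abs=1e-12)


def test_linear_ramp_auc_is_half():
    t = _trace_table(np.linspace(0, 1, 21))
    s = qt.summarize_window(t, window=(0.0, 20.0))
    assert s["mean_z_auc"].iloc[0] == pytest.approx(0.5, abs=1e-12)


def test_window_auc_matches_naive_trapezoid():
    rng = np.random.default_rng(11)
    for _ in range(50):
        n = rng.integers(5, 60)
        vals = rng.normal(size=n)
        t = _trace_table(vals)
        lo = float(rng.integers(0, n - 3))
        hi = float(rng.integers(int(lo) + 2, n))
        s = qt.summarize_window(t, window=(lo, hi))
        ts = np.arange(n, dtype=float)
        sel = (ts >= lo) & (ts <= hi)
        tt, vv = ts[sel], vals[sel]
        naive = sum((vv[i] + vv[i + 1]) / 2 * (tt[i + 1] - tt[i])
                    for i in range(len(tt) - 1)) / (tt[-1] - tt[0])
        assert s["mean_z_auc"].iloc[0] == pytest.approx(naive, abs=1e-12)


def test_delta_vs_reference_window():
    vals = np.concatenate([np.zeros(10), np.full(10, 2.0)])
    t = _trace_table(vals)
    s = qt.summarize_window(t, window=(10.0, 19.0), reference_window=(0.0, 9.0))
    assert s["delta_vs_reference"].iloc[0] == pytest.approx(2.0)


def test_window_too_short_rejected():
    t = _trace_table(np.ones(30))
    with pytest.raises(ValueError, match="fewer than 2 frames"):
        qt.summarize_window(t, window=(5.0, 5.5))
    with pytest.raises(ValueError, match="exceed"):
        qt.summarize_window(t, window=(5.0, 5.0))


# --- acute flux ------------------------------------------------------------

def test_acute_flux_examples():
    assert qt.acute_flux(_trace_table(np.ones(15)))["acute_flux"].iloc[0] == 0.0
    t = _trace_table([0.0, -2.0, 1.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0])
    assert qt.acute_flux(t)["acute_flux"].iloc[0] == pytest.approx(3.0)


def test_acute_flux_recovers_transient_amplitude():
    amp = 1.7
    vals = np.zeros(40)
    vals[3:8] = -amp  # scan-onset dip inside the first 10 s
    t = _trace_table(vals)
    got = qt.acute_flux(t, window=(0.0, 10.0))["acute_flux"].iloc[0]
    assert got == pytest.approx(amp)


# --- pipeline monotonicity -------------------------------------------------

def test_uniform_atp_increase_never_decreases_summary_z(small_scene):
    table, _ = quantify_scene(small_scene, noise=None)
    raised = sc.GroundTruthScene(
        cells=[sc.CellTruth(c.cell_id, c.centroid, c.radius, c.cell_type,
                            np.clip(c.atp_trajectory + 0.5, 0, 10),
                            brightness=c.brightness)
               for c in small_scene.cells],
        field_shape=small_scene.field_shape, n_frames=small_scene.n_frames,
        corner_mask=small_scene.corner_mask, rng_seed=small_scene.rng_seed)
    table2, _ = quantify_scene(raised, noise=None)
    m1 = table[qt.retained(table)].groupby("cell_id")["ratio_smoothed"].mean()
    m2 = table2[qt.retained(table2)].groupby("cell_id")["ratio_smoothed"].mean()
    assert (m2 - m1 >= -1e-12).all()
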
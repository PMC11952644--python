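import numpy as np
import pytest

from retfret import preprocess as pp
from retfret import quant as qt
from retfret import scene as sc
from retfret import segment as seg


@pytest.fixture(scope="session")
def small_scene() -> sc.GroundTruthScene:
    """A 20-cell noiseless-renderable baseline field used across modules."""
    return sc.make_scene(n_cells=20, field_shape=(128, 128), n_frames=30, seed=1)


@pytest.fixture(scope="session")
def noiseless_movie(small_scene):
    return sc.render_movie(small_scene, noise=None)


def match_to_truth(roiset: seg.RoiSet, scene: sc.GroundTruthScene,
                   radius_px: float = 5.0) -> dict[int, int]:
    """roi_id -> truth cell_id by nearest centroid within a radius."""
    truth = scene.truth_table()
    tc = truth[["centroid_y", "centroid_x"]].to_numpy()
    out = {}
    cents = roiset.centroids()
    for i, roi_id in enumerate(roiset.rois["roi_id"]):
        d = np.linalg.norm(tc - cents[i], axis=1)
        j = int(d.argmin())
        if d[j] <= radius_px:
            out[int(roi_id)] = int(truth["cell_id"].iloc[j])
    return out


def quantify_scene(scene: sc.GroundTruthScene, noise=sc.NoiseModel(),
                   acquisition_id: str = "baseline", min_pixels: int = 20,
                   use_truth_masks: bool = True):
    """Render -> background-subtract -> (truth-mask) quantify -> z-score."""
    movie = pp.subtract_background(sc.render_movie(scene, noise=noise))
    if use_truth_masks:
        roiset = seg.RoiSet.from_label_image(scene.truth_label_image())
    else:
        proj = (movie.yfp.mean(0) + movie.cfp.mean(0)) / 2
        roiset = seg.segment_somas(proj, scene.cells[0].radius,
                                   corner_mask=scene.corner_mask)
    table = qt.quantify(movie, roiset, acquisition_id, min_pixels=min_pixels)
    return qt.zscore_normalize(table, acquisition_id), roiset
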
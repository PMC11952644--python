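#!/usr/bin/env python
"""Generate the synthetic imaging cohorts used by the downstream analyses.

Writes, under results/data/:
  * a baseline two-channel movie + ground truth for one retina,
  * a repeat-imaging session of the same field 7 "days" later,
  * a complex-I-inhibition (rotenone) session,
  * a post hoc immunostain volume with its landmark table.

Everything is seeded; re-running reproduces the files byte for byte.
"""

import json
from pathlib import Path

import numpy as np
import tifffile

from retfret import movie_io
from retfret import scene as sc

SEED = 20260923
OUT = Path("results/data")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    base = sc.make_scene(n_cells=120, field_shape=(288, 288), n_frames=60,
                         seed=SEED, drift_per_frame=(0.11, -0.08))
    base.drift_path[:] = 0.0
    movie_io.save_interleaved(sc.render_movie(base), OUT / "baseline.tif")
    base.truth_table().to_csv(OUT / "baseline_truth.csv", index=False)
    tifffile.imwrite(OUT / "baseline_labels.tif",
                     base.truth_label_image().astype(np.uint16))

    later = sc.repeat_scene(base)
    later.drift_path[:] = np.array([6.0, -4.0])
    movie_io.save_interleaved(sc.render_movie(later), OUT / "retest_day7.tif")
    later.truth_table().to_csv(OUT / "retest_day7_truth.csv", index=False)

    rot_scene = sc.make_scene(n_cells=60, field_shape=(192, 192), n_frames=300,
                              soma_radius_px=6, seed=SEED + 1)
    rot = sc.apply_perturbation(rot_scene, "ROT")
    movie_io.save_interleaved(sc.render_movie(rot), OUT / "rotenone.tif")
    rot.truth_table().to_csv(OUT / "rotenone_truth.csv", index=False)
    tifffile.imwrite(OUT / "rotenone_labels.tif",
                     rot_scene.truth_label_image().astype(np.uint16))

    warp = sc.SmoothWarp(dy=4.0, dx=-3.0, amp=2.0, period=150.0)
    channels, labels3d, landmarks, conf_truth = sc.render_immunostain(base, warp)
    stack = np.stack([channels[k] for k in ("reference", "spp1", "tbr2", "cart",
                                            "mito")], axis=1)
    tifffile.imwrite(OUT / "immunostain.tif",
                     np.clip(stack, 0, 65535).astype(np.uint16))
    tifffile.imwrite(OUT / "immunostain_labels.tif", labels3d.astype(np.uint16))
    landmarks.to_csv(OUT / "landmarks.csv", index=False)
    conf_truth.to_csv(OUT / "immunostain_truth.csv", index=False)

    (OUT / "meta.json").write_text(json.dumps(
        {"seed": SEED, "channel_axis_order": "ZCYX",
         "immunostain_channels": ["reference", "spp1", "tbr2", "cart", "mito"]},
        indent=2))
    print(f"wrote baseline ({len(base.cells)} cells), retest, rotenone and "
          f"immunostain fixtures to {OUT}/")


if __name__ == "__main__":
    main()
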
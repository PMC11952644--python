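"""Two-channel interleaved TIFF movie container and IO.

Acquisition software writes both emission channels into a single multi-page
TIFF with pages interleaved frame by frame (YFP_t0, CFP_t0, YFP_t1, ...).
This module deinterleaves such stacks into a :class:`TwoChannelMovie` and
writes movies back in the same dialect, with acquisition metadata carried in
a JSON sidecar.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

DEFAULT_FRAME_RATE = 1.07  # frames/second of the raster scan

__all__ = ["TwoChannelMovie", "load_interleaved", "save_interleaved", "average_projection",
           "DEFAULT_FRAME_RATE"]


@dataclass
class TwoChannelMovie:
    """Time-ordered YFP/CFP intensity stacks plus acquisition metadata.

    Intensities are kept as float64 in memory (sums of uint16 data overflow);
    on disk they are stored as uint16.
    """

    yfp: np.ndarray  # (T, H, W)
    cfp: np.ndarray  # (T, H, W)
    frame_rate: float = DEFAULT_FRAME_RATE
    origin_tag: str = ""

    def __post_init__(self) -> None:
        self.yfp = np.asarray(self.yfp, dtype=float)
        self.cfp = np.asarray(self.cfp, dtype=float)
        if self.yfp.shape != self.cfp.shape:
            raise ValueError("yfp and cfp stacks must share a shape")
        if self.yfp.ndim != 3:
            raise ValueError("stacks must be (T, H, W)")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")

    @property
    def n_frames(self) -> int:
        return self.yfp.shape[0]

    @property
    def field_shape(self) -> tuple[int, int]:
        return self.yfp.shape[1:]

    @property
    def times_s(self) -> np.ndarray:
        """Frame acquisition times in seconds (frame 0 at t=0)."""
        return np.arange(self.n_frames) / self.frame_rate


def load_interleaved(path: str | Path, channel_order: str = "yfp_first") -> TwoChannelMovie:
    """Read an interleaved two-channel TIFF stack.

    Parameters
    ----------
    path:
        Multi-page TIFF whose pages alternate between the two detectors.
    channel_order:
        ``"yfp_first"`` (default) or ``"cfp_first"``; the detector page order
        is an acquisition convention, not discoverable from the file.
    """
    path = Path(path)
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    if pages.shape[0] % 2 != 0:
        raise ValueError(f"{path.name}: {pages.shape[0]} pages — not interleavable")
    if channel_order not in ("yfp_first", "cfp_first"):
        raise ValueError(f"unknown channel_order {channel_order!r}")
    a, b = pages[0::2], pages[1::2]
    yfp, cfp = (a, b) if channel_order == "yfp_first" else (b, a)

    meta = _sidecar_path(path)
    frame_rate, tag = DEFAULT_FRAME_RATE, path.stem
    if meta.exists():
        side = json.loads(meta.read_text())
        frame_rate = float(side.get("frame_rate", frame_rate))
        tag = side.get("origin_tag", tag)
        if side.get("channel_order", channel_order) != channel_order:
            raise ValueError("channel_order conflicts with sidecar metadata")
    return TwoChannelMovie(yfp=yfp, cfp=cfp, frame_rate=frame_rate, origin_tag=tag)


def save_interleaved(movie: TwoChannelMovie, path: str | Path,
                     channel_order: str = "yfp_first") -> Path:
    """Write the movie as an interleaved multi-page uint16 TIFF + JSON sidecar."""
    path = Path(path)
    t, h, w = movie.yfp.shape
    pages = np.empty((2 * t, h, w), dtype=np.uint16)
    a, b = (movie.yfp, movie.cfp) if channel_order == "yfp_first" else (movie.cfp, movie.yfp)
    pages[0::2] = np.clip(np.round(a), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    pages[1::2] = np.clip(np.round(b), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    tifffile.imwrite(path, pages)
    _sidecar_path(path).write_text(json.dumps(
        {"frame_rate": movie.frame_rate, "channel_order": channel_order,
         "origin_tag": movie.origin_tag}, indent=2))
    return path


def average_projection(movie: TwoChannelMovie) -> np.ndarray:
    """Time- and channel-average projection: per-pixel mean of (YFP+CFP)/2."""
    if movie.n_frames < 1:
        raise ValueError("empty movie")
    return (movie.yfp.mean(axis=0) + movie.cfp.mean(axis=0)) / 2.0


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")
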
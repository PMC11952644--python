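"""Background subtraction, motion correction and cross-acquisition alignment.

Background is one scalar per channel per acquisition: the median of pixel
values over all frames in the scan-clipped corner regions. Within-movie
motion is corrected by subpixel phase correlation of each summed-channel
frame against a running template; both channels of a frame receive the same
shift so the ratio is untouched. Acquisitions taken at different times are
brought into register with a similarity transform (rotation/scale via
log-polar Fourier magnitude correlation, then translation), falling back to
translation-only phase correlation when the projections carry too few
features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import feature, registration, transform

from .movie_io import TwoChannelMovie
from .scene import default_corner_mask

__all__ = ["RigidTransform", "estimate_background", "subtract_background",
           "motion_correct", "align_acquisitions", "apply_transform",
           "transform_points", "smooth_trace", "default_corner_mask"]


@dataclass
class RigidTransform:
    """Similarity transform (moving -> reference): rotate by ``rotation``
    about the image centre, scale, then translate by (dy, dx) pixels."""

    dy: float = 0.0
    dx: float = 0.0
    rotation: float = 0.0  # radians
    scale: float = 1.0

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale must be positive")

    def is_identity(self, tol: float = 1e-9) -> bool:
        return (abs(self.dy) < tol and abs(self.dx) < tol
                and abs(self.rotation) < tol and abs(self.scale - 1) < tol)

    def to_skimage(self, shape: tuple[int, int]) -> transform.SimilarityTransform:
        """Equivalent skimage transform in (x, y) convention, rotating about
        the image centre."""
        cy, cx = (shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0
        centre = transform.SimilarityTransform(translation=(-cx, -cy))
        rot = transform.SimilarityTransform(rotation=self.rotation, scale=self.scale)
        back = transform.SimilarityTransform(translation=(cx + self.dx, cy + self.dy))
        return centre + rot + back


def transform_points(points: np.ndarray, tf: RigidTransform,
                     shape: tuple[int, int]) -> np.ndarray:
    """Map (y, x) points through the transform (moving -> reference frame)."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    sk = tf.to_skimage(shape)
    xy = sk(pts[:, ::-1])
    return xy[:, ::-1]


def apply_transform(image: np.ndarray, tf: RigidTransform) -> np.ndarray:
    """Resample a moving image into the reference frame."""
    sk = tf.to_skimage(image.shape)
    return transform.warp(image, sk.inverse, order=1, preserve_range=True)


def estimate_background(movie: TwoChannelMovie,
                        corner_mask: np.ndarray | None = None) -> tuple[float, float]:
    """Per-channel background: median over every (corner pixel, frame) sample."""
    if corner_mask is None:
        corner_mask = default_corner_mask(movie.field_shape)
    corner_mask = np.asarray(corner_mask, dtype=bool)
    if not corner_mask.any():
        raise ValueError("empty corner mask")
    return (float(np.median(movie.yfp[:, corner_mask])),
            float(np.median(movie.cfp[:, corner_mask])))


def subtract_background(movie: TwoChannelMovie,
                        background: tuple[float, float] | None = None,
                        corner_mask: np.ndarray | None = None) -> TwoChannelMovie:
    """Subtract the per-channel background scalar from every pixel, clipping
    at zero."""
    if background is None:
        background = estimate_background(movie, corner_mask)
    by, bc = background
    return TwoChannelMovie(yfp=np.clip(movie.yfp - by, 0, None),
                           cfp=np.clip(movie.cfp - bc, 0, None),
                           frame_rate=movie.frame_rate, origin_tag=movie.origin_tag)


def motion_correct(movie: TwoChannelMovie,
                   max_shift_px: float | None = None,
                   upsample: int = 20) -> tuple[TwoChannelMovie, pd.DataFrame]:
    """Register each frame to a running template by subpixel phase
    correlation of the summed-channel image; apply the identical shift to
    both channels.

    Returns the corrected movie and a QC table with per-frame estimated
    drift (dy, dx) relative to frame 0 and a ``flagged`` column for frames
    whose shift exceeded ``max_shift_px`` (left uncorrected).
    """
    if movie.n_frames < 2:
        raise ValueError("need at least 2 frames")
    total = movie.yfp + movie.cfp
    yfp = movie.yfp.copy()
    cfp = movie.cfp.copy()
    template = total[0].astype(float)
    n_acc = 1
    rows = [{"frame": 0, "dy": 0.0, "dx": 0.0, "flagged": False}]
    for t in range(1, movie.n_frames):
        shift, _, _ = registration.phase_cross_correlation(
            template, total[t], upsample_factor=upsample, normalization=None)
        dy, dx = float(shift[0]), float(shift[1])
        # phase correlation returns the shift that moves frame onto template,
        # i.e. minus the content drift
        drift = (-dy, -dx)
        flagged = max_shift_px is not None and np.hypot(dy, dx) > max_shift_px
        if not flagged:
            for ch in (yfp, cfp):
                ch[t] = np.real(np.fft.ifft2(ndimage.fourier_shift(
                    np.fft.fft2(ch[t]), (dy, dx))))
            reg = np.real(np.fft.ifft2(ndimage.fourier_shift(
                np.fft.fft2(total[t].astype(float)), (dy, dx))))
            template = (template * n_acc + reg) / (n_acc + 1)
            n_acc += 1
        rows.append({"frame": t, "dy": drift[0], "dx": drift[1], "flagged": bool(flagged)})
    qc = pd.DataFrame(rows)
    out = TwoChannelMovie(yfp=np.clip(yfp, 0, None), cfp=np.clip(cfp, 0, None),
                          frame_rate=movie.frame_rate, origin_tag=movie.origin_tag)
    return out, qc


def _hann2d(shape: tuple[int, int]) -> np.ndarray:
    wy = np.hanning(shape[0])
    wx = np.hanning(shape[1])
    return np.outer(wy, wx)


def align_acquisitions(reference_proj: np.ndarray, moving_proj: np.ndarray,
                       allow_rotation: bool = True,
                       min_features: int = 3) -> RigidTransform:
    """Similarity transform mapping a moving average projection onto the
    reference projection.

    Rotation and scale come from phase correlation of the log-polar-warped
    Fourier magnitudes (with the 180-degree ambiguity resolved by intensity
    agreement); translation from a final phase correlation. If either
    projection shows fewer than ``min_features`` detectable somas, rotation
    recovery is unreliable and the routine falls back to translation-only
    registration with a warning.
    """
    ref = np.asarray(reference_proj, dtype=float)
    mov = np.asarray(moving_proj, dtype=float)
    if ref.size == 0 or mov.size == 0 or ref.shape != mov.shape:
        raise ValueError("projections must be non-empty and same-shaped")

    def _translation_only() -> RigidTransform:
        shift, _, _ = registration.phase_cross_correlation(
            ref, mov, upsample_factor=20, normalization=None)
        return RigidTransform(dy=float(shift[0]), dx=float(shift[1]))

    if not allow_rotation:
        return _translation_only()

    n_feat = min(_count_blobs(ref), _count_blobs(mov))
    if n_feat < min_features:
        warnings.warn(f"only {n_feat} features detected; translation-only fallback")
        return _translation_only()

    win = _hann2d(ref.shape)
    f_ref = np.abs(np.fft.fftshift(np.fft.fft2(ref * win)))
    f_mov = np.abs(np.fft.fftshift(np.fft.fft2(mov * win)))
    radius = min(ref.shape) // 2
    n_angle = 720
    lp_ref = transform.warp_polar(f_ref, radius=radius, scaling="log", output_shape=(n_angle, radius))
    lp_mov = transform.warp_polar(f_mov, radius=radius, scaling="log", output_shape=(n_angle, radius))
    # ignore the lowest frequencies (dominated by the window)
    lp_ref, lp_mov = lp_ref[:, radius // 8:], lp_mov[:, radius // 8:]
    shift, _, _ = registration.phase_cross_correlation(
        lp_ref, lp_mov, upsample_factor=20, normalization=None)
    coarse = shift[0] * (360.0 / n_angle)
    klog = radius / np.log(radius)
    scale = float(np.exp(shift[1] / klog))

    def _fit(angle_deg: float) -> tuple[float, RigidTransform]:
        rot = np.deg2rad(angle_deg)
        mov_rot = apply_transform(mov, RigidTransform(rotation=rot, scale=scale))
        sh, _, _ = registration.phase_cross_correlation(
            ref, mov_rot, upsample_factor=20, normalization=None)
        tf = RigidTransform(dy=float(sh[0]), dx=float(sh[1]), rotation=rot, scale=scale)
        warped = apply_transform(mov, tf)
        my, mx = ref.shape[0] // 8, ref.shape[1] // 8
        a = ref[my:-my, mx:-mx].ravel()
        b = warped[my:-my, mx:-mx].ravel()
        return float(np.corrcoef(a, b)[0, 1]), tf

    # the spectral estimate is sign- and 180-degree-ambiguous: score candidates
    best = max((_fit(c) for c in (coarse, -coarse, coarse + 180.0, -coarse + 180.0)),
               key=lambda sc: sc[0])
    # local refinement of the angle against the intensity overlap
    from scipy.optimize import minimize_scalar
    centre = np.rad2deg(best[1].rotation)
    res = minimize_scalar(lambda a: -_fit(a)[0],
                          bounds=(centre - 1.5, centre + 1.5), method="bounded",
                          options={"xatol": 0.01})
    refined = _fit(float(res.x))
    return refined[1] if refined[0] >= best[0] else best[1]


def _count_blobs(img: np.ndarray) -> int:
    norm = img - img.min()
    peak = norm.max()
    if peak <= 0:
        return 0
    blobs = feature.blob_log(norm / peak, min_sigma=2, max_sigma=8, num_sigma=4,
                             threshold=0.1)
    return len(blobs)


def align_movie(movie: TwoChannelMovie, tf: RigidTransform) -> TwoChannelMovie:
    """Apply a cross-acquisition transform to every frame of both channels."""
    if tf.is_identity():
        return movie
    yfp = np.stack([apply_transform(f, tf) for f in movie.yfp])
    cfp = np.stack([apply_transform(f, tf) for f in movie.cfp])
    return TwoChannelMovie(yfp=yfp, cfp=cfp, frame_rate=movie.frame_rate,
                           origin_tag=movie.origin_tag)


def smooth_trace(trace: np.ndarray, window: int = 20) -> np.ndarray:
    """Centred moving average with the window shrinking symmetrically at the
    edges; output length equals input length.

    For an even ``window`` the interior average spans exactly ``window``
    samples, left-heavy by one ([i - w//2, i + w - w//2)). Near the edges
    the span shrinks to the largest centred window that fits.
    """
    x = np.asarray(trace, dtype=float)
    if x.size == 0:
        raise ValueError("empty trace")
    if window < 1:
        raise ValueError("window must be >= 1")
    n = x.size
    csum = np.concatenate([[0.0], np.cumsum(x)])
    out = np.empty(n)
    for i in range(n):
        width = min(window, 2 * min(i, n - 1 - i) + 1)
        lo = i - width // 2
        out[i] = (csum[lo + width] - csum[lo]) / width
    return out
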
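"""Ground-truthed synthetic imaging scenes.

Emulates the study system: a field of retinal ganglion cell (RGC) somas
expressing a FRET ATP sensor, raster-scanned in two emission channels (YFP
acceptor / CFP donor) at ~1.07 frames/s on a 512x512 grid whose corners are
clipped by the objective and therefore carry only background. Each cell has
a type-specific ATP set-point; the rendered YFP/CFP split follows a
saturating Hill mapping of true ATP, saturating near 10 mM. Scenes support
rigid frame-to-frame drift, Poisson shot noise plus Gaussian read noise,
drug-induced ATP kinetics, and apoptotic sensor cleavage (ratio collapse).

The generator is the study-conditions oracle for every downstream stage:
its hidden truth (positions, types, trajectories, fates) is what recovery
tests measure against.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .movie_io import DEFAULT_FRAME_RATE, TwoChannelMovie

__all__ = [
    "HillParams", "NoiseModel", "CellTruth", "GroundTruthScene", "SmoothWarp",
    "DrugKinetics", "DRUG_KINETICS", "MARKER_RULES",
    "hill_ratio", "make_scene", "render_movie", "render_immunostain",
    "apply_perturbation", "default_corner_mask", "simulate_longitudinal_cohort",
]

CELL_TYPES = ("alpha", "alpha_on_s", "ip", "oods", "other")

# Baseline ATP set-points (mM). Alpha-type cells sit ~0.8 within-type SD below
# the rest of the population; alpha-ON-sustained cells match other alphas.
DEFAULT_SETPOINTS_MM = {
    "alpha": 2.40, "alpha_on_s": 2.38, "ip": 2.70, "oods": 2.65, "other": 2.60,
}
DEFAULT_SETPOINT_SD_MM = 0.25
# Each immunostain marker labels a minority of the population (alpha-family
# cells are a small fraction of RGCs in vivo); the within-image IQR
# positivity rule presumes exactly that regime.
DEFAULT_TYPE_PROPS = {
    "alpha": 0.08, "alpha_on_s": 0.05, "ip": 0.15, "oods": 0.15, "other": 0.57,
}


@dataclass(frozen=True)
class HillParams:
    """Saturating ATP -> YFP/CFP ratio mapping.

    ratio(A) = r_min + (r_max - r_min) * A^h / (K^h + A^h)

    Defaults are simulator configuration chosen so the dynamic range
    saturates near 10 mM ATP (ratio within 1% of r_max there); they are not
    a claimed sensor calibration.
    """

    r_min: float = 0.6
    r_max: float = 6.0
    k_mm: float = 1.0
    h: float = 2.5


DEFAULT_HILL = HillParams()


def hill_ratio(atp_mm: np.ndarray | float, params: HillParams = DEFAULT_HILL) -> np.ndarray | float:
    """Map true ATP concentration (mM) to the rendered YFP/CFP ratio."""
    a = np.asarray(atp_mm, dtype=float)
    frac = a ** params.h / (params.k_mm ** params.h + a ** params.h)
    out = params.r_min + (params.r_max - params.r_min) * frac
    return float(out) if np.isscalar(atp_mm) else out


@dataclass(frozen=True)
class NoiseModel:
    """Two-photon detector noise: Poisson shot noise on expected photon
    counts (with a gain converting photons to intensity units) plus additive
    Gaussian read noise."""

    gain: float = 1.0
    read_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.gain < 0 or self.read_sd < 0:
            raise ValueError("noise parameters must be non-negative")

    def sample(self, expected: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        out = expected
        if self.gain > 0:
            out = rng.poisson(expected / self.gain).astype(float) * self.gain
        if self.read_sd > 0:
            out = out + rng.normal(0.0, self.read_sd, size=expected.shape)
        return np.clip(out, 0.0, None)


@dataclass
class CellTruth:
    """Hidden truth for one soma."""

    cell_id: int
    centroid: tuple[float, float]  # (y, x) pixels
    radius: float                  # footprint truncation radius, pixels
    cell_type: str
    atp_trajectory: np.ndarray     # per-frame [mM], within [0, 10]
    fate: str = "survives"         # "survives" or "dies_day_k"
    death_day: int | None = None
    cleavage_frame: int | None = None  # within-acquisition frame of ratio collapse
    brightness: float = 400.0      # peak expected YFP+CFP intensity (a.u.)
    overlapping: bool = False

    def __post_init__(self) -> None:
        self.atp_trajectory = np.asarray(self.atp_trajectory, dtype=float)
        if self.cell_type not in CELL_TYPES:
            raise ValueError(f"unknown cell_type {self.cell_type!r}")
        if np.any(self.atp_trajectory < 0) or np.any(self.atp_trajectory > 10):
            raise ValueError("atp_trajectory must lie in [0, 10] mM")
        if self.fate.startswith("dies") and self.death_day is None and self.cleavage_frame is None:
            raise ValueError("a dying cell needs a cleavage time or death day")
        if self.brightness < 0:
            raise ValueError("negative brightness")

    def ratio_trajectory(self, hill: HillParams = DEFAULT_HILL,
                         cleaved_ratio: float = 0.25) -> np.ndarray:
        """Rendered per-frame YFP/CFP ratio: Hill-mapped ATP, collapsing to a
        fixed low value after sensor cleavage."""
        r = np.asarray(hill_ratio(self.atp_trajectory, hill), dtype=float)
        if self.cleavage_frame is not None:
            r[self.cleavage_frame:] = cleaved_ratio
        return r


@dataclass
class GroundTruthScene:
    cells: list[CellTruth]
    field_shape: tuple[int, int]
    frame_rate: float = DEFAULT_FRAME_RATE
    n_frames: int = 100
    corner_mask: np.ndarray | None = None
    drift_path: np.ndarray | None = None  # (n_frames, 2) of (dy, dx)
    rng_seed: int = 0
    hill: HillParams = DEFAULT_HILL
    background: float = 10.0  # per-channel background level (a.u.), also in corners

    def __post_init__(self) -> None:
        if self.corner_mask is None:
            self.corner_mask = default_corner_mask(self.field_shape)
        self.corner_mask = np.asarray(self.corner_mask, dtype=bool)
        if self.corner_mask.shape != tuple(self.field_shape):
            raise ValueError("corner_mask shape mismatch")
        if self.drift_path is None:
            self.drift_path = np.zeros((self.n_frames, 2))
        self.drift_path = np.asarray(self.drift_path, dtype=float)
        if self.drift_path.shape != (self.n_frames, 2):
            raise ValueError("drift_path must have exactly n_frames (dy, dx) entries")
        self.validate()

    def validate(self) -> None:
        h, w = self.field_shape
        for c in self.cells:
            y, x = c.centroid
            if not (0 <= y < h and 0 <= x < w):
                raise ValueError(f"cell {c.cell_id} centroid outside field")
            if self.corner_mask[int(round(y)), int(round(x))]:
                raise ValueError(f"cell {c.cell_id} centroid inside corner mask")
            if len(c.atp_trajectory) != self.n_frames:
                raise ValueError(f"cell {c.cell_id} trajectory length != n_frames")
        # flag (rather than forbid) overlapping footprints
        for i, a in enumerate(self.cells):
            for b in self.cells[i + 1:]:
                d = np.hypot(a.centroid[0] - b.centroid[0], a.centroid[1] - b.centroid[1])
                if d < a.radius + b.radius:
                    a.overlapping = b.overlapping = True

    def truth_table(self) -> pd.DataFrame:
        """Per-cell ground truth with noiseless mean rendered ratio."""
        rows = []
        for c in self.cells:
            r = c.ratio_trajectory(self.hill)
            rows.append({
                "cell_id": c.cell_id, "cell_type": c.cell_type,
                "centroid_y": c.centroid[0], "centroid_x": c.centroid[1],
                "radius": c.radius, "fate": c.fate, "death_day": c.death_day,
                "true_mean_atp_mm": float(c.atp_trajectory.mean()),
                "true_mean_ratio": float(r.mean()),
            })
        return pd.DataFrame(rows)

    def truth_label_image(self) -> np.ndarray:
        """Ground-truth soma label image (disc footprints, id = cell_id)."""
        h, w = self.field_shape
        labels = np.zeros((h, w), dtype=np.int32)
        yy, xx = np.mgrid[0:h, 0:w]
        for c in self.cells:
            d2 = (yy - c.centroid[0]) ** 2 + (xx - c.centroid[1]) ** 2
            labels[(d2 <= c.radius ** 2) & (labels == 0)] = c.cell_id
        labels[self.corner_mask] = 0
        return labels


def default_corner_mask(field_shape: tuple[int, int], radius_px: int | None = None) -> np.ndarray:
    """Four quarter-disc regions at the frame corners where the raster scan
    is clipped by the objective (default radius: 1/8 of the short side, i.e.
    64 px on a 512x512 frame)."""
    h, w = field_shape
    if radius_px is None:
        radius_px = min(h, w) // 8
    yy, xx = np.mgrid[0:h, 0:w]
    mask = np.zeros((h, w), dtype=bool)
    for cy, cx in ((0, 0), (0, w - 1), (h - 1, 0), (h - 1, w - 1)):
        mask |= (yy - cy) ** 2 + (xx - cx) ** 2 <= radius_px ** 2
    return mask


def make_scene(n_cells: int = 120,
               field_shape: tuple[int, int] = (256, 256),
               n_frames: int = 150,
               frame_rate: float = DEFAULT_FRAME_RATE,
               soma_radius_px: float = 8.0,
               type_props: dict[str, float] | None = None,
               setpoints_mm: dict[str, float] | None = None,
               setpoint_sd_mm: float = DEFAULT_SETPOINT_SD_MM,
               brightness: float = 400.0,
               brightness_cv: float = 0.15,
               drift_per_frame: tuple[float, float] = (0.0, 0.0),
               seed: int = 0) -> GroundTruthScene:
    """Draw a baseline scene: somas placed without overlap, outside the
    clipped corners, with per-cell constant ATP set-points drawn from
    type-specific normals (clipped to [0.2, 9.8] mM)."""
    rng = np.random.default_rng(seed)
    props = dict(DEFAULT_TYPE_PROPS if type_props is None else type_props)
    setp = dict(DEFAULT_SETPOINTS_MM if setpoints_mm is None else setpoints_mm)
    names = list(props)
    p = np.array([props[k] for k in names], dtype=float)
    p /= p.sum()

    h, w = field_shape
    corner = default_corner_mask(field_shape)
    max_drift = np.abs(np.array(drift_per_frame)) * (n_frames - 1)
    margin = soma_radius_px + 1 + max_drift
    cells: list[CellTruth] = []
    centroids: list[tuple[float, float]] = []
    tries = 0
    while len(cells) < n_cells and tries < n_cells * 400:
        tries += 1
        y = rng.uniform(margin[0], h - 1 - margin[0])
        x = rng.uniform(margin[1], w - 1 - margin[1])
        if corner[int(round(y)), int(round(x))]:
            continue
        if any(np.hypot(y - cy, x - cx) < 2.3 * soma_radius_px for cy, cx in centroids):
            continue
        ctype = names[rng.choice(len(names), p=p)]
        # truncated normal: baseline populations are approximately normal and
        # free of extreme tails that the saturating sensor would distort
        mu = setp[ctype]
        a = float(np.clip(rng.normal(mu, setpoint_sd_mm),
                          max(mu - 2.5 * setpoint_sd_mm, 0.2),
                          min(mu + 2.5 * setpoint_sd_mm, 9.8)))
        cells.append(CellTruth(
            cell_id=len(cells) + 1, centroid=(y, x), radius=soma_radius_px,
            cell_type=ctype, atp_trajectory=np.full(n_frames, a),
            brightness=float(brightness * rng.lognormal(0.0, brightness_cv)),
        ))
        centroids.append((y, x))
    if len(cells) < n_cells:
        warnings.warn(f"placed only {len(cells)}/{n_cells} cells without overlap")

    drift = np.outer(np.arange(n_frames), np.asarray(drift_per_frame, dtype=float))
    return GroundTruthScene(cells=cells, field_shape=field_shape, frame_rate=frame_rate,
                            n_frames=n_frames, corner_mask=corner, drift_path=drift,
                            rng_seed=seed)


def render_movie(scene: GroundTruthScene,
                 noise: NoiseModel | None = NoiseModel(),
                 cleaved_ratio: float = 0.25) -> TwoChannelMovie:
    """Render the scene to a two-channel movie.

    Per frame, each soma contributes an isotropic Gaussian intensity profile
    (sigma = radius/2.5, truncated at the footprint radius) whose total
    brightness splits between YFP and CFP so that YFP/CFP equals the cell's
    Hill-mapped (or cleavage-collapsed) ratio. Scene content translates
    along ``drift_path``; the corner aperture stays fixed and carries only
    background. ``noise=None`` renders the noiseless expectation.
    """
    h, w = scene.field_shape
    t_all = scene.n_frames
    rng = np.random.default_rng(scene.rng_seed + 1)

    ratios = [c.ratio_trajectory(scene.hill, cleaved_ratio) for c in scene.cells]
    sigmas = [c.radius / 2.5 for c in scene.cells]

    yfp = np.full((t_all, h, w), scene.background, dtype=float)
    cfp = np.full((t_all, h, w), scene.background, dtype=float)

    for t in range(t_all):
        dy, dx = scene.drift_path[t]
        for c, r_traj, sig in zip(scene.cells, ratios, sigmas):
            cy, cx = c.centroid[0] + dy, c.centroid[1] + dx
            rad = c.radius
            if cy - rad < 0 or cy + rad > h - 1 or cx - rad < 0 or cx + rad > w - 1:
                raise ValueError(f"cell {c.cell_id} footprint leaves the field at frame {t}")
            y0, y1 = int(np.floor(cy - rad)), int(np.ceil(cy + rad)) + 1
            x0, x1 = int(np.floor(cx - rad)), int(np.ceil(cx + rad)) + 1
            yy, xx = np.mgrid[y0:y1, x0:x1]
            d2 = (yy - cy) ** 2 + (xx - cx) ** 2
            prof = c.brightness * np.exp(-d2 / (2 * sig ** 2))
            prof[d2 > rad ** 2] = 0.0
            r = r_traj[t]
            f_yfp = r / (1.0 + r)
            yfp[t, y0:y1, x0:x1] += prof * f_yfp
            cfp[t, y0:y1, x0:x1] += prof * (1.0 - f_yfp)
        # clipped corners never see fluorescence, only background
        yfp[t][scene.corner_mask] = scene.background
        cfp[t][scene.corner_mask] = scene.background

    if noise is not None:
        yfp = noise.sample(yfp, rng)
        cfp = noise.sample(cfp, rng)
    return TwoChannelMovie(yfp=yfp, cfp=cfp, frame_rate=scene.frame_rate,
                           origin_tag=f"synthetic-seed{scene.rng_seed}")


def repeat_scene(scene: GroundTruthScene, stability: float = 0.75,
                 setpoint_sd_mm: float = DEFAULT_SETPOINT_SD_MM,
                 seed: int | None = None) -> GroundTruthScene:
    """The same field imaged again days later: identical cells and
    positions, set-points redrawn with correlation ``stability`` to the
    first session (per-cell ATP differences persist across a week but are
    not frozen). ``stability`` is the day-to-day set-point correlation."""
    if not (0.0 <= stability <= 1.0):
        raise ValueError("stability must lie in [0, 1]")
    rng = np.random.default_rng(scene.rng_seed + 101 if seed is None else seed)
    new_cells = []
    for c in scene.cells:
        a0 = float(c.atp_trajectory.mean())
        mu = DEFAULT_SETPOINTS_MM.get(c.cell_type, 2.6)
        a1 = mu + stability * (a0 - mu) + np.sqrt(1 - stability ** 2) * \
            rng.normal(0.0, setpoint_sd_mm)
        a1 = float(np.clip(a1, 0.2, 9.8))
        nc = replace(c, atp_trajectory=np.full(scene.n_frames, a1))
        nc.overlapping = c.overlapping
        new_cells.append(nc)
    return GroundTruthScene(cells=new_cells, field_shape=scene.field_shape,
                            frame_rate=scene.frame_rate, n_frames=scene.n_frames,
                            corner_mask=scene.corner_mask.copy(),
                            drift_path=scene.drift_path.copy(),
                            rng_seed=int(rng.integers(2 ** 31)), hill=scene.hill,
                            background=scene.background)


# ---------------------------------------------------------------------------
# pharmacological perturbations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DrugKinetics:
    """Piecewise-exponential ATP response of one cell type to one drug.

    From onset, ATP declines by ``amplitude_mm * (1 - exp(-(t-onset)/tau))``
    (negative amplitude = elevation). If ``recovery_start_s`` is set, the
    accumulated deflection relaxes back exponentially with
    ``tau_recovery_s`` from that time.
    """

    amplitude_mm: float
    onset_s: float = 60.0
    tau_s: float = 120.0
    recovery_start_s: float | None = None
    tau_recovery_s: float = 240.0

    def deflection(self, t_s: np.ndarray) -> np.ndarray:
        t = np.asarray(t_s, dtype=float)
        d = np.where(t >= self.onset_s,
                     self.amplitude_mm * -np.expm1(-(t - self.onset_s) / self.tau_s), 0.0)
        if self.recovery_start_s is not None:
            t0 = self.recovery_start_s
            d0 = self.amplitude_mm * -np.expm1(-max(t0 - self.onset_s, 0.0) / self.tau_s)
            d = np.where(t >= t0, d0 * np.exp(-(t - t0) / self.tau_recovery_s), d)
        return d


def _uniform(amp, **kw):
    return {t: DrugKinetics(amp, **kw) for t in CELL_TYPES}


# Phenomenology: complex I-III inhibitors hit alpha-type cells hardest;
# complex IV inhibition depletes the whole population; circuit disinhibition
# (Str/Bic) gives a uniform dip with recovery toward baseline by ~15 min;
# glutamatergic blockade (NBQX/AP5) a slight delayed elevation.
DRUG_KINETICS: dict[str, dict[str, DrugKinetics]] = {
    "ROT": {**_uniform(0.4, onset_s=60, tau_s=120),
            "alpha": DrugKinetics(1.6, 60, 120), "alpha_on_s": DrugKinetics(1.8, 60, 120)},
    "TTFA": {**_uniform(0.3, onset_s=90, tau_s=240),
             "alpha": DrugKinetics(1.3, 90, 240), "alpha_on_s": DrugKinetics(1.5, 90, 240)},
    "AA": {**_uniform(0.4, onset_s=45, tau_s=80),
           "alpha": DrugKinetics(1.5, 45, 80), "alpha_on_s": DrugKinetics(1.7, 45, 80)},
    "KCN": _uniform(1.5, onset_s=45, tau_s=100),
    "StrBic": _uniform(1.0, onset_s=30, tau_s=60, recovery_start_s=300, tau_recovery_s=240),
    "NBQXAP5": _uniform(-0.3, onset_s=120, tau_s=180),
}


def apply_perturbation(scene: GroundTruthScene, drug: str,
                       kinetics: dict[str, DrugKinetics] | None = None) -> GroundTruthScene:
    """Return a copy of the scene with drug-response kinetics applied to
    every cell's ATP trajectory (clipped to the sensor's [0, 10] mM range)."""
    if kinetics is None:
        if drug not in DRUG_KINETICS:
            raise ValueError(f"unknown drug {drug!r}; known: {sorted(DRUG_KINETICS)}")
        kinetics = DRUG_KINETICS[drug]
    t_s = np.arange(scene.n_frames) / scene.frame_rate
    new_cells = []
    for c in scene.cells:
        kin = kinetics[c.cell_type]
        traj = np.clip(c.atp_trajectory - kin.deflection(t_s), 0.0, 10.0)
        nc = replace(c, atp_trajectory=traj)
        nc.overlapping = c.overlapping
        new_cells.append(nc)
    return GroundTruthScene(cells=new_cells, field_shape=scene.field_shape,
                            frame_rate=scene.frame_rate, n_frames=scene.n_frames,
                            corner_mask=scene.corner_mask.copy(),
                            drift_path=scene.drift_path.copy(),
                            rng_seed=scene.rng_seed, hill=scene.hill,
                            background=scene.background)


# ---------------------------------------------------------------------------
# post hoc immunostain volumes
# ---------------------------------------------------------------------------

# Which immunostain markers each type expresses (Alpha -> SPP1, intrinsically
# photosensitive -> TBR2, ON-OFF direction-selective -> CART; the
# alpha-ON-sustained subtype expresses both SPP1 and TBR2).
MARKER_RULES: dict[str, tuple[str, ...]] = {
    "alpha": ("spp1",), "alpha_on_s": ("spp1", "tbr2"), "ip": ("tbr2",),
    "oods": ("cart",), "other": (),
}


class SmoothWarp:
    """Invertible smooth 2D deformation: affine part plus a low-frequency
    sinusoidal displacement field. Maps in vivo (y, x) -> confocal (y, x)."""

    def __init__(self, dy: float = 0.0, dx: float = 0.0, amp: float = 0.0,
                 period: float = 200.0, phase: float = 0.0):
        self.dy, self.dx, self.amp, self.period, self.phase = dy, dx, amp, period, phase

    @classmethod
    def identity(cls) -> "SmoothWarp":
        return cls()

    def __call__(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        k = 2 * np.pi / self.period
        out = pts.copy()
        out[:, 0] += self.dy + self.amp * np.sin(k * pts[:, 1] + self.phase)
        out[:, 1] += self.dx + self.amp * np.cos(k * pts[:, 0] + self.phase)
        return out


def render_immunostain(scene: GroundTruthScene,
                       deformation=None,
                       marker_rules: dict[str, tuple[str, ...]] | None = None,
                       n_landmarks: int = 8,
                       n_z: int = 12,
                       marker_high: float = 200.0,
                       marker_low: float = 5.0,
                       mito_means: dict[str, float] | None = None,
                       mito_sd: float = 10.0,
                       noise_sd: float = 2.0,
                       seed: int | None = None):
    """Emit a confocal-like multichannel z-stack of the scene plus a landmark
    correspondence table.

    Channels: ``reference`` (fixed sensor YFP), one per marker (spp1, tbr2,
    cart) expressed according to each cell's true type, and ``mito`` with
    per-type mean intensity (for mitochondrial-protein quantification
    tests). Cell positions are mapped through ``deformation`` (in vivo ->
    confocal). Returns ``(channels, labels3d, landmarks, confocal_truth)``
    where ``channels`` maps name -> (Z, H, W) array, ``labels3d`` is the
    ground-truth 3D soma mask, and ``landmarks`` is a DataFrame of >= 4
    matched point pairs.
    """
    if n_landmarks < 4:
        raise ValueError("need at least 4 landmarks (warp under-determined below that)")
    deformation = deformation or SmoothWarp.identity()
    rules = MARKER_RULES if marker_rules is None else marker_rules
    mito_means = mito_means or {t: 100.0 for t in CELL_TYPES}
    rng = np.random.default_rng(scene.rng_seed + 7 if seed is None else seed)

    h, w = scene.field_shape
    names = ["reference", "spp1", "tbr2", "cart", "mito"]
    channels = {n: np.full((n_z, h, w), marker_low, dtype=float) for n in names}
    labels = np.zeros((n_z, h, w), dtype=np.int32)

    conf_centroids = deformation(np.array([c.centroid for c in scene.cells]))
    truth_rows = []
    zz = np.arange(n_z)
    for c, (cy, cx) in zip(scene.cells, conf_centroids):
        if not (0 <= cy < h and 0 <= cx < w):
            continue
        cz = rng.uniform(n_z * 0.3, n_z * 0.7)
        sig_xy, sig_z = c.radius / 2.5, max(c.radius / 3.0, 1.0)
        y0, y1 = max(int(cy - c.radius), 0), min(int(cy + c.radius) + 2, h)
        x0, x1 = max(int(cx - c.radius), 0), min(int(cx + c.radius) + 2, w)
        yy, xx = np.mgrid[y0:y1, x0:x1]
        d2 = (yy - cy) ** 2 + (xx - cx) ** 2
        disc = d2 <= c.radius ** 2
        zprof = np.exp(-(zz - cz) ** 2 / (2 * sig_z ** 2))
        zmask = np.abs(zz - cz) <= 2.0 * sig_z
        prof = np.exp(-d2 / (2 * sig_xy ** 2)) * disc
        markers = rules.get(c.cell_type, ())
        mito_amp = max(rng.normal(mito_means[c.cell_type], mito_sd), 0.0)
        for iz in np.nonzero(zmask)[0]:
            channels["reference"][iz, y0:y1, x0:x1] += marker_high * zprof[iz] * prof
            for m in markers:
                channels[m][iz, y0:y1, x0:x1] += marker_high * zprof[iz] * prof
            channels["mito"][iz, y0:y1, x0:x1] += mito_amp * zprof[iz] * prof
            sl = labels[iz, y0:y1, x0:x1]
            sl[disc & (sl == 0)] = c.cell_id
        truth_rows.append({"cell_id": c.cell_id, "cell_type": c.cell_type,
                           "confocal_y": cy, "confocal_x": cx,
                           "true_mito": mito_amp})

    if noise_sd > 0:
        for n in names:
            channels[n] = np.clip(channels[n] + rng.normal(0, noise_sd, channels[n].shape),
                                  0, None)

    # landmark pairs: well-spread in vivo points and their warped positions
    gy = np.linspace(h * 0.15, h * 0.85, int(np.ceil(np.sqrt(n_landmarks))))
    gx = np.linspace(w * 0.15, w * 0.85, int(np.ceil(np.sqrt(n_landmarks))))
    pts = np.array([(y, x) for y in gy for x in gx])[:n_landmarks]
    warped = deformation(pts)
    landmarks = pd.DataFrame({
        "invivo_y": pts[:, 0], "invivo_x": pts[:, 1],
        "confocal_y": warped[:, 0], "confocal_x": warped[:, 1],
    })
    return channels, labels, landmarks, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# longitudinal (injury) cohorts at trace level
# ---------------------------------------------------------------------------

def simulate_longitudinal_cohort(n_cells: int = 500,
                                 days: tuple[int, ...] = (0, 2, 4, 6, 8, 10, 12, 14),
                                 frames_per_day: int = 60,
                                 frame_rate: float = DEFAULT_FRAME_RATE,
                                 survival_frac: float = 0.5,
                                 survivor_baseline_shift_sd: float = -0.5,
                                 day_course_peak_day: int = 4,
                                 day_course_amp_sd: float = 0.5,
                                 ratio_noise_cv: float = 0.01,
                                 hill: HillParams = DEFAULT_HILL,
                                 cleaved_ratio: float = 0.25,
                                 seed: int = 0):
    """Trace-level post-injury cohort: per-day measured YFP/CFP ratio traces
    for each tracked cell plus hidden fates.

    Day 0 is the uninjured baseline. Survivors' baseline set-points are
    shifted by ``survivor_baseline_shift_sd`` population SDs. After injury
    all living cells share a transient ATP elevation peaking at
    ``day_course_peak_day``; dying cells undergo sensor cleavage on a random
    day >= 4, collapsing their ratio. Returns ``(tables, truth)`` where
    ``tables`` maps day -> long DataFrame (cell_id, frame, ratio, ...)
    shaped for the quantification stage, and ``truth`` is a per-cell
    DataFrame with fate, death day, and true baseline values.
    """
    rng = np.random.default_rng(seed)
    mu, sd = 2.6, DEFAULT_SETPOINT_SD_MM
    survive = rng.random(n_cells) < survival_frac
    # truncated normal baselines (see make_scene) plus the survivor shift
    base = np.clip(rng.normal(mu, sd, n_cells), mu - 2.5 * sd, mu + 2.5 * sd)
    base[survive] += survivor_baseline_shift_sd * sd
    base = np.clip(base, 0.3, 9.5)
    death_days = np.full(n_cells, -1)
    dying = np.nonzero(~survive)[0]
    candidates = [d for d in days if d >= 4]
    death_days[dying] = rng.choice(candidates, size=dying.size)

    tables: dict[int, pd.DataFrame] = {}
    for day in days:
        bump_sd = day_course_amp_sd * np.exp(-0.5 * ((day - day_course_peak_day) / 1.8) ** 2) \
            if day > 0 else 0.0
        rows = []
        for i in range(n_cells):
            if death_days[i] >= 0 and day > death_days[i]:
                continue  # untrackable after cleavage
            atp = np.clip(base[i] + bump_sd * sd, 0.0, 10.0)
            r = hill_ratio(atp, hill)
            if death_days[i] == day:
                r = cleaved_ratio
            trace = r * (1.0 + rng.normal(0.0, ratio_noise_cv, frames_per_day))
            rows.append(pd.DataFrame({
                "cell_id": i + 1, "acquisition_id": f"day{day:02d}",
                "frame": np.arange(frames_per_day),
                "t_s": np.arange(frames_per_day) / frame_rate,
                "ratio": np.clip(trace, 1e-6, None),
                "pixel_count": 150, "yfp_mean": 100.0, "cfp_mean": 100.0,
            }))
        tables[day] = pd.concat(rows, ignore_index=True)

    truth = pd.DataFrame({
        "cell_id": np.arange(1, n_cells + 1),
        "fate": np.where(survive, "survived", "died"),
        "death_day": np.where(death_days >= 0, death_days, np.nan),
        "true_baseline_mm": base,
        "true_baseline_ratio": hill_ratio(base, hill),
    })
    truth["true_baseline_z"] = ((truth["true_baseline_ratio"]
                                 - truth["true_baseline_ratio"].mean())
                                / truth["true_baseline_ratio"].std(ddof=0))
    return tables, truth
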
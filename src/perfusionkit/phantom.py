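"""Synthetic first-pass perfusion phantom with analytic ground truth.

The phantom emulates a short-axis cardiac perfusion acquisition: three slice
levels (basal, mid-cavity, apical) under rest and stress.  Anatomy is an LV
blood-pool disk, an annular myocardium around it, and a crescent-shaped RV
pool abutting the epicardium between the two RV insertion points, all inside
an elliptical body.  Dynamics follow the first-pass ordering: the RV pool
enhances first (early bolus), the LV pool follows a gamma-variate arterial
input a few frames later, and myocardial voxels follow the two-compartment
exchange model driven by the LV input with per-voxel parameters drawn from
condition-specific ranges.

The signal model is linear in concentration, ``S(t) = S0 (1 + gamma C(t))``
plus optional noise, which makes quantification exactly invertible for
testing.  Every series comes with full ground truth: peak frame, bounding
box, masks, insertion points, per-voxel kinetic parameter maps, and the
generating arterial input function.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import ConcentrationCurve, GroundTruth, KineticParams, PerfusionSeries
from .kinetics import solve_2cxm
from .roi_detect import label_bbox_from_mask

__all__ = [
    "AifParams",
    "PhantomConfig",
    "gamma_variate_aif",
    "render_geometry",
    "generate_series",
    "generate_cohort",
    "desk_phantom_config",
]

SLICE_LEVELS = ("basal", "mid", "apical")
#: in-plane size scaling of the LV cross-section by slice level
SLICE_SCALES = {"basal": 1.0, "mid": 0.85, "apical": 0.7}


@dataclass(frozen=True)
class AifParams:
    """Gamma-variate bolus parameters: arrival ``t0`` (s), shape ``alpha``,
    timescale ``beta`` (s), and peak concentration ``scale``."""

    t0: float
    alpha: float
    beta: float
    scale: float


def _default_aif_params() -> dict[str, AifParams]:
    return {
        "rest": AifParams(t0=12.0, alpha=3.0, beta=3.5, scale=5.0),
        "stress": AifParams(t0=10.0, alpha=3.0, beta=2.5, scale=6.0),
    }


def _default_kinetic_ranges() -> dict[str, dict[str, tuple[float, float]]]:
    # Fp in mL/min/mL; rest/stress ranges bracket clinically typical MBF
    return {
        "rest": {"Fp": (0.5, 1.5), "vp": (0.03, 0.10), "PS": (0.4, 1.2), "ve": (0.15, 0.35)},
        "stress": {"Fp": (1.5, 3.5), "vp": (0.03, 0.10), "PS": (0.8, 2.0), "ve": (0.15, 0.35)},
    }


@dataclass
class PhantomConfig:
    image_size: int = 256
    n_frames: int = 50
    frame_interval: float = 1.0  # seconds
    pixel_spacing: float = 1.2  # mm, isotropic in-plane
    n_slices: int = 3
    conditions: tuple[str, ...] = ("rest", "stress")
    lv_center_range: tuple[float, float] = (-8.0, 8.0)  # offset from image center, px
    lv_pool_radius_range: tuple[float, float] = (18.0, 24.0)  # basal, px
    myo_thickness_range: tuple[float, float] = (9.0, 13.0)  # basal, px
    insertion_angle_anterior: float = 240.0  # degrees, see _angle_point
    insertion_angle_inferior: float = 120.0
    insertion_angle_jitter: float = 8.0  # degrees, per subject
    aif_params: dict = field(default_factory=_default_aif_params)
    kinetic_param_ranges: dict = field(default_factory=_default_kinetic_ranges)
    noise_sd: float = 0.02  # fraction of baseline signal
    noise_model: str = "gaussian"  # or "rician"
    motion_amplitude: float = 0.0  # px, per-frame random translation
    rv_delay_frames: int = 3  # LV bolus arrives this many frames after RV
    signal_gamma: float = 1.0  # signal units per concentration unit
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 5:
            raise ValueError("n_frames must be >= 5 (5-frame windows are built downstream)")
        for name in ("lv_center_range", "lv_pool_radius_range", "myo_thickness_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} must have low <= high")
        r_outer = self.lv_pool_radius_range[1] + self.myo_thickness_range[1]
        margin = max(abs(self.lv_center_range[0]), abs(self.lv_center_range[1])) + 4
        if r_outer + margin >= self.image_size / 2:
            raise ValueError("myocardium outer radius plus margin must fit inside the image")
        unknown = set(self.conditions) - {"rest", "stress"}
        if unknown:
            raise ValueError(f"unknown conditions: {sorted(unknown)}")


def desk_phantom_config(**overrides) -> PhantomConfig:
    """Desk-scale phantom: 128 px frames, 40 timeframes (enough to cover
    the myocardial washout at rest, which kinetic fitting needs), geometry
    scaled so anatomy occupies the same fraction of the field of view as
    the default 256 px configuration."""
    cfg = dict(
        image_size=128,
        n_frames=40,
        frame_interval=1.0,
        lv_center_range=(-5.0, 5.0),
        lv_pool_radius_range=(10.0, 13.0),
        myo_thickness_range=(5.0, 7.0),
    )
    cfg.update(overrides)
    return PhantomConfig(**cfg)


def gamma_variate_aif(
    t0: float, alpha: float, beta: float, scale: float, times: np.ndarray
) -> np.ndarray:
    """Gamma-variate bolus curve, zero before arrival.

    ``C(t) = scale ((t-t0)/(alpha beta))^alpha exp(alpha - (t-t0)/beta)`` for
    ``t > t0``; the maximum (value ``scale``) occurs at ``t0 + alpha*beta``.
    """
    if alpha <= 0 or beta <= 0 or scale <= 0:
        raise ValueError("alpha, beta and scale must be positive")
    times = np.asarray(times, dtype=np.float64)
    if not np.all(np.isfinite(times)):
        raise ValueError("times must be finite")
    dt = times - t0
    with np.errstate(invalid="ignore"):
        c = np.where(
            dt > 0,
            scale * (np.maximum(dt, 0.0) / (alpha * beta)) ** alpha * np.exp(alpha - dt / beta),
            0.0,
        )
    return c


def _angle_point(center: tuple[float, float], radius: float, angle_deg: float) -> np.ndarray:
    """Point on the circle: row = cr + R sin(theta), col = cc + R cos(theta).

    With row increasing downward this traverses the circle clockwise on
    screen as ``theta`` increases; theta=0 points toward +col (image right).
    """
    th = np.radians(angle_deg)
    return np.array([center[0] + radius * np.sin(th), center[1] + radius * np.cos(th)])


def render_geometry(
    config: PhantomConfig, rng: np.random.Generator, slice_level: str = "mid"
) -> dict:
    """Sample and rasterize one slice's anatomy.

    Returns a dict with boolean masks (``lv_pool``, ``myo``, ``rv``,
    ``body``), ``insertion_points`` (2x2 array, anterior then inferior, on
    the epicardial boundary), and the sampled center/radii.
    """
    n = config.image_size
    scale = SLICE_SCALES[slice_level]
    lo, hi = config.lv_center_range
    center = (n / 2.0 + rng.uniform(lo, hi), n / 2.0 + rng.uniform(lo, hi))
    r_pool = rng.uniform(*config.lv_pool_radius_range) * scale
    thickness = rng.uniform(*config.myo_thickness_range) * scale
    r_epi = r_pool + thickness
    if r_epi + 4 >= n / 2.0:
        raise ValueError("sampled geometry would leave the image bounds")

    ang_a = config.insertion_angle_anterior + rng.uniform(
        -config.insertion_angle_jitter, config.insertion_angle_jitter
    )
    ang_i = config.insertion_angle_inferior + rng.uniform(
        -config.insertion_angle_jitter, config.insertion_angle_jitter
    )

    rr, cc = np.mgrid[0:n, 0:n].astype(np.float64)
    d_lv = np.hypot(rr - center[0], cc - center[1])
    lv_pool = d_lv < r_pool
    myo = (d_lv >= r_pool) & (d_lv < r_epi)

    # RV crescent: a disk offset toward the septum, clipped away from the LV
    septum_mid = (ang_a + ((ang_i - ang_a) % 360.0) / 2.0) % 360.0
    if ((ang_i - ang_a) % 360.0) > 180.0:
        septum_mid = (ang_a - (360.0 - (ang_i - ang_a) % 360.0) / 2.0) % 360.0
    rv_center = _angle_point(center, r_epi * 1.35, septum_mid)
    rv_radius = r_epi * 0.95
    d_rv = np.hypot(rr - rv_center[0], cc - rv_center[1])
    rv = (d_rv < rv_radius) & (d_lv > r_epi + 1.5)

    body = (
        ((rr - n / 2.0) / (0.44 * n)) ** 2 + ((cc - n / 2.0) / (0.38 * n)) ** 2
    ) < 1.0
    rv &= body

    insertion_points = np.stack(
        [
            _angle_point(center, r_epi - 0.5, ang_a),
            _angle_point(center, r_epi - 0.5, ang_i),
        ]
    )
    return {
        "lv_pool": lv_pool,
        "myo": myo,
        "rv": rv,
        "body": body,
        "insertion_points": insertion_points,
        "center": center,
        "r_pool": r_pool,
        "r_epi": r_epi,
        "angles": (ang_a, ang_i),
    }


def _draw_params(
    ranges: dict[str, tuple[float, float]], n_vox: int, rng: np.random.Generator
) -> KineticParams:
    vals = {k: rng.uniform(lo, hi, size=n_vox) for k, (lo, hi) in ranges.items()}
    return KineticParams(**vals)


def generate_series(
    config: PhantomConfig, seed: int | None = None, subject_id: str = "phantom"
) -> list[tuple[PerfusionSeries, GroundTruth]]:
    """Generate one subject: ``n_slices`` slice levels under each condition.

    Geometry is shared across conditions (same anatomy at rest and stress);
    bolus parameters and per-voxel kinetics are condition-specific.  Fully
    reproducible for a fixed seed.  Output order is
    ``[(slice, condition) for slice in levels for condition in conditions]``.
    """
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    n = config.image_size
    times = np.arange(config.n_frames, dtype=np.float64) * config.frame_interval
    levels = SLICE_LEVELS[: config.n_slices]

    geoms = {level: render_geometry(config, rng, level) for level in levels}
    out: list[tuple[PerfusionSeries, GroundTruth]] = []
    for level in levels:
        geom = geoms[level]
        for condition in config.conditions:
            ap = config.aif_params[condition]
            if not isinstance(ap, AifParams):
                ap = AifParams(**ap)
            aif_vals = gamma_variate_aif(ap.t0, ap.alpha, ap.beta, ap.scale, times)
            rv_t0 = ap.t0 - config.rv_delay_frames * config.frame_interval
            rv_vals = gamma_variate_aif(rv_t0, ap.alpha, ap.beta * 0.8, ap.scale * 1.1, times)
            aif = ConcentrationCurve(times, aif_vals)

            myo_idx = np.nonzero(geom["myo"])
            n_vox = len(myo_idx[0])
            params = _draw_params(config.kinetic_param_ranges[condition], n_vox, rng)
            ct = solve_2cxm(params, aif).values  # (n_vox, T)

            s0 = np.full((n, n), 0.05)
            s0[geom["body"]] = 0.8
            for m in ("lv_pool", "myo", "rv"):
                s0[geom[m]] = 1.0
            g = config.signal_gamma
            frames = np.broadcast_to(s0, (config.n_frames, n, n)).copy()
            frames[:, geom["lv_pool"]] = (1.0 + g * aif_vals)[:, None]
            frames[:, geom["rv"]] = (1.0 + g * rv_vals)[:, None]
            frames[:, myo_idx[0], myo_idx[1]] = 1.0 + g * ct.T

            peak_frame = int(np.argmax(frames[:, geom["lv_pool"]].mean(axis=1)))

            translations = None
            if config.motion_amplitude > 0:
                translations = rng.uniform(
                    -config.motion_amplitude, config.motion_amplitude, size=(config.n_frames, 2)
                )
                shifted = np.empty_like(frames)
                for t in range(config.n_frames):
                    shifted[t] = ndimage.shift(
                        frames[t], translations[t], order=1, mode="nearest"
                    )
                frames = shifted
            if config.noise_sd > 0:
                sd = config.noise_sd * 1.0  # fraction of the unit baseline signal
                if config.noise_model == "rician":
                    n1 = rng.normal(0.0, sd, frames.shape)
                    n2 = rng.normal(0.0, sd, frames.shape)
                    frames = np.hypot(frames + n1, n2)
                else:
                    frames = frames + rng.normal(0.0, sd, frames.shape)
            frames = np.maximum(frames, 0.0)

            pm = KineticParams(
                Fp=_scatter(geom["myo"], params.Fp),
                vp=_scatter(geom["myo"], params.vp),
                PS=_scatter(geom["myo"], params.PS),
                ve=_scatter(geom["myo"], params.ve),
            )
            series = PerfusionSeries(
                frames=frames,
                pixel_spacing=(config.pixel_spacing, config.pixel_spacing),
                frame_times=times.copy(),
                slice_level=level,
                condition=condition,
                subject_id=subject_id,
            )
            truth = GroundTruth(
                peak_frame=peak_frame,
                bbox=label_bbox_from_mask(geom["myo"], margin=20, shape=(n, n)),
                myo_mask=geom["myo"],
                lv_pool_mask=geom["lv_pool"],
                rv_mask=geom["rv"],
                insertion_points=geom["insertion_points"].copy(),
                param_maps=pm,
                aif_true=ConcentrationCurve(times, aif_vals.copy()),
                translations=translations,
            )
            out.append((series, truth))
    return out


def _scatter(mask: np.ndarray, values: np.ndarray) -> np.ndarray:
    img = np.zeros(mask.shape, dtype=np.float64)
    img[mask] = values
    return img


def generate_cohort(
    config: PhantomConfig, n_subjects: int, seed: int = 0
) -> list[dict[tuple[str, str], tuple[PerfusionSeries, GroundTruth]]]:
    """Generate ``n_subjects`` phantoms keyed by ``(slice_level, condition)``.

    Subject seeds are derived deterministically from ``seed``.
    """
    root = np.random.default_rng(seed)
    subject_seeds = root.integers(0, 2**31 - 1, size=n_subjects)
    cohort = []
    for i, s in enumerate(subject_seeds):
        pairs = generate_series(config, seed=int(s), subject_id=f"subj{i:03d}")
        cohort.append({(ser.slice_level, ser.condition): (ser, tr) for ser, tr in pairs})
    return cohort
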
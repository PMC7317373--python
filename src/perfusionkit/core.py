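"""Core domain containers shared by every pipeline stage.

Coordinate convention (used package-wide): 0-based ``(row, col)`` indices,
row increasing downward.  Boxes are half-open integer ranges
``[row_min, row_max) x [col_min, col_max)`` once rasterized; box centers are
continuous (sub-pixel) and only rounded at crop time.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

SliceLevel = Literal["basal", "mid", "apical"]
Condition = Literal["rest", "stress"]

__all__ = [
    "PerfusionSeries",
    "GroundTruth",
    "BoundingBox",
    "BoxDelta",
    "KineticParams",
    "ConcentrationCurve",
]


@dataclass
class PerfusionSeries:
    """One short-axis slice's 2D+time image stack.

    ``frames`` has shape ``(n_frames, H, W)`` with arbitrary non-negative
    intensity units; ``pixel_spacing`` is (row, col) mm/pixel;
    ``frame_times`` is in seconds and strictly increasing.
    """

    frames: np.ndarray
    pixel_spacing: tuple[float, float] = (1.2, 1.2)
    frame_times: np.ndarray | None = None
    slice_level: SliceLevel = "mid"
    condition: Condition = "rest"
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 3:
            raise ValueError(
                f"frames must be (n_frames, H, W); got shape {self.frames.shape}"
            )
        if np.any(self.frames < 0):
            raise ValueError("negative intensities are not allowed")
        if self.frame_times is None:
            self.frame_times = np.arange(self.frames.shape[0], dtype=np.float64)
        self.frame_times = np.asarray(self.frame_times, dtype=np.float64)
        if self.frame_times.shape != (self.frames.shape[0],):
            raise ValueError("frame_times length must match n_frames")
        if np.any(np.diff(self.frame_times) <= 0):
            raise ValueError("frame_times must be strictly increasing")
        self.pixel_spacing = (float(self.pixel_spacing[0]), float(self.pixel_spacing[1]))

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    def with_frames(self, frames: np.ndarray, **updates) -> "PerfusionSeries":
        return replace(self, frames=frames, **updates)


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box with a continuous center and size in pixels."""

    center: tuple[float, float]  # (row, col)
    height: float
    width: float

    def __post_init__(self) -> None:
        if self.height <= 0 or self.width <= 0:
            raise ValueError("box height and width must be positive")

    @classmethod
    def from_bounds(cls, row_min: int, row_max: int, col_min: int, col_max: int) -> "BoundingBox":
        """Box covering the half-open pixel range [row_min,row_max) x [col_min,col_max)."""
        if row_max <= row_min or col_max <= col_min:
            raise ValueError("empty bounds")
        h = row_max - row_min
        w = col_max - col_min
        return cls(((row_min + row_max - 1) / 2.0, (col_min + col_max - 1) / 2.0), h, w)

    def bounds(self, shape: tuple[int, int] | None = None) -> tuple[int, int, int, int]:
        """Rasterize to integer half-open bounds, optionally clipped to ``shape``."""
        h = int(round(self.height))
        w = int(round(self.width))
        r0 = int(np.floor(self.center[0] - (h - 1) / 2.0 + 0.5))
        c0 = int(np.floor(self.center[1] - (w - 1) / 2.0 + 0.5))
        r1, c1 = r0 + h, c0 + w
        if shape is not None:
            r0, r1 = max(r0, 0), min(r1, shape[0])
            c0, c1 = max(c0, 0), min(c1, shape[1])
            if r1 <= r0 or c1 <= c0:
                raise ValueError("box does not overlap the image")
        return r0, r1, c0, c1

    def rasterize(self, shape: tuple[int, int]) -> np.ndarray:
        """Filled binary mask of the box clipped to an image of ``shape``."""
        mask = np.zeros(shape, dtype=bool)
        r0, r1, c0, c1 = self.bounds(shape)
        mask[r0:r1, c0:c1] = True
        return mask


@dataclass(frozen=True)
class BoxDelta:
    """Adjustment of a proposed ROI: center displacement plus size scaling.

    ``dx`` displaces the center along columns, ``dy`` along rows;
    ``sw``/``sh`` multiply width/height.
    """

    dx: float
    dy: float
    sw: float
    sh: float

    def __post_init__(self) -> None:
        if self.sw <= 0 or self.sh <= 0:
            raise ValueError("scale factors must be positive")

    def as_array(self) -> np.ndarray:
        return np.array([self.dx, self.dy, self.sw, self.sh], dtype=np.float64)


@dataclass
class KineticParams:
    """Two-compartment exchange model parameters.

    Fp (plasma flow, mL/min/mL — identical to MBF), vp (plasma volume
    fraction), PS (permeability-surface-area product, mL/min/mL), ve
    (interstitial volume fraction).  Fields may be scalars or equally
    shaped arrays (per-voxel maps).
    """

    Fp: np.ndarray | float
    vp: np.ndarray | float
    PS: np.ndarray | float
    ve: np.ndarray | float

    def __post_init__(self) -> None:
        for name in ("Fp", "vp", "PS", "ve"):
            v = np.asarray(getattr(self, name), dtype=np.float64)
            if np.any(v < 0):
                raise ValueError(f"{name} must be non-negative")
            setattr(self, name, v if v.ndim else float(v))
        vp = np.asarray(self.vp)
        ve = np.asarray(self.ve)
        if np.any(vp + ve > 1.0 + 1e-9):
            raise ValueError("vp + ve must not exceed 1")

    def as_array(self) -> np.ndarray:
        return np.stack(
            [np.asarray(self.Fp), np.asarray(self.vp), np.asarray(self.PS), np.asarray(self.ve)]
        )


@dataclass
class ConcentrationCurve:
    """Sampled contrast-agent concentration over time (arbitrary linear units)."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.float64)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.times.ndim != 1 or self.values.shape[-1] != self.times.shape[0]:
            raise ValueError("values must be sampled on times (last axis)")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("concentration values must be finite")


@dataclass
class GroundTruth:
    """Per-series labels; analytic truth for phantom data.

    ``insertion_points`` is a (2, 2) array of (row, col) coordinates ordered
    (anterior, inferior); ``param_maps`` holds per-voxel kinetic parameter
    images covering the myocardium (zero elsewhere).
    """

    peak_frame: int
    bbox: BoundingBox
    myo_mask: np.ndarray
    lv_pool_mask: np.ndarray
    rv_mask: np.ndarray
    insertion_points: np.ndarray
    param_maps: KineticParams | None = None
    aif_true: ConcentrationCurve | None = None
    translations: np.ndarray | None = field(default=None)  # (n_frames, 2) applied shifts

    def __post_init__(self) -> None:
        self.insertion_points = np.asarray(self.insertion_points, dtype=np.float64)
        if self.insertion_points.shape != (2, 2):
            raise ValueError("insertion_points must be a (2, 2) array")
        for name in ("myo_mask", "lv_pool_mask", "rv_mask"):
            setattr(self, name, np.asarray(getattr(self, name)).astype(bool))
        if (
            np.any(self.myo_mask & self.lv_pool_mask)
            or np.any(self.myo_mask & self.rv_mask)
            or np.any(self.lv_pool_mask & self.rv_mask)
        ):
            raise ValueError("masks must be pairwise disjoint")
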
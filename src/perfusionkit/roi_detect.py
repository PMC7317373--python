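"""LV bounding-box detection and cropping (pipeline stage 2).

The detector regresses an adjustment of a fixed 75x75 region proposal
centered on the image: a center displacement ``(dx, dy)`` plus width/height
scale factors ``(sw, sh)``.  The box found on the basal slice is reused for
the mid-ventricular and apical slices.  Cropped series are resampled to
96x96 with bicubic interpolation (nearest-neighbour for masks) and the
effective pixel spacing is rescaled accordingly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize

from .core import BoundingBox, BoxDelta, PerfusionSeries

PROPOSAL_SIZE = 75
CROP_SIZE = 96

__all__ = [
    "PROPOSAL_SIZE",
    "CROP_SIZE",
    "label_bbox_from_mask",
    "propose_roi",
    "apply_delta",
    "invert_delta",
    "delta_to_target",
    "target_to_delta",
    "detect_bbox",
    "crop_series",
    "crop_image",
    "crop_mask",
    "CropTransform",
    "box_dsc",
]


def label_bbox_from_mask(
    mask: np.ndarray, margin: int = 20, shape: tuple[int, int] | None = None
) -> BoundingBox:
    """Tightest box containing the mask, expanded by ``margin`` pixels on
    every side and clipped to the image bounds."""
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("empty mask has no bounding box")
    if shape is None:
        shape = mask.shape
    rows = np.nonzero(mask.any(axis=1))[0]
    cols = np.nonzero(mask.any(axis=0))[0]
    r0 = max(int(rows[0]) - margin, 0)
    r1 = min(int(rows[-1]) + 1 + margin, shape[0])
    c0 = max(int(cols[0]) - margin, 0)
    c1 = min(int(cols[-1]) + 1 + margin, shape[1])
    return BoundingBox.from_bounds(r0, r1, c0, c1)


def propose_roi(image_height: int, image_width: int) -> BoundingBox:
    """The fixed region proposal: a 75x75 box centered on the image."""
    if image_height < PROPOSAL_SIZE or image_width < PROPOSAL_SIZE:
        raise ValueError(f"image must be at least {PROPOSAL_SIZE}x{PROPOSAL_SIZE}")
    return BoundingBox(
        ((image_height - 1) / 2.0, (image_width - 1) / 2.0), PROPOSAL_SIZE, PROPOSAL_SIZE
    )


def apply_delta(proposal: BoundingBox, delta: BoxDelta) -> BoundingBox:
    return BoundingBox(
        (proposal.center[0] + delta.dy, proposal.center[1] + delta.dx),
        proposal.height * delta.sh,
        proposal.width * delta.sw,
    )


def invert_delta(proposal: BoundingBox, target: BoundingBox) -> BoxDelta:
    """The exact delta mapping ``proposal`` onto ``target`` under
    :func:`apply_delta` (round-trip identity)."""
    return BoxDelta(
        dx=target.center[1] - proposal.center[1],
        dy=target.center[0] - proposal.center[0],
        sw=target.width / proposal.width,
        sh=target.height / proposal.height,
    )


def delta_to_target(delta: BoxDelta) -> np.ndarray:
    """Normalized regression target: displacements divided by the proposal
    size for conditioning; scales as-is."""
    return np.array(
        [delta.dx / PROPOSAL_SIZE, delta.dy / PROPOSAL_SIZE, delta.sw, delta.sh],
        dtype=np.float64,
    )


def target_to_delta(target: np.ndarray) -> BoxDelta:
    return BoxDelta(
        dx=float(target[0]) * PROPOSAL_SIZE,
        dy=float(target[1]) * PROPOSAL_SIZE,
        sw=max(float(target[2]), 0.05),
        sh=max(float(target[3]), 0.05),
    )


def detect_bbox(basal_peak_frame: np.ndarray, model) -> BoundingBox:
    """Predict the LV bounding box from the normalized basal peak frame.

    The same box applies to the mid and apical slices.  The frame is
    resampled to the model's input size (bicubic) if necessary; the
    predicted displacements refer to original-frame pixels.
    """
    img = np.asarray(basal_peak_frame, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("expected a single 2D frame")
    h, w = img.shape
    size = getattr(model, "input_size", h)
    if (h, w) != (size, size):
        img = resize(img, (size, size), order=3, mode="edge", anti_aliasing=False, preserve_range=True)
    pred = np.asarray(model.predict(img[None, None].astype(np.float32)))[0]
    delta = target_to_delta(pred)
    return apply_delta(propose_roi(h, w), delta)


@dataclass(frozen=True)
class CropTransform:
    """Affine map between cropped-grid and original-grid pixel coordinates."""

    row_offset: float
    col_offset: float
    row_scale: float  # original px per cropped px
    col_scale: float
    bounds: tuple[int, int, int, int] | None = None  # (r0, r1, c0, c1) in the original grid

    def to_original(self, points: np.ndarray) -> np.ndarray:
        p = np.asarray(points, dtype=np.float64)
        out = np.empty_like(p)
        out[..., 0] = self.row_offset + (p[..., 0] + 0.5) * self.row_scale - 0.5
        out[..., 1] = self.col_offset + (p[..., 1] + 0.5) * self.col_scale - 0.5
        return out

    def to_cropped(self, points: np.ndarray) -> np.ndarray:
        p = np.asarray(points, dtype=np.float64)
        out = np.empty_like(p)
        out[..., 0] = (p[..., 0] - self.row_offset + 0.5) / self.row_scale - 0.5
        out[..., 1] = (p[..., 1] - self.col_offset + 0.5) / self.col_scale - 0.5
        return out

    def mask_to_original(self, mask: np.ndarray, original_shape: tuple[int, int]) -> np.ndarray:
        """Map a cropped-grid binary mask back onto the original grid
        (nearest-neighbour), zero outside the crop window."""
        if self.bounds is None:
            raise ValueError("transform does not carry crop bounds")
        r0, r1, c0, c1 = self.bounds
        sub = resize(
            np.asarray(mask).astype(np.float64),
            (r1 - r0, c1 - c0),
            order=0,
            mode="edge",
            anti_aliasing=False,
            preserve_range=True,
        )
        out = np.zeros(original_shape, dtype=bool)
        out[r0:r1, c0:c1] = sub > 0.5
        return out


def _crop_params(shape: tuple[int, int], box: BoundingBox, out_size: int):
    r0, r1, c0, c1 = box.bounds(shape)
    if r1 - r0 < 2 or c1 - c0 < 2:
        raise ValueError("degenerate box")
    tf = CropTransform(r0, c0, (r1 - r0) / out_size, (c1 - c0) / out_size, bounds=(r0, r1, c0, c1))
    return (r0, r1, c0, c1), tf


def crop_image(image: np.ndarray, box: BoundingBox, out_size: int = CROP_SIZE) -> np.ndarray:
    (r0, r1, c0, c1), _ = _crop_params(image.shape, box, out_size)
    sub = image[r0:r1, c0:c1]
    if sub.shape == (out_size, out_size):
        return sub.astype(np.float64)
    return resize(sub, (out_size, out_size), order=3, mode="edge", anti_aliasing=False, preserve_range=True)


def crop_mask(mask: np.ndarray, box: BoundingBox, out_size: int = CROP_SIZE) -> np.ndarray:
    (r0, r1, c0, c1), _ = _crop_params(mask.shape, box, out_size)
    sub = np.asarray(mask).astype(bool)[r0:r1, c0:c1]
    if sub.shape == (out_size, out_size):
        return sub
    out = resize(sub.astype(np.float64), (out_size, out_size), order=0, mode="edge", anti_aliasing=False, preserve_range=True)
    return out > 0.5


def crop_series(
    series: PerfusionSeries, box: BoundingBox, out_size: int = CROP_SIZE
) -> tuple[PerfusionSeries, CropTransform]:
    """Crop every frame to ``box`` and resample to ``out_size`` (bicubic).

    Returns the cropped series together with the coordinate transform back
    to the original grid; pixel spacing is rescaled by box-size/out-size.
    """
    (r0, r1, c0, c1), tf = _crop_params(series.shape, box, out_size)
    sub = series.frames[:, r0:r1, c0:c1]
    if sub.shape[1:] != (out_size, out_size):
        out = np.empty((series.n_frames, out_size, out_size), dtype=np.float64)
        for t in range(series.n_frames):  # frame-wise: interpolation is purely in-plane
            out[t] = resize(
                sub[t], (out_size, out_size), order=3, mode="edge", anti_aliasing=False, preserve_range=True
            )
        sub = out
    sub = np.maximum(sub, 0.0)  # bicubic overshoot must not go negative
    spacing = (series.pixel_spacing[0] * tf.row_scale, series.pixel_spacing[1] * tf.col_scale)
    return series.with_frames(sub, pixel_spacing=spacing), tf


def box_dsc(a: BoundingBox, b: BoundingBox, shape: tuple[int, int]) -> float:
    """Dice overlap of two boxes rasterized (filled) on an image grid."""
    from .myo_segment import dsc

    return dsc(a.rasterize(shape), b.rasterize(shape))
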
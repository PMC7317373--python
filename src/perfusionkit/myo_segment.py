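"""Myocardial segmentation postprocessing and quality control (stage 3).

The U-Net produces a per-pixel probability of myocardium on the cropped
peak-enhancement frame.  Postprocessing keeps the largest 4-connected
component; quality control accepts only masks with the expected
"closed-loop" (annular) shape, i.e. a single component that encloses at
least one hole.  On QC failure the network is applied to the frames within
two timeframes of the detected peak and the closest passing frame wins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import PerfusionSeries

_CROSS = ndimage.generate_binary_structure(2, 1)  # 4-connectivity

__all__ = ["dsc", "segment_frame", "qc_closed_loop", "segment_with_fallback", "SegmentationResult", "mask_interior"]


def dsc(a: np.ndarray, b: np.ndarray) -> float:
    """Dice similarity coefficient ``2|A n B| / (|A| + |B|)``.

    Defined as 1 when both masks are empty.
    """
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / denom


def _largest_component(mask: np.ndarray) -> np.ndarray:
    labels, n = ndimage.label(mask, structure=_CROSS)
    if n == 0:
        return mask
    sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
    return labels == (1 + int(np.argmax(sizes)))


def segment_frame(image: np.ndarray, model, threshold: float = 0.5) -> np.ndarray:
    """Segment one normalized cropped frame; returns a binary mask.

    Sigmoid output thresholded at ``threshold``, then the largest
    4-connected component is kept.  An all-background output yields an
    empty mask (QC will reject it).
    """
    img = np.asarray(image, dtype=np.float32)
    if img.ndim != 2:
        raise ValueError("expected a 2D image")
    logits = np.asarray(model.predict(img[None, None]))[0, 0]
    if logits.shape != img.shape:
        raise ValueError("model output shape does not match input")
    prob = 1.0 / (1.0 + np.exp(-logits.astype(np.float64)))
    mask = prob >= threshold
    if not mask.any():
        return mask
    return _largest_component(mask)


def qc_closed_loop(mask: np.ndarray) -> bool:
    """True iff the mask is a single 4-connected component enclosing a hole.

    Operationalized by flood-filling the complement from the image border:
    the mask passes when some complement component does not touch the
    border.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        return False
    _, n = ndimage.label(mask, structure=_CROSS)
    if n != 1:
        return False
    comp_labels, n_comp = ndimage.label(~mask, structure=_CROSS)
    border = np.zeros(mask.shape, dtype=bool)
    border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
    border_labels = set(np.unique(comp_labels[border & ~mask]))
    interior = set(range(1, n_comp + 1)) - border_labels
    return len(interior) >= 1


def mask_interior(mask: np.ndarray) -> np.ndarray:
    """The cavity enclosed by a (closed-loop) mask: complement components
    that do not touch the image border."""
    mask = np.asarray(mask).astype(bool)
    comp_labels, n_comp = ndimage.label(~mask, structure=_CROSS)
    border = np.zeros(mask.shape, dtype=bool)
    border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
    border_ids = set(np.unique(comp_labels[border & ~mask]))
    interior = np.zeros(mask.shape, dtype=bool)
    for i in range(1, n_comp + 1):
        if i not in border_ids:
            interior |= comp_labels == i
    return interior


@dataclass
class SegmentationResult:
    mask: np.ndarray
    used_frame: int
    passed_qc: bool


def segment_with_fallback(
    cropped_series: PerfusionSeries, peak: int, model, threshold: float = 0.5
) -> SegmentationResult:
    """Segment the peak frame, falling back to nearby frames on QC failure.

    Candidate frames are tried in order of distance from the peak
    (``t+1, t-1, t+2, t-2``; at equal distance the later frame first,
    since contrast persists after the peak), clipped to the series.  If no
    candidate passes QC the peak-frame mask is returned flagged as failed.
    The series is normalized to [0, 1] as a whole before inference.
    """
    from .training import normalize_series

    series = normalize_series(cropped_series)
    n = series.n_frames
    candidates = [peak, peak + 1, peak - 1, peak + 2, peak - 2]
    candidates = [t for t in candidates if 0 <= t < n]
    peak_mask = None
    for t in candidates:
        mask = segment_frame(series.frames[t], model, threshold)
        if t == peak:
            peak_mask = mask
        if qc_closed_loop(mask):
            return SegmentationResult(mask=mask, used_frame=t, passed_qc=True)
    if peak_mask is None:  # peak outside series bounds
        peak_mask = segment_frame(series.frames[int(np.clip(peak, 0, n - 1))], model, threshold)
    return SegmentationResult(mask=peak_mask, used_frame=peak, passed_qc=False)
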
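"""RV insertion-point detection via supervised action maps (stage 4).

For a landmark, the action map labels every pixel with the direction
(left, right, up, down) toward the landmark.  The four class regions are
separated by the two diagonals of slope +/-1 through the landmark, so the
landmark can be recovered by fitting the two boundary lines (slopes fixed
at -1 and +1) and intersecting them.  One U-Net per insertion point
(anterior, inferior) predicts the 4-class map from the cropped peak frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter

LEFT, RIGHT, UP, DOWN = 0, 1, 2, 3
CLASS_NAMES = ("left", "right", "up", "down")

__all__ = [
    "LEFT",
    "RIGHT",
    "UP",
    "DOWN",
    "build_action_map",
    "infer_point",
    "estimate_landmark",
    "detect_insertion_points",
    "landmark_error_mm",
    "LandmarkInferenceError",
    "InsertionPointResult",
]


class LandmarkInferenceError(RuntimeError):
    pass


def build_action_map(shape: tuple[int, int], landmark: tuple[float, float]) -> np.ndarray:
    """Per-pixel direction-to-landmark labels.

    For pixel p: with ``dr = landmark_row - p_row`` and ``dc = landmark_col
    - p_col``, the label is right/left when ``|dc| > |dr|`` (sign of dc),
    down/up when ``|dr| > |dc|`` (sign of dr); exact ties (including the
    landmark pixel itself) take the horizontal class (right when
    ``dc >= 0``, else left).
    """
    h, w = shape
    lr, lc = landmark
    if not (0 <= lr <= h - 1 and 0 <= lc <= w - 1):
        raise ValueError("landmark must lie inside the image")
    rr, cc = np.mgrid[0:h, 0:w]
    dr = lr - rr
    dc = lc - cc
    labels = np.empty(shape, dtype=np.uint8)
    horiz = np.abs(dc) > np.abs(dr)
    vert = np.abs(dr) > np.abs(dc)
    tie = ~horiz & ~vert
    labels[horiz & (dc > 0)] = RIGHT
    labels[horiz & (dc < 0)] = LEFT
    labels[vert & (dr > 0)] = DOWN
    labels[vert & (dr < 0)] = UP
    labels[tie & (dc >= 0)] = RIGHT
    labels[tie & (dc < 0)] = LEFT
    return labels


def majority_filter(labels: np.ndarray) -> np.ndarray:
    """3x3 modal filter over the four direction classes.

    Isolated label errors (network noise) would otherwise create spurious
    partition-boundary pairs everywhere in the map; a majority vote removes
    them while leaving the diagonal partition geometry intact.  Ties retain
    the center pixel's label.
    """
    labels = np.asarray(labels)
    counts = np.stack(
        [uniform_filter((labels == k).astype(np.float64), size=3, mode="nearest") for k in range(4)]
    )
    # keep the original label on ties
    rr, cc = np.indices(labels.shape)
    counts[labels, rr, cc] += 1e-6
    return np.argmax(counts, axis=0).astype(np.uint8)


def _boundary_midpoints(labels: np.ndarray, pair_sets: tuple[set, set]) -> np.ndarray:
    """Midpoints of 4-neighbour pixel pairs whose classes fall one in each
    of the two given sets."""
    a, b = pair_sets
    pts = []
    for axis in (0, 1):
        u = labels.take(range(labels.shape[axis] - 1), axis=axis)
        v = labels.take(range(1, labels.shape[axis]), axis=axis)
        hit = np.zeros(u.shape, dtype=bool)
        for ca in a:
            for cb in b:
                hit |= (u == ca) & (v == cb)
                hit |= (u == cb) & (v == ca)
        rr, cc = np.nonzero(hit)
        if axis == 0:
            pts.append(np.stack([rr + 0.5, cc], axis=1))
        else:
            pts.append(np.stack([rr, cc + 0.5], axis=1))
    return np.concatenate(pts, axis=0) if pts else np.empty((0, 2))


def infer_point(labels: np.ndarray) -> tuple[float, float]:
    """Landmark estimate from an action map.

    Fits the slope -1 line to the boundary between the {up,right} and
    {down,left} regions (``row + col = b1``) and the slope +1 line to the
    boundary between {up,left} and {down,right} (``row - col = b2``) by
    least squares with the slope fixed, and returns their intersection.
    The map is modal-filtered first to suppress isolated label errors.
    """
    labels = majority_filter(np.asarray(labels))
    present = set(np.unique(labels))
    if not {LEFT, RIGHT, UP, DOWN} <= present:
        raise LandmarkInferenceError(f"missing classes: present={sorted(present)}")
    # slope -1 diagonal: up|right and down|left adjacencies
    pts1 = np.concatenate(
        [
            _boundary_midpoints(labels, ({UP}, {RIGHT})),
            _boundary_midpoints(labels, ({DOWN}, {LEFT})),
        ]
    )
    # slope +1 diagonal: up|left and down|right adjacencies
    pts2 = np.concatenate(
        [
            _boundary_midpoints(labels, ({UP}, {LEFT})),
            _boundary_midpoints(labels, ({DOWN}, {RIGHT})),
        ]
    )
    if len(pts1) < 3 or len(pts2) < 3:
        raise LandmarkInferenceError("too few boundary pixels to fit the partition lines")
    b1 = float(np.mean(pts1[:, 0] + pts1[:, 1]))  # row = -col + b1
    b2 = float(np.mean(pts2[:, 0] - pts2[:, 1]))  # row = +col + b2
    return (b1 + b2) / 2.0, (b1 - b2) / 2.0


def _centroid_fallback(labels: np.ndarray) -> tuple[float, float]:
    def centroid(cls):
        rr, cc = np.nonzero(labels == cls)
        if len(rr) == 0:
            return None
        return rr.mean(), cc.mean()

    up, down = centroid(UP), centroid(DOWN)
    left, right = centroid(LEFT), centroid(RIGHT)
    h, w = labels.shape
    row = (up[0] + down[0]) / 2.0 if up and down else (h - 1) / 2.0
    col = (left[1] + right[1]) / 2.0 if left and right else (w - 1) / 2.0
    return row, col


def estimate_landmark(labels: np.ndarray) -> tuple[tuple[float, float], bool]:
    """Line-intersection estimate with a flagged class-centroid fallback."""
    try:
        return infer_point(labels), False
    except LandmarkInferenceError:
        return _centroid_fallback(labels), True


@dataclass
class InsertionPointResult:
    points_cropped: np.ndarray  # (2, 2): anterior, inferior
    points_original: np.ndarray | None
    fallback_used: tuple[bool, bool]


def detect_insertion_points(
    cropped_peak_frame: np.ndarray,
    model_anterior,
    model_inferior,
    transform=None,
) -> InsertionPointResult:
    """Predict both insertion points from the normalized cropped peak frame.

    Each network outputs 4-class logits per pixel; the argmax map feeds the
    line-intersection estimator.  If ``transform`` (a crop transform) is
    given, coordinates are also mapped back to the original frame.
    """
    img = np.asarray(cropped_peak_frame, dtype=np.float32)
    points = []
    flags = []
    for model in (model_anterior, model_inferior):
        logits = np.asarray(model.predict(img[None, None]))[0]  # (4, H, W)
        labels = np.argmax(logits, axis=0).astype(np.uint8)
        p, fb = estimate_landmark(labels)
        points.append(p)
        flags.append(fb)
    pts = np.array(points, dtype=np.float64)
    orig = transform.to_original(pts) if transform is not None else None
    return InsertionPointResult(pts, orig, (flags[0], flags[1]))


def landmark_error_mm(p, q, spacing) -> float:
    """Euclidean distance in mm with (possibly anisotropic) pixel spacing."""
    p = np.asarray(p, dtype=np.float64)
    q = np.asarray(q, dtype=np.float64)
    s = np.asarray(spacing, dtype=np.float64)
    if s.ndim == 0:
        s = np.array([s, s])
    d = (p - q) * s
    return float(np.hypot(d[0], d[1]))
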
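"""Peak LV contrast-enhancement frame detection (pipeline stage 1).

A binary classifier scores every timeframe from a 5-frame window (the frame
plus its two predecessors and two successors, edge-replicated at the series
boundaries); the frame with the highest positive-class probability is the
peak estimate, with ties broken toward the earlier frame.
"""

from __future__ import annotations

import numpy as np
from skimage.transform import resize

from .core import PerfusionSeries
from .training import normalize_series

WINDOW = 2  # frames on each side

__all__ = ["make_window", "detect_peak_frame", "peak_error", "WINDOW"]


def window_indices(n_frames: int, t: int) -> np.ndarray:
    if not 0 <= t < n_frames:
        raise IndexError(f"frame index {t} outside [0, {n_frames})")
    return np.clip(np.arange(t - WINDOW, t + WINDOW + 1), 0, n_frames - 1)


def make_window(series: PerfusionSeries, t: int) -> np.ndarray:
    """5-frame stack ``(t-2 .. t+2)`` as channels, edge-replicated at the
    series boundaries.  Channel order is chronological."""
    idx = window_indices(series.n_frames, t)
    return series.frames[idx]


def detect_peak_frame(series: PerfusionSeries, model) -> tuple[int, np.ndarray]:
    """Classify every frame's window; return (peak index, probability trace).

    The raw series is min-max normalized as a whole before inference, so the
    result is invariant to global intensity scaling.  ``np.argmax`` takes
    the first maximum, implementing the earlier-frame tie-break.
    """
    norm = normalize_series(series)
    n = norm.n_frames
    size = getattr(model, "input_size", norm.shape[0])
    frames = norm.frames
    if frames.shape[1:] != (size, size):
        resized = np.empty((n, size, size), dtype=np.float64)
        for t in range(n):  # frame-wise bicubic: interpolation is purely in-plane
            resized[t] = resize(
                frames[t], (size, size), order=3, mode="edge", anti_aliasing=False, preserve_range=True
            )
        frames = resized
    small = norm.with_frames(np.maximum(frames, 0.0))
    stacks = np.stack([make_window(small, t) for t in range(n)])  # (T, 5, size, size)
    logits = np.asarray(model.predict(stacks.astype(np.float32)))
    if logits.shape != (n, 2):
        raise ValueError(f"peak classifier must output (n_frames, 2) logits; got {logits.shape}")
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    trace = e[:, 1] / e.sum(axis=1)
    return int(np.argmax(trace)), trace


def peak_error(predicted: int, true: int) -> int:
    """Absolute timeframe difference."""
    return abs(int(predicted) - int(true))
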
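"""Shared fixtures: small phantom configurations and stub stage models.

Stub models implement the same ``predict`` protocol as trained networks but
compute their output from ground truth or from a fixed rule, which lets the
plumbing around each network be tested exactly and fast.
"""

from __future__ import annotations

import numpy as np
import pytest

from perfusionkit.phantom import desk_phantom_config, generate_series


@pytest.fixture(scope="session")
def desk_config():
    return desk_phantom_config()


@pytest.fixture(scope="session")
def noiseless_subject(desk_config):
    """One desk-scale subject without noise or motion (all six series)."""
    import dataclasses

    cfg = dataclasses.replace(desk_config, noise_sd=0.0, motion_amplitude=0.0)
    return generate_series(cfg, seed=11)


class ProbMapModel:
    """Segmentation stub: returns large +/- logits from a probability map."""

    def __init__(self, prob_map: np.ndarray):
        self.prob_map = np.asarray(prob_map, dtype=np.float64)
        self.input_size = self.prob_map.shape[-1]

    def predict(self, x):
        logit = np.where(self.prob_map >= 0.5, 20.0, -20.0)
        return np.broadcast_to(logit, (x.shape[0], 1) + logit.shape).copy()


class FrameTraceModel:
    """Peak-classifier stub driven by a fixed per-frame probability trace."""

    def __init__(self, trace, input_size: int = 64):
        self.trace = np.asarray(trace, dtype=np.float64)
        self.input_size = input_size
        self._i = 0

    def predict(self, x):
        n = x.shape[0]
        p = self.trace[self._i : self._i + n]
        self._i += n
        eps = 1e-9
        p = np.clip(p, eps, 1 - eps)
        return np.stack([np.log(1 - p), np.log(p)], axis=1)


class ActionMapModel:
    """Landmark stub emitting the exact action map of a known landmark."""

    def __init__(self, labels: np.ndarray):
        self.labels = np.asarray(labels)
        self.input_size = self.labels.shape[-1]

    def predict(self, x):
        logits = np.full((x.shape[0], 4) + self.labels.shape, -20.0)
        for k in range(4):
            logits[:, k][:, self.labels == k] = 20.0
        return logits
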
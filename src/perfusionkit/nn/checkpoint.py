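"""Single-file model checkpoints (.npz with an embedded JSON header)."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np


def save_checkpoint(path, model, meta: dict) -> None:
    """Save parameter values, batch-norm buffers, and a JSON metadata blob."""
    arrays = {}
    for i, p in enumerate(model.params()):
        arrays[f"param_{i}"] = p.value
    for k, v in model.buffers().items():
        arrays[f"buffer::{k}"] = v
    arrays["meta"] = np.frombuffer(json.dumps(meta, sort_keys=True).encode(), dtype=np.uint8)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, **arrays)


def load_checkpoint(path) -> tuple[dict, dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Return (meta, params-by-index, buffers-by-name)."""
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta"].tobytes()).decode())
        params = {k: data[k] for k in data.files if k.startswith("param_")}
        buffers = {k.split("::", 1)[1]: data[k] for k in data.files if k.startswith("buffer::")}
    return meta, params, buffers


def restore_into(model, params: dict[str, np.ndarray], buffers: dict[str, np.ndarray]) -> None:
    model_params = model.params()
    if len(model_params) != len(params):
        raise ValueError("checkpoint/architecture parameter count mismatch")
    for i, p in enumerate(model_params):
        v = params[f"param_{i}"]
        if v.shape != p.value.shape:
            raise ValueError(f"shape mismatch for parameter {i}: {v.shape} vs {p.value.shape}")
        p.value[...] = v
    model_buffers = model.buffers()
    for k, v in buffers.items():
        model_buffers[k][...] = v
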
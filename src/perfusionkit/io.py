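"""NIfTI / JSON / CSV input-output.

Axis contract: on disk a series is (H, W, T) with pixel spacing in the
header zooms (row mm, col mm, frame interval s); in memory it is
``frames[(T, H, W)]``.  A JSON sidecar next to each series carries frame
times, slice level, condition and subject id (all optional on read).
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import nibabel as nib
import numpy as np

from .core import BoundingBox, GroundTruth, PerfusionSeries

__all__ = [
    "read_series",
    "write_series",
    "read_mask",
    "write_mask",
    "write_truth",
    "read_truth",
    "write_cohort",
    "read_subject_dir",
    "dump_json",
]


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suf in (".nii.gz", ".nii"):
        if name.endswith(suf):
            return path.with_name(name[: -len(suf)] + ".json")
    return path.with_suffix(".json")


def write_series(path, series: PerfusionSeries) -> None:
    path = Path(path)
    data = np.ascontiguousarray(series.frames.transpose(1, 2, 0).astype(np.float32))
    dts = np.diff(series.frame_times)
    dt = float(dts.mean()) if len(dts) else 1.0
    affine = np.diag([series.pixel_spacing[0], series.pixel_spacing[1], dt, 1.0])
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms((series.pixel_spacing[0], series.pixel_spacing[1], dt))
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(img, str(path))
    sidecar = {
        "frame_times": series.frame_times.tolist(),
        "slice_level": series.slice_level,
        "condition": series.condition,
        "subject_id": series.subject_id,
        "pixel_spacing": list(series.pixel_spacing),
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, sort_keys=True, indent=2))


def read_series(path) -> PerfusionSeries:
    path = Path(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(
            f"{path.name}: expected a 3D (H, W, T) series, got {data.ndim} dims; "
            "2D single frames are not accepted here"
        )
    zooms = img.header.get_zooms()
    if len(zooms) >= 2 and zooms[0] > 0 and zooms[1] > 0:
        spacing = (float(zooms[0]), float(zooms[1]))
    else:
        warnings.warn(f"{path.name}: missing pixel spacing, defaulting to 1.0 mm", stacklevel=2)
        spacing = (1.0, 1.0)
    meta = {}
    sc = _sidecar_path(path)
    if sc.exists():
        meta = json.loads(sc.read_text())
    n_frames = data.shape[2]
    if "frame_times" in meta:
        times = np.asarray(meta["frame_times"], dtype=np.float64)
    else:
        dt = float(zooms[2]) if len(zooms) > 2 and zooms[2] > 0 else 1.0
        times = np.arange(n_frames) * dt
    return PerfusionSeries(
        frames=np.ascontiguousarray(data.transpose(2, 0, 1).astype(np.float64)),
        pixel_spacing=spacing,
        frame_times=times,
        slice_level=meta.get("slice_level", "mid"),
        condition=meta.get("condition", "rest"),
        subject_id=meta.get("subject_id", ""),
    )


def write_mask(path, mask: np.ndarray, spacing: tuple[float, float] = (1.0, 1.0)) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(np.asarray(mask).astype(np.uint8), np.diag([spacing[0], spacing[1], 1.0, 1.0]))
    nib.save(img, str(path))


def read_mask(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj).astype(bool)


def _box_dict(box: BoundingBox) -> dict:
    r0, r1, c0, c1 = box.bounds()
    return {
        "center": [box.center[0], box.center[1]],
        "height": box.height,
        "width": box.width,
        "corners": [r0, r1, c0, c1],
    }


def write_truth(path, truth: GroundTruth) -> None:
    d = {
        "peak_frame": truth.peak_frame,
        "bbox": _box_dict(truth.bbox),
        "insertion_points": truth.insertion_points.tolist(),
    }
    if truth.translations is not None:
        d["translations"] = truth.translations.tolist()
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(d, sort_keys=True, indent=2))


def read_truth(path) -> dict:
    d = json.loads(Path(path).read_text())
    d["bbox"] = BoundingBox(tuple(d["bbox"]["center"]), d["bbox"]["height"], d["bbox"]["width"])
    d["insertion_points"] = np.asarray(d["insertion_points"], dtype=np.float64)
    return d


def write_cohort(out_dir, cohort, with_truth: bool = True) -> None:
    """Write a phantom cohort: one NIfTI per slice/condition plus masks,
    truth JSON, AIF CSV and parameter maps per series."""
    out_dir = Path(out_dir)
    for subject in cohort:
        for (level, condition), (series, truth) in subject.items():
            sdir = out_dir / series.subject_id
            stem = f"{level}_{condition}"
            write_series(sdir / f"{stem}.nii.gz", series)
            if not with_truth:
                continue
            write_mask(sdir / f"{stem}_myo_mask.nii.gz", truth.myo_mask, series.pixel_spacing)
            write_mask(sdir / f"{stem}_lv_pool_mask.nii.gz", truth.lv_pool_mask, series.pixel_spacing)
            write_mask(sdir / f"{stem}_rv_mask.nii.gz", truth.rv_mask, series.pixel_spacing)
            write_truth(sdir / f"{stem}_truth.json", truth)
            if truth.aif_true is not None:
                lines = ["time_s,concentration"] + [
                    f"{t:.6f},{v:.8f}" for t, v in zip(truth.aif_true.times, truth.aif_true.values)
                ]
                (sdir / f"{stem}_aif.csv").write_text("\n".join(lines) + "\n")
            if truth.param_maps is not None:
                maps = np.stack(
                    [
                        np.asarray(truth.param_maps.Fp),
                        np.asarray(truth.param_maps.vp),
                        np.asarray(truth.param_maps.PS),
                        np.asarray(truth.param_maps.ve),
                    ],
                    axis=-1,
                ).astype(np.float32)
                img = nib.Nifti1Image(maps, np.eye(4))
                nib.save(img, str(sdir / f"{stem}_params.nii.gz"))


def read_subject_dir(subject_dir) -> dict:
    """Read all series of one subject directory keyed by (level, condition)."""
    subject_dir = Path(subject_dir)
    out = {}
    for f in sorted(subject_dir.glob("*.nii.gz")):
        parts = f.name.replace(".nii.gz", "").split("_")
        if len(parts) != 2:
            continue  # masks / parameter maps
        level, condition = parts
        out[(level, condition)] = read_series(f)
    if not out:
        raise FileNotFoundError(f"no series found under {subject_dir}")
    return out


def dump_json(path, obj: dict) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(obj, sort_keys=True, indent=2, default=_json_default))


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
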
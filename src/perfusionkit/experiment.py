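"""Desk-scale end-to-end experiment: generate phantoms, train the four
stage networks, run the automated pipeline on held-out subjects, and
compare its per-segment MBF against reference-label processing.

This module is the repository's self-contained counterpart of a clinical
train/validate/test study: 40/5/10 subjects by default, 128 px phantoms,
small channel widths, and short iteration budgets chosen so the whole
experiment runs on one CPU in minutes.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from skimage.transform import resize

from .agreement import bland_altman, icc_agreement, slope_through_origin
from .core import GroundTruth, PerfusionSeries
from .frame_select import peak_error, window_indices
from .myo_segment import dsc
from .phantom import PhantomConfig, desk_phantom_config, generate_cohort
from .pipeline import ModelBundle, PipelineConfig, process_with_reference, run_pipeline_subject
from .roi_detect import (
    box_dsc,
    crop_mask,
    delta_to_target,
    invert_delta,
    propose_roi,
)
from .rv_landmark import build_action_map
from .training import (
    ArchSpec,
    AugmentRanges,
    NetworkModel,
    TrainConfig,
    augment,
    normalize_stack,
    train_model,
)

__all__ = ["DeskExperimentConfig", "train_desk_models", "evaluate_pipeline", "run_desk_experiment"]

logger = logging.getLogger(__name__)

Cohort = list[dict[tuple[str, str], tuple[PerfusionSeries, GroundTruth]]]


@dataclass
class DeskExperimentConfig:
    n_train: int = 40
    n_val: int = 5
    n_test: int = 10
    phantom: PhantomConfig = field(default_factory=desk_phantom_config)
    cnn_input_size: int = 64
    cnn_channels: tuple[int, ...] = (8, 16, 32, 64)
    cnn_fc_units: int = 64
    unet_base: int = 8
    unet_depth: int = 3
    crop_size: int = 96
    peak_iterations: int = 400
    bbox_iterations: int = 600
    seg_iterations: int = 220
    action_iterations: int = 400
    seed: int = 7


def _stage_cfg(cfg: DeskExperimentConfig, stage: str, seed: int) -> TrainConfig:
    base = TrainConfig(
        learning_rate=1e-3,
        l2_weight=1e-3,
        eval_every=25,
        seed=seed,
    )
    if stage == "peak":
        return replace(
            base,
            batch_size=32,
            max_iterations=cfg.peak_iterations,
            patience=max(cfg.peak_iterations // 2, 100),
            augment=AugmentRanges(2.0, 0.0, 0.03, 0.05, 0.01),
        )
    if stage == "bbox":
        return replace(
            base,
            batch_size=32,
            max_iterations=cfg.bbox_iterations,
            patience=max(cfg.bbox_iterations // 2, 100),
        )
    if stage == "seg":
        return replace(
            base,
            batch_size=8,
            max_iterations=cfg.seg_iterations,
            patience=max(cfg.seg_iterations // 2, 100),
            augment=AugmentRanges(2.0, 0.0, 0.0, 0.05, 0.01),
        )
    if stage == "action":
        return replace(
            base,
            batch_size=8,
            max_iterations=cfg.action_iterations,
            patience=max(cfg.action_iterations // 2, 100),
            augment=AugmentRanges(2.0, 0.0, 0.0, 0.05, 0.01),
        )
    raise ValueError(stage)


def _resize_frames(frames: np.ndarray, size: int) -> np.ndarray:
    t = frames.shape[0]
    if frames.shape[1:] == (size, size):
        return frames.astype(np.float32)
    out = np.empty((t, size, size), dtype=np.float32)
    for i in range(t):  # frame-wise bicubic, matching the inference path
        out[i] = resize(frames[i], (size, size), order=3, mode="edge", anti_aliasing=False, preserve_range=True)
    return np.clip(out, 0.0, None)


def _series_list(cohort: Cohort):
    return [pair for subject in cohort for pair in subject.values()]


# --- stage datasets -------------------------------------------------------


def _peak_data(cohort: Cohort, size: int):
    stacks, peaks = [], []
    for series, truth in _series_list(cohort):
        stacks.append(_resize_frames(normalize_stack(series.frames), size))
        peaks.append(truth.peak_frame)
    return stacks, peaks


def _peak_sampler(stacks, peaks, ranges: AugmentRanges, pos_fraction: float = 0.2):
    n_series = len(stacks)

    def sample(rng: np.random.Generator, bs: int):
        xb = np.empty((bs, 5, stacks[0].shape[1], stacks[0].shape[2]), dtype=np.float32)
        yb = np.empty(bs, dtype=np.int64)
        for i in range(bs):
            s = int(rng.integers(n_series))
            t_peak = peaks[s]
            n = stacks[s].shape[0]
            if rng.random() < pos_fraction:
                t, y = t_peak, 1
            else:
                t = int(rng.integers(n - 1))
                if t >= t_peak:
                    t += 1
                y = 0
            win = stacks[s][window_indices(n, t)]
            if not ranges.is_identity:
                win, _ = augment(win, None, rng, ranges)
            xb[i] = win
            yb[i] = y
        return xb, yb

    return sample


def _peak_val_set(stacks, peaks, rng: np.random.Generator):
    xs, ys = [], []
    for s, t_peak in enumerate(peaks):
        n = stacks[s].shape[0]
        xs.append(stacks[s][window_indices(n, t_peak)])
        ys.append(1)
        for _ in range(4):
            t = int(rng.integers(n - 1))
            if t >= t_peak:
                t += 1
            xs.append(stacks[s][window_indices(n, t)])
            ys.append(0)
    return np.stack(xs).astype(np.float32), np.array(ys, dtype=np.int64)


def _bbox_data(cohort: Cohort, size: int):
    xs, ys = [], []
    for subject in cohort:
        for (level, _), (series, truth) in subject.items():
            if level != "basal":
                continue
            norm = normalize_stack(series.frames)
            frame = _resize_frames(norm[truth.peak_frame][None], size)[0]
            xs.append(frame[None])
            proposal = propose_roi(*series.shape)
            ys.append(delta_to_target(invert_delta(proposal, truth.bbox)))
    return np.stack(xs).astype(np.float32), np.stack(ys).astype(np.float32)


def _cropped_frames_and_labels(cohort: Cohort, crop_size: int):
    """Truth-box-cropped peak frames (normalized exactly as the pipeline
    normalizes cropped series) with cropped masks and points."""
    from .roi_detect import crop_series
    from .training import normalize_series

    imgs, masks, points = [], [], []
    for series, truth in _series_list(cohort):
        cropped, tf = crop_series(series, truth.bbox, crop_size)
        norm = normalize_series(cropped)
        imgs.append(norm.frames[truth.peak_frame])
        masks.append(crop_mask(truth.myo_mask, truth.bbox, crop_size))
        points.append(tf.to_cropped(truth.insertion_points))
    return imgs, masks, points


def _seg_sampler(imgs, masks, ranges: AugmentRanges):
    n = len(imgs)

    def sample(rng: np.random.Generator, bs: int):
        xb, yb = [], []
        for _ in range(bs):
            i = int(rng.integers(n))
            img, lab = augment(imgs[i], {"mask": masks[i]}, rng, ranges)
            xb.append(img[None])
            yb.append(lab["mask"][None] if lab else masks[i][None])
        return np.stack(xb).astype(np.float32), np.stack(yb).astype(np.float32)

    return sample


def _action_sampler(imgs, points, which: int, ranges: AugmentRanges):
    n = len(imgs)
    shape = imgs[0].shape

    def sample(rng: np.random.Generator, bs: int):
        xb, yb = [], []
        for _ in range(bs):
            i = int(rng.integers(n))
            img, lab = augment(imgs[i], {"points": points[i]}, rng, ranges)
            p = (lab["points"] if lab else points[i])[which]
            p = np.clip(p, 2.0, np.array(shape) - 3.0)
            xb.append(img[None])
            yb.append(build_action_map(shape, (p[0], p[1])))
        return np.stack(xb).astype(np.float32), np.stack(yb).astype(np.int64)

    return sample


def _fixed_set(sampler, rng: np.random.Generator, n: int, bs: int = 16):
    xs, ys = [], []
    remaining = n
    while remaining > 0:
        xb, yb = sampler(rng, min(bs, remaining))
        xs.append(xb)
        ys.append(yb)
        remaining -= len(xb)
    return np.concatenate(xs), np.concatenate(ys)


# --- training -------------------------------------------------------------


def train_desk_models(
    cfg: DeskExperimentConfig,
    train_cohort: Cohort,
    val_cohort: Cohort,
) -> tuple[ModelBundle, dict]:
    """Train all four stage networks with the desk-scale preset."""
    rng = np.random.default_rng(cfg.seed)
    seeds = rng.integers(0, 2**31 - 1, size=8)
    logs: dict = {}
    t0 = time.perf_counter()

    # 1. peak-frame classifier
    stacks, peaks = _peak_data(train_cohort, cfg.cnn_input_size)
    vstacks, vpeaks = _peak_data(val_cohort, cfg.cnn_input_size)
    pcfg = _stage_cfg(cfg, "peak", int(seeds[0]))
    sampler = _peak_sampler(stacks, peaks, pcfg.augment)
    val = _peak_val_set(vstacks, vpeaks, np.random.default_rng(int(seeds[1])))
    arch = ArchSpec(
        "classifier_cnn",
        in_channels=5,
        out_units=2,
        input_size=cfg.cnn_input_size,
        channels=cfg.cnn_channels,
        fc_units=cfg.cnn_fc_units,
    )
    peak_model, logs["peak"] = train_model(arch, None, val, pcfg, sampler=sampler)
    logger.info("peak stage trained (%.0f s)", time.perf_counter() - t0)
    t0 = time.perf_counter()

    # 2. bounding-box regressor (basal slices only)
    xb, yb = _bbox_data(train_cohort, cfg.cnn_input_size)
    xv, yv = _bbox_data(val_cohort, cfg.cnn_input_size)
    arch = ArchSpec(
        "bbox_cnn",
        in_channels=1,
        out_units=4,
        input_size=cfg.cnn_input_size,
        channels=cfg.cnn_channels,
        fc_units=cfg.cnn_fc_units,
    )
    bbox_model, logs["bbox"] = train_model(arch, (xb, yb), (xv, yv), _stage_cfg(cfg, "bbox", int(seeds[2])))
    logger.info("bbox stage trained (%.0f s)", time.perf_counter() - t0)
    t0 = time.perf_counter()

    # 3. myocardial segmentation U-Net
    imgs, masks, points = _cropped_frames_and_labels(train_cohort, cfg.crop_size)
    vimgs, vmasks, vpoints = _cropped_frames_and_labels(val_cohort, cfg.crop_size)
    scfg = _stage_cfg(cfg, "seg", int(seeds[3]))
    sampler = _seg_sampler(imgs, masks, scfg.augment)
    vx = np.stack([im[None] for im in vimgs]).astype(np.float32)
    vy = np.stack([m[None] for m in vmasks]).astype(np.float32)
    arch = ArchSpec(
        "unet_seg", in_channels=1, input_size=cfg.crop_size, base=cfg.unet_base, depth=cfg.unet_depth
    )
    seg_model, logs["seg"] = train_model(arch, None, (vx, vy), scfg, sampler=sampler)
    logger.info("segmentation stage trained (%.0f s)", time.perf_counter() - t0)
    t0 = time.perf_counter()

    # 4. action-map U-Nets, one per insertion point
    action_models = []
    for which, name in ((0, "anterior"), (1, "inferior")):
        acfg = _stage_cfg(cfg, "action", int(seeds[4 + which]))
        sampler = _action_sampler(imgs, points, which, acfg.augment)
        vyl = np.stack(
            [build_action_map(vimgs[0].shape, tuple(p[which])) for p in vpoints]
        ).astype(np.int64)
        arch = ArchSpec(
            "unet_action", in_channels=1, input_size=cfg.crop_size, base=cfg.unet_base, depth=cfg.unet_depth
        )
        model, logs[f"landmark_{name}"] = train_model(arch, None, (vx, vyl), acfg, sampler=sampler)
        logger.info("landmark (%s) stage trained (%.0f s)", name, time.perf_counter() - t0)
        t0 = time.perf_counter()
        action_models.append(model)

    bundle = ModelBundle(
        peak=peak_model,
        bbox=bbox_model,
        seg=seg_model,
        landmark_anterior=action_models[0],
        landmark_inferior=action_models[1],
    )
    return bundle, logs


# --- evaluation -----------------------------------------------------------


def evaluate_pipeline(
    bundle: ModelBundle,
    test_cohort: Cohort,
    pipeline_config: PipelineConfig | None = None,
) -> dict:
    """Run the automated pipeline on test subjects and score every stage
    against ground truth, including per-segment MBF agreement between the
    automated route and reference-label processing."""
    pipeline_config = pipeline_config or PipelineConfig()
    peak_errors: list[float] = []
    box_dscs: list[float] = []
    myo_dscs: list[float] = []
    insertion_px: list[float] = []
    insertion_mm: list[float] = []
    completions = 0
    mbf_rows: list[dict] = []
    mbf_rest: list[float] = []
    mbf_stress: list[float] = []

    for si, subject in enumerate(test_cohort):
        series_only = {k: s for k, (s, _) in subject.items()}
        result = run_pipeline_subject(series_only, bundle, pipeline_config)
        if result.complete:
            completions += 1
        for key, (series, truth) in subject.items():
            level, condition = key
            if key not in result.series:
                continue
            sr = result.series[key]
            peak_errors.append(peak_error(sr.peak, truth.peak_frame))
            if level == "basal":
                box_dscs.append(box_dsc(sr.box, truth.bbox, series.shape))
            myo_dscs.append(dsc(sr.mask_original, truth.myo_mask))
            for j in range(2):
                d = sr.insertion_points_original[j] - truth.insertion_points[j]
                insertion_px.append(float(np.hypot(*d)))
                insertion_mm.append(
                    float(np.hypot(d[0] * series.pixel_spacing[0], d[1] * series.pixel_spacing[1]))
                )
            ref_table = process_with_reference(series, truth, pipeline_config)
            merged = sr.segment_table.merge(ref_table, on="segment_id", suffixes=("_auto", "_ref"))
            for _, row in merged.iterrows():
                mbf_rows.append(
                    {
                        "subject": si,
                        "condition": condition,
                        "segment_id": int(row["segment_id"]),
                        "mbf_auto": row["mean_mbf_ml_min_ml_auto"],
                        "mbf_ref": row["mean_mbf_ml_min_ml_ref"],
                    }
                )
            vals = sr.segment_table["mean_mbf_ml_min_ml"].to_numpy()
            (mbf_rest if condition == "rest" else mbf_stress).extend(vals.tolist())

    mbf = pd.DataFrame(mbf_rows)
    metrics = {
        "n_subjects": len(test_cohort),
        "n_series_scored": len(myo_dscs),
        "peak_frame_mae": float(np.mean(peak_errors)) if peak_errors else float("nan"),
        "box_dsc_mean": float(np.mean(box_dscs)) if box_dscs else float("nan"),
        "myo_dsc_mean": float(np.mean(myo_dscs)) if myo_dscs else float("nan"),
        "insertion_error_px_mean": float(np.mean(insertion_px)) if insertion_px else float("nan"),
        "insertion_error_mm_mean": float(np.mean(insertion_mm)) if insertion_mm else float("nan"),
        "pipeline_completions": completions,
        "mbf_rest_mean": float(np.mean(mbf_rest)) if mbf_rest else float("nan"),
        "mbf_stress_mean": float(np.mean(mbf_stress)) if mbf_stress else float("nan"),
    }
    if len(mbf) >= 5:
        icc, lo, hi = icc_agreement(mbf["mbf_auto"], mbf["mbf_ref"])
        ba = bland_altman(mbf["mbf_auto"].to_numpy(), mbf["mbf_ref"].to_numpy())
        slope, r2 = slope_through_origin(mbf["mbf_ref"].to_numpy(), mbf["mbf_auto"].to_numpy())
        grand_mean = float(np.mean((mbf["mbf_auto"] + mbf["mbf_ref"]) / 2.0))
        metrics.update(
            {
                "segment_mbf_icc": float(icc),
                "segment_mbf_icc_ci": [float(lo), float(hi)],
                "segment_mbf_bias_pct_of_mean": float(100.0 * ba.bias / grand_mean),
                "segment_mbf_slope_through_origin": float(slope),
                "segment_mbf_r2": float(r2),
                "n_segment_pairs": int(len(mbf)),
            }
        )
    return metrics


def run_desk_experiment(
    seed: int = 7,
    cfg: DeskExperimentConfig | None = None,
    pipeline_config: PipelineConfig | None = None,
) -> tuple[dict, ModelBundle]:
    """The full desk-scale study: simulate, train, evaluate.

    All randomness flows from ``seed``; returns (metrics, trained models).
    """
    cfg = cfg or DeskExperimentConfig()
    cfg = replace(cfg, seed=seed)
    rng = np.random.default_rng(seed)
    s_train, s_val, s_test = (int(x) for x in rng.integers(0, 2**31 - 1, size=3))
    t0 = time.perf_counter()
    train_cohort = generate_cohort(cfg.phantom, cfg.n_train, seed=s_train)
    val_cohort = generate_cohort(cfg.phantom, cfg.n_val, seed=s_val)
    test_cohort = generate_cohort(cfg.phantom, cfg.n_test, seed=s_test)
    logger.info("simulated %d subjects (%.0f s)", cfg.n_train + cfg.n_val + cfg.n_test,
                time.perf_counter() - t0)
    bundle, _ = train_desk_models(cfg, train_cohort, val_cohort)
    t0 = time.perf_counter()
    metrics = evaluate_pipeline(bundle, test_cohort, pipeline_config)
    logger.info("evaluated %d test subjects (%.0f s)", cfg.n_test, time.perf_counter() - t0)
    return metrics, bundle
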
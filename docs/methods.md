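# Methods

`perfusionkit` re-implements a fully automated preprocessing and
quantification pipeline for first-pass myocardial perfusion MRI and pairs
it with a synthetic phantom so that every stage can be trained, run, and
verified at desk scale on one CPU. This note records the models, the
numerical choices, and what the phantom experiments do and do not
demonstrate.

## Pipeline model

A perfusion study is three short-axis slices (basal, mid-cavity, apical)
acquired over ~30–50 heartbeats at rest and under stress. The pipeline
processes each condition as:

1. **Peak-enhancement frame.** A small CNN scores every timeframe from a
   5-frame window (the frame plus two predecessors and two successors,
   edge-replicated at the series boundaries); the frame with the highest
   positive-class probability is the peak LV enhancement estimate, ties
   broken toward the earlier frame. The network is four 3×3-conv blocks
   (each conv → 2×2 max-pool → batch-norm → ReLU) and two fully-connected
   layers with a two-unit softmax head.
2. **Bounding box.** The same CNN body regresses an adjustment of a fixed
   75×75 proposal centered on the image: center displacement (dx, dy,
   normalized by 75 for conditioning) and width/height scale factors,
   trained with MSE on the basal peak frame only. The resulting box is
   reused for the mid and apical slices. The training label is the tight
   box around the myocardium expanded by 20 voxels per side (clipped at
   the image border after expansion).
3. **Crop.** All frames are cropped to the box and resampled to 96×96
   with bicubic interpolation (nearest-neighbour for masks); pixel spacing
   is rescaled by box-size/96. Box centers stay continuous and are only
   rasterized here.
4. **Myocardial segmentation.** A U-Net (sigmoid head) segments the
   cropped peak frame; the largest 4-connected component is kept. QC
   accepts only a "closed-loop" mask: a single 4-connected component whose
   complement, flood-filled from the border, leaves at least one enclosed
   hole. On failure the network is applied to frames within ±2 of the
   peak (closest first; at equal distance the later frame first, since
   contrast persists after the peak) and the first passing mask wins;
   if none passes the result is flagged, not raised.
5. **RV insertion points.** One U-Net per landmark (anterior, inferior)
   predicts a 4-class *action map* — for every pixel, the direction
   (left/right/up/down) toward the landmark. The class regions meet along
   two diagonals of slope ±1 through the landmark; after a 3×3 modal
   filter (suppresses isolated label errors, which would otherwise create
   spurious boundary pairs everywhere), boundary midpoints are fitted by
   least squares with the slopes fixed at −1 and +1, and the intersection
   is the landmark. A flagged class-centroid fallback covers degenerate
   maps. Exact ties in the map (|dr| = |dc|, including the landmark pixel)
   take the horizontal class — any fixed rule works; this one is
   documented and tested.
6. **Quantification.** The AIF is extracted by 4-connected region growing
   from the brightest peak-frame voxel inside the cavity enclosed by the
   myocardial mask (neighbours admitted at ≥ 0.9 × seed signal), averaged
   per frame and converted to concentration. Tissue curves are fitted with
   the two-compartment exchange model and aggregated into the AHA
   16-segment model (six 60° sectors on basal and mid slices, four 90° on
   apical, anchored at the anterior insertion point and proceeding toward
   the inferior point through the septum, angles measured about the mask
   centroid). MBF ≡ Fp.

Stage failures are recorded per series in a JSON manifest; the run never
prompts and never aborts sibling series.

## Signal and kinetic model

The phantom's signal model is linear in concentration, S(t) = S0(1 + γC(t))
plus optional Gaussian (or Rician) noise, which makes
signal-to-concentration conversion exactly invertible:
C(t) = (S − S0)/(γS0) with S0 the mean of the first 5 frames. Saturation
effects and dual-bolus AIF correction are out of scope; `aif_scale`
emulates a prebolus-derived rescaling if needed.

The 2CXM is

    vp dCp/dt = Fp (Ca − Cp) + PS (Ce − Cp)
    ve dCe/dt = PS (Cp − Ce),     Ct = vp Cp + ve Ce

with Fp (plasma flow ≡ MBF) and PS in mL/min/mL (converted to s⁻¹
internally; the factor 60 is the package's single unit constant), vp and
ve dimensionless volume fractions. The tissue curve is the convolution of
Ca with the model's bi-exponential impulse response, computed by an exact
piecewise-linear-input exponential recursion — so the only approximation
is linear interpolation of the sampled AIF between frames, and the result
matches a stiff ODE integration of the same interpolated input to ~1e−8.
Degenerate volumes use analytic limits (vp = 0: extraction-limited uptake
with E = Fp·PS/(Fp+PS); ve = 0 or PS = 0: one-compartment plasma kinetics).

Fitting is bounded multi-start nonlinear least squares (Fp ∈ [0,10],
vp ∈ [0,0.5], PS ∈ [0,5], ve ∈ [0,0.8]; five starts along the box
diagonal; a soft penalty keeps vp + ve ≤ 1; remaining starts are skipped
once one reaches a residual negligible against the data). This replaces
the hierarchical-Bayesian spatial inference used in the original clinical
work, which is a separate method in its own right. The consequence is
visible in noise studies: on single curves with 5% noise the *global*
optimum of the unregularized fit still has a median Fp error of ~15–25%
(verified by comparing truth-initialized and multi-start fits), because
vp/PS/ve compensate each other. An optional ridge penalty
(`ridge` ≈ 0.01) pulling the nuisance parameters toward physiologic
centers — never Fp itself — roughly halves that. Segment-mean curves
average this noise down and are well determined.

### Partial-volume guards

Quantification deliberately runs on the original-resolution voxels: the
segmentation is mapped back from the 96×96 crop grid to the scanner grid
(nearest-neighbour), because bicubic crop resampling smears the ~5–7×
brighter blood-pool signal into border myocardium and badly biases fits.
For the same reason the curves that feed the fit exclude likely
partial-volume voxels, identically in the automated and reference routes:
the mask is eroded by 1 voxel, voxels whose peak-frame signal exceeds
0.5 × the blood-pool level are dropped (endocardial spill-in), and voxels
whose enhancement is below 0.4 × the in-mask median are dropped
(epicardial spill-out into non-enhancing tissue). The AHA labels still
partition the full mask; a sector whose guarded set would be empty falls
back to its full voxel set. Without these guards, a ±1–2 px boundary
error turns rest MBF of ~1.0 into ~6.5.

The pipeline fits either per voxel (`fit_mode="voxel"`, producing
parameter maps) or one mean curve per AHA sector (`fit_mode="segment"`,
the default): the desk-scale experiment consumes only per-segment MBF, and
segment-mean curves are both better conditioned and ~100× cheaper.
Fitting a sector-mean of heterogeneous voxel curves carries a small
concave-averaging bias (a few percent low, largest at stress flows); the
guards and ridge add comparable-size systematic shifts. These cancel in
route-agreement comparisons (both routes share them) but mean that
absolute per-segment MBF can deviate up to ~10% from the generating truth
even without noise; with guards and ridge disabled the pure kinetics path
stays inside 10% per sector.

## Phantom

Anatomy per slice: an LV blood-pool disk (center jittered around the image
center), an annular myocardium, an RV crescent abutting the epicardium
across the septum, all inside an elliptical body. Slice levels scale the
LV cross-section (basal 1.0, mid 0.85, apical 0.7). Insertion points sit
on the epicardial boundary at configurable angles (defaults 240°/120° in
the convention row = c + R sinθ, col = c + R cosθ, ±8° subject jitter).

Dynamics: the RV pool follows a gamma-variate bolus
C(t) = scale·((t−t0)/(αβ))^α·exp(α−(t−t0)/β) (peak value `scale` at
t0+αβ); the LV pool follows the same family 3 frames later (the arterial
input, stress arriving earlier and peaking higher than rest); myocardial
voxels follow the 2CXM driven by the LV input with per-voxel parameters
drawn uniformly from condition-specific ranges — Fp 0.5–1.5 (rest) and
1.5–3.5 mL/min/mL (stress), bracketing clinically typical MBF; vp
0.03–0.10, PS 0.4–1.2/0.8–2.0, ve 0.15–0.35. The ground-truth peak frame
is the argmax of the mean noise-free LV-pool signal. Optional per-frame
random translation emulates breathing (off by default; truth records the
shifts and an intensity-based rigid registration utility is provided —
the validated motion-correction scheme of the clinical pipeline is a
separate method and out of scope).

Defaults follow the acquisition the pipeline targets where stated (256×256
matrix, 1.2×1.2 mm spacing, 3 slices, rest+stress); frame count and
interval are not pinned by the acquisition description, so 50 frames at
1 s are defaults, configurable. Two deliberately simple points: noise is
additive Gaussian at 2% of baseline (Rician optional) and there is no
dark-rim, k-space, or through-plane artefact model.

**What the phantom does not test:** real coil-shading, motion, saturation
nonlinearity, pathological perfusion defects, or anatomical variability
beyond disk/annulus geometry. Passing the desk-scale experiment shows the
pipeline's stages and their couplings are implemented correctly and learn
from data — it does not certify clinical performance.

## Training harness

All four networks train with Adam (default lr 1e−4), batch size 32, L2
weight 0.001 on convolution kernels only, dropout 0.5 on fully-connected
layers, on-the-fly augmentation (translation, rotation, scaling, intensity
gain, noise — identical transform applied to image and spatial labels),
and early stopping on a validation metric with patience 3000 iterations.
These recipe values are the `paper_train_config()` preset and the
dataclass defaults.

The `desk` preset scales the knobs a CPU cares about: learning rate 1e−3,
a few hundred iterations per stage, batch 8 for the U-Nets, batch 32 for
the CNNs, mild augmentation, channel widths 8/16/32/64 (CNN; FC width 64)
and base-8 depth-3 U-Nets, CNN input 64×64 (series are resampled to the
network's input size with bicubic interpolation, frame-wise). Channel
widths are configuration, not contract. The peak classifier's class
imbalance (one positive frame per series) is handled by sampling positives
and negatives at a 1:4 ratio per batch.

Loss functions: cross-entropy (peak classifier, action maps — per pixel),
MSE on normalized deltas (bounding box), soft Dice with ε = 1e−6
(segmentation; reduces to 1 − DSC on hard masks). Intensities are min-max
normalized to [0,1] over the whole series (not per frame), so inference is
invariant to global intensity scaling; a constant series maps to zero.

Because no deep-learning framework is part of the dependency set, the
networks run on a small numpy library (`perfusionkit.nn`) with manual
backpropagation; conv/pool/batch-norm backward passes are verified against
naive reference implementations in the test suite.

## Desk-scale experiment

`perfusionkit.experiment.run_desk_experiment(seed)` simulates 40/5/10
train/validation/test subjects (128 px, 32 frames — anatomy occupies the
same field-of-view fraction as the 256 px default), trains all four
networks with the desk preset, runs the automated pipeline on the 10 test
subjects, and scores: peak-frame MAE, box DSC (basal, rasterized boxes),
myocardial DSC on the original grid, insertion-point error in px and mm,
completion count, and per-segment MBF agreement (ICC(2,1), Bland–Altman
bias, through-origin slope and R²) between the automated route and
reference-label processing of the same series. Problem sizes were chosen
so the full study runs in minutes on one CPU. All randomness derives from
the single seed; phantoms are bit-stable and manifests byte-identical
across reruns.

## Statistics

Bland–Altman: bias = mean(x−y), LoA = bias ± 1.96·sd (sample sd), bias CI
via t, LoA CIs via the sd·√(3/n) normal approximation. ICC is fixed to
ICC(2,1) — two-way random effects, absolute agreement, single measure —
computed from the ANOVA decomposition with the standard F-based interval;
the form is stated because ICC variants differ numerically (the
implementation is cross-checked against an independent ANOVA-from-scratch
oracle and against `pingouin` in the tests). The through-origin R² uses
the no-intercept convention (total sum of squares about zero), stated
because no-intercept R² is not unique in the literature.

## Known limitations

- The linear signal model stands in for saturation-recovery signal
  physics; absolute concentrations are in arbitrary linear units.
- Bolus-arrival delay between AIF and tissue is not fitted by default (the
  phantom introduces none); `fit_2cxm(fit_delay=True)` adds a 0–10 s AIF
  shift parameter when needed.
- Voxelwise fitting is honest about its conditioning (see above); for
  per-voxel maps on noisy data the ridge flag is recommended.
- The action-map decoder assumes the two ±1 diagonals are visible inside
  the crop; landmarks within ~2 px of the border fall back to centroids.
- One detection CNN is trained across all slice levels; per-level models
  might do better but triple the training cost.
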
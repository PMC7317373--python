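"""Tracer-kinetic quantification: AIF extraction, the two-compartment
exchange model (2CXM), voxelwise/segmentwise fitting, and AHA 16-segment
aggregation.

Model
-----
The 2CXM describes contrast exchange between a plasma compartment (volume
fraction ``vp``, fed by plasma flow ``Fp``) and an interstitial compartment
(volume fraction ``ve``) across a barrier with permeability-surface-area
product ``PS``::

    vp dCp/dt = Fp (Ca - Cp) + PS (Ce - Cp)
    ve dCe/dt = PS (Cp - Ce)
    Ct        = vp Cp + ve Ce

``Fp`` and ``PS`` are carried in mL/min/mL externally and converted to s^-1
internally (division by 60, the only unit constant in the package).  ``Fp``
is the myocardial blood flow (MBF).

The tissue curve is the convolution of the arterial input ``Ca`` with the
model's bi-exponential impulse response; the convolution is evaluated with
an exact piecewise-linear-input exponential recursion, so the only
approximation is the linear interpolation of the sampled AIF between frames.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, optimize

from .core import ConcentrationCurve, KineticParams

SECONDS_PER_MINUTE = 60.0

#: fit box constraints: Fp, vp, PS, ve
FIT_BOUNDS_LOW = np.array([0.0, 0.0, 0.0, 0.0])
FIT_BOUNDS_HIGH = np.array([10.0, 0.5, 5.0, 0.8])

__all__ = [
    "solve_2cxm",
    "impulse_response_terms",
    "fit_2cxm",
    "FitResult",
    "signal_to_conc",
    "extract_aif",
    "aha_divide",
    "per_segment_mbf",
    "mpr",
    "exp_convolve",
]


def exp_convolve(lam: np.ndarray, f: np.ndarray, times: np.ndarray) -> np.ndarray:
    """Convolution ``y(t) = int_0^t exp(lam (t-s)) f(s) ds`` for piecewise-linear f.

    Exact for an input that is linear between samples.  ``lam`` may be any
    broadcastable shape; ``f`` is sampled on ``times`` along its last axis.
    Returns an array of shape ``broadcast(lam, f[..., 0]).shape + (len(times),)``.
    """
    times = np.asarray(times, dtype=np.float64)
    f = np.asarray(f, dtype=np.float64)
    lam = np.asarray(lam, dtype=np.float64)
    out_shape = np.broadcast_shapes(lam.shape, f.shape[:-1])
    n = times.shape[0]
    y = np.zeros(out_shape + (n,), dtype=np.float64)
    lam_b = np.broadcast_to(lam, out_shape)
    f_b = np.broadcast_to(f, out_shape + (n,))
    acc = np.zeros(out_shape, dtype=np.float64)
    for i in range(1, n):
        dt = times[i] - times[i - 1]
        z = lam_b * dt
        ez = np.exp(z)
        small = np.abs(z) < 1e-8
        zz = np.where(small, 1.0, z)  # avoid 0/0; overwritten below
        # int_0^dt e^{lam (dt-u)} du  and  int_0^dt e^{lam (dt-u)} (u/dt) du
        i0 = np.where(small, dt * (1.0 + z / 2.0), np.expm1(z) / (lam_b + small))
        i1 = np.where(
            small,
            dt * (0.5 + z / 3.0),
            (np.expm1(z) - zz) / (np.where(small, 1.0, lam_b**2) * dt),
        )
        f0 = f_b[..., i - 1]
        f1 = f_b[..., i]
        acc = acc * ez + f0 * i0 + (f1 - f0) * i1
        y[..., i] = acc
    return y


def impulse_response_terms(
    params: KineticParams,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Amplitudes and rates of the 2CXM impulse response ``h(t) = A e^{l1 t} + B e^{l2 t}``.

    Rates are in s^-1 (negative); amplitudes in s^-1.  Degenerate volumes
    (``vp == 0`` or ``ve == 0``) collapse to the analytic one-compartment
    limits with the second term zeroed.
    """
    Fp = np.asarray(params.Fp, dtype=np.float64)
    vp = np.asarray(params.vp, dtype=np.float64)
    PS = np.asarray(params.PS, dtype=np.float64)
    ve = np.asarray(params.ve, dtype=np.float64)
    Fp, vp, PS, ve = np.broadcast_arrays(Fp, vp, PS, ve)
    fp = Fp / SECONDS_PER_MINUTE
    ps = PS / SECONDS_PER_MINUTE

    A = np.zeros_like(fp)
    B = np.zeros_like(fp)
    l1 = np.zeros_like(fp)
    l2 = np.zeros_like(fp)

    general = (vp > 0) & (ve > 0) & (ps > 0) & (fp > 0)
    one_comp = (vp > 0) & (fp > 0) & ~general & ((ps == 0) | (ve == 0))
    uptake = (vp == 0) & (ve > 0) & (fp > 0) & (ps > 0)

    if np.any(general):
        a = (fp[general] + ps[general]) / vp[general]
        c = ps[general] / ve[general]
        b = ps[general] / vp[general]
        tr = -(a + c)
        det = fp[general] * ps[general] / (vp[general] * ve[general])
        disc = np.sqrt(np.maximum(tr**2 - 4.0 * det, 0.0))
        lam1 = (tr + disc) / 2.0
        lam2 = (tr - disc) / 2.0
        # h(t) = w expm(Mt) u, w = (vp, ve), u = (fp/vp, 0)
        # expm(Mt) = e^{l1 t}(M - l2 I)/(l1-l2) + e^{l2 t}(M - l1 I)/(l2-l1)
        # w (M - l I) u = fp (-a - l) + ve (ps/ve) (fp/vp) = fp (b + c ... )
        wMu = fp[general] * (-a) + ve[general] * (ps[general] / ve[general]) * (
            fp[general] / vp[general]
        )
        wu = fp[general]
        denom = np.where(np.abs(lam1 - lam2) < 1e-300, 1e-300, lam1 - lam2)
        A[general] = (wMu - lam2 * wu) / denom
        B[general] = -(wMu - lam1 * wu) / denom
        l1[general] = lam1
        l2[general] = lam2
    if np.any(one_comp):
        # no effective interstitial storage: plasma compartment alone
        A[one_comp] = fp[one_comp]
        l1[one_comp] = -fp[one_comp] / vp[one_comp]
    if np.any(uptake):
        # instantaneous plasma transit; extraction-limited uptake
        E = fp[uptake] * ps[uptake] / (fp[uptake] + ps[uptake])
        A[uptake] = E
        l1[uptake] = -E / ve[uptake]
    return A, B, l1, l2


def solve_2cxm(
    params: KineticParams,
    aif: ConcentrationCurve,
    times: np.ndarray | None = None,
) -> ConcentrationCurve:
    """Tissue concentration curve(s) predicted by the 2CXM for a sampled AIF.

    Parameter fields may be arrays; the returned values then carry those
    leading axes with time last.
    """
    if times is None:
        times = aif.times
    times = np.asarray(times, dtype=np.float64)
    if times.shape != aif.times.shape or not np.allclose(times, aif.times):
        ca = np.interp(times, aif.times, aif.values)
    else:
        ca = aif.values
    if not np.all(np.isfinite(ca)):
        raise ValueError("AIF values must be finite")
    A, B, l1, l2 = impulse_response_terms(params)
    ct = A[..., None] * exp_convolve(l1, ca, times)
    nonzero_b = np.any(B != 0)
    if nonzero_b:
        ct = ct + B[..., None] * exp_convolve(l2, ca, times)
    if ct.shape[:-1] == ():
        return ConcentrationCurve(times, ct.reshape(-1))
    return ConcentrationCurve(times, ct)


@dataclass
class FitResult:
    params: KineticParams
    residual_norm: float
    converged: bool
    n_starts: int
    delay_s: float = 0.0


def _impulse_terms_scalar(Fp: float, vp: float, PS: float, ve: float):
    """Scalar twin of :func:`impulse_response_terms` (kept in sync)."""
    fp = Fp / SECONDS_PER_MINUTE
    ps = PS / SECONDS_PER_MINUTE
    if fp <= 0:
        return 0.0, 0.0, 0.0, 0.0
    if vp > 0 and ve > 0 and ps > 0:
        a = (fp + ps) / vp
        c = ps / ve
        tr = -(a + c)
        det = fp * ps / (vp * ve)
        disc = np.sqrt(max(tr * tr - 4.0 * det, 0.0))
        lam1 = (tr + disc) / 2.0
        lam2 = (tr - disc) / 2.0
        wMu = fp * (-a) + ps * fp / vp
        denom = lam1 - lam2 if abs(lam1 - lam2) > 1e-300 else 1e-300
        A = (wMu - lam2 * fp) / denom
        B = -(wMu - lam1 * fp) / denom
        return A, B, lam1, lam2
    if vp > 0:  # no effective interstitial storage
        return fp, 0.0, -fp / vp, 0.0
    if ve > 0 and ps > 0:  # instantaneous plasma transit
        E = fp * ps / (fp + ps)
        return E, 0.0, -E / ve, 0.0
    return 0.0, 0.0, 0.0, 0.0


def _conv_exp_scalar(lam: float, ca: np.ndarray, dts: np.ndarray) -> np.ndarray:
    y = np.zeros_like(ca)
    acc = 0.0
    for i in range(1, len(ca)):
        dt = dts[i - 1]
        z = lam * dt
        if abs(z) < 1e-8:
            i0 = dt * (1.0 + z / 2.0)
            i1 = dt * (0.5 + z / 3.0)
            ez = 1.0 + z
        else:
            ez = np.exp(z)
            i0 = (ez - 1.0) / lam
            i1 = (ez - 1.0 - z) / (lam * lam * dt)
        acc = acc * ez + ca[i - 1] * i0 + (ca[i] - ca[i - 1]) * i1
        y[i] = acc
    return y


#: ridge prior centers and scales for (vp, PS, ve); Fp itself is never penalized
RIDGE_PRIOR_CENTER = np.array([0.06, 1.0, 0.25])
RIDGE_PRIOR_SCALE = np.array([0.06, 1.0, 0.25])


def _fit_residual(
    x: np.ndarray,
    ca: ConcentrationCurve,
    y: np.ndarray,
    times: np.ndarray,
    ridge: float = 0.0,
) -> np.ndarray:
    fp, vp, ps, ve = (max(float(v), 0.0) for v in x[:4])
    A, B, l1, l2 = _impulse_terms_scalar(fp, vp, ps, ve)
    dts = np.diff(times)
    ca_vals = ca.values
    if len(x) == 5:  # fitted bolus-arrival delay: shift the AIF later by tau
        tau = max(float(x[4]), 0.0)
        ca_vals = np.interp(times - tau, times, ca_vals, left=0.0)
    model = A * _conv_exp_scalar(l1, ca_vals, dts)
    if B != 0.0:
        model = model + B * _conv_exp_scalar(l2, ca_vals, dts)
    res = model - y
    excess = max(0.0, x[1] + x[3] - 1.0)
    parts = [res, [10.0 * excess * len(y)]]
    if ridge > 0.0:
        scale = np.sqrt(ridge * len(y)) * float(np.std(y))
        parts.append(scale * (x[1:4] - RIDGE_PRIOR_CENTER) / RIDGE_PRIOR_SCALE)
    return np.concatenate(parts)


def fit_2cxm(
    tissue: ConcentrationCurve,
    aif: ConcentrationCurve,
    n_starts: int = 5,
    bounds: tuple[np.ndarray, np.ndarray] | None = None,
    x0: np.ndarray | None = None,
    ridge: float = 0.0,
    fit_delay: bool = False,
) -> FitResult:
    """Bounded multi-start nonlinear least squares fit of the 2CXM.

    Starts are spread along the diagonal of the bounded parameter box
    (``n_starts`` points), plus ``x0`` if given; the best residual wins.
    Remaining starts are skipped once a start reaches a residual that is
    negligible against the data scale.

    ``ridge`` > 0 adds a quadratic penalty pulling (vp, PS, ve) toward
    physiologic prior centers (Fp, the quantity of interest, is never
    penalized).  The 2CXM is ill-conditioned on noisy single curves —
    compensation between the nuisance parameters inflates the variance of
    Fp — and a mild ridge (e.g. 0.01) stabilizes it at the cost of some
    bias in the nuisance parameters.  Off by default.

    ``fit_delay`` adds a bolus-arrival delay parameter (seconds, in
    [0, 10]) shifting the AIF later in time.  Off by default.
    """
    if not (np.all(np.isfinite(tissue.values)) and np.all(np.isfinite(aif.values))):
        raise ValueError("non-finite input curves")
    lo, hi = bounds if bounds is not None else (FIT_BOUNDS_LOW, FIT_BOUNDS_HIGH)
    if fit_delay and len(lo) == 4:
        lo = np.append(lo, 0.0)
        hi = np.append(hi, 10.0)
    times = tissue.times
    y = tissue.values
    starts = []
    if x0 is not None:
        x0 = np.asarray(x0, dtype=np.float64)
        if fit_delay and len(x0) == 4:
            x0 = np.append(x0, 0.0)
        starts.append(x0)
    fracs = np.linspace(0.1, 0.9, n_starts)
    for f in fracs:
        starts.append(lo + f * (hi - lo))
    good_enough = 1e-16 * max(float(np.sum(y**2)), 1e-12)
    best = None
    for s in starts:
        try:
            sol = optimize.least_squares(
                _fit_residual,
                np.clip(s, lo + 1e-9, hi - 1e-9),
                bounds=(lo, hi),
                args=(aif, y, times, ridge),
                x_scale=np.maximum(hi - lo, 1e-3),
                xtol=1e-11,
                ftol=1e-11,
                gtol=1e-11,
                max_nfev=300,
            )
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
        if best.cost <= good_enough:
            break
    if best is None:
        raise RuntimeError("2CXM fit failed for every start")
    x = best.x
    return FitResult(
        params=KineticParams(Fp=x[0], vp=x[1], PS=x[2], ve=x[3]),
        residual_norm=float(np.sqrt(2.0 * best.cost)),
        converged=bool(best.status > 0),
        n_starts=len(starts),
        delay_s=float(x[4]) if len(x) == 5 else 0.0,
    )


def signal_to_conc(
    signal: np.ndarray,
    times: np.ndarray | None = None,
    baseline_frames: int = 5,
    gamma: float = 1.0,
) -> np.ndarray | ConcentrationCurve:
    """Convert a signal-time curve to concentration with a linear signal model.

    ``C(t) = (S(t) - S0) / (gamma * S0)`` where ``S0`` is the mean of the
    first ``baseline_frames`` samples (computed along the last axis).
    Returns a bare array, or a :class:`ConcentrationCurve` when ``times``
    is given.
    """
    if baseline_frames < 1:
        raise ValueError("baseline_frames must be >= 1")
    s = np.asarray(signal, dtype=np.float64)
    s0 = s[..., :baseline_frames].mean(axis=-1, keepdims=True)
    if np.any(s0 <= 0):
        raise ValueError("baseline signal must be positive")
    conc = (s - s0) / (gamma * s0)
    if times is None:
        return conc
    return ConcentrationCurve(np.asarray(times, dtype=np.float64), conc)


_CROSS = ndimage.generate_binary_structure(2, 1)  # 4-connectivity


def extract_aif(
    cropped_series,
    endo_interior: np.ndarray,
    peak: int,
    grow_threshold: float = 0.9,
    baseline_frames: int = 5,
    gamma: float = 1.0,
) -> tuple[ConcentrationCurve, np.ndarray]:
    """Extract the arterial input function from the LV blood pool.

    Seeds at the brightest peak-frame voxel inside ``endo_interior`` (the
    cavity enclosed by the myocardial segmentation) and grows a 4-connected
    region admitting neighbours whose peak-frame signal is at least
    ``grow_threshold`` times the seed signal.  The AIF is the regional mean
    signal per frame converted to concentration.
    """
    endo_interior = np.asarray(endo_interior).astype(bool)
    if not endo_interior.any():
        raise ValueError("empty endocardial interior")
    peak_img = cropped_series.frames[peak]
    flat = np.where(endo_interior, peak_img, -np.inf)
    seed = np.unravel_index(int(np.argmax(flat)), flat.shape)
    thresh = grow_threshold * peak_img[seed]
    admissible = endo_interior & (peak_img >= thresh)
    labels, _ = ndimage.label(admissible, structure=_CROSS)
    region = labels == labels[seed]
    if region.sum() < 5:
        import warnings

        warnings.warn("AIF region smaller than 5 voxels", stacklevel=2)
    sig = cropped_series.frames[:, region].mean(axis=1)
    curve = signal_to_conc(sig, cropped_series.frame_times, baseline_frames, gamma)
    return curve, region


# --- AHA 16-segment model -------------------------------------------------

_SEGMENT_BASE = {"basal": (1, 6, 60.0), "mid": (7, 6, 60.0), "apical": (13, 4, 90.0)}


def aha_divide(
    myo_mask: np.ndarray,
    insertion_points: np.ndarray,
    slice_level: str,
) -> np.ndarray:
    """Partition a myocardial mask into AHA sectors anchored at the RV
    insertion points.

    Angles are measured about the mask centroid.  Sectors start at the
    anterior insertion point and proceed toward the inferior insertion point
    through the septum (the minor arc between the two points): basal slices
    get segments 1-6, mid 7-12 (six 60 degree sectors), apical 13-16 (four
    90 degree sectors).  The labels partition the mask exactly.
    """
    if slice_level not in _SEGMENT_BASE:
        raise ValueError(f"unknown slice level {slice_level!r}")
    myo_mask = np.asarray(myo_mask).astype(bool)
    pts = np.asarray(insertion_points, dtype=np.float64)
    if np.allclose(pts[0], pts[1]):
        raise ValueError("insertion points must be distinct")
    base, n_seg, width = _SEGMENT_BASE[slice_level]
    cr, cc = ndimage.center_of_mass(myo_mask)

    def angle(r, c):
        return np.degrees(np.arctan2(r - cr, c - cc)) % 360.0

    theta_a = angle(*pts[0])
    theta_i = angle(*pts[1])
    delta = (theta_i - theta_a) % 360.0
    direction = 1.0 if delta <= 180.0 else -1.0

    rr, cc_idx = np.nonzero(myo_mask)
    theta = angle(rr.astype(np.float64), cc_idx.astype(np.float64))
    u = ((theta - theta_a) * direction) % 360.0
    k = np.minimum((u // width).astype(int), n_seg - 1)
    labels = np.zeros(myo_mask.shape, dtype=np.int16)
    labels[rr, cc_idx] = base + k
    return labels


def mpr(stress_mbf, rest_mbf):
    """Myocardial perfusion reserve: stress MBF / rest MBF (elementwise)."""
    rest = np.asarray(rest_mbf, dtype=np.float64)
    stress = np.asarray(stress_mbf, dtype=np.float64)
    if np.any(rest <= 0):
        raise ValueError("rest MBF must be positive")
    out = stress / rest
    return float(out) if out.ndim == 0 else out


def per_segment_mbf(param_maps: KineticParams, labels: np.ndarray) -> pd.DataFrame:
    """Mean MBF (== Fp) per AHA segment.

    Returns a table with columns ``segment_id, mean_mbf_ml_min_ml,
    n_voxels``; segments with no voxels are absent rather than zero.
    """
    fp = np.asarray(param_maps.Fp, dtype=np.float64)
    labels = np.asarray(labels)
    rows = []
    for seg in np.unique(labels[labels > 0]):
        sel = labels == seg
        rows.append(
            {
                "segment_id": int(seg),
                "mean_mbf_ml_min_ml": float(fp[sel].mean()),
                "n_voxels": int(sel.sum()),
            }
        )
    return pd.DataFrame(rows, columns=["segment_id", "mean_mbf_ml_min_ml", "n_voxels"])
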
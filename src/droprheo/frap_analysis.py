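"""FRAP recovery quantification: trace extraction, normalization,
single-exponential recovery fits, and cross-condition comparisons.

The recovery model is I(t) = floor + (plateau - floor)(1 - e^(-k(t - t0))),
the minimal model consistent with reporting a half-time t_1/2 = ln2/k and a
mobile fraction (plateau - floor)/(1 - floor) on a pre-bleach-normalized
trace. Partial-droplet bleaches probe mixing inside the droplet; whole-droplet
bleaches probe exchange with the dilute phase (no exchange → no recovery).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "ROISpec",
    "FRAPTrace",
    "RecoveryFit",
    "extract_trace",
    "normalize_trace",
    "fit_recovery",
    "compare_halftimes",
    "compare_lengths",
]


@dataclass(frozen=True)
class ROISpec:
    """Bleach/measurement region, positioned relative to the droplet centroid.

    ``partial_disk`` needs ``radius`` (< droplet radius); ``half_droplet``
    takes a ``side``; ``whole_droplet`` covers the full droplet;
    ``reference`` is a fixed disk used for double normalization.
    """

    kind: str = "partial_disk"
    center: tuple[float, float] = (0.0, 0.0)   # μm, droplet-relative
    radius: float | None = None                # μm (partial_disk / reference)
    side: str | None = None                    # half_droplet

    def __post_init__(self) -> None:
        if self.kind not in ("partial_disk", "half_droplet",
                             "whole_droplet", "reference"):
            raise ValueError(f"unknown ROI kind: {self.kind!r}")
        if self.kind in ("partial_disk", "reference") and (
                self.radius is None or self.radius <= 0):
            raise ValueError(f"{self.kind} ROI requires a positive radius")


@dataclass
class FRAPTrace:
    """A (possibly normalized) fluorescence trace; times are 0 at bleach."""

    times: np.ndarray            # s, 0 at the bleach frame
    raw: np.ndarray
    normalized: np.ndarray | None = None
    prebleach_frames: int = 0
    bleach_frame: int | None = None
    bleach_found: bool = True

    def values(self) -> np.ndarray:
        return self.normalized if self.normalized is not None else self.raw


@dataclass
class RecoveryFit:
    """Single-exponential recovery parameters."""

    k: float                    # 1/s
    plateau: float
    bleach_floor: float
    rss: float
    n_points: int
    converged: bool = True
    mobile_fraction_flag: bool = False   # clipped by more than 0.05

    @property
    def t_half(self) -> float:
        return math.log(2.0) / self.k if self.k > 0 else float("nan")

    @property
    def mobile_fraction(self) -> float:
        denom = 1.0 - self.bleach_floor
        if denom <= 0:
            return float("nan")
        mf = (self.plateau - self.bleach_floor) / denom
        return float(min(1.0, max(0.0, mf)))

    def model(self, t: np.ndarray | float, t0: float = 0.0) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.bleach_floor + (self.plateau - self.bleach_floor) * (
            1.0 - np.exp(-self.k * (t - t0)))


def _roi_pixel_mask(roi: ROISpec, shape: tuple[int, int], pixel_size: float,
                    cx_um: float, cy_um: float,
                    droplet_radius_um: float) -> np.ndarray:
    h, w = shape
    xs = (np.arange(w) + 0.5) * pixel_size - cx_um
    ys = (np.arange(h) + 0.5) * pixel_size - cy_um
    xx = xs[None, :]
    yy = ys[:, None]
    rr2 = xx ** 2 + yy ** 2
    disk = rr2 <= droplet_radius_um ** 2
    ox, oy = roi.center
    if roi.kind in ("partial_disk", "reference"):
        return (xx - ox) ** 2 + (yy - oy) ** 2 <= roi.radius ** 2
    if roi.kind == "half_droplet":
        side = roi.side or "left"
        cond = {"left": xx <= 0, "right": xx >= 0,
                "top": yy <= 0, "bottom": yy >= 0}[side]
        return disk & cond
    if roi.kind == "whole_droplet":
        return disk
    raise ValueError(f"unsupported ROI kind: {roi.kind!r}")


def extract_trace(
    stack,
    droplet_track,
    roi: ROISpec,
    bleach_frame: int | None = None,
    min_drop_frac: float = 0.15,
    subtract_background: bool = True,
) -> FRAPTrace:
    """Mean ROI intensity per frame, with the ROI following the droplet.

    The droplet centroid is taken from the track observation in each frame
    (carried forward through frames where the droplet was not segmented, e.g.
    right after a deep bleach). With ``subtract_background`` (default) the
    per-frame median intensity outside the droplet is subtracted, so the
    normalized floor and plateau refer to droplet fluorescence rather than
    camera offset. The bleach frame is auto-detected as the largest
    single-frame fractional intensity drop unless given; a largest drop below
    ``min_drop_frac`` flags "no bleach found". For ``partial_disk`` ROIs an
    ROI leaving the droplet raises an error naming the frame.
    """
    T = stack.n_frames
    # per-frame centroid and radius, carried forward over gaps
    cents = np.empty((T, 2))
    radii = np.empty(T)
    obs0 = droplet_track.observations[0]
    cx, cy, r = obs0.x_um, obs0.y_um, obs0.radius_um
    for t in range(T):
        o = droplet_track.observation_at(t)
        if o is not None:
            cx, cy, r = o.x_um, o.y_um, o.radius_um
        cents[t] = (cx, cy)
        radii[t] = r

    raw = np.empty(T)
    for t in range(T):
        if roi.kind == "partial_disk":
            ox, oy = roi.center
            if math.hypot(ox, oy) + roi.radius > radii[t] + 1e-9:
                raise ValueError(
                    f"ROI exits the droplet at frame {t}: offset+radius "
                    f"{math.hypot(ox, oy) + roi.radius:.2f} μm > droplet "
                    f"radius {radii[t]:.2f} μm")
        mask = _roi_pixel_mask(roi, stack.shape, stack.pixel_size,
                               cents[t, 0], cents[t, 1], radii[t])
        if not mask.any():
            raise ValueError(f"empty ROI at frame {t}")
        val = float(stack.frames[t][mask].mean())
        if subtract_background:
            bg_mask = ~_roi_pixel_mask(
                ROISpec(kind="reference", radius=radii[t] + 1.0),
                stack.shape, stack.pixel_size,
                cents[t, 0], cents[t, 1], radii[t])
            if bg_mask.any():
                val -= float(np.median(stack.frames[t][bg_mask]))
        raw[t] = val

    found = True
    if bleach_frame is None:
        prev = raw[:-1]
        frac_drop = np.where(prev > 0, (prev - raw[1:]) / prev, 0.0)
        bleach_frame = int(np.argmax(frac_drop)) + 1
        if frac_drop.max() < min_drop_frac:
            found = False
    times = (np.arange(T) - bleach_frame) * stack.frame_interval
    return FRAPTrace(times=times, raw=raw, prebleach_frames=bleach_frame,
                     bleach_frame=bleach_frame, bleach_found=found)


def normalize_trace(
    trace: FRAPTrace,
    prebleach_frames: int | None = None,
    reference: FRAPTrace | None = None,
) -> FRAPTrace:
    """Normalize to the mean pre-bleach intensity (the convention used for
    condensate FRAP quantification).

    With a reference trace, double normalization corrects acquisition
    photobleaching: N(t) = [I(t)/I_ref(t)] · [mean(I_ref,pre)/mean(I_pre)].
    Normalizing an already-normalized trace is the identity.
    """
    npre = prebleach_frames if prebleach_frames is not None \
        else trace.prebleach_frames
    if npre < 2:
        raise ValueError("need at least 2 pre-bleach frames")
    src = trace.values()
    pre_mean = float(np.mean(src[:npre]))
    if pre_mean == 0:
        raise ValueError("zero pre-bleach mean intensity")
    if reference is not None:
        ref = reference.values()
        if np.any(ref == 0):
            raise ValueError("reference trace contains zeros")
        ref_pre = float(np.mean(ref[:npre]))
        norm = (src / ref) * (ref_pre / pre_mean)
    else:
        norm = src / pre_mean
    return replace(trace, normalized=norm, prebleach_frames=npre)


def fit_recovery(trace: FRAPTrace, t0: float = 0.0) -> RecoveryFit:
    """Least-squares single-exponential recovery fit for t >= t0.

    Initialization: floor from the first post-bleach point, plateau from the
    last point, rate from the empirical time to half recovery (fallback:
    quarter of the post-bleach span). Non-convergence yields a flagged fit
    with NaN parameters rather than an exception.
    """
    if trace.normalized is None:
        raise ValueError("trace must be normalized before fitting")
    t = np.asarray(trace.times, dtype=float)
    y = np.asarray(trace.normalized, dtype=float)
    post = t >= t0
    tp, yp = t[post], y[post]
    if tp.size < 8:
        raise ValueError("need at least 8 post-bleach points")

    floor0 = float(yp[0])
    plateau0 = float(yp[-1])
    half_level = floor0 + 0.5 * (plateau0 - floor0)
    above = np.nonzero(yp >= half_level)[0]
    span = tp[-1] - tp[0]
    if plateau0 > floor0 and above.size and tp[above[0]] > tp[0]:
        k0 = math.log(2.0) / (tp[above[0]] - tp[0])
    else:
        k0 = math.log(2.0) / max(span / 4.0, 1e-6)

    def model(tt, k, plateau, floor):
        return floor + (plateau - floor) * (1.0 - np.exp(-k * (tt - t0)))

    try:
        popt, _ = curve_fit(
            model, tp, yp, p0=[k0, plateau0, floor0],
            bounds=([1e-9, -0.5, -0.5], [np.inf, 2.0, 2.0]), maxfev=20000)
        k, plateau, floor = (float(v) for v in popt)
        resid = yp - model(tp, *popt)
        rss = float(resid @ resid)
        converged = True
    except RuntimeError:
        k = plateau = floor = float("nan")
        rss = float("nan")
        converged = False

    flag = False
    if converged and (1.0 - floor) > 0:
        mf_raw = (plateau - floor) / (1.0 - floor)
        flag = mf_raw < -0.05 or mf_raw > 1.05
    return RecoveryFit(k=k, plateau=plateau, bleach_floor=floor, rss=rss,
                       n_points=int(tp.size), converged=converged,
                       mobile_fraction_flag=flag)


def compare_halftimes(
    fits_by_condition: Mapping[str, Sequence[RecoveryFit]],
    n_boot: int = 2000,
    seed: int = 0,
    ci: float = 0.95,
) -> pd.DataFrame:
    """Pairwise fold-changes of mean t_1/2 with bootstrap CIs.

    Each condition needs >= 3 fits; fold(A, B) = mean t_half(A) /
    mean t_half(B), with a percentile bootstrap over replicate fits.
    """
    for name, fits in fits_by_condition.items():
        if len(fits) < 3:
            raise ValueError(f"condition {name!r} has fewer than 3 fits")
    rng = np.random.default_rng(seed)
    halves = {name: np.array([f.t_half for f in fits])
              for name, fits in fits_by_condition.items()}
    names = list(halves)
    lo_q, hi_q = 100 * (1 - ci) / 2, 100 * (1 + ci) / 2
    rows = []
    for a in names:
        for b in names:
            if a == b:
                continue
            fold = float(halves[a].mean() / halves[b].mean())
            boots = np.empty(n_boot)
            for i in range(n_boot):
                ra = rng.choice(halves[a], size=halves[a].size)
                rb = rng.choice(halves[b], size=halves[b].size)
                boots[i] = ra.mean() / rb.mean()
            lo, hi = np.percentile(boots, [lo_q, hi_q])
            rows.append({"condition_a": a, "condition_b": b,
                         "t_half_a_s": float(halves[a].mean()),
                         "t_half_b_s": float(halves[b].mean()),
                         "fold": fold,
                         "ci_low": float(lo), "ci_high": float(hi)})
    return pd.DataFrame(rows)


def compare_lengths(
    fits_by_length: Mapping[int, RecoveryFit],
    readout_time_s: float,
    tol: float = 0.01,
) -> dict:
    """Monotonicity of recovery versus polymer length.

    Evaluates each condition's fitted recovery at a fixed post-bleach readout
    time and reports whether recovery decreases monotonically as length
    increases (longer chromatin → more limited recovery), increases, or is
    non-monotone (within ``tol``).
    """
    lengths = sorted(fits_by_length)
    levels = {L: float(fits_by_length[L].model(readout_time_s))
              for L in lengths}
    vals = [levels[L] for L in lengths]
    diffs = np.diff(vals)
    if np.all(diffs < -tol):
        verdict = "monotone-decreasing"
    elif np.all(diffs > tol):
        verdict = "monotone-increasing"
    else:
        verdict = "non-monotone"
    return {"lengths": lengths, "recovery_at_readout": levels,
            "readout_time_s": readout_time_s, "verdict": verdict}
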
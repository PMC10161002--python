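"""Coalescence rheology: exponential aspect-ratio relaxation fits, the
relaxation-time-versus-length-scale regression yielding the inverse capillary
velocity (η/γ), and volume-conservation checks.

For a simple fluid the relaxation time of a coalescing droplet pair scales
with its size, τ ≈ (η/γ)·l; the aspect ratio of the fusing pair decays as
AR(t) = 1 + (AR_init − 1)·e^(−t/τ). Regressing τ against l over many fusion
events gives the inverse capillary velocity as the slope. The length scale l
used here is the sum of the pre-fusion diameters (the quantity plotted in
coalescence assays), and the regression is ordinary least squares with a free
intercept — the intercept absorbs detection-onset latency while the slope is
the reported material property.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.stats import linregress

from .detection_tracking import FusionEvent, welch_t_test

__all__ = [
    "RelaxationFit",
    "CapillaryFit",
    "fit_relaxation",
    "fit_icv",
    "volume_ratio",
    "compare_icv",
    "analyze_events",
]

# measurement noise can push AR slightly below 1; values below 1-AR_NOISE_TOL
# violate the model's domain outright
AR_NOISE_TOL = 0.02


@dataclass
class RelaxationFit:
    """Exponential AR(t) relaxation parameters for one fusion event."""

    tau: float                 # s
    ar_init_fit: float
    residual_sum_squares: float
    r_squared: float
    n_points: int
    converged: bool = True


@dataclass
class CapillaryFit:
    """τ-versus-l regression; the slope is the inverse capillary velocity."""

    slope_icv: float           # s/μm  (= η/γ)
    slope_se: float
    intercept: float           # s
    n_events: int
    r_squared: float
    taus: np.ndarray | None = None
    lengths: np.ndarray | None = None


def fit_relaxation(times: Sequence[float],
                   ar_values: Sequence[float]) -> RelaxationFit:
    """Nonlinear least squares of AR(t) = 1 + (AR_init − 1)·e^(−t/τ).

    Initialization: AR_init from the first point, τ from the time at which
    AR − 1 first falls below (AR_init − 1)/e (fallback: half the series
    span). The model is anchored at the first time point, so a uniform time
    shift leaves τ unchanged. A flat series (AR ≈ 1 throughout) has no
    relaxation to fit and is returned with ``converged=False``.
    """
    t = np.asarray(times, dtype=float)
    ar = np.asarray(ar_values, dtype=float)
    if t.size != ar.size:
        raise ValueError("times and ar_values must have equal length")
    if t.size < 5:
        raise ValueError("need at least 5 points to fit the relaxation")
    if np.any(ar < 1.0 - AR_NOISE_TOL):
        raise ValueError("aspect ratios below 1 beyond noise tolerance")
    ar = np.clip(ar, 1.0, None)

    if ar.max() - 1.0 < AR_NOISE_TOL:
        return RelaxationFit(tau=float("nan"), ar_init_fit=float("nan"),
                             residual_sum_squares=float("nan"),
                             r_squared=float("nan"),
                             n_points=int(t.size), converged=False)

    t0 = float(t[0])
    ar0 = float(ar[0])
    excess0 = max(ar0 - 1.0, AR_NOISE_TOL)
    below = np.nonzero(ar - 1.0 < excess0 / math.e)[0]
    span = float(t[-1] - t0)
    if below.size and t[below[0]] > t0:
        tau0 = float(t[below[0]] - t0)
    else:
        tau0 = max(span / 2.0, 1e-6)

    def model(tt, tau, ar_init):
        return 1.0 + (ar_init - 1.0) * np.exp(-(tt - t0) / tau)

    try:
        popt, _ = curve_fit(model, t, ar, p0=[tau0, max(ar0, 1.0 + 1e-6)],
                            bounds=([1e-12, 1.0], [np.inf, np.inf]),
                            maxfev=20000)
        tau, ar_init = (float(v) for v in popt)
        resid = ar - model(t, *popt)
        rss = float(resid @ resid)
        ss_tot = float(np.sum((ar - ar.mean()) ** 2))
        r2 = 1.0 - rss / ss_tot if ss_tot > 0 else float("nan")
        return RelaxationFit(tau=tau, ar_init_fit=ar_init,
                             residual_sum_squares=rss, r_squared=r2,
                             n_points=int(t.size), converged=tau > 0)
    except RuntimeError:
        return RelaxationFit(tau=float("nan"), ar_init_fit=float("nan"),
                             residual_sum_squares=float("nan"),
                             r_squared=float("nan"),
                             n_points=int(t.size), converged=False)


def fit_icv(taus: Sequence[float], lengths: Sequence[float],
            r_squared: Sequence[float] | None = None,
            r2_min: float = 0.8) -> CapillaryFit:
    """OLS regression τ = slope·l + intercept over fusion events.

    Events whose relaxation fit has r² below ``r2_min`` (when provided) are
    excluded. The slope is the inverse capillary velocity η/γ in s/μm.
    """
    taus = np.asarray(taus, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    if taus.shape != lengths.shape:
        raise ValueError("taus and lengths must have equal length")
    keep = np.isfinite(taus) & np.isfinite(lengths)
    if r_squared is not None:
        r2 = np.asarray(r_squared, dtype=float)
        keep &= np.isfinite(r2) & (r2 >= r2_min)
    taus, lengths = taus[keep], lengths[keep]
    if taus.size < 2:
        raise ValueError(
            f"fewer than 2 events survive the relaxation-fit filter "
            f"(r2 >= {r2_min}); got {taus.size}")
    res = linregress(lengths, taus)
    se = float(res.stderr) if np.isfinite(res.stderr) else 0.0
    return CapillaryFit(slope_icv=float(res.slope), slope_se=se,
                        intercept=float(res.intercept),
                        n_events=int(taus.size),
                        r_squared=float(res.rvalue ** 2),
                        taus=taus, lengths=lengths)


def volume_ratio(event: FusionEvent) -> float:
    """Post/pre volume ratio of a fusion event, spheres inferred from
    equivalent diameters: post³ / (d1³ + d2³). Exactly 1 for a
    volume-conserving coalescence."""
    if not (event.post_diameter_um > 0
            and math.isfinite(event.post_diameter_um)):
        raise ValueError("post-relaxation diameter unavailable")
    return float(event.post_diameter_um ** 3
                 / (event.d1_um ** 3 + event.d2_um ** 3))


def analyze_events(events: Sequence[FusionEvent],
                   r2_min: float = 0.8) -> tuple[pd.DataFrame, CapillaryFit]:
    """Fit every event's relaxation, filter, and regress τ against l.

    Returns the per-event table (tau_s, ar_init, r2, l_um, volume_ratio,
    converged) and the capillary fit over surviving events.
    """
    rows = []
    for idx, ev in enumerate(events):
        fit = fit_relaxation(ev.ar_times_s, ev.ar_values)
        rows.append({
            "event_id": idx,   # sequential over the pooled panel
            "onset_frame": ev.onset_frame,
            "d1_um": ev.d1_um, "d2_um": ev.d2_um,
            "l_um": ev.length_scale_um,
            "tau_s": fit.tau, "ar_init": fit.ar_init_fit,
            "r2": fit.r_squared, "converged": fit.converged,
            "volume_ratio": volume_ratio(ev),
        })
    table = pd.DataFrame(rows)
    conv = table[table["converged"]]
    cap = fit_icv(conv["tau_s"].to_numpy(), conv["l_um"].to_numpy(),
                  r_squared=conv["r2"].to_numpy(), r2_min=r2_min)
    return table, cap


def compare_icv(
        fits_by_condition: Mapping[str, Sequence[CapillaryFit]]
) -> pd.DataFrame:
    """Per-condition mean ± SD of replicate slopes plus pairwise Welch tests.

    With a single replicate per condition the SD is 0 and pairwise tests are
    omitted for that condition (a t-test needs n >= 2 per group).
    """
    summary = []
    slopes = {}
    for name, fits in fits_by_condition.items():
        if len(fits) < 1:
            raise ValueError(f"condition {name!r} has no capillary fits")
        s = np.array([f.slope_icv for f in fits])
        slopes[name] = s
        summary.append({"condition": name, "mean_icv": float(s.mean()),
                        "sd_icv": float(s.std(ddof=1)) if s.size > 1 else 0.0,
                        "n_replicates": int(s.size),
                        "comparison": "", "p_value": float("nan")})
    table = pd.DataFrame(summary)
    rows = []
    for a, b in combinations(slopes, 2):
        sa, sb = slopes[a], slopes[b]
        if sa.size < 2 or sb.size < 2:
            continue
        if sa.size == sb.size and np.allclose(sa, sb):
            t, df, p = 0.0, float(sa.size + sb.size - 2), 1.0
        else:
            t, df, p = welch_t_test(sa, sb)
        rows.append({"condition": f"{a} vs {b}", "mean_icv": float("nan"),
                     "sd_icv": float("nan"), "n_replicates": 0,
                     "comparison": f"{a}/{b}", "p_value": p})
    if rows:
        table = pd.concat([table, pd.DataFrame(rows)], ignore_index=True)
    return table
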
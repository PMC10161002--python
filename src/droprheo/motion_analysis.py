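"""Condensate mobility: trajectory windows, ensemble mean-squared
displacement, diffusion-coefficient and anomalous-exponent fits, and
mobility classification.

Centroids are 2D projections, so the diffusive scaling is MSD = 4·D·τ_lag.
Overlapping sub-trajectory windows reproduce the many-trajectories-per-droplet
accounting used in condensate tracking studies; the SE over windows
understates their correlation, which is the common practice this follows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .detection_tracking import Track

__all__ = [
    "MSDCurve",
    "DiffusionFit",
    "extract_windows",
    "compute_msd",
    "fit_diffusion",
    "filter_by_diameter",
    "classify_mobility",
]


@dataclass
class MSDCurve:
    """Ensemble MSD over lag time, with SE over trajectory windows."""

    lags_s: np.ndarray
    msd_um2: np.ndarray
    se_um2: np.ndarray
    n_windows: int


@dataclass
class DiffusionFit:
    """Linear MSD fit (D, localization-noise offset) plus the log-log
    anomalous exponent over the same lag range."""

    D: float                    # μm²/s
    D_se: float
    offset_um2: float
    alpha: float                # NaN when undefined (non-positive MSD)
    fit_lag_range_s: tuple[float, float]


def extract_windows(track: Track, window_length_frames: int,
                    stride_frames: int = 1) -> list[np.ndarray]:
    """Overlapping fixed-length position windows taken every ``stride``
    frames; windows crossing frame gaps are dropped."""
    if window_length_frames < 4:
        raise ValueError("window_length_frames must be >= 4")
    if stride_frames < 1:
        raise ValueError("stride_frames must be >= 1")
    frames = track.frames()
    pos = track.positions()
    windows = []
    for start in range(0, len(frames) - window_length_frames + 1,
                       stride_frames):
        f = frames[start:start + window_length_frames]
        if f[-1] - f[0] != window_length_frames - 1:   # gap inside window
            continue
        windows.append(pos[start:start + window_length_frames])
    return windows


def compute_msd(windows: Sequence[np.ndarray], max_lag_frames: int,
                frame_interval: float) -> MSDCurve:
    """Time-averaged MSD per window, then ensemble mean and SE over windows.

    For each window and lag k: mean over t of |r(t+k) − r(t)|² (2D).
    """
    if len(windows) == 0:
        raise ValueError("need at least one window")
    wlen = len(windows[0])
    if max_lag_frames >= wlen:
        raise ValueError("max_lag_frames must be < window length")
    per_window = np.empty((len(windows), max_lag_frames))
    for i, w in enumerate(windows):
        w = np.asarray(w, dtype=float)
        for k in range(1, max_lag_frames + 1):
            d = w[k:] - w[:-k]
            per_window[i, k - 1] = np.mean(np.sum(d * d, axis=1))
    msd = per_window.mean(axis=0)
    if len(windows) > 1:
        se = per_window.std(axis=0, ddof=1) / math.sqrt(len(windows))
    else:
        se = np.zeros(max_lag_frames)
    lags = np.arange(1, max_lag_frames + 1) * frame_interval
    return MSDCurve(lags_s=lags, msd_um2=msd, se_um2=se,
                    n_windows=len(windows))


def fit_diffusion(curve: MSDCurve, n_fit_lags: int = 5) -> DiffusionFit:
    """Weighted linear fit MSD = 4·D·lag + offset over the first lags.

    Weights are 1/SE² when all SEs are positive, otherwise unweighted. The
    anomalous exponent alpha is the unweighted log-log slope over the same
    range and is NaN when any MSD there is non-positive (D is still fit).
    The free intercept absorbs the ~4σ_loc² localization-noise offset.
    """
    if n_fit_lags < 2:
        raise ValueError("n_fit_lags must be >= 2")
    if n_fit_lags > curve.lags_s.size:
        raise ValueError("n_fit_lags exceeds available lags")
    x = curve.lags_s[:n_fit_lags]
    y = curve.msd_um2[:n_fit_lags]
    se = curve.se_um2[:n_fit_lags]
    w = 1.0 / se ** 2 if np.all(se > 0) else np.ones_like(x)

    X = np.column_stack([x, np.ones_like(x)])
    W = np.diag(w)
    xtwx = X.T @ W @ X
    beta = np.linalg.solve(xtwx, X.T @ W @ y)
    slope, offset = float(beta[0]), float(beta[1])
    resid = y - X @ beta
    dof = max(x.size - 2, 1)
    sigma2 = float(resid @ (w * resid)) / dof
    cov = sigma2 * np.linalg.inv(xtwx)
    slope_se = math.sqrt(max(cov[0, 0], 0.0))

    if np.all(y > 0):
        a, _ = np.polyfit(np.log(x), np.log(y), 1)
        alpha = float(a)
    else:
        alpha = float("nan")
    return DiffusionFit(D=slope / 4.0, D_se=slope_se / 4.0,
                        offset_um2=offset, alpha=alpha,
                        fit_lag_range_s=(float(x[0]), float(x[-1])))


def filter_by_diameter(tracks: Sequence[Track], d_min_um: float,
                       d_max_um: float) -> list[Track]:
    """Keep tracks whose median equivalent diameter lies in [d_min, d_max]
    (e.g. the 4–8 μm band used for condensate diffusion estimates)."""
    return [t for t in tracks
            if d_min_um <= t.median_diameter() <= d_max_um]


def classify_mobility(fit: DiffusionFit,
                      alpha_band: tuple[float, float] = (0.9, 1.1),
                      d_floor: float = 1e-3) -> tuple[str, bool]:
    """Label a diffusion fit as diffusive / subdiffusive / immobile.

    Immobile when D < d_floor (μm²/s); otherwise diffusive when alpha lies in
    ``alpha_band``. An undefined alpha with mobile D is labelled subdiffusive
    with the returned flag set.
    """
    if fit.D < d_floor:
        return "immobile", False
    if math.isnan(fit.alpha):
        return "subdiffusive", True
    lo, hi = alpha_band
    if lo <= fit.alpha <= hi:
        return "diffusive", False
    return "subdiffusive", False
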
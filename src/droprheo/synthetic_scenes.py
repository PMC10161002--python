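"""Ground-truth-annotated synthetic microscopy movies of biomolecular
condensates.

Every generator renders fluorescence-like 2D frames through a common optics
model (Gaussian point-spread blur, Poisson shot noise scaled by an expected
photon count, Gaussian read noise, uniform background) and returns the exact
physical ground truth alongside the stack, so the downstream measurement
pipeline can be validated without real data.

Physical models
---------------
* Fusion: after coalescence onset the projected droplet is an ellipse whose
  aspect ratio relaxes as AR(t) = 1 + (AR_init - 1) e^(-t/τ) with
  τ = (η/γ)(d1 + d2), while the 3D spheroid volume stays fixed at
  (π/6)(d1³ + d2³). Axes follow from volume conservation:
  b = (d_final³ / AR)^(1/3), a = AR·b, so that a·b² = d_final³ exactly.
* Brownian motion: per-frame displacements are independent zero-mean
  Gaussians with variance 2·D·Δt per axis; an optional confinement radius
  reflects excursions about each droplet's anchor point.
* FRAP: two species on a disk lattice — a mobile fraction diffusing at D_in
  with a reflecting (no-flux) boundary and an immobile static fraction.
  Bleaching multiplies both species inside the ROI by (1 - bleach_depth).
  With exchange_rate > 0 the mobile species relaxes toward the unbleached
  dilute-phase reservoir. The explicit scheme is sub-stepped automatically to
  keep D·dt/dx² ≤ 0.25.

Droplets are rendered as flat-top ellipses on a 4× supersampled grid and
block-averaged down, so segmentation can recover diameters at the few-percent
level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .detection_tracking import ImageStack
from .frap_analysis import ROISpec

__all__ = [
    "OpticsModel",
    "FusionGroundTruth",
    "MotionGroundTruth",
    "FrapGroundTruth",
    "photon_scale_for_snr",
    "render_frame",
    "simulate_fusion_movie",
    "simulate_fusion_panel",
    "simulate_brownian_movie",
    "simulate_frap_movie",
    "simulate_dissolution_movie",
    "simulate_condition_grid",
]

_SUPERSAMPLE = 4  # sub-pixel rendering factor


@dataclass(frozen=True)
class OpticsModel:
    """Imaging model: calibration, PSF blur and noise strengths.

    ``photon_scale`` is the expected photon count per unit of intensity; shot
    noise SD at intensity I is sqrt(I/photon_scale) in intensity units, so a
    larger value means cleaner images. ``read_noise_sigma`` and
    ``background_level`` are in intensity units.
    """

    pixel_size: float                 # μm / pixel
    blur_sigma: float = 1.0           # pixels
    background_level: float = 0.1
    photon_scale: float = 5000.0
    read_noise_sigma: float = 0.0

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.blur_sigma < 0:
            raise ValueError("blur_sigma must be non-negative")
        if self.photon_scale <= 0:
            raise ValueError("photon_scale must be positive")


def photon_scale_for_snr(snr: float, droplet_intensity: float = 1.0,
                         background: float = 0.1,
                         read_noise_sigma: float = 0.0) -> float:
    """Photon scale giving a target peak SNR.

    SNR is defined as droplet contrast over the shot+read noise SD at the
    droplet: snr = I·√p / sqrt(I + b + p·σ_read²).
    """
    if snr <= 0:
        raise ValueError("snr must be positive")
    total = droplet_intensity + background
    # solve I²·p = snr²·(total + p σr²)  →  p (I² − snr² σr²) = snr² total
    denom = droplet_intensity ** 2 - snr ** 2 * read_noise_sigma ** 2
    if denom <= 0:
        raise ValueError("read noise too large for the requested SNR")
    return snr ** 2 * total / denom


def _apply_noise(ideal: np.ndarray, optics: OpticsModel,
                 rng: np.random.Generator | None) -> np.ndarray:
    """Blur + background + (optional) Poisson shot noise and read noise."""
    img = gaussian_filter(ideal, optics.blur_sigma) + optics.background_level
    if rng is None:
        return img
    counts = rng.poisson(np.clip(img, 0, None) * optics.photon_scale)
    img = counts / optics.photon_scale
    if optics.read_noise_sigma > 0:
        img = img + rng.normal(0.0, optics.read_noise_sigma, img.shape)
    return np.clip(img, 0.0, None)


def _draw_ellipses(
    droplets: Sequence[tuple],
    optics: OpticsModel,
    shape: tuple[int, int],
) -> np.ndarray:
    """Flat-top ellipse projection on a supersampled grid, block-averaged.

    ``droplets``: (center_xy_um, (major_um, minor_um), orientation_rad,
    intensity) tuples; axes are full lengths (diameters). Overlapping
    droplets take the maximum intensity (a uniform dense phase does not
    double its density where projections overlap).
    """
    h, w = shape
    ss = _SUPERSAMPLE
    px = optics.pixel_size / ss
    canvas = np.zeros((h * ss, w * ss))
    w_um, h_um = w * optics.pixel_size, h * optics.pixel_size

    for (cx, cy), (major, minor), theta, intensity in droplets:
        if major <= 0 or minor <= 0:
            raise ValueError("ellipse axes must be positive")
        if intensity < 0:
            raise ValueError("intensity must be non-negative")
        sa, sb = major / 2.0, minor / 2.0
        ext = max(sa, sb)
        if not (0 <= cx - ext and cx + ext <= w_um
                and 0 <= cy - ext and cy + ext <= h_um):
            raise ValueError(
                f"droplet at ({cx:.2f}, {cy:.2f}) μm with extent "
                f"{ext:.2f} μm does not fit the {w_um:.1f}×{h_um:.1f} μm field")
        if intensity == 0:
            continue
        # patch bounds in supersampled pixels
        c0 = max(int((cx - ext) / px) - 1, 0)
        c1 = min(int((cx + ext) / px) + 2, w * ss)
        r0 = max(int((cy - ext) / px) - 1, 0)
        r1 = min(int((cy + ext) / px) + 2, h * ss)
        cols = (np.arange(c0, c1) + 0.5) * px - cx
        rows = (np.arange(r0, r1) + 0.5) * px - cy
        dx = cols[None, :]
        dy = rows[:, None]
        ct, st = math.cos(theta), math.sin(theta)
        u = (dx * ct + dy * st) / sa
        v = (-dx * st + dy * ct) / sb
        mask = (u * u + v * v) <= 1.0
        patch = canvas[r0:r1, c0:c1]
        np.maximum(patch, mask * intensity, out=patch)

    return canvas.reshape(h, ss, w, ss).mean(axis=(1, 3))


def render_frame(
    droplets: Sequence[tuple],
    optics: OpticsModel,
    shape: tuple[int, int],
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Render one grayscale frame.

    The ideal flat-top projection of the droplets is blurred by the PSF,
    offset by the background, and (when an RNG is given) corrupted by Poisson
    shot noise at ``photon_scale`` expected photons per intensity unit plus
    Gaussian read noise. Deterministic given the RNG state.
    """
    ideal = _draw_ellipses(droplets, optics, shape)
    return _apply_noise(ideal, optics, rng)


# ---------------------------------------------------------------------------
# fusion
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FusionGroundTruth:
    """Exact parameters of a simulated two-droplet coalescence."""

    d1: float                 # pre-fusion diameter, μm
    d2: float                 # pre-fusion diameter, μm
    icv_true: float           # inverse capillary velocity η/γ, s/μm
    ar_init_true: float = 0.0
    onset_frame: int = 0

    def __post_init__(self) -> None:
        if self.d1 <= 0 or self.d2 <= 0:
            raise ValueError("pre-fusion diameters must be positive")
        if self.icv_true <= 0:
            raise ValueError("icv_true must be positive")
        if self.ar_init_true == 0.0:
            # touching-spheres bounding geometry at fusion onset
            object.__setattr__(self, "ar_init_true",
                               (self.d1 + self.d2) / max(self.d1, self.d2))

    @property
    def length_scale(self) -> float:
        return self.d1 + self.d2

    @property
    def tau_true(self) -> float:
        return self.icv_true * self.length_scale

    @property
    def d_final(self) -> float:
        return (self.d1 ** 3 + self.d2 ** 3) ** (1.0 / 3.0)

    def ar_at(self, t: float | np.ndarray) -> float | np.ndarray:
        return 1.0 + (self.ar_init_true - 1.0) * np.exp(-np.asarray(t)
                                                        / self.tau_true)

    def spheroid_axes(self, t: float) -> tuple[float, float]:
        """Full (major, minor) in-plane axes at time t after onset; the
        prolate spheroid a·b² equals d_final³ at all times."""
        ar = float(self.ar_at(t))
        b = (self.d_final ** 3 / ar) ** (1.0 / 3.0)
        return ar * b, b

    def to_dict(self) -> dict:
        return {
            "d1_um": self.d1, "d2_um": self.d2,
            "icv_true_s_per_um": self.icv_true,
            "tau_true_s": self.tau_true,
            "ar_init_true": self.ar_init_true,
            "d_final_um": self.d_final,
            "onset_frame": self.onset_frame,
        }


def simulate_fusion_movie(
    truth: FusionGroundTruth,
    optics: OpticsModel,
    n_frames: int | None = None,
    frame_interval: float = 0.25,
    seed: int | None = 0,
    n_pre_frames: int = 5,
    shape: tuple[int, int] | None = None,
    noise: bool = True,
) -> tuple[ImageStack, FusionGroundTruth]:
    """Render a fusion movie with exact exponential shape relaxation.

    Pre-onset frames show the two droplets nearly touching (separated by a
    small gap so segmentation resolves them); from the onset frame the pair
    is replaced by a single volume-conserving spheroid whose projected aspect
    ratio follows the exponential relaxation schedule. The movie must span at
    least 3 relaxation times so the decay is observable.
    """
    if frame_interval <= 0:
        raise ValueError("frame_interval must be positive")
    tau = truth.tau_true
    if n_frames is None:
        n_frames = n_pre_frames + int(math.ceil(3.5 * tau / frame_interval)) + 1
    if (n_frames - n_pre_frames) * frame_interval < 3.0 * tau:
        raise ValueError("movie too short: need n_frames*frame_interval "
                         ">= 3*tau after onset")

    gap = 3.0 * optics.pixel_size  # keeps the pair 8-disconnected pre-onset
    d1, d2 = truth.d1, truth.d2
    a0, _ = truth.spheroid_axes(0.0)
    extent_x = max(d1 + d2 + gap, a0)
    extent_y = truth.d_final
    margin = 2.0 + 6 * optics.blur_sigma * optics.pixel_size
    if shape is None:
        w = int(math.ceil((extent_x + 2 * margin) / optics.pixel_size))
        h = int(math.ceil((extent_y + 2 * margin) / optics.pixel_size))
        shape = (h, w)
    h, w = shape
    cx = w * optics.pixel_size / 2.0
    cy = h * optics.pixel_size / 2.0

    # volume-weighted centre of mass stays fixed through coalescence
    v1, v2 = d1 ** 3, d2 ** 3
    sep = (d1 + d2) / 2.0 + gap
    x1 = cx - sep * v2 / (v1 + v2)
    x2 = x1 + sep

    rng = np.random.default_rng(seed) if noise else None
    frames = np.empty((n_frames, h, w))
    truth = FusionGroundTruth(d1=d1, d2=d2, icv_true=truth.icv_true,
                              ar_init_true=truth.ar_init_true,
                              onset_frame=n_pre_frames)
    for k in range(n_frames):
        if k < n_pre_frames:
            droplets = [((x1, cy), (d1, d1), 0.0, 1.0),
                        ((x2, cy), (d2, d2), 0.0, 1.0)]
        else:
            t = (k - n_pre_frames) * frame_interval
            a, b = truth.spheroid_axes(t)
            droplets = [((cx, cy), (a, b), 0.0, 1.0)]
        frames[k] = render_frame(droplets, optics, shape, rng)

    stack = ImageStack(frames=frames, pixel_size=optics.pixel_size,
                       frame_interval=frame_interval)
    return stack, truth


def simulate_fusion_panel(
    n_events: int,
    icv_true: float,
    optics: OpticsModel,
    diameter_range: tuple[float, float] = (2.0, 6.0),
    frame_interval: float = 0.25,
    seed: int = 0,
    noise: bool = True,
) -> list[tuple[ImageStack, FusionGroundTruth]]:
    """A panel of independent single-fusion movies with diameters drawn
    uniformly from ``diameter_range`` (one movie per event)."""
    rng = np.random.default_rng(seed)
    panel = []
    for i in range(n_events):
        d1, d2 = rng.uniform(*diameter_range, size=2)
        truth = FusionGroundTruth(d1=float(d1), d2=float(d2),
                                  icv_true=icv_true)
        movie_seed = int(rng.integers(0, 2 ** 31 - 1))
        panel.append(simulate_fusion_movie(
            truth, optics, frame_interval=frame_interval,
            seed=movie_seed, noise=noise))
    return panel


# ---------------------------------------------------------------------------
# droplet mobility
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MotionGroundTruth:
    """Brownian (optionally confined) droplet ensemble parameters."""

    D_true: float                         # μm²/s
    diameters: tuple[float, ...]          # μm, one per droplet
    arena: tuple[float, float]            # (width, height) μm
    confinement_radius: float | None = None

    def __post_init__(self) -> None:
        if self.D_true < 0:
            raise ValueError("D_true must be non-negative")
        if self.confinement_radius is not None and self.confinement_radius <= 0:
            raise ValueError("confinement_radius must be positive when finite")
        if any(d <= 0 for d in self.diameters):
            raise ValueError("diameters must be positive")


def _reflect_interval(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Reflect values into [lo, hi] (assumes excursions < interval width)."""
    x = np.where(x < lo, 2 * lo - x, x)
    x = np.where(x > hi, 2 * hi - x, x)
    return x


def simulate_brownian_movie(
    truth: MotionGroundTruth,
    optics: OpticsModel,
    n_frames: int,
    frame_interval: float,
    seed: int | None = 0,
    start_positions: np.ndarray | None = None,
    noise: bool = True,
) -> tuple[ImageStack, pd.DataFrame]:
    """Render a droplet ensemble undergoing 2D Brownian motion.

    Displacements per frame are independent N(0, 2·D·Δt) per axis. With a
    finite confinement radius each droplet is radially reflected about its
    starting anchor; otherwise droplets reflect at the arena walls. Returns
    the stack and the exact trajectories (frame, droplet, x_um, y_um).
    """
    if frame_interval <= 0:
        raise ValueError("frame_interval must be positive")
    w_um, h_um = truth.arena
    n = len(truth.diameters)
    radii = np.asarray(truth.diameters) / 2.0
    margin = radii.max() + 4 * optics.blur_sigma * optics.pixel_size + 0.5
    rng = np.random.default_rng(seed)

    if start_positions is None:
        # spread droplets on a grid well inside the arena, so wall
        # reflections stay rare over the excursion of a typical movie
        inset = max(margin, 0.2 * min(w_um, h_um))
        ncol = int(math.ceil(math.sqrt(n * w_um / h_um)))
        nrow = int(math.ceil(n / ncol))
        xs = np.linspace(inset, w_um - inset, ncol)
        ys = np.linspace(inset, h_um - inset, nrow)
        grid = [(x, y) for y in ys for x in xs][:n]
        pos = np.array(grid, dtype=float)
    else:
        pos = np.array(start_positions, dtype=float)
        if pos.shape != (n, 2):
            raise ValueError("start_positions must be (n_droplets, 2)")
    anchors = pos.copy()

    step_sd = math.sqrt(2.0 * truth.D_true * frame_interval)
    shape = (int(round(h_um / optics.pixel_size)),
             int(round(w_um / optics.pixel_size)))
    # float32 keeps long ensemble movies at a workable memory footprint
    frames = np.empty((n_frames,) + shape, dtype=np.float32)
    rows = []
    noise_rng = rng if noise else None
    for k in range(n_frames):
        droplets = [((pos[i, 0], pos[i, 1]),
                     (truth.diameters[i], truth.diameters[i]), 0.0, 1.0)
                    for i in range(n)]
        frames[k] = render_frame(droplets, optics, shape, noise_rng)
        for i in range(n):
            rows.append((k, i, pos[i, 0], pos[i, 1]))
        if k == n_frames - 1:
            break
        if step_sd > 0:
            pos = pos + rng.normal(0.0, step_sd, size=pos.shape)
        if truth.confinement_radius is not None:
            delta = pos - anchors
            dist = np.hypot(delta[:, 0], delta[:, 1])
            over = dist > truth.confinement_radius
            if over.any():
                fold = (2 * truth.confinement_radius - dist[over]) / dist[over]
                pos[over] = anchors[over] + delta[over] * fold[:, None]
        else:
            pos[:, 0] = _reflect_interval(pos[:, 0], margin, w_um - margin)
            pos[:, 1] = _reflect_interval(pos[:, 1], margin, h_um - margin)

    stack = ImageStack(frames=frames, pixel_size=optics.pixel_size,
                       frame_interval=frame_interval)
    traj = pd.DataFrame(rows, columns=["frame", "droplet", "x_um", "y_um"])
    return stack, traj


# ---------------------------------------------------------------------------
# FRAP
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FrapGroundTruth:
    """Parameters of an intradroplet diffusion + photobleach simulation."""

    droplet_radius: float              # μm
    D_in: float                        # μm²/s
    immobile_fraction: float = 0.0
    bleach_depth: float = 0.8          # fraction of fluorescence removed
    bleach_roi: ROISpec | None = None  # default: partial disk, 0.2·R
    exchange_rate: float = 0.0         # 1/s toward the dilute-phase reservoir

    def __post_init__(self) -> None:
        if self.droplet_radius <= 0:
            raise ValueError("droplet_radius must be positive")
        if self.D_in < 0:
            raise ValueError("D_in must be non-negative")
        if not 0.0 <= self.immobile_fraction <= 1.0:
            raise ValueError("immobile_fraction must be in [0, 1]")
        if not 0.0 <= self.bleach_depth <= 1.0:
            raise ValueError("bleach_depth must be in [0, 1]")
        if self.bleach_roi is None:
            object.__setattr__(self, "bleach_roi", ROISpec(
                kind="partial_disk", radius=0.2 * self.droplet_radius))


def _roi_mask(roi: ROISpec, xx: np.ndarray, yy: np.ndarray,
              disk: np.ndarray, radius: float) -> np.ndarray:
    """Boolean ROI mask on droplet-centred coordinate grids (μm)."""
    ox, oy = roi.center
    if roi.kind == "partial_disk":
        if roi.radius is None or roi.radius >= radius:
            raise ValueError("partial_disk radius must be < droplet radius")
        return disk & ((xx - ox) ** 2 + (yy - oy) ** 2 <= roi.radius ** 2)
    if roi.kind == "half_droplet":
        side = roi.side or "left"
        if side == "left":
            return disk & (xx <= 0)
        if side == "right":
            return disk & (xx >= 0)
        if side == "top":
            return disk & (yy <= 0)
        if side == "bottom":
            return disk & (yy >= 0)
        raise ValueError(f"unknown half_droplet side: {side!r}")
    if roi.kind == "whole_droplet":
        return disk.copy()
    raise ValueError(f"unsupported bleach ROI kind: {roi.kind!r}")


def _diffuse(c: np.ndarray, disk: np.ndarray, alpha: float,
             n_steps: int) -> np.ndarray:
    """Explicit 5-point diffusion with no-flux boundary on the disk mask.

    Each site exchanges only with in-mask neighbours, which conserves total
    mass exactly (reflecting boundary)."""
    c = c.copy()
    nbr_count = np.zeros_like(c)
    shifts = [(1, 0), (-1, 0), (0, 1), (0, -1)]
    masks = []
    for dr, dc in shifts:
        m = np.zeros_like(disk)
        src = np.roll(disk, (dr, dc), axis=(0, 1))
        # roll wraps; wrapped cells are outside the disk anyway because the
        # disk never touches the array edge (enforced by the caller)
        m = disk & src
        masks.append((dr, dc, m))
        nbr_count += m
    for _ in range(n_steps):
        acc = -nbr_count * c
        for dr, dc, m in masks:
            acc += np.where(m, np.roll(c, (dr, dc), axis=(0, 1)), 0.0)
        c = c + alpha * acc
        c[~disk] = 0.0
    return c


def simulate_frap_movie(
    truth: FrapGroundTruth,
    optics: OpticsModel,
    n_frames: int,
    frame_interval: float,
    bleach_frame: int = 5,
    seed: int | None = 0,
    noise: bool = True,
    acquisition_decay: float = 0.0,
) -> tuple[ImageStack, FrapGroundTruth, pd.DataFrame]:
    """Simulate a photobleach-recovery movie of one droplet.

    The droplet interior is a disk lattice at the pixel resolution carrying
    a mobile species (diffusing at ``D_in``, reflecting boundary) and an
    immobile one. At ``bleach_frame`` both species inside the bleach ROI are
    scaled by (1 - bleach_depth). The explicit diffusion update is sub-stepped
    so that D·dt/dx² ≤ 0.25 always holds. ``acquisition_decay`` (1/s) applies
    an exponential whole-frame intensity decay emulating acquisition
    photobleaching. Returns the stack, the truth, and the noiseless ROI/whole
    droplet concentration trace per frame.
    """
    if frame_interval <= 0:
        raise ValueError("frame_interval must be positive")
    if not 0 <= bleach_frame < n_frames:
        raise ValueError("bleach_frame must lie within the stack")
    dx = optics.pixel_size
    R = truth.droplet_radius
    if dx > R / 10.0:
        raise ValueError("lattice spacing (pixel_size) must be <= radius/10")

    # field comfortably larger than the droplet (keeps its area fraction in
    # the range global thresholding handles well)
    pad = int(math.ceil((1.6 * R + 2.0 + 6 * optics.blur_sigma * dx) / dx))
    npx = 2 * pad + 1
    coords = (np.arange(npx) - pad) * dx
    xx = coords[None, :]
    yy = coords[:, None]
    disk = (xx ** 2 + yy ** 2) <= R ** 2
    roi = _roi_mask(truth.bleach_roi, xx, yy, disk, R)

    mobile = np.where(disk, 1.0 - truth.immobile_fraction, 0.0)
    immob = np.where(disk, truth.immobile_fraction, 0.0)
    reservoir = 1.0 - truth.immobile_fraction

    # automatic sub-stepping for stability of the explicit scheme
    if truth.D_in > 0:
        n_sub = max(1, int(math.ceil(truth.D_in * frame_interval
                                     / (0.25 * dx * dx))))
        alpha = truth.D_in * (frame_interval / n_sub) / (dx * dx)
    else:
        n_sub, alpha = 0, 0.0

    rng = np.random.default_rng(seed) if noise else None
    h = w = npx
    frames = np.empty((n_frames, h, w))
    rows = []
    for k in range(n_frames):
        if k == bleach_frame:
            mobile = np.where(roi, mobile * (1 - truth.bleach_depth), mobile)
            immob = np.where(roi, immob * (1 - truth.bleach_depth), immob)
        field = mobile + immob
        decay = math.exp(-acquisition_decay * k * frame_interval)
        img = gaussian_filter(field * decay, optics.blur_sigma) \
            + optics.background_level
        if rng is not None:
            counts = rng.poisson(np.clip(img, 0, None) * optics.photon_scale)
            img = counts / optics.photon_scale
            if optics.read_noise_sigma > 0:
                img = img + rng.normal(0.0, optics.read_noise_sigma,
                                       img.shape)
            img = np.clip(img, 0.0, None)
        frames[k] = img
        rows.append((k, k * frame_interval,
                     float(field[roi].mean()), float(field[disk].mean())))
        # evolve to the next frame
        if n_sub:
            mobile = _diffuse(mobile, disk, alpha, n_sub)
        if truth.exchange_rate > 0:
            f = 1.0 - math.exp(-truth.exchange_rate * frame_interval)
            mobile = np.where(disk, mobile + f * (reservoir - mobile), 0.0)

    stack = ImageStack(frames=frames, pixel_size=dx,
                       frame_interval=frame_interval)
    trace = pd.DataFrame(
        rows, columns=["frame", "time_s", "roi_concentration",
                       "droplet_concentration"])
    return stack, truth, trace


# ---------------------------------------------------------------------------
# dissolution and phase grids
# ---------------------------------------------------------------------------

def _place_droplets(rng: np.random.Generator, n: int,
                    diam_range: tuple[float, float],
                    w_um: float, h_um: float, margin: float,
                    max_tries: int = 200) -> list[tuple[float, float, float]]:
    """Random non-overlapping (x, y, diameter) placements."""
    placed: list[tuple[float, float, float]] = []
    for _ in range(n):
        for _try in range(max_tries):
            d = float(rng.uniform(*diam_range))
            x = float(rng.uniform(margin + d / 2, w_um - margin - d / 2))
            y = float(rng.uniform(margin + d / 2, h_um - margin - d / 2))
            ok = all(math.hypot(x - px, y - py) > (d + pd) / 2 + 1.0
                     for px, py, pd in placed)
            if ok:
                placed.append((x, y, d))
                break
    return placed


def simulate_dissolution_movie(
    crosslinked: bool,
    optics: OpticsModel,
    treatment_frame: int,
    n_frames: int = 30,
    seed: int | None = 0,
    n_droplets: int = 10,
    persist_fraction: float | None = None,
    decay_frames: int = 5,
    shape: tuple[int, int] = (256, 256),
    diam_range: tuple[float, float] = (2.0, 5.0),
    noise: bool = True,
) -> tuple[ImageStack, pd.DataFrame]:
    """Simulate a chelation-dissolution assay field.

    Non-crosslinked droplets shrink to nothing within ``decay_frames`` after
    the treatment frame (EDTA chelation dissolving magnesium-dependent
    condensates); photocrosslinked droplets persist unchanged. A mixed field
    is produced by ``persist_fraction`` (overrides ``crosslinked``). Returns
    the stack and a per-droplet table with the persistence ground truth.
    """
    if not 0 <= treatment_frame < n_frames:
        raise ValueError("treatment_frame must lie within the stack")
    rng = np.random.default_rng(seed)
    h, w = shape
    w_um, h_um = w * optics.pixel_size, h * optics.pixel_size
    placed = _place_droplets(rng, n_droplets, diam_range, w_um, h_um,
                             margin=1.0)
    n = len(placed)
    if persist_fraction is not None:
        n_persist = int(round(persist_fraction * n))
        persist = np.zeros(n, dtype=bool)
        persist[rng.permutation(n)[:n_persist]] = True
    else:
        persist = np.full(n, bool(crosslinked))

    noise_rng = rng if noise else None
    frames = np.empty((n_frames, h, w))
    for k in range(n_frames):
        droplets = []
        for i, (x, y, d) in enumerate(placed):
            if persist[i] or k <= treatment_frame:
                scale = 1.0
            else:
                scale = max(0.0, 1.0 - (k - treatment_frame) / decay_frames)
            if scale * d < 2 * optics.pixel_size:
                continue
            dd = d * scale
            droplets.append(((x, y), (dd, dd), 0.0, 1.0))
        frames[k] = render_frame(droplets, optics, shape, noise_rng)

    stack = ImageStack(frames=frames, pixel_size=optics.pixel_size,
                       frame_interval=1.0)
    info = pd.DataFrame({
        "droplet": np.arange(n),
        "x_um": [p[0] for p in placed],
        "y_um": [p[1] for p in placed],
        "diameter_um": [p[2] for p in placed],
        "persists": persist,
    })
    return stack, info


def simulate_condition_grid(
    grid: np.ndarray,
    optics: OpticsModel,
    seed: int | None = 0,
    min_count: int = 8,
    shape: tuple[int, int] = (192, 192),
    diam_range: tuple[float, float] = (1.5, 4.0),
    speckle: bool = False,
    noise: bool = True,
) -> tuple[list[list[np.ndarray]], np.ndarray]:
    """Render one field per cell of a condensate-presence truth grid.

    Present cells contain at least ``min_count`` droplets above the minimum
    diameter; absent cells contain background only (optionally sub-diameter
    speckle). Returns (images nested row-major, truth matrix copy).
    """
    grid = np.asarray(grid, dtype=bool)
    if grid.ndim != 2:
        raise ValueError("grid must be 2D")
    rng = np.random.default_rng(seed)
    h, w = shape
    w_um, h_um = w * optics.pixel_size, h * optics.pixel_size
    images: list[list[np.ndarray]] = []
    noise_src = rng if noise else None
    for i in range(grid.shape[0]):
        row_imgs = []
        for j in range(grid.shape[1]):
            droplets = []
            if grid[i, j]:
                n = int(rng.integers(min_count, min_count + 8))
                for x, y, d in _place_droplets(rng, n, diam_range,
                                               w_um, h_um, margin=0.5):
                    droplets.append(((x, y), (d, d), 0.0, 1.0))
            elif speckle:
                for x, y, d in _place_droplets(rng, 3, (0.3, 0.45),
                                               w_um, h_um, margin=0.5):
                    droplets.append(((x, y), (d, d), 0.0, 0.5))
            row_imgs.append(render_frame(droplets, optics, shape, noise_src))
        images.append(row_imgs)
    return images, grid.copy()
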
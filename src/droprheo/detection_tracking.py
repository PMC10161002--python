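"""Droplet segmentation, frame-to-frame linking, fusion-event detection and
size statistics.

Conventions
-----------
Pixel indices are 0-based ``(row, col)``. Physical centroids are reported in
micrometres as ``x = col * pixel_size`` and ``y = row * pixel_size``. All
user-facing lengths are in μm, areas in μm², times in seconds.

The aspect ratio of a droplet is the ratio of the major to the minor axis of
the ellipse with the same second central moments as the segmented region
(rotation-invariant, unlike a bounding-box ratio).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import linear_sum_assignment
from scipy.stats import ttest_ind
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

__all__ = [
    "ImageStack",
    "DropletObservation",
    "Track",
    "FusionEvent",
    "segment_frame",
    "segment_stack",
    "link_tracks",
    "detect_fusions",
    "diameter_distribution",
    "welch_t_test",
    "observations_to_frame",
    "tracks_to_frame",
    "tracks_from_frame",
]

# Foreground fractions above this are treated as a segmentation failure
# (thresholding pure noise splits the histogram near its median); droplet
# fields analysed here never cover more than ~1/3 of the frame.
_MAX_FOREGROUND_FRACTION = 0.35

# Minimum Otsu class separation in pooled within-class SDs. Thresholding a
# unimodal noise histogram yields d ≈ 2.7 regardless of the noise scale;
# genuine droplet/background bimodality gives d well above this.
_MIN_CLASS_SEPARATION = 4.0


@dataclass
class ImageStack:
    """A calibrated time-lapse stack: T×H×W intensities (non-negative)."""

    frames: np.ndarray          # (T, H, W) float array
    pixel_size: float           # μm per pixel
    frame_interval: float       # seconds between frames

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if not np.issubdtype(self.frames.dtype, np.floating):
            self.frames = self.frames.astype(float)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValueError("frames must be a T×H×W array with T >= 1")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    def times(self) -> np.ndarray:
        """Acquisition time of each frame, seconds from the first frame."""
        return np.arange(self.n_frames) * self.frame_interval


@dataclass
class DropletObservation:
    """One segmented droplet in one frame; lengths in μm, area in μm²."""

    frame_index: int
    x_um: float
    y_um: float
    area_um2: float
    equivalent_diameter_um: float
    major_axis_um: float
    minor_axis_um: float
    aspect_ratio: float
    mean_intensity: float
    touches_border: bool = False

    @property
    def radius_um(self) -> float:
        return self.equivalent_diameter_um / 2.0

    @property
    def centroid(self) -> tuple[float, float]:
        return (self.x_um, self.y_um)


@dataclass
class Track:
    """Temporal linkage of droplet observations (strictly increasing frames)."""

    track_id: int
    observations: list[DropletObservation] = field(default_factory=list)
    max_gap: int = 0  # gap policy the linker was run with

    @property
    def start_frame(self) -> int:
        return self.observations[0].frame_index

    @property
    def end_frame(self) -> int:
        return self.observations[-1].frame_index

    def __len__(self) -> int:
        return len(self.observations)

    def positions(self) -> np.ndarray:
        """(n, 2) array of (x, y) centroids in μm."""
        return np.array([[o.x_um, o.y_um] for o in self.observations])

    def frames(self) -> np.ndarray:
        return np.array([o.frame_index for o in self.observations])

    def median_diameter(self) -> float:
        return float(np.median(
            [o.equivalent_diameter_um for o in self.observations]))

    def observation_at(self, frame: int) -> DropletObservation | None:
        for o in self.observations:
            if o.frame_index == frame:
                return o
        return None


@dataclass
class FusionEvent:
    """A detected droplet coalescence.

    ``d1``/``d2`` are the pre-fusion equivalent diameters (mean over the
    ``k`` frames preceding onset); the length scale regressed against the
    relaxation time is their sum.
    """

    event_id: int
    onset_frame: int
    d1_um: float
    d2_um: float
    product_track_id: int
    ar_times_s: np.ndarray      # seconds, 0 at onset
    ar_values: np.ndarray
    post_diameter_um: float
    parent_track_ids: tuple[int, int] = (-1, -1)

    @property
    def length_scale_um(self) -> float:
        return self.d1_um + self.d2_um


def segment_frame(
    image: np.ndarray,
    pixel_size: float,
    min_diameter_um: float = 0.5,
    threshold_mode: str = "otsu",
    threshold_value: float | None = None,
) -> list[DropletObservation]:
    """Segment droplets in a single frame.

    Global Otsu threshold (default) or a fixed absolute threshold, binary
    hole filling, 8-connected components; regions with equivalent diameter
    below ``min_diameter_um`` are discarded. Border-touching regions are
    returned flagged (``touches_border``) so shape statistics can exclude
    them. An all-constant image yields an empty list.
    """
    image = np.asarray(image, dtype=float)
    if image.size == 0:
        raise ValueError("empty image")
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")

    if image.max() == image.min():
        return []
    if threshold_mode == "otsu":
        thr = threshold_otsu(image)
    elif threshold_mode == "fixed":
        if threshold_value is None:
            raise ValueError("fixed threshold_mode requires threshold_value")
        thr = float(threshold_value)
    else:
        raise ValueError(f"unknown threshold_mode: {threshold_mode!r}")

    binary = image > thr
    frac = binary.mean()
    if frac == 0.0 or frac > _MAX_FOREGROUND_FRACTION:
        return []
    if threshold_mode == "otsu":
        fg, bg = image[binary], image[~binary]
        pooled = math.sqrt((fg.var() + bg.var()) / 2.0)
        if pooled > 0 and (fg.mean() - bg.mean()) / pooled \
                < _MIN_CLASS_SEPARATION:
            return []   # unimodal histogram: nothing but noise to threshold
    binary = ndimage.binary_fill_holes(binary)
    labels = label(binary, connectivity=2)

    h, w = image.shape
    out: list[DropletObservation] = []
    for region in regionprops(labels, intensity_image=image):
        eq_diam = region.equivalent_diameter_area * pixel_size
        if eq_diam < min_diameter_um:
            continue
        minr, minc, maxr, maxc = region.bbox
        touches = minr == 0 or minc == 0 or maxr == h or maxc == w
        row, col = region.centroid
        major = region.axis_major_length * pixel_size
        minor = region.axis_minor_length * pixel_size
        ar = major / minor if minor > 0 else float("inf")
        out.append(DropletObservation(
            frame_index=0,
            x_um=col * pixel_size,
            y_um=row * pixel_size,
            area_um2=region.area * pixel_size ** 2,
            equivalent_diameter_um=eq_diam,
            major_axis_um=major,
            minor_axis_um=minor,
            aspect_ratio=ar,
            mean_intensity=float(region.intensity_mean),
            touches_border=touches,
        ))
    return out


def segment_stack(
    stack: ImageStack,
    min_diameter_um: float = 0.5,
    threshold_mode: str = "otsu",
    threshold_value: float | None = None,
) -> list[list[DropletObservation]]:
    """Segment every frame; returns one observation list per frame."""
    per_frame = []
    for t in range(stack.n_frames):
        obs = segment_frame(stack.frames[t], stack.pixel_size,
                            min_diameter_um=min_diameter_um,
                            threshold_mode=threshold_mode,
                            threshold_value=threshold_value)
        for o in obs:
            o.frame_index = t
        per_frame.append(obs)
    return per_frame


def link_tracks(
    per_frame: Sequence[Sequence[DropletObservation]],
    max_displacement_um: float,
    memory_frames: int = 0,
) -> list[Track]:
    """Link per-frame observations into tracks.

    Frame-to-frame assignment minimises the total centroid displacement
    (optimal bipartite assignment); pairs farther than
    ``max_displacement_um`` (scaled by the gap length for tracks coasting
    through missed detections) are forbidden. Unmatched tracks stay open for
    up to ``memory_frames`` frames before closing.
    """
    if max_displacement_um <= 0:
        raise ValueError("max_displacement_um must be positive")

    tracks: list[Track] = []
    open_tracks: list[Track] = []
    next_id = 0
    big = 1e12

    for t, obs in enumerate(per_frame):
        obs = list(obs)
        # retire tracks that exceeded the memory window
        still_open = []
        for tr in open_tracks:
            if t - tr.end_frame > memory_frames + 1:
                continue
            still_open.append(tr)
        open_tracks = still_open

        if open_tracks and obs:
            cost = np.full((len(open_tracks), len(obs)), big)
            for i, tr in enumerate(open_tracks):
                last = tr.observations[-1]
                gap = t - last.frame_index
                gate = max_displacement_um * gap
                for j, o in enumerate(obs):
                    d = math.hypot(o.x_um - last.x_um, o.y_um - last.y_um)
                    if d <= gate:
                        cost[i, j] = d
            rows, cols = linear_sum_assignment(cost)
            matched_obs = set()
            for i, j in zip(rows, cols):
                if cost[i, j] >= big:
                    continue
                open_tracks[i].observations.append(obs[j])
                matched_obs.add(j)
            unmatched = [o for j, o in enumerate(obs) if j not in matched_obs]
        else:
            unmatched = obs

        for o in unmatched:
            tr = Track(track_id=next_id, observations=[o],
                       max_gap=memory_frames)
            next_id += 1
            open_tracks.append(tr)
            tracks.append(tr)

    return tracks


def detect_fusions(
    tracks: Sequence[Track],
    frame_interval: float,
    proximity_tol_um: float = 1.0,
    area_tol_frac: float = 0.25,
    k_pre_frames: int = 3,
) -> list[FusionEvent]:
    """Detect coalescence events among linked tracks.

    An event is declared when two tracks end at frame ``f-1`` with centroid
    separation at most ``(r1 + r2) + proximity_tol_um`` and a track exists at
    frame ``f`` whose centroid lies inside the parents' joint bounding box
    and whose area is within ``area_tol_frac`` of the summed parent areas.
    When the coalesced droplet's centroid lands close to the larger parent
    (very unequal pair), the linker continues that parent's track through the
    merge instead of opening a new one; such events are recovered by the
    complementary rule — one track ends at ``f-1`` next to a surviving track
    whose area jumps by the ended track's area at ``f``. Overlapping
    candidates sharing a parent keep the geometrically closest pair. The
    aspect-ratio series of the product is reported with time zero at onset.
    """
    if frame_interval <= 0:
        raise ValueError("frame_interval must be positive")

    ends: dict[int, list[Track]] = {}
    for tr in tracks:
        ends.setdefault(tr.end_frame, []).append(tr)

    def _bbox_ok(oa: DropletObservation, ob: DropletObservation,
                 prod: DropletObservation) -> bool:
        x_lo = min(oa.x_um - oa.radius_um, ob.x_um - ob.radius_um)
        x_hi = max(oa.x_um + oa.radius_um, ob.x_um + ob.radius_um)
        y_lo = min(oa.y_um - oa.radius_um, ob.y_um - ob.radius_um)
        y_hi = max(oa.y_um + oa.radius_um, ob.y_um + ob.radius_um)
        return x_lo <= prod.x_um <= x_hi and y_lo <= prod.y_um <= y_hi

    # candidate: (separation, onset frame, parent_a, parent_b, product track)
    # where the product's observations at frames >= onset describe the
    # coalesced droplet (parent_b may be the same track as the product)
    candidates: list[tuple[float, int, Track, Track, Track]] = []
    for tr in tracks:
        f = tr.start_frame
        parents = ends.get(f - 1, [])
        if len(parents) < 2:
            continue
        prod0 = tr.observations[0]
        for i in range(len(parents)):
            for j in range(i + 1, len(parents)):
                a, b = parents[i], parents[j]
                oa, ob = a.observations[-1], b.observations[-1]
                sep = math.hypot(oa.x_um - ob.x_um, oa.y_um - ob.y_um)
                if sep > oa.radius_um + ob.radius_um + proximity_tol_um:
                    continue
                if not _bbox_ok(oa, ob, prod0):
                    continue
                area_sum = oa.area_um2 + ob.area_um2
                if abs(prod0.area_um2 - area_sum) > area_tol_frac * area_sum:
                    continue
                candidates.append((sep, f, a, b, tr))

    # continuation form: ended track absorbed by a surviving neighbour
    for f, ended in ends.items():
        f += 1
        for a in ended:
            oa = a.observations[-1]
            for c in tracks:
                if c.track_id == a.track_id:
                    continue
                prev = c.observation_at(f - 1)
                merged = c.observation_at(f)
                if prev is None or merged is None:
                    continue
                sep = math.hypot(oa.x_um - prev.x_um, oa.y_um - prev.y_um)
                if sep > oa.radius_um + prev.radius_um + proximity_tol_um:
                    continue
                if not _bbox_ok(oa, prev, merged):
                    continue
                area_sum = oa.area_um2 + prev.area_um2
                if abs(merged.area_um2 - area_sum) > area_tol_frac * area_sum:
                    continue
                candidates.append((sep, f, a, c, c))

    # resolve overlaps: keep the geometrically closest per parent/product
    candidates.sort(key=lambda c: (c[0], c[1]))
    used: set[int] = set()
    events: list[FusionEvent] = []
    for sep, f, a, b, prod in candidates:
        if a.track_id in used or b.track_id in used or prod.track_id in used:
            continue
        used.update((a.track_id, b.track_id, prod.track_id))

        def _pre_diam(parent: Track, onset: int) -> float:
            obs = [o for o in parent.observations if o.frame_index < onset]
            obs = obs[-k_pre_frames:]
            return float(np.mean([o.equivalent_diameter_um for o in obs]))

        d1 = _pre_diam(a, f)
        d2 = _pre_diam(b, f)
        ar_t, ar_v = [], []
        post_obs = [o for o in prod.observations if o.frame_index >= f]
        for o in post_obs:
            if o.touches_border or not math.isfinite(o.aspect_ratio):
                continue
            ar_t.append((o.frame_index - f) * frame_interval)
            ar_v.append(o.aspect_ratio)
        post = float(np.mean([o.equivalent_diameter_um
                              for o in post_obs[-k_pre_frames:]]))
        events.append(FusionEvent(
            event_id=len(events),
            onset_frame=f,
            d1_um=d1,
            d2_um=d2,
            product_track_id=prod.track_id,
            ar_times_s=np.asarray(ar_t, dtype=float),
            ar_values=np.asarray(ar_v, dtype=float),
            post_diameter_um=post,
            parent_track_ids=(a.track_id, b.track_id),
        ))
    events.sort(key=lambda e: e.onset_frame)
    for i, e in enumerate(events):
        e.event_id = i
    return events


def diameter_distribution(diameters: Iterable[float]) -> dict[str, float]:
    """Order statistics of a droplet-diameter sample (linear-interpolated
    quartiles), as plotted in condensate growth boxplots."""
    d = np.asarray(list(diameters), dtype=float)
    if d.size == 0:
        raise ValueError("diameter_distribution requires at least one value")
    q1, med, q3 = np.percentile(d, [25, 50, 75])
    return {
        "n": int(d.size),
        "mean": float(d.mean()),
        "sd": float(d.std(ddof=1)) if d.size > 1 else 0.0,
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
    }


def welch_t_test(sample_a: Iterable[float],
                 sample_b: Iterable[float]) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test; returns (t, df, two-sided p).

    Two samples with zero variance and equal means return t=0, p=1 by
    convention (no evidence of a difference, rather than NaN).
    """
    a = np.asarray(list(sample_a), dtype=float)
    b = np.asarray(list(sample_b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs n >= 2")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return 0.0, float(a.size + b.size - 2), 1.0
        return math.inf * math.copysign(1, a.mean() - b.mean()), \
            float(a.size + b.size - 2), 0.0
    res = ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def observations_to_frame(
        per_frame: Sequence[Sequence[DropletObservation]]) -> pd.DataFrame:
    rows = []
    for obs in per_frame:
        for o in obs:
            rows.append({
                "frame": o.frame_index, "x_um": o.x_um, "y_um": o.y_um,
                "area_um2": o.area_um2, "eq_diam_um": o.equivalent_diameter_um,
                "major_um": o.major_axis_um, "minor_um": o.minor_axis_um,
                "ar": o.aspect_ratio, "mean_intensity": o.mean_intensity,
                "touches_border": o.touches_border,
            })
    return pd.DataFrame(rows)


def tracks_from_frame(df: pd.DataFrame) -> list[Track]:
    """Rebuild Track objects from a tracks CSV table (inverse of
    :func:`tracks_to_frame`)."""
    tracks = []
    for tid, grp in df.groupby("track_id", sort=True):
        grp = grp.sort_values("frame")
        obs = [DropletObservation(
            frame_index=int(r.frame), x_um=float(r.x_um), y_um=float(r.y_um),
            area_um2=float(r.area_um2),
            equivalent_diameter_um=float(r.eq_diam_um),
            major_axis_um=float(r.major_um), minor_axis_um=float(r.minor_um),
            aspect_ratio=float(r.ar), mean_intensity=float(r.mean_intensity),
        ) for r in grp.itertuples()]
        tracks.append(Track(track_id=int(tid), observations=obs))
    return tracks


def tracks_to_frame(tracks: Sequence[Track]) -> pd.DataFrame:
    rows = []
    for tr in tracks:
        for o in tr.observations:
            rows.append({
                "track_id": tr.track_id, "frame": o.frame_index,
                "x_um": o.x_um, "y_um": o.y_um, "area_um2": o.area_um2,
                "eq_diam_um": o.equivalent_diameter_um,
                "major_um": o.major_axis_um, "minor_um": o.minor_axis_um,
                "ar": o.aspect_ratio, "mean_intensity": o.mean_intensity,
            })
    return pd.DataFrame(rows)
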
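"""Phase-diagram presence classification over salt-condition grids and the
EDTA-dissolution score distinguishing photocrosslinked from fluid condensates.

A condition cell is scored "condensates present" when segmentation finds at
least ``min_count`` droplets whose median diameter clears a minimum size —
an explicit quantitative stand-in for the by-eye presence call of phase
diagrams. The dissolution assay compares total condensate area before and
after a treatment (chelation) frame: fluid, magnesium-dependent condensates
dissolve (remaining fraction → 0) while photocrosslinked ones persist
(remaining fraction → 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .detection_tracking import ImageStack, segment_frame

__all__ = [
    "PhaseDiagram",
    "DissolutionResult",
    "classify_presence",
    "build_phase_diagram",
    "dissolution_score",
]


@dataclass
class PhaseDiagram:
    """Presence grid over (monovalent mM, divalent mM) salt conditions.

    ``grid[i, j]`` corresponds to ``di_axis[i]`` (rows) and ``mono_axis[j]``
    (columns), both in increasing order.
    """

    mono_axis_mM: np.ndarray
    di_axis_mM: np.ndarray
    grid: np.ndarray            # bool (n_di, n_mono)
    counts: np.ndarray          # int
    median_diameters: np.ndarray  # μm, NaN where absent

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.grid, index=self.di_axis_mM,
                            columns=self.mono_axis_mM)


@dataclass
class DissolutionResult:
    """Condensate-area bookkeeping around a treatment frame."""

    pre_area_um2: float
    post_area_um2: float
    remaining_fraction: float
    verdict: str                # "dissolved" | "crosslinked"
    threshold: float


def classify_presence(
    image: np.ndarray,
    pixel_size: float,
    min_count: int = 5,
    min_diameter_um: float = 1.0,
    threshold_mode: str = "otsu",
    threshold_value: float | None = None,
) -> tuple[bool, int, float]:
    """Classify a field as containing condensates.

    Present iff the droplet count is at least ``min_count`` and the median
    equivalent diameter is at least ``min_diameter_um``. Returns
    (present, count, median_diameter); the median is NaN for an empty field.
    """
    obs = segment_frame(image, pixel_size, min_diameter_um=min_diameter_um,
                        threshold_mode=threshold_mode,
                        threshold_value=threshold_value)
    count = len(obs)
    if count == 0:
        return False, 0, float("nan")
    med = float(np.median([o.equivalent_diameter_um for o in obs]))
    present = count >= min_count and med >= min_diameter_um
    return present, count, med


def build_phase_diagram(
    images: Mapping[tuple[float, float], np.ndarray],
    pixel_size: float,
    min_count: int = 5,
    min_diameter_um: float = 1.0,
    threshold_mode: str = "otsu",
    threshold_value: float | None = None,
) -> PhaseDiagram:
    """Assemble a phase diagram from fields keyed by (mono_mM, di_mM).

    The grid must be a complete cartesian product of the observed axis
    values; missing cells raise an error listing their coordinates.
    """
    monos = np.array(sorted({k[0] for k in images}))
    dis = np.array(sorted({k[1] for k in images}))
    missing = [(float(m), float(d)) for d in dis for m in monos
               if (m, d) not in images]
    if missing:
        raise ValueError(f"missing phase-diagram cells: {missing}")
    grid = np.zeros((dis.size, monos.size), dtype=bool)
    counts = np.zeros_like(grid, dtype=int)
    meds = np.full(grid.shape, np.nan)
    for i, d in enumerate(dis):
        for j, m in enumerate(monos):
            present, count, med = classify_presence(
                images[(m, d)], pixel_size, min_count=min_count,
                min_diameter_um=min_diameter_um,
                threshold_mode=threshold_mode,
                threshold_value=threshold_value)
            grid[i, j] = present
            counts[i, j] = count
            meds[i, j] = med
    return PhaseDiagram(mono_axis_mM=monos, di_axis_mM=dis, grid=grid,
                        counts=counts, median_diameters=meds)


def dissolution_score(
    stack: ImageStack,
    treatment_frame: int,
    settle_frames: int = 3,
    threshold: float = 0.5,
    k_pre_frames: int = 3,
    min_diameter_um: float = 0.5,
) -> DissolutionResult:
    """Fraction of condensate area remaining after a treatment frame.

    ``pre_area`` is the mean total segmented droplet area over the
    ``k_pre_frames`` frames before treatment; ``post_area`` the mean over the
    frames after ``treatment_frame + settle_frames``. The verdict is
    "crosslinked" when the remaining fraction is at least ``threshold``,
    otherwise "dissolved".
    """
    if not 0 < treatment_frame < stack.n_frames:
        raise ValueError("treatment_frame must lie within the stack")
    if treatment_frame + settle_frames >= stack.n_frames:
        raise ValueError("no frames left after treatment + settle window")

    def total_area(t: int) -> float:
        obs = segment_frame(stack.frames[t], stack.pixel_size,
                            min_diameter_um=min_diameter_um)
        return float(sum(o.area_um2 for o in obs))

    pre_frames = range(max(0, treatment_frame - k_pre_frames),
                       treatment_frame)
    post_frames = range(treatment_frame + settle_frames + 1, stack.n_frames)
    pre = float(np.mean([total_area(t) for t in pre_frames]))
    post = float(np.mean([total_area(t) for t in post_frames]))
    if pre <= 0:
        raise ValueError("no condensates before treatment")
    frac = post / pre
    verdict = "crosslinked" if frac >= threshold else "dissolved"
    return DissolutionResult(pre_area_um2=pre, post_area_um2=post,
                             remaining_fraction=frac, verdict=verdict,
                             threshold=threshold)
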
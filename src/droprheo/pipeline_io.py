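"""File I/O, configuration and end-to-end pipeline orchestration.

Stacks are written as multi-page uint16 TIFF with a flat key=value sidecar
(``<stack>.meta.txt``) carrying the calibration (pixel size in μm/px, frame
interval in s), the intensity quantization scale, the RNG seed, and any
ground-truth annotations. Loading never silently assumes a calibration: it
must come from the sidecar or be passed explicitly.

``run_pipeline`` ties the stages together for the five analysis modes
(fusion, msd, frap, phase, dissolve), writing intermediate CSVs, a result
JSON and a run manifest with the full parameter set and seed, so re-running
with the same configuration reproduces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import tifffile

from . import detection_tracking as dt
from . import frap_analysis as fa
from . import fusion_rheology as fr
from . import motion_analysis as ma
from . import phase_and_dissolution as pdx
from .detection_tracking import ImageStack

__all__ = [
    "RunConfig",
    "write_sidecar",
    "read_sidecar",
    "save_stack",
    "load_stack",
    "run_pipeline",
]

log = logging.getLogger("droprheo")

_UINT16_TOP = 60000.0  # headroom below the uint16 ceiling for noise spikes

_VALID_MODES = ("fusion", "msd", "frap", "phase", "dissolve")


@dataclass
class RunConfig:
    """Parameters of one pipeline run.

    Either ``input_path`` (a TIFF stack with sidecar / explicit calibration)
    or a ``simulate`` block (passed to the synthetic generators) must be
    given. ``params`` holds per-stage keyword blocks keyed by stage name
    (``segment``, ``track``, ``fusions``, ``rheology``, ``msd``, ``frap``,
    ``phase``, ``dissolve``).
    """

    outdir: str = "results"
    seed: int = 0
    input_path: str | None = None
    pixel_size_um: float | None = None
    frame_interval_s: float | None = None
    simulate: dict[str, Any] = field(default_factory=dict)
    params: dict[str, dict[str, Any]] = field(default_factory=dict)
    log_level: str = "INFO"

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        import tomllib
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def stage(self, name: str) -> dict[str, Any]:
        return dict(self.params.get(name, {}))


# ---------------------------------------------------------------------------
# sidecar + stack I/O
# ---------------------------------------------------------------------------

def _sidecar_path(stack_path: str | Path) -> Path:
    return Path(str(stack_path) + ".meta.txt")


def write_sidecar(path: str | Path, values: Mapping[str, Any]) -> None:
    """Flat ``key=value`` text file, keys sorted for byte-stable output."""
    lines = [f"{k}={values[k]}" for k in sorted(values)]
    Path(path).write_text("\n".join(lines) + "\n")


def read_sidecar(path: str | Path) -> dict[str, str]:
    out: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"malformed sidecar line: {line!r}")
        k, v = line.split("=", 1)
        out[k.strip()] = v.strip()
    return out


def save_stack(stack: ImageStack, path: str | Path,
               seed: int | None = None,
               ground_truth: Mapping[str, Any] | None = None) -> Path:
    """Write a multi-page uint16 TIFF plus its calibration sidecar.

    Intensities are quantized with a stack-wide scale chosen so the maximum
    maps near the top of the uint16 range; the scale is stored in the sidecar
    so loading recovers intensities up to quantization.
    """
    path = Path(path)
    peak = float(stack.frames.max())
    scale = _UINT16_TOP / peak if peak > 0 else 1.0
    arr = np.clip(np.round(stack.frames * scale), 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, arr)
    meta: dict[str, Any] = {
        "pixel_size_um": repr(stack.pixel_size),
        "frame_interval_s": repr(stack.frame_interval),
        "intensity_scale": repr(scale),
    }
    if seed is not None:
        meta["seed"] = seed
    if ground_truth:
        for k, v in ground_truth.items():
            meta[f"gt_{k}"] = v
    write_sidecar(_sidecar_path(path), meta)
    return path


def load_stack(path: str | Path,
               sidecar: str | Path | None = None,
               pixel_size_um: float | None = None,
               frame_interval_s: float | None = None) -> ImageStack:
    """Read a multi-page TIFF with calibration from sidecar or arguments.

    Integer frames are normalized: by the stored intensity scale when the
    sidecar has one, otherwise by the dtype maximum (so 8- and 16-bit stacks
    of the same scene segment identically). A missing calibration is an
    error — never a silent 1 μm/px assumption. A corrupt page raises an error
    naming the page.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    sc = Path(sidecar) if sidecar is not None else _sidecar_path(path)
    if sc.exists():
        meta = read_sidecar(sc)

    px = pixel_size_um if pixel_size_um is not None else (
        float(meta["pixel_size_um"]) if "pixel_size_um" in meta else None)
    dt_s = frame_interval_s if frame_interval_s is not None else (
        float(meta["frame_interval_s"]) if "frame_interval_s" in meta else None)
    if px is None or dt_s is None:
        raise ValueError(
            f"calibration missing for {path.name}: provide a sidecar "
            f"({sc.name}) or explicit pixel_size_um and frame_interval_s")

    frames = []
    with tifffile.TiffFile(path) as tf:
        for i, page in enumerate(tf.pages):
            try:
                frames.append(page.asarray())
            except Exception as exc:
                raise ValueError(f"corrupt TIFF page {i} in {path}") from exc
    arr = np.stack(frames).astype(float)
    if "intensity_scale" in meta:
        arr = arr / float(meta["intensity_scale"])
    elif np.issubdtype(np.stack(frames).dtype, np.integer):
        arr = arr / float(np.iinfo(np.stack(frames).dtype).max)
    log.info("loaded %s: %d frames of %s px", path.name, arr.shape[0],
             arr.shape[1:])
    return ImageStack(frames=arr, pixel_size=px, frame_interval=dt_s)


# ---------------------------------------------------------------------------
# JSON / CSV helpers
# ---------------------------------------------------------------------------

def _write_json(path: Path, obj: Any) -> None:
    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")
    path.write_text(json.dumps(obj, indent=2, sort_keys=True,
                               default=default) + "\n")


def _write_csv(path: Path, df: pd.DataFrame) -> None:
    df.to_csv(path, index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# pipeline orchestration
# ---------------------------------------------------------------------------

def _get_stack(config: RunConfig, mode: str):
    """Load the input stack, or synthesize per the config's simulate block.

    Returns (stack-or-collection, extra) where extra carries ground truth for
    synthetic inputs.
    """
    from . import synthetic_scenes as ss

    if config.input_path:
        stack = load_stack(config.input_path,
                           pixel_size_um=config.pixel_size_um,
                           frame_interval_s=config.frame_interval_s)
        return stack, {}

    sim = dict(config.simulate)
    if not sim:
        raise ValueError("config needs input_path or a simulate block")
    optics = ss.OpticsModel(
        pixel_size=float(sim.pop("pixel_size_um", 0.1)),
        blur_sigma=float(sim.pop("blur_sigma_px", 1.0)),
        background_level=float(sim.pop("background_level", 0.1)),
        photon_scale=float(sim.pop("photon_scale",
                                   ss.photon_scale_for_snr(10.0))),
        read_noise_sigma=float(sim.pop("read_noise_sigma", 0.0)),
    )
    seed = config.seed
    if mode == "fusion":
        panel = ss.simulate_fusion_panel(
            n_events=int(sim.pop("n_events", 10)),
            icv_true=float(sim.pop("icv_true", 0.5)),
            optics=optics,
            diameter_range=tuple(sim.pop("diameter_range", (2.0, 6.0))),
            frame_interval=float(sim.pop("frame_interval_s", 0.25)),
            seed=seed, **sim)
        return panel, {"icv_true": panel[0][1].icv_true}
    if mode == "msd":
        truth = ss.MotionGroundTruth(
            D_true=float(sim.pop("D_true", 0.035)),
            diameters=tuple(sim.pop("diameters", (5.0,) * 4)),
            arena=tuple(sim.pop("arena_um", (60.0, 45.0))),
            confinement_radius=sim.pop("confinement_radius", None))
        stack, traj = ss.simulate_brownian_movie(
            truth, optics,
            n_frames=int(sim.pop("n_frames", 200)),
            frame_interval=float(sim.pop("frame_interval_s", 0.5)),
            seed=seed, **sim)
        return stack, {"truth": truth, "trajectories": traj}
    if mode == "frap":
        truth = ss.FrapGroundTruth(
            droplet_radius=float(sim.pop("droplet_radius_um", 5.0)),
            D_in=float(sim.pop("D_in", 0.5)),
            immobile_fraction=float(sim.pop("immobile_fraction", 0.0)),
            bleach_depth=float(sim.pop("bleach_depth", 0.8)),
            exchange_rate=float(sim.pop("exchange_rate", 0.0)))
        stack, truth, gt_trace = ss.simulate_frap_movie(
            truth, optics,
            n_frames=int(sim.pop("n_frames", 120)),
            frame_interval=float(sim.pop("frame_interval_s", 0.5)),
            bleach_frame=int(sim.pop("bleach_frame", 5)),
            seed=seed, **sim)
        return stack, {"truth": truth, "gt_trace": gt_trace}
    if mode == "phase":
        grid = np.asarray(sim.pop("grid",
                                  [[0, 0, 1], [0, 1, 1], [1, 1, 1]]),
                          dtype=bool)
        images, truth = ss.simulate_condition_grid(grid, optics, seed=seed,
                                                   **sim)
        return (images, optics.pixel_size), {"truth_grid": truth}
    if mode == "dissolve":
        stack, info = ss.simulate_dissolution_movie(
            crosslinked=bool(sim.pop("crosslinked", False)),
            optics=optics,
            treatment_frame=int(sim.pop("treatment_frame", 10)),
            n_frames=int(sim.pop("n_frames", 30)),
            seed=seed, **sim)
        return stack, {"droplets": info}
    raise ValueError(f"unknown mode {mode!r}; valid modes: {_VALID_MODES}")


def run_pipeline(config: RunConfig, mode: str) -> dict[str, Any]:
    """Execute the stage chain for one analysis mode.

    Writes intermediate CSVs, a ``result.json`` and a ``manifest.json``
    (parameters + seed + package version) under ``config.outdir``. On a stage
    failure, partial outputs are retained and the manifest records the failed
    stage. Returns the result dictionary.
    """
    if mode not in _VALID_MODES:
        raise ValueError(f"unknown mode {mode!r}; valid modes: {_VALID_MODES}")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level,
                        format="%(levelname)s %(name)s: %(message)s")

    from . import __version__
    manifest: dict[str, Any] = {
        "mode": mode,
        "seed": config.seed,
        "version": __version__,
        "config": dataclasses.asdict(config),
        "failed_stage": None,
    }
    result: dict[str, Any] = {"mode": mode, "seed": config.seed}
    stage = "input"
    try:
        data, extra = _get_stack(config, mode)
        stage = mode
        if mode == "fusion":
            result.update(_run_fusion(config, data, extra, outdir))
        elif mode == "msd":
            result.update(_run_msd(config, data, extra, outdir))
        elif mode == "frap":
            result.update(_run_frap(config, data, extra, outdir))
        elif mode == "phase":
            result.update(_run_phase(config, data, extra, outdir))
        elif mode == "dissolve":
            result.update(_run_dissolve(config, data, extra, outdir))
    except Exception:
        manifest["failed_stage"] = stage if stage else mode
        _write_json(outdir / "manifest.json", manifest)
        raise
    _write_json(outdir / "result.json", result)
    _write_json(outdir / "manifest.json", manifest)
    return result


def _segment_and_track(config: RunConfig, stack: ImageStack):
    seg = config.stage("segment")
    trk = config.stage("track")
    per_frame = dt.segment_stack(stack, **seg)
    tracks = dt.link_tracks(
        per_frame,
        max_displacement_um=float(trk.pop("max_displacement_um", 0.8)),
        memory_frames=int(trk.pop("memory_frames", 0)))
    return per_frame, tracks


def _run_fusion(config: RunConfig, data, extra, outdir: Path):
    movies = data if isinstance(data, list) else [(data, None)]
    fus = config.stage("fusions")
    rhe = config.stage("rheology")
    all_events = []
    obs_frames = []
    for idx, (stack, truth) in enumerate(movies):
        per_frame, tracks = _segment_and_track(config, stack)
        df = dt.observations_to_frame(per_frame)
        df.insert(0, "movie", idx)
        obs_frames.append(df)
        events = dt.detect_fusions(tracks, stack.frame_interval, **fus)
        all_events.extend(events)
    _write_csv(outdir / "observations.csv",
               pd.concat(obs_frames, ignore_index=True))
    table, cap = fr.analyze_events(all_events,
                                   r2_min=float(rhe.get("r2_min", 0.8)))
    _write_csv(outdir / "event_fits.csv", table)
    ar_rows = []
    for ev in all_events:
        for t, a in zip(ev.ar_times_s, ev.ar_values):
            ar_rows.append({"event_id": ev.event_id, "t_s": t, "ar": a})
    _write_csv(outdir / "ar_series.csv", pd.DataFrame(ar_rows))
    cap_dict = {
        "slope_icv_s_per_um": cap.slope_icv, "slope_se": cap.slope_se,
        "intercept_s": cap.intercept, "n_events": cap.n_events,
        "r_squared": cap.r_squared,
    }
    if "icv_true" in extra:
        cap_dict["icv_true_s_per_um"] = extra["icv_true"]
    _write_json(outdir / "capillary_fit.json", cap_dict)
    return {"capillary_fit": cap_dict,
            "n_fusion_events": len(all_events),
            "mean_volume_ratio": float(table["volume_ratio"].mean())
            if len(table) else float("nan")}


def _run_msd(config: RunConfig, stack, extra, outdir: Path):
    msd_p = config.stage("msd")
    per_frame, tracks = _segment_and_track(config, stack)
    _write_csv(outdir / "tracks.csv", dt.tracks_to_frame(tracks))
    d_min = float(msd_p.pop("d_min_um", 0.0))
    d_max = float(msd_p.pop("d_max_um", math.inf))
    tracks = ma.filter_by_diameter(tracks, d_min, d_max)
    window = int(msd_p.pop("window_frames", 20))
    stride = int(msd_p.pop("stride_frames", 1))
    n_fit = int(msd_p.pop("n_fit_lags", 5))
    max_lag = int(msd_p.pop("max_lag_frames", window - 1))
    windows = []
    for tr in tracks:
        windows.extend(ma.extract_windows(tr, window, stride))
    curve = ma.compute_msd(windows, max_lag, stack.frame_interval)
    _write_csv(outdir / "msd.csv", pd.DataFrame({
        "lag_s": curve.lags_s, "msd_um2": curve.msd_um2,
        "se_um2": curve.se_um2, "n_windows": curve.n_windows}))
    fit = ma.fit_diffusion(curve, n_fit_lags=n_fit)
    label, flagged = ma.classify_mobility(fit)
    fit_dict = {
        "D_um2_per_s": fit.D, "D_se": fit.D_se,
        "offset_um2": fit.offset_um2, "alpha": fit.alpha,
        "label": label, "alpha_undefined": flagged,
        "n_windows": curve.n_windows,
    }
    _write_json(outdir / "diffusion_fit.json", fit_dict)
    return {"diffusion_fit": fit_dict}


def _run_frap(config: RunConfig, stack, extra, outdir: Path):
    frap_p = config.stage("frap")
    per_frame, tracks = _segment_and_track(config, stack)
    if not tracks:
        raise ValueError("no droplet found in the FRAP stack")
    track = max(tracks, key=len)
    kind = frap_p.pop("roi_kind", "partial_disk")
    radius = frap_p.pop("roi_radius_um", None)
    if kind == "partial_disk" and radius is None:
        radius = 0.2 * track.observations[0].radius_um
    roi = fa.ROISpec(kind=kind, radius=radius,
                     side=frap_p.pop("roi_side", None))
    trace = fa.extract_trace(stack, track, roi,
                             bleach_frame=frap_p.pop("bleach_frame", None))
    trace = fa.normalize_trace(
        trace, prebleach_frames=frap_p.pop("prebleach_frames", None))
    _write_csv(outdir / "frap_trace.csv", pd.DataFrame({
        "t_s": trace.times, "raw": trace.raw,
        "normalized": trace.normalized}))
    fit = fa.fit_recovery(trace)
    fit_dict = {
        "k_per_s": fit.k, "t_half_s": fit.t_half, "plateau": fit.plateau,
        "bleach_floor": fit.bleach_floor,
        "mobile_fraction": fit.mobile_fraction,
        "converged": fit.converged,
    }
    _write_json(outdir / "recovery_fit.json", fit_dict)
    return {"recovery_fit": fit_dict}


def _run_phase(config: RunConfig, data, extra, outdir: Path):
    images, pixel_size = data
    phase_p = config.stage("phase")
    keyed = {}
    for i, row in enumerate(images):
        for j, img in enumerate(row):
            keyed[(float(j), float(i))] = img
    diagram = pdx.build_phase_diagram(keyed, pixel_size, **phase_p)
    _write_csv(outdir / "phase_diagram.csv",
               diagram.to_frame().reset_index(names="di_mM"))
    result = {"grid": diagram.grid.astype(int).tolist(),
              "counts": diagram.counts.tolist()}
    if "truth_grid" in extra:
        truth = np.asarray(extra["truth_grid"], dtype=bool)
        result["accuracy"] = float((diagram.grid == truth).mean())
    return {"phase_diagram": result}


def _run_dissolve(config: RunConfig, stack, extra, outdir: Path):
    dis_p = config.stage("dissolve")
    treatment = int(dis_p.pop("treatment_frame",
                              config.simulate.get("treatment_frame", 10)))
    res = pdx.dissolution_score(stack, treatment, **dis_p)
    res_dict = {
        "pre_area_um2": res.pre_area_um2, "post_area_um2": res.post_area_um2,
        "remaining_fraction": res.remaining_fraction, "verdict": res.verdict,
        "threshold": res.threshold,
    }
    _write_json(outdir / "dissolution.json", res_dict)
    return {"dissolution": res_dict}
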
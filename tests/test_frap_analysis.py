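"""FRAP trace extraction, normalization and recovery fitting."""

import math

import numpy as np
import pytest

import droprheo as dr
from droprheo.frap_analysis import (
    FRAPTrace,
    RecoveryFit,
    ROISpec,
    compare_halftimes,
    compare_lengths,
    extract_trace,
    fit_recovery,
    normalize_trace,
)


def make_trace(times, values, prebleach=5):
    return FRAPTrace(times=np.asarray(times, dtype=float),
                     raw=np.asarray(values, dtype=float),
                     prebleach_frames=prebleach, bleach_frame=prebleach)


def recovery(times, k, floor=0.2, plateau=1.0):
    return floor + (plateau - floor) * (1 - np.exp(-k * np.clip(times, 0,
                                                                None)))


def frap_track(stack):
    per_frame = dr.segment_stack(stack)
    tracks = dr.link_tracks(per_frame, max_displacement_um=1.0,
                            memory_frames=stack.n_frames)
    return max(tracks, key=len)


class TestNormalize:
    def test_constant_trace_normalizes_to_one(self):
        tr = normalize_trace(make_trace(np.arange(10) - 5.0, np.full(10, 7.)))
        assert np.allclose(tr.normalized, 1.0)

    def test_idempotent(self):
        t = np.arange(20) - 5.0
        raw = 3.0 * recovery(t, 0.1)
        raw[:5] = 3.0
        once = normalize_trace(make_trace(t, raw))
        twice = normalize_trace(once)
        assert np.allclose(once.normalized, twice.normalized)

    def test_double_normalization_cancels_acquisition_decay(self):
        t = np.arange(40) - 5.0
        clean = recovery(t, 0.1)
        clean[:5] = 1.0
        decay = np.exp(-0.005 * np.arange(40))     # ~20% by the end
        trace = make_trace(t, clean * decay)
        ref = make_trace(t, np.ones(40) * decay)
        double = normalize_trace(trace, reference=ref)
        assert np.allclose(double.normalized, clean, atol=0.02)

    def test_reference_cancellation_is_exact_for_shared_decay(self):
        t = np.arange(30) - 5.0
        clean = recovery(t, 0.2)
        clean[:5] = 1.0
        halving = 0.5 ** (np.arange(30) / 29)
        plain = normalize_trace(make_trace(t, clean))
        double = normalize_trace(make_trace(t, clean * halving),
                                 reference=make_trace(t, halving))
        assert np.allclose(double.normalized, plain.normalized)

    def test_needs_two_prebleach_frames(self):
        with pytest.raises(ValueError, match="pre-bleach"):
            normalize_trace(make_trace(np.arange(10), np.ones(10),
                                       prebleach=1))

    def test_zero_prebleach_mean_errors(self):
        with pytest.raises(ValueError, match="zero pre-bleach"):
            normalize_trace(make_trace(np.arange(10) - 5.0, np.zeros(10)))


class TestFitRecovery:
    def test_exact_curve_halftime(self):
        t = np.arange(-5, 400, 2.0)
        trace = make_trace(t, recovery(t, 0.01))
        trace.normalized = trace.raw
        fit = fit_recovery(trace)
        assert fit.t_half == pytest.approx(math.log(2) / 0.01, rel=1e-6)
        assert fit.t_half == pytest.approx(69.3, abs=0.05)
        assert fit.mobile_fraction == pytest.approx(1.0, rel=1e-6)

    def test_flat_post_bleach_has_zero_mobile_fraction(self):
        t = np.arange(-5, 30, 1.0)
        y = np.where(t < 0, 1.0, 0.2)
        trace = make_trace(t, y)
        trace.normalized = trace.raw
        fit = fit_recovery(trace)
        assert fit.mobile_fraction == pytest.approx(0.0, abs=1e-6)

    def test_invariant_to_time_shift_and_intensity_scale(self):
        t = np.arange(-5, 60, 1.0)
        raw = 40.0 * recovery(t, 0.05)
        raw[t < 0] = 40.0
        base = fit_recovery(normalize_trace(make_trace(t, raw)))
        scaled = fit_recovery(normalize_trace(make_trace(t, raw * 12.5)))
        assert scaled.k == pytest.approx(base.k, rel=1e-9)
        shifted = FRAPTrace(times=t + 100.0, raw=raw, prebleach_frames=5)
        shifted = normalize_trace(shifted)
        fit_shift = fit_recovery(shifted, t0=100.0)
        assert fit_shift.k == pytest.approx(base.k, rel=1e-6)

    def test_requires_enough_post_bleach_points(self):
        t = np.arange(-5, 4, 1.0)
        trace = make_trace(t, np.ones(t.size))
        trace.normalized = trace.raw
        with pytest.raises(ValueError, match="post-bleach"):
            fit_recovery(trace)


class TestExtractTrace:
    def test_uniform_droplet_partial_roi_equals_droplet_mean(self,
                                                             frap_optics):
        truth = dr.FrapGroundTruth(droplet_radius=4.0, D_in=0.5,
                                   bleach_depth=0.0)
        stack, _, _ = dr.simulate_frap_movie(truth, frap_optics, n_frames=20,
                                             frame_interval=0.5,
                                             bleach_frame=5, seed=0,
                                             noise=False)
        track = frap_track(stack)
        part = extract_trace(stack, track,
                             ROISpec(kind="partial_disk", radius=0.8),
                             bleach_frame=5)
        whole = extract_trace(stack, track, ROISpec(kind="whole_droplet"),
                              bleach_frame=5)
        # uniform concentration: small interior ROI ~ whole-droplet mean
        # (whole-droplet mean is slightly diluted by the blurred rim)
        assert part.raw[0] == pytest.approx(1.0, abs=0.02)
        assert whole.raw[0] <= part.raw[0] + 1e-9

    def test_extracted_trace_tracks_ground_truth(self, frap_optics):
        roi = ROISpec(kind="partial_disk", radius=1.0)
        truth = dr.FrapGroundTruth(droplet_radius=5.0, D_in=0.5,
                                   bleach_depth=0.8, bleach_roi=roi)
        stack, _, gt = dr.simulate_frap_movie(truth, frap_optics, n_frames=60,
                                              frame_interval=0.5,
                                              bleach_frame=5, seed=1)
        trace = extract_trace(stack, frap_track(stack), roi)
        assert trace.bleach_frame == 5
        norm = normalize_trace(trace).normalized
        gt_norm = gt["roi_concentration"].to_numpy()
        gt_norm = gt_norm / gt_norm[:5].mean()
        # blur + shot noise envelope around the lattice ground truth
        assert np.max(np.abs(norm[8:] - gt_norm[8:])) < 0.12

    def test_no_bleach_is_flagged(self, frap_optics):
        truth = dr.FrapGroundTruth(droplet_radius=4.0, D_in=0.5,
                                   bleach_depth=0.0)
        stack, _, _ = dr.simulate_frap_movie(truth, frap_optics, n_frames=20,
                                             frame_interval=0.5,
                                             bleach_frame=5, seed=2)
        trace = extract_trace(stack, frap_track(stack),
                              ROISpec(kind="partial_disk", radius=0.8))
        assert not trace.bleach_found

    def test_roi_exiting_droplet_names_frame(self, frap_optics):
        truth = dr.FrapGroundTruth(droplet_radius=4.0, D_in=0.5,
                                   bleach_depth=0.8)
        stack, _, _ = dr.simulate_frap_movie(truth, frap_optics, n_frames=20,
                                             frame_interval=0.5,
                                             bleach_frame=5, seed=3)
        roi = ROISpec(kind="partial_disk", center=(3.5, 0.0), radius=1.0)
        with pytest.raises(ValueError, match="frame 0"):
            extract_trace(stack, frap_track(stack), roi)

    def test_mobile_fraction_recovery_with_immobile_split(self, frap_optics):
        roi = ROISpec(kind="partial_disk", radius=1.0)
        truth = dr.FrapGroundTruth(droplet_radius=8.0, D_in=1.0,
                                   immobile_fraction=0.3, bleach_depth=0.8,
                                   bleach_roi=roi)
        stack, _, _ = dr.simulate_frap_movie(truth, frap_optics, n_frames=240,
                                             frame_interval=0.5,
                                             bleach_frame=5, seed=4)
        trace = normalize_trace(extract_trace(stack, frap_track(stack), roi))
        fit = fit_recovery(trace)
        assert fit.mobile_fraction == pytest.approx(0.7, abs=0.05)


class TestComparisons:
    def _fit(self, t_half):
        return RecoveryFit(k=math.log(2) / t_half, plateau=1.0,
                           bleach_floor=0.2, rss=0.0, n_points=50)

    def test_identical_conditions_fold_one(self):
        fits = [self._fit(10.0)] * 3
        table = compare_halftimes({"a": fits, "b": list(fits)}, n_boot=200,
                                  seed=0)
        row = table[(table["condition_a"] == "a")
                    & (table["condition_b"] == "b")].iloc[0]
        assert row["fold"] == pytest.approx(1.0)
        assert row["ci_low"] <= 1.0 <= row["ci_high"]

    def test_single_fit_condition_errors(self):
        with pytest.raises(ValueError, match="fewer than 3"):
            compare_halftimes({"a": [self._fit(10.0)],
                               "b": [self._fit(10.0)] * 3})

    def test_threefold_difference_recovered(self):
        rng = np.random.default_rng(5)
        slow = [self._fit(30.0 * (1 + rng.normal(0, 0.05)))
                for _ in range(6)]
        fast = [self._fit(10.0 * (1 + rng.normal(0, 0.05)))
                for _ in range(6)]
        table = compare_halftimes({"slow": slow, "fast": fast}, n_boot=500,
                                  seed=1)
        row = table[(table["condition_a"] == "slow")
                    & (table["condition_b"] == "fast")].iloc[0]
        assert 2.5 <= row["fold"] <= 3.6

    def test_length_monotonicity_verdicts(self):
        dec = {7: self._fit(5.0), 12: self._fit(15.0), 17: self._fit(60.0)}
        # slower recovery at larger length -> recovery level decreases
        rep = compare_lengths(dec, readout_time_s=10.0)
        assert rep["verdict"] == "monotone-decreasing"
        inc = {7: self._fit(60.0), 12: self._fit(15.0), 17: self._fit(5.0)}
        assert compare_lengths(inc, 10.0)["verdict"] == "monotone-increasing"
        flat = {7: self._fit(10.0), 12: self._fit(10.0), 17: self._fit(10.0)}
        assert compare_lengths(flat, 10.0)["verdict"] == "non-monotone"
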
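"""Generator-level checks: optics model limits, physical invariants of each
ground truth, and reproducibility."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import droprheo as dr
from droprheo.frap_analysis import ROISpec
from droprheo.synthetic_scenes import _diffuse


class TestRenderFrame:
    def test_background_only_limit(self):
        optics = dr.OpticsModel(pixel_size=0.1, background_level=10.0,
                                photon_scale=1e6, read_noise_sigma=0.0)
        img = dr.render_frame([], optics, (32, 32),
                              np.random.default_rng(0))
        assert np.allclose(img, 10.0, rtol=1e-2)

    def test_zero_intensity_droplet_is_background(self):
        optics = dr.OpticsModel(pixel_size=0.1, background_level=0.2)
        blank = dr.render_frame([], optics, (64, 64))
        ghost = dr.render_frame([((3.2, 3.2), (2.0, 2.0), 0.0, 0.0)],
                                optics, (64, 64))
        assert np.array_equal(blank, ghost)

    def test_diameter_round_trip_within_2pct(self, optics):
        img = dr.render_frame([((6.4, 6.4), (4.0, 4.0), 0.0, 1.0)],
                              optics, (128, 128))
        obs = dr.segment_frame(img, optics.pixel_size)
        assert len(obs) == 1
        assert obs[0].equivalent_diameter_um == pytest.approx(4.0, rel=0.02)

    def test_droplet_outside_field_errors(self, optics):
        with pytest.raises(ValueError, match="does not fit"):
            dr.render_frame([((0.5, 5.0), (4.0, 4.0), 0.0, 1.0)],
                            optics, (128, 128))

    def test_non_positive_axes_error(self, optics):
        with pytest.raises(ValueError, match="axes"):
            dr.render_frame([((5.0, 5.0), (0.0, 2.0), 0.0, 1.0)],
                            optics, (128, 128))

    def test_seeded_rendering_is_bit_reproducible(self, optics):
        args = ([((5.0, 5.0), (3.0, 3.0), 0.0, 1.0)], optics, (100, 100))
        a = dr.render_frame(*args, np.random.default_rng(7))
        b = dr.render_frame(*args, np.random.default_rng(7))
        assert np.array_equal(a, b)


class TestFusionGroundTruth:
    def test_tau_is_icv_times_length(self):
        truth = dr.FusionGroundTruth(d1=3.0, d2=3.0, icv_true=0.5)
        assert truth.tau_true == pytest.approx(3.0)

    def test_final_diameter_conserves_volume(self):
        truth = dr.FusionGroundTruth(d1=3.0, d2=3.0, icv_true=0.5)
        assert truth.d_final == pytest.approx(3.0 * 2 ** (1 / 3))

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(d1=st.floats(1.0, 8.0), d2=st.floats(1.0, 8.0),
           icv=st.floats(0.1, 2.0), t=st.floats(0.0, 50.0))
    def test_spheroid_volume_conserved_at_all_times(self, d1, d2, icv, t):
        truth = dr.FusionGroundTruth(d1=d1, d2=d2, icv_true=icv)
        a, b = truth.spheroid_axes(t)
        assert a * b * b == pytest.approx(d1 ** 3 + d2 ** 3, rel=1e-12)
        assert a / b == pytest.approx(float(truth.ar_at(t)), rel=1e-12)

    def test_ar_schedule_log_linear(self):
        truth = dr.FusionGroundTruth(d1=2.0, d2=4.0, icv_true=0.5)
        t = np.linspace(0, 3 * truth.tau_true, 40)
        log_excess = np.log(np.asarray(truth.ar_at(t)) - 1.0)
        slope = np.polyfit(t, log_excess, 1)[0]
        assert slope == pytest.approx(-1.0 / truth.tau_true, rel=1e-10)

    def test_movie_too_short_errors(self, optics):
        truth = dr.FusionGroundTruth(d1=3.0, d2=3.0, icv_true=0.5)
        with pytest.raises(ValueError, match="3\\*tau"):
            dr.simulate_fusion_movie(truth, optics, n_frames=8,
                                     frame_interval=0.25)

    def test_bad_frame_interval_errors(self, optics):
        truth = dr.FusionGroundTruth(d1=3.0, d2=3.0, icv_true=0.5)
        with pytest.raises(ValueError, match="frame_interval"):
            dr.simulate_fusion_movie(truth, optics, frame_interval=0.0)


class TestBrownianGenerator:
    def test_zero_diffusion_is_static(self, coarse_optics):
        truth = dr.MotionGroundTruth(D_true=0.0, diameters=(4.0,),
                                     arena=(20.0, 20.0))
        _, traj = dr.simulate_brownian_movie(truth, coarse_optics,
                                             n_frames=10,
                                             frame_interval=0.5, seed=0)
        pos = traj[["x_um", "y_um"]].to_numpy()
        assert np.ptp(pos, axis=0) == pytest.approx([0.0, 0.0])

    def test_step_variance_matches_2d_dt(self, coarse_optics):
        # empirical per-step displacement variance within 3 SE of 2·D·Δt
        D, dt = 0.05, 0.5
        truth = dr.MotionGroundTruth(D_true=D, diameters=(4.0,) * 6,
                                     arena=(80.0, 60.0))
        _, traj = dr.simulate_brownian_movie(truth, coarse_optics,
                                             n_frames=200,
                                             frame_interval=dt, seed=3)
        steps = []
        for _, g in traj.groupby("droplet"):
            steps.append(np.diff(g[["x_um", "y_um"]].to_numpy(), axis=0))
        steps = np.concatenate(steps).ravel()   # per-axis increments
        var = steps.var()
        se = steps.var() * np.sqrt(2.0 / (steps.size - 1))
        assert abs(var - 2 * D * dt) < 3 * se
        assert steps.size >= 2000

    def test_confined_mode_respects_radius(self, coarse_optics):
        truth = dr.MotionGroundTruth(D_true=0.05, diameters=(4.0,),
                                     arena=(20.0, 20.0),
                                     confinement_radius=1.0)
        _, traj = dr.simulate_brownian_movie(truth, coarse_optics,
                                             n_frames=300,
                                             frame_interval=0.5, seed=4)
        pos = traj[["x_um", "y_um"]].to_numpy()
        d = np.hypot(*(pos - pos[0]).T)
        assert d.max() <= 1.0 + 1e-9

    def test_same_seed_same_movie(self, coarse_optics):
        truth = dr.MotionGroundTruth(D_true=0.05, diameters=(4.0,),
                                     arena=(20.0, 20.0))
        s1, t1 = dr.simulate_brownian_movie(truth, coarse_optics, 5, 0.5,
                                            seed=11)
        s2, t2 = dr.simulate_brownian_movie(truth, coarse_optics, 5, 0.5,
                                            seed=11)
        assert np.array_equal(s1.frames, s2.frames)
        assert t1.equals(t2)


class TestFrapGenerator:
    def test_mass_conserved_without_exchange(self):
        # reflecting boundary: total fluorescence constant between bleaches
        rng = np.random.default_rng(0)
        n = 41
        yy, xx = np.mgrid[:n, :n] - n // 2
        disk = xx ** 2 + yy ** 2 <= 18 ** 2
        c = np.where(disk, rng.uniform(0.5, 1.5, (n, n)), 0.0)
        before = c.sum()
        after = _diffuse(c, disk, alpha=0.2, n_steps=1000).sum()
        assert after == pytest.approx(before, rel=1e-9)

    def test_no_transport_without_diffusion(self, frap_optics):
        truth = dr.FrapGroundTruth(droplet_radius=4.0, D_in=0.0,
                                   immobile_fraction=0.0, bleach_depth=0.8)
        _, _, gt = dr.simulate_frap_movie(truth, frap_optics, n_frames=30,
                                          frame_interval=0.5, bleach_frame=5,
                                          seed=0, noise=False)
        post = gt["roi_concentration"].to_numpy()[5:]
        assert np.allclose(post, post[0])
        assert post[0] == pytest.approx(0.2, abs=1e-9)

    def test_zero_bleach_depth_stays_flat(self, frap_optics):
        truth = dr.FrapGroundTruth(droplet_radius=4.0, D_in=0.5,
                                   bleach_depth=0.0)
        _, _, gt = dr.simulate_frap_movie(truth, frap_optics, n_frames=30,
                                          frame_interval=0.5, bleach_frame=5,
                                          seed=0, noise=False)
        trace = gt["roi_concentration"].to_numpy()
        assert np.allclose(trace / trace[:5].mean(), 1.0)

    def test_whole_droplet_bleach_never_recovers(self, frap_optics):
        # closed droplet: no exchange with the dilute phase, no recovery
        truth = dr.FrapGroundTruth(
            droplet_radius=4.0, D_in=0.5, bleach_depth=0.8,
            bleach_roi=ROISpec(kind="whole_droplet"))
        _, _, gt = dr.simulate_frap_movie(truth, frap_optics, n_frames=40,
                                          frame_interval=0.5, bleach_frame=5,
                                          seed=0, noise=False)
        post = gt["droplet_concentration"].to_numpy()[5:]
        assert np.allclose(post, 0.2, atol=1e-9)

    def test_exchange_refills_whole_droplet(self, frap_optics):
        truth = dr.FrapGroundTruth(
            droplet_radius=4.0, D_in=0.5, bleach_depth=0.8,
            bleach_roi=ROISpec(kind="whole_droplet"), exchange_rate=0.05)
        _, _, gt = dr.simulate_frap_movie(truth, frap_optics, n_frames=100,
                                          frame_interval=0.5, bleach_frame=5,
                                          seed=0, noise=False)
        trace = gt["droplet_concentration"].to_numpy()
        assert trace[-1] > 0.85   # recovers toward the reservoir level

    def test_lattice_spacing_guard(self):
        coarse = dr.OpticsModel(pixel_size=1.0)
        truth = dr.FrapGroundTruth(droplet_radius=4.0, D_in=0.5)
        with pytest.raises(ValueError, match="radius/10"):
            dr.simulate_frap_movie(truth, coarse, n_frames=20,
                                   frame_interval=0.5)


class TestDissolutionAndGrid:
    def test_fluid_droplets_vanish_after_treatment(self, optics):
        stack, info = dr.simulate_dissolution_movie(
            False, optics, treatment_frame=8, n_frames=20, seed=0,
            shape=(200, 200), n_droplets=6)
        late = stack.frames[-1]
        early = stack.frames[0]
        bg = optics.background_level
        # bright pixels (droplets) present early, gone late
        assert np.percentile(early, 99) > 5 * bg
        assert np.percentile(late, 99) < 2 * bg

    def test_crosslinked_field_is_static(self, optics):
        stack, info = dr.simulate_dissolution_movie(
            True, optics, treatment_frame=8, n_frames=20, seed=0,
            shape=(200, 200), n_droplets=6, noise=False)
        assert np.array_equal(stack.frames[0], stack.frames[-1])
        assert info["persists"].all()

    def test_grid_truth_matches_request(self, optics):
        grid = np.array([[True, False], [False, True]])
        images, truth = dr.simulate_condition_grid(grid, optics, seed=0,
                                                   shape=(128, 128))
        assert np.array_equal(truth, grid)
        # absent cells are background-only (up to shot noise)
        bg = optics.background_level
        assert images[0][1].mean() == pytest.approx(bg, rel=0.1)
        assert np.percentile(images[0][1], 99) < 2 * bg
        assert np.percentile(images[0][0], 99) > 5 * bg
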
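import numpy as np
import pytest

import droprheo as dr


@pytest.fixture(scope="session")
def optics():
    """Default fluorescence-like optics at SNR 10."""
    return dr.OpticsModel(pixel_size=0.1, blur_sigma=1.0,
                          background_level=0.1,
                          photon_scale=dr.photon_scale_for_snr(10.0))


@pytest.fixture(scope="session")
def coarse_optics():
    """Coarser calibration for larger fields (mobility movies)."""
    return dr.OpticsModel(pixel_size=0.15, blur_sigma=1.0,
                          background_level=0.1,
                          photon_scale=dr.photon_scale_for_snr(10.0))


@pytest.fixture(scope="session")
def frap_optics():
    """Sharp, clean optics for FRAP lattices (PSF small vs bleach spot)."""
    return dr.OpticsModel(pixel_size=0.2, blur_sigma=0.75,
                          background_level=0.1,
                          photon_scale=dr.photon_scale_for_snr(20.0))


def analyze_fusion_movie(stack, max_displacement_um=0.8):
    """segment → track → detect fusions on a single movie."""
    per_frame = dr.segment_stack(stack)
    tracks = dr.link_tracks(per_frame, max_displacement_um=max_displacement_um)
    return dr.detect_fusions(tracks, stack.frame_interval)


def track_brownian_movie(stack, min_diameter_um=2.0, max_displacement_um=1.0):
    per_frame = dr.segment_stack(stack, min_diameter_um=min_diameter_um)
    return dr.link_tracks(per_frame, max_displacement_um=max_displacement_um)


@pytest.fixture(scope="session")
def fusion_event(optics):
    """One clean detected fusion event (d1=d2=3 μm, η/γ=0.5 s/μm)."""
    truth = dr.FusionGroundTruth(d1=3.0, d2=3.0, icv_true=0.5)
    stack, truth = dr.simulate_fusion_movie(truth, optics,
                                            frame_interval=0.3, seed=1)
    events = analyze_fusion_movie(stack)
    assert len(events) == 1
    return events[0], truth


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
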
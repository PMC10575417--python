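import numpy as np
import pytest

from uctnet import (
    default_sim_config,
    embed_clot,
    feature_matrix,
    make_head_phantom,
    normalize_matrix,
    place_sensors,
    ricker_wavelet,
    sample_clot,
    scaled_2d_spec,
    simulate_survey,
)


@pytest.fixture(scope="session")
def small_spec():
    """32 mm desk phantom: fast enough for per-test simulation."""
    return scaled_2d_spec(grid=32, spacing=1.0)


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    return make_head_phantom(small_spec)


@pytest.fixture(scope="session")
def small_sensors(small_phantom):
    return place_sensors(small_phantom, 8)


@pytest.fixture(scope="session")
def small_survey(small_phantom, small_sensors):
    """8-shot survey on a clot-bearing heterogeneous 32 mm phantom."""
    clot = sample_clot(small_phantom, (1.5, 2.5), 1700.0, seed=11)
    ph = embed_clot(small_phantom, clot)
    cfg = default_sim_config(ph, record_time=8e-5, sponge_width=5, sponge_strength=0.06)
    wav = ricker_wavelet(300e3, cfg.dt, 2.4e-5)
    survey = simulate_survey(ph, small_sensors, wav, cfg)
    return {"survey": survey, "phantom": ph, "clot": clot, "cfg": cfg, "wavelet": wav}


@pytest.fixture(scope="session")
def small_feature(small_survey):
    survey = small_survey["survey"]
    return normalize_matrix(feature_matrix(survey, 300e3))
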
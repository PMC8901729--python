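"""Shared synthetic acquisitions (generated once per session)."""

from __future__ import annotations

import numpy as np
import pytest

from radialtherm import make_scene, simulate_acquisition, track
from radialtherm.preprocess import (correct_all, estimate_noise,
                                    prewhiten_and_compress)
from radialtherm.simulate import default_params


@pytest.fixture(scope="session")
def static_scene():
    """Noiseless static 48-matrix scene (exact-oracle work)."""
    return make_scene({"matrix": 48, "fov_mm": 96.0, "snr": 0,
                       "motion": {"kind": "static"}, "motion_phase_rad": 0.0,
                       "hotspot": {"t_start_s": 500.0, "t_stop_s": 600.0}})


@pytest.fixture(scope="session")
def static_params(static_scene):
    return default_params(static_scene)


@pytest.fixture(scope="session")
def noisy_static_run():
    """Static scene at the default SNR with 400 spokes (tracking noise)."""
    scene = make_scene({"matrix": 48, "fov_mm": 96.0, "seed": 3,
                        "motion": {"kind": "static"},
                        "hotspot": {"t_start_s": 500.0, "t_stop_s": 600.0}})
    params = default_params(scene)
    k = simulate_acquisition(scene, params, 400, seed=3)
    return scene, params, k


@pytest.fixture(scope="session")
def phantom_run():
    """Square-wave phantom: 60 s of data, tracked, whitened and corrected.

    Learning span is the first 30 s (1242 spokes); heating never starts
    within the simulated 60 s, so the whole span is a valid baseline.
    """
    scene = make_scene({"matrix": 48, "fov_mm": 96.0, "seed": 1,
                        "motion": {"kind": "square_wave",
                                   "amplitude_mm": (26.0, 0.0),
                                   "frequency_hz": 0.33},
                        "hotspot": {"t_start_s": 60.0, "t_stop_s": 90.0}})
    params = default_params(scene)
    n_spokes = int(60.0 / params.tr_s) // 2 * 2
    k = simulate_acquisition(scene, params, n_spokes, seed=1)
    n_learning = 1242
    traces = track(k, learning_mask=np.arange(n_spokes) < n_learning)
    k_white, model = prewhiten_and_compress(k, estimate_noise(k), 0.90)
    k_corr = correct_all(k_white, traces["filtered"], mean_span_s=(0.0, 30.0))
    return {"scene": scene, "params": params, "k": k, "traces": traces,
            "k_white": k_white, "k_corr": k_corr, "n_learning": n_learning}
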
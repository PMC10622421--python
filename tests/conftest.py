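"""Shared fixtures: small synthetic scenes with exact ground truth."""

import logging

import numpy as np
import pytest

import capiflow as cf

logging.getLogger("capiflow").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def straight_path() -> cf.VesselPath:
    """A long straight capillary centreline, well inside a 48x256 image."""
    return cf.VesselPath("v0", "SL", "C", ((8.0, 24.0), (248.0, 24.0)))


@pytest.fixture(scope="session")
def clean_movie(straight_path):
    """Noise-free single-vessel movie at 1000 µm/s (the worked-example speed)."""
    vessel = cf.VesselSpec(
        path=straight_path, diameter_um=8.0, mean_speed_um_s=1000.0,
        spot_rate_per_s=4.0,
    )
    spec = cf.SynthSpec(
        image_size=(48, 256), duration_s=3.1, vessels=[vessel], seed=11
    )
    series, truth = cf.render_movie(spec)
    return spec, series, truth


@pytest.fixture(scope="session")
def noisy_movie(straight_path):
    """Same scene with Poisson + Gaussian noise (spot SNR ≈ 13)."""
    vessel = cf.VesselSpec(
        path=straight_path, diameter_um=8.0, mean_speed_um_s=1000.0,
        spot_rate_per_s=4.0,
    )
    spec = cf.SynthSpec(
        image_size=(48, 256), duration_s=3.1, vessels=[vessel],
        gaussian_sd=2.0, poisson_scale=1.0, seed=11,
    )
    series, truth = cf.render_movie(spec)
    return spec, series, truth


@pytest.fixture(scope="session")
def branching_network():
    return cf.make_network("branching", (64, 128), 4.93, seed=2)


def match_detections(found: np.ndarray, truth: np.ndarray, tol_px: float = 1.5):
    """Greedy nearest matching of detections to ground-truth centres."""
    used: set[int] = set()
    matched = 0
    for t in truth:
        if len(found) == 0:
            break
        d = np.hypot(found[:, 0] - t[0], found[:, 1] - t[1])
        cand = [i for i in np.argsort(d) if d[i] <= tol_px and i not in used]
        if cand:
            used.add(cand[0])
            matched += 1
    tp = matched
    fn = len(truth) - matched
    fp = len(found) - matched
    return tp, fp, fn
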
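"""Shared fixtures: phantom recordings and end-to-end pipeline runs.

Pipeline runs are session-scoped because each one costs several seconds;
every test that needs a segmented phantom reuses the same run.
"""

from __future__ import annotations

import numpy as np
import pytest

import glottikit as gk
from glottikit.pipeline import RunConfig, segment_video


@pytest.fixture(scope="session")
def clean_run():
    """Clean 200-frame phantom segmented end to end."""
    spec = gk.load_preset("clean", n_frames=200, seed=1)
    cube, truth = gk.generate(spec)
    track = segment_video(cube, RunConfig(roi_f0_hz=spec.f0))
    return spec, cube, truth, track


@pytest.fixture(scope="session")
def full_run():
    """Stress phantom (drift + chink + flashes + noise) segmented end to end."""
    spec = gk.load_preset("full", n_frames=200, seed=1)
    cube, truth = gk.generate(spec)
    track = segment_video(cube, RunConfig(roi_f0_hz=spec.f0))
    return spec, cube, truth, track


@pytest.fixture(scope="session")
def drift_phantom():
    """One full endoscope-drift cycle (15 Hz at 4000 fps, 8 px amplitude)."""
    spec = gk.load_preset("drift", n_frames=267, seed=3)
    cube, truth = gk.generate(spec)
    return spec, cube, truth


@pytest.fixture(scope="session")
def angled_runs():
    """Phantoms at 60/90/120-degree glottal axes, segmented end to end."""
    out = {}
    for ang in (60.0, 90.0, 120.0):
        spec = gk.PhantomSpec(n_frames=150, seed=2, glottis_angle=ang,
                              noise_sigma=2.0)
        cube, truth = gk.generate(spec)
        track = segment_video(cube, RunConfig(roi_f0_hz=spec.f0))
        out[ang] = (spec, cube, truth, track)
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
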
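"""Shared fixtures: noiseless and noisy synthetic dissolution runs."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

import gridrelease as gr

settings.register_profile("ci", derandomize=True, max_examples=200)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def implant_names():
    return [rec.name for rec in gr.STUDY_IMPLANTS]


@pytest.fixture(scope="session")
def noiseless_spec():
    """One implant run with every measurement imperfection switched off."""
    return gr.implant_spec("0.8 × 0.8", seed=7, noise_sigma=0.0,
                           degradant_fraction=0.0, recovery=1.0)


@pytest.fixture(scope="session")
def noiseless_profile(noiseless_spec):
    events = gr.simulate_study(noiseless_spec)
    return gr.cumulative_release(events, noiseless_spec.dose_mg,
                                 noiseless_spec.unit_id)


@pytest.fixture(scope="session")
def study_profiles(implant_names):
    """Nine fixture implants with the default measurement imperfections."""
    profiles = {}
    for i, name in enumerate(implant_names):
        spec = gr.implant_spec(name, seed=100 + i)
        events = gr.simulate_study(spec)
        profiles[name] = gr.cumulative_release(events, spec.dose_mg, name)
    return profiles


def power_law_profile(k=0.05, n=0.65, dose=30.0, times=None, unit_id="toy"):
    """Exact power-law release profile M_t/M_inf = k·tⁿ."""
    t = np.asarray(times if times is not None else np.arange(1.0, 61.0))
    return gr.ReleaseProfile(unit_id, t, dose * k * t**n, dose)
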
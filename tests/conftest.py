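"""Shared fixtures: one small synthetic head/sensor/lead-field setup,
built once per session and reused read-only by the module tests."""

import numpy as np
import pytest

from sourcestorm import forward as fw
from sourcestorm import inverse as inv
from sourcestorm import simulate as sim
from sourcestorm.core_io import ChannelInfo, Recording, SensorArray


@pytest.fixture(scope="session")
def sim_spec():
    return sim.SimSpec(seed=11, n_eeg=24, n_meg=32, cortex_subdivisions=3)


@pytest.fixture(scope="session")
def head(sim_spec):
    return sim.make_head(sim_spec)


@pytest.fixture(scope="session")
def sensors(sim_spec, head):
    return sim.make_sensors(sim_spec, head["scalp"])


@pytest.fixture(scope="session")
def source_space(head):
    return fw.build_source_space(head["cortex"], target_n=300, seed=0)


@pytest.fixture(scope="session")
def sphere_model(head):
    center, radius = fw.fit_sphere(head["scalp"].vertices)
    return fw.SphereModel.three_shell(center, radius)


@pytest.fixture(scope="session")
def leadfield(sphere_model, source_space, sensors):
    return fw.compute_leadfield(sphere_model, source_space, sensors)


@pytest.fixture(scope="session")
def noise_cov(leadfield):
    """Noise covariance estimated from a long simulated noise-only recording."""
    rng = np.random.default_rng(99)
    profile = sim.noise_profile(leadfield)
    data = profile[:, None] * rng.standard_normal((len(profile), 20000))
    channels = [
        ChannelInfo(name=n,
                    kind="MEG_MAG" if n.startswith("MEG") else "EEG",
                    orientation=[0, 0, 1.0] if n.startswith("MEG") else None)
        for n in leadfield.row_channels]
    rec = Recording(data=data, sfreq=250.0, sensors=SensorArray(channels=channels))
    return inv.estimate_noise_cov(rec, loading=0.1)


@pytest.fixture(scope="session")
def noise_profile(leadfield):
    return sim.noise_profile(leadfield)
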
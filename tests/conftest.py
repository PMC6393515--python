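import numpy as np
import pytest

from deepmeg.forward import Sphere, compute_leadfield, make_grid, make_helmet
from deepmeg.io import Contact, build_bipolar_montage
from deepmeg.simulate import make_default_montage, scenario_presets, simulate_session


@pytest.fixture(scope="session")
def sphere():
    return Sphere()


@pytest.fixture(scope="session")
def sensors64(sphere):
    return make_helmet(n_sensors=64)


@pytest.fixture(scope="session")
def leadfield_coarse(sphere, sensors64):
    grid = make_grid(sphere, spacing=0.015)
    return compute_leadfield(grid, sensors64, sphere, spacing=0.015)


@pytest.fixture(scope="session")
def m_session(sphere, sensors64):
    """A small mesial-network session shared by slow integration tests."""
    scenario = scenario_presets("M", seed=11, duration=80.0)
    montage = make_default_montage(scenario, n_electrodes=6, sphere=sphere, seed=11)
    return simulate_session(scenario, sensors64, sphere, montage)


def make_electrode(electrode: str, tissues, label="hippocampus", start=(20.0, 15.0, 0.0)):
    """Linear electrode with the given per-contact tissue sequence."""
    contacts = []
    for k, tissue in enumerate(tissues):
        contacts.append(
            Contact(
                contact_id=f"{electrode}{k + 1}",
                electrode=electrode,
                index=k + 1,
                position_mm=(start[0] + 3.5 * k, start[1], start[2]),
                label=label,
                tissue=tissue,
            )
        )
    return contacts


@pytest.fixture
def simple_montage():
    return build_bipolar_montage(make_electrode("A", ["gray", "gray", "gray"]))
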
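import numpy as np
import pytest

import dsbkit as dk


@pytest.fixture(scope="session")
def fixture_20bp():
    return dk.build_bdna_fixture(20)


@pytest.fixture(scope="session")
def fixture_60bp():
    return dk.build_bdna_fixture(60)


@pytest.fixture(scope="session")
def linac_spectrum():
    return dk.synth_linac_spectrum()


@pytest.fixture(scope="session")
def physics():
    return dk.default_physics()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260925)


def random_events_on(geometry, rng, n, energy_lo=5.0, energy_hi=120.0):
    """Uniform random deposition events inside a geometry's bounding box."""
    pos = geometry.box_min + rng.random((n, 3)) * (
        geometry.box_max - geometry.box_min
    )
    energies = energy_lo + rng.random(n) * (energy_hi - energy_lo)
    return [
        dk.DepositionEvent(position=p, energy_ev=float(e), primary_id=i)
        for i, (p, e) in enumerate(zip(pos, energies))
    ]
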
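"""Shared fixtures.

Expensive simulations (steady-state pacing of the TNNP model, the
reference bundle) are session-scoped so that every test file reuses the
same paced beat instead of re-integrating it.
"""

import numpy as np
import pytest

from cardiofit.models import build_passive_membrane, build_tnnp_model
from cardiofit.pacing import StimulusProtocol, pace_to_steady_state
from cardiofit.pipeline import prepare_reference
from cardiofit.rm import define_regions, find_singularities, segment_ap


@pytest.fixture(scope="session")
def protocol():
    return StimulusProtocol()  # 20 pA/pF, 2 ms, 1 Hz, 20 beats


@pytest.fixture(scope="session")
def protocol5():
    """Scaled-down pacing used by optimization tests (5 beats)."""
    return StimulusProtocol(n_beats=5)


@pytest.fixture(scope="session")
def tnnp_model():
    return build_tnnp_model()


@pytest.fixture(scope="session")
def tnnp_paced(tnnp_model, protocol):
    return pace_to_steady_state(tnnp_model, protocol)


@pytest.fixture(scope="session")
def tnnp_segments(tnnp_paced):
    return segment_ap(tnnp_paced.trace)


@pytest.fixture(scope="session")
def tnnp_singularities(tnnp_model, protocol, tnnp_paced):
    return find_singularities(tnnp_model, protocol, 1.0, paced=tnnp_paced)


@pytest.fixture(scope="session")
def tnnp_regions(tnnp_paced, tnnp_singularities):
    vm = tnnp_paced.trace.vm
    return define_regions([tnnp_singularities],
                          span_mV=(float(vm.min()), float(vm.max())))


@pytest.fixture(scope="session")
def passive_model():
    return build_passive_membrane(1.0, -85.0, 180.0)


@pytest.fixture(scope="session")
def baseline_bundle(protocol5):
    """Baseline-configuration reference bundle at the scaled-down budget."""
    return prepare_reference("baseline", protocol5)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
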
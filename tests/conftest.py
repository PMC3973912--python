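"""Shared fixtures: the packaged models and the expensive solved states.

The calibrated document and the aerobiosis sweep are session-scoped so the
acceptance tests share one continuation run.
"""

import numpy as np
import pytest

from tkm import (
    build_fixture,
    calibrate_oxygen_supply,
    solve_steady_state,
    sweep,
)


@pytest.fixture(scope="session")
def toy_doc():
    return build_fixture("toy")


@pytest.fixture(scope="session")
def core_doc():
    return build_fixture("core")


@pytest.fixture(scope="session")
def anaerobic_state(core_doc):
    state = solve_steady_state(core_doc)
    assert state.outcome == "steady"
    return state


@pytest.fixture(scope="session")
def calibrated_doc(core_doc):
    doc = core_doc.copy()
    calibrate_oxygen_supply(doc)
    return doc


@pytest.fixture(scope="session")
def aerobiosis_sweep(calibrated_doc):
    grid = np.linspace(0.0, 100.0, 41)
    return sweep(calibrated_doc, "chemostat.aerobiosis", grid)
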
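"""Shared fixtures: expensive steady-state models are session-scoped."""

import numpy as np
import pytest

from myoloop import HeartModel


@pytest.fixture(scope="session")
def steady_reference():
    """Reference model converged under homeostatic regulation."""
    model = HeartModel()
    beat = model.run_to_steady_state(beats_max=150)
    return model, beat


@pytest.fixture()
def reference_clone(steady_reference):
    model, _ = steady_reference
    return model.clone()
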
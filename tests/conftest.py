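import math

import numpy as np
import pytest

from nucleorheo.models import (
    Interface,
    MaterialParams,
    ModelClass,
    StressContext,
)
from nucleorheo import synthetic as syn


@pytest.fixture
def gc_context():
    """GC aspirated at 5 Pa through a 1 um pipette with a flat outer surface."""
    return StressContext(
        applied_pressure=5.0, interfaces=(Interface(1.7, 1.0, math.inf),)
    )


@pytest.fixture
def dfc_context():
    """DFC aspirated at 20 Pa; only the outer GC-nucleoplasm interface counted."""
    return StressContext(
        applied_pressure=20.0, interfaces=(Interface(1.7, 1.0, math.inf),)
    )


@pytest.fixture
def dfc_params():
    return MaterialParams(eta_eff=250.0, E_eff=3.1)


@pytest.fixture
def gc_params():
    return MaterialParams(eta_eff=220.0)


@pytest.fixture
def noiseless_kv_trace(dfc_context, dfc_params):
    return syn.simulate_aspiration_trace(
        ModelClass.KELVIN_VOIGT,
        dfc_params,
        dfc_context,
        duration=300.0,
        frame_interval=2.0,
        noise_sd=0.0,
        seed=0,
        phase="DFC",
    )


@pytest.fixture
def noiseless_newtonian_trace(gc_context, gc_params):
    return syn.simulate_aspiration_trace(
        ModelClass.NEWTONIAN,
        gc_params,
        gc_context,
        duration=300.0,
        frame_interval=2.0,
        noise_sd=0.0,
        seed=0,
        phase="GC",
    )
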
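"""Shared fixtures: the calibrated reference simulation and derived runs.

The heavy artifacts (calibration, disease phases, the coarse substrate
grid) are session-scoped; all tests reuse them.
"""

from __future__ import annotations

import pytest

from mrla.calibrate import ReferenceConfig, _cached_reference
from mrla.echo import compute_echo_indices
from mrla.inference import sweep_grid
from mrla.presets import PRESETS
from mrla.substrates import apply_substrates

COARSE_HYP = (100.0, 150.0, 200.0, 250.0, 300.0)
COARSE_STIFF = (100.0, 200.0, 300.0, 400.0, 500.0, 600.0)


@pytest.fixture(scope="session")
def reference():
    """(model, beat) of the calibrated healthy baseline."""
    return _cached_reference(ReferenceConfig())


@pytest.fixture(scope="session")
def reference_model(reference):
    return reference[0]


@pytest.fixture(scope="session")
def reference_beat(reference):
    return reference[1]


@pytest.fixture(scope="session")
def phase_runs(reference):
    """Calibrated steady beats of all six disease phases, keyed by preset."""
    model, ref_beat = reference
    runs = {"baseline": (model, ref_beat)}
    for name, spec in PRESETS.items():
        if name == "baseline":
            continue
        runs[name] = apply_substrates(model, spec,
                                      init_state=ref_beat.states[-1].copy())
    return runs


@pytest.fixture(scope="session")
def phase_indices(phase_runs, reference_beat):
    return {name: compute_echo_indices(beat, reference_beat)
            for name, (_m, beat) in phase_runs.items()}


@pytest.fixture(scope="session")
def coarse_grid(reference):
    """Coarse (LA hypertrophy x stiffness) sweep on top of acute MR."""
    model, ref_beat = reference
    return sweep_grid(model, PRESETS["acute_mr"], COARSE_HYP, COARSE_STIFF,
                      reference_beat=ref_beat)
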
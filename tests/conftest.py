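import numpy as np
import pytest

from synapse_modes import ephys, synthdata as sd


@pytest.fixture(scope="session")
def control5_pair():
    """One simulated control paired recording (5 mM EGTA) plus analysis."""
    cfg = sd.load_calibration("control", 5.0, "fluo4")
    cell = sd.simulate_cell(cfg, seed=11)
    events = ephys.classify_events(ephys.detect_events(cell.trace), cell.stim)
    course = ephys.charge_decomposition(cell.trace, cell.stim)
    return cell, events, course


@pytest.fixture(scope="session")
def gvia5_pair():
    """One simulated ω-conotoxin-condition paired recording (5 mM EGTA)."""
    cfg = sd.load_calibration("gvia", 5.0, "fluo4")
    cell = sd.simulate_cell(cfg, seed=21)
    events = ephys.classify_events(ephys.detect_events(cell.trace), cell.stim)
    course = ephys.charge_decomposition(cell.trace, cell.stim)
    return cell, events, course


@pytest.fixture(scope="session")
def gvia05_cell():
    """One ω-conotoxin-condition cell at 0.5 mM EGTA (imaging only)."""
    cfg = sd.load_calibration("gvia", 0.5, "fluo4")
    return sd.simulate_cell(cfg, seed=31, n_boutons=14, with_trace=False)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
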
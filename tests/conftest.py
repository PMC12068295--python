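import numpy as np
import pandas as pd
import pytest

from bh3kit import DoseResponseTruth, VariabilityModel, WellSpec, simulate_well
from bh3kit.events import LOGICAL_CHANNELS, EventTable
from bh3kit.presets import DEFAULT_BASELINE


@pytest.fixture
def baseline_truth():
    """Healthy vehicle-well truth: 90% alive, 5% early, 5% dead."""
    return DoseResponseTruth(
        "S1", "venetoclax",
        baseline_fractions=dict(DEFAULT_BASELINE),
        early_by_dose={0.0: 0.05, 1000.0: 0.60},
    )


@pytest.fixture
def vehicle_well(baseline_truth):
    spec = WellSpec("P1", "A1", "S1", drug="vehicle", dose_nM=0.0, beads_added=5000)
    return simulate_well(spec, baseline_truth, variability=VariabilityModel(rng_seed=0),
                         n_events=20_000)


@pytest.fixture
def treated_well(baseline_truth):
    spec = WellSpec("P1", "A2", "S1", drug="venetoclax", dose_nM=1000.0, beads_added=5000)
    return simulate_well(spec, baseline_truth, variability=VariabilityModel(rng_seed=0),
                         n_events=20_000)


def constant_event_table(n: int = 1000, value: float = 1.0, transformed: bool = True) -> EventTable:
    """All-channel constant events (transformed space), handy for threshold edge cases."""
    data = pd.DataFrame({ch: np.full(n, value) for ch in LOGICAL_CHANNELS})
    data["fsc"] = 50_000.0
    data["ssc"] = 30_000.0
    data["bead"] = 0.0
    return EventTable(data=data, transformed=transformed, cofactor=150.0)
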
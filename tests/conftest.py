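import numpy as np
import pytest

from mirpanel.simchip import (
    INTERNAL_CONTROL,
    NEGATIVE_CONTROL,
    TARGET,
    ChipProfile,
    PlantedMarker,
    SimConfig,
)


def make_chip(
    sample_id="C1",
    targets=None,
    negctrl=(90.0, 100.0, 110.0),
    controls=None,
    n_flagged=0,
):
    """Hand-built chip for unit tests.

    ``targets`` and ``controls`` are {probe_id: linear signal} mappings;
    ``negctrl`` a sequence of negative-control signals.
    """
    targets = dict(targets or {"miR-A": 500.0, "miR-B": 300.0})
    controls = dict(controls or {})
    ids, types, signals = [], [], []
    for pid, s in targets.items():
        ids.append(pid); types.append(TARGET); signals.append(s)
    for pid, s in controls.items():
        ids.append(pid); types.append(INTERNAL_CONTROL); signals.append(s)
    for i, s in enumerate(negctrl):
        ids.append(f"NEG-{i:03d}"); types.append(NEGATIVE_CONTROL); signals.append(s)
    flagged = np.zeros(len(ids), dtype=bool)
    flagged[:n_flagged] = True
    return ChipProfile(
        sample_id,
        np.array(ids, dtype=object),
        np.array(types, dtype=object),
        np.array(signals, dtype=float),
        flagged,
    )


@pytest.fixture
def small_config():
    """Small two-marker cohort used across integration-style tests."""
    return SimConfig(
        n_mirnas=80,
        n_negctrl_probes=40,
        n_cancer=40,
        n_control=40,
        planted_markers=(
            PlantedMarker("miR-0001", "up", 2.0),
            PlantedMarker("miR-0002", "down", 2.0),
        ),
        seed=42,
    )
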
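import pytest

from clonaldyn.model_core import ReducedParameters, SimulationControls
from clonaldyn.presets import PRESETS, ORACLE_SUITE


@pytest.fixture
def controls():
    return SimulationControls()


@pytest.fixture
def sweep_controls():
    # coarser output sampling: classification only needs the event times
    return SimulationControls(dt_out=0.2)


def reduced_preset(preset_id: str) -> ReducedParameters:
    cfg = PRESETS[preset_id]["config"]["reduced"]
    return ReducedParameters(**cfg)


@pytest.fixture
def oracle_suite():
    """The ten frozen single-clone presets with their expected labels."""
    return [(pid, reduced_preset(pid), PRESETS[pid]["expected_label"])
            for pid in ORACLE_SUITE]
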
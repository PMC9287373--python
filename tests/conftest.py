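import logging

import pytest

from ferrynoise.pipeline import analyze
from ferrynoise.scenarios import generate_scenario, paper_calibrated_preset

logging.getLogger("ferrynoise").setLevel(logging.ERROR)

#: seed for the shared study-scale batch (chosen once, arbitrary)
BATCH_SEED = 1


@pytest.fixture(scope="session")
def preset_batch():
    """100 outgoing + 100 incoming transits of the paper-calibrated preset."""
    config = paper_calibrated_preset()
    return generate_scenario(config, 100, 100, seed=BATCH_SEED)


@pytest.fixture(scope="session")
def preset_analysis(preset_batch):
    """Full-pipeline analysis of the shared preset batch."""
    return analyze(preset_batch)


@pytest.fixture(scope="session")
def small_quiet_batch():
    """3 outgoing transits, ambient off, fully paired — for exact identities."""
    config = paper_calibrated_preset()
    config.ambient_enabled = False
    config.source.unpaired_fraction = 0.0
    return generate_scenario(config, 3, 0, seed=7)
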
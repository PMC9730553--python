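import numpy as np
import pytest
from hypothesis import settings

import fdd11

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def artifact() -> fdd11.CalibrationArtifact:
    return fdd11.published()


@pytest.fixture(scope="session")
def items(artifact):
    return artifact.items


@pytest.fixture(scope="session")
def model_true_5000(items):
    """Complete 11-item responses simulated from the published calibration
    with a normal ability population (no floor group, no DIF)."""
    cfg = fdd11.SimConfig(
        n_persons=5000,
        seed=11,
        ability=fdd11.AbilityModel(p_floor=0.0, mean=-1.2733, sd=1.0822),
    )
    data, truth = fdd11.simulate(cfg)
    return data, np.asarray(truth["thetas"])


@pytest.fixture(scope="session")
def score_lookup(items, artifact):
    return fdd11.score_table(items, anchors=artifact.anchors)
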
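import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from spikedet.backbone import BackboneConfig
from spikedet.head import HeadConfig


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_backbone_cfg():
    """A thin backbone for fast structural tests (same topology)."""
    return BackboneConfig(stem_channels=8, stage_channels=(16, 32, 64),
                         stage_repeats=(2, 2, 2), input_size=96, seed=0)


@pytest.fixture
def small_head_cfg():
    return HeadConfig(head_channels=24, seed=0)
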
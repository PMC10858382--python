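import numpy as np
import pytest

from dardose.phantom import PhantomConfig, make_phantom
from dardose.pipeline import train_default_classifier


@pytest.fixture(scope="session")
def small_cfg():
    """Fast phantom for unit tests that only need plausible geometry."""
    return PhantomConfig(image_height_px=256, image_width_px=128, seed=7)


@pytest.fixture(scope="session")
def default_phantom():
    """One full-size synthetic section with ground truth."""
    cfg = PhantomConfig(seed=11)
    rgb, dar, truth = make_phantom(cfg)
    return cfg, rgb, dar, truth


@pytest.fixture(scope="session")
def trained_classifier():
    """Bone classifier trained on 20 labeled synthetic sections.

    Session-scoped: training is the slowest segmentation step and every
    consumer uses the same corpus, mirroring the fixed training set of the
    original workflow.
    """
    return train_default_classifier(PhantomConfig(seed=0), n_sections=20, seed=900)
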
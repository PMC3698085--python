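"""Shared fixtures: synthetic images and trained components.

Everything is generated programmatically at test time from fixed seeds;
session scope keeps the expensive objects (retina maps, trained pools, the
end-to-end screener) shared across test modules.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from retscreen.image_ops import build_retina_map
from retscreen.screening import FundusScreener
from retscreen.synth import SynthConfig, generate_image

warnings.filterwarnings("ignore", category=FutureWarning)

SMALL = (256, 256)


def abnormal_config(seed: int, **kw) -> SynthConfig:
    defaults = dict(image_size=SMALL, n_ma=5, n_haem=3, n_bright=2, rng_seed=seed)
    defaults.update(kw)
    return SynthConfig(**defaults)


def normal_config(seed: int, **kw) -> SynthConfig:
    defaults = dict(image_size=SMALL, rng_seed=seed)
    defaults.update(kw)
    return SynthConfig(**defaults)


@pytest.fixture(scope="session")
def abnormal_image():
    return generate_image(abnormal_config(7))


@pytest.fixture(scope="session")
def normal_image():
    return generate_image(normal_config(11))


@pytest.fixture(scope="session")
def abnormal_map(abnormal_image):
    return build_retina_map(abnormal_image)


@pytest.fixture(scope="session")
def normal_map(normal_image):
    return build_retina_map(normal_image)


@pytest.fixture(scope="session")
def trained_screener():
    """Full screener trained on the canonical synthetic study conditions."""
    train = [generate_image(abnormal_config(1000 + i)) for i in range(10)] + \
            [generate_image(normal_config(2000 + i)) for i in range(6)]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return FundusScreener(random_state=0).fit(train)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
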
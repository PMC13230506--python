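import numpy as np
import pytest

from hbvision.synthetic_data import CohortConfig, RenderParams, SubgroupParams


def tiny_subgroups(n_a=8, n_b=6, n_c=10):
    return {
        "A": SubgroupParams(n=n_a, hb_median=8.6, hb_range=(6.5, 11.4)),
        "B": SubgroupParams(n=n_b, hb_median=5.2, hb_range=(3.4, 6.2)),
        "C": SubgroupParams(n=n_c, hb_median=7.9, hb_range=(6.3, 11.3)),
    }


@pytest.fixture
def tiny_cohort_config():
    return CohortConfig(subgroups=tiny_subgroups(), qol_fraction=0.4, seed=7)


@pytest.fixture
def small_render():
    return RenderParams(image_size=(64, 64), eyelid_images=1, fingernail_images=1)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
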
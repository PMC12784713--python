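import logging

import numpy as np
import pytest

from methylstruct import simulate
from methylstruct.io import MethylRadCounts, SampleMetadata

logging.getLogger("methylstruct").setLevel(logging.ERROR)


@pytest.fixture
def tiny_counts():
    """3 individuals x 4 markers with easy round numbers."""
    return MethylRadCounts(
        individuals=["a", "b", "c"],
        markers=["m1", "m2", "m3", "m4"],
        counts=np.array([[100, 0, 50, 10], [20, 5, 0, 1], [7, 7, 7, 7]]),
        library_sizes=np.array([1_000_000, 500_000, 700_000]),
        motif=np.array(["CCGG", "CCWGG", "CCGG", "CCWGG"], dtype=object),
    )


@pytest.fixture
def tiny_meta():
    return SampleMetadata(
        individuals=["a", "b", "c"],
        site={"a": "s1", "b": "s1", "c": "s2"},
    )


@pytest.fixture(scope="session")
def strong_site_dataset():
    """30 sites x 10 individuals with 5 planted site clusters, strong tier
    of 30 markers plus a weakly differentiated background."""
    cfg = simulate.SyntheticConfig(
        n_markers=2000,
        effect_size=5.0,
        weak_effect_size=2.5,
        fraction_informative=0.015,
        fraction_weak=0.08,
        seed=1,
    )
    return simulate.generate(cfg), cfg


@pytest.fixture(scope="session")
def latent_state_dataset():
    """No site structure; 3 latent methylation states cross-cutting sites."""
    cfg = simulate.SyntheticConfig(
        n_markers=2000,
        effect_size=4.0,
        weak_effect_size=2.5,
        fraction_informative=0.015,
        fraction_weak=0.08,
        n_site_clusters=1,
        n_latent_states=3,
        seed=2,
    )
    return simulate.generate(cfg), cfg
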
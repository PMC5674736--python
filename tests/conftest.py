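from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_genome():
    """A 100-kb synthetic genome with ~300 planted repeats and its truth."""
    from ssrkit.detect import GenomeRecord
    from ssrkit.simulate import (
        SyntheticGenomeSpec,
        generate_genome,
        random_planted_repeats,
    )

    gen_rng = np.random.default_rng(42)
    plants, length = random_planted_repeats(gen_rng, 300)
    spec = SyntheticGenomeSpec(
        genome_length=max(length, 100_000), planted=plants, rng_seed=7
    )
    sequence, truth, _ = generate_genome(spec)
    return GenomeRecord("synth1", sequence), truth
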
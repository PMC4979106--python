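import numpy as np
import pytest
from hypothesis import settings

import csslkit as ck
from csslkit import breeding_sim as bs

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rice_map() -> ck.GeneticMap:
    return ck.default_rice_map()


@pytest.fixture(scope="session")
def cssl_population():
    """Full-scale simulated CSSL population (198 lines, 313 markers).

    Session-scoped: the crossing scheme takes ~half a minute and several
    acceptance-level checks share it.
    """
    config = bs.SimConfig(seed=1)
    matrix, pedigree = bs.run_scheme(config)
    return config, matrix, pedigree


@pytest.fixture(scope="session")
def tiny_sim_config() -> bs.SimConfig:
    """Down-scaled crossing scheme for fast smoke/determinism tests."""
    return bs.SimConfig(
        seed=3,
        n_bc1=10, n_bc2=20, n_bc3=40,
        bc3_rule=bs.MASRule(max_segments=5, target=12),
        branch_sizes={4: 20, 5: 20},
        branch_rules={4: bs.MASRule(3, 4), 5: bs.MASRule(3, 4)},
        selfing_generations={4: 2, 5: 2},
        n_self_progeny=3,
        map=ck.default_rice_map(
            lengths={"1": 120.0, "2": 90.0},
            marker_counts={"1": 12, "2": 9},
        ),
    )
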
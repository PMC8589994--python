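import numpy as np
import pytest

from tempassort import (DynamicsSpec, PayoffParams, SelectionPool,
                        TransitionRule, UpdateDynamic, build_lattice)
from tempassort.cli_io import make_fixture

REGIMES = {
    "fps-async": DynamicsSpec(TransitionRule.FITNESS_PROPORTIONAL, UpdateDynamic.ASYNC),
    "fps-sync": DynamicsSpec(TransitionRule.FITNESS_PROPORTIONAL, UpdateDynamic.SYNC),
    "pairwise-async": DynamicsSpec(TransitionRule.PAIRWISE, UpdateDynamic.ASYNC),
    "pairwise-sync": DynamicsSpec(TransitionRule.PAIRWISE, UpdateDynamic.SYNC),
}

GLOBAL_POOL_REGIMES = {
    "fps-async-global": DynamicsSpec(TransitionRule.FITNESS_PROPORTIONAL,
                                     UpdateDynamic.ASYNC, SelectionPool.GLOBAL),
    "fps-sync-global": DynamicsSpec(TransitionRule.FITNESS_PROPORTIONAL,
                                    UpdateDynamic.SYNC, SelectionPool.GLOBAL),
}


@pytest.fixture
def params():
    return PayoffParams(b=2.0, c=1.0)


@pytest.fixture
def grid9():
    return build_lattice(9)


@pytest.fixture
def path2():
    graph, state = make_fixture("2-path-CD")
    return graph, state


@pytest.fixture
def checkerboard4():
    graph, state = make_fixture("4-cycle-checkerboard")
    return graph, state


def rule_codes(spec: DynamicsSpec):
    """(rule, update, pool) integer encoding used by the engine and oracle."""
    return (
        0 if spec.transition_rule is TransitionRule.FITNESS_PROPORTIONAL else 1,
        0 if spec.update is UpdateDynamic.ASYNC else 1,
        0 if spec.selection_pool is SelectionPool.NEIGHBOR else 1,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
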
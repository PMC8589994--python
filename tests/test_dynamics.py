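import numpy as np
import pytest

from conftest import GLOBAL_POOL_REGIMES, REGIMES, rule_codes
from oracle import enumerate_one_step
from tempassort import (Behavior, DynamicsSpec, PayoffParams, PopulationState,
                        SelectionPool, Strategy, StructuralError,
                        TransitionRule, UpdateDynamic, build_lattice,
                        compute_payoffs, step, strategy_fitness_table)
from tempassort import _engine
from tempassort.cli_io import make_fixture
from tempassort.dynamics import (fps_async_step, pairwise_async_step,
                                 pairwise_sync_step)

C, D = Behavior.COOPERATE, Behavior.DEFECT
PARAMS = PayoffParams(b=2.0, c=1.0)


class TestStrategyFitnessTable:
    def test_weights_are_clipped_payoff_sums(self):
        state = PopulationState([1, 1, 0], [1, 1, 1],
                                payoffs=np.array([2.0, 1.0, 1.0]))
        table = strategy_fitness_table(state, t=1)
        assert table.weights == {Strategy(C, 1): 3.0, Strategy(D, 1): 1.0}
        assert table.probabilities[Strategy(C, 1)] == pytest.approx(0.75)
        assert table.probabilities[Strategy(D, 1)] == pytest.approx(0.25)
        assert not table.degenerate

    def test_negative_sums_clip_to_zero(self):
        state = PopulationState([1, 0], [1, 1], payoffs=np.array([-2.0, 4.0]))
        table = strategy_fitness_table(state, t=1)
        assert table.weights == {Strategy(C, 1): 0.0, Strategy(D, 1): 4.0}
        assert table.probabilities[Strategy(D, 1)] == 1.0

    def test_all_zero_weights_fall_back_to_uniform(self):
        state = PopulationState([1, 1, 0], [1, 2, 1],
                                payoffs=np.zeros(3))
        table = strategy_fitness_table(state, t=2)
        assert table.degenerate
        probs = table.probabilities
        assert len(probs) == 3
        assert all(p == pytest.approx(1 / 3) for p in probs.values())

    def test_extinct_strategies_absent(self):
        state = PopulationState([1, 1], [1, 3], payoffs=np.array([1.0, 2.0]))
        table = strategy_fitness_table(state, t=4)
        assert set(table.weights) == {Strategy(C, 1), Strategy(C, 3)}

    def test_probabilities_sum_to_one(self):
        rng = np.random.default_rng(0)
        state = PopulationState(rng.integers(0, 2, 50), rng.integers(1, 6, 50),
                                payoffs=rng.normal(size=50))
        table = strategy_fitness_table(state, t=5)
        assert sum(table.probabilities.values()) == pytest.approx(1.0)

    def test_requires_payoffs(self):
        with pytest.raises(StructuralError):
            strategy_fitness_table(PopulationState([1], [1]), t=1)


class TestGlobalPoolExamples:
    """The global strategy-level pool: replacement drawn from the
    population-wide fitness table."""

    def test_two_path_replacement_is_always_the_defector_strategy(self, path2):
        graph, state = path2  # payoffs (-1, 2): weights {(C,1): 0, (D,1): 2}
        state = compute_payoffs(graph, state, PARAMS)
        spec = DynamicsSpec(TransitionRule.FITNESS_PROPORTIONAL,
                            UpdateDynamic.ASYNC, SelectionPool.GLOBAL)
        for seed in range(40):
            out = fps_async_step(graph, state, PARAMS, spec,
                                 np.random.default_rng(seed), t=1)
            changed = np.flatnonzero(out.behaviors != state.behaviors)
            # whichever node died, the refill is (D, 1)
            died = changed[0] if changed.size else None
            if died is not None:
                assert out.strategy(died) == Strategy(D, 1)
            assert (out.behaviors[out.behaviors != state.behaviors] == 0).all()

    def test_monopoly_weight_fixes_sync_batch(self, grid9):
        rng = np.random.default_rng(3)
        behaviors = np.array([1, 0, 0, 0, 0, 0, 0, 0, 0])
        state = PopulationState(behaviors, np.ones(9, dtype=int),
                                payoffs=np.array([5.0] + [0.0] * 8))
        spec = DynamicsSpec(TransitionRule.FITNESS_PROPORTIONAL,
                            UpdateDynamic.SYNC, SelectionPool.GLOBAL)
        out = step(grid9, state, PARAMS, spec, rng, t=1)
        assert (out.behaviors == 1).all()


class TestNeighborDeathBirth:
    def test_two_path_site_competition(self, path2):
        """If the cooperator dies its defector neighbour wins outright; if
        the defector dies its only (negative-payoff) neighbour wins by the
        uniform fallback — so the successor is all-D or all-C, equally often."""
        graph, state = path2
        state = compute_payoffs(graph, state, PARAMS)
        spec = REGIMES["fps-async"]
        rng = np.random.default_rng(99)
        outcomes = {"C": 0, "D": 0}
        n_steps = 2000
        for _ in range(n_steps):
            out = fps_async_step(graph, state, PARAMS, spec, rng, t=1)
            assert out.behaviors[0] == out.behaviors[1]
            outcomes["C" if out.behaviors[0] == 1 else "D"] += 1
        se = (n_steps * 0.25) ** 0.5
        assert abs(outcomes["C"] - n_steps / 2) <= 3 * se


@pytest.mark.parametrize("name,spec", {**REGIMES, **GLOBAL_POOL_REGIMES}.items())
class TestAbsorbingFixation:
    def test_monomorphic_behavior_is_absorbing(self, name, spec, grid9):
        for behavior, b in ((1, 1.0), (1, 3.0), (0, 2.0)):
            params = PayoffParams(b=b, c=1.0)
            state = PopulationState(np.full(9, behavior),
                                    np.tile([1, 2, 3], 3))
            state = compute_payoffs(grid9, state, params)
            for seed in range(10):
                out = step(grid9, state, params, spec,
                           np.random.default_rng(seed), t=3)
                assert (out.behaviors == behavior).all()


class TestUpdateGranularity:
    def test_async_changes_at_most_one_node(self, grid9):
        rng = np.random.default_rng(7)
        for name in ("fps-async", "pairwise-async"):
            for seed in range(30):
                state = PopulationState(rng.integers(0, 2, 9), rng.integers(1, 4, 9))
                state = compute_payoffs(grid9, state, PARAMS)
                out = step(grid9, state, PARAMS, REGIMES[name],
                           np.random.default_rng(seed), t=3)
                changed = (out.behaviors != state.behaviors) | (out.slots != state.slots)
                assert changed.sum() <= 1

    def test_sync_can_change_many_nodes(self, grid9):
        state = PopulationState(np.array([1, 0, 1, 0, 1, 0, 1, 0, 1]),
                                np.ones(9, dtype=int))
        state = compute_payoffs(grid9, state, PayoffParams(b=8, c=1))
        out = step(grid9, state, PayoffParams(b=8, c=1), REGIMES["fps-sync"],
                   np.random.default_rng(0), t=1)
        changed = (out.behaviors != state.behaviors).sum()
        assert changed > 1


class TestPairwiseRules:
    def test_adopts_strictly_better_neighbor_tuple(self):
        graph, _ = make_fixture("2-path-CD")
        state = PopulationState([1, 0], [1, 2], payoffs=np.array([2.0, 3.0]))
        spec = REGIMES["pairwise-async"]
        seen_adoption = False
        for seed in range(30):
            out = pairwise_async_step(graph, state, PARAMS, spec,
                                      np.random.default_rng(seed))
            if out.behaviors[0] == 0:  # node 0 was focal and adopted
                assert out.slots[0] == 2  # full tuple copied, not just behavior
                seen_adoption = True
            assert out.behaviors[1] == 0 and out.slots[1] == 2  # never degrades
        assert seen_adoption

    def test_equal_payoffs_keep_incumbent(self, checkerboard4):
        graph, state = checkerboard4
        state = PopulationState(state.behaviors, state.slots,
                                payoffs=np.full(4, 1.5))
        for seed in range(20):
            out = pairwise_sync_step(graph, state, PARAMS, REGIMES["pairwise-sync"],
                                     np.random.default_rng(seed))
            assert np.array_equal(out.behaviors, state.behaviors)
            assert np.array_equal(out.slots, state.slots)

    def test_isolated_focal_node_skipped(self):
        from tempassort.networks import GraphKind, InteractionGraph
        graph = InteractionGraph(3, np.array([[0, 1]]), GraphKind.LATTICE, 1)
        state = PopulationState([1, 0, 0], [1, 1, 1],
                                payoffs=np.array([0.0, 5.0, 9.0]))
        for seed in range(30):
            out = pairwise_async_step(graph, state, PARAMS,
                                      REGIMES["pairwise-async"],
                                      np.random.default_rng(seed))
            assert out.behaviors[2] == 0 and out.slots[2] == 1


# -- one-step successor distributions vs exhaustive enumeration ------------

FOUR_CYCLE_EDGES = [(0, 1), (1, 2), (2, 3), (0, 3)]
MIXED_BEHAV = (1, 0, 1, 0)
MIXED_SLOT0 = (0, 1, 0, 0)  # 0-based; two slots
N_SAMPLES = 20_000


def _assert_matches_enumeration(counts, exact, n_samples):
    assert set(counts) <= set(exact), "sampled a successor with probability 0"
    for key, p in exact.items():
        expected = p * n_samples
        se = (n_samples * p * (1 - p)) ** 0.5
        assert abs(counts.get(key, 0) - expected) <= 3 * se + 1e-9, (
            f"successor {key}: observed {counts.get(key, 0)}, expected {expected:.1f}")


@pytest.mark.parametrize("name,spec", {**REGIMES, **GLOBAL_POOL_REGIMES}.items())
def test_one_step_distribution_matches_enumeration(name, spec, checkerboard4):
    """Empirical successor distribution of each regime on a 4-cycle with two
    slots agrees with exact exhaustive enumeration (3 binomial SEs)."""
    graph, _ = checkerboard4
    state = PopulationState(np.array(MIXED_BEHAV), np.array(MIXED_SLOT0) + 1)
    state = compute_payoffs(graph, state, PARAMS)
    rule, update, pool = rule_codes(spec)
    exact = enumerate_one_step(FOUR_CYCLE_EDGES, MIXED_BEHAV, MIXED_SLOT0,
                               2, 2.0, 1.0, rule, update, pool)
    rng = np.random.default_rng(2024)
    counts = {}
    for _ in range(N_SAMPLES):
        out = step(graph, state, PARAMS, spec, rng, t=2)
        key = (tuple(int(x) for x in out.behaviors),
               tuple(int(x) - 1 for x in out.slots))
        counts[key] = counts.get(key, 0) + 1
    _assert_matches_enumeration(counts, exact, N_SAMPLES)


@pytest.mark.parametrize("name,spec", {**REGIMES, **GLOBAL_POOL_REGIMES}.items())
def test_engine_one_step_distribution_matches_enumeration(name, spec):
    """The compiled engine's single-generation transition obeys the same
    exact distribution as the interpreted enumeration."""
    rule, update, pool = rule_codes(spec)
    exact = enumerate_one_step(FOUR_CYCLE_EDGES, MIXED_BEHAV, MIXED_SLOT0,
                               2, 2.0, 1.0, rule, update, pool)
    indptr = np.array([0, 2, 4, 6, 8], dtype=np.int64)
    indices = np.array([1, 3, 0, 2, 1, 3, 0, 2], dtype=np.int64)
    occ = np.zeros((1, 2, 2), dtype=np.int64)
    occ_gens = np.zeros(1, dtype=np.int64)
    counts = {}
    for seed in range(N_SAMPLES):
        behav = np.array(MIXED_BEHAV, dtype=np.int8)
        slot = np.array(MIXED_SLOT0, dtype=np.int64)
        _engine.run_population(indptr, indices, behav, slot, 2, 2.0, 1.0,
                               rule, update, pool, 1, seed, 0, occ, occ_gens)
        key = (tuple(int(x) for x in behav), tuple(int(x) for x in slot))
        counts[key] = counts.get(key, 0) + 1
    _assert_matches_enumeration(counts, exact, N_SAMPLES)
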
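"""Exact DP learner, brute-force oracle, and greedy hill climbing."""

import itertools

import numpy as np
import pytest

from bnscore import (
    CapabilityError,
    DirectedGraph,
    ScoreSpec,
    VariableSpec,
    CategoricalDataset,
    best_parents_dp,
    brute_force_learn,
    build_counts,
    enumerate_local_scores,
    exact_learn,
    hill_climb,
    local_score,
    network_score,
    logic_sample,
    shd,
)
from bnscore.search import _all_dag_parent_masks
from conftest import random_dataset


class TestLocalScoreTables:
    def test_all_parent_sets_enumerated(self, make_dataset):
        data = make_dataset(3, 20, seed=0)
        table = enumerate_local_scores(data, ScoreSpec("MDL"))
        assert all(len(table.scores[i]) == 4 for i in range(3))  # 2^(n-1)

    def test_max_parents_bound_limits_sets(self, make_dataset):
        data = make_dataset(5, 20, seed=1)
        table = enumerate_local_scores(data, ScoreSpec("MDL"), max_parents=1)
        assert all(len(table.scores[i]) == 5 for i in range(5))  # empty + 4 singles

    def test_limit_exceeded_raises_capability_error(self, make_dataset):
        data = make_dataset(6, 10, seed=2)
        with pytest.raises(CapabilityError, match="hill_climb"):
            enumerate_local_scores(data, ScoreSpec("MDL"), limit=5)

    def test_table_matches_direct_network_score(self, make_dataset):
        data = make_dataset(4, 50, seed=3)
        spec = ScoreSpec("BDeu", 1.0)
        table = enumerate_local_scores(data, spec)
        rng = np.random.default_rng(0)
        for _ in range(10):
            masks = _all_dag_parent_masks(4)[rng.integers(0, 543)]
            edges = {
                (data.names[j], data.names[i])
                for i, m in enumerate(masks)
                for j in range(4)
                if m >> j & 1
            }
            g = DirectedGraph(data.names, frozenset(edges))
            total = sum(table.scores[i][m] for i, m in enumerate(masks))
            assert total == pytest.approx(network_score(spec, g, data))


class TestBestParents:
    def test_empty_candidate_set(self, make_dataset):
        data = make_dataset(3, 30, seed=4)
        table = enumerate_local_scores(data, ScoreSpec("MDL"))
        best = best_parents_dp(table, 0, set())
        assert best[frozenset()] == (frozenset(), table.scores[0][0])

    def test_matches_exhaustive_scan(self, make_dataset):
        data = make_dataset(5, 80, seed=5)
        spec = ScoreSpec("fNML")
        table = enumerate_local_scores(data, spec)
        cands = {1, 2, 3, 4}
        best = best_parents_dp(table, 0, cands)
        for size in range(5):
            for sub in itertools.combinations(sorted(cands), size):
                expect = max(
                    (
                        table.score(0, ps)
                        for k in range(len(sub) + 1)
                        for ps in itertools.combinations(sub, k)
                    ),
                )
                got_set, got = best[frozenset(sub)]
                assert got == pytest.approx(expect)
                assert got_set <= frozenset(sub)

    def test_monotone_in_candidate_set(self, make_dataset):
        data = make_dataset(4, 40, seed=6)
        table = enumerate_local_scores(data, ScoreSpec("AIC"))
        best = best_parents_dp(table, 0, {1, 2, 3})
        for sub, (_, sc) in best.items():
            for bigger, (_, sc2) in best.items():
                if sub < bigger:
                    assert sc2 >= sc - 1e-12


class TestBruteForce:
    def test_labeled_dag_counts(self):
        assert len(_all_dag_parent_masks(1)) == 1
        assert len(_all_dag_parent_masks(2)) == 3
        assert len(_all_dag_parent_masks(3)) == 25
        assert len(_all_dag_parent_masks(4)) == 543

    def test_single_variable(self, make_dataset):
        data = make_dataset(1, 10, seed=7)
        res = brute_force_learn(data, ScoreSpec("MDL"))
        assert res.graph.edges == frozenset()
        assert res.score == pytest.approx(
            local_score(ScoreSpec("MDL"), build_counts(data, 0, ()))
        )

    def test_capability_limit(self, make_dataset):
        with pytest.raises(CapabilityError):
            brute_force_learn(make_dataset(6, 10, seed=8), ScoreSpec("MDL"))


class TestExactLearner:
    @pytest.mark.parametrize("family,alpha", [("MDL", None), ("BDeu", 10.0)])
    def test_matches_brute_force_oracle(self, family, alpha, make_dataset):
        spec = ScoreSpec(family, alpha)
        for seed in range(6):
            data = make_dataset(4, 60, seed=50 + seed)
            assert exact_learn(data, spec).score == pytest.approx(
                brute_force_learn(data, spec).score
            )

    def test_independent_uniform_variables_give_empty_graph(self):
        specs = tuple(
            VariableSpec(f"U{i}", ("0", "1")) for i in range(4)
        )
        rng = np.random.default_rng(9)
        data = CategoricalDataset(specs, rng.integers(0, 2, size=(1000, 4)))
        res = exact_learn(data, ScoreSpec("MDL"))
        assert res.graph.edges == frozenset()

    def test_strong_pairwise_dependence_recovered_up_to_equivalence(self, noisy_chain):
        data = logic_sample(noisy_chain, 1000, seed=12)
        res = exact_learn(data, ScoreSpec("MDL"))
        assert res.graph.edges in (
            frozenset({("X", "Y")}),
            frozenset({("Y", "X")}),
        )
        assert shd(noisy_chain.graph, res.graph).total == 0

    def test_result_score_consistent_with_network_score(self, make_dataset):
        data = make_dataset(4, 80, seed=13)
        spec = ScoreSpec("fNML")
        res = exact_learn(data, spec)
        assert res.score == pytest.approx(network_score(spec, res.graph, data))

    def test_score_invariant_to_variable_permutation(self, make_dataset):
        data = make_dataset(4, 70, seed=14)
        perm = [2, 0, 3, 1]
        pdata = CategoricalDataset(
            tuple(data.specs[j] for j in perm), data.rows[:, perm]
        )
        spec = ScoreSpec("MDL")
        assert exact_learn(data, spec).score == pytest.approx(
            exact_learn(pdata, spec).score
        )

    def test_capability_limit(self, make_dataset):
        with pytest.raises(CapabilityError):
            exact_learn(make_dataset(6, 10, seed=15), ScoreSpec("MDL"), limit=5)


def _no_single_move_improves(data, spec, graph, tol=1e-9) -> bool:
    """Move-scan oracle: no add/delete/reverse strictly improves the score."""
    base = network_score(spec, graph, data)
    names = data.names
    for u in names:
        for v in names:
            if u == v:
                continue
            e = (u, v)
            if e in graph.edges:
                for new in (graph.edges - {e}, graph.edges - {e} | {(v, u)}):
                    g2 = DirectedGraph(names, frozenset(new))
                    if g2.is_acyclic() and network_score(spec, g2, data) > base + tol:
                        return False
            else:
                g2 = DirectedGraph(names, graph.edges | {e})
                if g2.is_acyclic() and network_score(spec, g2, data) > base + tol:
                    return False
    return True


class TestHillClimb:
    def test_independent_data_yields_empty_graph(self):
        specs = tuple(VariableSpec(f"U{i}", ("0", "1")) for i in range(4))
        rng = np.random.default_rng(16)
        data = CategoricalDataset(specs, rng.integers(0, 2, size=(500, 4)))
        res = hill_climb(data, ScoreSpec("MDL"), seed=0)
        assert res.graph.edges == frozenset()

    def test_deterministic_given_seed(self, make_dataset):
        data = make_dataset(5, 150, seed=17)
        a = hill_climb(data, ScoreSpec("BDeu", 1.0), seed=21)
        b = hill_climb(data, ScoreSpec("BDeu", 1.0), seed=21)
        assert a.graph == b.graph and a.score == b.score

    def test_never_beats_exact_learner(self, make_dataset):
        for seed in range(5):
            data = make_dataset(5, 120, seed=60 + seed)
            spec = ScoreSpec("MDL")
            greedy = hill_climb(data, spec, seed=seed)
            assert greedy.score <= exact_learn(data, spec).score + 1e-6

    def test_reaches_exact_score_on_most_small_fixtures(self):
        hits = 0
        for seed in range(8):
            data = random_dataset(5, 100, seed=80 + seed)
            spec = ScoreSpec("MDL")
            greedy = hill_climb(data, spec, seed=seed)
            if abs(greedy.score - exact_learn(data, spec).score) < 1e-9:
                hits += 1
        assert hits >= 4

    def test_terminates_at_a_local_optimum(self, make_dataset):
        data = make_dataset(4, 90, seed=18)
        spec = ScoreSpec("fNML")
        res = hill_climb(data, spec, restarts=2, seed=5)
        assert _no_single_move_improves(data, spec, res.graph)

    def test_result_score_matches_graph_score(self, make_dataset):
        data = make_dataset(4, 60, seed=19)
        spec = ScoreSpec("AIC")
        res = hill_climb(data, spec, seed=2)
        assert res.score == pytest.approx(network_score(spec, res.graph, data))
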
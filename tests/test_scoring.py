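"""Sufficient statistics and the four decomposable scoring functions."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bnscore import (
    CategoricalDataset,
    CountTable,
    DirectedGraph,
    ScoreSpec,
    VariableSpec,
    bdeu_local,
    build_counts,
    fnml_local,
    local_score,
    log_likelihood_local,
    log_multinomial_regret,
    network_score,
    num_params,
    bdeu_alpha_grid,
    penalty_aic,
    penalty_mdl,
)
from conftest import random_dataset


def _binary_counts(*counts: int) -> CountTable:
    """Parentless count table for a variable with the given state tallies."""
    n_ijk = np.array([counts], dtype=np.int64)
    return CountTable(
        var=0, parents=(), q=1, r=len(counts),
        config_ids=np.array([0]), n_ij=n_ijk.sum(axis=1), n_ijk=n_ijk,
        N=int(n_ijk.sum()),
    )


EMPTY_COUNTS = CountTable(
    var=0, parents=(), q=1, r=2,
    config_ids=np.array([], dtype=np.int64),
    n_ij=np.array([], dtype=np.int64),
    n_ijk=np.zeros((0, 2), dtype=np.int64), N=0,
)


class TestCounts:
    def test_parentless_tally(self):
        specs = (VariableSpec("A", ("0", "1")),)
        data = CategoricalDataset(specs, np.array([[0], [1], [0], [0]]))
        ct = build_counts(data, 0, ())
        assert ct.q == 1 and ct.r == 2
        assert ct.dense_n_ijk().tolist() == [[3, 1]]

    def test_unseen_configuration_has_zero_row(self):
        specs = (
            VariableSpec("P1", ("0", "1")),
            VariableSpec("P2", ("0", "1")),
            VariableSpec("C", ("0", "1")),
        )
        rows = np.array([[0, 0, 0], [0, 1, 1], [1, 0, 0]])
        ct = build_counts(CategoricalDataset(specs, rows), 2, (0, 1))
        dense = ct.dense_n_ijk()
        assert ct.q == 4
        assert dense[3].tolist() == [0, 0]  # configuration (1,1) never observed

    def test_hand_tallied_fixture(self):
        specs = (VariableSpec("X", ("0", "1")), VariableSpec("Y", ("0", "1")))
        rows = np.array([[0, 0], [0, 0], [0, 1], [1, 1], [1, 1], [1, 0]])
        ct = build_counts(CategoricalDataset(specs, rows), 1, (0,))
        assert ct.dense_n_ijk().tolist() == [[2, 1], [1, 2]]
        assert ct.n_ij.tolist() == [3, 3]

    def test_child_cannot_be_own_parent(self, make_dataset):
        with pytest.raises(ValueError):
            build_counts(make_dataset(3, 10, seed=0), 1, (1,))


class TestLikelihoodAndPenalties:
    def test_log_likelihood_three_one_split(self):
        ct = _binary_counts(3, 1)
        assert log_likelihood_local(ct) == pytest.approx(
            3 * math.log(0.75) + math.log(0.25)
        )

    def test_deterministic_column_fits_perfectly(self):
        assert log_likelihood_local(_binary_counts(4, 0)) == 0.0

    def test_empty_slice_is_zero(self):
        assert log_likelihood_local(EMPTY_COUNTS) == 0.0
        assert fnml_local(EMPTY_COUNTS) == 0.0
        assert bdeu_local(EMPTY_COUNTS, 1.0) == 0.0

    @pytest.mark.parametrize(
        "r, parent_arities, expected",
        [(2, (), 1), (3, (2, 2), 8), (2, (3, 2), 6)],
    )
    def test_free_parameter_count(self, r, parent_arities, expected):
        q = int(np.prod(parent_arities)) if parent_arities else 1
        ct = CountTable(
            var=0, parents=tuple(range(1, len(parent_arities) + 1)), q=q, r=r,
            config_ids=np.array([0]), n_ij=np.array([1]),
            n_ijk=np.eye(1, r, dtype=np.int64), N=1,
        )
        assert num_params(ct) == expected

    def test_mdl_penalty_values(self):
        assert penalty_mdl(1, 100) == pytest.approx(math.log(100) / 2)
        assert penalty_mdl(0, 7) == 0.0
        assert penalty_mdl(5, 1) == 0.0

    def test_aic_penalty_is_parameter_count(self):
        assert penalty_aic(8) == 8.0
        assert penalty_aic(0) == 0.0

    def test_aic_lighter_than_mdl_beyond_e_squared(self):
        assert penalty_aic(3) < penalty_mdl(3, 9)  # N = 9 > e^2


class TestBDeu:
    def test_single_observation_uniform_prior(self):
        assert bdeu_local(_binary_counts(1, 0), 1.0) == pytest.approx(math.log(0.5))

    def test_matches_sequential_predictive_product(self):
        """BDeu marginal likelihood equals the chain of posterior predictives.

        For observations x_1..x_N of one variable, P(D) factorizes as
        prod_t (a_k + n_k(t)) / (a + t) with running counts n_k(t).
        """
        rng = np.random.default_rng(3)
        for alpha in (0.5, 1.0, 7.0):
            seq = rng.integers(0, 3, size=12)
            counts = np.bincount(seq, minlength=3)
            expected = 0.0
            running = np.zeros(3)
            for t, x in enumerate(seq):
                expected += math.log(
                    (alpha / 3 + running[x]) / (alpha + t)
                )
                running[x] += 1
            ct = _binary_counts(*counts)
            assert bdeu_local(ct, alpha) == pytest.approx(expected)

    def test_rejects_nonpositive_alpha(self):
        with pytest.raises(ValueError):
            bdeu_local(_binary_counts(1, 1), 0.0)
        with pytest.raises(ValueError):
            ScoreSpec("BDeu", -1.0)

    def test_alpha_grid_is_the_nine_point_study_grid(self):
        assert bdeu_alpha_grid() == (0.1, 0.5, 1, 5, 10, 20, 50, 80, 100)


def brute_force_regret(N: int, k: int) -> float:
    """C(N, k) by literal enumeration of all k^N datasets."""
    if N == 0:
        return 1.0
    total = 0.0
    for seq in itertools.product(range(k), repeat=N):
        counts = np.bincount(seq, minlength=k)
        p = counts / N
        total += float(np.prod(p**counts))
    return total


class TestRegret:
    def test_single_state_is_one(self):
        for N in (0, 1, 5, 100):
            assert log_multinomial_regret(N, 1) == 0.0

    def test_two_term_binary_sum(self):
        assert math.exp(log_multinomial_regret(1, 2)) == pytest.approx(2.0)

    def test_three_state_pair_enumeration(self):
        assert math.exp(log_multinomial_regret(2, 3)) == pytest.approx(4.5)

    @pytest.mark.parametrize("k", [2, 3, 4])
    @pytest.mark.parametrize("N", [1, 2, 3, 4])
    def test_matches_exhaustive_enumeration(self, N, k):
        assert math.exp(log_multinomial_regret(N, k)) == pytest.approx(
            brute_force_regret(N, k), rel=1e-9
        )

    def test_nondecreasing_in_n_and_k(self):
        for k in range(1, 6):
            vals = [log_multinomial_regret(N, k) for N in range(0, 30)]
            assert all(b >= a for a, b in zip(vals, vals[1:]))
        for N in (1, 10, 100):
            vals = [log_multinomial_regret(N, k) for k in range(1, 8)]
            assert all(b >= a for a, b in zip(vals, vals[1:]))

    def test_stable_at_large_n(self):
        v = log_multinomial_regret(100_000, 4)
        assert math.isfinite(v) and v > 0


class TestFnml:
    def test_single_observation(self):
        assert fnml_local(_binary_counts(1, 0)) == pytest.approx(-math.log(2))

    def test_equals_per_slice_nml_by_brute_force(self):
        """fNML local = sum over parent slices of log NML(slice).

        NML(slice) = ML(slice) / C(N_ij, r) with both factors enumerated
        independently of the recurrence-based implementation.
        """
        specs = (VariableSpec("P", ("0", "1")), VariableSpec("C", ("0", "1", "2")))
        rows = np.array(
            [[0, 0], [0, 0], [0, 2], [1, 1], [1, 1], [1, 0], [1, 2]]
        )
        data = CategoricalDataset(specs, rows)
        ct = build_counts(data, 1, (0,))
        expected = 0.0
        for j in range(ct.n_ij.shape[0]):
            nij = int(ct.n_ij[j])
            ml = float(
                np.prod((ct.n_ijk[j] / nij) ** ct.n_ijk[j])
            )
            expected += math.log(ml / brute_force_regret(nij, ct.r))
        assert fnml_local(ct) == pytest.approx(expected)


def _two_node_dataset(seed: int, N: int = 60) -> CategoricalDataset:
    return random_dataset(2, N, seed)


class TestNetworkScore:
    def test_empty_graph_decomposes_into_parentless_locals(self, make_dataset):
        data = make_dataset(3, 40, seed=2)
        spec = ScoreSpec("MDL")
        total = network_score(spec, DirectedGraph(data.names), data)
        parts = sum(
            local_score(spec, build_counts(data, i, ())) for i in range(3)
        )
        assert total == pytest.approx(parts)

    @pytest.mark.parametrize("seed", range(5))
    def test_adding_an_arc_never_decreases_likelihood(self, seed):
        data = _two_node_dataset(seed)
        base = log_likelihood_local(build_counts(data, 1, ()))
        with_arc = log_likelihood_local(build_counts(data, 1, (0,)))
        assert with_arc >= base - 1e-12

    @pytest.mark.parametrize("family,alpha", [("MDL", None), ("AIC", None), ("BDeu", 2.5)])
    def test_score_equivalent_families_on_reversed_edge(self, family, alpha):
        data = _two_node_dataset(17)
        spec = ScoreSpec(family, alpha)
        fwd = DirectedGraph(data.names, frozenset({("V0", "V1")}))
        bwd = DirectedGraph(data.names, frozenset({("V1", "V0")}))
        assert network_score(spec, fwd, data) == pytest.approx(
            network_score(spec, bwd, data), abs=1e-10
        )

    def test_mdl_superset_score_gap_is_ll_gain_minus_penalty_growth(self):
        data = random_dataset(3, 80, seed=23)
        spec = ScoreSpec("MDL")
        small = build_counts(data, 0, (1,))
        big = build_counts(data, 0, (1, 2))
        gap = local_score(spec, big) - local_score(spec, small)
        ll_gain = log_likelihood_local(big) - log_likelihood_local(small)
        pen_growth = penalty_mdl(num_params(big), data.n_rows) - penalty_mdl(
            num_params(small), data.n_rows
        )
        assert gap == pytest.approx(ll_gain - pen_growth)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=25, derandomize=True, deadline=None)
    def test_invariant_to_row_order_and_state_relabeling(self, seed):
        data = random_dataset(3, 30, seed)
        rng = np.random.default_rng(seed + 1)
        perm_rows = rng.permutation(data.n_rows)
        shuffled = CategoricalDataset(data.specs, data.rows[perm_rows])
        # relabel states of variable 0 with a matched spec permutation
        r0 = data.specs[0].arity
        sperm = rng.permutation(r0)
        new_states = tuple(data.specs[0].states[s] for s in np.argsort(sperm))
        relabeled_specs = (VariableSpec("V0", new_states),) + data.specs[1:]
        rows = data.rows.copy()
        rows[:, 0] = sperm[rows[:, 0]]
        relabeled = CategoricalDataset(relabeled_specs, rows)
        g = DirectedGraph(data.names, frozenset({("V0", "V1")}))
        for spec in (ScoreSpec("MDL"), ScoreSpec("fNML"), ScoreSpec("BDeu", 1.0)):
            ref = network_score(spec, g, data)
            assert network_score(spec, g, shuffled) == pytest.approx(ref)
            assert network_score(spec, g, relabeled) == pytest.approx(ref)
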
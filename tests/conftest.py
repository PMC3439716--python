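"""Shared fixtures: random datasets, tiny hand-built networks."""

from __future__ import annotations

import numpy as np
import pytest

from bnscore import BayesianNetwork, CategoricalDataset, DirectedGraph, VariableSpec


def random_dataset(n_vars: int, n_rows: int, seed: int,
                   arity_range: tuple[int, int] = (2, 3)) -> CategoricalDataset:
    """Uniform random categorical data with random small arities."""
    rng = np.random.default_rng(seed)
    arities = rng.integers(arity_range[0], arity_range[1] + 1, size=n_vars)
    specs = tuple(
        VariableSpec(f"V{i}", tuple(str(k) for k in range(a)))
        for i, a in enumerate(arities)
    )
    rows = rng.integers(0, arities, size=(n_rows, n_vars))
    return CategoricalDataset(specs, rows)


@pytest.fixture
def make_dataset():
    return random_dataset


@pytest.fixture
def fair_pair() -> BayesianNetwork:
    """Two independent fair binary variables."""
    specs = (VariableSpec("A", ("0", "1")), VariableSpec("B", ("0", "1")))
    graph = DirectedGraph(("A", "B"))
    return BayesianNetwork(specs, graph, {"A": [[0.5, 0.5]], "B": [[0.5, 0.5]]})


@pytest.fixture
def noisy_chain() -> BayesianNetwork:
    """X -> Y with a strong (0.9) dependence."""
    specs = (VariableSpec("X", ("0", "1")), VariableSpec("Y", ("0", "1")))
    graph = DirectedGraph(("X", "Y"), frozenset({("X", "Y")}))
    return BayesianNetwork(
        specs, graph, {"X": [[0.5, 0.5]], "Y": [[0.9, 0.1], [0.1, 0.9]]}
    )
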
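"""Synthetic gold-standard networks and forward (logic) sampling.

Gold networks here stand in for structures learned from real categorical
tables: small variable counts (5-25), average in-degree around 1.3-2.7 and
small arities, with fully parameterized CPTs drawn from symmetric Dirichlet
distributions.  The 13-profile benchmark suite reproduces the node and edge
counts of the study's gold networks exactly, so downstream recovery
experiments run against structures of the same shape without any external
data.

Logic sampling draws each row by visiting variables in topological order and
sampling every variable from its CPT row given the already-sampled parent
states; over rows this is vectorized per variable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .networks import (
    BayesianNetwork,
    CategoricalDataset,
    DirectedGraph,
    VariableSpec,
    mixed_radix_index,
    topological_order,
)


@dataclass(frozen=True)
class GoldNetworkProfile:
    """Shape parameters of a synthetic gold network.

    ``cpt_mode`` selects the parameterization: ``"dirichlet"`` draws each CPT
    row from a symmetric Dirichlet with the given concentration; the
    ``"sharpened"`` determinism-boost mode instead gives every row one
    dominant state with probability 0.9 (rest uniform), rejection-sampled so
    each parent actually changes the child's distribution.  Sharpened CPTs
    are strictly positive and keep every edge identifiable, so the gold
    structure is recoverable at moderate sample sizes — which a plain
    Dirichlet draw does not guarantee.
    """

    n: int
    avg_in_degree: float
    arity_range: tuple[int, int] = (2, 4)
    concentration: float = 1.0
    cpt_mode: str = "dirichlet"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 5 <= self.n <= 25:
            raise ValueError("n must be in [5, 25]")
        if not 0.0 <= self.avg_in_degree <= 3.0:
            raise ValueError("average in-degree must be in [0, 3]")
        lo, hi = self.arity_range
        if lo < 2 or hi < lo:
            raise ValueError("arities must be >= 2 and the range ordered")
        if self.concentration <= 0:
            raise ValueError("Dirichlet concentration must be positive")
        if self.cpt_mode not in ("dirichlet", "sharpened"):
            raise ValueError("cpt_mode must be 'dirichlet' or 'sharpened'")


def _dirichlet_cpts(
    variables: tuple[VariableSpec, ...],
    graph: DirectedGraph,
    concentration: float,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    spec = {v.name: v for v in variables}
    pm = graph.parent_map()
    cpts = {}
    for v in variables:
        q = int(np.prod([spec[p].arity for p in pm[v.name]], dtype=np.int64))
        cpts[v.name] = rng.dirichlet(np.full(v.arity, concentration), size=q)
    return cpts


DOMINANT_PROB = 0.9


def _sharpened_cpts(
    variables: tuple[VariableSpec, ...],
    graph: DirectedGraph,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Determinism-boost CPTs: one dominant state per row at probability 0.9.

    The vector of dominant states over parent configurations is rejected
    while it is constant along any single parent's axis, so every declared
    edge changes the child's conditional distribution somewhere.  Rows stay
    strictly positive, keeping the sampling distribution faithful enough for
    the gold equivalence class to be the large-sample optimum.
    """
    spec = {v.name: v for v in variables}
    pm = graph.parent_map()
    cpts = {}
    for v in variables:
        arities = [spec[p].arity for p in pm[v.name]]
        q = int(np.prod(arities, dtype=np.int64))
        for _ in range(1000):
            dom = rng.integers(0, v.arity, size=q)
            if not arities:
                break
            shaped = dom.reshape(arities)
            if all(
                np.any(np.ptp(shaped, axis=ax) > 0)
                for ax in range(len(arities))
            ):
                break
        eps = (1.0 - DOMINANT_PROB) / (v.arity - 1)
        table = np.full((q, v.arity), eps)
        table[np.arange(q), dom] = DOMINANT_PROB
        cpts[v.name] = table
    return cpts


def _make_cpts(variables, graph, profile_mode: str, concentration: float,
               rng: np.random.Generator) -> dict[str, np.ndarray]:
    if profile_mode == "sharpened":
        return _sharpened_cpts(variables, graph, rng)
    return _dirichlet_cpts(variables, graph, concentration, rng)


def _variables(n: int, arity_range: tuple[int, int], rng: np.random.Generator):
    arities = rng.integers(arity_range[0], arity_range[1] + 1, size=n)
    return tuple(
        VariableSpec(f"X{i + 1:02d}", tuple(f"s{k}" for k in range(arities[i])))
        for i in range(n)
    )


def random_gold_network(profile: GoldNetworkProfile) -> BayesianNetwork:
    """Sample a gold network matching the profile in expectation.

    A random generation order is drawn; each (predecessor, variable) pair
    becomes an edge independently with probability 2*avg_in_degree/(n-1), so
    the expected average in-degree equals the target.
    """
    rng = np.random.default_rng(profile.seed)
    variables = _variables(profile.n, profile.arity_range, rng)
    names = tuple(v.name for v in variables)
    perm = rng.permutation(profile.n)
    p = min(1.0, 2.0 * profile.avg_in_degree / (profile.n - 1))
    edges = set()
    for pos in range(1, profile.n):
        v = perm[pos]
        for u in perm[:pos]:
            if rng.random() < p:
                edges.add((names[u], names[v]))
    graph = DirectedGraph(names, frozenset(edges))
    return BayesianNetwork(
        variables, graph,
        _make_cpts(variables, graph, profile.cpt_mode, profile.concentration, rng),
    )


def random_gold_network_exact_edges(
    n: int,
    n_edges: int,
    arity_range: tuple[int, int] = (2, 4),
    concentration: float = 1.0,
    cpt_mode: str = "dirichlet",
    seed: int = 0,
) -> BayesianNetwork:
    """Gold network with an exact edge count: n_edges pairs drawn uniformly
    without replacement along a random generation order."""
    max_edges = n * (n - 1) // 2
    if not 0 <= n_edges <= max_edges:
        raise ValueError(f"edge count must be in [0, {max_edges}]")
    rng = np.random.default_rng(seed)
    variables = _variables(n, arity_range, rng)
    names = tuple(v.name for v in variables)
    perm = rng.permutation(n)
    pairs = [(perm[a], perm[b]) for b in range(n) for a in range(b)]
    chosen = rng.choice(len(pairs), size=n_edges, replace=False)
    edges = frozenset((names[pairs[c][0]], names[pairs[c][1]]) for c in chosen)
    graph = DirectedGraph(names, edges)
    return BayesianNetwork(
        variables, graph, _make_cpts(variables, graph, cpt_mode, concentration, rng)
    )


def logic_sample(bn: BayesianNetwork, N: int, seed: int = 0) -> CategoricalDataset:
    """Draw N i.i.d. rows by ancestral sampling in topological order."""
    if N < 1:
        raise ValueError("N must be >= 1")
    rng = np.random.default_rng(seed)
    names = bn.names
    idx = {n: i for i, n in enumerate(names)}
    pm = bn.graph.parent_map()
    rows = np.zeros((N, len(names)), dtype=np.int64)
    for name in topological_order(bn.graph):
        parents = pm[name]
        arities = [bn.spec(p).arity for p in parents]
        conf = mixed_radix_index(rows[:, [idx[p] for p in parents]], arities)
        probs = bn.cpts[name][conf]  # (N, r)
        u = rng.random(N)
        rows[:, idx[name]] = (probs.cumsum(axis=1) < u[:, None]).sum(axis=1)
    return CategoricalDataset(bn.variables, rows)


@dataclass(frozen=True)
class SampleGrid:
    """Strictly increasing dataset sizes for a sampling experiment."""

    sizes: tuple[int, ...]

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.sizes):
            raise ValueError("sizes must be positive")
        if any(b <= a for a, b in zip(self.sizes, self.sizes[1:])):
            raise ValueError("sizes must be strictly increasing")


def benchmark_sample_grid() -> SampleGrid:
    """200..1000 by 200 plus 2000..10000 by 1000: 14 distinct sizes."""
    sizes = tuple(range(200, 1001, 200)) + tuple(range(2000, 10001, 1000))
    return SampleGrid(sizes)


#: (name, nodes, edges) of the 13 gold-network shapes the suite reproduces.
BENCHMARK_PROFILES: tuple[tuple[str, int, int], ...] = (
    ("austra-like", 15, 33),
    ("breast-like", 10, 20),
    ("car-like", 7, 9),
    ("cleve-like", 14, 22),
    ("crx-like", 16, 35),
    ("diabetes-like", 9, 13),
    ("glass-like", 10, 17),
    ("heart-like", 14, 21),
    ("hepatitis-like", 20, 36),
    ("iris-like", 5, 8),
    ("nursery-like", 9, 14),
    ("vehicle-like", 19, 40),
    ("voting-like", 17, 46),
)


def benchmark_suite(
    seed: int = 0,
    concentration: float = 1.0,
    cpt_mode: str = "dirichlet",
    arity_range: tuple[int, int] = (2, 4),
) -> list[tuple[str, BayesianNetwork]]:
    """13 synthetic gold networks matching the benchmark (nodes, edges) pairs."""
    suite = []
    for k, (name, n, m) in enumerate(BENCHMARK_PROFILES):
        bn = random_gold_network_exact_edges(
            n, m, arity_range=arity_range, concentration=concentration,
            cpt_mode=cpt_mode, seed=seed * 1000 + k,
        )
        suite.append((name, bn))
    return suite
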
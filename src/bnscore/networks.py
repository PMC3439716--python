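"""Discrete Bayesian networks: graphs, CPTs, MLE fitting and serialization.

A Bayesian network is a pair (G, Theta): a DAG over discrete variables plus,
for every variable X_i, a conditional probability table P(X_i | PA_i) with one
row per joint configuration of the parents and one column per state.  The
joint density factorizes as P(V) = prod_i P(x_i | pa_i).

All log quantities in this package are natural log; :data:`LOG2` converts
where a result is wanted in bits.  Node identity is by name and every
serialized order is declaration order, so all outputs are deterministic.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

LOG2 = math.log(2.0)

NEG_INF = float("-inf")


class AcyclicityError(ValueError):
    """Raised when a directed graph required to be acyclic contains a cycle."""


@dataclass(frozen=True)
class VariableSpec:
    """A named discrete variable with an ordered list of state labels."""

    name: str
    states: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "states", tuple(str(s) for s in self.states))
        if len(self.states) < 2:
            raise ValueError(f"variable {self.name!r} needs >= 2 states")
        if len(set(self.states)) != len(self.states):
            raise ValueError(f"variable {self.name!r} has duplicate state labels")

    @property
    def arity(self) -> int:
        return len(self.states)


@dataclass(frozen=True)
class DirectedGraph:
    """A directed graph over named nodes; edges are (parent, child) pairs.

    The node tuple fixes declaration order, which every deterministic
    tie-break in the package refers back to.  Acyclicity is not enforced at
    construction; :func:`topological_order` certifies it on demand.
    """

    nodes: tuple[str, ...]
    edges: frozenset[tuple[str, str]] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(self, "nodes", tuple(self.nodes))
        object.__setattr__(
            self, "edges", frozenset((str(a), str(b)) for a, b in self.edges)
        )
        nodeset = set(self.nodes)
        if len(nodeset) != len(self.nodes):
            raise ValueError("duplicate node names")
        for a, b in self.edges:
            if a == b:
                raise ValueError(f"self-loop on {a!r}")
            if a not in nodeset or b not in nodeset:
                raise ValueError(f"edge ({a!r}, {b!r}) references unknown node")

    def parents(self, node: str) -> tuple[str, ...]:
        """Parents of *node* in declaration order."""
        ps = {a for a, b in self.edges if b == node}
        return tuple(n for n in self.nodes if n in ps)

    def children(self, node: str) -> tuple[str, ...]:
        cs = {b for a, b in self.edges if a == node}
        return tuple(n for n in self.nodes if n in cs)

    def parent_map(self) -> dict[str, tuple[str, ...]]:
        ps: dict[str, list[str]] = {n: [] for n in self.nodes}
        for a, b in self.edges:
            ps[b].append(a)
        order = {n: i for i, n in enumerate(self.nodes)}
        return {n: tuple(sorted(v, key=order.__getitem__)) for n, v in ps.items()}

    def with_edges(self, edges: Iterable[tuple[str, str]]) -> "DirectedGraph":
        return DirectedGraph(self.nodes, frozenset(edges))

    def is_acyclic(self) -> bool:
        try:
            topological_order(self)
            return True
        except AcyclicityError:
            return False


def topological_order(graph: DirectedGraph) -> list[str]:
    """Topological order with ties broken by node declaration order.

    Raises :class:`AcyclicityError` naming one cycle if the graph is cyclic.
    """
    g = nx.DiGraph()
    g.add_nodes_from(graph.nodes)
    g.add_edges_from(graph.edges)
    rank = {n: i for i, n in enumerate(graph.nodes)}
    try:
        return list(nx.lexicographical_topological_sort(g, key=rank.__getitem__))
    except nx.NetworkXUnfeasible:
        cycle = [a for a, _ in nx.find_cycle(g)]
        raise AcyclicityError(f"graph contains a cycle: {' -> '.join(cycle + cycle[:1])}")


def mixed_radix_index(states: np.ndarray, arities: Sequence[int]) -> np.ndarray:
    """Configuration index with the first column most significant.

    ``states`` is an (N, p) integer array of parent states; the result maps
    each row to its rank in the mixed-radix enumeration of parent
    configurations (the row order of every CPT and count table).
    """
    states = np.atleast_2d(np.asarray(states, dtype=np.int64))
    if states.shape[1] == 0:
        return np.zeros(states.shape[0], dtype=np.int64)
    radix = np.ones(len(arities), dtype=np.int64)
    for j in range(len(arities) - 2, -1, -1):
        radix[j] = radix[j + 1] * arities[j + 1]
    return states @ radix


@dataclass(frozen=True)
class BayesianNetwork:
    """A DAG plus one row-stochastic CPT per variable.

    CPT for variable *v* has shape (q_v, r_v): one row per mixed-radix parent
    configuration (first-declared parent most significant), one column per
    state.  Rows must sum to 1 within 1e-9.
    """

    variables: tuple[VariableSpec, ...]
    graph: DirectedGraph
    cpts: Mapping[str, np.ndarray]

    def __post_init__(self) -> None:
        object.__setattr__(self, "variables", tuple(self.variables))
        names = tuple(v.name for v in self.variables)
        if names != self.graph.nodes:
            raise ValueError("graph nodes must match variable declaration order")
        spec = {v.name: v for v in self.variables}
        cpts = {}
        pm = self.graph.parent_map()
        for v in self.variables:
            table = np.asarray(self.cpts[v.name], dtype=float)
            q = int(np.prod([spec[p].arity for p in pm[v.name]], dtype=np.int64))
            if table.shape != (q, v.arity):
                raise ValueError(
                    f"CPT for {v.name!r} has shape {table.shape}, expected {(q, v.arity)}"
                )
            if np.any(table < -1e-12) or np.any(table > 1 + 1e-12):
                raise ValueError(f"CPT for {v.name!r} has entries outside [0, 1]")
            if not np.allclose(table.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError(f"CPT rows for {v.name!r} do not sum to 1")
            cpts[v.name] = table
        object.__setattr__(self, "cpts", cpts)
        topological_order(self.graph)  # certify acyclicity

    @property
    def names(self) -> tuple[str, ...]:
        return self.graph.nodes

    def spec(self, name: str) -> VariableSpec:
        return {v.name: v for v in self.variables}[name]

    # -- serialization -----------------------------------------------------

    def to_json(self) -> str:
        obj = {
            "variables": [
                {"name": v.name, "states": list(v.states)} for v in self.variables
            ],
            "edges": sorted([list(e) for e in self.graph.edges]),
            "cpts": {v.name: self.cpts[v.name].tolist() for v in self.variables},
        }
        return json.dumps(obj, indent=1)

    @staticmethod
    def from_json(text: str) -> "BayesianNetwork":
        obj = json.loads(text)
        variables = tuple(
            VariableSpec(d["name"], tuple(d["states"])) for d in obj["variables"]
        )
        graph = DirectedGraph(
            tuple(v.name for v in variables),
            frozenset(tuple(e) for e in obj["edges"]),
        )
        cpts = {k: np.asarray(v, dtype=float) for k, v in obj["cpts"].items()}
        return BayesianNetwork(variables, graph, cpts)


@dataclass(frozen=True)
class CategoricalDataset:
    """N complete rows of integer-coded observations of discrete variables."""

    specs: tuple[VariableSpec, ...]
    rows: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "specs", tuple(self.specs))
        rows = np.asarray(self.rows, dtype=np.int64)
        if rows.ndim != 2 or rows.shape[1] != len(self.specs):
            raise ValueError("rows must be an (N, n) array matching the specs")
        if rows.shape[0] < 1:
            raise ValueError("dataset must contain at least one row")
        for j, v in enumerate(self.specs):
            col = rows[:, j]
            if col.min() < 0 or col.max() >= v.arity:
                raise ValueError(f"state index out of range for variable {v.name!r}")
        object.__setattr__(self, "rows", rows)

    @property
    def n_rows(self) -> int:
        return int(self.rows.shape[0])

    @property
    def n_vars(self) -> int:
        return len(self.specs)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(v.name for v in self.specs)

    def column(self, name: str) -> np.ndarray:
        return self.rows[:, self.names.index(name)]

    # -- CSV round trip (values are state labels) --------------------------

    def to_csv(self, path) -> None:
        df = pd.DataFrame(
            {v.name: [v.states[s] for s in self.rows[:, j]]
             for j, v in enumerate(self.specs)}
        )
        df.to_csv(path, index=False)

    @staticmethod
    def from_csv(path, specs: Sequence[VariableSpec]) -> "CategoricalDataset":
        df = pd.read_csv(path, dtype=str)
        cols = []
        for v in specs:
            lut = {s: i for i, s in enumerate(v.states)}
            try:
                cols.append(df[v.name].map(lut).to_numpy(dtype=np.int64))
            except (TypeError, ValueError) as exc:
                raise ValueError(f"unknown state label in column {v.name!r}") from exc
        return CategoricalDataset(tuple(specs), np.column_stack(cols))


def joint_log_probability(bn: BayesianNetwork, instance: Sequence[int]) -> float:
    """log P(instance) = sum_i log P(x_i | pa_i) in nats; -inf on a zero factor."""
    names = bn.names
    if len(instance) != len(names):
        raise ValueError("instance length does not match variable count")
    idx = {n: i for i, n in enumerate(names)}
    pm = bn.graph.parent_map()
    total = 0.0
    for v in bn.variables:
        x = int(instance[idx[v.name]])
        if not 0 <= x < v.arity:
            raise ValueError(f"state index {x} out of range for {v.name!r}")
        parents = pm[v.name]
        pstates = np.array([[instance[idx[p]] for p in parents]], dtype=np.int64)
        j = int(mixed_radix_index(pstates, [bn.spec(p).arity for p in parents])[0])
        p = bn.cpts[v.name][j, x]
        if p <= 0.0:
            return NEG_INF
        total += math.log(p)
    return total


def fit_mle(graph: DirectedGraph, data: CategoricalDataset) -> BayesianNetwork:
    """Maximum-likelihood CPTs: row j of variable i is N_ijk / N_ij.

    Parent configurations never observed (N_ij = 0) get the uniform
    distribution so that sampling from the fitted network stays well defined.
    """
    if graph.nodes != data.names:
        raise ValueError("graph nodes must match dataset variables")
    topological_order(graph)
    spec = {v.name: v for v in data.specs}
    pm = graph.parent_map()
    cpts = {}
    for j, v in enumerate(data.specs):
        parents = pm[v.name]
        arities = [spec[p].arity for p in parents]
        q = int(np.prod(arities, dtype=np.int64)) if parents else 1
        cols = data.rows[:, [data.names.index(p) for p in parents]]
        conf = mixed_radix_index(cols, arities)
        counts = np.zeros((q, v.arity))
        np.add.at(counts, (conf, data.rows[:, j]), 1.0)
        totals = counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            table = counts / totals
        table[totals[:, 0] == 0] = 1.0 / v.arity
        cpts[v.name] = table
    return BayesianNetwork(tuple(data.specs), graph, cpts)
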
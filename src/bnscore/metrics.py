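"""Structural comparison of learned versus gold networks.

Two families of metrics are provided.  The confusion-based metrics
(accuracy, sensitivity, average Hamming distance) operate directly on the
DAGs: over the n(n-1)/2 unordered variable pairs, a correctly oriented edge
is a TP, an absent-in-both pair a TN, an extra edge an FP, a missing edge an
FN, and an edge present in both but oriented the wrong way counts as both an
FP and an FN.

The structural Hamming distance (SHD) instead compares Markov equivalence
classes: each DAG is first converted to its completed PDAG (CPDAG) with
compelled edges directed and reversible edges undirected, via the
edge-ordering/labeling procedure of Chickering; SHD then counts unordered
pairs whose adjacency, edge type or orientation differ between the two
CPDAGs.  Two DAGs in the same equivalence class therefore have SHD 0.
"""

from __future__ import annotations

from dataclasses import dataclass

from .networks import AcyclicityError, DirectedGraph, topological_order


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int


def edge_confusion(gold: DirectedGraph, learned: DirectedGraph) -> ConfusionCounts:
    """Per-pair confusion counts; a wrongly oriented edge is both FP and FN."""
    if set(gold.nodes) != set(learned.nodes):
        raise ValueError("gold and learned networks must share the same nodes")
    nodes = gold.nodes
    tp = tn = fp = fn = 0
    for a in range(len(nodes)):
        for b in range(a + 1, len(nodes)):
            u, v = nodes[a], nodes[b]
            g = ((u, v) in gold.edges) - ((v, u) in gold.edges)
            gl = (u, v) in gold.edges or (v, u) in gold.edges
            ll = (u, v) in learned.edges or (v, u) in learned.edges
            l = ((u, v) in learned.edges) - ((v, u) in learned.edges)
            if not gl and not ll:
                tn += 1
            elif gl and ll:
                if g == l:
                    tp += 1
                else:
                    fp += 1
                    fn += 1
            elif ll:
                fp += 1
            else:
                fn += 1
    return ConfusionCounts(tp, tn, fp, fn)


def accuracy(counts: ConfusionCounts) -> float:
    """(TP+TN)/(TP+TN+FP+FN); 1 when both graphs are empty (no pair can err)."""
    denom = counts.tp + counts.tn + counts.fp + counts.fn
    return 1.0 if denom == 0 else (counts.tp + counts.tn) / denom


def sensitivity(counts: ConfusionCounts) -> float:
    """TP/(TP+FN); 1 when the gold network has no edges."""
    denom = counts.tp + counts.fn
    return 1.0 if denom == 0 else counts.tp / denom


def ahd(counts: ConfusionCounts, n: int) -> float:
    """Average Hamming distance (FP+FN)/n."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return (counts.fp + counts.fn) / n


@dataclass(frozen=True)
class PDAG:
    """A partially directed graph: compelled edges directed, reversible undirected."""

    nodes: tuple[str, ...]
    directed: frozenset  # (parent, child) pairs
    undirected: frozenset  # sorted (a, b) pairs

    def __post_init__(self) -> None:
        und = frozenset(tuple(sorted(e)) for e in self.undirected)
        object.__setattr__(self, "undirected", und)
        dpairs = {tuple(sorted(e)) for e in self.directed}
        if dpairs & self.undirected:
            raise ValueError("a pair cannot be both directed and undirected")

    def pair_state(self, a: str, b: str):
        """'none', 'undirected', or the ordered compelled pair."""
        key = tuple(sorted((a, b)))
        if key in self.undirected:
            return "undirected"
        if (a, b) in self.directed:
            return (a, b)
        if (b, a) in self.directed:
            return (b, a)
        return "none"


def _order_edges(dag: DirectedGraph) -> list[tuple[str, str]]:
    """Chickering's edge ordering: repeatedly take the lowest-ordered node y
    with an unordered incoming edge and the highest-ordered tail x of such an
    edge, and order x -> y next."""
    topo = topological_order(dag)
    rank = {n: i for i, n in enumerate(topo)}
    unordered = set(dag.edges)
    ordered = []
    while unordered:
        y = min((e[1] for e in unordered), key=rank.__getitem__)
        x = max((e[0] for e in unordered if e[1] == y), key=rank.__getitem__)
        ordered.append((x, y))
        unordered.remove((x, y))
    return ordered


def to_cpdag(dag: DirectedGraph) -> PDAG:
    """Completed PDAG of the Markov equivalence class of *dag*.

    Labels every edge compelled or reversible by Chickering's procedure:
    edges are processed in a fixed total order; an edge x -> y is compelled
    when a compelled edge into x does not reach y (which also compels every
    other edge into y) or when some third parent of y is not adjacent to x
    (the v-structure case); otherwise it and the remaining edges into y are
    reversible.
    """
    edges = _order_edges(dag)  # raises AcyclicityError on cyclic input
    label: dict[tuple[str, str], str] = {}
    parents = dag.parent_map()
    for x, y in edges:
        if (x, y) in label:
            continue
        decided = False
        for w in parents[x]:
            if label.get((w, x)) != "compelled":
                continue
            if w not in parents[y]:
                for p in parents[y]:
                    label[(p, y)] = "compelled"
                decided = True
                break
            label[(w, y)] = "compelled"
        if decided:
            continue
        if any(z != x and z not in parents[x] for z in parents[y]):
            for p in parents[y]:
                if (p, y) not in label:
                    label[(p, y)] = "compelled"
        else:
            for p in parents[y]:
                if (p, y) not in label:
                    label[(p, y)] = "reversible"
    directed = frozenset(e for e in dag.edges if label[e] == "compelled")
    undirected = frozenset(
        tuple(sorted(e)) for e in dag.edges if label[e] == "reversible"
    )
    return PDAG(dag.nodes, directed, undirected)


@dataclass(frozen=True)
class ShdResult:
    """SHD total plus its add/delete/reverse/missing decomposition.

    add: pair adjacent only in the learned CPDAG; delete: adjacency present
    only in gold as a reversible edge; missing: adjacency present only in
    gold as a compelled edge; reverse: adjacent in both with a differing
    orientation or edge type.
    """

    total: int
    add: int
    delete: int
    reverse: int
    missing: int


def shd(gold: DirectedGraph, learned: DirectedGraph) -> ShdResult:
    """Structural Hamming distance between the CPDAGs of two DAGs."""
    if set(gold.nodes) != set(learned.nodes):
        raise ValueError("gold and learned networks must share the same nodes")
    gp = to_cpdag(gold)
    lp = to_cpdag(learned)
    nodes = gold.nodes
    add = delete = reverse = missing = 0
    for a in range(len(nodes)):
        for b in range(a + 1, len(nodes)):
            gs = gp.pair_state(nodes[a], nodes[b])
            ls = lp.pair_state(nodes[a], nodes[b])
            if gs == ls:
                continue
            if gs == "none":
                add += 1
            elif ls == "none":
                if gs == "undirected":
                    delete += 1
                else:
                    missing += 1
            else:
                reverse += 1
    total = add + delete + reverse + missing
    return ShdResult(total, add, delete, reverse, missing)


def same_equivalence_class(g1: DirectedGraph, g2: DirectedGraph) -> bool:
    """Independent equivalence oracle: same skeleton and same v-structures.

    A v-structure is a collider a -> c <- b with a and b non-adjacent.  This
    characterization (Verma-Pearl) is deliberately separate from the CPDAG
    construction so the two routes can cross-check each other.
    """
    if set(g1.nodes) != set(g2.nodes):
        raise ValueError("graphs must share the same nodes")

    def skeleton(g: DirectedGraph):
        return {tuple(sorted(e)) for e in g.edges}

    def vstructs(g: DirectedGraph):
        adj = skeleton(g)
        out = set()
        for c in g.nodes:
            ps = g.parents(c)
            for i in range(len(ps)):
                for j in range(i + 1, len(ps)):
                    a, b = ps[i], ps[j]
                    if tuple(sorted((a, b))) not in adj:
                        out.add((tuple(sorted((a, b))), c))
        return out

    return skeleton(g1) == skeleton(g2) and vstructs(g1) == vstructs(g2)
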
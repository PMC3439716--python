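"""Structure learners: exact subset dynamic programming, a brute-force
all-DAG oracle, and greedy hill climbing with random restarts and a tabu list.

The exact learner finds the global maximizer of any decomposable score in two
dynamic programs: ``best_parents`` computes, for every variable and every
candidate set, the best-scoring parent set drawn from that candidate set; the
sink sweep then builds the best network over every variable subset W as

    best(W) = max_{s in W} best(W \\ {s}) + best_parents(s, W \\ {s}).

Both run over bitmask-indexed subsets, so memory and time are O(n 2^n); the
default variable limit is 16.  All optimal learners return score-equivalent
networks, so ties are broken deterministically (smaller parent set, then
lexicographic; smallest-index sink) purely for reproducibility.
"""

from __future__ import annotations

import itertools
from collections import deque
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .networks import CategoricalDataset, DirectedGraph
from .scoring import ScoreSpec, build_counts, local_score

EXACT_LIMIT = 16


class CapabilityError(RuntimeError):
    """Raised when a learner is asked for a problem size beyond its design range."""


def _bits(mask: int) -> list[int]:
    out = []
    j = 0
    while mask:
        if mask & 1:
            out.append(j)
        mask >>= 1
        j += 1
    return out


def _mask(indices) -> int:
    m = 0
    for j in indices:
        m |= 1 << j
    return m


@dataclass(frozen=True)
class LocalScoreTable:
    """Per-variable map from candidate parent set (bitmask) to local score."""

    names: tuple[str, ...]
    scores: tuple[dict, ...]  # scores[i][mask] -> float, bit i never set
    max_parents: Optional[int] = None

    @property
    def n(self) -> int:
        return len(self.names)

    def score(self, i: int, parents) -> float:
        mask = parents if isinstance(parents, int) else _mask(parents)
        return self.scores[i][mask]


def enumerate_local_score_tables(
    data: CategoricalDataset,
    specs: Sequence[ScoreSpec],
    max_parents: Optional[int] = None,
    limit: int = EXACT_LIMIT,
) -> dict[ScoreSpec, LocalScoreTable]:
    """Score every (variable, parent set) pair once, for several score specs.

    Counting dominates the cost, so sufficient statistics are shared across
    the requested specs.
    """
    n = data.n_vars
    if n > limit:
        raise CapabilityError(
            f"{n} variables exceeds the exact-learning limit of {limit}; "
            "use hill_climb for larger problems"
        )
    bound = n - 1 if max_parents is None else min(max_parents, n - 1)
    tables: dict[ScoreSpec, list[dict]] = {s: [dict() for _ in range(n)] for s in specs}
    for i in range(n):
        others = [j for j in range(n) if j != i]
        for size in range(bound + 1):
            for combo in itertools.combinations(others, size):
                counts = build_counts(data, i, combo)
                mask = _mask(combo)
                for s in specs:
                    tables[s][i][mask] = local_score(s, counts)
    return {
        s: LocalScoreTable(data.names, tuple(tables[s]), max_parents) for s in specs
    }


def enumerate_local_scores(
    data: CategoricalDataset,
    spec: ScoreSpec,
    max_parents: Optional[int] = None,
    limit: int = EXACT_LIMIT,
) -> LocalScoreTable:
    return enumerate_local_score_tables(data, [spec], max_parents, limit)[spec]


def _prefer(a: tuple[float, int], b: tuple[float, int]) -> tuple[float, int]:
    """Pick the better (score, parent-mask) pair; ties favour the smaller set,
    then the lexicographically smaller sorted index tuple."""
    if a[0] != b[0]:
        return a if a[0] > b[0] else b
    abits, bbits = _bits(a[1]), _bits(b[1])
    if len(abits) != len(bbits):
        return a if len(abits) < len(bbits) else b
    return a if abits <= bbits else b


def _best_parents_masks(
    table: LocalScoreTable, i: int, cand_mask: int
) -> dict[int, tuple[float, int]]:
    """best(C) = max(score(C), max_{c in C} best(C \\ {c})) over all C ⊆ cand_mask."""
    stored = table.scores[i]
    sub: list[int] = []
    s = cand_mask
    while True:
        sub.append(s)
        if s == 0:
            break
        s = (s - 1) & cand_mask
    sub.sort(key=lambda m: (bin(m).count("1"), m))
    best: dict[int, tuple[float, int]] = {}
    for m in sub:
        entry = (stored[m], m) if m in stored else None
        for j in _bits(m):
            prev = best[m & ~(1 << j)]
            entry = prev if entry is None else _prefer(entry, prev)
        if entry is None:
            raise ValueError("empty parent set missing from score table")
        best[m] = entry
    return best


def best_parents_dp(table: LocalScoreTable, i: int, candidates) -> dict:
    """For every subset C of *candidates*: the best parent set ⊆ C and its score."""
    cand = frozenset(candidates)
    if i in cand:
        raise ValueError("candidates must exclude the child variable")
    best = _best_parents_masks(table, i, _mask(cand))
    return {
        frozenset(_bits(m)): (frozenset(_bits(pm)), sc)
        for m, (sc, pm) in best.items()
    }


@dataclass(frozen=True)
class LearnResult:
    """A learned structure with its total score and provenance."""

    graph: DirectedGraph
    score: float
    learner: str
    seed: Optional[int]
    spec: ScoreSpec


def _result(data, spec, parent_masks, table, learner, seed) -> LearnResult:
    names = data.names
    edges = set()
    total = 0.0
    for i, m in enumerate(parent_masks):
        total += table.scores[i][m]
        for j in _bits(m):
            edges.add((names[j], names[i]))
    return LearnResult(DirectedGraph(names, frozenset(edges)), total, learner, seed, spec)


def exact_learn(
    data: CategoricalDataset,
    spec: ScoreSpec,
    max_parents: Optional[int] = None,
    limit: int = EXACT_LIMIT,
    table: Optional[LocalScoreTable] = None,
) -> LearnResult:
    """Globally optimal structure for a decomposable score (sink-based DP)."""
    n = data.n_vars
    if n > limit:
        raise CapabilityError(
            f"{n} variables exceeds the exact-learning limit of {limit}; "
            "use hill_climb for larger problems"
        )
    if table is None:
        table = enumerate_local_scores(data, spec, max_parents, limit)
    full = (1 << n) - 1
    bp = [_best_parents_masks(table, i, full & ~(1 << i)) for i in range(n)]
    order = sorted(range(1 << n), key=lambda m: (bin(m).count("1"), m))
    best_net = {0: 0.0}
    choice: dict[int, tuple[int, int]] = {}  # mask -> (sink, parent mask)
    for m in order:
        if m == 0:
            continue
        best_val = None
        best_choice = None
        for s in _bits(m):
            prev = m & ~(1 << s)
            sc, pmask = bp[s][prev]
            val = best_net[prev] + sc
            if best_val is None or val > best_val:
                best_val, best_choice = val, (s, pmask)
        best_net[m] = best_val
        choice[m] = best_choice
    parent_masks = [0] * n
    m = full
    while m:
        s, pmask = choice[m]
        parent_masks[s] = pmask
        m &= ~(1 << s)
    return _result(data, spec, parent_masks, table, "exact", None)


def _all_dag_parent_masks(n: int) -> list[tuple[int, ...]]:
    """Every labeled DAG on n nodes as a tuple of per-variable parent masks.

    Enumerated by topological permutation (each variable picks parents among
    its predecessors), de-duplicated across linear extensions.
    """
    seen = set()
    for perm in itertools.permutations(range(n)):
        options = []
        for pos, v in enumerate(perm):
            preds = perm[:pos]
            opts = []
            for size in range(pos + 1):
                for combo in itertools.combinations(preds, size):
                    opts.append((v, _mask(combo)))
            options.append(opts)
        for combo in itertools.product(*options):
            masks = [0] * n
            for v, m in combo:
                masks[v] = m
            seen.add(tuple(masks))
    return sorted(seen)


def brute_force_learn(
    data: CategoricalDataset,
    spec: ScoreSpec,
    table: Optional[LocalScoreTable] = None,
) -> LearnResult:
    """Exhaustive maximum over all labeled DAGs (test oracle, n <= 5).

    Ties broken toward the lexicographically smallest canonical edge list.
    """
    n = data.n_vars
    if n > 5:
        raise CapabilityError("brute-force learning is limited to 5 variables")
    if table is None:
        table = enumerate_local_scores(data, spec)
    names = data.names
    best = None
    for masks in _all_dag_parent_masks(n):
        total = sum(table.scores[i][m] for i, m in enumerate(masks))
        edges = tuple(sorted((j, i) for i, m in enumerate(masks) for j in _bits(m)))
        key = (total, [tuple(reversed(e)) for e in edges])
        if best is None or total > best[0] or (total == best[0] and edges < best[1]):
            best = (total, edges, masks)
    return _result(data, spec, list(best[2]), table, "brute", None)


# -- greedy hill climbing ----------------------------------------------------


def _has_path(children: list[int], src: int, dst: int) -> bool:
    """Is there a directed path src -> ... -> dst? (children[i] is a bitmask)."""
    seen = 1 << src
    stack = [src]
    while stack:
        v = stack.pop()
        m = children[v] & ~seen
        if m >> dst & 1:
            return True
        while m:
            j = (m & -m).bit_length() - 1
            m &= m - 1
            seen |= 1 << j
            stack.append(j)
    return False


def _random_dag_masks(n: int, rng: np.random.Generator) -> list[int]:
    """Random DAG with edge probability 2/n along a random order."""
    perm = rng.permutation(n)
    masks = [0] * n
    p = min(1.0, 2.0 / n)
    for pos in range(1, n):
        v = perm[pos]
        for prev in perm[:pos]:
            if rng.random() < p:
                masks[v] |= 1 << int(prev)
    return masks


def hill_climb(
    data: CategoricalDataset,
    spec: ScoreSpec,
    restarts: int = 10,
    tabu_length: int = 100,
    max_no_improve: int = 50,
    seed: int = 0,
    max_parents: Optional[int] = None,
) -> LearnResult:
    """Steepest-ascent search over add/delete/reverse moves.

    Only strictly improving moves are accepted, so every climb terminates at
    a local optimum.  A fixed-length tabu list blocks the inverse of recent
    moves (with aspiration: a tabu move that would beat the incumbent best is
    allowed).  Restart 0 starts from the empty graph; later restarts from
    random DAGs with edge probability 2/n.  A restart is abandoned after
    ``max_no_improve`` accepted moves that fail to beat the incumbent best.
    Fully reproducible given *seed*.
    """
    n = data.n_vars
    names = data.names
    rng = np.random.default_rng(seed)
    bound = n - 1 if max_parents is None else max_parents
    cache: dict[tuple[int, int], float] = {}

    def local(i: int, mask: int) -> float:
        key = (i, mask)
        if key not in cache:
            cache[key] = local_score(spec, build_counts(data, i, _bits(mask)))
        return cache[key]

    best_overall: Optional[tuple[float, list[int]]] = None
    for restart in range(restarts):
        masks = [0] * n if restart == 0 else _random_dag_masks(n, rng)
        current = sum(local(i, masks[i]) for i in range(n))
        tabu: deque = deque(maxlen=max(tabu_length, 1))
        stalled = 0
        while True:
            children = [0] * n
            for i in range(n):
                for j in _bits(masks[i]):
                    children[j] |= 1 << i
            best_move = None  # (delta, order key, apply fn signature)
            for u in range(n):
                for v in range(n):
                    if u == v:
                        continue
                    has = masks[v] >> u & 1
                    if not has:
                        if bin(masks[v]).count("1") >= bound:
                            continue
                        if _has_path(children, v, u):
                            continue
                        delta = local(v, masks[v] | 1 << u) - local(v, masks[v])
                        move = ("add", u, v, delta)
                    else:
                        delta = local(v, masks[v] & ~(1 << u)) - local(v, masks[v])
                        move = ("delete", u, v, delta)
                        # reversal considered separately below
                        rev_ok = (
                            bin(masks[u]).count("1") < bound
                            and not _has_path(
                                [c & ~(1 << v) if k == u else c
                                 for k, c in enumerate(children)],
                                u, v,
                            )
                        )
                        if rev_ok:
                            rdelta = (
                                local(v, masks[v] & ~(1 << u)) - local(v, masks[v])
                                + local(u, masks[u] | 1 << v) - local(u, masks[u])
                            )
                            rmove = ("reverse", u, v, rdelta)
                            best_move = _consider(best_move, rmove, tabu, current,
                                                  best_overall)
                    best_move = _consider(best_move, move, tabu, current, best_overall)
            if best_move is None or best_move[3] <= 1e-9:
                break
            kind, u, v, delta = best_move
            if kind == "add":
                masks[v] |= 1 << u
                tabu.append(("delete", u, v))
            elif kind == "delete":
                masks[v] &= ~(1 << u)
                tabu.append(("add", u, v))
            else:
                masks[v] &= ~(1 << u)
                masks[u] |= 1 << v
                tabu.append(("reverse", v, u))
            current += delta
            if best_overall is None or current > best_overall[0]:
                stalled = 0
            else:
                stalled += 1
                if stalled >= max_no_improve:
                    break
        if best_overall is None or current > best_overall[0]:
            best_overall = (current, list(masks))
    score, masks = best_overall
    edges = {(names[j], names[i]) for i in range(n) for j in _bits(masks[i])}
    return LearnResult(
        DirectedGraph(names, frozenset(edges)), score, "greedy", seed, spec
    )


def _consider(best_move, move, tabu, current, best_overall):
    kind, u, v, delta = move
    if (kind, u, v) in tabu:
        aspire = best_overall is not None and current + delta > best_overall[0]
        if not aspire and not (best_overall is None):
            return best_move
    if best_move is None or delta > best_move[3] + 1e-12:
        return move
    return best_move
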
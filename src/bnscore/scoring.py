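"""Decomposable scores for discrete Bayesian network structures.

All four families are penalized log-likelihoods of the form
``LL(D | G) - Penalty(X_i)`` summed over variables, where the local term for
X_i depends only on the sufficient statistics of X_i under its parent set:

* MDL/BIC:  penalty (ln N / 2) * p_i with p_i = (r_i - 1) q_i free parameters;
* AIC:      penalty p_i;
* BDeu(α):  log marginal likelihood under symmetric Dirichlet priors with
            equivalent sample size α (α_ij = α/q_i, per-cell α/(r_i q_i));
* fNML:     per-parent-configuration normalized maximum likelihood, whose
            penalty is the log multinomial regret  sum_j log C(N_ij, r_i).

Scores are in nats and larger is better.  The multinomial regret C(N, k) is
the stochastic-complexity normalizer — the sum over every k-ary dataset of
size N of its maximized likelihood — computed exactly via the closed-form
binomial sum for k = 2 and the linear-in-k recurrence
C(N, k+2) = C(N, k+1) + (N / k) C(N, k), all in log space.

Count tables store only parent configurations that actually occur in the
data: configurations with N_ij = 0 contribute nothing to any of the four
scores, and the number of occupied configurations is bounded by N while the
nominal q_i grows exponentially with the parent-set size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Optional

import numpy as np
from scipy.special import gammaln, logsumexp

from .networks import CategoricalDataset, DirectedGraph, mixed_radix_index

FAMILIES = ("MDL", "AIC", "BDeu", "fNML")


@dataclass(frozen=True)
class ScoreSpec:
    """A scoring-function choice: family plus, for BDeu, the equivalent sample size."""

    family: str
    alpha: Optional[float] = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown score family {self.family!r}")
        if self.family == "BDeu":
            if self.alpha is None or self.alpha <= 0:
                raise ValueError("BDeu requires alpha > 0")
        elif self.alpha is not None:
            raise ValueError(f"{self.family} takes no alpha")

    @property
    def label(self) -> str:
        if self.family == "BDeu":
            return f"BDeu({self.alpha:g})"
        return self.family


@dataclass(frozen=True)
class CountTable:
    """Sufficient statistics for one variable under one parent set.

    Occupied parent configurations only: ``config_ids[m]`` is the mixed-radix
    index of the m-th occupied configuration, ``n_ijk[m, k]`` the count of
    rows with X_i = k there, ``n_ij[m]`` the row totals.  ``q`` is the full
    number of parent configurations (product of parent arities), ``r`` the
    arity of X_i and ``N`` the dataset size; configurations absent from
    ``config_ids`` have all-zero counts.
    """

    var: int
    parents: tuple[int, ...]
    q: int
    r: int
    config_ids: np.ndarray
    n_ij: np.ndarray
    n_ijk: np.ndarray
    N: int

    def __post_init__(self) -> None:
        if not np.array_equal(self.n_ijk.sum(axis=1), self.n_ij):
            raise ValueError("n_ijk rows must sum to n_ij")
        if int(self.n_ij.sum()) != self.N:
            raise ValueError("n_ij must sum to N")

    def dense_n_ijk(self) -> np.ndarray:
        """Full (q, r) count matrix; only sensible for small q."""
        out = np.zeros((self.q, self.r), dtype=np.int64)
        out[self.config_ids] = self.n_ijk
        return out


def build_counts(
    data: CategoricalDataset, i: int, parents: Iterable[int]
) -> CountTable:
    """Tally N_ij / N_ijk for variable *i* under *parents* in one pass."""
    parents = tuple(parents)
    if i in parents:
        raise ValueError("a variable cannot be its own parent")
    arities = [data.specs[p].arity for p in parents]
    r = data.specs[i].arity
    q = int(np.prod(arities, dtype=np.int64)) if parents else 1
    conf = mixed_radix_index(data.rows[:, list(parents)], arities)
    uniq, inv = np.unique(conf, return_inverse=True)
    m = len(uniq)
    flat = np.bincount(inv * r + data.rows[:, i], minlength=m * r)
    n_ijk = flat.reshape(m, r)
    return CountTable(
        i, parents, q, r, uniq, n_ijk.sum(axis=1), n_ijk, data.n_rows
    )


def log_likelihood_local(counts: CountTable) -> float:
    """sum_j sum_k N_ijk ln(N_ijk / N_ij) with 0 ln 0 = 0; always <= 0."""
    n_ijk = counts.n_ijk
    if n_ijk.size == 0:
        return 0.0
    mask = n_ijk > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = n_ijk * (np.log(n_ijk) - np.log(counts.n_ij)[:, None])
    return float(terms[mask].sum())


def num_params(counts: CountTable) -> int:
    """Free parameters p_i = (r_i - 1) q_i."""
    return (counts.r - 1) * counts.q


def penalty_mdl(p_i: int, N: int) -> float:
    """MDL/BIC penalty (ln N / 2) p_i in nats."""
    if N < 1:
        raise ValueError("N must be >= 1")
    return 0.5 * math.log(N) * p_i


def penalty_aic(p_i: int) -> float:
    """AIC penalty: one unit per free parameter."""
    return float(p_i)


def bdeu_local(counts: CountTable, alpha: float) -> float:
    """BDeu log marginal likelihood of the X_i slice under its parent set.

    sum_j [lnG(a_j) - lnG(a_j + N_ij)] + sum_jk [lnG(a_jk + N_ijk) - lnG(a_jk)]
    with a_j = alpha/q_i and a_jk = alpha/(r_i q_i); empty configurations cancel.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    a_j = alpha / counts.q
    a_jk = alpha / (counts.q * counts.r)
    term_j = gammaln(a_j) - gammaln(a_j + counts.n_ij)
    term_jk = gammaln(a_jk + counts.n_ijk) - gammaln(a_jk)
    return float(term_j.sum() + term_jk.sum())


@lru_cache(maxsize=None)
def _log_regret_row(N: int, kmax: int) -> tuple[float, ...]:
    """log C(N, k) for k = 1..kmax at fixed N (log space throughout)."""
    if N == 0:
        return tuple(0.0 for _ in range(kmax))
    out = [0.0]  # k = 1: a single outcome, C = 1
    if kmax >= 2:
        h = np.arange(N + 1, dtype=float)
        # log [ binom(N, h) (h/N)^h ((N-h)/N)^(N-h) ], with 0 log 0 = 0
        logbin = gammaln(N + 1) - gammaln(h + 1) - gammaln(N - h + 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t1 = np.where(h > 0, h * (np.log(h) - math.log(N)), 0.0)
            t2 = np.where(N - h > 0, (N - h) * (np.log(N - h) - math.log(N)), 0.0)
        out.append(float(logsumexp(logbin + t1 + t2)))
    for k in range(1, kmax - 1):
        # C(N, k+2) = C(N, k+1) + (N/k) C(N, k)
        out.append(float(np.logaddexp(out[k], math.log(N / k) + out[k - 1])))
    return tuple(out[:kmax])


def log_multinomial_regret(N: int, k: int) -> float:
    """log C(N, k): log parametric complexity of the k-ary multinomial at size N."""
    if N < 0 or k < 1:
        raise ValueError("require N >= 0 and k >= 1")
    return _log_regret_row(N, k)[k - 1]


def fnml_local(counts: CountTable) -> float:
    """Factorized NML local score: LL minus sum_j log C(N_ij, r_i)."""
    penalty = sum(
        log_multinomial_regret(int(nij), counts.r) for nij in counts.n_ij if nij > 0
    )
    return log_likelihood_local(counts) - penalty


def local_score(spec: ScoreSpec, counts: CountTable) -> float:
    """Dispatch the local (per-variable) score for one parent set."""
    if spec.family == "MDL":
        return log_likelihood_local(counts) - penalty_mdl(num_params(counts), counts.N)
    if spec.family == "AIC":
        return log_likelihood_local(counts) - penalty_aic(num_params(counts))
    if spec.family == "BDeu":
        return bdeu_local(counts, float(spec.alpha))
    return fnml_local(counts)


def network_score(
    spec: ScoreSpec, graph: DirectedGraph, data: CategoricalDataset
) -> float:
    """Total score: exact sum of local scores of every (variable, parent set)."""
    if graph.nodes != data.names:
        raise ValueError("graph nodes must match dataset variables")
    if not graph.is_acyclic():
        raise ValueError("graph must be acyclic")
    pm = graph.parent_map()
    names = data.names
    total = 0.0
    for i, v in enumerate(data.specs):
        parents = tuple(names.index(p) for p in pm[v.name])
        total += local_score(spec, build_counts(data, i, parents))
    return total


def bdeu_alpha_grid() -> tuple[float, ...]:
    """BDeu equivalent-sample-size grid used throughout the study."""
    return (0.1, 0.5, 1.0, 5.0, 10.0, 20.0, 50.0, 80.0, 100.0)


def default_score_specs() -> tuple[ScoreSpec, ...]:
    """MDL, AIC, fNML plus BDeu over the nine-point alpha grid (12 specs)."""
    specs = [ScoreSpec("MDL"), ScoreSpec("AIC"), ScoreSpec("fNML")]
    specs += [ScoreSpec("BDeu", a) for a in bdeu_alpha_grid()]
    return tuple(specs)
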
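"""Raw-table preprocessing: kNN imputation and supervised MDLP discretization.

Real categorical-modelling pipelines start from mixed tables with missing
values.  The stages here mirror that preparation: missing cells are filled
by a k-nearest-neighbour vote/average over the complete records, then each
continuous column is discretized against a designated class column by
recursive entropy-minimizing binary splitting with the Fayyad-Irani MDL
stopping rule.  Entropies in this module are in bits (base 2), matching the
coding interpretation of the stopping criterion.

A split of segment S into S1, S2 at boundary T is accepted when

    Gain(A, T; S) > [log2(|S| - 1) + Delta(A, T; S)] / |S|,
    Delta = log2(3^k - 2) - [k Ent(S) - k1 Ent(S1) - k2 Ent(S2)],

where Gain is the class-entropy reduction and k, k1, k2 count the distinct
class labels in S, S1, S2.  Columns that end up with no accepted cut carry a
single state and are dropped from downstream modelling.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .networks import CategoricalDataset, VariableSpec

log = logging.getLogger(__name__)

MISSING = "?"


@dataclass(frozen=True)
class RawTable:
    """A mixed continuous/categorical table with possible missing cells.

    ``df`` holds object/float cells with NaN for missing; ``kinds`` maps each
    column to "continuous" or "categorical"; ``class_column`` names the
    categorical target the discretization is supervised against.
    """

    df: pd.DataFrame
    kinds: dict
    class_column: str

    def __post_init__(self) -> None:
        for c in self.df.columns:
            if self.kinds.get(c) not in ("continuous", "categorical"):
                raise ValueError(f"column {c!r} needs a kind")
        if self.kinds.get(self.class_column) != "categorical":
            raise ValueError("class column must exist and be categorical")
        if self.df[self.class_column].isna().any():
            raise ValueError("class column may not contain missing values")

    @staticmethod
    def from_csv(path, kinds: dict, class_column: str) -> "RawTable":
        df = pd.read_csv(path, na_values=[MISSING], keep_default_na=False)
        for c, kind in kinds.items():
            if kind == "continuous":
                df[c] = pd.to_numeric(df[c])
        return RawTable(df, dict(kinds), class_column)


@dataclass(frozen=True)
class CutPointList:
    """Strictly increasing boundary values for one discretized column."""

    variable: str
    cuts: tuple[float, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.cuts, self.cuts[1:])):
            raise ValueError("cut points must be strictly increasing")

    def bin_index(self, values) -> np.ndarray:
        return np.searchsorted(np.asarray(self.cuts), np.asarray(values, float),
                               side="right")


def entropy(labels) -> float:
    """Class entropy in bits: -sum_c p_c log2 p_c, 0 log 0 = 0."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("entropy of an empty set is undefined")
    _, counts = np.unique(labels, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def best_cut(values, labels) -> Optional[tuple[float, float]]:
    """Boundary T minimizing the size-weighted split entropy
    E = (|S1|/|S|) Ent(S1) + (|S2|/|S|) Ent(S2).

    Candidates are midpoints between consecutive distinct sorted values;
    ties break toward the smaller T.  None when all values are identical.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if values.size < 2:
        return None
    order = np.argsort(values, kind="stable")
    v, y = values[order], labels[order]
    _, codes = np.unique(y, return_inverse=True)
    ncls = codes.max() + 1
    n = len(v)
    # prefix class counts at each split position i (left part = first i rows)
    onehot = np.zeros((n, ncls))
    onehot[np.arange(n), codes] = 1.0
    prefix = onehot.cumsum(axis=0)
    splits = np.nonzero(v[1:] > v[:-1])[0] + 1  # left sizes at distinct-value gaps
    if splits.size == 0:
        return None

    def _ent(counts: np.ndarray, tot: np.ndarray) -> np.ndarray:
        p = counts / tot[:, None]
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(p > 0, p * np.log2(p), 0.0)
        return -t.sum(axis=1)

    left = prefix[splits - 1]
    right = prefix[-1] - left
    sizes = splits.astype(float)
    e = (sizes / n) * _ent(left, sizes) + ((n - sizes) / n) * _ent(right, n - sizes)
    best = int(np.argmin(e))  # argmin takes the first minimum: smallest T
    i = splits[best]
    return (float((v[i - 1] + v[i]) / 2.0), float(e[best]))


def mdlp_accept(s_labels, s1_labels, s2_labels) -> bool:
    """Fayyad-Irani MDL stopping rule: accept iff Gain strictly exceeds
    [log2(|S|-1) + Delta]/|S|."""
    s_labels = np.asarray(s_labels)
    s1_labels = np.asarray(s1_labels)
    s2_labels = np.asarray(s2_labels)
    ns, n1, n2 = len(s_labels), len(s1_labels), len(s2_labels)
    if ns < 2 or sorted(np.concatenate([s1_labels, s2_labels]).tolist()) != sorted(
        s_labels.tolist()
    ):
        raise ValueError("S1, S2 must partition S with |S| >= 2")
    ent_s = entropy(s_labels)
    ent_1 = entropy(s1_labels)
    ent_2 = entropy(s2_labels)
    gain = ent_s - (n1 / ns) * ent_1 - (n2 / ns) * ent_2
    k = len(np.unique(s_labels))
    k1 = len(np.unique(s1_labels))
    k2 = len(np.unique(s2_labels))
    delta = math.log2(3.0**k - 2.0) - (k * ent_s - k1 * ent_1 - k2 * ent_2)
    return gain > (math.log2(ns - 1) + delta) / ns


def discretize_mdlp(values, labels, name: str = "x") -> CutPointList:
    """Recursive binary splitting until no cut passes the MDL criterion."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    cuts: list[float] = []

    def recurse(mask: np.ndarray) -> None:
        if mask.sum() < 2:
            return
        found = best_cut(values[mask], labels[mask])
        if found is None:
            return
        t, _ = found
        left = mask & (values <= t)
        right = mask & (values > t)
        if not mdlp_accept(labels[mask], labels[left], labels[right]):
            return
        cuts.append(t)
        recurse(left)
        recurse(right)

    recurse(np.ones(len(values), dtype=bool))
    return CutPointList(name, tuple(sorted(cuts)))


def knn_impute(table: RawTable, k: int = 5) -> RawTable:
    """Fill missing cells from the k nearest complete records.

    Distance is Euclidean over min-max scaled continuous columns plus a 0/1
    mismatch per categorical column, always excluding the column being
    imputed and any column missing in the query record.  Continuous targets
    get the neighbour mean, categorical targets the majority vote (ties to
    the smallest value in sorted order).
    """
    df = table.df.copy()
    cols = list(df.columns)
    is_missing = df.isna().to_numpy()
    complete = ~is_missing.any(axis=1)
    if not is_missing.any():
        return table
    if complete.sum() < k:
        raise ValueError(f"need at least k={k} complete records, have {int(complete.sum())}")

    # numeric working matrix: continuous columns min-max scaled, categorical coded
    work = np.zeros(df.shape)
    is_cont = np.array([table.kinds[c] == "continuous" for c in cols])
    for j, c in enumerate(cols):
        if is_cont[j]:
            col = df[c].to_numpy(dtype=float)
            lo, hi = np.nanmin(col), np.nanmax(col)
            span = hi - lo if hi > lo else 1.0
            work[:, j] = (col - lo) / span
        else:
            vals = df[c].astype(object)
            _, codes = np.unique(vals.fillna("\0missing"), return_inverse=True)
            work[:, j] = codes
    ref = work[complete]
    ref_rows = np.nonzero(complete)[0]

    for i in np.nonzero(is_missing.any(axis=1))[0]:
        targets = np.nonzero(is_missing[i])[0]
        use = ~is_missing[i]
        use[targets] = False
        d_cont = ((ref[:, use & is_cont] - work[i, use & is_cont]) ** 2).sum(axis=1)
        d_cat = (ref[:, use & ~is_cont] != work[i, use & ~is_cont]).sum(axis=1)
        dist = np.sqrt(d_cont + d_cat)
        nearest = ref_rows[np.argsort(dist, kind="stable")[:k]]
        for j in targets:
            c = cols[j]
            neigh = df[c].iloc[nearest]
            if is_cont[j]:
                df.iloc[i, j] = float(neigh.astype(float).mean())
            else:
                counts = neigh.value_counts()
                top = counts[counts == counts.max()]
                df.iloc[i, j] = sorted(top.index)[0]
    return RawTable(df, table.kinds, table.class_column)


def preprocess_table(
    table: RawTable, k: int = 5
) -> tuple[CategoricalDataset, dict[str, CutPointList]]:
    """Impute, then discretize every continuous column against the class.

    Continuous columns with no accepted cut are single-state and dropped
    (with a logged warning); categorical columns keep their observed labels
    as states in sorted order.
    """
    filled = knn_impute(table, k=k)
    df = filled.df
    class_labels = df[table.class_column].to_numpy()
    specs: list[VariableSpec] = []
    columns: list[np.ndarray] = []
    cutlists: dict[str, CutPointList] = {}
    for c in df.columns:
        if table.kinds[c] == "continuous":
            values = df[c].to_numpy(dtype=float)
            cl = discretize_mdlp(values, class_labels, name=c)
            cutlists[c] = cl
            if not cl.cuts:
                log.warning("column %r has no accepted cut; dropped", c)
                continue
            codes = cl.bin_index(values)
            states = tuple(f"bin{b}" for b in range(len(cl.cuts) + 1))
            specs.append(VariableSpec(c, states))
            columns.append(codes)
        else:
            uniq, codes = np.unique(df[c].astype(str).to_numpy(), return_inverse=True)
            if len(uniq) < 2:
                log.warning("categorical column %r has a single state; dropped", c)
                continue
            specs.append(VariableSpec(c, tuple(uniq)))
            columns.append(codes)
    return CategoricalDataset(tuple(specs), np.column_stack(columns)), cutlists
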
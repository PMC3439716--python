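"""Experiment orchestration: gold networks x sample grid x scores x learners.

For every (gold network, sample size, replicate) cell, a dataset is drawn by
logic sampling, a structure is learned under every requested scoring
function and learner, and the learned structure is compared with the gold
standard via accuracy, sensitivity, AHD, and CPDAG-based SHD with its
add/delete/reverse/missing decomposition.  Every cell's sampling and search
seeds are derived deterministically from the base seed, so a rerun with the
same configuration reproduces the records bit for bit.

Summary tables report Min / Mean / Max / population STD of SHD across the
sample grid per (gold, learner, score), with replicates averaged within each
size first.  A metric series is called converged at the smallest grid size
from which its value never changes again.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .metrics import accuracy, ahd, edge_confusion, sensitivity, shd
from .networks import BayesianNetwork
from .scoring import ScoreSpec, default_score_specs
from .search import (
    CapabilityError,
    EXACT_LIMIT,
    enumerate_local_score_tables,
    exact_learn,
    hill_climb,
)
from .simulate import (
    GoldNetworkProfile,
    benchmark_suite,
    logic_sample,
    benchmark_sample_grid,
    random_gold_network,
)

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class GreedyParams:
    restarts: int = 10
    tabu_length: int = 100
    max_no_improve: int = 50


@dataclass(frozen=True)
class ExperimentConfig:
    """Fully explicit description of one experiment run."""

    profiles: tuple[GoldNetworkProfile, ...] = ()
    use_benchmark_suite: bool = False
    suite_concentration: float = 1.0
    suite_cpt_mode: str = "dirichlet"
    sizes: tuple[int, ...] = field(
        default_factory=lambda: benchmark_sample_grid().sizes
    )
    replicates: int = 1
    base_seed: int = 0
    score_specs: tuple[ScoreSpec, ...] = field(default_factory=default_score_specs)
    learners: tuple[str, ...] = ("exact",)
    greedy: GreedyParams = GreedyParams()
    max_parents: Optional[int] = None
    exact_limit: int = EXACT_LIMIT
    nested_samples: bool = False

    def __post_init__(self) -> None:
        for l in self.learners:
            if l not in ("exact", "greedy"):
                raise ValueError(f"unknown learner {l!r}")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    # -- YAML round trip ---------------------------------------------------

    def to_yaml(self) -> str:
        obj = {
            "profiles": [
                {
                    "n": p.n,
                    "avg_in_degree": p.avg_in_degree,
                    "arity_range": list(p.arity_range),
                    "concentration": p.concentration,
                    "cpt_mode": p.cpt_mode,
                    "seed": p.seed,
                }
                for p in self.profiles
            ],
            "use_benchmark_suite": self.use_benchmark_suite,
            "suite_concentration": self.suite_concentration,
            "suite_cpt_mode": self.suite_cpt_mode,
            "sizes": list(self.sizes),
            "replicates": self.replicates,
            "base_seed": self.base_seed,
            "score_specs": [
                {"family": s.family, "alpha": s.alpha} for s in self.score_specs
            ],
            "learners": list(self.learners),
            "greedy": {
                "restarts": self.greedy.restarts,
                "tabu_length": self.greedy.tabu_length,
                "max_no_improve": self.greedy.max_no_improve,
            },
            "max_parents": self.max_parents,
            "exact_limit": self.exact_limit,
            "nested_samples": self.nested_samples,
        }
        return yaml.safe_dump(obj, sort_keys=False)

    @staticmethod
    def from_yaml(text: str) -> "ExperimentConfig":
        obj = yaml.safe_load(text)
        return ExperimentConfig(
            profiles=tuple(
                GoldNetworkProfile(
                    n=p["n"],
                    avg_in_degree=p["avg_in_degree"],
                    arity_range=tuple(p["arity_range"]),
                    concentration=p["concentration"],
                    cpt_mode=p.get("cpt_mode", "dirichlet"),
                    seed=p["seed"],
                )
                for p in obj.get("profiles", [])
            ),
            use_benchmark_suite=obj.get("use_benchmark_suite", False),
            suite_concentration=obj.get("suite_concentration", 1.0),
            suite_cpt_mode=obj.get("suite_cpt_mode", "dirichlet"),
            sizes=tuple(obj["sizes"]),
            replicates=obj["replicates"],
            base_seed=obj["base_seed"],
            score_specs=tuple(
                ScoreSpec(s["family"], s.get("alpha")) for s in obj["score_specs"]
            ),
            learners=tuple(obj["learners"]),
            greedy=GreedyParams(**obj.get("greedy", {})),
            max_parents=obj.get("max_parents"),
            exact_limit=obj.get("exact_limit", EXACT_LIMIT),
            nested_samples=obj.get("nested_samples", False),
        )


def derive_seed(base: int, *key: int) -> int:
    """Deterministic child seed below 2**31 from a base seed and an index path."""
    ss = np.random.SeedSequence([int(base), *[int(k) for k in key]])
    return int(ss.generate_state(1)[0] % (2**31))


def gold_networks(config: ExperimentConfig) -> list[tuple[str, BayesianNetwork]]:
    if config.use_benchmark_suite:
        return benchmark_suite(
            seed=config.base_seed,
            concentration=config.suite_concentration,
            cpt_mode=config.suite_cpt_mode,
        )
    golds = []
    for p in config.profiles:
        seeded = replace(p, seed=derive_seed(config.base_seed, 0, p.seed))
        golds.append((f"profile-n{p.n}-seed{p.seed}", random_gold_network(seeded)))
    return golds


def run_experiment(config: ExperimentConfig) -> pd.DataFrame:
    """One tidy record per (gold, size, replicate, score, learner)."""
    golds = gold_networks(config)
    records = []
    for gi, (gname, bn) in enumerate(golds):
        n = len(bn.names)
        for si, size in enumerate(config.sizes):
            for rep in range(config.replicates):
                sample_key = (1, gi, 0 if config.nested_samples else si, rep)
                seed = derive_seed(config.base_seed, *sample_key)
                draw = max(config.sizes) if config.nested_samples else size
                data = logic_sample(bn, draw, seed=seed)
                if config.nested_samples and draw != size:
                    data = type(data)(data.specs, data.rows[:size])
                t0 = time.perf_counter()
                tables = None
                if "exact" in config.learners and n <= config.exact_limit:
                    tables = enumerate_local_score_tables(
                        data, config.score_specs, config.max_parents,
                        config.exact_limit,
                    )
                for spec in config.score_specs:
                    for learner in config.learners:
                        row = {
                            "gold": gname,
                            "n_vars": n,
                            "gold_edges": len(bn.graph.edges),
                            "size": size,
                            "replicate": rep,
                            "seed": seed,
                            "score": spec.label,
                            "family": spec.family,
                            "alpha": spec.alpha,
                            "learner": learner,
                        }
                        try:
                            if learner == "exact":
                                res = exact_learn(
                                    data, spec, config.max_parents,
                                    config.exact_limit,
                                    table=None if tables is None else tables[spec],
                                )
                            else:
                                res = hill_climb(
                                    data, spec,
                                    restarts=config.greedy.restarts,
                                    tabu_length=config.greedy.tabu_length,
                                    max_no_improve=config.greedy.max_no_improve,
                                    seed=derive_seed(config.base_seed, 2, gi, si, rep),
                                    max_parents=config.max_parents,
                                )
                        except CapabilityError as exc:
                            row.update(error=str(exc))
                            records.append(row)
                            continue
                        cm = edge_confusion(bn.graph, res.graph)
                        sd = shd(bn.graph, res.graph)
                        row.update(
                            learned_edges=len(res.graph.edges),
                            total_score=res.score,
                            accuracy=accuracy(cm),
                            sensitivity=sensitivity(cm),
                            ahd=ahd(cm, n),
                            shd=sd.total,
                            shd_add=sd.add,
                            shd_delete=sd.delete,
                            shd_reverse=sd.reverse,
                            shd_missing=sd.missing,
                            error="",
                        )
                        records.append(row)
                log.info(
                    "gold=%s size=%d rep=%d done in %.2fs",
                    gname, size, rep, time.perf_counter() - t0,
                )
    return pd.DataFrame.from_records(records)


def summarize(records: pd.DataFrame, metric: str = "shd") -> pd.DataFrame:
    """Min/Mean/Max/population-STD of *metric* across the sample grid.

    Replicates are averaged within each size first, so the grid sizes are
    the units of the summary.
    """
    if records.empty:
        raise ValueError("no records to summarize")
    ok = records[records["error"] == ""] if "error" in records else records
    per_size = (
        ok.groupby(["gold", "learner", "score", "size"], sort=True)[metric]
        .mean()
        .reset_index()
    )
    out = (
        per_size.groupby(["gold", "learner", "score"], sort=True)[metric]
        .agg(
            min="min",
            mean="mean",
            max="max",
            std=lambda s: float(np.std(s.to_numpy())),  # population STD
        )
        .reset_index()
    )
    return out


def detect_convergence(series: Sequence[float]) -> tuple[bool, Optional[int]]:
    """Smallest grid index from which the series never changes again.

    Returns (False, None) when the last two values differ (or the series is
    a single point, which cannot witness convergence).
    """
    vals = list(series)
    if len(vals) < 2 or vals[-1] != vals[-2]:
        return (False, None)
    i = len(vals) - 1
    while i > 0 and vals[i - 1] == vals[i]:
        i -= 1
    return (True, i)


def convergence_table(records: pd.DataFrame, metric: str = "shd") -> pd.DataFrame:
    """Per (gold, learner, score): whether *metric* converged over the grid
    and the size at which it did."""
    ok = records[records["error"] == ""] if "error" in records else records
    rows = []
    for (gold, learner, score), grp in ok.groupby(["gold", "learner", "score"]):
        per_size = grp.groupby("size")[metric].mean().sort_index()
        conv, idx = detect_convergence(per_size.to_list())
        rows.append(
            {
                "gold": gold,
                "learner": learner,
                "score": score,
                "metric": metric,
                "converged": conv,
                "size_at_convergence": None if idx is None else int(per_size.index[idx]),
            }
        )
    return pd.DataFrame(rows)
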
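"""Aggregation of individual priorities (AIP).

Each included respondent contributes one priority vector; the cohort
aggregate is the componentwise arithmetic mean, geometric mean, or median of
those vectors.  Geometric-mean and median aggregates generally do not sum to
1, so aggregates are renormalized (globally over leaves, per node for local
weights); ranking is unaffected by the rescaling.

Ranks are competition-style ("1224"): leaves sorted by descending global
weight, ties sharing the smallest rank of their group.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .core import PriorityResult

__all__ = ["METHODS", "AggregateReport", "aggregate", "rank_table",
           "outlier_sensitivity"]

METHODS = ("arithmetic", "geometric", "median")


def _combine(stack: np.ndarray, method: str) -> np.ndarray:
    """Componentwise aggregate of row vectors, renormalized to sum 1."""
    if method == "arithmetic":
        agg = stack.mean(axis=0)
    elif method == "geometric":
        if np.any(stack <= 0):
            raise ValueError("geometric mean undefined for nonpositive weights")
        agg = np.exp(np.log(stack).mean(axis=0))
    elif method == "median":
        agg = np.median(stack, axis=0)
    else:
        raise ValueError(f"unknown aggregation method {method!r}; "
                         f"choose from {METHODS}")
    total = agg.sum()
    if total <= 0:
        raise ValueError("aggregate weights are not positive")
    return agg / total


@dataclass
class AggregateReport:
    """Cohort-level weights and ranks for one aggregation method."""

    method: str
    local_weights: dict[str, pd.Series]  # parent id -> child weights (sum 1)
    global_weights: pd.Series            # leaf id -> weight (sum 1)
    ranks: pd.Series                     # leaf id -> competition rank, 1 = top
    n_respondents: int

    @property
    def has_ties(self) -> bool:
        return self.ranks.duplicated().any()


def _rank_descending(weights: pd.Series) -> pd.Series:
    ranks = rankdata(-weights.to_numpy(), method="min").astype(int)
    return pd.Series(ranks, index=weights.index, name="rank")


def aggregate(results: Sequence[PriorityResult], method: str) -> AggregateReport:
    """Aggregate the global and local priority vectors of *results*.

    All results must share one hierarchy (same leaf and node sets).
    """
    if not results:
        raise ValueError("cannot aggregate an empty result list")
    leaf_order = list(results[0].global_weights)
    node_ids = list(results[0].node_priorities)
    for res in results[1:]:
        if list(res.global_weights) != leaf_order or \
                list(res.node_priorities) != node_ids:
            raise ValueError("results span different hierarchies")

    stack = np.array([res.global_vector(leaf_order) for res in results])
    if np.any(stack <= 0):
        raise ValueError("all priority weights must be positive")
    global_weights = pd.Series(_combine(stack, method), index=leaf_order,
                               name="weight")

    local: dict[str, pd.Series] = {}
    for node_id in node_ids:
        child_ids = results[0].node_priorities[node_id].child_ids
        node_stack = np.array([res.node_priorities[node_id].weights
                               for res in results])
        local[node_id] = pd.Series(_combine(node_stack, method),
                                   index=child_ids, name="weight")

    return AggregateReport(
        method=method, local_weights=local, global_weights=global_weights,
        ranks=_rank_descending(global_weights), n_respondents=len(results),
    )


def rank_table(reports: Sequence[AggregateReport]) -> tuple[pd.DataFrame, list[str]]:
    """Leaf x method table of global ranks, plus the leaves whose rank
    differs between any pair of methods."""
    if not reports:
        raise ValueError("no reports to tabulate")
    leaf_index = reports[0].ranks.index
    for rep in reports[1:]:
        if not rep.ranks.index.equals(leaf_index):
            raise ValueError("reports cover different leaf sets")
    table = pd.DataFrame({rep.method: rep.ranks for rep in reports})
    differing = [leaf for leaf in table.index if table.loc[leaf].nunique() > 1]
    return table, differing


def outlier_sensitivity(base: Sequence[PriorityResult],
                        outlier: PriorityResult) -> dict[str, float]:
    """Per-method L1 shift of the aggregate when *outlier* joins *base*.

    The arithmetic mean moves with any outlier; the median of a sample with a
    constant majority does not, and the geometric mean damps large ratios.
    """
    if not base:
        raise ValueError("base cohort must be non-empty")
    shifts = {}
    for method in METHODS:
        before = aggregate(base, method).global_weights
        after = aggregate(list(base) + [outlier], method).global_weights
        shifts[method] = float((before - after).abs().sum())
    return shifts
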
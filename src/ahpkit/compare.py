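"""Individual-vs-group comparison analytics.

The study elicited judgements twice — one-on-one interviews and moderated
consensus groups — and asked whether the two protocols produce the same
priorities and the same response behaviour.  This module provides the three
analyses: per-node local-rank agreement, per-category priority distribution
summaries (box-plot statistics), and the cumulative distribution of judgement
magnitudes with a two-sample t-test on response behaviour.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .aggregate import AggregateReport
from .core import JudgementSet, PriorityResult

__all__ = [
    "NodeRankComparison",
    "local_rank_comparison",
    "distribution_summary",
    "AnswerDistribution",
    "answer_distribution",
    "response_behavior_test",
]


@dataclass(frozen=True)
class NodeRankComparison:
    parent_id: str
    order_a: tuple[str, ...]  # children, best first
    order_b: tuple[str, ...]
    identical: bool


def _child_order(report: AggregateReport, parent_id: str) -> tuple[str, ...]:
    w = report.local_weights[parent_id]
    # stable sort: ties broken by child id for a deterministic display order
    return tuple(w.sort_index().sort_values(ascending=False, kind="stable").index)


def local_rank_comparison(a: AggregateReport, b: AggregateReport,
                          ) -> list[NodeRankComparison]:
    """Compare the within-node child orderings of two aggregate reports
    (typically individual vs group), flagging each node as identical or not."""
    if set(a.local_weights) != set(b.local_weights):
        raise ValueError("reports cover different hierarchies")
    out = []
    for parent_id in a.local_weights:
        oa, ob = _child_order(a, parent_id), _child_order(b, parent_id)
        out.append(NodeRankComparison(parent_id, oa, ob, oa == ob))
    return out


def distribution_summary(results: Sequence[PriorityResult]) -> pd.DataFrame:
    """Box-plot statistics of global weights per leaf and source.

    Returns a tidy frame indexed by (leaf, source) with columns
    min/q1/median/q3/max (quartiles by linear interpolation, the type-7
    convention most software defaults to).
    """
    if not results:
        raise ValueError("no results to summarize")
    rows = []
    frame = pd.DataFrame(
        [{"source": r.source, **r.global_weights} for r in results])
    for source, grp in frame.groupby("source"):
        for leaf in grp.columns.drop("source"):
            x = grp[leaf].to_numpy()
            q1, med, q3 = np.percentile(x, [25, 50, 75])
            rows.append({"leaf": leaf, "source": source,
                         "min": x.min(), "q1": q1, "median": med,
                         "q3": q3, "max": x.max()})
    return pd.DataFrame(rows).set_index(["leaf", "source"]).sort_index()


@dataclass
class AnswerDistribution:
    """Cumulative relative frequency of judgement magnitudes.

    Judgements are folded to their magnitude max(v, 1/v), so 3 and 1/3 both
    count as strength 3.  ``cumulative[k-1]`` is the share of judgements with
    magnitude <= k, for k = 1..9; the final entry is 1.  A cohort that uses
    the whole scale uniformly lies on the diagonal reference line.
    """

    source: str
    cumulative: np.ndarray  # length 9

    def reaches_one_at(self) -> int:
        """Smallest scale step at which the cumulative share hits 1."""
        return int(np.argmax(self.cumulative >= 1.0 - 1e-12) + 1)


def pooled_magnitudes(sets: Sequence[JudgementSet]) -> np.ndarray:
    """All judgement magnitudes of a cohort, pooled across slots."""
    return np.concatenate([np.asarray(s.magnitudes()) for s in sets])


def answer_distribution(sets: Sequence[JudgementSet],
                        source: str | None = None) -> AnswerDistribution:
    """Cumulative magnitude distribution of all judgements in *sets*."""
    if not sets:
        raise ValueError("no judgement sets")
    mags = pooled_magnitudes(sets)
    steps = np.arange(1, 10)
    cumulative = np.array([(mags <= k + 1e-12).mean() for k in steps])
    if source is None:
        labels = {s.source for s in sets}
        source = labels.pop() if len(labels) == 1 else "mixed"
    return AnswerDistribution(source=source, cumulative=cumulative)


def response_behavior_test(ind_sets: Sequence[JudgementSet],
                           grp_sets: Sequence[JudgementSet],
                           variant: str = "welch") -> tuple[float, float]:
    """Two-sample t-test on pooled judgement magnitudes.

    The unit of analysis is the individual judgement magnitude (answers are
    pooled across respondents and slots); Welch's unequal-variance test is
    the default, Student's pooled-variance test is available as
    ``variant="student"``.  Returns ``(t, two-sided p)``.

    The degenerate case of two zero-variance samples with equal means returns
    ``(0.0, 1.0)`` with a warning.
    """
    a = pooled_magnitudes(ind_sets)
    b = pooled_magnitudes(grp_sets)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least 2 judgements")
    if variant not in ("welch", "student"):
        raise ValueError(f"unknown t-test variant {variant!r}")
    if a.std() == 0 and b.std() == 0:
        if a.mean() == b.mean():
            warnings.warn("both samples are constant and equal; returning "
                          "t=0, p=1 by convention")
            return 0.0, 1.0
        warnings.warn("both samples are constant with different means; "
                      "t is infinite, p = 0")
        return float(np.inf) * np.sign(a.mean() - b.mean()), 0.0
    res = stats.ttest_ind(a, b, equal_var=(variant == "student"))
    return float(res.statistic), float(res.pvalue)
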
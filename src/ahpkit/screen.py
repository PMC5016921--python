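"""Consistency screening of respondents.

A respondent is included in the downstream analysis only if the comparison
matrices at the required hierarchy levels meet a consistency-ratio threshold
(the study's inclusion rule was CR <= 0.2 at level 2).  The sample-size curve
tabulates how many respondents survive as the threshold and the level
requirement vary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .core import PriorityResult

__all__ = ["ScreenPolicy", "Exclusion", "ScreenOutcome", "screen",
           "sample_size_curve"]


@dataclass(frozen=True)
class ScreenPolicy:
    """Inclusion rule: every matrix at each level in ``levels_required`` must
    have CR <= ``threshold``.  Ties at the threshold are included (CR <= t)."""

    threshold: float = 0.2
    levels_required: frozenset[int] = frozenset({2})

    def __post_init__(self):
        if not (0 < self.threshold <= 1):
            raise ValueError("threshold must be in (0, 1]")
        if not self.levels_required:
            raise ValueError("levels_required must be non-empty")
        object.__setattr__(self, "levels_required",
                           frozenset(self.levels_required))

    @property
    def label(self) -> str:
        lv = "+".join(str(x) for x in sorted(self.levels_required))
        return f"CR<={self.threshold:g}@L{lv}"


@dataclass(frozen=True)
class Exclusion:
    respondent_id: str
    parent_id: str  # worst offending matrix
    cr: float


@dataclass
class ScreenOutcome:
    included: list[str] = field(default_factory=list)
    excluded: list[Exclusion] = field(default_factory=list)

    @property
    def excluded_ids(self) -> list[str]:
        return [e.respondent_id for e in self.excluded]


def screen(results: Sequence[PriorityResult], policy: ScreenPolicy) -> ScreenOutcome:
    """Partition respondents into included and excluded under *policy*.

    Each exclusion names the worst offending matrix (largest CR among the
    matrices at the required levels).
    """
    if not results:
        raise ValueError("cannot screen an empty result list")
    outcome = ScreenOutcome()
    for res in results:
        offenders = [
            np_ for np_ in res.node_priorities.values()
            if np_.level in policy.levels_required and np_.cr > policy.threshold
        ]
        if offenders:
            worst = max(offenders, key=lambda np_: np_.cr)
            outcome.excluded.append(
                Exclusion(res.respondent_id, worst.parent_id, worst.cr))
        else:
            outcome.included.append(res.respondent_id)
    return outcome


def sample_size_curve(results: Sequence[PriorityResult],
                      thresholds: Sequence[float],
                      level_policies: Sequence[frozenset[int] | set[int]],
                      ) -> pd.DataFrame:
    """Included-respondent counts for every threshold x level-policy cell.

    Rows are thresholds (ascending), columns the level policies.  Counts are
    non-decreasing in the threshold and non-increasing as levels are added.
    """
    thresholds = list(thresholds)
    if sorted(thresholds) != thresholds:
        raise ValueError("thresholds must be sorted ascending")
    table = {}
    for levels in level_policies:
        label = "level " + "+".join(str(x) for x in sorted(levels))
        col = []
        for t in thresholds:
            outcome = screen(results, ScreenPolicy(t, frozenset(levels)))
            col.append(len(outcome.included))
        table[label] = col
    return pd.DataFrame(table, index=pd.Index(thresholds, name="cr_threshold"))
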
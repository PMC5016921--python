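"""Synthetic respondents with the statistical structure of an AHP interview
study.

Each respondent carries latent true priorities; an answered comparison is the
latent ratio w_left / w_right perturbed by multiplicative log-normal noise
and snapped to the nearest 9-point-scale value in log space.  Judgements are
ratio-scale, so multiplicative noise and log-space snapping keep 2 and 1/2
symmetric.  Larger noise produces less consistent matrices, giving cohorts a
realistic spread of consistency ratios.

Consensus groups answer jointly: each member perturbs the latent ratio
independently, the consensus is the geometric mean of the members' ratios,
clamped to a maximum answer magnitude (default 5) before snapping.  The clamp
is an explicit model knob reproducing the empirical observation that group
consensus avoids the extreme end of the scale; it is not a claim about group
dynamics.

Every respondent draws from an RNG stream derived from (seed, stream index),
so cohorts are extensible without reshuffling existing respondents.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Sequence

import numpy as np

from .core import SAATY_SCALE, JudgementSet
from .hierarchy import Hierarchy, enumerate_slots, study_hierarchy

__all__ = ["SimulationConfig", "default_latent_weights", "snap_to_scale",
           "consensus_judgement", "simulate_individual", "simulate_group",
           "simulate_cohort"]

_LOG_SCALE = np.log([float(v) for v in SAATY_SCALE])

#: Stream-index offset separating group-member draws from individual draws.
_GROUP_STREAM_OFFSET = 1_000_000


def snap_to_scale(ratio: float) -> Fraction:
    """Nearest 9-point-scale value to *ratio* in log space."""
    if ratio <= 0:
        raise ValueError("ratios must be positive")
    idx = int(np.argmin(np.abs(_LOG_SCALE - np.log(ratio))))
    return SAATY_SCALE[idx]


def default_latent_weights(h: Hierarchy) -> dict[str, dict[str, float]]:
    """Plausible latent local weights for the packaged study hierarchy.

    Chosen to mirror the study's qualitative findings: medical questions the
    clearly dominant field, social counselling second, current events last;
    within medical questions diagnostics > therapy > disease pattern.  For
    any other hierarchy, mildly non-uniform weights are generated so that
    ranks are well defined without ties.
    """
    study = {
        "goal": {"medical": 0.45, "research": 0.15,
                 "current_events": 0.10, "social": 0.30},
        "medical": {"diagnostics": 0.45, "therapy": 0.35,
                    "disease_pattern": 0.20},
        "research": {"new_studies": 0.40, "study_results": 0.35,
                     "registers": 0.25},
        "social": {"social_legal": 0.40, "psychosocial": 0.35,
                   "self_help": 0.25},
    }
    internal = {n.id: [c.id for c in n.children] for n in h.internal_nodes()}
    if all(pid in study and set(kids) == set(study[pid])
           for pid, kids in internal.items()):
        return {pid: dict(study[pid]) for pid in internal}
    out = {}
    for pid, kids in internal.items():
        raw = np.array([1.0 / (i + 1) for i in range(len(kids))])
        out[pid] = dict(zip(kids, raw / raw.sum()))
    return out


@dataclass
class SimulationConfig:
    """Study-shaped simulation parameters.

    Defaults emulate the study design: 40 individual interviews, three
    consensus groups of three or four members, log-normal judgement noise
    with sigma = 0.6 on the log-ratio scale (wide enough that a noticeable
    minority of respondents fail the CR <= 0.2 screen, as real cohorts do),
    and a consensus answer-magnitude cap of 5.
    """

    hierarchy: Hierarchy = field(default_factory=study_hierarchy)
    latent_weights: dict[str, dict[str, float]] | None = None
    sigma: float = 0.6
    n_individuals: int = 40
    group_sizes: tuple[int, ...] = (3, 4, 4)
    group_cap: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.latent_weights is None:
            self.latent_weights = default_latent_weights(self.hierarchy)
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if any(size < 2 for size in self.group_sizes):
            raise ValueError("group sizes must be >= 2")
        if not (1 <= self.group_cap <= 9):
            raise ValueError("group cap must be an answer magnitude in 1..9")
        for pid, w in self.latent_weights.items():
            vals = np.array(list(w.values()))
            if np.any(vals <= 0) or abs(vals.sum() - 1) > 1e-9:
                raise ValueError(
                    f"latent weights under {pid!r} must be positive and sum to 1")

    def latent_ratio(self, slot) -> float:
        w = self.latent_weights[slot.parent_id]
        return w[slot.left_id] / w[slot.right_id]

    def latent_global_weights(self) -> dict[str, float]:
        """Ground-truth global leaf weights implied by the latent locals."""
        out: dict[str, float] = {}

        def descend(node, weight):
            if node.is_leaf:
                out[node.id] = weight
                return
            for child in node.children:
                descend(child, weight * self.latent_weights[node.id][child.id])

        descend(self.hierarchy.root, 1.0)
        return out


def _perturbed_ratios(cfg: SimulationConfig, stream: int) -> np.ndarray:
    """One respondent's noisy latent ratios, one per slot (fixed slot order)."""
    slots = enumerate_slots(cfg.hierarchy)
    rng = np.random.default_rng([cfg.seed, stream])
    eps = rng.normal(0.0, cfg.sigma, size=len(slots))
    return np.array([cfg.latent_ratio(s) for s in slots]) * np.exp(eps)


def simulate_individual(cfg: SimulationConfig, index: int) -> JudgementSet:
    """Simulate respondent *index*'s questionnaire.

    Deterministic given (cfg.seed, index).  With sigma = 0 and latent ratios
    on the scale, answers equal the exact latent ratios and every matrix is
    perfectly consistent.
    """
    slots = enumerate_slots(cfg.hierarchy)
    ratios = _perturbed_ratios(cfg, index)
    js = JudgementSet(respondent_id=f"ind{index + 1:03d}", source="individual")
    for slot, r in zip(slots, ratios):
        js.add(slot, snap_to_scale(r))
    return js


def consensus_judgement(member_ratios: Sequence[float], cap: int) -> Fraction:
    """Consensus rule for one slot: geometric mean of the members' ratios,
    clamped to magnitude <= *cap*, snapped to the scale in log space."""
    ratios = np.asarray(member_ratios, dtype=float)
    if np.any(ratios <= 0):
        raise ValueError("ratios must be positive")
    consensus = float(np.exp(np.log(ratios).mean()))
    consensus = min(max(consensus, 1.0 / cap), float(cap))
    return snap_to_scale(consensus)


def simulate_group(cfg: SimulationConfig, group_index: int,
                   size: int) -> JudgementSet:
    """Simulate one consensus group of *size* members.

    Per slot the consensus is the geometric mean of the members' perturbed
    ratios, clamped to magnitude <= ``cfg.group_cap``, then snapped to the
    scale.  Member RNG streams are disjoint from individual streams.
    """
    if size < 2:
        raise ValueError("a consensus group needs at least 2 members")
    slots = enumerate_slots(cfg.hierarchy)
    member_streams = [
        _GROUP_STREAM_OFFSET + group_index * 100 + m for m in range(size)
    ]
    member_ratios = np.array([_perturbed_ratios(cfg, s) for s in member_streams])
    js = JudgementSet(respondent_id=f"grp{group_index + 1:02d}", source="group")
    for k, slot in enumerate(slots):
        js.add(slot, consensus_judgement(member_ratios[:, k], cfg.group_cap))
    return js


def simulate_cohort(cfg: SimulationConfig,
                    ) -> tuple[list[JudgementSet], list[JudgementSet],
                               dict[str, dict[str, float]]]:
    """Simulate the full study: individual sets, group sets, and the latent
    local weights that generated them (for recovery experiments)."""
    individuals = [simulate_individual(cfg, i) for i in range(cfg.n_individuals)]
    groups = [simulate_group(cfg, g, size)
              for g, size in enumerate(cfg.group_sizes)]
    return individuals, groups, {pid: dict(w)
                                 for pid, w in cfg.latent_weights.items()}
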
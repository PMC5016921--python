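"""Shared fixtures: hierarchies, scale-exact latent weights, and helpers to
build judgement sets and priority results without going through files."""

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import settings

from ahpkit import (ComparisonSlot, CriterionNode, Hierarchy, JudgementSet,
                    NodePriorities, PriorityResult, enumerate_slots,
                    snap_to_scale, study_hierarchy)

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def study():
    return study_hierarchy()


@pytest.fixture
def toy_pair():
    """Goal with two childless criteria: the smallest legal hierarchy."""
    return Hierarchy(CriterionNode("g", "goal", [
        CriterionNode("a", "A"), CriterionNode("b", "B")]))


#: Latent local weights whose pairwise ratios all lie on the 9-point scale,
#: so zero-noise simulation involves no snapping error.
SCALE_EXACT_LATENTS = {
    "goal": {"medical": 8 / 15, "research": 4 / 15,
             "current_events": 2 / 15, "social": 1 / 15},
    "medical": {"diagnostics": 4 / 7, "therapy": 2 / 7, "disease_pattern": 1 / 7},
    "research": {"new_studies": 4 / 7, "study_results": 2 / 7, "registers": 1 / 7},
    "social": {"social_legal": 4 / 7, "psychosocial": 2 / 7, "self_help": 1 / 7},
}


def judgements_from_latents(h, latents, respondent_id="resp",
                            source="individual"):
    """A perfectly consistent judgement set: each answer is the latent ratio
    snapped to the scale (exact when the ratio is on the scale)."""
    js = JudgementSet(respondent_id=respondent_id, source=source)
    for slot in enumerate_slots(h):
        w = latents[slot.parent_id]
        js.add(slot, snap_to_scale(w[slot.left_id] / w[slot.right_id]))
    return js


def all_ones_judgements(h, respondent_id="flat", source="individual"):
    js = JudgementSet(respondent_id=respondent_id, source=source)
    for slot in enumerate_slots(h):
        js.add(slot, Fraction(1))
    return js


def make_result(respondent_id, weights, source="individual"):
    """A minimal PriorityResult over one flat node, for aggregation tests.

    *weights* maps leaf id -> global weight (must sum to 1).
    """
    leaf_ids = list(weights)
    w = np.array([weights[k] for k in leaf_ids], dtype=float)
    np_ = NodePriorities(parent_id="goal", child_ids=leaf_ids, weights=w,
                         lambda_max=float(len(w)), ci=0.0, cr=0.0, level=2)
    return PriorityResult(respondent_id=respondent_id, source=source,
                          node_priorities={"goal": np_},
                          global_weights=dict(weights),
                          worst_cr_by_level={2: 0.0})
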
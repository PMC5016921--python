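"""Criterion hierarchies for the Analytic Hierarchy Process.

A hierarchy is a tree of criteria: the goal at level 1, coarse *information
fields* at level 2 and finer *information types* at level 3 (deeper trees are
supported structurally).  Every internal node with k >= 2 children induces
k*(k-1)/2 pairwise-comparison slots; a questionnaire is one answer per slot.

The rare-disease information-needs hierarchy used throughout the package
(four fields, nine types, 13 criteria, 15 comparison slots) ships as a
packaged YAML fixture and is returned by :func:`study_hierarchy`.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Iterator

import yaml

__all__ = [
    "CriterionNode",
    "Hierarchy",
    "ComparisonSlot",
    "study_hierarchy",
    "enumerate_slots",
    "validate",
    "load_hierarchy",
    "dump_hierarchy",
]


@dataclass
class CriterionNode:
    """One criterion: a short stable ``id``, a display ``label`` and an
    ordered list of child criteria (empty for leaves)."""

    id: str
    label: str
    children: list["CriterionNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class Hierarchy:
    """A criterion tree rooted at the goal (level 1)."""

    root: CriterionNode

    def preorder(self) -> Iterator[tuple[CriterionNode, int]]:
        """Yield ``(node, level)`` pairs in pre-order; the root is level 1."""
        stack = [(self.root, 1)]
        while stack:
            node, level = stack.pop()
            yield node, level
            for child in reversed(node.children):
                stack.append((child, level + 1))

    @property
    def depth(self) -> int:
        return max(level for _, level in self.preorder())

    def nodes(self) -> list[CriterionNode]:
        return [n for n, _ in self.preorder()]

    def node(self, node_id: str) -> CriterionNode:
        for n, _ in self.preorder():
            if n.id == node_id:
                return n
        raise KeyError(f"no node with id {node_id!r}")

    def level_of(self, node_id: str) -> int:
        for n, level in self.preorder():
            if n.id == node_id:
                return level
        raise KeyError(f"no node with id {node_id!r}")

    def internal_nodes(self) -> list[CriterionNode]:
        """Nodes with children, in pre-order."""
        return [n for n, _ in self.preorder() if n.children]

    def leaves(self) -> list[CriterionNode]:
        """Leaf criteria in pre-order; a childless level-2 node is a leaf."""
        return [n for n, _ in self.preorder() if n.is_leaf]

    def leaf_ids(self) -> list[str]:
        return [n.id for n in self.leaves()]

    def n_criteria(self) -> int:
        """Number of criteria, excluding the goal itself."""
        return len(self.nodes()) - 1


@dataclass(frozen=True)
class ComparisonSlot:
    """One pairwise comparison a questionnaire asks for: ``left`` vs
    ``right`` with respect to their shared ``parent``."""

    parent_id: str
    left_id: str
    right_id: str


def enumerate_slots(h: Hierarchy) -> list[ComparisonSlot]:
    """Enumerate every pairwise-comparison slot of *h* in a fixed order.

    Parents are visited in pre-order; within a parent, child pairs follow the
    lexicographic order of child *positions* ((0,1), (0,2), ..., (1,2), ...).
    The order is a package convention so that questionnaire files are stable
    across runs; it carries no meaning.

    Raises
    ------
    ValueError
        If the hierarchy is malformed (see :func:`validate`).
    """
    violations = validate(h)
    if violations:
        raise ValueError("invalid hierarchy: " + "; ".join(violations))
    slots: list[ComparisonSlot] = []
    for node in h.internal_nodes():
        kids = node.children
        for i in range(len(kids)):
            for j in range(i + 1, len(kids)):
                slots.append(ComparisonSlot(node.id, kids[i].id, kids[j].id))
    return slots


def validate(h: Hierarchy) -> list[str]:
    """Check hierarchy invariants; return a list of human-readable violations
    (empty iff the hierarchy is valid).  Never raises."""
    violations: list[str] = []
    seen: set[str] = set()
    for node, _ in h.preorder():
        if node.id in seen:
            violations.append(f"duplicate node id {node.id!r}")
        seen.add(node.id)
        if not node.label:
            violations.append(f"node {node.id!r} has an empty label")
        if len(node.children) == 1:
            violations.append(
                f"node {node.id!r} has exactly one child; a single child "
                "cannot be pairwise-compared"
            )
    return violations


# --- serialization ----------------------------------------------------------

def _node_to_mapping(node: CriterionNode) -> dict:
    out: dict = {"id": node.id, "label": node.label}
    if node.children:
        out["children"] = [_node_to_mapping(c) for c in node.children]
    return out


def _node_from_mapping(mapping: dict) -> CriterionNode:
    try:
        node_id, label = mapping["id"], mapping["label"]
    except (KeyError, TypeError) as exc:
        raise ValueError(f"hierarchy node must map 'id' and 'label': {mapping!r}") from exc
    children = [_node_from_mapping(c) for c in mapping.get("children", [])]
    return CriterionNode(id=str(node_id), label=str(label), children=children)


def load_hierarchy(path_or_stream) -> Hierarchy:
    """Read a hierarchy from a YAML file: a nested mapping with keys ``id``,
    ``label`` and optional ``children`` (list of the same shape)."""
    if hasattr(path_or_stream, "read"):
        data = yaml.safe_load(path_or_stream)
    else:
        with open(path_or_stream, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
    h = Hierarchy(root=_node_from_mapping(data))
    violations = validate(h)
    if violations:
        raise ValueError("invalid hierarchy file: " + "; ".join(violations))
    return h


def dump_hierarchy(h: Hierarchy, path) -> None:
    """Write *h* to a YAML file in the dialect :func:`load_hierarchy` reads."""
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(_node_to_mapping(h.root), fh, sort_keys=False,
                       allow_unicode=True)


def study_hierarchy() -> Hierarchy:
    """The packaged rare-disease information-needs hierarchy.

    Goal -> four information fields (medical questions, research, current
    events, social counselling and assistance services); medical questions,
    research and social counselling each split into three information types,
    while *current events* is a childless field and therefore itself a leaf
    criterion.  13 criteria, 10 leaves, 15 comparison slots.
    """
    ref = importlib.resources.files("ahpkit.data") / "rare_disease_hierarchy.yaml"
    with ref.open("r", encoding="utf-8") as fh:
        return load_hierarchy(fh)
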
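"""Core Analytic Hierarchy Process computations.

Judgements on Saaty's 9-point ratio scale are assembled into positive
reciprocal comparison matrices, priorities are the normalized principal right
eigenvector (power iteration), and consistency is measured by

    CI = (lambda_max - n) / (n - 1),      CR = CI / RI(n)

where RI(n) is the random index: the mean CI of random reciprocal matrices of
order n.  A perfectly cardinally consistent matrix (a_ij = w_i / w_j) has
lambda_max = n and hence CR = 0.

Judgement values below 1 are stored as exact ``fractions.Fraction``
reciprocals (1/2 ... 1/9) so that reciprocity a_ij * a_ji = 1 holds
bit-exactly; floats enter only at eigencomputation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Mapping, Sequence

import numpy as np

from .hierarchy import ComparisonSlot, Hierarchy, enumerate_slots

__all__ = [
    "SAATY_SCALE",
    "parse_scale_value",
    "format_scale_value",
    "Judgement",
    "JudgementSet",
    "ComparisonMatrix",
    "NodePriorities",
    "PriorityResult",
    "IncompleteJudgementError",
    "ScaleError",
    "matrix_from_judgements",
    "principal_eigenvector",
    "consistency_index",
    "random_index",
    "consistency_ratio",
    "prioritize",
    "SAATY_RI_TABLE",
]

#: The 17 admissible judgement values: 1/9 ... 1/2, 1, 2 ... 9.
SAATY_SCALE: tuple[Fraction, ...] = tuple(
    [Fraction(1, k) for k in range(9, 1, -1)] + [Fraction(k) for k in range(1, 10)]
)

_SAATY_SET = frozenset(SAATY_SCALE)

#: Random-index constants for orders 2..10 (Saaty's classic simulation values).
#: Variant tables exist in the literature; pass ``table=`` to override.
SAATY_RI_TABLE: dict[int, float] = {
    2: 0.00, 3: 0.58, 4: 0.90, 5: 1.12, 6: 1.24,
    7: 1.32, 8: 1.41, 9: 1.45, 10: 1.49,
}


class ScaleError(ValueError):
    """A judgement value is not on the 9-point scale."""


class IncompleteJudgementError(ValueError):
    """A judgement set does not cover every comparison slot."""


def parse_scale_value(text: str) -> Fraction:
    """Parse ``"3"`` or ``"1/3"`` to an exact scale value.

    Raises :class:`ScaleError` for anything off the 17-value scale.
    """
    try:
        value = Fraction(str(text).strip())
    except (ValueError, ZeroDivisionError) as exc:
        raise ScaleError(f"unparseable judgement value {text!r}") from exc
    if value not in _SAATY_SET:
        raise ScaleError(
            f"value {text!r} is not on the 9-point scale (1/9..9)"
        )
    return value


def format_scale_value(value: Fraction) -> str:
    """Render a scale value as ``"3"`` or ``"1/3"``."""
    return str(value)


@dataclass(frozen=True)
class Judgement:
    """One answered comparison: *left* is ``value`` times as important as
    *right*.  Recording (left, right, v) is equivalent to (right, left, 1/v)."""

    slot: ComparisonSlot
    value: Fraction

    def __post_init__(self):
        if self.value not in _SAATY_SET:
            raise ScaleError(
                f"judgement value {self.value} for slot {self.slot} is not "
                "on the 9-point scale"
            )


@dataclass
class JudgementSet:
    """All of one respondent's (or one consensus group's) answers."""

    respondent_id: str
    source: str  # "individual" | "group"
    judgements: dict[ComparisonSlot, Fraction] = field(default_factory=dict)

    def __post_init__(self):
        if self.source not in ("individual", "group"):
            raise ValueError(f"source must be 'individual' or 'group', got {self.source!r}")

    def add(self, slot: ComparisonSlot, value: Fraction) -> None:
        if slot in self.judgements:
            raise ValueError(f"duplicate judgement for slot {slot}")
        if value not in _SAATY_SET:
            raise ScaleError(f"value {value} is not on the 9-point scale")
        self.judgements[slot] = value

    def value(self, parent_id: str, left_id: str, right_id: str) -> Fraction:
        """Judged ratio left:right, applying the reciprocal convention when
        the slot was recorded in the opposite orientation."""
        direct = self.judgements.get(ComparisonSlot(parent_id, left_id, right_id))
        if direct is not None:
            return direct
        flipped = self.judgements.get(ComparisonSlot(parent_id, right_id, left_id))
        if flipped is not None:
            return 1 / flipped
        raise IncompleteJudgementError(
            f"respondent {self.respondent_id!r} has no judgement for "
            f"{left_id!r} vs {right_id!r} under {parent_id!r}"
        )

    def magnitudes(self) -> list[float]:
        """Judgement magnitudes folded to >= 1: max(v, 1/v) per answer."""
        return [float(max(v, 1 / v)) for v in self.judgements.values()]


@dataclass
class ComparisonMatrix:
    """Positive reciprocal matrix over the children of one node.

    Entries are exact rationals; reciprocity ``a_ij * a_ji == 1`` and a unit
    diagonal are enforced at construction.
    """

    parent_id: str
    child_ids: list[str]
    entries: list[list[Fraction]]

    def __post_init__(self):
        n = len(self.child_ids)
        if n < 2:
            raise ValueError("a comparison matrix needs at least 2 criteria")
        if len(self.entries) != n or any(len(row) != n for row in self.entries):
            raise ValueError("entry grid does not match the number of children")
        for i in range(n):
            if self.entries[i][i] != 1:
                raise ValueError("diagonal entries must equal 1")
            for j in range(n):
                if self.entries[i][j] <= 0:
                    raise ValueError("entries must be positive")
                if self.entries[i][j] * self.entries[j][i] != 1:
                    raise ValueError(
                        f"reciprocity violated at ({i},{j}): "
                        f"{self.entries[i][j]} * {self.entries[j][i]} != 1"
                    )

    @property
    def n(self) -> int:
        return len(self.child_ids)

    @classmethod
    def from_upper_triangle(
        cls, parent_id: str, child_ids: Sequence[str],
        upper: Mapping[tuple[int, int], Fraction],
    ) -> "ComparisonMatrix":
        """Build from upper-triangle ratios; the lower triangle is filled with
        exact reciprocals."""
        n = len(child_ids)
        grid = [[Fraction(1)] * n for _ in range(n)]
        for i in range(n):
            for j in range(i + 1, n):
                v = Fraction(upper[(i, j)])
                grid[i][j] = v
                grid[j][i] = 1 / v
        return cls(parent_id, list(child_ids), grid)

    @classmethod
    def from_weights(cls, parent_id: str, child_ids: Sequence[str],
                     weights: Sequence[Fraction]) -> "ComparisonMatrix":
        """Perfectly consistent matrix with a_ij = w_i / w_j."""
        w = [Fraction(x) for x in weights]
        upper = {(i, j): w[i] / w[j]
                 for i in range(len(w)) for j in range(i + 1, len(w))}
        return cls.from_upper_triangle(parent_id, child_ids, upper)

    def to_array(self) -> np.ndarray:
        return np.array([[float(v) for v in row] for row in self.entries])


@dataclass
class NodePriorities:
    """Local priorities of one node's children plus consistency diagnostics.

    ``level`` is the hierarchy level of the children being compared (the
    matrix over the information fields is the level-2 matrix).
    """

    parent_id: str
    child_ids: list[str]
    weights: np.ndarray
    lambda_max: float
    ci: float
    cr: float
    level: int

    def weight_of(self, child_id: str) -> float:
        return float(self.weights[self.child_ids.index(child_id)])


@dataclass
class PriorityResult:
    """One respondent's full prioritization of a hierarchy."""

    respondent_id: str
    source: str
    node_priorities: dict[str, NodePriorities]
    global_weights: dict[str, float]  # leaf id -> weight, sums to 1
    worst_cr_by_level: dict[int, float]

    def global_vector(self, leaf_order: Sequence[str]) -> np.ndarray:
        return np.array([self.global_weights[leaf] for leaf in leaf_order])


# --- operations -------------------------------------------------------------

def matrix_from_judgements(js: JudgementSet, parent_id: str,
                           h: Hierarchy) -> ComparisonMatrix:
    """Assemble the reciprocal comparison matrix for one node from a
    respondent's judgements.

    Raises :class:`IncompleteJudgementError` if any slot under *parent_id* is
    unanswered, :class:`ScaleError` for off-scale values.
    """
    node = h.node(parent_id)
    if len(node.children) < 2:
        raise ValueError(f"node {parent_id!r} has no comparisons")
    child_ids = [c.id for c in node.children]
    upper = {}
    for i in range(len(child_ids)):
        for j in range(i + 1, len(child_ids)):
            upper[(i, j)] = js.value(parent_id, child_ids[i], child_ids[j])
    return ComparisonMatrix.from_upper_triangle(parent_id, child_ids, upper)


def principal_eigenvector(M: ComparisonMatrix | np.ndarray,
                          tol: float = 1e-12,
                          max_iter: int = 10_000) -> tuple[np.ndarray, float]:
    """Normalized principal right eigenvector and principal eigenvalue.

    Power iteration from the uniform vector; for a positive matrix the
    Perron-Frobenius eigenvector is unique and the iteration converges.
    Convergence is declared when the relative change of every component falls
    below *tol*.

    Returns ``(w, lambda_max)`` with ``w > 0`` and ``sum(w) == 1``.
    """
    A = M.to_array() if isinstance(M, ComparisonMatrix) else np.asarray(M, dtype=float)
    n = A.shape[0]
    if A.shape != (n, n) or n < 2:
        raise ValueError("expected a square matrix of order >= 2")
    w = np.full(n, 1.0 / n)
    lam = float(n)
    for _ in range(max_iter):
        Aw = A @ w
        lam = float(Aw.sum())  # since sum(w) == 1, sum(Aw) is the Rayleigh ratio
        w_new = Aw / lam
        if np.max(np.abs(w_new - w) / w_new) < tol:
            # one more multiply for the eigenvalue at the converged vector
            lam = float((A @ w_new).sum())
            return w_new, lam
        w = w_new
    raise ArithmeticError(
        f"power iteration did not converge in {max_iter} iterations"
    )


def consistency_index(lambda_max: float, n: int) -> float:
    """CI = (lambda_max - n) / (n - 1), floored at 0.

    Tiny negative excesses of numerical origin are clamped; a genuinely
    deficient lambda_max (< n - 1e-9) is rejected since lambda_max >= n for
    every positive reciprocal matrix.
    """
    if n < 2:
        raise ValueError("consistency index requires n >= 2")
    if lambda_max < n - 1e-9:
        raise ValueError(f"lambda_max {lambda_max} < n = {n} is impossible "
                         "for a positive reciprocal matrix")
    return max(0.0, (lambda_max - n) / (n - 1))


def random_index(n: int, mode: str = "table", *,
                 table: Mapping[int, float] | None = None,
                 n_matrices: int = 10_000,
                 seed: int | None = None) -> float:
    """Random index RI(n): the expected CI of a random reciprocal matrix.

    mode="table" looks *n* up in the configured constants (default: the
    classic Saaty values for n = 2..10).  mode="simulate" estimates RI as the
    mean CI over ``n_matrices`` random reciprocal matrices whose
    upper-triangle entries are drawn uniformly from the 17-value scale.
    """
    if n < 2:
        raise ValueError("random index requires n >= 2")
    if mode == "table":
        tbl = SAATY_RI_TABLE if table is None else dict(table)
        if n not in tbl:
            raise KeyError(
                f"no RI table entry for n = {n}; use mode='simulate' or "
                "supply a table"
            )
        return tbl[n]
    if mode == "simulate":
        rng = np.random.default_rng(seed)
        scale = np.array([float(v) for v in SAATY_SCALE])
        iu = np.triu_indices(n, k=1)
        total = 0.0
        for _ in range(n_matrices):
            A = np.ones((n, n))
            draws = rng.choice(scale, size=len(iu[0]))
            A[iu] = draws
            A[(iu[1], iu[0])] = 1.0 / draws
            _, lam = principal_eigenvector(A, tol=1e-10)
            total += consistency_index(lam, n)
        return total / n_matrices
    raise ValueError(f"unknown mode {mode!r}")


def consistency_ratio(M: ComparisonMatrix | np.ndarray, *,
                      ri_table: Mapping[int, float] | None = None) -> float:
    """CR = CI / RI(n), using table-mode RI.

    For n = 2 a reciprocal matrix is always consistent and RI = 0; CR is
    defined as 0 rather than dividing by zero.
    """
    w, lam = principal_eigenvector(M)
    n = len(w)
    if n == 2:
        return 0.0
    ci = consistency_index(lam, n)
    return ci / random_index(n, "table", table=ri_table)


def prioritize(js: JudgementSet, h: Hierarchy, *,
               ri_table: Mapping[int, float] | None = None) -> PriorityResult:
    """Full prioritization of one judgement set.

    Computes local eigenvector weights plus lambda_max/CI/CR for every
    internal node, then propagates global leaf weights as the product of
    local weights along each root-to-leaf path.  A childless non-root node is
    a leaf; its global weight is its local weight under its parent.
    """
    missing = [s for s in enumerate_slots(h) if s not in js.judgements
               and ComparisonSlot(s.parent_id, s.right_id, s.left_id)
               not in js.judgements]
    if missing:
        raise IncompleteJudgementError(
            f"respondent {js.respondent_id!r} is missing judgements for "
            f"{len(missing)} slot(s), first: {missing[0]}"
        )

    node_priorities: dict[str, NodePriorities] = {}
    for node in h.internal_nodes():
        M = matrix_from_judgements(js, node.id, h)
        w, lam = principal_eigenvector(M)
        n = M.n
        ci = consistency_index(lam, n)
        cr = 0.0 if n == 2 else ci / random_index(n, "table", table=ri_table)
        node_priorities[node.id] = NodePriorities(
            parent_id=node.id, child_ids=list(M.child_ids), weights=w,
            lambda_max=lam, ci=ci, cr=cr, level=h.level_of(node.id) + 1,
        )

    global_weights: dict[str, float] = {}

    def descend(node, weight: float) -> None:
        if node.is_leaf:
            global_weights[node.id] = weight
            return
        np_ = node_priorities[node.id]
        for child in node.children:
            descend(child, weight * np_.weight_of(child.id))

    descend(h.root, 1.0)

    worst: dict[int, float] = {}
    for np_ in node_priorities.values():
        worst[np_.level] = max(worst.get(np_.level, 0.0), np_.cr)

    return PriorityResult(
        respondent_id=js.respondent_id, source=js.source,
        node_priorities=node_priorities, global_weights=global_weights,
        worst_cr_by_level=worst,
    )
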
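"""Multi-department aggregation of interval prospect matrices.

Each participating department contributes a scheme × criterion matrix of
interval prospect values.  A consensus matrix (entry-wise endpoint mean)
anchors a similarity distance per department; departments closer to the
consensus receive larger weights, and the weighted endpoint combination
yields the comprehensive group matrix from which the scheme with the
largest weighted-midpoint utility is selected.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .prospect import CriterionSpec, Interval, ProspectMatrix, validate_criteria


@dataclass(frozen=True)
class DepartmentMatrix:
    department_id: str
    matrix: ProspectMatrix
    multiplier: float = 1.0  # hook for collaboration adjustments; scales the weight

    def __post_init__(self) -> None:
        if self.multiplier <= 0:
            raise ValueError("department multiplier must be positive")


@dataclass(frozen=True)
class GroupResult:
    consensus: ProspectMatrix
    distances: dict[str, float]
    weights: dict[str, float]
    group_matrix: ProspectMatrix
    utilities: dict[str, float]
    selected: str


def _check_congruent(matrices: Sequence[DepartmentMatrix]) -> None:
    if not matrices:
        raise ValueError("at least one department matrix is required")
    first = matrices[0].matrix
    for dm in matrices[1:]:
        if (
            dm.matrix.schemes != first.schemes
            or dm.matrix.criteria_ids != first.criteria_ids
        ):
            raise ValueError("department matrices must share scheme/criterion axes")


def consensus_matrix(matrices: Sequence[DepartmentMatrix]) -> ProspectMatrix:
    """Entry-wise arithmetic mean of interval endpoints across departments."""
    _check_congruent(matrices)
    first = matrices[0].matrix
    k = len(matrices)
    rows = []
    for i in range(len(first.schemes)):
        row = []
        for j in range(len(first.criteria_ids)):
            lo = sum(dm.matrix.entries[i][j].lo for dm in matrices) / k
            hi = sum(dm.matrix.entries[i][j].hi for dm in matrices) / k
            row.append(Interval(lo, hi))
        rows.append(tuple(row))
    return ProspectMatrix(first.schemes, first.criteria_ids, tuple(rows))


def interval_distance(a: Interval, b: Interval) -> float:
    """d([a,b],[c,e]) = (|a−c| + |b−e|)/2."""
    return (abs(a.lo - b.lo) + abs(a.hi - b.hi)) / 2.0


def consensus_distance(dept: DepartmentMatrix, consensus: ProspectMatrix) -> float:
    """Entry-summed interval distance between a department and the
    consensus."""
    m = dept.matrix
    if m.schemes != consensus.schemes or m.criteria_ids != consensus.criteria_ids:
        raise ValueError("matrix shapes do not match the consensus")
    return sum(
        interval_distance(m.entries[i][j], consensus.entries[i][j])
        for i in range(len(m.schemes))
        for j in range(len(m.criteria_ids))
    )


def department_weights(
    distances: Sequence[float], multipliers: Sequence[float] | None = None
) -> tuple[float, ...]:
    """Inverse-distance weights w_k ∝ m_k/(1+d_k), normalised to sum 1."""
    if any(d < 0 for d in distances):
        raise ValueError("distances must be non-negative")
    mult = multipliers if multipliers is not None else [1.0] * len(distances)
    raw = [m / (1.0 + d) for d, m in zip(distances, mult)]
    total = sum(raw)
    return tuple(r / total for r in raw)


def group_aggregate(
    matrices: Sequence[DepartmentMatrix],
    criteria: Sequence[CriterionSpec],
    weights: Sequence[float] | None = None,
) -> GroupResult:
    """Consensus → distances → weights → comprehensive group matrix →
    scheme selection by weighted midpoint utility.

    Explicit ``weights`` (summing to 1) override the inverse-distance
    weighting.
    """
    _check_congruent(matrices)
    validate_criteria(criteria)
    first = matrices[0].matrix
    if tuple(c.id for c in criteria) != first.criteria_ids:
        raise ValueError("criteria do not match the department matrices")
    cons = consensus_matrix(matrices)
    dists = {dm.department_id: consensus_distance(dm, cons) for dm in matrices}
    if weights is not None:
        if len(weights) != len(matrices) or abs(sum(weights) - 1.0) > 1e-9:
            raise ValueError("explicit weights must match departments and sum to 1")
        w = tuple(weights)
    else:
        w = department_weights(
            [dists[dm.department_id] for dm in matrices],
            [dm.multiplier for dm in matrices],
        )
    wmap = {dm.department_id: wk for dm, wk in zip(matrices, w)}
    rows = []
    for i in range(len(first.schemes)):
        row = []
        for j in range(len(first.criteria_ids)):
            lo = sum(wk * dm.matrix.entries[i][j].lo for dm, wk in zip(matrices, w))
            hi = sum(wk * dm.matrix.entries[i][j].hi for dm, wk in zip(matrices, w))
            row.append(Interval(lo, hi))
        rows.append(tuple(row))
    group = ProspectMatrix(first.schemes, first.criteria_ids, tuple(rows))
    cw = {c.id: c.weight for c in criteria}
    utilities = {
        s: sum(
            cw[c] * group.entry(s, c).midpoint for c in first.criteria_ids
        )
        for s in first.schemes
    }
    order = {s: i for i, s in enumerate(first.schemes)}
    selected = min(utilities, key=lambda s: (-utilities[s], order[s]))
    return GroupResult(cons, dists, wmap, group, utilities, selected)
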
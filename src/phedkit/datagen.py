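"""Worked-example fixtures and seeded synthetic generators.

The six-object covering decision table and the COVID-19 rescue-scheme
evaluation case are reproduced programmatically so that every pipeline
stage is testable without external data.  The synthetic table generator
plants a known set of "informative" coverings (whose within-class blocks
certify every object at full consistency) among class-straddling noise
coverings, providing ground truth for reduct-recovery experiments in
place of the unavailable real emergency dataset (81 events, 15 numeric
condition attributes, 3 response levels).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .covering import Covering, CoveringDecisionTable, DecisionPartition, Universe
from .prospect import CriterionSpec, EvaluationMatrix


def worked_example_table() -> CoveringDecisionTable:
    """The six-object, five-covering table with a two-class decision."""
    objs = ("x1", "x2", "x3", "x4", "x5", "x6")

    def c(cov_id: str, *blocks: tuple[str, ...]) -> Covering:
        return Covering(id=cov_id, blocks=tuple(frozenset(b) for b in blocks))

    coverings = (
        c("C1", ("x1", "x2"), ("x3", "x4"), ("x5", "x6")),
        c(
            "C2",
            ("x1", "x2", "x4"),
            ("x3",),
            ("x1", "x2", "x4", "x5"),
            ("x4", "x5"),
            ("x6",),
        ),
        c("C3", ("x1",), ("x2", "x3", "x4"), ("x5", "x6")),
        c(
            "C4",
            ("x1", "x2", "x4"),
            ("x1", "x2", "x3", "x4"),
            ("x3", "x4", "x5", "x6"),
            ("x3", "x5", "x6"),
        ),
        c(
            "C5",
            ("x1", "x2"),
            ("x1", "x3"),
            ("x1", "x2", "x3"),
            ("x4",),
            ("x5", "x6"),
        ),
    )
    decision = DecisionPartition.from_dict(
        {"D1": ("x1", "x2", "x3"), "D2": ("x4", "x5", "x6")}
    )
    return CoveringDecisionTable(Universe(objs), coverings, decision)


def covid_case_matrix() -> tuple[EvaluationMatrix, tuple[CriterionSpec, ...], dict]:
    """The three-scheme rescue-decision case over four time frames.

    Criteria: c1 health status of the infected case (gain), c2 number of
    rescuers (gain), c3 rescue equipment and labour costs (cost,
    linguistic).  Returns (matrix, criteria, reference vector).
    """
    values = {
        "x1": {
            "c1": (4, 3, 3, 3),
            "c2": ([2, 5], [4, 6], [4, 6], [5, 6]),
            "c3": (["VG", "MG"], ["G", "MG"], ["G", "MG"], ["G", "MG"]),
        },
        "x2": {
            "c1": (4, 6, 5, 7),
            "c2": ([4, 7], [6, 12], [6, 11], [9, 12]),
            "c3": (["G", "MG"], ["MG", "M"], ["MG", "M"], ["M", "MP"]),
        },
        "x3": {
            "c1": (5, 5, 6, 6),
            "c2": ([3, 6], [5, 9], [8, 15], [7, 10]),
            "c3": (["MG", "MP"], ["MG", "M"], ["MG", "M"], ["MG", "M"]),
        },
    }
    matrix = EvaluationMatrix(
        schemes=("x1", "x2", "x3"),
        criteria_ids=("c1", "c2", "c3"),
        frames=("t1", "t2", "t3", "t4"),
        values=values,
    )
    criteria = (
        CriterionSpec("c1", "gain", 0.4),
        CriterionSpec("c2", "gain", 0.45),
        CriterionSpec("c3", "cost", 0.15),
    )
    reference = {"c1": 6, "c2": [5, 11], "c3": ["G", "M"]}
    return matrix, criteria, reference


@dataclass(frozen=True)
class SynthSpec:
    """Recipe for a seeded synthetic covering decision table."""

    n_objects: int = 30
    n_coverings: int = 8
    n_classes: int = 3
    blocks_per_covering: tuple[int, int] = (3, 6)
    consistency: float = 1.0
    planted_reduct_size: int = 3
    cost_range: tuple[float, float] = (0.5, 3.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.consistency <= 1:
            raise ValueError("consistency must lie in [0, 1]")
        if self.planted_reduct_size > self.n_coverings:
            raise ValueError("more planted coverings than coverings requested")
        if not 2 <= self.n_classes <= self.n_objects:
            raise ValueError("need between 2 and n_objects decision classes")


def _straddling_partition(
    pool: list[str],
    decision: DecisionPartition,
    all_objects: tuple[str, ...],
    n_blocks: int,
    rng: np.random.Generator,
) -> list[frozenset[str]]:
    """Split ``pool`` into blocks and force every block to straddle at
    least two decision classes, borrowing one outside object per pure
    block if needed (overlap across blocks is legal in a covering)."""
    if not pool:
        return []
    members = list(pool)
    rng.shuffle(members)
    n_blocks = max(1, min(n_blocks, len(members)))
    blocks = [set(members[i::n_blocks]) for i in range(n_blocks)]
    for b in blocks:
        labels = {decision.class_of(o) for o in b}
        if len(labels) < 2:
            lab = next(iter(labels))
            donors = [o for o in all_objects if decision.class_of(o) != lab]
            b.add(donors[int(rng.integers(0, len(donors)))])
    return [frozenset(b) for b in blocks]


def synth_table(spec: SynthSpec) -> tuple[CoveringDecisionTable, frozenset[str]]:
    """Generate a table with a planted informative covering set.

    The decision partition is drawn first.  Informative coverings
    partition the "consistent" objects within their classes (so every
    such block is effective) and bundle the remaining objects into
    class-straddling blocks.  Noise coverings consist solely of
    class-straddling blocks and can contribute no effective block.
    Returns the table and the planted (informative) covering ids.
    """
    rng = np.random.default_rng(spec.seed)
    objs = tuple(f"x{i + 1}" for i in range(spec.n_objects))

    assignment = list(rng.integers(0, spec.n_classes, size=spec.n_objects))
    for k in range(spec.n_classes):  # guarantee non-empty classes
        if k not in assignment:
            assignment[int(rng.integers(0, spec.n_objects))] = k
    labels = [f"D{k + 1}" for k in range(spec.n_classes)]
    classes = {
        lab: frozenset(o for o, a in zip(objs, assignment) if a == k)
        for k, lab in enumerate(labels)
    }
    classes = {lab: mem for lab, mem in classes.items() if mem}
    decision = DecisionPartition.from_dict(classes)

    n_cons = int(round(spec.consistency * spec.n_objects))
    cons_idx = sorted(rng.choice(spec.n_objects, size=n_cons, replace=False))
    cons_objs = frozenset(objs[i] for i in cons_idx)
    incons = [o for o in objs if o not in cons_objs]

    lo_b, hi_b = spec.blocks_per_covering
    coverings: list[Covering] = []
    planted = [f"C{i + 1}" for i in range(spec.planted_reduct_size)]
    for cid in planted:
        blocks: list[frozenset[str]] = []
        for mem in classes.values():
            inside = sorted(mem & cons_objs, key=objs.index)
            if not inside:
                continue
            rng.shuffle(inside)
            n_split = int(rng.integers(1, max(2, len(inside) // 3 + 1)))
            blocks.extend(
                frozenset(inside[i::n_split]) for i in range(n_split) if inside[i::n_split]
            )
        blocks.extend(
            _straddling_partition(
                incons, decision, objs, int(rng.integers(lo_b, hi_b + 1)), rng
            )
        )
        cost = float(rng.uniform(*spec.cost_range))
        coverings.append(
            Covering(id=cid, blocks=tuple(dict.fromkeys(blocks)), cost=cost)
        )

    for i in range(spec.planted_reduct_size, spec.n_coverings):
        blocks = _straddling_partition(
            list(objs), decision, objs, int(rng.integers(lo_b, hi_b + 1)), rng
        )
        cost = float(rng.uniform(*spec.cost_range))
        coverings.append(
            Covering(
                id=f"C{i + 1}", blocks=tuple(dict.fromkeys(blocks)), cost=cost
            )
        )

    table = CoveringDecisionTable(Universe(objs), tuple(coverings), decision)
    return table, frozenset(planted)


def synth_evaluation(
    n_schemes: int = 3,
    n_criteria: int = 3,
    n_frames: int = 4,
    seed: int = 0,
    scale_terms: tuple[str, ...] = ("VP", "P", "MP", "M", "MG", "G", "VG"),
) -> tuple[EvaluationMatrix, tuple[CriterionSpec, ...], dict]:
    """Seeded grey evaluation matrix mixing scalar, interval and
    linguistic entries, with per-cell state probabilities summing to 1."""
    if min(n_schemes, n_criteria, n_frames) < 1:
        raise ValueError("dimensions must be positive")
    rng = np.random.default_rng(seed)
    schemes = tuple(f"x{i + 1}" for i in range(n_schemes))
    crit_ids = tuple(f"c{j + 1}" for j in range(n_criteria))
    frames = tuple(f"t{k + 1}" for k in range(n_frames))
    kinds = rng.integers(0, 3, size=n_criteria)  # one entry kind per criterion

    def draw(kind: int):
        if kind == 0:
            return float(np.round(rng.uniform(0, 10), 2))
        if kind == 1:
            lo = float(np.round(rng.uniform(0, 8), 2))
            return [lo, float(np.round(lo + rng.uniform(0, 4), 2))]
        return str(rng.choice(scale_terms))

    values = {
        s: {c: tuple(draw(kinds[j]) for _ in frames) for j, c in enumerate(crit_ids)}
        for s in schemes
    }
    probabilities: dict = {}
    for s in schemes:
        probabilities[s] = {}
        for c in crit_ids:
            raw = rng.uniform(0.1, 1.0, size=n_frames)
            p = raw / raw.sum()
            p[-1] = 1.0 - float(p[:-1].sum())  # exact unit sum
            probabilities[s][c] = tuple(float(v) for v in p)
    raw_w = rng.uniform(0.1, 1.0, size=n_criteria)
    w = raw_w / raw_w.sum()
    w[-1] = 1.0 - float(w[:-1].sum())
    criteria = tuple(
        CriterionSpec(c, "cost" if j == n_criteria - 1 else "gain", float(w[j]))
        for j, c in enumerate(crit_ids)
    )
    reference = {c: draw(kinds[j]) for j, c in enumerate(crit_ids)}
    matrix = EvaluationMatrix(schemes, crit_ids, frames, values, probabilities)
    return matrix, criteria, reference
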
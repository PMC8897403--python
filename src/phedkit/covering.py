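"""Covering rough-set primitives and family-method attribute reduction.

A covering decision table ``S = (U, Δ, D)`` consists of a universe of
objects ``U``, a family ``Δ`` of coverings (one per condition attribute;
blocks may overlap, unlike a partition), and a decision partition ``U/D``.
The *family method* computes, for each object, the set of coverings that
certify its decision class through an *effective block* (a block wholly
inside one decision class).  Every minimal set of coverings hitting all
distinct such certificate sets is a reduct: it preserves the table's
classification ability with the fewest attributes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence


class InconsistentTableError(ValueError):
    """Raised when a table has no effective blocks (empty family)."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Universe:
    """Ordered, duplicate-free collection of object identifiers."""

    objects: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.objects:
            raise ValueError("universe must be non-empty")
        if len(set(self.objects)) != len(self.objects):
            raise ValueError("object identifiers must be unique")

    def __contains__(self, obj: str) -> bool:
        return obj in set(self.objects)

    def __len__(self) -> int:
        return len(self.objects)

    def index(self, obj: str) -> int:
        return self.objects.index(obj)

    def sort_key(self, objs: Iterable[str]) -> tuple[int, ...]:
        """Deterministic serialization order for a set of objects."""
        order = {o: i for i, o in enumerate(self.objects)}
        return tuple(sorted(order[o] for o in objs))


@dataclass(frozen=True)
class Covering:
    """A family of blocks over the universe whose union is the universe.

    ``block_meta`` optionally carries, per block, the predicates that
    generated it during granulation (used to match unseen records); it is
    ignored by all set-theoretic operations.
    """

    id: str
    blocks: tuple[frozenset[str], ...]
    cost: float = 1.0
    block_meta: tuple[tuple, ...] | None = None

    def __post_init__(self) -> None:
        if self.cost <= 0:
            raise ValueError(f"covering {self.id!r}: cost must be positive")
        if any(not b for b in self.blocks):
            raise ValueError(f"covering {self.id!r}: blocks must be non-empty")

    def validate_against(self, universe: Universe) -> None:
        union = frozenset().union(*self.blocks) if self.blocks else frozenset()
        missing = set(universe.objects) - union
        if missing:
            raise ValueError(
                f"covering {self.id!r} does not cover objects: {sorted(missing)}"
            )
        extra = union - set(universe.objects)
        if extra:
            raise ValueError(
                f"covering {self.id!r} references unknown objects: {sorted(extra)}"
            )

    def blocks_containing(self, x: str) -> list[frozenset[str]]:
        return [b for b in self.blocks if x in b]


@dataclass(frozen=True)
class DecisionPartition:
    """Decision classes: a partition of the universe keyed by label."""

    classes: tuple[tuple[str, frozenset[str]], ...]

    @classmethod
    def from_dict(cls, mapping: Mapping[str, Iterable[str]]) -> "DecisionPartition":
        return cls(tuple((lab, frozenset(objs)) for lab, objs in mapping.items()))

    def validate_against(self, universe: Universe) -> None:
        seen: set[str] = set()
        for label, objs in self.classes:
            if seen & objs:
                raise ValueError(f"decision classes overlap at class {label!r}")
            seen |= objs
        if seen != set(universe.objects):
            raise ValueError("decision classes must partition the universe")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(lab for lab, _ in self.classes)

    def class_of(self, x: str) -> str | None:
        for label, objs in self.classes:
            if x in objs:
                return label
        return None

    def members(self, label: str) -> frozenset[str]:
        for lab, objs in self.classes:
            if lab == label:
                return objs
        raise KeyError(label)

    def blocks(self) -> tuple[frozenset[str], ...]:
        return tuple(objs for _, objs in self.classes)


@dataclass(frozen=True)
class CoveringDecisionTable:
    """``S = (U, Δ, D)``: universe, ordered coverings, decision partition."""

    universe: Universe
    coverings: tuple[Covering, ...]
    decision: DecisionPartition

    def __post_init__(self) -> None:
        ids = [c.id for c in self.coverings]
        if len(set(ids)) != len(ids):
            raise ValueError("covering ids must be unique")
        for cov in self.coverings:
            cov.validate_against(self.universe)
        self.decision.validate_against(self.universe)

    def covering(self, cid: str) -> Covering:
        for cov in self.coverings:
            if cov.id == cid:
                return cov
        raise KeyError(cid)

    @property
    def costs(self) -> dict[str, float]:
        return {c.id: c.cost for c in self.coverings}


@dataclass(frozen=True)
class EffectiveBlock:
    """A block wholly inside one decision class — a unit of certain
    classification."""

    covering_id: str
    block: frozenset[str]
    decision_label: str


@dataclass(frozen=True)
class RelatedFamily:
    """Per-object certificate sets r(x) and their deduplicated family.

    ``uncovered`` lists objects lying in no effective block; they carry no
    certificate and are excluded from the family rather than silently
    dropped.
    """

    per_object: tuple[tuple[str, frozenset[str]], ...]
    family: frozenset[frozenset[str]]
    uncovered: tuple[str, ...] = ()

    def r(self, x: str) -> frozenset[str]:
        for obj, cids in self.per_object:
            if obj == x:
                return cids
        raise KeyError(x)


@dataclass(frozen=True)
class BooleanReductFormula:
    """Discernibility function: CNF over covering ids and its minimal DNF.

    Each CNF clause is one family member; each minimal DNF term is a
    reduct (minimal hitting set of the clauses).
    """

    cnf: tuple[frozenset[str], ...]
    dnf_minimal: frozenset[frozenset[str]]


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def granulate(
    objects: Sequence[str],
    values: Sequence,
    kind: str,
    cov_id: str,
    delta: float | None = None,
    cost: float = 1.0,
) -> Covering:
    """Granulate one attribute's raw values into a covering.

    Symbolic attributes yield the equal-value partition.  Numeric
    attributes yield, for each object x, the δ-neighbourhood block
    ``{y : |a(y) − a(x)| ≤ δ·range(a)}``; duplicate blocks are merged.
    A zero-range numeric attribute degenerates to the single block U.

    Each block carries generator predicates in ``block_meta`` —
    ``("eq", value)`` for symbolic, ``("interval", lo, hi)`` for numeric —
    so unseen records can later be matched to blocks.
    """
    if len(values) == 0:
        raise ValueError("empty value vector")
    if len(values) != len(objects):
        raise ValueError("one value per universe object required")
    if kind == "symbolic":
        groups: dict = {}
        for obj, v in zip(objects, values):
            groups.setdefault(v, set()).add(obj)
        blocks = tuple(frozenset(g) for g in groups.values())
        meta = tuple((("eq", v),) for v in groups)
        return Covering(id=cov_id, blocks=blocks, cost=cost, block_meta=meta)
    if kind != "numeric":
        raise ValueError(f"unknown attribute kind {kind!r}")
    if delta is None or not (0 < delta <= 1):
        raise ValueError("numeric granulation requires delta in (0, 1]")
    vals = [float(v) for v in values]
    rng = max(vals) - min(vals)
    if rng == 0.0:
        return Covering(
            id=cov_id,
            blocks=(frozenset(objects),),
            cost=cost,
            block_meta=((("interval", float("-inf"), float("inf")),),),
        )
    tol = delta * rng
    block_to_preds: dict[frozenset[str], list] = {}
    order: list[frozenset[str]] = []
    for obj, v in zip(objects, vals):
        block = frozenset(
            y for y, w in zip(objects, vals) if abs(w - v) <= tol
        )
        if block not in block_to_preds:
            block_to_preds[block] = []
            order.append(block)
        block_to_preds[block].append(("interval", v - tol, v + tol))
    return Covering(
        id=cov_id,
        blocks=tuple(order),
        cost=cost,
        block_meta=tuple(tuple(block_to_preds[b]) for b in order),
    )


def approximation_pair(
    blocks: Iterable[frozenset[str]], X: frozenset[str], universe: Universe
) -> tuple[frozenset[str], frozenset[str]]:
    """Lower and upper approximation of X under a partition's blocks.

    lower = union of blocks contained in X; upper = union of blocks
    meeting X.  Always lower ⊆ X ⊆ upper.
    """
    unknown = X - set(universe.objects)
    if unknown:
        raise ValueError(f"unknown object ids: {sorted(unknown)}")
    lower: frozenset[str] = frozenset()
    upper: frozenset[str] = frozenset()
    for b in blocks:
        if b <= X:
            lower |= b
        if b & X:
            upper |= b
    return lower, upper


def neighborhood(cover: Covering, x: str) -> frozenset[str]:
    """N(x): intersection of all blocks of the covering containing x."""
    containing = cover.blocks_containing(x)
    if not containing:
        raise ValueError(f"object {x!r} not covered by {cover.id!r}")
    out = containing[0]
    for b in containing[1:]:
        out &= b
    return out


def descriptions(
    cover: Covering, x: str
) -> tuple[frozenset[frozenset[str]], frozenset[frozenset[str]]]:
    """Minimal and maximal descriptions of x.

    Minimal: containing blocks with no proper containing sub-block.
    Maximal: containing blocks with no proper containing super-block.
    """
    containing = cover.blocks_containing(x)
    if not containing:
        raise ValueError(f"object {x!r} not covered by {cover.id!r}")
    minimal = frozenset(
        k for k in containing if not any(s < k for s in containing)
    )
    maximal = frozenset(
        k for k in containing if not any(k < s for s in containing)
    )
    return minimal, maximal


def positive_region(
    cover: Covering, decision: DecisionPartition, universe: Universe
) -> frozenset[str]:
    """Objects whose neighbourhood under the covering lies inside one
    decision class — the covering's positive domain."""
    return frozenset(
        x
        for x in universe.objects
        if any(neighborhood(cover, x) <= objs for _, objs in decision.classes)
    )


def effective_blocks(table: CoveringDecisionTable) -> tuple[EffectiveBlock, ...]:
    """All (covering, block) pairs whose block sits inside one decision
    class."""
    out: list[EffectiveBlock] = []
    for cov in table.coverings:
        for block in cov.blocks:
            for label, objs in table.decision.classes:
                if block <= objs:
                    out.append(EffectiveBlock(cov.id, block, label))
                    break
    return tuple(out)


def related_family(table: CoveringDecisionTable) -> RelatedFamily:
    """r(x) for every covered object and the deduplicated family R(U,Δ,D)."""
    eff = effective_blocks(table)
    per: list[tuple[str, frozenset[str]]] = []
    uncovered: list[str] = []
    for x in table.universe.objects:
        cids = frozenset(e.covering_id for e in eff if x in e.block)
        if cids:
            per.append((x, cids))
        else:
            uncovered.append(x)
    family = frozenset(cids for _, cids in per)
    return RelatedFamily(tuple(per), family, tuple(uncovered))


def _minimal_sets(sets: Iterable[frozenset[str]]) -> frozenset[frozenset[str]]:
    pool = set(sets)
    return frozenset(s for s in pool if not any(t < s for t in pool))


def all_reducts(table: CoveringDecisionTable) -> BooleanReductFormula:
    """Every reduct, via the discernibility function.

    The CNF has one clause per family member; CNF→DNF expansion with
    absorption yields exactly the minimal hitting sets (minimal
    transversals), i.e. all reducts.
    """
    fam = related_family(table)
    if not fam.family:
        raise InconsistentTableError(
            "table has no effective blocks; the family is empty"
        )
    clause_order = sorted(fam.family, key=lambda s: (len(s), sorted(s)))
    # incremental product with absorption keeps terms minimal throughout
    terms: set[frozenset[str]] = {frozenset()}
    for clause in clause_order:
        expanded = {t | {lit} for t in terms for lit in clause}
        terms = set(_minimal_sets(expanded))
    return BooleanReductFormula(
        cnf=tuple(clause_order), dnf_minimal=frozenset(terms)
    )


def brute_force_reducts(table: CoveringDecisionTable) -> frozenset[frozenset[str]]:
    """Independent oracle: enumerate every covering subset, keep those
    hitting all family members, filter to minimal.  Exponential; for
    small tables and cross-checks only."""
    fam = related_family(table)
    if not fam.family:
        raise InconsistentTableError("empty family")
    ids = [c.id for c in table.coverings]
    hitting = [
        frozenset(sub)
        for r in range(1, len(ids) + 1)
        for sub in itertools.combinations(ids, r)
        if all(set(sub) & member for member in fam.family)
    ]
    return _minimal_sets(hitting)
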
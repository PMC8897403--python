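"""A-DRE: cost-aware attribute reduction and ordered decision rules.

Pipeline: related family → hypergraph (one vertex per covering, one
hyperedge per distinct certificate set) → greedy minimum-cost vertex
cover → minimality pruning.  The resulting reduct drives rule
extraction: one rule per effective block of each retained covering,
ranked by coverage then support, with a majority-class fallback.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .covering import (
    CoveringDecisionTable,
    InconsistentTableError,
    RelatedFamily,
    effective_blocks,
    positive_region,
    related_family,
)


@dataclass(frozen=True)
class Hypergraph:
    """Vertices are covering ids (with costs); edges are the family's
    distinct certificate sets, each to be hit by the cover."""

    vertices: tuple[str, ...]
    costs: dict[str, float]
    edges: tuple[frozenset[str], ...]

    def __post_init__(self) -> None:
        vs = set(self.vertices)
        for e in self.edges:
            if not e:
                raise ValueError("hypergraph edges must be non-empty")
            if not e <= vs:
                raise ValueError(f"edge {sorted(e)} has non-vertex members")


@dataclass(frozen=True)
class Reduct:
    covering_ids: frozenset[str]
    total_cost: float
    minimal: bool
    preserves_positive_region: bool | None = None


@dataclass(frozen=True)
class DecisionRule:
    """``x ∈ block (under covering) ⇒ decision_label``.

    support = |block| / |U|, coverage = |block| / |class|.
    """

    covering_id: str
    block: frozenset[str]
    decision_label: str
    support: float
    coverage: float
    rank: int


@dataclass(frozen=True)
class RuleList:
    rules: tuple[DecisionRule, ...]
    default_label: str

    def __post_init__(self) -> None:
        if [r.rank for r in self.rules] != list(range(1, len(self.rules) + 1)):
            raise ValueError("ranks must be 1..n without gaps")


def build_hypergraph(
    family: RelatedFamily, costs: dict[str, float] | None = None
) -> Hypergraph:
    """Transform the family into a hypergraph; vertex order follows first
    appearance in sorted edges for determinism."""
    if not family.family:
        raise InconsistentTableError("cannot build hypergraph from empty family")
    edges = tuple(sorted(family.family, key=lambda s: (len(s), sorted(s))))
    verts = sorted({v for e in edges for v in e})
    cost_map = {v: (costs or {}).get(v, 1.0) for v in verts}
    return Hypergraph(tuple(verts), cost_map, edges)


def greedy_min_cost_cover(
    h: Hypergraph, vertex_order: tuple[str, ...] | None = None
) -> Reduct:
    """Greedy cover: repeatedly take the vertex maximising
    (uncovered edges hit) / cost, ties to the earlier vertex in input
    order, until every edge is hit."""
    order = vertex_order if vertex_order is not None else h.vertices
    rank = {v: i for i, v in enumerate(order)}
    uncovered = set(h.edges)
    chosen: list[str] = []
    while uncovered:
        best = max(
            (v for v in order if v not in chosen),
            key=lambda v: (
                sum(1 for e in uncovered if v in e) / h.costs[v],
                -rank[v],
            ),
        )
        if not any(best in e for e in uncovered):
            raise InconsistentTableError("edge cannot be covered by any vertex")
        chosen.append(best)
        uncovered = {e for e in uncovered if best not in e}
    ids = frozenset(chosen)
    return Reduct(
        covering_ids=ids,
        total_cost=sum(h.costs[v] for v in ids),
        minimal=_is_minimal(ids, h.edges),
    )


def _hits_all(ids: frozenset[str], edges) -> bool:
    return all(ids & e for e in edges)


def _is_minimal(ids: frozenset[str], edges) -> bool:
    return _hits_all(ids, edges) and not any(
        _hits_all(ids - {v}, edges) for v in ids
    )


def prune_to_minimal(reduct: Reduct, h: Hypergraph) -> Reduct:
    """Drop redundant members, trying highest-cost first, until the set is
    a minimal hitting set."""
    ids = set(reduct.covering_ids)
    order = {v: i for i, v in enumerate(h.vertices)}
    for v in sorted(ids, key=lambda v: (-h.costs[v], order[v])):
        if _hits_all(frozenset(ids - {v}), h.edges):
            ids.discard(v)
    out = frozenset(ids)
    return Reduct(
        covering_ids=out,
        total_cost=sum(h.costs[v] for v in out),
        minimal=True,
    )


def adre_reduce(table: CoveringDecisionTable) -> Reduct:
    """Full A-DRE reduction on a covering decision table.

    Also verifies that the reduct preserves the table's positive region
    (union over retained coverings of their positive domains covers the
    union over all coverings) and reports the result on the Reduct.
    """
    fam = related_family(table)
    h = build_hypergraph(fam, table.costs)
    greedy = greedy_min_cost_cover(h)
    pruned = prune_to_minimal(greedy, h)
    full_pos = frozenset().union(
        *(
            positive_region(c, table.decision, table.universe)
            for c in table.coverings
        )
    )
    red_pos = frozenset().union(
        *(
            positive_region(table.covering(cid), table.decision, table.universe)
            for cid in pruned.covering_ids
        )
    )
    return Reduct(
        covering_ids=pruned.covering_ids,
        total_cost=pruned.total_cost,
        minimal=True,
        preserves_positive_region=red_pos >= full_pos,
    )


def exhaustive_min_cost_cover(h: Hypergraph) -> Reduct:
    """Oracle: cheapest hitting set by exhaustive subset search (use only
    for small vertex counts)."""
    best: frozenset[str] | None = None
    best_cost = float("inf")
    for r in range(1, len(h.vertices) + 1):
        for sub in itertools.combinations(h.vertices, r):
            ids = frozenset(sub)
            cost = sum(h.costs[v] for v in ids)
            if cost < best_cost and _hits_all(ids, h.edges):
                best, best_cost = ids, cost
    if best is None:
        raise InconsistentTableError("no hitting set exists")
    return Reduct(best, best_cost, _is_minimal(best, h.edges))


# ---------------------------------------------------------------------------
# rules
# ---------------------------------------------------------------------------


def extract_rules(table: CoveringDecisionTable, reduct: Reduct) -> RuleList:
    """One rule per effective block of each reduct covering, ordered by
    (coverage desc, support desc, covering cost asc, serialization order).
    The fallback label is the majority decision class."""
    if not reduct.covering_ids:
        raise ValueError("cannot extract rules from an empty reduct")
    for cid in reduct.covering_ids:
        table.covering(cid)  # raises KeyError if absent
    n = len(table.universe)
    costs = table.costs
    eff = [e for e in effective_blocks(table) if e.covering_id in reduct.covering_ids]
    keyed = []
    for e in eff:
        support = len(e.block) / n
        coverage = len(e.block) / len(table.decision.members(e.decision_label))
        keyed.append(
            (
                -coverage,
                -support,
                costs[e.covering_id],
                table.universe.sort_key(e.block),
                e.covering_id,
                e,
                support,
                coverage,
            )
        )
    keyed.sort(key=lambda t: t[:5])
    rules = tuple(
        DecisionRule(e.covering_id, e.block, e.decision_label, support, coverage, i)
        for i, (*_, e, support, coverage) in enumerate(keyed, start=1)
    )
    majority = max(
        table.decision.classes, key=lambda kv: (len(kv[1]), -table.decision.labels.index(kv[0]))
    )[0]
    return RuleList(rules=rules, default_label=majority)


def classify(rules: RuleList, record: dict[str, frozenset[str] | int],
             table: CoveringDecisionTable | None = None) -> str:
    """Classify a record by the highest-ranked matching rule.

    A record maps covering id → block, given either as the block's object
    set or as an index into the covering's block list (requires ``table``).
    Partial records are allowed; with no match the default label applies.
    """
    resolved: dict[str, frozenset[str]] = {}
    for cid, blk in record.items():
        if isinstance(blk, int):
            if table is None:
                raise ValueError("block indices require the source table")
            resolved[cid] = table.covering(cid).blocks[blk]
        else:
            resolved[cid] = frozenset(blk)
    for rule in rules.rules:
        if resolved.get(rule.covering_id) == rule.block:
            return rule.decision_label
    return rules.default_label


def classify_object(rules: RuleList, x: str) -> str:
    """Classify a universe object by membership in rule blocks."""
    for rule in rules.rules:
        if x in rule.block:
            return rule.decision_label
    return rules.default_label


def evaluate_rules(table: CoveringDecisionTable, folds: int = 5, seed: int = 0) -> float:
    """Stratified cross-validated accuracy of the reduce→rules→classify
    pipeline.

    Training restricts effectiveness and rule statistics to the training
    objects while keeping full blocks, so held-out objects can be matched
    by block membership.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    objs = list(table.universe.objects)
    if len(objs) < folds:
        raise ValueError("too few objects for the requested folds")
    rng = np.random.default_rng(seed)
    # stratified assignment: shuffle within class, deal round-robin
    fold_of: dict[str, int] = {}
    offset = 0
    for _, members in table.decision.classes:
        cls = sorted(members, key=objs.index)
        rng.shuffle(cls)
        for i, x in enumerate(cls):
            fold_of[x] = (i + offset) % folds
        offset += len(cls)
    correct = total = 0
    for k in range(folds):
        train = frozenset(x for x in objs if fold_of[x] != k)
        test = [x for x in objs if fold_of[x] == k]
        if not test or not train:
            continue
        sub = _restrict(table, train)
        try:
            reduct = adre_reduce(sub)
            rules = _full_block_rules(table, sub, reduct)
        except InconsistentTableError:
            majority = max(sub.decision.classes, key=lambda kv: len(kv[1]))[0]
            rules = RuleList(rules=(), default_label=majority)
        for x in test:
            if classify_object(rules, x) == table.decision.class_of(x):
                correct += 1
            total += 1
    return correct / total if total else 0.0


def _restrict(table: CoveringDecisionTable, keep: frozenset[str]) -> CoveringDecisionTable:
    from .covering import Covering, CoveringDecisionTable as CDT, DecisionPartition, Universe

    objs = tuple(x for x in table.universe.objects if x in keep)
    covs = []
    for c in table.coverings:
        blocks = tuple(dict.fromkeys(b & keep for b in c.blocks if b & keep))
        covs.append(Covering(id=c.id, blocks=blocks, cost=c.cost))
    classes = tuple(
        (lab, objs_ & keep) for lab, objs_ in table.decision.classes if objs_ & keep
    )
    return CDT(Universe(objs), tuple(covs), DecisionPartition(classes))


def _full_block_rules(
    full: CoveringDecisionTable, sub: CoveringDecisionTable, reduct: Reduct
) -> RuleList:
    """Rules whose effectiveness and statistics come from the training
    sub-table but whose blocks are the full-universe blocks, so test
    objects have defined membership."""
    keep = frozenset(sub.universe.objects)
    n = len(sub.universe)
    keyed = []
    for c in full.coverings:
        if c.id not in reduct.covering_ids:
            continue
        for block in c.blocks:
            tb = block & keep
            if not tb:
                continue
            for lab, members in sub.decision.classes:
                if tb <= members:
                    support = len(tb) / n
                    coverage = len(tb) / len(members)
                    keyed.append(
                        (
                            -coverage,
                            -support,
                            c.cost,
                            full.universe.sort_key(block),
                            c.id,
                            block,
                            lab,
                            support,
                            coverage,
                        )
                    )
                    break
    keyed.sort(key=lambda t: t[:5])
    rules = tuple(
        DecisionRule(cid, block, lab, support, coverage, i)
        for i, (_, _, _, _, cid, block, lab, support, coverage) in enumerate(
            keyed, start=1
        )
    )
    majority = max(sub.decision.classes, key=lambda kv: len(kv[1]))[0]
    return RuleList(rules=rules, default_label=majority)
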
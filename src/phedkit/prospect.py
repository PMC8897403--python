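"""Interval (grey) cumulative-prospect-theory evaluation of schemes.

Alternatives are scored against a per-criterion reference vector: each
entry — a scalar, a closed interval, or a linguistic term resolved
through an ordered scale — is edited into an interval of gains/losses,
valued through the S-shaped value function

    v(d) = d^α            for d ≥ 0
    v(d) = −λ·(−d)^β      for d < 0

and aggregated over states (or time frames) with the inverse-S
probability weights

    π(p) = p^γ / [p^γ + (1−p)^γ]^{1/γ}

with γ = χ on the gain branch and γ = δ on the loss branch.  Per-scheme
utility is the criterion-weighted sum of interval midpoints; the scheme
with the largest utility is selected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

PROB_TOL = 1e-9


@dataclass(frozen=True)
class Interval:
    """Closed real interval [lo, hi]; a grey number."""

    lo: float
    hi: float

    def __post_init__(self) -> None:
        if self.lo > self.hi:
            raise ValueError(f"interval requires lo <= hi, got [{self.lo}, {self.hi}]")

    @property
    def midpoint(self) -> float:
        return (self.lo + self.hi) / 2.0

    def __add__(self, other: "Interval") -> "Interval":
        return Interval(self.lo + other.lo, self.hi + other.hi)

    def scale(self, k: float) -> "Interval":
        assert k >= 0
        return Interval(k * self.lo, k * self.hi)


#: default 7-term ordered scale tiling [0, 1]; adjacent terms share endpoints
DEFAULT_SCALE_TERMS: tuple[tuple[str, float, float], ...] = (
    ("VP", 0.0, 0.1),
    ("P", 0.1, 0.25),
    ("MP", 0.25, 0.4),
    ("M", 0.4, 0.55),
    ("MG", 0.55, 0.7),
    ("G", 0.7, 0.85),
    ("VG", 0.85, 1.0),
)


@dataclass(frozen=True)
class LinguisticScale:
    """Ordered linguistic terms mapped to intervals tiling [0, 1]."""

    terms: tuple[tuple[str, float, float], ...] = DEFAULT_SCALE_TERMS

    def __post_init__(self) -> None:
        lo0 = self.terms[0][1]
        hi_prev = lo0
        for _, lo, hi in self.terms:
            if lo != hi_prev or hi < lo:
                raise ValueError("scale intervals must be ordered and tile the range")
            hi_prev = hi

    def __contains__(self, term: str) -> bool:
        return any(t == term for t, _, _ in self.terms)

    def interval(self, term: str) -> Interval:
        for t, lo, hi in self.terms:
            if t == term:
                return Interval(lo, hi)
        raise KeyError(f"unknown linguistic term {term!r}")


def map_linguistic(term: str, scale: LinguisticScale | None = None) -> Interval:
    """Resolve a linguistic term to its scale interval."""
    return (scale or LinguisticScale()).interval(term)


def resolve_grey(value, scale: LinguisticScale | None = None) -> Interval:
    """Resolve a grey value — scalar, [lo, hi], term, Interval, or a pair
    of terms (resolved to the spanning interval) — to an Interval."""
    scale = scale or LinguisticScale()
    if isinstance(value, Interval):
        return value
    if isinstance(value, str):
        return scale.interval(value)
    if isinstance(value, (int, float)):
        return Interval(float(value), float(value))
    seq = list(value)
    if all(isinstance(v, str) for v in seq):
        ivs = [scale.interval(v) for v in seq]
        return Interval(min(iv.lo for iv in ivs), max(iv.hi for iv in ivs))
    if len(seq) == 2 and all(isinstance(v, (int, float)) for v in seq):
        return Interval(float(seq[0]), float(seq[1]))
    raise ValueError(f"cannot resolve grey value {value!r}")


@dataclass(frozen=True)
class CriterionSpec:
    id: str
    type: str  # "gain" | "cost"
    weight: float

    def __post_init__(self) -> None:
        if self.type not in ("gain", "cost"):
            raise ValueError(f"criterion type must be gain or cost, got {self.type!r}")
        if not 0 <= self.weight <= 1:
            raise ValueError("criterion weight must lie in [0, 1]")


def validate_criteria(criteria: Sequence[CriterionSpec]) -> None:
    total = sum(c.weight for c in criteria)
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"criterion weights must sum to 1, got {total}")


@dataclass(frozen=True)
class ProspectParams:
    """Behavioural parameters of the value and weighting functions.

    Defaults are the canonical Tversky–Kahneman estimates.  alpha/beta
    are the gain/loss risk-curvature exponents in (0, 1]; lam ≥ 1 is the
    loss-aversion multiplier; chi and delta_w are the gain- and
    loss-branch probability-weighting exponents, kept above ~0.28 where
    the weighting function stays monotone.
    """

    alpha: float = 0.88
    beta: float = 0.88
    lam: float = 2.25
    chi: float = 0.61
    delta_w: float = 0.69

    def __post_init__(self) -> None:
        if not (0 < self.alpha <= 1 and 0 < self.beta <= 1):
            raise ValueError("alpha and beta must lie in (0, 1]")
        if self.lam < 1:
            raise ValueError("lambda must be >= 1")
        if not (0.28 < self.chi <= 1 and 0.28 < self.delta_w <= 1):
            raise ValueError("chi and delta_w must lie in (0.28, 1]")


def value_fn(d: float, params: ProspectParams | None = None) -> float:
    """S-shaped value function: d^α for gains, −λ(−d)^β for losses."""
    p = params or ProspectParams()
    if not math.isfinite(d):
        raise ValueError("value function requires finite input")
    if d >= 0:
        return d**p.alpha
    return -p.lam * (-d) ** p.beta


def value_fn_interval(d: Interval, params: ProspectParams | None = None) -> Interval:
    # v is increasing, so endpoint-wise application preserves order
    return Interval(value_fn(d.lo, params), value_fn(d.hi, params))


def prob_weight(p: float, branch: str, params: ProspectParams | None = None) -> float:
    """Inverse-S probability weight π(p) = p^γ/[p^γ+(1−p)^γ]^{1/γ},
    γ = χ for the gain branch, γ = δ for the loss branch."""
    pp = params or ProspectParams()
    if not 0 <= p <= 1:
        raise ValueError(f"probability outside [0, 1]: {p}")
    if branch == "gain":
        g = pp.chi
    elif branch == "loss":
        g = pp.delta_w
    else:
        raise ValueError(f"branch must be gain or loss, got {branch!r}")
    if p in (0.0, 1.0):
        return p
    return p**g / (p**g + (1 - p) ** g) ** (1 / g)


def delta_vs_reference(value: Interval, ref: Interval, ctype: str) -> Interval:
    """Edit an evaluation against its reference into a gain/loss interval.

    Gain criteria: [v.lo − r.hi, v.hi − r.lo].  Cost criteria flip the
    sign so that falling below the reference counts as a gain.
    """
    if ctype == "gain":
        return Interval(value.lo - ref.hi, value.hi - ref.lo)
    if ctype == "cost":
        return Interval(ref.lo - value.hi, ref.hi - value.lo)
    raise ValueError(f"criterion type must be gain or cost, got {ctype!r}")


def prospect_value(
    deltas: Sequence[Interval],
    probs: Sequence[float],
    params: ProspectParams | None = None,
) -> Interval:
    """Interval prospect value Σ_i π(p_i)·v(Δ_i) over states.

    Each state's weighting branch is chosen by the sign of its delta
    midpoint (gain branch for midpoint ≥ 0).
    """
    params = params or ProspectParams()
    if len(deltas) != len(probs):
        raise ValueError("deltas and probabilities must have equal length")
    if abs(sum(probs) - 1.0) > PROB_TOL:
        raise ValueError(f"probabilities must sum to 1, got {sum(probs)}")
    total = Interval(0.0, 0.0)
    for d, p in zip(deltas, probs):
        branch = "gain" if d.midpoint >= 0 else "loss"
        total = total + value_fn_interval(d, params).scale(
            prob_weight(p, branch, params)
        )
    return total


@dataclass(frozen=True)
class EvaluationMatrix:
    """Grey evaluations: scheme × criterion × state (or time frame).

    ``values[scheme][criterion]`` is the per-state sequence of grey
    values; ``probabilities``, when absent, default to equiprobable
    states.
    """

    schemes: tuple[str, ...]
    criteria_ids: tuple[str, ...]
    frames: tuple[str, ...]
    values: Mapping[str, Mapping[str, tuple]]
    probabilities: Mapping[str, Mapping[str, tuple[float, ...]]] | None = None

    def __post_init__(self) -> None:
        for s in self.schemes:
            for c in self.criteria_ids:
                entry = self.values[s][c]
                if len(entry) != len(self.frames):
                    raise ValueError(
                        f"scheme {s!r}, criterion {c!r}: expected "
                        f"{len(self.frames)} states, got {len(entry)}"
                    )
                if self.probabilities is not None:
                    ps = self.probabilities[s][c]
                    if len(ps) != len(self.frames):
                        raise ValueError("probability shape mismatch")
                    if abs(sum(ps) - 1.0) > PROB_TOL:
                        raise ValueError("probabilities must sum to 1")

    def probs(self, scheme: str, criterion: str) -> tuple[float, ...]:
        if self.probabilities is not None:
            return tuple(self.probabilities[scheme][criterion])
        k = len(self.frames)
        return tuple(1.0 / k for _ in range(k))


@dataclass(frozen=True)
class ProspectMatrix:
    """Interval prospect values V_ij per scheme × criterion."""

    schemes: tuple[str, ...]
    criteria_ids: tuple[str, ...]
    entries: tuple[tuple[Interval, ...], ...]  # rows: schemes

    def entry(self, scheme: str, criterion: str) -> Interval:
        return self.entries[self.schemes.index(scheme)][
            self.criteria_ids.index(criterion)
        ]


@dataclass(frozen=True)
class DecisionOutcome:
    utilities: dict[str, float]
    ranking: tuple[str, ...]
    selected: str
    tie: bool
    prospect_matrix: ProspectMatrix = field(repr=False, default=None)


def prospect_matrix(
    matrix: EvaluationMatrix,
    criteria: Sequence[CriterionSpec],
    reference: Mapping[str, object],
    params: ProspectParams | None = None,
    scale: LinguisticScale | None = None,
) -> ProspectMatrix:
    """Per-scheme, per-criterion interval prospect values."""
    validate_criteria(criteria)
    params = params or ProspectParams()
    scale = scale or LinguisticScale()
    if tuple(c.id for c in criteria) != matrix.criteria_ids:
        raise ValueError("criteria do not match the evaluation matrix")
    ref_iv = {c.id: resolve_grey(reference[c.id], scale) for c in criteria}
    rows = []
    for s in matrix.schemes:
        row = []
        for c in criteria:
            deltas = [
                delta_vs_reference(resolve_grey(v, scale), ref_iv[c.id], c.type)
                for v in matrix.values[s][c.id]
            ]
            row.append(prospect_value(deltas, matrix.probs(s, c.id), params))
        rows.append(tuple(row))
    return ProspectMatrix(matrix.schemes, matrix.criteria_ids, tuple(rows))


def cumulative_prospect(
    matrix: EvaluationMatrix,
    criteria: Sequence[CriterionSpec],
    reference: Mapping[str, object],
    params: ProspectParams | None = None,
    scale: LinguisticScale | None = None,
) -> DecisionOutcome:
    """Cumulative prospect utility U(x) = Σ_j ω_j·midpoint(V_j) per scheme
    and the resulting ranking (descending; ties reported)."""
    pm = prospect_matrix(matrix, criteria, reference, params, scale)
    weights = {c.id: c.weight for c in criteria}
    utilities = {
        s: sum(
            weights[c] * pm.entry(s, c).midpoint for c in matrix.criteria_ids
        )
        for s in matrix.schemes
    }
    order = {s: i for i, s in enumerate(matrix.schemes)}
    ranking = tuple(sorted(utilities, key=lambda s: (-utilities[s], order[s])))
    best_u = utilities[ranking[0]]
    tie = sum(1 for u in utilities.values() if u == best_u) > 1
    return DecisionOutcome(utilities, ranking, ranking[0], tie, pm)
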
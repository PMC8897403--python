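"""Readers, writers and run configuration.

JSON is the canonical interchange format (keys sorted, UTF-8,
newline-terminated); CSV is accepted for raw attribute-value tables that
are granulated on load; YAML carries run configuration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .covering import (
    Covering,
    CoveringDecisionTable,
    DecisionPartition,
    Universe,
    granulate,
)
from .prospect import (
    DEFAULT_SCALE_TERMS,
    CriterionSpec,
    EvaluationMatrix,
    LinguisticScale,
    ProspectParams,
)


@dataclass
class RunConfig:
    """Validated run-wide settings loaded from YAML."""

    prospect: ProspectParams = field(default_factory=ProspectParams)
    scale: LinguisticScale = field(default_factory=LinguisticScale)
    delta: dict[str, float] = field(default_factory=dict)  # per attribute
    default_delta: float = 0.2
    costs: dict[str, float] = field(default_factory=dict)
    folds: int = 5
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        prospect = ProspectParams(**raw.get("prospect", {}))
        if "scale" in raw:
            scale = LinguisticScale(
                tuple((t["term"], float(t["lo"]), float(t["hi"])) for t in raw["scale"])
            )
        else:
            scale = LinguisticScale(DEFAULT_SCALE_TERMS)
        return cls(
            prospect=prospect,
            scale=scale,
            delta={k: float(v) for k, v in raw.get("delta", {}).items()},
            default_delta=float(raw.get("default_delta", 0.2)),
            costs={k: float(v) for k, v in raw.get("costs", {}).items()},
            folds=int(raw.get("folds", 5)),
            seed=int(raw.get("seed", 0)),
            log_level=str(raw.get("log_level", "INFO")),
        )


def dumps_json(obj) -> str:
    """Canonical JSON: sorted keys, newline-terminated, diff-stable."""
    return json.dumps(obj, sort_keys=True, indent=2, ensure_ascii=False) + "\n"


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(dumps_json(obj), encoding="utf-8")


# ---------------------------------------------------------------------------
# covering decision tables
# ---------------------------------------------------------------------------


def table_to_dict(table: CoveringDecisionTable) -> dict:
    order = table.universe.objects

    def ser(block):  # serialize sets sorted by universe order
        return sorted(block, key=order.index)

    return {
        "objects": list(order),
        "coverings": [
            {"id": c.id, "cost": c.cost, "blocks": [ser(b) for b in c.blocks]}
            for c in table.coverings
        ],
        "decision": {lab: ser(mem) for lab, mem in table.decision.classes},
    }


def table_from_dict(data: dict) -> CoveringDecisionTable:
    universe = Universe(tuple(data["objects"]))
    coverings = tuple(
        Covering(
            id=c["id"],
            blocks=tuple(frozenset(b) for b in c["blocks"]),
            cost=float(c.get("cost", 1.0)),
        )
        for c in data["coverings"]
    )
    decision = DecisionPartition.from_dict(
        {lab: frozenset(mem) for lab, mem in data["decision"].items()}
    )
    return CoveringDecisionTable(universe, coverings, decision)


def load_table(
    path: str | Path,
    fmt: str | None = None,
    config: RunConfig | None = None,
    decision_column: str | None = None,
) -> CoveringDecisionTable:
    """Load a covering decision table from canonical JSON or granulate a
    raw CSV attribute-value table.

    CSV: header row names the attributes; ``decision_column`` (default:
    last column) holds the decision label; numeric columns are granulated
    with the per-attribute (or default) δ, object columns symbolically.
    """
    path = Path(path)
    fmt = fmt or ("csv" if path.suffix.lower() == ".csv" else "json")
    if fmt == "json":
        return table_from_dict(json.loads(path.read_text()))
    if fmt != "csv":
        raise ValueError(f"unknown table format {fmt!r}")
    config = config or RunConfig()
    df = pd.read_csv(path)
    if decision_column is None:
        decision_column = df.columns[-1]
    if decision_column not in df.columns:
        raise ValueError(f"unknown decision column {decision_column!r}")
    objects = tuple(f"x{i + 1}" for i in range(len(df)))
    coverings = []
    for col in df.columns:
        if col == decision_column:
            continue
        series = df[col]
        kind = "numeric" if pd.api.types.is_numeric_dtype(series) else "symbolic"
        coverings.append(
            granulate(
                objects,
                series.tolist(),
                kind,
                cov_id=col,
                delta=config.delta.get(col, config.default_delta),
                cost=config.costs.get(col, 1.0),
            )
        )
    decision = DecisionPartition.from_dict(
        {
            str(lab): frozenset(objects[i] for i in idx)
            for lab, idx in df.groupby(decision_column, sort=True).groups.items()
        }
    )
    return CoveringDecisionTable(Universe(objects), tuple(coverings), decision)


# ---------------------------------------------------------------------------
# evaluation matrices
# ---------------------------------------------------------------------------


def evaluation_to_dict(
    matrix: EvaluationMatrix,
    criteria: tuple[CriterionSpec, ...],
    reference: dict,
) -> dict:
    def ser(v):
        return list(v) if isinstance(v, (list, tuple)) else v

    out = {
        "schemes": list(matrix.schemes),
        "criteria": [
            {"id": c.id, "type": c.type, "weight": c.weight} for c in criteria
        ],
        "frames": list(matrix.frames),
        "values": {
            s: {c: [ser(v) for v in matrix.values[s][c]] for c in matrix.criteria_ids}
            for s in matrix.schemes
        },
        "reference": {k: ser(v) for k, v in reference.items()},
    }
    if matrix.probabilities is not None:
        out["probabilities"] = {
            s: {c: list(matrix.probabilities[s][c]) for c in matrix.criteria_ids}
            for s in matrix.schemes
        }
    return out


def evaluation_from_dict(
    data: dict,
) -> tuple[EvaluationMatrix, tuple[CriterionSpec, ...], dict]:
    criteria = tuple(
        CriterionSpec(c["id"], c["type"], float(c["weight"]))
        for c in data["criteria"]
    )
    crit_ids = tuple(c.id for c in criteria)
    values = {
        s: {c: tuple(data["values"][s][c]) for c in crit_ids}
        for s in data["schemes"]
    }
    probs = None
    if "probabilities" in data:
        probs = {
            s: {c: tuple(data["probabilities"][s][c]) for c in crit_ids}
            for s in data["schemes"]
        }
    matrix = EvaluationMatrix(
        tuple(data["schemes"]), crit_ids, tuple(data["frames"]), values, probs
    )
    return matrix, criteria, data.get("reference", {})


def load_evaluation(path: str | Path):
    return evaluation_from_dict(json.loads(Path(path).read_text()))
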
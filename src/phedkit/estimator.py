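"""Scikit-learn compatible rule-list classifier built on the A-DRE
pipeline.

``fit`` granulates each feature column into a covering (numeric columns
via δ-neighbourhood blocks, non-numeric symbolically), runs cost-aware
attribute reduction, and extracts the ordered decision rules.
``predict`` matches each sample against the rules' generator predicates
in rank order, falling back to the majority class.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .adre import adre_reduce, extract_rules
from .covering import (
    CoveringDecisionTable,
    DecisionPartition,
    InconsistentTableError,
    Universe,
    granulate,
)


class ADREClassifier(ClassifierMixin, BaseEstimator):
    """Ordered-rule classifier over a cost-aware covering-rough-set
    reduct.

    Parameters
    ----------
    delta : float, default 0.2
        Numeric granulation radius as a fraction of each feature's range.
    costs : dict or None
        Per-feature acquisition costs (default 1.0 each); the reduction
        prefers cheap features with equal classification power.

    Attributes
    ----------
    reduct_ : frozenset of retained feature names
    rules_ : RuleList of ordered decision rules
    classes_ : ndarray of class labels
    """

    def __init__(self, delta: float = 0.2, costs: dict | None = None):
        self.delta = delta
        self.costs = costs

    def _column_frame(self, X) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            return X
        arr = np.asarray(X)
        if arr.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        return pd.DataFrame(arr, columns=[f"f{j}" for j in range(arr.shape[1])])

    def fit(self, X, y) -> "ADREClassifier":
        df = self._column_frame(X).reset_index(drop=True)
        y = np.asarray(y)
        if len(y) != len(df):
            raise ValueError("X and y length mismatch")
        if len(df) == 0:
            raise ValueError("empty training set")
        self.classes_ = np.unique(y)
        objects = tuple(f"x{i + 1}" for i in range(len(df)))
        costs = self.costs or {}
        coverings = []
        for col in df.columns:
            series = df[col]
            kind = "numeric" if pd.api.types.is_numeric_dtype(series) else "symbolic"
            coverings.append(
                granulate(
                    objects,
                    series.tolist(),
                    kind,
                    cov_id=str(col),
                    delta=self.delta,
                    cost=float(costs.get(col, 1.0)),
                )
            )
        decision = DecisionPartition.from_dict(
            {
                str(lab): frozenset(o for o, lab_ in zip(objects, y) if lab_ == lab)
                for lab in self.classes_
            }
        )
        table = CoveringDecisionTable(Universe(objects), tuple(coverings), decision)
        try:
            reduct = adre_reduce(table)
            rules = extract_rules(table, reduct)
            self.reduct_ = reduct.covering_ids
            self.rules_ = rules
        except InconsistentTableError:
            # no certain rule exists: degrade to majority-class prediction
            counts = {lab: int((y == lab).sum()) for lab in self.classes_}
            majority = max(self.classes_, key=lambda lab: counts[lab])
            from .adre import RuleList

            self.reduct_ = frozenset()
            self.rules_ = RuleList(rules=(), default_label=str(majority))
        self.table_ = table
        self.feature_names_in_ = np.asarray([str(c) for c in df.columns], dtype=object)
        self.n_features_in_ = df.shape[1]
        self._block_meta = {c.id: c.block_meta for c in coverings}
        self._label_map = {str(lab): lab for lab in self.classes_}
        return self

    def _matches(self, cov_id: str, block, value) -> bool:
        cov = self.table_.covering(cov_id)
        idx = cov.blocks.index(block)
        preds = (cov.block_meta or ())[idx]
        for pred in preds:
            if pred[0] == "eq" and value == pred[1]:
                return True
            if pred[0] == "interval" and pred[1] <= float(value) <= pred[2]:
                return True
        return False

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "rules_")
        df = self._column_frame(X)
        cols = {str(c): c for c in df.columns}
        out = []
        for _, row in df.iterrows():
            label = self.rules_.default_label
            for rule in self.rules_.rules:
                if rule.covering_id in cols and self._matches(
                    rule.covering_id, rule.block, row[cols[rule.covering_id]]
                ):
                    label = rule.decision_label
                    break
            out.append(self._label_map.get(label, label))
        return np.asarray(out)
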
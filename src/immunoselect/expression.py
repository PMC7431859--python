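"""Predicting RNA expression of a mutation from DNA allelic fraction.

Most external validation cohorts lack tumor RNA, so the binary expressed
label (>= 5 mutant RNA reads) is predicted from DNA features: the variant
allele fraction, the VAF's percentile rank within the patient, and the
mutated gene.  The classifier is a logistic regression with internal
regularization-strength selection, evaluated by stratified 10-fold
cross-validated AUROC.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegressionCV
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

FEATURES = ("vaf", "vaf_percentile_rank")


@dataclass
class ExpressionModel:
    """Fitted logistic expression classifier with its feature manifest."""

    coef: np.ndarray          # aligned with FEATURES + gene one-hots
    intercept: float
    genes: tuple[str, ...]    # one-hot vocabulary; unseen genes use the baseline
    mean_auroc: float | None = None
    threshold: float = 0.5

    def _matrix(self, rows: pd.DataFrame) -> np.ndarray:
        missing = [c for c in FEATURES if c not in rows.columns]
        if missing:
            raise ValueError(f"missing feature column(s): {missing}")
        X = rows.loc[:, list(FEATURES)].to_numpy(dtype=float)
        if np.any(~np.isfinite(X)):
            bad = int(np.argwhere(~np.isfinite(X))[0, 0])
            raise ValueError(f"non-finite feature in row {bad}")
        onehot = np.zeros((len(rows), len(self.genes)))
        if "gene" in rows.columns and self.genes:
            gene_idx = {g: k for k, g in enumerate(self.genes)}
            for i, g in enumerate(rows["gene"]):
                k = gene_idx.get(str(g))
                if k is not None:  # unseen gene -> all-zero row = baseline path
                    onehot[i, k] = 1.0
        return np.hstack([X, onehot])

    def predict_proba(self, rows: pd.DataFrame) -> np.ndarray:
        z = self._matrix(rows) @ self.coef + self.intercept
        return 1.0 / (1.0 + np.exp(-z))

    def predict(self, rows: pd.DataFrame, threshold: float | None = None) -> np.ndarray:
        thr = self.threshold if threshold is None else threshold
        return (self.predict_proba(rows) >= thr).astype(int)

    def save(self, path) -> None:
        payload = {
            "format": "immunoselect-expression-model/1",
            "features": list(FEATURES),
            "genes": list(self.genes),
            "coef": self.coef.tolist(),
            "intercept": self.intercept,
            "mean_auroc": self.mean_auroc,
            "threshold": self.threshold,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def load(cls, path) -> "ExpressionModel":
        payload = json.loads(Path(path).read_text())
        if payload.get("format") != "immunoselect-expression-model/1":
            raise ValueError("unrecognized expression model file")
        return cls(
            coef=np.asarray(payload["coef"], dtype=float),
            intercept=float(payload["intercept"]),
            genes=tuple(payload["genes"]),
            mean_auroc=payload.get("mean_auroc"),
            threshold=float(payload.get("threshold", 0.5)),
        )


def _training_matrix(rows: pd.DataFrame) -> tuple[np.ndarray, tuple[str, ...]]:
    genes = tuple(sorted(rows["gene"].astype(str).unique())) if "gene" in rows.columns else ()
    stub = ExpressionModel(coef=np.zeros(len(FEATURES) + len(genes)), intercept=0.0, genes=genes)
    return stub._matrix(rows), genes


def fit_expression_classifier(
    rows: pd.DataFrame,
    n_folds: int = 10,
    seed: int = 0,
) -> tuple[ExpressionModel, float]:
    """Fit the expression classifier and report stratified CV mean AUROC.

    The final model is refit on all rows; the reported AUROC is the mean
    over held-out folds, each fold's model selecting its own regularization
    strength internally.
    """
    y = rows["expressed"].astype(int).to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("both expressed and unexpressed examples are required")
    if min(np.bincount(y)) < n_folds:
        raise ValueError(f"need at least {n_folds} examples of each class")
    X, genes = _training_matrix(rows)

    inner = max(3, min(5, min(np.bincount(y)) // 2))
    aurocs = []
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        for train, test in skf.split(X, y):
            clf = LogisticRegressionCV(cv=inner, max_iter=2000, scoring="roc_auc",
                                       random_state=seed)
            clf.fit(X[train], y[train])
            aurocs.append(roc_auc_score(y[test], clf.predict_proba(X[test])[:, 1]))
        mean_auroc = float(np.mean(aurocs))

        final = LogisticRegressionCV(cv=inner, max_iter=2000, scoring="roc_auc",
                                     random_state=seed)
        final.fit(X, y)
    model = ExpressionModel(
        coef=final.coef_.ravel().copy(),
        intercept=float(final.intercept_[0]),
        genes=genes,
        mean_auroc=mean_auroc,
    )
    return model, mean_auroc


def predict_expression(model: ExpressionModel, rows: pd.DataFrame,
                       threshold: float | None = None) -> pd.DataFrame:
    """Expressed-probability and binary call per row."""
    proba = model.predict_proba(rows)
    out = rows.copy()
    out["expressed_proba"] = proba
    out["expressed_call"] = (proba >= (model.threshold if threshold is None else threshold)).astype(int)
    return out
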
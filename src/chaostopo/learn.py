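"""Downstream prediction and evaluation.

Cross-validated classification (KNN / random forest / gradient boosting)
reported as accuracy, macro-averaged sensitivity and specificity, and
balanced accuracy; per-protein multiple linear regression of B-factors
scored by the Pearson correlation coefficient; and residue-similarity
(R-S) scores for visualizing multiclass prediction quality.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.stats import pearsonr
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .features import FeatureMatrix

__all__ = [
    "EvaluationReport",
    "RSScores",
    "classification_metrics",
    "crossval_classify",
    "bfactor_regression",
    "rs_scores",
]

DEFAULT_SEEDS = tuple(range(10))

# KNN is scale-sensitive, and trajectory statistics span orders of
# magnitude across components; the distance is taken on standardized
# features (scaler fit on training folds only).
_MODELS = {
    "knn": lambda seed: make_pipeline(
        StandardScaler(), KNeighborsClassifier(n_neighbors=5)
    ),
    "random_forest": lambda seed: RandomForestClassifier(
        n_estimators=100, random_state=seed
    ),
    "gbdt": lambda seed: GradientBoostingClassifier(
        n_estimators=100, max_depth=3, random_state=seed
    ),
}


@dataclass
class EvaluationReport:
    """Per-fold and aggregate cross-validation metrics."""

    model: str
    folds: int
    seeds: tuple[int, ...]
    classes: list
    per_fold: pd.DataFrame  # seed, fold, acc, sen, spec, ba
    confusions: list[np.ndarray]
    fold_assignments: dict[int, np.ndarray]

    @property
    def aggregate(self) -> dict[str, float]:
        return {
            m: float(self.per_fold[m].mean())
            for m in ("acc", "sen", "spec", "ba")
        }

    def summary(self) -> str:
        agg = self.aggregate
        lines = [
            f"{self.model} | {self.folds}-fold CV x {len(self.seeds)} seeds "
            f"| {len(self.classes)} classes",
            "metric        mean     std",
        ]
        for m in ("acc", "sen", "spec", "ba"):
            lines.append(
                f"{m:<10}{agg[m]:>9.4f}{self.per_fold[m].std():>9.4f}"
            )
        return "\n".join(lines)

    def to_json(self, path) -> None:
        payload = {
            "model": self.model,
            "folds": self.folds,
            "seeds": list(self.seeds),
            "classes": [str(c) for c in self.classes],
            "aggregate": self.aggregate,
            "per_fold": self.per_fold.to_dict(orient="records"),
            "confusions": [c.tolist() for c in self.confusions],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


@dataclass
class RSScores:
    """Residue (inter-class separation) and similarity (intra-class
    cohesion) scores per sample, each normalized to [0, 1]."""

    residue: np.ndarray
    similarity: np.ndarray
    labels: np.ndarray
    predictions: np.ndarray | None = None


def classification_metrics(cm: np.ndarray) -> dict[str, float]:
    """ACC, macro SEN/SPEC and balanced accuracy from a confusion matrix.

    Rows are true classes, columns predicted.  Sensitivity and
    specificity are computed one-vs-rest per class and macro-averaged;
    balanced accuracy is the mean per-class recall.
    """
    cm = np.asarray(cm)
    if cm.size == 0:
        raise ValueError("empty confusion matrix")
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1]:
        raise ValueError("confusion matrix must be square")
    if np.any(cm < 0):
        raise ValueError("confusion matrix entries must be nonnegative")
    total = cm.sum()
    if total == 0:
        raise ValueError("confusion matrix has no observations")
    acc = np.trace(cm) / total
    sens, specs = [], []
    for k in range(cm.shape[0]):
        tp = cm[k, k]
        fn = cm[k].sum() - tp
        fp = cm[:, k].sum() - tp
        tn = total - tp - fn - fp
        sens.append(tp / (tp + fn) if tp + fn else np.nan)
        specs.append(tn / (tn + fp) if tn + fp else np.nan)
    sen = float(np.nanmean(sens))
    spec = float(np.nanmean(specs))
    ba = float(np.nanmean(sens))  # balanced accuracy = mean per-class recall
    return {"acc": float(acc), "sen": sen, "spec": spec, "ba": ba}


def crossval_classify(
    X: FeatureMatrix | np.ndarray,
    y,
    model: str = "knn",
    folds: int = 10,
    seeds: tuple[int, ...] = DEFAULT_SEEDS,
) -> EvaluationReport:
    """Stratified k-fold cross-validation repeated over random seeds.

    Each seed reshuffles the stratified folds; the aggregate metrics are
    means over all folds x seeds.  Classifier hyperparameters are the
    conventional defaults (KNN k=5, RF 100 trees, GBDT 100 stages of
    depth 3).
    """
    Xv = X.values if isinstance(X, FeatureMatrix) else np.asarray(X, float)
    y = np.asarray(y)
    if len(y) != Xv.shape[0]:
        raise ValueError("labels length must match feature rows")
    if folds < 2:
        raise ValueError("folds must be >= 2")
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("need at least two classes")
    if counts.min() < folds:
        small = classes[counts.argmin()]
        raise ValueError(
            f"class {small!r} has {counts.min()} members, fewer than "
            f"{folds} folds: stratified folds impossible"
        )
    if model not in _MODELS:
        raise ValueError(f"unknown model {model!r}")
    rows, confusions, assignments = [], [], {}
    for seed in seeds:
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        assign = np.empty(len(y), dtype=int)
        for fold, (tr, te) in enumerate(skf.split(Xv, y)):
            assign[te] = fold
            clf = _MODELS[model](seed)
            clf.fit(Xv[tr], y[tr])
            pred = clf.predict(Xv[te])
            cm = confusion_matrix(y[te], pred, labels=classes)
            m = classification_metrics(cm)
            rows.append({"seed": seed, "fold": fold, **m})
            confusions.append(cm)
        assignments[seed] = assign
    return EvaluationReport(
        model=model,
        folds=folds,
        seeds=tuple(seeds),
        classes=classes.tolist(),
        per_fold=pd.DataFrame(rows),
        confusions=confusions,
        fold_assignments=assignments,
    )


def bfactor_regression(
    X: FeatureMatrix | np.ndarray, b: np.ndarray
) -> tuple[np.ndarray, float]:
    """Per-protein multiple linear regression of experimental B-factors.

    Ordinary least squares of b on the features (with intercept), fitted
    in-sample as in the Gaussian-network-model literature; returns fitted
    values and the Pearson correlation between fit and experiment.
    Rank-deficient design matrices fall back to the minimum-norm
    pseudoinverse solution with a warning.
    """
    Xv = X.values if isinstance(X, FeatureMatrix) else np.asarray(X, float)
    b = np.asarray(b, dtype=float)
    if b.shape[0] != Xv.shape[0]:
        raise ValueError("B-factor count must match feature rows")
    if not np.all(np.isfinite(b)):
        raise ValueError("B-factors must be finite")
    D = np.column_stack([np.ones(len(b)), Xv])
    coef, _, rank, _ = np.linalg.lstsq(D, b, rcond=None)
    if rank < min(D.shape):
        warnings.warn(
            f"rank-deficient design (rank {rank} < {min(D.shape)}); "
            "using the pseudoinverse solution",
            RuntimeWarning,
        )
    fitted = D @ coef
    if np.std(fitted) == 0 or np.std(b) == 0:
        pcc = 0.0  # degenerate fit carries no correlation signal
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pcc = float(pearsonr(fitted, b).statistic)
        if not np.isfinite(pcc):
            pcc = 0.0
    return fitted, pcc


def rs_scores(
    X: FeatureMatrix | np.ndarray,
    y,
    predictions=None,
) -> RSScores:
    """Residue and similarity scores per sample.

    For sample i in class k the residue score is the summed distance to
    all samples outside k, normalized by the maximum such sum over the
    data set; the similarity score is the mean over classmates j of
    ``1 - d_ij / d_max`` with ``d_max`` the largest pairwise distance.
    Both land in [0, 1]; singleton classes get similarity 1 with a
    warning.
    """
    Xv = X.values if isinstance(X, FeatureMatrix) else np.asarray(X, float)
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("need at least two classes")
    D = cdist(Xv, Xv)
    d_max = D.max()
    n = len(y)
    residue = np.zeros(n)
    similarity = np.zeros(n)
    for k in classes:
        mask = y == k
        if mask.sum() == 1:
            warnings.warn(
                f"singleton class {k!r}: similarity defined as 1",
                RuntimeWarning,
            )
    for i in range(n):
        out = y != y[i]
        residue[i] = D[i, out].sum()
        mates = (y == y[i]) & (np.arange(n) != i)
        if mates.sum() == 0:
            similarity[i] = 1.0
        elif d_max == 0:
            similarity[i] = 1.0
        else:
            similarity[i] = np.mean(1.0 - D[i, mates] / d_max)
    rmax = residue.max()
    if rmax > 0:
        residue = residue / rmax
    residue = np.clip(residue, 0.0, 1.0)
    similarity = np.clip(similarity, 0.0, 1.0)
    return RSScores(
        residue=residue,
        similarity=similarity,
        labels=y,
        predictions=None if predictions is None else np.asarray(predictions),
    )
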
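"""Measure-guided classifier ensembles (stages 2-3) and meta-models.

For each feature-cluster, every (family, hyperparameter) candidate in a roster
is scored by stratified cross-validation under the chosen objective (MCC or
PPV) and the maximizer is refit on all rows. The per-cluster winners plus a
voting scheme form an :class:`MCSModel`; an MCC-optimized and a PPV-optimized
model combine into a :class:`MetaModel` whose AND rule minimizes false
positives and whose OR rule minimizes false negatives.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import joblib
import numpy as np
from sklearn.base import clone
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import ParameterGrid, StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from mcscreen.core_data import ACTIVE, INACTIVE, CompoundTable
from mcscreen.feature_clustering import FeatureClustering
from mcscreen.metrics import confusion_matrix, mcc as mcc_metric, ppv as ppv_metric

logger = logging.getLogger(__name__)

MODEL_FORMAT_VERSION = 1

#: hard-label threshold on the Active probability (Active > 0.5, Inactive <= 0.5)
ACTIVE_THRESHOLD = 0.5

OBJECTIVES = ("MCC", "PPV")
MINIMIZE_FP = "minimize_fp"
MINIMIZE_FN = "minimize_fn"

#: two PPV scores within this distance are treated as tied, and the tie is
#: broken by the higher cross-validated MCC
PPV_TIE_TOLERANCE = 1e-6


@dataclass
class ClassifierSpec:
    """One classifier family: a factory plus a hyperparameter grid.

    Every family must expose an Active-class probability via
    ``predict_proba`` (margin-only learners are configured with internal
    sigmoid calibration, e.g. ``SVC(probability=True)``).
    """

    name: str
    factory: Callable[[int], object]
    grid: dict[str, list]

    def __post_init__(self) -> None:
        if not self.grid:
            raise ValueError(f"spec {self.name!r}: hyperparameter grid must be non-empty")

    def grid_points(self) -> list[dict]:
        return list(ParameterGrid(self.grid))


def default_roster() -> list[ClassifierSpec]:
    """Default classifier families spanning linear, margin, tree-ensemble,
    instance-based and probabilistic learners. Grids are deliberately small."""
    return [
        ClassifierSpec(
            "logistic",
            lambda seed: LogisticRegression(max_iter=2000, random_state=seed),
            {"C": [0.1, 1.0, 10.0]},
        ),
        ClassifierSpec(
            "svm_linear",
            lambda seed: SVC(kernel="linear", probability=True, random_state=seed),
            {"C": [0.1, 1.0]},
        ),
        ClassifierSpec(
            "svm_rbf",
            lambda seed: SVC(kernel="rbf", probability=True, random_state=seed),
            {"C": [1.0, 10.0], "gamma": ["scale"]},
        ),
        ClassifierSpec(
            "random_forest",
            lambda seed: RandomForestClassifier(random_state=seed),
            {"n_estimators": [100], "max_features": ["sqrt"]},
        ),
        ClassifierSpec(
            "gradient_boosting",
            lambda seed: GradientBoostingClassifier(random_state=seed),
            {"n_estimators": [100], "learning_rate": [0.1]},
        ),
        ClassifierSpec(
            "knn",
            lambda seed: KNeighborsClassifier(),
            {"n_neighbors": [5, 15]},
        ),
        ClassifierSpec(
            "naive_bayes",
            lambda seed: GaussianNB(),
            {"var_smoothing": [1e-9]},
        ),
        ClassifierSpec(
            "decision_tree",
            lambda seed: DecisionTreeClassifier(random_state=seed),
            {"max_depth": [None, 5]},
        ),
    ]


def compact_roster() -> list[ClassifierSpec]:
    """Fast roster (linear + tree + probabilistic) for tests and smoke runs."""
    return [
        ClassifierSpec(
            "logistic",
            lambda seed: LogisticRegression(max_iter=2000, random_state=seed),
            {"C": [1.0]},
        ),
        ClassifierSpec(
            "random_forest",
            lambda seed: RandomForestClassifier(random_state=seed),
            {"n_estimators": [50]},
        ),
        ClassifierSpec(
            "naive_bayes",
            lambda seed: GaussianNB(),
            {"var_smoothing": [1e-9]},
        ),
    ]


ROSTERS = {"default": default_roster, "compact": compact_roster}


@dataclass
class TrainedClusterClassifier:
    """Winner of the per-cluster model search, refit on all rows."""

    cluster_index: int
    spec_name: str
    params: dict
    estimator: object
    objective: str
    cv_score: float
    cv_mcc: float
    columns: list[str]

    def active_probability(self, X: np.ndarray) -> np.ndarray:
        proba = self.estimator.predict_proba(X)
        active_col = list(self.estimator.classes_).index(ACTIVE)
        return proba[:, active_col]


def _objective_from_cm(cm, objective: str) -> float:
    if objective == "MCC":
        return mcc_metric(cm)
    if objective == "PPV":
        return ppv_metric(cm)
    raise ValueError(f"unknown objective {objective!r}")


def _cv_confusion(estimator, X, y, cv_folds: int, seed: int):
    """Pooled out-of-fold confusion matrix under stratified K-fold CV."""
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    pred = np.empty(len(y), dtype=object)
    for train_idx, test_idx in skf.split(X, y):
        est = clone(estimator)
        est.fit(X[train_idx], y[train_idx])
        proba = est.predict_proba(X[test_idx])
        active_col = list(est.classes_).index(ACTIVE)
        p = proba[:, active_col]
        pred[test_idx] = np.where(p > ACTIVE_THRESHOLD, ACTIVE, INACTIVE)
    return confusion_matrix(list(y), list(pred))


def optimize_cluster_classifier(
    X: np.ndarray,
    y: Sequence[str],
    objective: str,
    roster: Sequence[ClassifierSpec] | None = None,
    cv_folds: int = 5,
    seed: int = 0,
    cluster_index: int = 0,
    columns: Sequence[str] | None = None,
) -> TrainedClusterClassifier:
    """Grid-search the roster under stratified CV and refit the winner.

    The objective is computed on the pooled out-of-fold predictions (stable
    for PPV on small folds). Under the PPV objective, candidates within
    ``PPV_TIE_TOLERANCE`` of the best PPV are re-ranked by CV MCC, so a
    single-lucky-positive classifier never wins on PPV alone. Remaining ties
    fall to roster/grid order. Deterministic for a fixed seed.
    """
    if objective not in OBJECTIVES:
        raise ValueError(f"objective must be one of {OBJECTIVES}")
    if cv_folds < 2:
        raise ValueError("cv_folds must be >= 2")
    roster = list(roster) if roster is not None else default_roster()
    if not roster:
        raise ValueError("roster must be non-empty")
    X = np.asarray(X, dtype=float)
    y = np.asarray(list(y), dtype=object)
    classes = set(y)
    if not {ACTIVE, INACTIVE} <= classes or classes - {ACTIVE, INACTIVE}:
        raise ValueError("labels must contain both Active and Inactive (and nothing else)")

    candidates: list[tuple[float, float, int, ClassifierSpec, dict]] = []
    order = 0
    for spec in roster:
        for params in spec.grid_points():
            try:
                est = spec.factory(seed)
                est.set_params(**params)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    cm = _cv_confusion(est, X, y, cv_folds, seed)
            except Exception as exc:  # noqa: BLE001 - a failing family is not fatal
                logger.warning("spec %s%s failed during CV: %s", spec.name, params, exc)
                continue
            score = _objective_from_cm(cm, objective)
            candidates.append((score, mcc_metric(cm), order, spec, params))
            order += 1
    if not candidates:
        raise RuntimeError("every roster candidate failed to fit")

    best_score = max(c[0] for c in candidates)
    if objective == "PPV":
        pool = [c for c in candidates if c[0] >= best_score - PPV_TIE_TOLERANCE]
        pool.sort(key=lambda c: (-c[1], c[2]))
    else:
        pool = [c for c in candidates if c[0] == best_score]
        pool.sort(key=lambda c: c[2])
    score, cv_mcc, _, spec, params = pool[0]

    final = spec.factory(seed)
    final.set_params(**params)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        final.fit(X, y)
    return TrainedClusterClassifier(
        cluster_index=cluster_index,
        spec_name=spec.name,
        params=dict(params),
        estimator=final,
        objective=objective,
        cv_score=float(score),
        cv_mcc=float(cv_mcc),
        columns=list(columns) if columns is not None else [],
    )


@dataclass
class MCSModel:
    """One measure-optimized ensemble: k per-cluster classifiers + a voting scheme."""

    objective: str
    classifiers: list[TrainedClusterClassifier]
    clustering: FeatureClustering
    voting: str = "majority"

    def __post_init__(self) -> None:
        if self.voting not in ("majority", "weighted"):
            raise ValueError("voting must be 'majority' or 'weighted'")
        if len(self.classifiers) != self.clustering.k:
            raise ValueError("exactly one classifier per feature-cluster is required")

    @property
    def prob_column_names(self) -> list[str]:
        tag = self.objective.lower()
        return [f"{tag}_c{c.cluster_index}" for c in self.classifiers]

    def save(self, path: str | Path) -> Path:
        """Persist as a joblib archive with a JSON metadata sidecar."""
        path = Path(path)
        joblib.dump({"format_version": MODEL_FORMAT_VERSION, "model": self}, path)
        meta = {
            "format_version": MODEL_FORMAT_VERSION,
            "objective": self.objective,
            "voting": self.voting,
            "k": self.clustering.k,
            "classifiers": [
                {
                    "cluster_index": c.cluster_index,
                    "spec": c.spec_name,
                    "params": c.params,
                    "cv_score": c.cv_score,
                    "cv_mcc": c.cv_mcc,
                }
                for c in self.classifiers
            ],
        }
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(meta, indent=2), encoding="utf-8"
        )
        return path

    @classmethod
    def load(cls, path: str | Path) -> "MCSModel":
        payload = joblib.load(path)
        if payload.get("format_version") != MODEL_FORMAT_VERSION:
            raise ValueError(f"unsupported model format: {payload.get('format_version')}")
        return payload["model"]


@dataclass
class PredictionResult:
    """Per-compound final labels plus the ordered vector of inner-classifier
    Active probabilities (one column per contributing inner classifier)."""

    ids: list[str]
    probabilities: np.ndarray  # (n_compounds, n_inner)
    labels: np.ndarray  # (n_compounds,) of Active/Inactive
    prob_columns: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        n = len(self.ids)
        if self.probabilities.shape[0] != n or self.labels.shape[0] != n:
            raise ValueError("ids, probabilities and labels must align")
        if self.probabilities.size and (
            (self.probabilities < 0).any() or (self.probabilities > 1).any()
        ):
            raise ValueError("probabilities must lie in [0, 1]")

    def label_of(self, compound_id: str) -> str:
        return self.labels[self.ids.index(compound_id)]


def majority_vote(votes: Sequence[str]) -> str:
    """Simple majority with the tie awarded to Active: the compound is Active
    whenever #Active >= #Inactive."""
    votes = list(votes)
    if not votes:
        raise ValueError("empty vote vector")
    n_active = sum(v == ACTIVE for v in votes)
    return ACTIVE if n_active >= len(votes) - n_active else INACTIVE


def weighted_vote(
    probabilities: Sequence[float], weights: Sequence[float]
) -> str:
    """Weighted voting: Active iff sum(w*p) >= sum(w*(1-p)) (ties to Active)."""
    p = np.asarray(list(probabilities), dtype=float)
    w = np.asarray(list(weights), dtype=float)
    if p.shape != w.shape or p.size == 0:
        raise ValueError("probabilities and weights must be equal-length and non-empty")
    if (w < 0).any():
        raise ValueError("weights must be non-negative")
    if w.sum() == 0:
        raise ValueError("weights must not be all zero")
    return ACTIVE if float(w @ p) >= float(w @ (1.0 - p)) else INACTIVE


def build_mcs(
    table: CompoundTable,
    clustering: FeatureClustering,
    objective: str,
    roster: Sequence[ClassifierSpec] | None = None,
    cv_folds: int = 5,
    seed: int = 0,
    voting: str = "majority",
) -> MCSModel:
    """Train one measure-optimized classifier per feature-cluster."""
    labels = table.labels
    classifiers = []
    for idx, columns in enumerate(clustering.clusters, start=1):
        X = table.feature_matrix(columns)
        logger.info(
            "optimizing cluster %d/%d (%d columns, objective=%s)",
            idx, clustering.k, len(columns), objective,
        )
        classifiers.append(
            optimize_cluster_classifier(
                X,
                labels,
                objective=objective,
                roster=roster,
                cv_folds=cv_folds,
                seed=seed,
                cluster_index=idx,
                columns=columns,
            )
        )
    return MCSModel(
        objective=objective,
        classifiers=classifiers,
        clustering=clustering,
        voting=voting,
    )


def predict(model: MCSModel, table: CompoundTable) -> PredictionResult:
    """Screen a table: record every inner classifier's Active probability and
    derive the final label via the model's voting scheme.

    Inner hard labels follow the fixed threshold (Active > 0.5, Inactive
    <= 0.5). Under weighted voting the weights are the inner classifiers'
    cross-validated objective scores clipped at zero (equal weights if all
    clip to zero).
    """
    available = set(table.feature_names)
    missing = [c for cl in model.clustering.clusters for c in cl if c not in available]
    if missing:
        raise ValueError(f"table is missing model columns: {missing[:5]}...")
    n = len(table)
    probs = np.empty((n, len(model.classifiers)), dtype=float)
    for j, clf in enumerate(model.classifiers):
        X = table.feature_matrix(clf.columns or model.clustering.clusters[j])
        probs[:, j] = clf.active_probability(X)
    inner_labels = np.where(probs > ACTIVE_THRESHOLD, ACTIVE, INACTIVE)
    if model.voting == "majority":
        final = np.array([majority_vote(list(row)) for row in inner_labels], dtype=object)
    else:
        weights = np.clip([c.cv_score for c in model.classifiers], 0.0, None)
        if weights.sum() == 0:
            weights = np.ones_like(weights)
        final = np.array(
            [weighted_vote(list(row), list(weights)) for row in probs], dtype=object
        )
    return PredictionResult(
        ids=list(table.ids),
        probabilities=probs,
        labels=final,
        prob_columns=model.prob_column_names,
    )


def combine_meta(
    pred_a: PredictionResult, pred_b: PredictionResult, rule: str
) -> PredictionResult:
    """Combine two ensemble predictions into a meta-prediction.

    ``minimize_fp`` labels Active only when both constituents agree on Active
    (logical AND); ``minimize_fn`` when at least one does (logical OR).
    Probability vectors are concatenated, first model first.
    """
    if rule not in (MINIMIZE_FP, MINIMIZE_FN):
        raise ValueError(f"rule must be {MINIMIZE_FP!r} or {MINIMIZE_FN!r}")
    if pred_a.ids != pred_b.ids:
        raise ValueError("predictions cover different compound id sets/orders")
    a = pred_a.labels == ACTIVE
    b = pred_b.labels == ACTIVE
    active = (a & b) if rule == MINIMIZE_FP else (a | b)
    return PredictionResult(
        ids=list(pred_a.ids),
        probabilities=np.hstack([pred_a.probabilities, pred_b.probabilities]),
        labels=np.where(active, ACTIVE, INACTIVE).astype(object),
        prob_columns=list(pred_a.prob_columns) + list(pred_b.prob_columns),
    )


@dataclass
class MetaModel:
    """Two measure-optimized ensembles joined by an AND/OR rule.

    The probability vector order is documented and fixed: the MCC model's
    inner classifiers by cluster index, then the PPV model's.
    """

    model_mcc: MCSModel
    model_ppv: MCSModel
    rule: str

    def __post_init__(self) -> None:
        if self.rule not in (MINIMIZE_FP, MINIMIZE_FN):
            raise ValueError(f"rule must be {MINIMIZE_FP!r} or {MINIMIZE_FN!r}")
        if self.model_mcc.clustering.all_columns != self.model_ppv.clustering.all_columns:
            raise ValueError("constituent models must share one feature clustering")

    def predict(self, table: CompoundTable) -> PredictionResult:
        return combine_meta(
            predict(self.model_mcc, table), predict(self.model_ppv, table), self.rule
        )
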
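"""Selector-by-classifier discrimination grid with fivefold CV.

Every combination of the 24 feature-selection strategies and 8
classifier families (192 models) is evaluated by stratified fivefold
cross-validation with patient-level grouping: the pre- and post-gel
rows of one patient always land in the same fold, so a model can never
score by recognising the patient.  Within each training fold, features
are z-scored by the training statistics and the selector is refit on the
training portion only (no selection leakage); the model AUC is the mean
of the five held-out-fold AUCs.  Features selected in the top-20 of
folds belonging to models with mean AUC above a gate (0.80) are counted
into a selection-frequency ranking.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components
from sklearn.base import BaseEstimator
from sklearn.ensemble import (AdaBoostClassifier, BaggingClassifier,
                              RandomForestClassifier)
from sklearn.linear_model import LogisticRegression
from sklearn.manifold import Isomap
from sklearn.metrics import roc_auc_score
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier, kneighbors_graph
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .selection import SELECTOR_NAMES, FeatureSelector

log = logging.getLogger(__name__)

CLASSIFIER_NAMES = ["logistic_regression", "svm", "naive_bayes", "knn",
                    "decision_tree", "bagging", "random_forest", "adaboost"]


def make_classifier(name: str, seed: int = 0):
    """Default-hyperparameter classifier instances (fixed, not tuned)."""
    if name == "logistic_regression":
        return LogisticRegression(C=1.0, max_iter=2000, random_state=seed)
    if name == "svm":
        return SVC(C=1.0, kernel="rbf", probability=False, random_state=seed)
    if name == "naive_bayes":
        return GaussianNB()
    if name == "knn":
        return KNeighborsClassifier(n_neighbors=5)
    if name == "decision_tree":
        return DecisionTreeClassifier(random_state=seed)
    if name == "bagging":
        return BaggingClassifier(n_estimators=50, random_state=seed)
    if name == "random_forest":
        return RandomForestClassifier(n_estimators=100, random_state=seed)
    if name == "adaboost":
        return AdaBoostClassifier(
            estimator=DecisionTreeClassifier(max_depth=1),
            n_estimators=50, random_state=seed)
    raise KeyError(f"unknown classifier {name!r}; valid: {', '.join(CLASSIFIER_NAMES)}")


def _score_column(clf, X) -> np.ndarray:
    if hasattr(clf, "predict_proba"):
        return clf.predict_proba(X)[:, 1]
    return clf.decision_function(X)


@dataclass
class ModelResult:
    selector: str
    classifier: str
    fold_aucs: list[float]
    mean_auc: float
    pooled_auc: float
    fold_features: list[list[str]]      # ordered top-k names per fold
    fold_hash: str

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class FrequencyReport:
    counts: pd.Series                   # per feature, over passing-model folds
    percentages: pd.Series
    n_passing_models: int
    top10: list[str] = field(default_factory=list)
    empty: bool = False


def make_folds(patient_ids, labels, n_splits: int = 5, seed: int = 0,
               max_retries: int = 20):
    """Patient-grouped stratified folds for the paired design.

    Patients are shuffled and split into ``n_splits`` groups; both
    conditions of one patient share a fold, which for a fully paired
    cohort keeps every fold class-balanced.  A fold that would end up
    single-class (possible with unpaired input) triggers a reshuffle
    with the next seed, logged.
    """
    patient_ids = np.asarray(patient_ids)
    labels = np.asarray(labels)
    for attempt in range(max_retries):
        rng = np.random.default_rng(seed + attempt)
        uniq = np.unique(patient_ids)
        rng.shuffle(uniq)
        groups = np.array_split(uniq, n_splits)
        folds = []
        ok = True
        for g in groups:
            test = np.isin(patient_ids, g)
            if len(np.unique(labels[test])) < 2 or len(np.unique(labels[~test])) < 2:
                ok = False
                break
            folds.append((np.flatnonzero(~test), np.flatnonzero(test)))
        if ok:
            if attempt:
                log.info("fold split reshuffled %d time(s) to balance classes", attempt)
            assign = np.zeros(len(patient_ids), dtype=int)
            for fi, (_, te) in enumerate(folds):
                assign[te] = fi
            fold_hash = hashlib.sha1(assign.tobytes()).hexdigest()[:12]
            return folds, fold_hash
    raise ValueError("could not build class-balanced patient-grouped folds")


def _prepare(features, labels):
    if isinstance(features, pd.DataFrame):
        names = [c for c in features.columns
                 if c not in ("patient_id", "condition", "region")]
        X = features[names].to_numpy(dtype=float)
    else:
        X = np.asarray(features, dtype=float)
        names = [str(i) for i in range(X.shape[1])]
    y = np.unique(np.asarray(labels), return_inverse=True)[1]
    return X, y, names


def run_model_grid(features, labels, patient_ids, seed: int = 0,
                   selectors=None, classifiers=None, k: int = 20,
                   n_splits: int = 5) -> list[ModelResult]:
    """Evaluate every selector x classifier pair on shared CV folds.

    Selector fits are shared across the classifiers of a fold (the
    selected subset depends only on the training portion), so the grid
    costs n_folds x n_selectors selector fits, not n_folds x n_models.
    """
    selectors = list(selectors) if selectors is not None else list(SELECTOR_NAMES)
    classifiers = list(classifiers) if classifiers is not None else list(CLASSIFIER_NAMES)
    X, y, names = _prepare(features, labels)
    folds, fold_hash = make_folds(patient_ids, y, n_splits=n_splits, seed=seed)

    per_pair_scores: dict[tuple[str, str], list[float]] = {
        (s, c): [] for s in selectors for c in classifiers}
    per_pair_pool: dict[tuple[str, str], list[np.ndarray]] = {
        (s, c): [] for s in selectors for c in classifiers}
    sel_features: dict[str, list[list[str]]] = {s: [] for s in selectors}
    pooled_truth: list[np.ndarray] = []

    for tr, te in folds:
        mu = X[tr].mean(axis=0)
        sd = X[tr].std(axis=0)
        sd[sd < 1e-8] = 1.0      # constant-in-fold features stay at 0

        Xtr = (X[tr] - mu) / sd
        Xte = (X[te] - mu) / sd
        pooled_truth.append(y[te])
        for s in selectors:
            sel = FeatureSelector(strategy=s, k=k).fit(Xtr, y[tr])
            idx = sel.selected_idx_
            sel_features[s].append([names[i] for i in idx])
            for c in classifiers:
                clf = make_classifier(c, seed=seed)
                clf.fit(Xtr[:, idx], y[tr])
                score = _score_column(clf, Xte[:, idx])
                per_pair_scores[(s, c)].append(
                    float(roc_auc_score(y[te], score)))
                per_pair_pool[(s, c)].append(score)

    ytrue = np.concatenate(pooled_truth)
    results = []
    for s in selectors:
        for c in classifiers:
            aucs = per_pair_scores[(s, c)]
            pooled = float(roc_auc_score(ytrue, np.concatenate(per_pair_pool[(s, c)])))
            results.append(ModelResult(
                selector=s, classifier=c, fold_aucs=aucs,
                mean_auc=float(np.mean(aucs)), pooled_auc=pooled,
                fold_features=sel_features[s], fold_hash=fold_hash))
    return results


def fit_eval(selector: str, classifier: str, features, labels, patient_ids,
             seed: int = 0, k: int = 20, n_splits: int = 5) -> ModelResult:
    """Cross-validated evaluation of a single selector/classifier pair."""
    return run_model_grid(features, labels, patient_ids, seed=seed,
                          selectors=[selector], classifiers=[classifier],
                          k=k, n_splits=n_splits)[0]


def rank_feature_frequency(results: list[ModelResult],
                           auc_min: float = 0.80,
                           gate: str = "mean") -> FrequencyReport:
    """Top-20 selection frequency over the folds of models above the gate.

    Percentage denominator = n_folds x number of passing models; ranking
    descending by count with alphabetical tie-break; the ten most
    frequent features are flagged.
    """
    if not results:
        raise ValueError("no model results")
    passing = [r for r in results
               if (r.mean_auc if gate == "mean" else r.pooled_auc) > auc_min]
    if not passing:
        log.warning("no model exceeded AUC %.2f: empty frequency report", auc_min)
        empty = pd.Series(dtype=float)
        return FrequencyReport(counts=empty, percentages=empty,
                               n_passing_models=0, top10=[], empty=True)
    counts: dict[str, int] = {}
    n_fold_lists = 0
    for r in passing:
        for fl in r.fold_features:
            n_fold_lists += 1
            for f in fl:
                counts[f] = counts.get(f, 0) + 1
    ser = pd.Series(counts, dtype=float)
    ser = ser.sort_index().sort_values(ascending=False, kind="stable")
    pct = 100.0 * ser / n_fold_lists
    return FrequencyReport(counts=ser.astype(int), percentages=pct,
                           n_passing_models=len(passing),
                           top10=list(ser.index[:10]), empty=False)


def isomap_embed(X, n_neighbors: int = 5, n_components: int = 2) -> np.ndarray:
    """Isomap projection of the top-feature matrix to 2D.

    If the k-NN graph is disconnected, k is increased (logged) until the
    graph is connected so that geodesic distances exist for all pairs.
    """
    X = np.asarray(X, dtype=float)
    if len(X) < n_neighbors + 1:
        raise ValueError("need at least n_neighbors + 1 rows")
    k = n_neighbors
    while k < len(X) - 1:
        g = kneighbors_graph(X, n_neighbors=k, include_self=False)
        n_comp, _ = connected_components(g, directed=False)
        if n_comp == 1:
            break
        log.info("isomap neighbour graph disconnected at k=%d; trying k=%d", k, k + 1)
        k += 1
    emb = Isomap(n_neighbors=k, n_components=n_components).fit_transform(X)
    return emb


class DiscriminationGrid(BaseEstimator):
    """sklearn-style estimator over the whole selector x classifier grid.

    ``fit(X, y, groups=...)`` runs every registered pair under the shared
    patient-grouped fivefold CV and exposes ``results_`` (list of
    :class:`ModelResult`), ``frequency_`` (the top-20 selection-frequency
    report over models above ``auc_gate``) and ``best_model_``.
    """

    def __init__(self, selectors=None, classifiers=None, k: int = 20,
                 n_splits: int = 5, auc_gate: float = 0.80, seed: int = 0):
        self.selectors = selectors
        self.classifiers = classifiers
        self.k = k
        self.n_splits = n_splits
        self.auc_gate = auc_gate
        self.seed = seed

    def fit(self, X, y, groups=None):
        if groups is None:
            if hasattr(X, "columns") and "patient_id" in getattr(X, "columns", []):
                groups = X["patient_id"]
            else:
                raise ValueError("patient-level groups are required")
        self.results_ = run_model_grid(
            X, y, groups, seed=self.seed, selectors=self.selectors,
            classifiers=self.classifiers, k=self.k, n_splits=self.n_splits)
        self.frequency_ = rank_feature_frequency(self.results_,
                                                 auc_min=self.auc_gate)
        self.best_model_ = max(self.results_, key=lambda r: r.mean_auc)
        return self
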
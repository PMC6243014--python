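"""Cross-validation protocol, scoring, and interpretation analyses.

All classifier families are compared under one shared plan: stratified
5-fold splits repeated 5 times, identical fold assignments for every
method, with all feature extractors (autoencoder, factor models,
binarization) refitted inside each training fold.  Reported values are
medians across the 25 runs.  Rankings are kept for every test sample so
Top-N accuracy (true label among the N best-ranked candidates) and
neighbor tables can be computed after the fact.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import f1_score
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.naive_bayes import GaussianNB

from herbprint.autoencode import Autoencoder
from herbprint.bayesnet import ChowLiuBNClassifier
from herbprint.featurize import Dataset
from herbprint.subspace import SubspaceClassifier

METHODS = ("large_bn", "ae_logreg", "ae_gnb", "sntd_pa", "sntd_dcor", "snmf_pa", "snmf_dcor")


@dataclass(frozen=True)
class CVPlan:
    """Repeated stratified fold assignment shared across methods.

    ``assignment[r, i]`` is the test-fold index of sample i in repeat r;
    each fold holds its class-proportional share of every class (within
    one sample), and every sample is in exactly one test fold per repeat.
    """

    n_folds: int
    n_repeats: int
    seed: int
    assignment: np.ndarray

    def splits(self):
        """Yield (repeat, fold, train_idx, test_idx) tuples."""
        for r in range(self.n_repeats):
            for f in range(self.n_folds):
                test = np.flatnonzero(self.assignment[r] == f)
                train = np.flatnonzero(self.assignment[r] != f)
                yield r, f, train, test


def make_cv_plan(y: np.ndarray, n_folds: int = 5, n_repeats: int = 5,
                 seed: int = 0) -> CVPlan:
    """Build the repeated stratified k-fold plan; deterministic given seed.

    Raises if any class is too small to appear in every training fold.
    """
    y = np.asarray(y)
    labels, counts = np.unique(y, return_counts=True)
    small = labels[counts < n_folds]
    if small.size:
        raise ValueError(
            f"class(es) {list(small)} have fewer than {n_folds} samples; "
            "they would be absent from some training fold"
        )
    assignment = np.empty((n_repeats, y.size), dtype=int)
    for r in range(n_repeats):
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed + r)
        for f, (_, test) in enumerate(skf.split(np.zeros(y.size), y)):
            assignment[r, test] = f
    return CVPlan(n_folds, n_repeats, seed, assignment)


class RankedProbaClassifier:
    """Wraps a probabilistic classifier with deterministic ranked output."""

    def __init__(self, estimator):
        self.estimator = estimator

    def fit(self, X, y):
        self.estimator.fit(X, y)
        self.classes_ = self.estimator.classes_
        return self

    def predict_proba(self, X):
        return self.estimator.predict_proba(X)

    def predict(self, X):
        return self.estimator.predict(X)

    def predict_ranked(self, X):
        proba = self.predict_proba(X)
        order = np.argsort(-proba, axis=1, kind="stable")
        return self.classes_[order]


def fit_l1_logreg(Z: np.ndarray, y: np.ndarray, strength: float = 1.0,
                  seed: int = 0, max_iter: int = 2000) -> RankedProbaClassifier:
    """l1-regularized multinomial logistic regression on encoded features.

    `strength` is the regularization weight (sklearn's ``C = 1/strength``);
    class-probability scores drive the Top-N ranking.
    """
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise ValueError("need at least 2 classes")
    clf = LogisticRegression(
        l1_ratio=1.0, C=1.0 / strength, solver="saga",
        max_iter=max_iter, random_state=seed,
    )
    return RankedProbaClassifier(clf).fit(Z, y)


def fit_gaussian_nb(Z: np.ndarray, y: np.ndarray,
                    var_floor: float = 1e-9) -> RankedProbaClassifier:
    """Gaussian naive Bayes with an absolute per-feature variance floor."""
    y = np.asarray(y)
    labels, counts = np.unique(y, return_counts=True)
    if labels.size < 2:
        raise ValueError("need at least 2 classes")
    tiny = labels[counts < 2]
    if tiny.size:
        raise ValueError(f"class(es) {list(tiny)} have a single sample")
    gnb = GaussianNB(var_smoothing=0.0)
    wrapped = RankedProbaClassifier(gnb).fit(Z, y)
    gnb.var_ = np.maximum(gnb.var_, var_floor)
    return wrapped


def compute_metrics(y_true: np.ndarray, y_ranked: np.ndarray,
                    labels: np.ndarray | None = None) -> dict:
    """Accuracy, weighted F1, confusion matrix, and Top-N table.

    ``y_ranked`` holds per-sample labels in decreasing preference; column 0
    is the top-1 prediction.  Top-N accuracy is the fraction of samples
    whose true label appears among the first N columns.
    """
    y_true = np.asarray(y_true)
    y_ranked = np.atleast_2d(np.asarray(y_ranked))
    if y_true.shape[0] != y_ranked.shape[0]:
        raise ValueError("y_true and y_ranked lengths differ")
    y_pred = y_ranked[:, 0]
    if labels is None:
        labels = np.unique(np.concatenate([y_true, y_pred]))
    undefined = set(labels) - set(np.unique(y_true)) - set(np.unique(y_pred))
    if undefined:
        warnings.warn(
            f"F1 undefined (no true or predicted samples) for {sorted(map(str, undefined))}; set to 0"
        )
    acc = float(np.mean(y_pred == y_true))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        wf1 = float(f1_score(y_true, y_pred, labels=labels, average="weighted",
                             zero_division=0))
    conf = pd.DataFrame(
        _sk_confusion(y_true, y_pred, labels=labels), index=labels, columns=labels
    )
    n_ranks = y_ranked.shape[1]
    hits = y_ranked == y_true[:, None]
    topn = {
        n: float(np.mean(hits[:, :n].any(axis=1)))
        for n in range(1, min(5, n_ranks) + 1)
    }
    return {"accuracy": acc, "weighted_f1": wf1, "confusion": conf, "topn": topn}


def _sample_max_normalize(X: np.ndarray) -> np.ndarray:
    m = X.max(axis=1, keepdims=True)
    m[m == 0] = 1.0
    return X / m


def _build_method(method: str, seed: int, config: dict | None):
    config = dict(config or {})
    if method == "large_bn":
        return ChowLiuBNClassifier(**config)
    if method in ("sntd_pa", "sntd_dcor", "snmf_pa", "snmf_dcor"):
        model = "sntd" if method.startswith("sntd") else "snmf"
        metric = "principal_angle" if method.endswith("_pa") else "dcor"
        config.setdefault("seed", seed)
        return SubspaceClassifier(model=model, metric=metric, **config)
    if method in ("ae_logreg", "ae_gnb"):
        return _AEPipeline(method, seed, config)
    raise ValueError(f"unknown method {method!r}; choose from {METHODS}")


class _AEPipeline:
    """Autoencoder feature extraction + shallow classifier, refit per fold."""

    def __init__(self, method: str, seed: int, config: dict):
        self.method = method
        self.seed = config.pop("seed", seed)
        self.ae_params = {
            k[3:]: config.pop(k) for k in list(config) if k.startswith("ae_")
        }
        self.clf_params = config

    def fit(self, X, y):
        Xn = _sample_max_normalize(np.asarray(X, dtype=float))
        self.ae_ = Autoencoder(seed=self.seed, **self.ae_params).fit(Xn)
        Z = self.ae_.transform(Xn)
        if self.method == "ae_logreg":
            self.clf_ = fit_l1_logreg(Z, y, seed=self.seed, **self.clf_params)
        else:
            self.clf_ = fit_gaussian_nb(Z, y, **self.clf_params)
        self.classes_ = self.clf_.classes_
        return self

    def _encode(self, X):
        return self.ae_.transform(_sample_max_normalize(np.asarray(X, dtype=float)))

    def predict(self, X):
        return self.clf_.predict(self._encode(X))

    def predict_proba(self, X):
        return self.clf_.predict_proba(self._encode(X))

    def predict_ranked(self, X):
        return self.clf_.predict_ranked(self._encode(X))


@dataclass
class EvalReport:
    """Per-run metrics plus the full ranked-prediction store."""

    method: str
    records: pd.DataFrame          # method, repeat, fold, split, metric, value
    ranked: pd.DataFrame           # repeat, fold, split, sample_id, y_true, rank, label
    classes: list = field(default_factory=list)

    def median(self, metric: str = "accuracy", split: str = "test") -> float:
        sel = self.records.query("metric == @metric and split == @split")
        return float(sel["value"].median())

    def topn_table(self, split: str = "test") -> pd.Series:
        """Median Top-N accuracy across runs, N = 1..5."""
        sel = self.records[
            self.records["metric"].str.startswith("top")
            & (self.records["split"] == split)
        ]
        return sel.groupby("metric")["value"].median()

    def ranked_store(self, split: str = "test") -> tuple[np.ndarray, np.ndarray]:
        """(y_true, y_ranked) stacked across all runs for a split."""
        sel = self.ranked[self.ranked["split"] == split]
        wide = sel.pivot_table(
            index=["repeat", "fold", "sample_id", "y_true"],
            columns="rank", values="label", aggfunc="first",
        ).sort_index()
        y_true = wide.index.get_level_values("y_true").to_numpy()
        return y_true, wide.to_numpy()

    def confusion(self, split: str = "test") -> pd.DataFrame:
        y_true, y_ranked = self.ranked_store(split)
        return compute_metrics(y_true, y_ranked, np.asarray(self.classes))["confusion"]

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)


def run_cv(
    dataset: Dataset,
    method: str,
    plan: CVPlan,
    method_config: dict | None = None,
    seed: int = 0,
    eval_train: bool = True,
    max_rank_store: int = 5,
) -> EvalReport:
    """Run one method through the shared CV plan and collect its report.

    Every feature extractor is fitted on the training fold only; test
    samples are scored exactly once per repeat.  Rankings are truncated to
    `max_rank_store` candidates for the store.
    """
    X = dataset.X
    y = dataset.labels()
    if plan.assignment.shape[1] != X.shape[0]:
        raise ValueError("plan was built for a different number of samples")
    rec_rows, rank_rows = [], []
    for r, f, train, test in plan.splits():
        clf = _build_method(method, seed, method_config)
        clf.fit(X[train], y[train])
        splits = [("test", test)] + ([("train", train)] if eval_train else [])
        for split, idx in splits:
            ranked = np.atleast_2d(clf.predict_ranked(X[idx]))
            m = compute_metrics(y[idx], ranked, labels=np.asarray(dataset.classes))
            rows = {"accuracy": m["accuracy"], "weighted_f1": m["weighted_f1"]}
            rows.update({f"top{n}": v for n, v in m["topn"].items()})
            for name, value in rows.items():
                rec_rows.append(dict(method=method, repeat=r, fold=f, split=split,
                                     metric=name, value=value))
            keep = min(max_rank_store, ranked.shape[1])
            for i, si in enumerate(idx):
                for rank in range(keep):
                    rank_rows.append(dict(
                        repeat=r, fold=f, split=split,
                        sample_id=dataset.sample_ids[si], y_true=y[si],
                        rank=rank + 1, label=ranked[i, rank],
                    ))
    return EvalReport(method, pd.DataFrame(rec_rows), pd.DataFrame(rank_rows),
                      classes=dataset.classes)


def neighbor_analysis(y_true: np.ndarray, y_ranked: np.ndarray,
                      n: int = 5) -> dict:
    """Per true class: how often each label lands in the Top-n candidates.

    Returns {class: [(label, count), ...]} with counts sorted descending
    (ties by label), the "most frequent hits" view of classifier confusions.
    """
    y_true = np.asarray(y_true)
    y_ranked = np.atleast_2d(np.asarray(y_ranked))
    if n > y_ranked.shape[1]:
        raise ValueError(f"only {y_ranked.shape[1]} ranks stored, asked for top {n}")
    out = {}
    for cls in np.unique(y_true):
        hits = y_ranked[y_true == cls, :n].ravel()
        labels, counts = np.unique(hits, return_counts=True)
        order = np.lexsort((labels, -counts))
        out[cls] = [(labels[i], int(counts[i])) for i in order]
    return out


def variable_importance_curve(
    ae: Autoencoder,
    dataset: Dataset,
    order: str = "descending",
    step_sizes: list[int] | None = None,
    seed: int = 0,
    test_size: float = 0.2,
    strength: float = 1.0,
) -> pd.DataFrame:
    """Held-out accuracy of l1 logistic regression on growing variable sets.

    Variables are ranked by the Euclidean norm of their first-layer
    autoencoder weight column ('descending' puts the heaviest first); for
    each prefix size a logistic regression is trained on the raw
    (unencoded) prefix variables and scored on a stratified held-out split.
    """
    if order not in ("descending", "ascending"):
        raise ValueError("order must be 'descending' or 'ascending'")
    X = dataset.X
    if dataset.normalize == "none":
        X = _sample_max_normalize(X)
    y = dataset.labels()
    d = X.shape[1]
    importance = ae.first_layer_importance()
    if importance.size != d:
        raise ValueError("autoencoder was trained on a different feature layout")
    ranking = np.argsort(-importance, kind="stable")
    if order == "ascending":
        ranking = ranking[::-1]
    if step_sizes is None:
        step_sizes = [d // 20, d // 10, d // 4, d // 2, d]
    steps = []
    for s in step_sizes:
        if s > d:
            warnings.warn(f"step size {s} exceeds {d} variables; clipped")
            s = d
        steps.append(max(1, s))
    tr, te = train_test_split(
        np.arange(X.shape[0]), test_size=test_size, stratify=y, random_state=seed
    )
    rows = []
    for s in steps:
        cols = ranking[:s]
        clf = fit_l1_logreg(X[np.ix_(tr, cols)], y[tr], strength=strength, seed=seed)
        acc = float(np.mean(clf.predict(X[np.ix_(te, cols)]) == y[te]))
        rows.append({"n_variables": s, "accuracy": acc})
    return pd.DataFrame(rows)
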
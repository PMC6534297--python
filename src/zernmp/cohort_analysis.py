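"""Group classification of Zernike coefficient vectors.

Four binary hypotheses are tested on the three-group cohort (1: under 50 no
AMD, 2: 50+ no AMD, 3: 50+ AMD): disease regardless of age (1&2 vs 3),
disease in the age-matched groups (2 vs 3), age regardless of disease
(1 vs 2&3), and age without disease (1 vs 2).  Two classifiers mirror the
study protocol: shrinkage LDA evaluated with leave-one-out, and a
feedforward pattern-recognition network evaluated over repeated random
train/validation/test splits.  Classifier and hyperparameter selection uses
the ROC operating point closest to perfect classification.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

logger = logging.getLogger(__name__)

#: The four binary tests: name -> (negative-class groups, positive-class groups).
#: The positive class is the later-listed side of each test.
TESTS = {
    "12v3": ((1, 2), (3,)),
    "2v3": ((2,), (3,)),
    "1v23": ((1,), (2, 3)),
    "1v2": ((1,), (2,)),
}
_TEST_ALIASES = {"1&2v3": "12v3", "1v2&3": "1v23", "1&2vs3": "12v3",
                 "2vs3": "2v3", "1vs2&3": "1v23", "1vs2": "1v2"}

DEFAULT_SPLIT_FRACTIONS = (0.70, 0.15, 0.15)


def canonical_test(name: str) -> str:
    name = name.replace(" ", "").lower()
    name = _TEST_ALIASES.get(name, name)
    if name not in TESTS:
        raise ValueError(f"unknown test {name!r}; expected one of {list(TESTS)}")
    return name


@dataclass
class LabelledDataset:
    """Coefficient feature matrix with group labels and subject ids."""

    X: np.ndarray
    groups: np.ndarray
    subjects: np.ndarray
    centring: str = "not_centred"

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.groups = np.asarray(self.groups, dtype=int)
        self.subjects = np.asarray(self.subjects)
        if self.X.ndim != 2 or len(self.X) != len(self.groups):
            raise ValueError("feature matrix and labels are inconsistent")
        if np.any(~np.isfinite(self.X)):
            raise ValueError("features contain non-finite values")

    def binary(self, test: str):
        """Select samples for one test; returns (X, y) with y=1 positive."""
        neg, pos = TESTS[canonical_test(test)]
        sel = np.isin(self.groups, neg + pos)
        y = np.isin(self.groups[sel], pos).astype(int)
        return self.X[sel], y, self.subjects[sel]


@dataclass
class ClassificationReport:
    """Accuracy / sensitivity / specificity with confusion counts."""

    accuracy: float
    sensitivity: float
    specificity: float
    tp: int
    tn: int
    fp: int
    fn: int
    positive_class: str = "later-listed group(s)"
    extra: dict = dc_field(default_factory=dict)

    @classmethod
    def from_predictions(cls, y_true, y_pred, **extra) -> "ClassificationReport":
        y_true = np.asarray(y_true, int)
        y_pred = np.asarray(y_pred, int)
        tp = int(np.sum((y_true == 1) & (y_pred == 1)))
        tn = int(np.sum((y_true == 0) & (y_pred == 0)))
        fp = int(np.sum((y_true == 0) & (y_pred == 1)))
        fn = int(np.sum((y_true == 1) & (y_pred == 0)))
        n = len(y_true)
        return cls(accuracy=(tp + tn) / n,
                   sensitivity=tp / (tp + fn) if tp + fn else np.nan,
                   specificity=tn / (tn + fp) if tn + fp else np.nan,
                   tp=tp, tn=tn, fp=fp, fn=fn, extra=extra)

    def to_dict(self) -> dict:
        return {"accuracy": self.accuracy, "sensitivity": self.sensitivity,
                "specificity": self.specificity,
                "confusion": {"tp": self.tp, "tn": self.tn,
                              "fp": self.fp, "fn": self.fn},
                "positive_class": self.positive_class, **self.extra}


def _make_lda() -> LinearDiscriminantAnalysis:
    # lsqr + Ledoit-Wolf shrinkage: the within-class covariance of ~100
    # correlated coefficients over a few hundred samples is ill-conditioned.
    return LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")


def _check_class_sizes(y: np.ndarray, minimum: int = 2) -> None:
    for cls_ in np.unique(y):
        if np.sum(y == cls_) < minimum:
            raise ValueError(f"class {cls_} has fewer than {minimum} samples")


def lda_loo(dataset: LabelledDataset, test: str,
            feature_indices=None, subject_level: bool = False
            ) -> ClassificationReport:
    """Leave-one-out LDA classification for one binary test.

    Each sample is classified by a shrinkage-LDA model trained on all other
    samples.  With ``subject_level=True`` all images of the held-out
    subject leave together (prevents subject leakage when subjects
    contribute multiple images); the default leaves out single images.
    Deterministic.
    """
    X, y, subjects = dataset.binary(test)
    if feature_indices is not None:
        X = X[:, np.asarray(feature_indices, int)]
    _check_class_sizes(y)
    y_pred = np.empty_like(y)
    if subject_level:
        units = pd.unique(subjects)
        folds = [np.flatnonzero(subjects == u) for u in units]
    else:
        folds = [np.array([i]) for i in range(len(y))]
    for held in folds:
        train = np.setdiff1d(np.arange(len(y)), held)
        model = _make_lda().fit(X[train], y[train])
        y_pred[held] = model.predict(X[held])
    rep = ClassificationReport.from_predictions(
        y_true=y, y_pred=y_pred, test=canonical_test(test),
        classifier="lda_loo", n=len(y),
        loo_unit="subject" if subject_level else "image")
    rep.positive_class = "group(s) " + "&".join(
        map(str, TESTS[canonical_test(test)][1]))
    return rep


def lda_loo_topk(dataset: LabelledDataset, test: str, ranked_indices,
                 k: int, **kw) -> ClassificationReport:
    """LOO-LDA restricted to the first ``k`` ranked coefficients."""
    ranked = np.asarray(ranked_indices, int)
    if k > len(ranked):
        raise ValueError(f"k={k} exceeds ranking length {len(ranked)}")
    return lda_loo(dataset, test, feature_indices=ranked[:k], **kw)


def _three_way_split(rng, y, fractions):
    """Stratified-ish random train/val/test split; resamples degenerate ones."""
    n = len(y)
    for _ in range(100):
        perm = rng.permutation(n)
        n_train = int(round(fractions[0] * n))
        n_val = int(round(fractions[1] * n))
        train = perm[:n_train]
        val = perm[n_train:n_train + n_val]
        test = perm[n_train + n_val:]
        if (len(test) > 0 and len(np.unique(y[train])) == 2
                and len(np.unique(y[test])) == 2):
            return train, val, test
        logger.info("degenerate split resampled")
    raise RuntimeError("could not draw a non-degenerate split")


def prnn_repeated(dataset: LabelledDataset, test: str,
                  hidden_neurons: int = 100, n_repeats: int = 100,
                  split_fractions=DEFAULT_SPLIT_FRACTIONS,
                  solver: str = "lbfgs", max_iter: int = 300,
                  seed: int | None = None) -> ClassificationReport:
    """Pattern-recognition feedforward network over repeated random splits.

    A single-hidden-layer network (standardised inputs, ReLU) is trained per
    repeat on a random train/validation/test partition (default 70/15/15).
    With the default full-batch ``lbfgs`` solver the validation part is
    simply held out; with a stochastic solver (``adam``/``sgd``) it drives
    early stopping.  The returned report holds the mean triple over
    repeats, with the best (accuracy-maximal) triple under ``extra``.
    Reproducible per seed.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be at least 1")
    X, y, _ = dataset.binary(test)
    _check_class_sizes(y)
    rng = np.random.default_rng(seed)
    triples = []
    for r in range(n_repeats):
        train, val, test_idx = _three_way_split(rng, y, split_fractions)
        stochastic = solver in ("adam", "sgd")
        fit_idx = np.concatenate([train, val]) if stochastic else train
        val_fraction = len(val) / max(len(fit_idx), 1)
        mlp_kw = dict(hidden_layer_sizes=(hidden_neurons,),
                      activation="relu", solver=solver, max_iter=max_iter,
                      random_state=int(rng.integers(2 ** 31)))
        if stochastic:
            mlp_kw.update(early_stopping=True,
                          validation_fraction=max(val_fraction, 0.1),
                          learning_rate_init=0.01, n_iter_no_change=20)
        model = make_pipeline(StandardScaler(), MLPClassifier(**mlp_kw))
        model.fit(X[fit_idx], y[fit_idx])
        rep = ClassificationReport.from_predictions(y[test_idx],
                                                    model.predict(X[test_idx]))
        triples.append((rep.accuracy, rep.sensitivity, rep.specificity))
    arr = np.asarray(triples, dtype=float)
    mean = np.nanmean(arr, axis=0)
    best = arr[int(np.argmax(arr[:, 0]))]
    rep = ClassificationReport(
        accuracy=float(mean[0]), sensitivity=float(mean[1]),
        specificity=float(mean[2]), tp=-1, tn=-1, fp=-1, fn=-1,
        extra={"best": {"accuracy": float(best[0]),
                        "sensitivity": float(best[1]),
                        "specificity": float(best[2])},
               "n_repeats": n_repeats, "classifier": "prnn",
               "hidden_neurons": hidden_neurons,
               "test": canonical_test(test)})
    rep.positive_class = "group(s) " + "&".join(
        map(str, TESTS[canonical_test(test)][1]))
    return rep


def roc_select(candidates):
    """Pick the candidate whose ROC point is closest to perfect (1, 1).

    ``candidates`` is a sequence of dicts with at least ``sensitivity`` and
    ``specificity``; distance is ``sqrt((1-sens)^2 + (1-spec)^2)``.  Ties
    break to higher ``accuracy`` then to smaller ``model_size`` where given.
    """
    candidates = [c for c in candidates
                  if np.isfinite(c["sensitivity"]) and
                  np.isfinite(c["specificity"])]
    if not candidates:
        raise ValueError("no candidates to select from")

    def sort_key(c):
        d = np.hypot(1.0 - c["sensitivity"], 1.0 - c["specificity"])
        return (round(float(d), 12), -c.get("accuracy", 0.0),
                c.get("model_size", 0))

    return min(candidates, key=sort_key)


_MODEL_FAMILIES = {
    "knn": lambda p, seed: KNeighborsClassifier(**p),
    "svm": lambda p, seed: SVC(random_state=seed, **p),
    "softmax_net": lambda p, seed: LogisticRegression(
        max_iter=2000, random_state=seed, **p),
    "prnn": lambda p, seed: make_pipeline(
        StandardScaler(),
        MLPClassifier(
            max_iter=300, random_state=seed, learning_rate_init=0.01,
            **{("hidden_layer_sizes" if k == "hidden_neurons" else k):
               ((v,) if k == "hidden_neurons" else v) for k, v in p.items()})),
    "lda": lambda p, seed: LinearDiscriminantAnalysis(
        solver="lsqr", shrinkage="auto", **p),
}


def hyperparameter_search(dataset: LabelledDataset, test: str,
                          model_family: str, grid,
                          n_folds: int = 5, seed: int | None = None):
    """Exhaustive grid search scored by the ROC operating point.

    Every parameter combination is evaluated by seeded stratified k-fold
    cross-validation; the winner is chosen with :func:`roc_select`.
    Returns ``(best_params, results)`` where ``results`` is the full
    evaluation table (one row per grid point).
    """
    if model_family not in _MODEL_FAMILIES:
        raise ValueError(f"unknown model family {model_family!r}")
    grid = list(grid)
    if not grid:
        raise ValueError("empty hyperparameter grid")
    X, y, _ = dataset.binary(test)
    _check_class_sizes(y, minimum=n_folds)
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    rows = []
    for params in grid:
        y_pred = np.empty_like(y)
        try:
            for train, held in cv.split(X, y):
                model = _MODEL_FAMILIES[model_family](dict(params), seed)
                model.fit(X[train], y[train])
                y_pred[held] = model.predict(X[held])
        except ValueError as exc:  # infeasible configuration for this data
            logger.warning("grid point %s failed: %s", params, exc)
            rows.append({"params": dict(params), "model_size": np.inf,
                         "accuracy": np.nan, "sensitivity": np.nan,
                         "specificity": np.nan})
            continue
        rep = ClassificationReport.from_predictions(y, y_pred)
        rows.append({"params": dict(params),
                     "model_size": sum(v for v in params.values()
                                       if isinstance(v, (int, float))),
                     "accuracy": rep.accuracy,
                     "sensitivity": rep.sensitivity,
                     "specificity": rep.specificity})
    best = roc_select(rows)
    return best["params"], pd.DataFrame(rows)
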
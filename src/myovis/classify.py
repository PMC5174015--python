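"""Classifier evaluation under the repeated stratified hold-out protocol.

Three classifier families are evaluated on the selected features: k-nearest
neighbors, a multilayer perceptron, and a radial-basis SVM.  For each test
fraction the data are repeatedly split (stratified), features standardized
on the training portion only, any tuned hyperparameter chosen by 5-fold
cross-validation on the training portion, and the four report metrics
computed on the held-out portion; means and standard deviations are taken
over the repeats.

Report metrics (percent): specificity (correct normal / total normal),
sensitivity for neuropathy and for myopathy (class-conditional correct
rates), and total accuracy (trace of the confusion matrix / grand total).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import GridSearchCV, StratifiedKFold, train_test_split
from sklearn.multiclass import OneVsRestClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .io import FeatureMatrix

#: serialized class coding
CLASS_CODES = {"normal": 0, "neuropathy": 1, "myopathy": 2}
CLASS_ORDER = ["normal", "neuropathy", "myopathy"]

CLASSIFIER_NAMES = ("knn", "mlpnn", "svm")
METRIC_NAMES = ("specificity", "sensitivity_neuropathy", "sensitivity_myopathy",
                "total_accuracy")

DEFAULT_TEST_FRACTIONS = (0.20, 0.40, 0.50, 0.60, 0.80)

DEFAULT_HYPERPARAMS = {
    "knn": {"n_neighbors": 3},
    # full-batch quasi-Newton: at a few hundred epochs per study the
    # stochastic solvers stop on tiny validation splits long before the
    # loss has moved
    "mlpnn": {"hidden_layer_sizes": (10,), "activation": "logistic",
              "solver": "lbfgs", "max_iter": 500},
    "svm": {"C": 1.0},
}


@dataclass(frozen=True)
class SplitProtocol:
    """Evaluation protocol: stratified hold-out fractions, 5 folds, repeats."""

    test_fractions: tuple = DEFAULT_TEST_FRACTIONS
    folds: int = 5
    repeats: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        for f in self.test_fractions:
            if not 0 < f < 1:
                raise ValueError("test fractions must lie in (0, 1)")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")


def confusion_metrics(cm: np.ndarray) -> dict[str, float]:
    """The four report metrics (percent) from a 3x3 true-by-predicted matrix.

    Rows follow the class order normal, neuropathy, myopathy.
    """
    cm = np.asarray(cm, dtype=float)
    if cm.shape != (3, 3) or (cm < 0).any():
        raise ValueError("need a 3x3 matrix of non-negative counts")
    totals = cm.sum(axis=1)
    for name, tot in zip(CLASS_ORDER, totals):
        if tot == 0:
            raise ValueError(f"no true instances of class {name!r}")
    return {
        "specificity": 100.0 * cm[0, 0] / totals[0],
        "sensitivity_neuropathy": 100.0 * cm[1, 1] / totals[1],
        "sensitivity_myopathy": 100.0 * cm[2, 2] / totals[2],
        "total_accuracy": 100.0 * np.trace(cm) / cm.sum(),
    }


def median_heuristic_gamma(X: np.ndarray) -> float:
    """RBF kernel width gamma = 1 / (2 m^2), m the median pairwise distance."""
    d = pdist(np.asarray(X, dtype=float))
    d = d[d > 0]
    if d.size == 0:
        return 1.0
    m = float(np.median(d))
    return 1.0 / (2.0 * m * m)


def make_classifier(name: str, seed: int = 0, X_train: np.ndarray | None = None,
                    **overrides):
    """Instantiate one of the three classifier families with its defaults.

    The SVM's kernel width comes from the median heuristic on the
    (standardized) training features, so ``X_train`` should be supplied for
    ``svm``.  Any keyword overrides the defaults.
    """
    if name == "knn":
        params = DEFAULT_HYPERPARAMS["knn"] | overrides
        return KNeighborsClassifier(metric="euclidean", **params)
    if name == "mlpnn":
        params = DEFAULT_HYPERPARAMS["mlpnn"] | overrides
        return MLPClassifier(random_state=seed, **params)
    if name == "svm":
        params = DEFAULT_HYPERPARAMS["svm"] | overrides
        gamma = params.pop("gamma", None)
        if gamma is None:
            gamma = median_heuristic_gamma(X_train) if X_train is not None else "scale"
        return OneVsRestClassifier(SVC(kernel="rbf", gamma=gamma, **params))
    raise ValueError(f"unknown classifier {name!r}; expected one of {CLASSIFIER_NAMES}")


@dataclass
class ClassificationReport:
    """Per-classifier, per-fraction metric means and standard deviations."""

    table: pd.DataFrame          # columns: classifier, test_fraction, metric, mean, sd
    protocol: SplitProtocol

    def mean(self, classifier: str, test_fraction: float, metric: str) -> float:
        t = self.table
        row = t[(t.classifier == classifier)
                & np.isclose(t.test_fraction, test_fraction)
                & (t.metric == metric)]
        return float(row["mean"].iloc[0])

    def to_wide(self) -> pd.DataFrame:
        """Layout with one row per (fraction, metric) and one column per
        classifier, each cell ``mean ± sd``."""
        t = self.table.copy()
        t["cell"] = t.apply(lambda r: f"{r['mean']:.2f} ± {r['sd']:.2f}", axis=1)
        wide = t.pivot_table(index=["test_fraction", "metric"],
                             columns="classifier", values="cell",
                             aggfunc="first")
        return wide.reindex(columns=[c for c in CLASSIFIER_NAMES if c in wide.columns])

    def to_dict(self) -> dict:
        out: dict = {"repeats": self.protocol.repeats, "seed": self.protocol.seed}
        for (clf, frac), grp in self.table.groupby(["classifier", "test_fraction"]):
            key = f"{clf}@test={frac:g}"
            out[key] = {r.metric: {"mean": round(float(r.mean), 4),
                                   "sd": round(float(r.sd), 4)}
                        for r in grp.itertuples()}
        return out


def run_protocol(fm: FeatureMatrix | tuple, protocol: SplitProtocol | None = None,
                 classifiers=CLASSIFIER_NAMES,
                 hyperparams: dict | None = None,
                 param_grids: dict | None = None) -> ClassificationReport:
    """Evaluate the classifiers under the repeated hold-out protocol.

    ``fm`` is a :class:`~myovis.io.FeatureMatrix` with labels, or an
    ``(X, y)`` pair.  ``hyperparams`` holds fixed per-classifier overrides;
    ``param_grids`` optionally maps a classifier name to a grid searched by
    5-fold stratified CV on each training portion.  Identical protocol seeds
    give bitwise-identical reports.
    """
    protocol = protocol or SplitProtocol()
    if isinstance(fm, FeatureMatrix):
        if fm.labels is None:
            raise ValueError("feature matrix carries no class labels")
        X, y = fm.X, np.asarray([CLASS_CODES.get(l, l) for l in fm.labels])
    else:
        X, y = fm
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
    _, counts = np.unique(y, return_counts=True)
    hyperparams = hyperparams or {}
    param_grids = param_grids or {}

    rows = []
    for clf_name in classifiers:
        for frac in protocol.test_fractions:
            if (counts * min(frac, 1 - frac)).min() < 1:
                raise ValueError(
                    f"a class is too small for stratified splitting at "
                    f"test fraction {frac}")
            per_repeat = {m: [] for m in METRIC_NAMES}
            child_seeds = np.random.SeedSequence(
                [protocol.seed, int(round(frac * 100))]
            ).generate_state(protocol.repeats) % (2 ** 31)
            for rep_seed in child_seeds:
                rep_seed = int(rep_seed)
                X_tr, X_te, y_tr, y_te = train_test_split(
                    X, y, test_size=frac, stratify=y, random_state=rep_seed)
                scaler = StandardScaler().fit(X_tr)
                X_tr_s, X_te_s = scaler.transform(X_tr), scaler.transform(X_te)
                clf = make_classifier(clf_name, seed=rep_seed, X_train=X_tr_s,
                                      **hyperparams.get(clf_name, {}))
                if clf_name in param_grids:
                    cv = StratifiedKFold(n_splits=protocol.folds, shuffle=True,
                                         random_state=rep_seed)
                    clf = GridSearchCV(clf, param_grids[clf_name], cv=cv)
                clf.fit(X_tr_s, y_tr)
                cm = confusion_matrix(y_te, clf.predict(X_te_s), labels=[0, 1, 2])
                for m, v in confusion_metrics(cm).items():
                    per_repeat[m].append(v)
            for m in METRIC_NAMES:
                vals = np.asarray(per_repeat[m])
                rows.append({"classifier": clf_name, "test_fraction": frac,
                             "metric": m, "mean": float(vals.mean()),
                             "sd": float(vals.std(ddof=1)) if vals.size > 1 else 0.0})
    return ClassificationReport(table=pd.DataFrame(rows), protocol=protocol)
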
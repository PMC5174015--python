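"""Feature-matrix assembly and one-way ANOVA feature selection.

Candidate features are the per-epoch network measures; the effective subset
is chosen by a one-way fixed-effects ANOVA across the three diagnostic
groups, keeping features with p below a significance level (default 0.001).
No multiple-testing correction is applied by default, matching per-feature
reporting; Bonferroni across the candidates is available as an option.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted, validate_data

from .io import FeatureMatrix
from .measures import MEASURE_NAMES

log = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.001

#: the six measures that separate the three diagnostic groups
DEFAULT_FEATURES = ["AD", "ACC", "Den", "AW", "skewness", "kurtosis"]


def default_feature_set() -> list[str]:
    """The six effective features, in canonical order."""
    return list(DEFAULT_FEATURES)


def assemble(measure_records, feature_names: list[str] | None = None,
             epoch_ids: list[str] | None = None,
             labels: list | None = None) -> FeatureMatrix:
    """Stack per-epoch measure records into an M-features x N-epochs matrix.

    ``measure_records`` is a DataFrame (one row per epoch) or a list of
    dicts.  Epochs with an undefined (NaN) value in any requested feature
    are dropped; the drop count is logged and stored on the result.
    """
    df = pd.DataFrame(measure_records)
    names = list(feature_names) if feature_names is not None else [
        c for c in df.columns if c in MEASURE_NAMES]
    missing = [nm for nm in names if nm not in df.columns]
    if missing:
        raise KeyError(f"requested feature(s) not in records: {missing}")
    if epoch_ids is None:
        epoch_ids = [f"epoch-{i}" for i in range(len(df))]
    values = df[names].to_numpy(dtype=float)
    keep = ~np.isnan(values).any(axis=1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        log.warning("dropped %d epoch(s) with undefined measures", n_dropped)
    if not keep.any():
        raise ValueError("no usable epochs after dropping undefined measures")
    kept_labels = ([lab for lab, k in zip(labels, keep) if k]
                   if labels is not None else None)
    return FeatureMatrix(
        values=values[keep].T,
        feature_names=names,
        epoch_ids=[eid for eid, k in zip(epoch_ids, keep) if k],
        labels=kept_labels,
        n_dropped=n_dropped,
    )


@dataclass
class AnovaResult:
    """Per-feature F statistics, p values and the selected mask."""

    feature_names: list[str]
    f_statistic: np.ndarray
    p_values: np.ndarray
    selected: np.ndarray
    alpha: float

    def selected_names(self) -> list[str]:
        return [nm for nm, s in zip(self.feature_names, self.selected) if s]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "feature": self.feature_names,
            "F": self.f_statistic,
            "p": self.p_values,
            "selected": self.selected,
        })


def anova_select(fm: FeatureMatrix, alpha: float = DEFAULT_ALPHA,
                 bonferroni: bool = False) -> AnovaResult:
    """One-way fixed-effects ANOVA of each feature across the class groups.

    A feature is selected when its p value is below ``alpha`` (divided by
    the number of candidates when ``bonferroni`` is set).  Features that are
    constant within every group have an undefined F and are rejected with a
    warning.
    """
    if fm.labels is None:
        raise ValueError("feature matrix carries no class labels")
    selector = AnovaFeatureSelector(alpha=alpha, bonferroni=bonferroni)
    selector.fit(fm.X, np.asarray(fm.labels))
    return AnovaResult(
        feature_names=list(fm.feature_names),
        f_statistic=selector.f_statistic_,
        p_values=selector.p_values_,
        selected=selector.get_support(),
        alpha=alpha,
    )


class AnovaFeatureSelector(SelectorMixin, BaseEstimator):
    """Select features whose one-way ANOVA p value falls below ``alpha``.

    A scikit-learn selector: ``fit(X, y)`` on an (n_samples, n_features)
    matrix with class labels ``y``; ``transform`` keeps the selected
    columns.  Fitted attributes: ``f_statistic_``, ``p_values_``,
    ``support_``.
    """

    def __init__(self, alpha: float = DEFAULT_ALPHA, bonferroni: bool = False):
        self.alpha = alpha
        self.bonferroni = bonferroni

    def fit(self, X, y):
        X = validate_data(self, X, ensure_min_samples=4)
        y = np.asarray(y)
        if y.shape[0] != X.shape[0]:
            raise ValueError("X and y have incompatible lengths")
        classes, counts = np.unique(y, return_counts=True)
        if classes.size < 2:
            raise ValueError("ANOVA needs at least 2 classes")
        for cls, cnt in zip(classes, counts):
            if cnt < 2:
                raise ValueError(f"class {cls!r} has fewer than 2 epochs")
        groups_by_feature = lambda j: [X[y == cls, j] for cls in classes]
        n_feat = X.shape[1]
        F = np.full(n_feat, np.nan)
        p = np.full(n_feat, np.nan)
        for j in range(n_feat):
            groups = groups_by_feature(j)
            if all(np.ptp(g) == 0 for g in groups) and np.ptp(X[:, j]) == 0:
                warnings.warn(
                    f"feature column {j} is constant in all groups; "
                    "F undefined, feature rejected", UserWarning)
                continue
            with np.errstate(invalid="ignore", divide="ignore"):
                F[j], p[j] = stats.f_oneway(*groups)
        threshold = self.alpha / n_feat if self.bonferroni else self.alpha
        self.f_statistic_ = F
        self.p_values_ = p
        self.support_ = np.nan_to_num(p, nan=1.0) < threshold
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_
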
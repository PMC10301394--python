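"""Clean-vs-noisy evaluation protocol.

Binary classification between clean and noisy epochs (okay epochs are
excluded) with a logistic-regression classifier under leave-P-subjects-out
cross-validation: every size-P subset of subjects serves once as the test
set, so no subject contributes to both halves of a split. Per split,
feature standardization, missing-value imputation and mRMR top-k feature
selection are fit on the training subjects only.

Figures of merit: sensitivity, specificity, balanced accuracy
(BACC = (Sens + Spec)/2) and F1, with the noisy class as positive.
Separability of individual SQIs is ranked by AUCtrans — the rank-based AUC
folded about 0.5 so both directions of separation score in [0.5, 1].

:class:`MRMRSelector` is a scikit-learn compatible transformer implementing
greedy minimum-redundancy maximum-relevance selection with the MID
(mutual-information difference) criterion over equal-frequency-binned
features.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import mutual_info_score, roc_auc_score
from sklearn.utils.validation import check_is_fitted, validate_data

from .benchmark import FEATURE_FAMILIES, SQI_NAMES

__all__ = [
    "SplitPlan",
    "MetricSet",
    "SeparabilityEntry",
    "FeatureImportance",
    "WavelengthResult",
    "make_split_plan",
    "confusion_metrics",
    "auc_separability",
    "MRMRSelector",
    "mrmr_select",
    "run_within_wavelength",
    "run_cross_wavelength",
]

POSITIVE_LABEL = "noisy"
NEGATIVE_LABEL = "clean"


@dataclass(frozen=True)
class SplitPlan:
    iterations: list[tuple[tuple[str, ...], tuple[str, ...]]]
    p_out: int

    def __len__(self) -> int:
        return len(self.iterations)


@dataclass(frozen=True)
class MetricSet:
    """Confusion counts and the derived figures of merit."""

    tp: int
    fp: int
    tn: int
    fn: int
    sens: float
    spec: float
    bacc: float
    f1: float


@dataclass(frozen=True)
class SeparabilityEntry:
    sqi_name: str
    auc: float
    auc_trans: float
    direction: str  # which class scores higher


@dataclass(frozen=True)
class FeatureImportance:
    sqi_name: str
    freq_top: float  # % of iterations in the selected top set
    mean_weight: float  # mean |standardized coefficient| when selected


@dataclass
class WavelengthResult:
    wavelength: str
    per_split: list[MetricSet]
    summary: dict[str, tuple[float, float]]  # metric -> (mean, sd)
    importances: list[FeatureImportance]
    n_excluded_folds: int = 0
    feature_pool: list[str] = field(default_factory=list)


def make_split_plan(subject_ids: Sequence[str], p_out: int = 3) -> SplitPlan:
    """Leave-P-subjects-out plan: one iteration per size-P subject subset.

    Iterations are ordered lexicographically over the sorted subject ids,
    so the plan is deterministic. With 8 subjects and P=3 this yields
    C(8,3) = 56 iterations.
    """
    subjects = tuple(sorted(set(subject_ids)))
    if p_out >= len(subjects):
        raise ValueError(
            f"p_out={p_out} must be smaller than the number of subjects "
            f"({len(subjects)})"
        )
    iterations = [
        (tuple(s for s in subjects if s not in test), test)
        for test in combinations(subjects, p_out)
    ]
    return SplitPlan(iterations=iterations, p_out=p_out)


def confusion_metrics(predictions, labels, positive=POSITIVE_LABEL) -> MetricSet:
    """Sens/Spec/BACC/F1 from a prediction vector, noisy as positive class.

    Sens = TP/(TP+FN), Spec = TN/(TN+FP), BACC = (Sens+Spec)/2,
    F1 = 2TP/(2TP+FP+FN). A zero denominator flags the metric as NaN.
    """
    pred = np.asarray(predictions) == positive
    true = np.asarray(labels) == positive
    tp = int(np.count_nonzero(pred & true))
    fp = int(np.count_nonzero(pred & ~true))
    tn = int(np.count_nonzero(~pred & ~true))
    fn = int(np.count_nonzero(~pred & true))
    sens = tp / (tp + fn) if tp + fn else math.nan
    spec = tn / (tn + fp) if tn + fp else math.nan
    bacc = (sens + spec) / 2
    f1 = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else math.nan
    return MetricSet(tp, fp, tn, fn, sens, spec, bacc, f1)


def auc_separability(
    features: pd.DataFrame, labels: Sequence[str]
) -> list[SeparabilityEntry]:
    """Rank-based AUC of each SQI for noisy vs. clean, sorted by AUCtrans.

    AUC is computed with the noisy class as positive; values <= 0.5 are
    folded as AUCtrans = 1 - AUC so both directions of separation are
    comparable. Rows with NaN feature values are dropped per feature.
    """
    y = np.asarray(labels) == POSITIVE_LABEL
    if y.all() or not y.any():
        raise ValueError("both clean and noisy epochs are required")
    entries = []
    for name in features.columns:
        x = np.asarray(features[name], dtype=float)
        ok = np.isfinite(x)
        if y[ok].all() or not y[ok].any():
            continue
        auc = float(roc_auc_score(y[ok], x[ok]))
        auc_trans = auc if auc > 0.5 else 1.0 - auc
        entries.append(
            SeparabilityEntry(
                sqi_name=name,
                auc=auc,
                auc_trans=auc_trans,
                direction=POSITIVE_LABEL if auc > 0.5 else NEGATIVE_LABEL,
            )
        )
    entries.sort(key=lambda e: e.auc_trans, reverse=True)
    return entries


def _equal_frequency_bins(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Discretize to equal-frequency bins (degenerate edges collapsed)."""
    qs = np.quantile(x, np.linspace(0, 1, n_bins + 1)[1:-1])
    return np.searchsorted(np.unique(qs), x)


class MRMRSelector(SelectorMixin, BaseEstimator):
    """Greedy minimum-redundancy maximum-relevance feature selection.

    Features and labels are discretized (labels are assumed categorical;
    features are binned into ``n_bins`` equal-frequency bins) and mutual
    information is estimated from the contingency tables. The first feature
    maximizes MI(feature; label); each subsequent feature maximizes the MID
    criterion MI(f; label) - mean MI(f; selected) (or the MIQ quotient
    variant). Deterministic: ties resolve to the lowest column index.

    Attributes
    ----------
    selected_idx_ : list of int
        Column indices in greedy selection order.
    relevance_ : ndarray
        MI(feature; label) per column.
    n_features_in_, feature_names_in_ : see scikit-learn conventions.
    """

    def __init__(self, k: int = 3, n_bins: int = 5, scheme: str = "MID"):
        self.k = k
        self.n_bins = n_bins
        self.scheme = scheme

    def fit(self, X, y):
        X = validate_data(self, X, ensure_min_features=1, dtype=float)
        y = np.asarray(y)
        n_features = X.shape[1]
        if self.k > n_features:
            raise ValueError(f"k={self.k} exceeds feature count {n_features}")
        if self.scheme not in ("MID", "MIQ"):
            raise ValueError(f"scheme must be 'MID' or 'MIQ', got {self.scheme!r}")

        binned = [_equal_frequency_bins(X[:, j], self.n_bins) for j in range(n_features)]
        relevance = np.array([mutual_info_score(b, y) for b in binned])

        selected: list[int] = [int(np.argmax(relevance))]
        redundancy = np.zeros(n_features)
        pair_mi_cache: dict[tuple[int, int], float] = {}

        def pair_mi(i: int, j: int) -> float:
            key = (min(i, j), max(i, j))
            if key not in pair_mi_cache:
                pair_mi_cache[key] = mutual_info_score(binned[i], binned[j])
            return pair_mi_cache[key]

        while len(selected) < self.k:
            last = selected[-1]
            for j in range(n_features):
                if j not in selected:
                    redundancy[j] += pair_mi(j, last)
            best_j, best_score = None, -np.inf
            for j in range(n_features):
                if j in selected:
                    continue
                mean_red = redundancy[j] / len(selected)
                if self.scheme == "MID":
                    score = relevance[j] - mean_red
                else:
                    score = relevance[j] / max(mean_red, 1e-12)
                if score > best_score + 1e-15:
                    best_j, best_score = j, score
            selected.append(int(best_j))

        self.selected_idx_ = selected
        self.relevance_ = relevance
        return self

    def _get_support_mask(self):
        check_is_fitted(self)
        mask = np.zeros(self.n_features_in_, dtype=bool)
        mask[self.selected_idx_] = True
        return mask

    @property
    def selected_names_(self) -> list[str]:
        check_is_fitted(self)
        names = getattr(self, "feature_names_in_", None)
        if names is None:
            return [str(j) for j in self.selected_idx_]
        return [str(names[j]) for j in self.selected_idx_]


def mrmr_select(features: pd.DataFrame, labels, k: int = 3, **kwargs) -> list[str]:
    """Greedy mRMR column names in selection order (thin wrapper)."""
    sel = MRMRSelector(k=k, **kwargs).fit(features, np.asarray(labels))
    return sel.selected_names_


# ---------------------------------------------------------------------------
# protocol runners


def _binary_table(table: pd.DataFrame, wavelength: str | None) -> pd.DataFrame:
    sub = table if wavelength is None else table[table["wavelength"] == wavelength]
    return sub[sub["label"].isin([NEGATIVE_LABEL, POSITIVE_LABEL])].reset_index(
        drop=True
    )


def _fit_and_score(
    train: pd.DataFrame,
    test: pd.DataFrame,
    feature_pool: list[str],
    k: int,
    C: float,
) -> tuple[MetricSet, list[str], np.ndarray]:
    """Impute/standardize/select/fit on train, score on test."""
    X_train = train[feature_pool].astype(float)
    X_test = test[feature_pool].astype(float)
    medians = X_train.median()
    X_train = X_train.fillna(medians)
    X_test = X_test.fillna(medians)
    mu, sd = X_train.mean(), X_train.std(ddof=0).replace(0.0, 1.0)
    X_train = (X_train - mu) / sd
    X_test = (X_test - mu) / sd

    k_eff = min(k, len(feature_pool))
    names = mrmr_select(X_train, train["label"].to_numpy(), k=k_eff)
    clf = LogisticRegression(C=C, max_iter=2000)
    clf.fit(X_train[names], train["label"] == POSITIVE_LABEL)
    pred = clf.predict(X_test[names])
    pred_labels = np.where(pred, POSITIVE_LABEL, NEGATIVE_LABEL)
    metrics = confusion_metrics(pred_labels, test["label"].to_numpy())
    return metrics, names, np.abs(clf.coef_.ravel())


def _summarize(per_split: list[MetricSet]) -> dict[str, tuple[float, float]]:
    out = {}
    for metric in ("bacc", "f1", "sens", "spec"):
        vals = np.array([getattr(m, metric) for m in per_split], dtype=float)
        vals = vals[np.isfinite(vals)]
        out[metric] = (float(vals.mean()), float(vals.std(ddof=1))) if len(vals) else (
            math.nan,
            math.nan,
        )
    return out


def run_within_wavelength(
    table: pd.DataFrame,
    wavelength: str,
    k: int = 3,
    p_out: int = 3,
    feature_pool: Sequence[str] | None = None,
    C: float = 1.0,
) -> WavelengthResult:
    """Leave-P-subjects-out evaluation for one wavelength.

    Per iteration, imputation, standardization, mRMR selection and the
    classifier are all fit on the training subjects only. Test folds that
    contain a single class are excluded from the averages (counted in
    ``n_excluded_folds``). Feature importances aggregate how often each
    feature entered the selected top-k set (``freq_top``, %) and its mean
    absolute standardized coefficient when selected.
    """
    pool = list(feature_pool) if feature_pool is not None else list(SQI_NAMES)
    data = _binary_table(table, wavelength)
    if data.empty or data["label"].nunique() < 2:
        raise ValueError(f"need clean and noisy epochs for wavelength {wavelength!r}")
    plan = make_split_plan(data["subject_id"].unique(), p_out=p_out)

    per_split: list[MetricSet] = []
    sel_counts: dict[str, int] = {name: 0 for name in pool}
    sel_weights: dict[str, list[float]] = {name: [] for name in pool}
    n_excluded = 0
    for train_ids, test_ids in plan.iterations:
        train = data[data["subject_id"].isin(train_ids)]
        test = data[data["subject_id"].isin(test_ids)]
        if test["label"].nunique() < 2 or train["label"].nunique() < 2:
            n_excluded += 1
            continue
        metrics, names, weights = _fit_and_score(train, test, pool, k, C)
        per_split.append(metrics)
        for name, w in zip(names, weights):
            sel_counts[name] += 1
            sel_weights[name].append(float(w))

    n_valid = max(1, len(per_split))
    importances = [
        FeatureImportance(
            sqi_name=name,
            freq_top=100.0 * sel_counts[name] / n_valid,
            mean_weight=float(np.mean(sel_weights[name])) if sel_weights[name] else 0.0,
        )
        for name in pool
        if sel_counts[name] > 0
    ]
    importances.sort(key=lambda e: (e.freq_top, e.mean_weight), reverse=True)
    return WavelengthResult(
        wavelength=wavelength,
        per_split=per_split,
        summary=_summarize(per_split),
        importances=importances,
        n_excluded_folds=n_excluded,
        feature_pool=pool,
    )


def run_cross_wavelength(
    table: pd.DataFrame,
    train_wavelength: str,
    test_wavelength: str,
    k: int = 3,
    feature_pool: Sequence[str] | None = None,
    C: float = 1.0,
) -> MetricSet:
    """Train on all epochs of one wavelength, test on another.

    The feature set is the top-k selected on the training wavelength.
    """
    if train_wavelength == test_wavelength:
        raise ValueError("train and test wavelengths must differ")
    pool = list(feature_pool) if feature_pool is not None else list(SQI_NAMES)
    train = _binary_table(table, train_wavelength)
    test = _binary_table(table, test_wavelength)
    for name, part in (("train", train), ("test", test)):
        if part.empty or part["label"].nunique() < 2:
            raise ValueError(f"{name} wavelength lacks clean and noisy epochs")
    metrics, _, _ = _fit_and_score(train, test, pool, k, C)
    return metrics


def family_pool(name: str) -> list[str]:
    """Feature-name pool for a named family ('benchstat', ..., 'all')."""
    return list(FEATURE_FAMILIES[name])
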
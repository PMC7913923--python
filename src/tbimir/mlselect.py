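"""Nested cross-validated logistic-regression feature selection.

The selection mirrors a small-cohort biomarker-discovery workflow: an
outer leave-one-out loop gives an unbiased cross-validated AUC, while an
inner cross-validation grid search — over regularization strength, L1 vs
L2 penalty, feature-selection method (recursive feature elimination or
univariate F-score filtering) and the number of retained features — picks
hyperparameters on each outer training set only. Zero-variance features
are dropped and the remainder standardized using outer-training
statistics alone, so no information about the held-out sample leaks into
selection or scaling. Feature importance is the fold-average of absolute
logistic-regression coefficients, normalized to sum to one; model
significance comes from a label-permutation test of the cross-validated
AUC.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.feature_selection import RFE, SelectKBest, f_classif
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .containers import SampleMeta
from .de import DEResults
from .rocstats import roc_auc

__all__ = [
    "HyperGrid",
    "NestedCVReport",
    "CandidateSet",
    "nested_cv",
    "permutation_test",
    "aggregate_importance",
    "feature_importance",
    "select_candidates",
    "binary_labels",
]


@dataclass(frozen=True)
class HyperGrid:
    """Hyperparameter grid for the inner-loop search."""

    C: tuple[float, ...] = (0.01, 0.1, 1.0, 10.0)
    n_features: tuple[int, ...] = (1, 2, 5, 10, 20)
    selection: tuple[str, ...] = ("rfe", "f_score")
    penalty: tuple[str, ...] = ("l1", "l2")

    def combos(self) -> list[dict]:
        return [
            {"C": c, "n_features": k, "selection": s, "penalty": p}
            for c, k, s, p in itertools.product(
                self.C, self.n_features, self.selection, self.penalty
            )
        ]


@dataclass
class NestedCVReport:
    """Outcome of one nested-CV comparison."""

    comparison: tuple[str, str]
    outer_predictions: pd.Series  # held-out class-1 probability per sample
    outer_labels: pd.Series
    cv_auc: float
    importance: pd.Series  # normalized mean |coefficient| per feature
    selected_grid: dict[str, dict]  # held-out sample -> chosen hyperparameters
    fold_coefficients: pd.DataFrame | None = None  # held-out sample x feature
    permutation_p: float | None = None
    n_permutations: int | None = None

    def summary(self) -> str:
        neg, pos = self.comparison
        lines = [
            f"Nested leave-one-out CV: {pos} (positive) vs {neg} (negative)",
            f"  samples: {len(self.outer_labels)}  CV AUC: {self.cv_auc:.3f}",
        ]
        if self.permutation_p is not None:
            lines.append(
                f"  permutation p: {self.permutation_p:.4g}"
                f" ({self.n_permutations} permutations)"
            )
        lines.append("  top features by normalized importance:")
        for feat, imp in feature_importance(self)[:8]:
            lines.append(f"    {feat:<20} {imp:.3f}")
        return "\n".join(lines)


def binary_labels(meta: SampleMeta, positive_groups: Sequence[str],
                  negative_groups: Sequence[str]) -> pd.Series:
    """0/1 labels for (possibly merged) group comparisons.

    Returns labels for the samples belonging to either side, e.g. positive
    ("mTBI", "sTBI") vs negative ("naive", "sham") for the injured-vs-
    uninjured comparison.
    """
    groups = meta.groups
    keep = groups.isin(list(positive_groups) + list(negative_groups))
    return groups[keep].isin(list(positive_groups)).astype(int)


def _fit_combo(X: np.ndarray, y: np.ndarray, feature_idx: np.ndarray,
               combo: Mapping, seed: int) -> tuple[LogisticRegression, np.ndarray]:
    """Select features then fit logistic regression; returns (model, kept idx)."""
    k = min(int(combo["n_features"]), X.shape[1])
    estimator = LogisticRegression(
        l1_ratio=1.0 if combo["penalty"] == "l1" else 0.0,
        C=combo["C"], solver="liblinear", random_state=seed, max_iter=200,
    )
    if k >= X.shape[1]:
        kept = np.arange(X.shape[1])
        X_sel = X
    elif combo["selection"] == "f_score":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            selector = SelectKBest(f_classif, k=k).fit(X, y)
        kept = np.flatnonzero(selector.get_support())
        X_sel = X[:, kept]
    elif combo["selection"] == "rfe":
        rfe = RFE(estimator, n_features_to_select=k, step=1).fit(X, y)
        kept = np.flatnonzero(rfe.support_)
        X_sel = X[:, kept]
    else:
        raise ValueError(f"unknown selection method {combo['selection']!r}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        model = estimator.fit(X_sel, y)
    return model, feature_idx[kept]


def _inner_score(X: np.ndarray, y: np.ndarray, combo: Mapping,
                 n_splits: int, seed: int) -> float:
    """Pooled held-out AUC of one hyperparameter combo under inner CV."""
    n_splits = min(n_splits, int(np.bincount(y).min()))
    if n_splits < 2:
        return 0.5
    cv = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    scores = np.empty(len(y))
    dummy_idx = np.arange(X.shape[1])
    for train, test in cv.split(X, y):
        mu = X[train].mean(axis=0)
        sd = X[train].std(axis=0)
        sd[sd == 0] = 1.0
        model, kept = _fit_combo((X[train] - mu) / sd, y[train], dummy_idx, combo, seed)
        X_test = (X[test] - mu) / sd
        scores[test] = model.predict_proba(X_test[:, kept])[:, 1]
    return roc_auc(scores[y == 1], scores[y == 0])[0]


def nested_cv(
    features: pd.DataFrame,
    labels: Sequence[int] | pd.Series,
    grid: HyperGrid | None = None,
    seed: int = 0,
    inner_splits: int = 3,
    comparison: tuple[str, str] = ("0", "1"),
) -> NestedCVReport:
    """Leave-one-out nested CV with inner grid search.

    ``features`` is sample x feature (raw counts, pre-filtered for
    prevalence upstream); ``labels`` are binary with class 1 the positive
    class. Each outer fold drops zero-variance features, standardizes on
    the outer-training statistics, picks the grid combination maximizing
    pooled inner-CV AUC (a single-combination grid skips the search), and
    scores the held-out sample with the refit model. The CV AUC is
    computed from the held-out scores only. Deterministic under ``seed``.
    """
    grid = grid or HyperGrid()
    y = np.asarray(labels, dtype=int)
    if set(np.unique(y)) - {0, 1}:
        raise ValueError("labels must be binary 0/1")
    counts = np.bincount(y, minlength=2)
    if counts.min() < 2:
        raise ValueError("each class needs at least 2 samples")
    if features.shape[0] != len(y):
        raise ValueError("features and labels disagree in length")

    X_all = features.to_numpy(dtype=float)
    sample_ids = list(features.index)
    feature_ids = list(features.columns)
    combos = grid.combos()
    rng = np.random.default_rng(seed)

    held_out = np.empty(len(y))
    coef_records = np.zeros((len(y), len(feature_ids)))
    selected: dict[str, dict] = {}

    for i in range(len(y)):
        train = np.delete(np.arange(len(y)), i)
        X_tr, y_tr = X_all[train], y[train]

        variable = X_tr.std(axis=0) > 0
        feat_idx = np.flatnonzero(variable)
        X_tr = X_tr[:, variable]

        fold_seed = int(rng.integers(2**31))
        if len(combos) == 1:
            best = combos[0]
        else:
            best, best_score = None, -np.inf
            for combo in combos:
                score = _inner_score(X_tr, y_tr, combo, inner_splits, fold_seed)
                if score > best_score:
                    best, best_score = combo, score
        selected[sample_ids[i]] = dict(best)

        mu = X_tr.mean(axis=0)
        sd = X_tr.std(axis=0)
        sd[sd == 0] = 1.0
        model, kept = _fit_combo((X_tr - mu) / sd, y_tr, feat_idx, best, fold_seed)
        coef_records[i, kept] = model.coef_.ravel()

        x_test = (X_all[i, feat_idx] - mu) / sd
        kept_local = np.searchsorted(feat_idx, kept)
        held_out[i] = model.predict_proba(x_test[kept_local][None, :])[:, 1][0]

    cv_auc = roc_auc(held_out[y == 1], held_out[y == 0])[0]
    return NestedCVReport(
        comparison=comparison,
        outer_predictions=pd.Series(held_out, index=sample_ids, name="score"),
        outer_labels=pd.Series(y, index=sample_ids, name="label"),
        cv_auc=float(cv_auc),
        importance=aggregate_importance(coef_records, feature_ids),
        selected_grid=selected,
        fold_coefficients=pd.DataFrame(coef_records, index=sample_ids,
                                       columns=feature_ids),
    )


def aggregate_importance(fold_coefs: np.ndarray,
                         feature_ids: Sequence[str]) -> pd.Series:
    """Fold-averaged absolute coefficients, normalized to sum to one.

    ``fold_coefs`` is folds x features with zeros for features eliminated
    in a fold. An all-zero record degenerates to uniform importance.
    """
    mean_abs = np.abs(np.asarray(fold_coefs, dtype=float)).mean(axis=0)
    total = mean_abs.sum()
    if total == 0:
        warnings.warn("all coefficients zero; importance set uniform")
        values = np.full(len(feature_ids), 1.0 / len(feature_ids))
    else:
        values = mean_abs / total
    return pd.Series(values, index=list(feature_ids), name="importance")


def permutation_test(
    features: pd.DataFrame,
    labels: Sequence[int] | pd.Series,
    grid: HyperGrid | None = None,
    n_permutations: int = 1000,
    seed: int = 0,
    inner_splits: int = 3,
    observed: NestedCVReport | None = None,
) -> float:
    """Permutation p-value for the cross-validated AUC.

    Labels are uniformly permuted ``n_permutations`` times; the p-value is
    (1 + #{permuted CV AUC >= observed}) / (n_permutations + 1), the
    add-one estimator that can never return zero. ``observed`` may pass in
    an already-computed report for the unpermuted labels.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    y = np.asarray(labels, dtype=int)
    if observed is None:
        observed = nested_cv(features, y, grid, seed=seed, inner_splits=inner_splits)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        perm = rng.permutation(y)
        perm_seed = int(rng.integers(2**31))
        report = nested_cv(features, perm, grid, seed=perm_seed,
                           inner_splits=inner_splits)
        if report.cv_auc >= observed.cv_auc:
            exceed += 1
    return (1 + exceed) / (n_permutations + 1)


def feature_importance(report: NestedCVReport) -> list[tuple[str, float]]:
    """Importance pairs in descending order, ties broken by feature id."""
    items = list(report.importance.items())
    items.sort(key=lambda kv: (-kv[1], kv[0]))
    return [(k, float(v)) for k, v in items]


@dataclass
class CandidateSet:
    """Top-k features annotated with differential-expression support."""

    comparison: tuple[str, str]
    candidates: list[dict] = field(default_factory=list)

    @property
    def feature_ids(self) -> list[str]:
        return [c["feature"] for c in self.candidates]

    @property
    def validation_priority(self) -> list[str]:
        """Candidates also significant in the DE analysis."""
        return [c["feature"] for c in self.candidates if c["de_significant"]]


def select_candidates(report: NestedCVReport, de_results: DEResults | None,
                      top_k: int = 5) -> CandidateSet:
    """Top-k features by importance, flagged if DE-significant.

    The intersection of the importance ranking with the DE hits is the
    validation-priority set carried into PCR-based confirmation.
    """
    ranked = feature_importance(report)
    if top_k > len(ranked):
        warnings.warn(f"top_k={top_k} exceeds {len(ranked)} features; truncating")
        top_k = len(ranked)
    sig = set(de_results.significant.index) if de_results is not None else set()
    out = CandidateSet(comparison=report.comparison)
    for feature, importance in ranked[: max(top_k, 0)]:
        out.candidates.append(
            {"feature": feature, "importance": importance,
             "de_significant": feature in sig}
        )
    return out
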
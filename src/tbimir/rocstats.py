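"""Nonparametric group statistics, ROC analysis and cutpoint selection.

Group comparisons follow the small-cohort convention: an omnibus
Kruskal-Wallis test followed by pairwise two-sided Mann-Whitney U tests
(exact for small samples without ties, normal approximation with tie
correction otherwise), Spearman rank correlations, rank-based ROC AUC
with Mann-Whitney significance, an optimal cutpoint maximizing
sensitivity + specificity, and mean + k*SD elevated-subpopulation
flagging with optional covariate cross-tabulation (e.g. S100B above its
0.1 ug/L clinical cutoff).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .containers import SampleMeta

__all__ = [
    "GroupComparison",
    "CutpointResult",
    "FlagTable",
    "group_compare",
    "spearman",
    "roc_auc",
    "optimal_cutpoint",
    "flag_elevated",
]


@dataclass
class GroupComparison:
    """Kruskal-Wallis omnibus plus pairwise Mann-Whitney U results."""

    groups: list[str]
    kw_statistic: float
    kw_p: float
    pairwise: list[tuple[tuple[str, str], float, float]]  # (pair, U, p)
    excluded_groups: list[str] = field(default_factory=list)

    def summary(self) -> str:
        lines = [
            f"Kruskal-Wallis over {self.groups}: H = {self.kw_statistic:.3f},"
            f" p = {self.kw_p:.4g}"
        ]
        for (a, b), u, p in self.pairwise:
            lines.append(f"  {a} vs {b}: U = {u:.1f}, p = {p:.4g}")
        if self.excluded_groups:
            lines.append(f"  excluded singleton groups: {self.excluded_groups}")
        return "\n".join(lines)


def _mwu(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann-Whitney U; exact for combined n <= 20 without ties."""
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    if len(x) + len(y) <= 20 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def group_compare(values: Mapping[str, float] | pd.Series,
                  meta: SampleMeta) -> GroupComparison:
    """Omnibus and pairwise nonparametric comparison of per-sample values."""
    series = pd.Series(values, dtype=float)
    groups = meta.groups.reindex(series.index)
    if groups.isna().any():
        missing = list(series.index[groups.isna()])
        raise ValueError(f"samples missing from metadata: {missing}")

    by_group: dict[str, np.ndarray] = {
        g: series[groups == g].to_numpy() for g in pd.unique(groups)
    }
    excluded = [g for g, v in by_group.items() if len(v) < 2]
    if excluded:
        warnings.warn(f"excluding singleton groups from comparison: {excluded}")
    usable = {g: v for g, v in by_group.items() if len(v) >= 2}
    if len(usable) < 2:
        raise ValueError("need at least 2 groups with >= 2 samples")

    kw = stats.kruskal(*usable.values())
    pairwise = []
    names = list(usable)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            u, p = _mwu(usable[names[i]], usable[names[j]])
            pairwise.append(((names[i], names[j]), u, p))
    return GroupComparison(names, float(kw.statistic), float(kw.pvalue),
                           pairwise, excluded)


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation with mid-ranks for ties; two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("correlation undefined for a constant vector")
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def roc_auc(positive: Sequence[float], negative: Sequence[float]) -> tuple[float, float]:
    """ROC AUC under the higher-is-positive convention, with MWU p-value.

    AUC = U / (n_pos * n_neg) with mid-rank tie handling — the fraction of
    (positive, negative) pairs ranked concordantly, ties counting half.
    """
    pos = np.asarray(positive, dtype=float)
    neg = np.asarray(negative, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be non-empty")
    u, p = _mwu(pos, neg)
    return u / (pos.size * neg.size), p


@dataclass
class CutpointResult:
    """Optimal copy-number cutoff with its operating characteristics."""

    comparison: tuple[str, str]  # (positive group, negative group)
    auc: float
    auc_p: float
    cutoff: float
    sensitivity: float  # percent
    specificity: float  # percent
    degenerate: bool = False

    def summary(self) -> str:
        pos, neg = self.comparison
        line = (
            f"ROC {pos} vs {neg}: AUC {self.auc:.3f} (p = {self.auc_p:.4g}); "
            f"cutoff {self.cutoff:g} -> sensitivity {self.sensitivity:.0f}%, "
            f"specificity {self.specificity:.0f}%"
        )
        if self.degenerate:
            line += " [degenerate: no value separates the classes]"
        return line

    def to_dict(self) -> dict:
        return {
            "positive_group": self.comparison[0],
            "negative_group": self.comparison[1],
            "auc": self.auc,
            "auc_p": self.auc_p,
            "cutoff": self.cutoff,
            "sensitivity_percent": self.sensitivity,
            "specificity_percent": self.specificity,
            "degenerate": self.degenerate,
        }


def _sens_spec(pos: np.ndarray, neg: np.ndarray, cutoff: float) -> tuple[float, float]:
    sens = np.mean(pos >= cutoff) * 100.0
    spec = np.mean(neg < cutoff) * 100.0
    return float(sens), float(spec)


def optimal_cutpoint(
    positive: Sequence[float],
    negative: Sequence[float],
    comparison: tuple[str, str] = ("positive", "negative"),
) -> CutpointResult:
    """Cutoff maximizing sensitivity + specificity (value >= cutoff => positive).

    Candidate cutoffs are the midpoints between adjacent distinct observed
    values plus one below and one above the observed range. Ties on the
    objective are broken toward higher specificity, then the smallest
    cutoff. If all values coincide the best achievable sum is 100
    (classify everything one way) and the result is flagged degenerate.
    """
    pos = np.asarray(positive, dtype=float)
    neg = np.asarray(negative, dtype=float)
    auc, auc_p = roc_auc(pos, neg)

    values = np.unique(np.concatenate([pos, neg]))
    candidates = [values[0] - 1.0]
    candidates += [(a + b) / 2.0 for a, b in zip(values[:-1], values[1:])]
    candidates.append(values[-1] + 1.0)

    best = None
    for cut in candidates:
        sens, spec = _sens_spec(pos, neg, cut)
        key = (sens + spec, spec, -cut)
        if best is None or key > best[0]:
            best = (key, cut, sens, spec)
    _, cutoff, sens, spec = best
    return CutpointResult(
        comparison=comparison, auc=auc, auc_p=auc_p, cutoff=float(cutoff),
        sensitivity=sens, specificity=spec, degenerate=len(values) == 1,
    )


@dataclass
class FlagTable:
    """Elevated-value flags relative to a reference group, with covariate."""

    reference_group: str
    threshold: float
    flags: pd.DataFrame  # columns: value, elevated, covariate flag (optional)
    crosstab: pd.DataFrame | None = None

    def counts(self) -> dict:
        out = {"n_elevated": int(self.flags["elevated"].sum()),
               "n_total": int(len(self.flags))}
        if self.crosstab is not None:
            out["crosstab"] = {
                str(i): {str(c): int(v) for c, v in row.items()}
                for i, row in self.crosstab.iterrows()
            }
        return out


def flag_elevated(
    values: Mapping[str, float] | pd.Series,
    meta: SampleMeta,
    reference_group: str,
    k_sd: float = 1.0,
    covariate_threshold: tuple[str, float] | None = None,
) -> FlagTable:
    """Flag samples strictly above mean + k_sd * SD of the reference group.

    SD uses the n-1 denominator. With ``covariate_threshold`` (name,
    cutoff), e.g. ("s100b", 0.1), samples are additionally flagged on the
    metadata covariate (strictly above the cutoff; missing values count
    as unknown) and a 2x2 cross-tabulation of the two flags is attached.
    Reference-group samples are included in the output table but the
    threshold derives from the reference group only.
    """
    series = pd.Series(values, dtype=float)
    ref_ids = [s for s in meta.samples_in(reference_group) if s in series.index]
    if len(ref_ids) < 2:
        raise ValueError("reference group needs at least 2 samples with values")
    ref = series[ref_ids]
    threshold = float(ref.mean() + k_sd * ref.std(ddof=1))

    flags = pd.DataFrame({"value": series})
    flags["group"] = meta.groups.reindex(series.index)
    flags["elevated"] = series > threshold

    crosstab = None
    if covariate_threshold is not None:
        name, cutoff = covariate_threshold
        if name not in meta.table.columns:
            raise ValueError(f"metadata lacks covariate column {name!r}")
        cov = meta.table[name].reindex(series.index)
        cov_flag = pd.Series(
            np.where(cov.isna(), "unknown", np.where(cov > cutoff, "above", "below")),
            index=series.index,
        )
        flags[f"{name}_flag"] = cov_flag
        known = cov_flag != "unknown"
        crosstab = pd.crosstab(
            flags.loc[known, "elevated"].map({True: "elevated", False: "not_elevated"}),
            cov_flag[known],
        )
    return FlagTable(reference_group=reference_group, threshold=threshold,
                     flags=flags, crosstab=crosstab)
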
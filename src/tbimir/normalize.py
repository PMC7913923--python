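"""Normalization and exploratory summaries for miRNA count and Cq data.

Covers counts-per-million scaling of the raw count matrix, the
prevalence filter used upstream of differential expression and machine
learning (count >= 1 in at least 80% of samples), relative RT-qPCR
quantification by 2**(-dCt) against an endogenous reference assay,
reference-assay stability ranking by intra/inter-group variance
decomposition, small-RNA input normalization with CV% reporting, and an
exploratory summary (PCA, Spearman correlation, complete-linkage
clustering, per-group detection Venn counts).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .containers import CountMatrix, CqTable

__all__ = [
    "cpm",
    "prevalence_filter",
    "RelativeExpression",
    "delta_ct_relative",
    "StabilityResult",
    "normfinder_stability",
    "small_rna_input_normalize",
    "cv_percent",
    "EDASummary",
    "eda_summary",
    "shared_mirna_percent",
]


def cpm(cm: CountMatrix) -> pd.DataFrame:
    """Counts per million miRNA-mapped reads.

    cpm[i, s] = counts[i, s] / mirna_mapped_total[s] * 1e6. When the
    totals are the in-matrix column sums each column sums to one million.
    """
    totals = cm.mirna_mapped_total
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise ValueError(f"zero miRNA-mapped total for samples: {bad}")
    return cm.counts.div(totals, axis=1) * 1e6


def prevalence_filter(cm: CountMatrix, min_count: int = 1,
                      min_fraction: float = 0.8) -> CountMatrix:
    """Keep miRNAs with count >= min_count in at least min_fraction of samples.

    The sample threshold is ceil(min_fraction * n_samples); row order is
    preserved, and per-sample totals are untouched (they keep counting
    reads mapped to filtered miRNAs).
    """
    if not 0 < min_fraction <= 1:
        raise ValueError("min_fraction must be in (0, 1]")
    needed = math.ceil(min_fraction * cm.n_samples)
    prevalent = (cm.counts >= min_count).sum(axis=1) >= needed
    if not prevalent.any():
        raise ValueError("prevalence filter removed every miRNA")
    return CountMatrix(cm.counts.loc[prevalent].copy(), cm.mirna_mapped_total.copy())


@dataclass
class RelativeExpression:
    """2**(-dCt) expression of a target assay relative to the reference."""

    sample_id: str
    assay: str
    value: float


def delta_ct_relative(cq: CqTable, reference_assay: str = "miR-28-3p") -> list[RelativeExpression]:
    """Relative quantification 2**-(Cq_target - Cq_reference) per sample.

    Samples without a reference Cq are skipped with a warning; values are
    strictly positive and dimensionless.
    """
    if reference_assay not in cq.cq.columns:
        raise ValueError(f"reference assay {reference_assay!r} not in Cq table")
    out: list[RelativeExpression] = []
    for sample_id in cq.sample_ids:
        ref = cq.cq.at[sample_id, reference_assay]
        if pd.isna(ref):
            warnings.warn(f"sample {sample_id} lacks reference Cq; skipped")
            continue
        for assay in cq.assays:
            if assay == reference_assay:
                continue
            target = cq.cq.at[sample_id, assay]
            if pd.isna(target):
                continue
            out.append(
                RelativeExpression(sample_id, assay, float(2.0 ** -(target - ref)))
            )
    return out


@dataclass
class StabilityResult:
    """Variance decomposition of one candidate reference assay."""

    assay: str
    intra_group_variance: float
    inter_group_variance: float
    stability_value: float


def normfinder_stability(
    data: pd.DataFrame,
    groups: Sequence[str] | pd.Series,
    log_transform: bool = True,
) -> list[StabilityResult]:
    """Rank candidate reference assays by expression stability.

    ``data`` is assay x sample. Per assay the variation is decomposed into
    pooled within-group variance (intra) and the between-group variance of
    group means, bias-corrected by the expected sampling contribution of
    the within-group noise and floored at zero (inter). The stability
    value sqrt(intra + inter) is on the scale of the (transformed) data;
    lower is more stable, and results come back sorted ascending. With
    ``log_transform`` the decomposition runs on log2(x + 1), appropriate
    when the inputs are raw counts with multiplicative noise.
    """
    if data.shape[0] < 2:
        raise ValueError("need at least 2 candidate assays")
    groups = pd.Series(np.asarray(groups), index=data.columns)
    sizes = groups.value_counts()
    if len(sizes) < 2:
        raise ValueError("need at least 2 groups")
    if (sizes < 2).any():
        small = list(sizes.index[sizes < 2])
        raise ValueError(f"groups with fewer than 2 samples: {small}")

    values = np.log2(data.astype(float) + 1.0) if log_transform else data.astype(float)

    results = []
    group_labels = list(sizes.index)
    inv_n_mean = float(np.mean([1.0 / sizes[g] for g in group_labels]))
    for assay in values.index:
        row = values.loc[assay]
        group_means = []
        ss_within = 0.0
        df_within = 0
        for g in group_labels:
            x = row[groups == g].to_numpy()
            group_means.append(float(np.mean(x)))
            ss_within += float(np.sum((x - np.mean(x)) ** 2))
            df_within += len(x) - 1
        intra = ss_within / df_within if df_within > 0 else 0.0
        raw_inter = float(np.var(group_means, ddof=1))
        inter = max(raw_inter - intra * inv_n_mean, 0.0)
        results.append(
            StabilityResult(
                assay=assay,
                intra_group_variance=intra,
                inter_group_variance=inter,
                stability_value=math.sqrt(intra + inter),
            )
        )
    results.sort(key=lambda r: (r.stability_value, r.assay))
    return results


def cv_percent(values: Sequence[float]) -> float:
    """Coefficient of variation in percent: 100 * sample SD / mean."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("CV% needs at least 2 values")
    mean = arr.mean()
    if mean == 0:
        raise ValueError("CV% undefined for zero mean")
    return float(100.0 * arr.std(ddof=1) / mean)


def small_rna_input_normalize(
    concentrations: Mapping[str, float],
    target: float,
) -> tuple[dict[str, float], float, float]:
    """Dilution factors equalizing small-RNA input concentrations.

    Each sample is diluted by factor = concentration / target so that all
    post-normalization concentrations equal ``target`` (which must not
    exceed the smallest concentration). Returns (factors, CV% before,
    CV% after); the after-CV is 0 by construction and is computed, not
    assumed.
    """
    conc = pd.Series(concentrations, dtype=float)
    if (conc <= 0).any():
        raise ValueError("concentrations must be positive")
    if target > conc.min():
        raise ValueError(
            f"target {target} exceeds the smallest concentration {conc.min()}"
        )
    factors = (conc / target).to_dict()
    after = conc / (conc / target)
    return factors, cv_percent(conc.to_numpy()), cv_percent(after.to_numpy())


@dataclass
class EDASummary:
    """Exploratory overview of a normalized expression matrix."""

    explained_variance_ratio: np.ndarray
    spearman: pd.DataFrame
    linkage_matrix: np.ndarray
    venn_counts: dict
    constant_samples: list[str]

    def to_dict(self) -> dict:
        return {
            "explained_variance_ratio": [float(v) for v in self.explained_variance_ratio],
            "spearman": {
                s: {t: (None if pd.isna(v) else float(v)) for t, v in row.items()}
                for s, row in self.spearman.iterrows()
            },
            "linkage": self.linkage_matrix.tolist(),
            "venn_counts": self.venn_counts,
            "constant_samples": self.constant_samples,
        }


def shared_mirna_percent(n_detected_total: int, n_shared_all_groups: int) -> int:
    """Percentage of detected miRNAs expressed in every group (integer %)."""
    if n_detected_total <= 0:
        raise ValueError("no detected miRNAs")
    if not 0 <= n_shared_all_groups <= n_detected_total:
        raise ValueError("shared count outside [0, detected]")
    return round(100.0 * n_shared_all_groups / n_detected_total)


def eda_summary(cpm_matrix: pd.DataFrame, groups: Sequence[str] | pd.Series,
                raw_counts: pd.DataFrame | None = None) -> EDASummary:
    """PCA, Spearman correlation, clustering and group detection counts.

    PCA runs on log2(cpm + 1) with features centred; the Spearman matrix
    is between samples; complete linkage uses distance 1 - rho. "Detected"
    in a group means raw count > 0 in at least one of its samples (the
    CPM matrix stands in when raw counts are not given — zeros coincide).
    """
    if cpm_matrix.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    groups = pd.Series(np.asarray(groups), index=cpm_matrix.columns)

    log_matrix = np.log2(cpm_matrix.to_numpy(dtype=float) + 1.0)
    centred = log_matrix - log_matrix.mean(axis=1, keepdims=True)
    # Samples as observations: SVD of the sample x feature matrix.
    _, svals, _ = np.linalg.svd(centred.T, full_matrices=False)
    var = svals**2
    explained = var / var.sum() if var.sum() > 0 else np.zeros_like(var)

    constant = [
        s for s in cpm_matrix.columns
        if np.all(cpm_matrix[s].to_numpy() == cpm_matrix[s].iloc[0])
    ]
    spear = cpm_matrix.corr(method="spearman")
    for s in constant:
        spear.loc[s, :] = np.nan
        spear.loc[:, s] = np.nan
    values = spear.to_numpy()
    np.fill_diagonal(values, 1.0)
    spear = pd.DataFrame(values, index=cpm_matrix.columns, columns=cpm_matrix.columns)

    dist = 1.0 - spear.to_numpy(dtype=float)
    dist = np.nan_to_num(dist, nan=2.0)  # undefined correlations -> maximal distance
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0
    link = linkage(squareform(np.maximum(dist, 0.0), checks=False), method="complete")

    detection = raw_counts if raw_counts is not None else cpm_matrix
    group_sets = {
        g: set(detection.index[(detection.loc[:, groups[groups == g].index] > 0).any(axis=1)])
        for g in groups.unique()
    }
    detected_any = set().union(*group_sets.values()) if group_sets else set()
    shared_all = set.intersection(*group_sets.values()) if group_sets else set()
    venn = {
        "per_group_detected": {g: len(s) for g, s in group_sets.items()},
        "detected_total": len(detected_any),
        "shared_all_groups": len(shared_all),
        "shared_percent": shared_mirna_percent(len(detected_any), len(shared_all))
        if detected_any else 0,
    }
    return EDASummary(explained, spear, link, venn, constant)
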
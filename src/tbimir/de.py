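"""Differential expression of miRNA counts between two groups.

A deliberately transparent negative-binomial Wald pipeline: library
composition is corrected with median-of-ratios size factors, per-miRNA
dispersion is estimated by method of moments on normalized counts (pooled
within groups, floored at a small positive value), and the Wald statistic
tests the log2 fold change between group means with Benjamini-Hochberg
control of the false discovery rate across miRNAs. There is no dispersion
shrinkage toward a mean-variance trend, no fold-change shrinkage, and no
independent filtering; exact concordance with heavier DE machinery is not
claimed — concordance on well-powered simulations is the supported
contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import CountMatrix, SampleMeta

__all__ = ["size_factors", "nb_wald_test", "DEResults", "DISPERSION_FLOOR"]

DISPERSION_FLOOR = 1e-8


def size_factors(cm: CountMatrix) -> pd.Series:
    """Median-of-ratios size factors.

    For each miRNA with all-positive counts, the per-sample ratio to its
    geometric mean is formed; the size factor of a sample is the median of
    those ratios. When no miRNA is positive everywhere, geometric means
    fall back to the positive subset of each row (with a warning), so
    sparse matrices still normalize.
    """
    counts = cm.counts.to_numpy(dtype=float)
    all_positive = (counts > 0).all(axis=1)
    if all_positive.any():
        ref_rows = counts[all_positive]
        geo = np.exp(np.mean(np.log(ref_rows), axis=1))
        ratios = ref_rows / geo[:, None]
    else:
        import warnings

        warnings.warn(
            "no miRNA with all-positive counts; using positive-subset geometric means"
        )
        with np.errstate(divide="ignore"):
            logs = np.where(counts > 0, np.log(counts), np.nan)
        geo = np.exp(np.nanmean(logs, axis=1))
        keep = np.isfinite(geo) & (geo > 0)
        with np.errstate(invalid="ignore"):
            ratios = np.where(counts[keep] > 0, counts[keep] / geo[keep, None], np.nan)
    factors = np.nanmedian(ratios, axis=0)
    if np.any(~np.isfinite(factors)) or np.any(factors <= 0):
        raise ValueError("could not compute positive size factors for all samples")
    return pd.Series(factors, index=cm.sample_ids, name="size_factor")


@dataclass
class DEResults:
    """Results of a two-group NB Wald contrast.

    ``table`` has one row per tested miRNA: base_mean (mean normalized
    count over both groups), log2_fold_change (group A over group B),
    wald_stat, wald_p, fdr and the significance call at ``alpha``.
    """

    contrast: tuple[str, str]
    alpha: float
    table: pd.DataFrame
    excluded: list[str] = field(default_factory=list)
    size_factors: pd.Series | None = None

    @property
    def significant(self) -> pd.DataFrame:
        return self.table[self.table["significant"]]

    def summary(self) -> str:
        a, b = self.contrast
        n_sig = int(self.table["significant"].sum())
        up = int((self.significant["direction"] == "up").sum())
        down = n_sig - up
        lines = [
            f"NB Wald differential expression: {a} vs {b}",
            f"  miRNAs tested: {len(self.table)}"
            + (f" (excluded all-zero: {len(self.excluded)})" if self.excluded else ""),
            f"  significant at FDR < {self.alpha:g}: {n_sig} ({up} up, {down} down)",
        ]
        top = self.table.nsmallest(min(10, len(self.table)), "fdr")
        lines.append(f"  {'miRNA':<18}{'baseMean':>10}{'log2FC':>9}{'p':>11}{'FDR':>11}")
        for mirna, row in top.iterrows():
            lines.append(
                f"  {mirna:<18}{row.base_mean:>10.1f}{row.log2_fold_change:>9.2f}"
                f"{row.wald_p:>11.2e}{row.fdr:>11.2e}"
            )
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out.insert(0, "contrast", f"{self.contrast[0]}:{self.contrast[1]}")
        out.to_csv(path, sep="\t", index_label="mirna_id")


def _moment_dispersion(norm: np.ndarray, idx_a: np.ndarray, idx_b: np.ndarray) -> np.ndarray:
    """Pooled within-group method-of-moments dispersion per miRNA."""
    disp_num = np.zeros(norm.shape[0])
    disp_den = np.zeros(norm.shape[0])
    for idx in (idx_a, idx_b):
        x = norm[:, idx]
        mean = x.mean(axis=1)
        var = x.var(axis=1, ddof=1)
        w = len(idx) - 1
        disp_num += w * (var - mean)
        disp_den += w * mean**2
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = np.where(disp_den > 0, disp_num / disp_den, 0.0)
    return np.maximum(alpha, DISPERSION_FLOOR)


def nb_wald_test(
    cm: CountMatrix,
    meta: SampleMeta,
    contrast: tuple[str, str],
    alpha: float = 0.05,
) -> DEResults:
    """Wald test of the log2 fold change of group A over group B.

    Counts are divided by median-of-ratios size factors (computed on the
    contrast's samples); each miRNA gets a moment dispersion estimate and
    a Wald z statistic for log2(mean_A / mean_B) with delta-method
    standard errors under the NB variance mu + alpha*mu^2. Two-sided
    normal p-values are BH-adjusted across tested miRNAs. miRNAs with all
    zeros in both groups are excluded and listed on the results object;
    a zero group mean is replaced by half a normalized count for the fold
    change so the statistic stays finite.
    """
    group_a, group_b = contrast
    ids_a = meta.samples_in(group_a)
    ids_b = meta.samples_in(group_b)
    if len(ids_a) < 2 or len(ids_b) < 2:
        raise ValueError("both contrast groups need at least 2 samples")
    sub = cm.subset_samples(ids_a + ids_b)
    sf = size_factors(sub)

    counts = sub.counts.to_numpy(dtype=float)
    norm = counts / sf.to_numpy()[None, :]
    nonzero = counts.sum(axis=1) > 0
    excluded = [m for m, keep in zip(sub.mirna_ids, nonzero) if not keep]
    norm = norm[nonzero]
    mirnas = [m for m, keep in zip(sub.mirna_ids, nonzero) if keep]
    if not mirnas:
        raise ValueError("no non-zero miRNAs to test")

    idx_a = np.arange(len(ids_a))
    idx_b = np.arange(len(ids_a), len(ids_a) + len(ids_b))
    mean_a = norm[:, idx_a].mean(axis=1)
    mean_b = norm[:, idx_b].mean(axis=1)
    disp = _moment_dispersion(norm, idx_a, idx_b)

    # Half a normalized count keeps zero-mean groups finite and the
    # contrast antisymmetric under swapping.
    pseudo_a = np.maximum(mean_a, 0.5 / len(idx_a))
    pseudo_b = np.maximum(mean_b, 0.5 / len(idx_b))
    lfc = np.log2(pseudo_a / pseudo_b)

    s = sf.to_numpy()
    var_log_a = (np.sum(1.0 / (pseudo_a[:, None] * s[None, idx_a]) + disp[:, None], axis=1)
                 / len(idx_a) ** 2)
    var_log_b = (np.sum(1.0 / (pseudo_b[:, None] * s[None, idx_b]) + disp[:, None], axis=1)
                 / len(idx_b) ** 2)
    se_lfc = np.sqrt(var_log_a + var_log_b) / np.log(2.0)
    z = lfc / se_lfc
    p = 2.0 * stats.norm.sf(np.abs(z))
    _, fdr, _, _ = multipletests(p, method="fdr_bh")

    table = pd.DataFrame(
        {
            "base_mean": norm.mean(axis=1),
            "log2_fold_change": lfc,
            "dispersion": disp,
            "wald_stat": z,
            "wald_p": p,
            "fdr": fdr,
            "significant": fdr < alpha,
            "direction": np.where(lfc >= 0, "up", "down"),
        },
        index=pd.Index(mirnas, name="mirna_id"),
    )
    return DEResults(contrast=contrast, alpha=alpha, table=table,
                     excluded=excluded, size_factors=sf)
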
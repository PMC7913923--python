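"""Absolute miRNA quantification from droplet digital PCR data.

Each 20-uL ddPCR reaction is partitioned into ~10^4 droplets; template
molecules distribute into droplets at random, so the per-droplet
occupancy is Poisson. Inverting the observed positive-droplet fraction p
gives the mean occupancy lambda = -ln(1 - p) and the template count
among the analyzed droplets, copies = lambda * n_total. Droplets are
called positive at or above the assay's fluorescence amplitude threshold
(a manually set input here: 10000 AU for miR-9a-3p and miR-434-3p, 6000
AU for miR-136-3p). Duplicate wells are averaged into one copies/well
value per sample, and group contrasts are summarized as ratios of
arithmetic group means.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import SampleMeta
from .normalize import cv_percent
from .simdata import DropletWell

__all__ = [
    "DropletWell",
    "CopyNumber",
    "ASSAY_THRESHOLDS",
    "quantify_well",
    "summarize_replicates",
    "copy_number_table",
    "group_fold_change",
    "cv_percent",
    "read_droplet_csv",
]

# Default per-assay droplet-calling thresholds (fluorescence AU).
ASSAY_THRESHOLDS: dict[str, float] = {
    "miR-9a-3p": 10_000.0,
    "miR-434-3p": 10_000.0,
    "miR-136-3p": 6_000.0,
    "miR-9-3p": 10_000.0,
}


@dataclass
class CopyNumber:
    """Mean copies per 20-uL reaction well over replicates of one sample."""

    sample_id: str
    assay: str
    copies_per_well: float
    n_replicates: int


def quantify_well(well: DropletWell, droplet_volume_nl: float | None = None) -> float:
    """Poisson-corrected template copies in one well.

    With positive fraction p, lambda = -ln(1 - p) and copies =
    lambda * n_total (template molecules among the analyzed droplets).
    Passing ``droplet_volume_nl`` switches to the per-reaction-volume
    convention copies = lambda * 20000 nL / droplet_volume_nl instead.
    A fully positive well is saturated and cannot be quantified.
    """
    n_positive, n_total = well.positive_and_total()
    if n_positive == n_total:
        if n_positive == 0:
            raise ValueError("well has no droplets")
        raise ValueError(
            f"saturated well ({well.sample_id}/{well.assay} rep {well.replicate}):"
            " every droplet positive"
        )
    lam = -math.log(1.0 - n_positive / n_total)
    if droplet_volume_nl is not None:
        return lam * 20_000.0 / droplet_volume_nl
    return lam * n_total


def summarize_replicates(wells: Sequence[DropletWell],
                         droplet_volume_nl: float | None = None) -> CopyNumber:
    """Average replicate wells of one (sample, assay) into copies/well."""
    if not wells:
        raise ValueError("no wells to summarize")
    keys = {(w.sample_id, w.assay) for w in wells}
    if len(keys) > 1:
        raise ValueError(f"wells mix samples/assays: {sorted(keys)}")
    copies = [quantify_well(w, droplet_volume_nl) for w in wells]
    (sample_id, assay), = keys
    return CopyNumber(sample_id, assay, float(np.mean(copies)), len(copies))


def copy_number_table(wells: Sequence[DropletWell],
                      droplet_volume_nl: float | None = None) -> pd.DataFrame:
    """Per-sample copies/well table from a mixed list of wells.

    Rows are samples, columns assays; replicates of the same (sample,
    assay) are averaged.
    """
    grouped: dict[tuple[str, str], list[DropletWell]] = {}
    for well in wells:
        grouped.setdefault((well.sample_id, well.assay), []).append(well)
    records = [summarize_replicates(v, droplet_volume_nl) for v in grouped.values()]
    frame = pd.DataFrame(
        [{"sample_id": r.sample_id, "assay": r.assay, "copies": r.copies_per_well}
         for r in records]
    )
    return frame.pivot(index="sample_id", columns="assay", values="copies")


def group_fold_change(
    copies: Sequence[CopyNumber] | pd.Series,
    meta: SampleMeta,
    contrast: tuple[str, str],
) -> float:
    """Ratio of arithmetic group-mean copies/well, A over B, one decimal.

    Matches how ddPCR group differences are conventionally reported: the
    fold value is the ratio of group means rounded to one decimal place
    (e.g. means 19.2 vs 4.6 -> 4.2).
    """
    if isinstance(copies, pd.Series):
        series = copies.astype(float)
    else:
        series = pd.Series({c.sample_id: c.copies_per_well for c in copies})
    group_a, group_b = contrast
    vals_a = series[[s for s in meta.samples_in(group_a) if s in series.index]]
    vals_b = series[[s for s in meta.samples_in(group_b) if s in series.index]]
    if vals_a.empty or vals_b.empty:
        raise ValueError("both contrast groups need copy-number values")
    mean_b = vals_b.mean()
    if mean_b == 0:
        raise ValueError(f"zero mean copies in denominator group {group_b!r}")
    ratio = float(vals_a.mean() / mean_b)
    # Half-up rounding to one decimal (the reporting convention for fold
    # values, where 5.05 prints as 5.1); Python's bankers' rounding would
    # turn exact .x5 halves downward half of the time.
    return math.floor(ratio * 10.0 + 0.5) / 10.0


def read_droplet_csv(path) -> list[DropletWell]:
    """Read long-format droplet records (sample, assay, replicate, amplitude)."""
    table = pd.read_csv(path)
    required = {"sample_id", "assay", "replicate", "amplitude", "threshold"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"droplet CSV missing columns: {sorted(missing)}")
    wells = []
    for (sample_id, assay, rep), sub in table.groupby(
        ["sample_id", "assay", "replicate"], sort=True
    ):
        thresholds = sub["threshold"].unique()
        if len(thresholds) > 1:
            raise ValueError(
                f"inconsistent thresholds for {sample_id}/{assay} rep {rep}"
            )
        wells.append(
            DropletWell(str(sample_id), str(assay), int(rep),
                        float(thresholds[0]),
                        amplitudes=sub["amplitude"].to_numpy(float))
        )
    return wells
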
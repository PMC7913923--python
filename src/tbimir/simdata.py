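"""Synthetic cohorts with the statistical structure of a plasma small-RNA study.

Real plasma small-RNA-seq from the rat fluid-percussion-injury cohorts is not
shipped with the package; this module generates cohorts with the same
statistical structure so that every downstream stage (QC, normalization,
differential expression, nested-CV selection, ddPCR quantification, ROC) is
testable offline:

* a count matrix of negative-binomial reads with per-sample library sizes and
  planted per-group log2 fold effects,
* RT-qPCR Cq tables including the endogenous reference miR-28-3p and the
  hemolysis indicator pair miR-23a / miR-451,
* duplicate ddPCR wells with Poisson template occupancy and two-cluster
  droplet amplitude distributions,
* a human cohort (controls, mild TBI with an elevated subpopulation, severe
  TBI) with an S100B covariate.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import AssayRole, CountMatrix, CqTable, SampleMeta

__all__ = [
    "SimDesign",
    "DdpcrAmplitudeParams",
    "rat_sequencing_design",
    "rat_whole_cohort_design",
    "RAT_DDPCR_MEAN_COPIES",
    "simulate_count_matrix",
    "simulate_cq_table",
    "simulate_ddpcr_wells",
    "simulate_human_cohort",
    "simulate_copies",
]

# Mean ddPCR copies/20-uL well of miR-9a-3p printed for the rat whole cohort
# (naive / sham / mTBI / sTBI); the default planted effects reproduce them.
RAT_DDPCR_MEAN_COPIES: dict[str, float] = {
    "naive": 4.6,
    "sham": 5.1,
    "mTBI": 19.2,
    "sTBI": 118.8,
}

# Default planted expression effects (log2 fold vs naive baseline) for the
# three validated markers, from the whole-cohort relative RT-qPCR fold
# changes (sham/mTBI/sTBI vs naive: miR-9a-3p 2.4/14.8/65.9-fold,
# miR-136-3p 2.4/4.3/9.7, miR-434-3p 3.8/7.1/17.2) — the cohort the
# default designs simulate.
RAT_COUNT_EFFECTS: dict[str, dict[str, float]] = {
    "rno-miR-9a-3p": {
        "sham": math.log2(2.4), "mTBI": math.log2(14.8), "sTBI": math.log2(65.9),
    },
    "rno-miR-136-3p": {
        "sham": math.log2(2.4), "mTBI": math.log2(4.3), "sTBI": math.log2(9.7),
    },
    "rno-miR-434-3p": {
        "sham": math.log2(3.8), "mTBI": math.log2(7.1), "sTBI": math.log2(17.2),
    },
}


@dataclass(frozen=True)
class SimDesign:
    """Design of a synthetic sequencing cohort.

    Parameters
    ----------
    group_names, group_sizes
        Study groups and animals per group. The defaults mirror the rat
        sequencing subset (naive 4, sham 5, mTBI 5, sTBI 5).
    n_mirnas
        Number of simulated miRNAs (748 detected species by default).
    baseline_log_mean
        Natural log of the typical per-miRNA mean read count at the centre
        of the library-size range.
    mirna_log_sd
        Log-scale spread of per-miRNA baseline abundances (0 makes all
        miRNAs share the baseline mean).
    dispersion
        Negative-binomial size parameter k (variance mu + mu^2/k);
        ``math.inf`` gives the Poisson limit. The default 10 puts the
        biological coefficient of variation near 0.3, matching the
        log-scale SD 0.3 used for the copies/well generator.
    library_size_range
        Per-sample sequencing depths are drawn uniformly from this range;
        depths act as relative scale factors around the range midpoint.
    effect_table
        miRNA id -> {group -> log2 fold effect relative to baseline}.
    """

    group_names: tuple[str, ...] = ("naive", "sham", "mTBI", "sTBI")
    group_sizes: tuple[int, ...] = (4, 5, 5, 5)
    n_mirnas: int = 748
    baseline_log_mean: float = math.log(120.0)
    dispersion: float = 10.0
    library_size_range: tuple[int, int] = (800_000, 1_200_000)
    effect_table: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    mirna_log_sd: float = 1.2
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.group_names) != len(self.group_sizes):
            raise ValueError("group_names and group_sizes differ in length")
        if any(n < 1 for n in self.group_sizes):
            raise ValueError("all group sizes must be >= 1")
        if self.n_mirnas < len(self.effect_table):
            raise ValueError("n_mirnas smaller than the number of effect miRNAs")
        if not self.dispersion > 0:
            raise ValueError("dispersion must be positive")
        lo, hi = self.library_size_range
        if not (0 < lo <= hi):
            raise ValueError("library_size_range must satisfy 0 < low <= high")
        unknown_groups = {
            g for eff in self.effect_table.values() for g in eff
        } - set(self.group_names)
        if unknown_groups:
            raise ValueError(f"effect_table refers to unknown groups: {sorted(unknown_groups)}")


def rat_sequencing_design(seed: int = 0, **overrides) -> SimDesign:
    """The rat sequencing subset: naive 4, sham 5, mTBI 5, sTBI 5."""
    return replace(SimDesign(seed=seed), **overrides)


def rat_whole_cohort_design(seed: int = 0, **overrides) -> SimDesign:
    """The whole rat cohort: naive 5, sham 8, mTBI 10, sTBI 8."""
    design = SimDesign(group_sizes=(5, 8, 10, 8), seed=seed)
    return replace(design, **overrides)


def _sample_frame(design: SimDesign) -> pd.DataFrame:
    rows = []
    for group, size in zip(design.group_names, design.group_sizes):
        for i in range(size):
            rows.append({"sample_id": f"{group}_{i + 1}", "group": group})
    return pd.DataFrame(rows).set_index("sample_id")


def simulate_count_matrix(design: SimDesign) -> tuple[CountMatrix, SampleMeta]:
    """Draw a negative-binomial count matrix for the given design.

    The expected count of miRNA i in sample s of group g is

        mu_is = exp(baseline_log_mean + eps_i) * depth_s * 2**effect[i][g]

    with eps_i ~ N(0, mirna_log_sd) a per-miRNA abundance offset and
    depth_s the sample's library size divided by the range midpoint.
    Counts are NB(k=dispersion) around mu (Poisson when dispersion is
    infinite); recorded miRNA-mapped totals are the realized column sums.
    """
    rng = np.random.default_rng(design.seed)
    meta_table = _sample_frame(design)
    n_samples = len(meta_table)

    named = list(design.effect_table)
    n_noise = design.n_mirnas - len(named)
    mirna_ids = named + [f"miR-sim-{i + 1}" for i in range(n_noise)]

    eps = rng.normal(0.0, design.mirna_log_sd, size=design.n_mirnas)
    base_mean = np.exp(design.baseline_log_mean + eps)

    lo, hi = design.library_size_range
    lib_sizes = rng.integers(lo, hi + 1, size=n_samples)
    depth = lib_sizes / ((lo + hi) / 2.0)

    log2_effect = np.zeros((design.n_mirnas, n_samples))
    groups = meta_table["group"].to_numpy()
    for i, mirna in enumerate(named):
        for g, eff in design.effect_table[mirna].items():
            log2_effect[i, groups == g] = eff

    mu = base_mean[:, None] * depth[None, :] * np.exp2(log2_effect)
    if math.isinf(design.dispersion):
        counts = rng.poisson(mu)
    else:
        k = design.dispersion
        counts = rng.negative_binomial(k, k / (k + mu))

    frame = pd.DataFrame(counts, index=mirna_ids, columns=meta_table.index)
    return CountMatrix.from_counts(frame), SampleMeta(meta_table)


DEFAULT_BASELINE_CQ: dict[str, float] = {
    "miR-28-3p": 24.0,
    "miR-23a": 26.0,
    "miR-451": 23.0,
    "UniSp6": 19.0,
}
_TARGET_DEFAULT_CQ = 28.0


def simulate_cq_table(
    meta: SampleMeta,
    assays: Mapping[str, str],
    effects: Mapping[str, Mapping[str, float]] | None = None,
    noise_sd: float = 0.25,
    seed: int = 0,
    baseline_cq: Mapping[str, float] | None = None,
    hemolysis_dcq_range: tuple[float, float] = (5.5, 8.0),
    clean_dcq_range: tuple[float, float] = (1.0, 4.0),
) -> CqTable:
    """Simulate an RT-qPCR Cq table for the cohort in ``meta``.

    ``assays`` maps assay name -> role and must include a reference assay
    plus the hemolysis pair (miR-23a role ``hemolysis_23a``, miR-451 role
    ``hemolysis_451``). Relative abundance enters as Cq = baseline -
    log2-effect + Gaussian noise, so a +1 log2 effect lowers Cq by one
    cycle. Samples flagged ``hemolyzed`` in the metadata get a planted
    dCq(miR-23a - miR-451) above 5; clean samples get one well below.
    """
    roles = dict(assays)
    if AssayRole.REFERENCE not in roles.values():
        raise ValueError("assays must include a reference-role assay")
    pair_23a = [a for a, r in roles.items() if r == AssayRole.HEMOLYSIS_23A]
    pair_451 = [a for a, r in roles.items() if r == AssayRole.HEMOLYSIS_451]
    if not pair_23a or not pair_451:
        raise ValueError("assays must include the miR-23a/miR-451 hemolysis pair")

    effects = effects or {}
    baselines = dict(DEFAULT_BASELINE_CQ)
    if baseline_cq:
        baselines.update(baseline_cq)

    rng = np.random.default_rng(seed)
    groups = meta.groups
    hemolyzed = meta.table.get("hemolyzed", pd.Series(False, index=meta.table.index))

    table = pd.DataFrame(index=meta.table.index, columns=list(roles), dtype=float)
    for assay in roles:
        base = baselines.get(assay, _TARGET_DEFAULT_CQ)
        eff = effects.get(assay, {})
        shift = groups.map(lambda g: eff.get(g, 0.0)).astype(float)
        noise = rng.normal(0.0, noise_sd, size=len(table))
        table[assay] = base - shift.to_numpy() + noise

    # Plant the hemolysis signal on the 23a/451 pair.
    a23, a451 = pair_23a[0], pair_451[0]
    dcq_hemo = rng.uniform(*hemolysis_dcq_range, size=len(table))
    dcq_clean = rng.uniform(*clean_dcq_range, size=len(table))
    dcq = np.where(hemolyzed.to_numpy(bool), dcq_hemo, dcq_clean)
    table[a451] = table[a23] - dcq

    return CqTable(table, roles)


@dataclass(frozen=True)
class DdpcrAmplitudeParams:
    """Two-cluster droplet fluorescence model around a calling threshold."""

    threshold: float = 10_000.0
    negative_mean: float = 4_000.0
    positive_mean: float = 14_000.0
    negative_sd: float = 900.0
    positive_sd: float = 900.0


@dataclass
class DropletWell:
    """One ddPCR well: droplet amplitudes or positive/total counts.

    Exactly one representation is required; when amplitudes are present
    positives are the droplets at or above ``threshold``.
    """

    sample_id: str
    assay: str
    replicate: int
    threshold: float
    amplitudes: np.ndarray | None = None
    n_positive: int | None = None
    n_total: int | None = None

    def __post_init__(self) -> None:
        if self.amplitudes is None:
            if self.n_positive is None or self.n_total is None:
                raise ValueError("need droplet amplitudes or (n_positive, n_total)")
            if self.n_total < 1:
                raise ValueError("n_total must be >= 1")
            if not 0 <= self.n_positive <= self.n_total:
                raise ValueError("require 0 <= n_positive <= n_total")
        else:
            self.amplitudes = np.asarray(self.amplitudes, dtype=float)
            if self.amplitudes.size == 0:
                raise ValueError("amplitudes list is empty")

    def positive_and_total(self) -> tuple[int, int]:
        if self.amplitudes is not None:
            total = int(self.amplitudes.size)
            positive = int(np.count_nonzero(self.amplitudes >= self.threshold))
            return positive, total
        return int(self.n_positive), int(self.n_total)


def simulate_ddpcr_wells(
    meta: SampleMeta,
    assay: str,
    copies_per_well: Mapping[str, float],
    n_droplets: int = 15_000,
    amplitude_params: DdpcrAmplitudeParams | None = None,
    replicates: int = 2,
    seed: int = 0,
    emit_amplitudes: bool = True,
) -> list[DropletWell]:
    """Simulate replicate ddPCR wells for each sample.

    Template molecules partition into droplets at random, so with c copies
    among d droplets the per-droplet occupancy is Poisson(c/d) and the
    positive-droplet count is Binomial(d, 1 - exp(-c/d)). Positive and
    negative droplets then emit fluorescence from two separated Gaussian
    clusters clipped to the correct side of the calling threshold, which
    keeps cluster membership unambiguous — mirroring the manually adjusted
    thresholds with clear cluster separation that the assay relies on.
    """
    if n_droplets < 1:
        raise ValueError("n_droplets must be >= 1")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    params = amplitude_params or DdpcrAmplitudeParams()
    rng = np.random.default_rng(seed)

    # Positive-droplet counts are drawn before any amplitudes so that the
    # two output modes agree on the counts under the same seed.
    pos_counts: dict[tuple[str, int], int] = {}
    for sample_id in meta.sample_ids:
        copies = float(copies_per_well.get(sample_id, 0.0))
        if copies < 0:
            raise ValueError(f"negative copies for sample {sample_id}")
        p_pos = 1.0 - math.exp(-copies / n_droplets)
        for rep in range(1, replicates + 1):
            pos_counts[(sample_id, rep)] = int(rng.binomial(n_droplets, p_pos))

    wells: list[DropletWell] = []
    for sample_id in meta.sample_ids:
        for rep in range(1, replicates + 1):
            n_pos = pos_counts[(sample_id, rep)]
            if emit_amplitudes:
                neg = rng.normal(params.negative_mean, params.negative_sd,
                                 size=n_droplets - n_pos)
                pos = rng.normal(params.positive_mean, params.positive_sd, size=n_pos)
                neg = np.minimum(neg, params.threshold - 1.0)
                pos = np.maximum(pos, params.threshold)
                amplitudes = rng.permutation(np.concatenate([neg, pos]))
                wells.append(DropletWell(sample_id, assay, rep, params.threshold,
                                         amplitudes=amplitudes))
            else:
                wells.append(DropletWell(sample_id, assay, rep, params.threshold,
                                         n_positive=n_pos, n_total=n_droplets))
    return wells


def simulate_copies(
    meta: SampleMeta,
    group_geometric_means: Mapping[str, float],
    log_sd: float = 0.3,
    seed: int = 0,
    elevated: Mapping[str, float] | None = None,
) -> pd.Series:
    """Draw per-sample copies/well as log-normals around group geometric means.

    ``elevated`` optionally remaps individual samples to a different
    geometric mean (used for elevated subpopulations). The between-animal
    log-scale SD defaults to 0.3 (log10-ish spread of ~2-fold at 1 SD),
    a free parameter of the generator.
    """
    rng = np.random.default_rng(seed)
    gm = meta.groups.map(group_geometric_means).astype(float)
    if elevated:
        for sample_id, value in elevated.items():
            gm.loc[sample_id] = value
    if gm.isna().any():
        missing = list(gm.index[gm.isna()])
        raise ValueError(f"no geometric mean for groups of samples: {missing}")
    draws = np.exp(np.log(gm.to_numpy()) + rng.normal(0.0, log_sd, size=len(gm)))
    return pd.Series(draws, index=meta.table.index, name="copies_per_well")


# Printed normalized human ddPCR geometric means (copies/well): miR-9-3p
# control 14, mTBI bulk below the elevation threshold with an elevated
# subpopulation, sTBI 126; miR-136-3p control 138 / mTBI 220 / sTBI 188.
HUMAN_GROUP_MEANS: dict[str, dict[str, float]] = {
    "miR-9-3p": {"control": 14.0, "mTBI": 12.0, "sTBI": 126.0},
    "miR-136-3p": {"control": 138.0, "mTBI": 150.0, "sTBI": 188.0},
}
HUMAN_ELEVATED_MULTIPLIER: dict[str, float] = {"miR-9-3p": 4.0, "miR-136-3p": 3.5}
HUMAN_N_ELEVATED: dict[str, int] = {"miR-9-3p": 7, "miR-136-3p": 5}


def simulate_human_cohort(
    n_control: int = 14,
    n_mtbi: int = 15,
    n_stbi: int = 2,
    log_sd: float = 0.3,
    s100b_cutoff: float = 0.1,
    n_s100b_elevated: int = 11,
    seed: int = 0,
) -> tuple[SampleMeta, pd.DataFrame]:
    """Human cohort: controls, mTBI with elevated subpopulations, sTBI.

    Returns sample metadata (group, S100B ug/L) and a copies/well table
    with one column per assay. A fixed-size subset of mTBI patients is
    planted at an elevated geometric mean per assay (7/15 for miR-9-3p,
    5/15 for miR-136-3p, overlapping), and 11/15 mTBI patients get S100B
    above the 0.1 ug/L clinical cutoff, mirroring the cohort structure the
    clinical analysis expects.
    """
    rng = np.random.default_rng(seed)
    rows = (
        [{"sample_id": f"control_{i+1}", "group": "control"} for i in range(n_control)]
        + [{"sample_id": f"mTBI_{i+1}", "group": "mTBI"} for i in range(n_mtbi)]
        + [{"sample_id": f"sTBI_{i+1}", "group": "sTBI"} for i in range(n_stbi)]
    )
    table = pd.DataFrame(rows).set_index("sample_id")

    mtbi_ids = [s for s in table.index if table.loc[s, "group"] == "mTBI"]
    copies = {}
    for j, (assay, means) in enumerate(HUMAN_GROUP_MEANS.items()):
        n_elev = min(HUMAN_N_ELEVATED.get(assay, 0), len(mtbi_ids))
        # Overlapping subpopulations: take the first n_elev mTBI patients so
        # the miR-136 elevated set nests inside the miR-9 one.
        elevated = {
            s: means["mTBI"] * HUMAN_ELEVATED_MULTIPLIER[assay]
            for s in mtbi_ids[:n_elev]
        }
        copies[assay] = simulate_copies(
            SampleMeta(table), means, log_sd=log_sd,
            seed=int(rng.integers(2**31)), elevated=elevated,
        )
    copies_table = pd.DataFrame(copies)

    s100b = np.full(len(table), np.nan)
    group = table["group"].to_numpy()
    s100b[group == "control"] = np.exp(
        rng.normal(math.log(0.05), 0.4, size=int((group == "control").sum()))
    )
    n_mtbi_actual = int((group == "mTBI").sum())
    elev = np.zeros(n_mtbi_actual, dtype=bool)
    elev[: min(n_s100b_elevated, n_mtbi_actual)] = True
    mtbi_vals = np.where(
        elev,
        np.exp(rng.normal(math.log(0.25), 0.4, size=n_mtbi_actual)),
        np.exp(rng.normal(math.log(0.05), 0.3, size=n_mtbi_actual)),
    )
    mtbi_vals[elev] = np.maximum(mtbi_vals[elev], s100b_cutoff * 1.05)
    mtbi_vals[~elev] = np.minimum(mtbi_vals[~elev], s100b_cutoff * 0.95)
    s100b[group == "mTBI"] = mtbi_vals
    s100b[group == "sTBI"] = np.exp(
        rng.normal(math.log(0.8), 0.4, size=int((group == "sTBI").sum()))
    )
    table["s100b"] = s100b
    return SampleMeta(table), copies_table


def wells_to_frame(wells: Sequence[DropletWell]) -> pd.DataFrame:
    """Long-format droplet table (sample, assay, replicate, amplitude)."""
    records = []
    for well in wells:
        if well.amplitudes is None:
            raise ValueError("well carries counts only; nothing to serialize per droplet")
        for amp in well.amplitudes:
            records.append(
                {"sample_id": well.sample_id, "assay": well.assay,
                 "replicate": well.replicate, "amplitude": amp,
                 "threshold": well.threshold}
            )
    return pd.DataFrame(records)
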
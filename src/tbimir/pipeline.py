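"""End-to-end orchestration of the biomarker-discovery pipeline.

A single YAML-configurable run executes, in order: synthetic-cohort
generation (or ingestion of a count matrix / Cq table), sample QC,
normalization and exploratory summaries, differential expression,
nested-CV feature selection, ddPCR quantification, and ROC/cutpoint plus
elevated-subpopulation analyses. Every stage writes its artifact into the
output directory and is recorded — with a SHA-256 checksum — in a JSON
run manifest, so identical configurations reproduce identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import de, mlselect, normalize, qc, quant, rocstats, simdata
from .containers import AssayRole

logger = logging.getLogger("tbimir")

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "DEFAULT_CONFIG"]

# All analysis thresholds appear here as named defaults so the published
# analysis profile is the default profile.
DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 7,
    "outdir": "tbimir_run",
    "design": {
        "cohort": "rat_whole",  # rat_whole | rat_sequencing
        "n_mirnas": 748,
        "dispersion": 10.0,
        "effect_table": "validated_markers",  # planted marker defaults
    },
    "qc": {"a414_threshold": 0.25, "dcq_threshold": 5.0,
           "hemolyzed_fraction": 0.1},
    "normalize": {"min_count": 1, "min_fraction": 0.8,
                  "reference_assay": "miR-28-3p"},
    "de": {"contrast": ["mTBI", "naive"], "alpha": 0.05},
    "select": {
        "comparison": ["mTBI", "naive"],
        "top_k": 5,
        "n_permutations": 99,
        "grid": {"C": [1.0], "n_features": [5, 10],
                 "selection": ["f_score"], "penalty": ["l2"]},
    },
    "quantify": {
        "assay": "miR-9a-3p",
        "threshold": 10_000.0,
        "n_droplets": 15_000,
        "replicates": 2,
        "copies_log_sd": 0.3,
        "group_geometric_means": dict(simdata.RAT_DDPCR_MEAN_COPIES),
    },
    "roc": {"positive": "mTBI", "negative": "naive"},
    "flag": {"reference_group": "naive", "k_sd": 1.0},
}


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (see ``DEFAULT_CONFIG`` for keys)."""

    settings: dict[str, Any] = field(default_factory=lambda: _merge({}, DEFAULT_CONFIG))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        return cls(_merge(user, DEFAULT_CONFIG))

    @classmethod
    def from_dict(cls, user: dict[str, Any]) -> "PipelineConfig":
        return cls(_merge(user, DEFAULT_CONFIG))

    def __post_init__(self) -> None:
        s = self.settings
        if s.get("seed") is None:
            raise ValueError("a seed is mandatory for stochastic stages")
        if not 0 < s["normalize"]["min_fraction"] <= 1:
            raise ValueError("normalize.min_fraction must be in (0, 1]")
        if not 0 < s["de"]["alpha"] < 1:
            raise ValueError("de.alpha must be in (0, 1)")
        if s["qc"]["a414_threshold"] < 0 or s["qc"]["dcq_threshold"] < 0:
            raise ValueError("QC thresholds must be non-negative")


def _merge(user: dict, defaults: dict) -> dict:
    out = {}
    for key, value in defaults.items():
        if key in user and isinstance(value, dict) and isinstance(user[key], dict):
            out[key] = _merge(user[key], value)
        elif key in user:
            out[key] = user[key]
        else:
            out[key] = json.loads(json.dumps(value)) if isinstance(value, (dict, list)) else value
    for key in user:
        if key not in out:
            out[key] = user[key]
    return out


@dataclass
class RunManifest:
    """Record of one pipeline run: stages, artifacts, checksums, summaries."""

    seed: int
    outdir: str
    stages: list[dict] = field(default_factory=list)
    failed_stage: str | None = None
    error: str | None = None

    def record(self, stage: str, artifacts: list[Path], summary: dict) -> None:
        self.stages.append(
            {
                "stage": stage,
                "artifacts": [
                    {"path": str(p), "sha256": _sha256(p)} for p in artifacts
                ],
                "summary": summary,
            }
        )

    @property
    def complete(self) -> bool:
        return self.failed_stage is None

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "outdir": self.outdir,
            "complete": self.complete,
            "failed_stage": self.failed_stage,
            "error": self.error,
            "stages": self.stages,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, default=_jsonable)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    digest.update(path.read_bytes())
    return digest.hexdigest()


def _build_design(cfg: dict, seed: int) -> simdata.SimDesign:
    effects = cfg.get("effect_table")
    if effects == "validated_markers":
        effects = simdata.RAT_COUNT_EFFECTS
    kwargs = {"n_mirnas": cfg["n_mirnas"], "dispersion": cfg["dispersion"],
              "effect_table": effects or {}}
    if cfg["cohort"] == "rat_whole":
        return simdata.rat_whole_cohort_design(seed=seed, **kwargs)
    if cfg["cohort"] == "rat_sequencing":
        return simdata.rat_sequencing_design(seed=seed, **kwargs)
    raise ValueError(f"unknown cohort {cfg['cohort']!r}")


def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None) -> RunManifest:
    """Execute all stages in order, writing artifacts and a manifest.

    On a stage failure the manifest records the failing stage and the
    stages already completed, and is still written to disk.
    """
    s = config.settings
    seed = int(s["seed"])
    out = Path(outdir or s["outdir"])
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    manifest = RunManifest(seed=seed, outdir=str(out))

    stage = "simulate"
    try:
        # --- simulate -----------------------------------------------------
        logger.info("stage simulate")
        design = _build_design(s["design"], seed)
        cm, meta = simdata.simulate_count_matrix(design)
        frac_hemo = s["qc"]["hemolyzed_fraction"]
        n_hemo = int(round(frac_hemo * len(meta.sample_ids)))
        hemo_flags = np.zeros(len(meta.sample_ids), dtype=bool)
        hemo_flags[:n_hemo] = True
        meta.table["hemolyzed"] = rng.permutation(hemo_flags)
        meta.table["a414"] = np.where(
            meta.table["hemolyzed"],
            rng.uniform(0.30, 0.60, len(meta.table)),
            rng.uniform(0.05, 0.22, len(meta.table)),
        )
        assays = {
            "miR-9a-3p": AssayRole.TARGET,
            "miR-136-3p": AssayRole.TARGET,
            "miR-434-3p": AssayRole.TARGET,
            "miR-28-3p": AssayRole.REFERENCE,
            "miR-23a": AssayRole.HEMOLYSIS_23A,
            "miR-451": AssayRole.HEMOLYSIS_451,
        }
        cq_effects = {
            assay: effects
            for assay, effects in simdata.RAT_COUNT_EFFECTS.items()
        }
        cq = simdata.simulate_cq_table(
            meta, assays, effects={k.replace("rno-", ""): v for k, v in cq_effects.items()},
            seed=int(rng.integers(2**31)),
        )
        counts_path = out / "counts.tsv"
        meta_path = out / "samples.tsv"
        cq_path = out / "cq.csv"
        cm.to_tsv(counts_path)
        meta.to_tsv(meta_path)
        cq.to_csv(cq_path)
        manifest.record(stage, [counts_path, meta_path, cq_path],
                        {"n_mirnas": cm.n_mirnas, "n_samples": cm.n_samples})

        # --- qc -----------------------------------------------------------
        stage = "qc"
        logger.info("stage qc")
        hemo_abs = qc.assess_absorbance(
            meta.table["a414"].to_dict(), threshold=s["qc"]["a414_threshold"]
        )
        hemo_dcq = qc.assess_dcq(cq, threshold=s["qc"]["dcq_threshold"])
        ranges = {"miR-28-3p": (18.0, 30.0), "miR-23a": (18.0, 32.0)}
        report = qc.build_qc_report(hemo_abs + hemo_dcq, cq, ranges)
        qc_path = out / "qc_report.json"
        report.to_json(qc_path)
        manifest.record(stage, [qc_path], {
            "fraction_hemolyzed_absorbance": qc.hemolyzed_fraction(hemo_abs),
            "fraction_hemolyzed_dcq": qc.hemolyzed_fraction(hemo_dcq),
        })

        # --- normalize ----------------------------------------------------
        stage = "normalize"
        logger.info("stage normalize")
        cpm_matrix = normalize.cpm(cm)
        filtered = normalize.prevalence_filter(
            cm, min_count=s["normalize"]["min_count"],
            min_fraction=s["normalize"]["min_fraction"],
        )
        eda = normalize.eda_summary(cpm_matrix, meta.groups, raw_counts=cm.counts)
        cpm_path = out / "cpm.tsv"
        eda_path = out / "eda_summary.json"
        cpm_matrix.to_csv(cpm_path, sep="\t", index_label="mirna_id")
        with open(eda_path, "w") as fh:
            json.dump(eda.to_dict(), fh, indent=2)
        manifest.record(stage, [cpm_path, eda_path], {
            "n_after_prevalence_filter": filtered.n_mirnas,
            "venn": eda.venn_counts,
        })

        # --- de -------------------------------------------------------------
        stage = "de"
        logger.info("stage de")
        contrast = tuple(s["de"]["contrast"])
        de_res = de.nb_wald_test(filtered, meta, contrast, alpha=s["de"]["alpha"])
        de_path = out / "de_results.tsv"
        de_res.to_tsv(de_path)
        manifest.record(stage, [de_path], {
            "contrast": list(contrast),
            "n_significant": int(de_res.table["significant"].sum()),
        })

        # --- select ---------------------------------------------------------
        stage = "select"
        logger.info("stage select")
        pos_group, neg_group = s["select"]["comparison"]
        ids = meta.samples_in(pos_group) + meta.samples_in(neg_group)
        features = filtered.subset_samples(ids).counts.T
        labels = [1] * len(meta.samples_in(pos_group)) + [0] * len(meta.samples_in(neg_group))
        grid = mlselect.HyperGrid(
            C=tuple(s["select"]["grid"]["C"]),
            n_features=tuple(s["select"]["grid"]["n_features"]),
            selection=tuple(s["select"]["grid"]["selection"]),
            penalty=tuple(s["select"]["grid"]["penalty"]),
        )
        ml_seed = int(rng.integers(2**31))
        report_cv = mlselect.nested_cv(
            features, labels, grid, seed=ml_seed,
            comparison=(neg_group, pos_group),
        )
        report_cv.permutation_p = mlselect.permutation_test(
            features, labels, grid,
            n_permutations=int(s["select"]["n_permutations"]),
            seed=ml_seed, observed=report_cv,
        )
        report_cv.n_permutations = int(s["select"]["n_permutations"])
        candidates = mlselect.select_candidates(report_cv, de_res,
                                                top_k=int(s["select"]["top_k"]))
        select_path = out / "selection_report.json"
        with open(select_path, "w") as fh:
            json.dump(
                {
                    "comparison": list(report_cv.comparison),
                    "cv_auc": report_cv.cv_auc,
                    "permutation_p": report_cv.permutation_p,
                    "n_permutations": report_cv.n_permutations,
                    "importance": {k: float(v) for k, v in report_cv.importance.items()},
                    "selected_grid": report_cv.selected_grid,
                    "candidates": candidates.candidates,
                },
                fh, indent=2, default=_jsonable,
            )
        manifest.record(stage, [select_path], {
            "cv_auc": report_cv.cv_auc,
            "permutation_p": report_cv.permutation_p,
            "candidates": candidates.feature_ids,
            "validation_priority": candidates.validation_priority,
        })

        # --- quantify -------------------------------------------------------
        stage = "quantify"
        logger.info("stage quantify")
        qcfg = s["quantify"]
        copies_truth = simdata.simulate_copies(
            meta, qcfg["group_geometric_means"], log_sd=qcfg["copies_log_sd"],
            seed=int(rng.integers(2**31)),
        )
        wells = simdata.simulate_ddpcr_wells(
            meta, qcfg["assay"], copies_truth.to_dict(),
            n_droplets=int(qcfg["n_droplets"]),
            amplitude_params=simdata.DdpcrAmplitudeParams(threshold=qcfg["threshold"]),
            replicates=int(qcfg["replicates"]),
            seed=int(rng.integers(2**31)),
            emit_amplitudes=False,
        )
        copies_table = pd.Series(
            {w.sample_id: quant.summarize_replicates(
                [x for x in wells if x.sample_id == w.sample_id]).copies_per_well
             for w in wells},
            name=qcfg["assay"],
        )
        fold = quant.group_fold_change(copies_table, meta,
                                       tuple(s["de"]["contrast"]))
        copies_path = out / "copies.tsv"
        copies_table.to_csv(copies_path, sep="\t", index_label="sample_id",
                            header=["copies_per_well"])
        manifest.record(stage, [copies_path], {
            "assay": qcfg["assay"],
            "fold_change": fold,
            "contrast": s["de"]["contrast"],
        })

        # --- roc ------------------------------------------------------------
        stage = "roc"
        logger.info("stage roc")
        pos = copies_table[meta.samples_in(s["roc"]["positive"])]
        neg = copies_table[meta.samples_in(s["roc"]["negative"])]
        cut = rocstats.optimal_cutpoint(
            pos.to_numpy(), neg.to_numpy(),
            comparison=(s["roc"]["positive"], s["roc"]["negative"]),
        )
        roc_path = out / "cutpoint.json"
        with open(roc_path, "w") as fh:
            json.dump(cut.to_dict(), fh, indent=2)
        manifest.record(stage, [roc_path], cut.to_dict())

        # --- flag -----------------------------------------------------------
        stage = "flag"
        logger.info("stage flag")
        flags = rocstats.flag_elevated(
            copies_table, meta, s["flag"]["reference_group"],
            k_sd=float(s["flag"]["k_sd"]),
        )
        flag_path = out / "elevated_flags.tsv"
        flags.flags.to_csv(flag_path, sep="\t", index_label="sample_id")
        manifest.record(stage, [flag_path], {
            "threshold": flags.threshold, **flags.counts(),
        })
    except Exception as exc:  # record partial completion, then re-raise
        manifest.failed_stage = stage
        manifest.error = f"{type(exc).__name__}: {exc}"
        manifest.to_json(out / "manifest.json")
        raise

    manifest.to_json(out / "manifest.json")
    return manifest
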
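"""Sample-level quality control for plasma miRNA studies.

Two independent hemolysis checks are supported: absorbance at 414 nm
(free-hemoglobin peak; a hemolysis coefficient above 0.25 flags the
sample) and the dCq method, where red-blood-cell-derived miR-451 inflates
with hemolysis so that Cq(miR-23a) - Cq(miR-451) above 5 cycles flags the
sample. The two checks assess different stages (plasma vs extracted RNA)
and may disagree; both flags are carried and no sample is excluded here.
A QC report additionally checks that endogenous and spike-in assays fall
within expected Cq ranges.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import AssayRole, CqTable

__all__ = [
    "HemolysisRecord",
    "QCReport",
    "assess_absorbance",
    "assess_dcq",
    "hemolyzed_fraction",
    "build_qc_report",
    "A414_THRESHOLD",
    "DCQ_THRESHOLD",
]

A414_THRESHOLD = 0.25
DCQ_THRESHOLD = 5.0


@dataclass
class HemolysisRecord:
    """Hemolysis status of one sample under either or both checks."""

    sample_id: str
    a414_coefficient: float | None = None
    delta_cq: float | None = None
    hemolyzed_by_absorbance: bool | None = None
    hemolyzed_by_dcq: bool | None = None

    @property
    def hemolyzed(self) -> bool:
        """Flagged by at least one applicable method."""
        return bool(self.hemolyzed_by_absorbance) or bool(self.hemolyzed_by_dcq)


def assess_absorbance(
    records: Sequence[tuple[str, float]] | Mapping[str, float],
    threshold: float = A414_THRESHOLD,
) -> list[HemolysisRecord]:
    """Flag samples whose 414-nm hemolysis coefficient exceeds ``threshold``.

    The inequality is strict: a coefficient exactly at the threshold passes.
    """
    if isinstance(records, Mapping):
        records = list(records.items())
    out = []
    for sample_id, a414 in records:
        if a414 < 0:
            raise ValueError(f"negative absorbance coefficient for {sample_id}")
        out.append(
            HemolysisRecord(
                sample_id=sample_id,
                a414_coefficient=float(a414),
                hemolyzed_by_absorbance=a414 > threshold,
            )
        )
    return out


def assess_dcq(cq: CqTable, threshold: float = DCQ_THRESHOLD,
               assay_23a: str | None = None,
               assay_451: str | None = None) -> list[HemolysisRecord]:
    """Flag samples with dCq(miR-23a - miR-451) strictly above ``threshold``.

    Samples missing either pair member are marked unassessable (both the
    delta and the flag stay None) rather than flagged.
    """
    a23 = assay_23a or _single_role(cq, AssayRole.HEMOLYSIS_23A, "miR-23a")
    a451 = assay_451 or _single_role(cq, AssayRole.HEMOLYSIS_451, "miR-451")
    out = []
    for sample_id in cq.sample_ids:
        cq23 = cq.cq.at[sample_id, a23] if a23 in cq.cq.columns else np.nan
        cq451 = cq.cq.at[sample_id, a451] if a451 in cq.cq.columns else np.nan
        if pd.isna(cq23) or pd.isna(cq451):
            out.append(HemolysisRecord(sample_id=sample_id))
            continue
        dcq = float(cq23 - cq451)
        out.append(
            HemolysisRecord(sample_id=sample_id, delta_cq=dcq,
                            hemolyzed_by_dcq=dcq > threshold)
        )
    return out


def _single_role(cq: CqTable, role: str, fallback_name: str) -> str:
    assays = cq.assays_with_role(role)
    if assays:
        return assays[0]
    if fallback_name in cq.cq.columns:
        return fallback_name
    raise ValueError(f"Cq table has no assay for role {role!r}")


def hemolyzed_fraction(records: Sequence[HemolysisRecord]) -> float:
    """Fraction of assessable samples flagged by any applicable method."""
    assessable = [
        r for r in records
        if r.hemolyzed_by_absorbance is not None or r.hemolyzed_by_dcq is not None
    ]
    if not assessable:
        raise ValueError("no assessable samples")
    return sum(r.hemolyzed for r in assessable) / len(assessable)


@dataclass
class QCReport:
    """Per-sample QC outcome: hemolysis flags plus Cq range checks."""

    hemolysis: list[HemolysisRecord]
    range_checks: pd.DataFrame  # samples x assays, boolean pass
    failed_assays: dict[str, list[str]] = field(default_factory=dict)

    @property
    def overall_pass(self) -> pd.Series:
        return self.range_checks.all(axis=1)

    def to_dict(self) -> dict:
        return {
            "hemolysis": [asdict(r) for r in self.hemolysis],
            "range_checks": {
                s: {a: bool(v) for a, v in row.items()}
                for s, row in self.range_checks.iterrows()
            },
            "failed_assays": self.failed_assays,
            "overall_pass": {s: bool(v) for s, v in self.overall_pass.items()},
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def to_text(self) -> str:
        lines = ["Sample QC report", "================"]
        for rec in self.hemolysis:
            bits = []
            if rec.a414_coefficient is not None:
                verdict = "HEMOLYZED" if rec.hemolyzed_by_absorbance else "ok"
                bits.append(f"A414 {rec.a414_coefficient:.3f} ({verdict})")
            if rec.delta_cq is not None:
                verdict = "HEMOLYZED" if rec.hemolyzed_by_dcq else "ok"
                bits.append(f"dCq {rec.delta_cq:+.2f} ({verdict})")
            if not bits:
                bits.append("hemolysis unassessable")
            lines.append(f"  {rec.sample_id}: " + "; ".join(bits))
        lines.append("Cq range checks:")
        for sample_id, ok in self.overall_pass.items():
            if ok:
                lines.append(f"  {sample_id}: pass")
            else:
                failed = ", ".join(self.failed_assays.get(sample_id, []))
                lines.append(f"  {sample_id}: FAIL ({failed})")
        return "\n".join(lines)


def build_qc_report(
    hemo: Sequence[HemolysisRecord],
    cq: CqTable,
    expected_ranges: Mapping[str, tuple[float, float]],
) -> QCReport:
    """Combine hemolysis records with per-assay Cq range checks.

    A sample passes overall iff every checked assay's Cq lies inside its
    expected (lo, hi) range, inclusive; missing Cq values fail the check.
    """
    if not list(hemo) and cq.cq.empty:
        raise ValueError("empty QC inputs")
    if not expected_ranges:
        raise ValueError("no expected Cq ranges supplied")
    unknown = set(expected_ranges) - set(cq.assays)
    if unknown:
        raise ValueError(f"expected ranges for unknown assays: {sorted(unknown)}")

    checks = pd.DataFrame(index=cq.cq.index, columns=list(expected_ranges), dtype=bool)
    failed: dict[str, list[str]] = {}
    for assay, (lo, hi) in expected_ranges.items():
        values = cq.cq[assay]
        ok = (values >= lo) & (values <= hi) & values.notna()
        checks[assay] = ok
        for sample_id in checks.index[~ok]:
            failed.setdefault(sample_id, []).append(assay)
    return QCReport(hemolysis=list(hemo), range_checks=checks, failed_assays=failed)
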
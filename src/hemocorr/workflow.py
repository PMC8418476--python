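"""Automated result-handling workflow for hemolyzed NSE specimens.

Routes each specimen through a rule cascade: clean specimens are released;
hemolyzed ones are annotated with the HI, and only those where a corrected
value would change a clinical decision (diagnosis of SCLC/NB, or a >25%
move in trend monitoring) trigger the individualized correction — which
requires the patient's NSE/HI lysate ratio, so specimens lacking it are
flagged ``needs_ratio`` instead.  Gating correction on clinical need keeps
alert volume down (alert-fatigue avoidance).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import pandas as pd

from .correction import (
    NSE_ASSAY_CEILING,
    NSE_ASSAY_FLOOR,
    PersonalizedModel,
    RbcRatio,
    correct_nse,
)
from .exceptions import ValidationError
from .indices import HemolysisIndex

__all__ = [
    "Purpose",
    "Action",
    "SpecimenRecord",
    "DecisionConfig",
    "ReportEntry",
    "decide",
    "run_pipeline",
    "PipelineSummary",
    "read_specimens",
    "write_report",
]

#: NSE stratum boundaries (μg/L) used in prevalence summaries; intervals are
#: left-open, right-closed: (0, 16.3], (16.3, 50], (50, 100], (100, 370].
DEFAULT_STRATA = (16.3, 50.0, 100.0, 370.0)


class Purpose(str, Enum):
    TREND = "trend"
    DIAGNOSIS = "diagnosis"
    OTHER = "other"


class Action(str, Enum):
    RELEASE = "release"
    RELEASE_WITH_HI_NOTE = "release_with_hi_note"
    NEEDS_RATIO = "needs_ratio"
    CORRECTED_REPORT = "corrected_report"


@dataclass(frozen=True)
class SpecimenRecord:
    """One serum NSE measurement event flowing through the pipeline."""

    specimen_id: str
    patient_id: str
    nse_meas: float
    hi: HemolysisIndex
    purpose: Purpose = Purpose.OTHER
    prior_nse: Optional[float] = None
    r: Optional[RbcRatio] = None
    timestamp: Optional[str] = None

    def __post_init__(self) -> None:
        if not NSE_ASSAY_FLOOR <= self.nse_meas <= NSE_ASSAY_CEILING:
            raise ValueError(
                f"NSE {self.nse_meas} μg/L outside assay range "
                f"[{NSE_ASSAY_FLOOR}, {NSE_ASSAY_CEILING}]"
            )


@dataclass(frozen=True)
class DecisionConfig:
    """Cutoffs driving the decision cascade."""

    hi_cutoff: float = 5.0
    nse_cutoff: float = 16.3  # reference upper limit of the NSE assay
    trend_delta_pct: float = 25.0  # clinically important trend change
    bias_limit_pct: float = 20.0

    def __post_init__(self) -> None:
        for name in ("hi_cutoff", "nse_cutoff", "trend_delta_pct", "bias_limit_pct"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @classmethod
    def from_json(cls, path) -> "DecisionConfig":
        with open(path, encoding="utf-8") as fh:
            d = json.load(fh)
        return cls(**{k: d[k] for k in
                      ("hi_cutoff", "nse_cutoff", "trend_delta_pct", "bias_limit_pct")
                      if k in d})


@dataclass(frozen=True)
class ReportEntry:
    """Per-specimen routing outcome with a rule trace."""

    specimen_id: str
    action: Action
    original_nse: float
    hi: int
    rationale: str
    corrected_nse: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.rationale:
            raise ValueError("rationale must be nonempty")
        has_corr = self.corrected_nse is not None
        if has_corr != (self.action is Action.CORRECTED_REPORT):
            raise ValueError("corrected_nse present iff action is corrected_report")


def decide(
    record: SpecimenRecord,
    config: DecisionConfig | None = None,
    model: PersonalizedModel | None = None,
) -> ReportEntry:
    """Route one specimen through the decision cascade.

    Rules, in order (exactly one fires):

    1. HI at or below the cutoff -> ``release`` (no hemolysis interference).
    2. Hemolyzed but NSE at or below the reference limit -> release with an
       HI note (a correction could only lower an already-normal value).
    3. Hemolyzed, NSE above the limit, and clinically actionable — purpose is
       diagnosis, or purpose is trend with a prior result and a move larger
       than the trend threshold -> ``corrected_report`` when the patient's
       lysate ratio is available, else ``needs_ratio``.
    4. Otherwise -> release with an HI note (annotate, don't alert).
    """
    config = config or DecisionConfig()
    hi_v = record.hi.value

    if hi_v <= config.hi_cutoff:
        return ReportEntry(
            record.specimen_id, Action.RELEASE, record.nse_meas, hi_v,
            rationale=f"rule1: HI {hi_v} <= cutoff {config.hi_cutoff:g}",
        )
    if record.nse_meas <= config.nse_cutoff:
        return ReportEntry(
            record.specimen_id, Action.RELEASE_WITH_HI_NOTE, record.nse_meas, hi_v,
            rationale=(
                f"rule2: hemolyzed (HI {hi_v}) but NSE {record.nse_meas:g} <= "
                f"{config.nse_cutoff:g} μg/L"
            ),
        )

    need, why = _clinical_need(record, config)
    if need:
        if record.r is None:
            return ReportEntry(
                record.specimen_id, Action.NEEDS_RATIO, record.nse_meas, hi_v,
                rationale=f"rule3: {why}; patient NSE/HI ratio not on file",
            )
        if model is None:
            raise ValueError("a PersonalizedModel is required to correct results")
        corr = correct_nse(record.nse_meas, hi_v, record.r, model)
        return ReportEntry(
            record.specimen_id, Action.CORRECTED_REPORT, record.nse_meas, hi_v,
            rationale=(
                f"rule3: {why}; corrected with R={record.r.r:g} "
                f"(increment {corr.increment:.2f} μg/L"
                + (", clamped at assay floor)" if corr.clamped else ")")
            ),
            corrected_nse=corr.nse_corr,
        )
    return ReportEntry(
        record.specimen_id, Action.RELEASE_WITH_HI_NOTE, record.nse_meas, hi_v,
        rationale=f"rule4: hemolyzed, NSE above limit, but {why}",
    )


def _clinical_need(record: SpecimenRecord, config: DecisionConfig) -> tuple[bool, str]:
    if record.purpose is Purpose.DIAGNOSIS:
        return True, "auxiliary diagnosis (SCLC/NB)"
    if record.purpose is Purpose.TREND:
        if record.prior_nse is None:
            return False, "trend purpose without prior result (warning)"
        delta = abs(record.nse_meas - record.prior_nse) / record.prior_nse * 100.0
        if delta > config.trend_delta_pct:
            return True, (
                f"trend change {delta:.1f}% > {config.trend_delta_pct:g}%"
            )
        return False, (
            f"trend change {delta:.1f}% <= {config.trend_delta_pct:g}% "
            "(not clinically important)"
        )
    return False, "no diagnosis/trend indication"


@dataclass
class PipelineSummary:
    """Hemolysis prevalence overall and per NSE stratum."""

    n_total: int
    n_hemolyzed: int
    strata: list[dict]  # label, n, n_hemolyzed, rate (None when n == 0)
    action_counts: dict[str, int] = field(default_factory=dict)

    @property
    def overall_rate(self) -> float:
        return self.n_hemolyzed / self.n_total


def run_pipeline(
    records: Sequence[SpecimenRecord],
    config: DecisionConfig | None = None,
    model: PersonalizedModel | None = None,
    strata: Sequence[float] = DEFAULT_STRATA,
) -> tuple[list[ReportEntry], PipelineSummary]:
    """Decide every record and summarize hemolysis prevalence.

    Strata are left-open/right-closed NSE intervals with upper edges from
    ``strata``.  Empty strata report a rate of ``None`` rather than dividing
    by zero.  Order of entries follows the input order.
    """
    if not records:
        raise ValueError("no records to process")
    config = config or DecisionConfig()
    entries = [decide(r, config, model) for r in records]

    edges = [0.0] + list(strata)
    stratum_stats = []
    for lo, hi_edge in zip(edges[:-1], edges[1:]):
        members = [r for r in records if lo < r.nse_meas <= hi_edge]
        n = len(members)
        n_hem = sum(1 for r in members if r.hi.value > config.hi_cutoff)
        stratum_stats.append(
            {
                "label": f"{lo:g} < NSE <= {hi_edge:g}",
                "n": n,
                "n_hemolyzed": n_hem,
                "rate": (n_hem / n) if n else None,
            }
        )
    n_hem_total = sum(1 for r in records if r.hi.value > config.hi_cutoff)
    counts: dict[str, int] = {}
    for e in entries:
        counts[e.action.value] = counts.get(e.action.value, 0) + 1
    summary = PipelineSummary(
        n_total=len(records),
        n_hemolyzed=n_hem_total,
        strata=stratum_stats,
        action_counts=counts,
    )
    return entries, summary


_SPECIMEN_COLUMNS = ["specimen_id", "patient_id", "nse_meas", "hi", "purpose",
                     "prior_nse", "r", "timestamp"]


def read_specimens(path) -> tuple[list[SpecimenRecord], list[str]]:
    """Read specimen records from CSV; returns ``(records, row_errors)``.

    Malformed rows are collected with their row number rather than aborting
    the whole file or being silently dropped.
    """
    df = pd.read_csv(path, dtype={"specimen_id": str, "patient_id": str,
                                  "timestamp": str})
    missing = [c for c in _SPECIMEN_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"missing required columns: {missing}")
    records: list[SpecimenRecord] = []
    errors: list[str] = []
    for i, row in enumerate(df.itertuples(), start=2):  # header is line 1
        try:
            hi_val = int(row.hi)
            hi = (HemolysisIndex(0, censored_low=True) if hi_val < 1
                  else HemolysisIndex(hi_val))
            prior = None if pd.isna(row.prior_nse) else float(row.prior_nse)
            r = None if pd.isna(row.r) else RbcRatio(float(row.r))
            ts = None if pd.isna(row.timestamp) else str(row.timestamp)
            records.append(
                SpecimenRecord(
                    specimen_id=str(row.specimen_id),
                    patient_id=str(row.patient_id),
                    nse_meas=float(row.nse_meas),
                    hi=hi,
                    purpose=Purpose(str(row.purpose)),
                    prior_nse=prior,
                    r=r,
                    timestamp=ts,
                )
            )
        except (ValueError, TypeError) as exc:
            errors.append(f"line {i}: {exc}")
    return records, errors


def write_specimens(records: Sequence[SpecimenRecord], path) -> None:
    """CSV writer; inverse of :func:`read_specimens` for valid records."""
    rows = [
        {
            "specimen_id": r.specimen_id,
            "patient_id": r.patient_id,
            "nse_meas": r.nse_meas,
            "hi": r.hi.value,
            "purpose": r.purpose.value,
            "prior_nse": r.prior_nse,
            "r": r.r.r if r.r is not None else None,
            "timestamp": r.timestamp,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=_SPECIMEN_COLUMNS).to_csv(path, index=False)


def write_report(entries: Sequence[ReportEntry], path) -> None:
    """Write routing decisions as CSV."""
    rows = [
        {
            "specimen_id": e.specimen_id,
            "action": e.action.value,
            "original_nse": e.original_nse,
            "hi": e.hi,
            "corrected_nse": e.corrected_nse,
            "rationale": e.rationale,
        }
        for e in entries
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
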
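"""Record-level quality-control rules for cohort assembly.

Records are excluded when TST falls outside [180, 720] minutes, sleep
latency outside [60, 18000] seconds, sleep efficiency below 0.6, or
overall STE below 1 bit (too few episodes for the entropy to be
informative). All comparisons are strict inequalities, so a record sitting
exactly on a threshold (TST = 180 min, SE = 0.6, STE = 1.0) is retained.
A record with no sleep at all fails with a dedicated flag rather than a
numeric rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .classic import ClassicMetrics
from .entropy import EntropyProfile

#: First-rule attribution order for cohort summaries.
RULE_ORDER: tuple[str, ...] = ("tst_out_of_range", "sol_out_of_range", "se_low", "ste_low")


@dataclass(frozen=True)
class QCThresholds:
    """Exclusion thresholds; all bounds are strict (value < lo or > hi fails)."""

    tst_lo_min: float = 180.0
    tst_hi_min: float = 720.0
    sol_lo_sec: float = 60.0
    sol_hi_sec: float = 18000.0
    se_lo: float = 0.6
    overall_ste_lo_bits: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.tst_lo_min < self.tst_hi_min):
            raise ValueError("TST bounds must satisfy 0 < lo < hi")
        if not (0 < self.sol_lo_sec < self.sol_hi_sec):
            raise ValueError("SOL bounds must satisfy 0 < lo < hi")
        if self.se_lo <= 0 or self.overall_ste_lo_bits <= 0:
            raise ValueError("SE and STE thresholds must be positive")


@dataclass(frozen=True)
class QCResult:
    """Per-rule outcomes for one record; ``passed`` iff every flag is False."""

    record_id: str
    tst_out_of_range: bool
    sol_out_of_range: bool
    se_low: bool
    ste_low: bool
    no_sleep: bool

    @property
    def passed(self) -> bool:
        return not (
            self.tst_out_of_range
            or self.sol_out_of_range
            or self.se_low
            or self.ste_low
            or self.no_sleep
        )

    def as_dict(self) -> dict[str, object]:
        return {
            "record_id": self.record_id,
            "tst_out_of_range": self.tst_out_of_range,
            "sol_out_of_range": self.sol_out_of_range,
            "se_low": self.se_low,
            "ste_low": self.ste_low,
            "no_sleep": self.no_sleep,
            "qc_pass": self.passed,
        }


def apply_qc(
    metrics: ClassicMetrics | None,
    profile: EntropyProfile | None,
    thresholds: QCThresholds | None = None,
) -> QCResult:
    """Evaluate every exclusion rule for one record.

    ``metrics``/``profile`` may be ``None`` for a record with no sleep
    period; such a record fails with the ``no_sleep`` flag only.
    """
    t = thresholds or QCThresholds()
    if metrics is None or profile is None:
        rid = metrics.record_id if metrics is not None else "unknown"
        return QCResult(rid, False, False, False, False, True)
    return QCResult(
        record_id=metrics.record_id,
        tst_out_of_range=(metrics.tst_min < t.tst_lo_min or metrics.tst_min > t.tst_hi_min),
        sol_out_of_range=(metrics.sol_sec < t.sol_lo_sec or metrics.sol_sec > t.sol_hi_sec),
        se_low=metrics.se_fraction < t.se_lo,
        ste_low=profile.overall_ste < t.overall_ste_lo_bits,
        no_sleep=False,
    )


def qc_cohort(
    records: Sequence[tuple[ClassicMetrics | None, EntropyProfile | None]],
    thresholds: QCThresholds | None = None,
) -> tuple[pd.DataFrame, list[QCResult]]:
    """Apply QC across a cohort and summarize per-rule exclusions.

    Returns a one-row summary DataFrame — overlapping counts per rule
    (a record may trip several), first-rule-attributed counts in the order
    TST -> SOL -> SE -> STE, and the retained count — plus the per-record
    results.
    """
    results = [apply_qc(m, p, thresholds) for m, p in records]
    summary: dict[str, int] = {"n_records": len(results)}
    for rule in RULE_ORDER + ("no_sleep",):
        summary[f"{rule}_overlapping"] = sum(getattr(r, rule) for r in results)
    attributed = {rule: 0 for rule in RULE_ORDER + ("no_sleep",)}
    for r in results:
        if r.passed:
            continue
        if r.no_sleep:
            attributed["no_sleep"] += 1
            continue
        for rule in RULE_ORDER:
            if getattr(r, rule):
                attributed[rule] += 1
                break
    for rule, n in attributed.items():
        summary[f"{rule}_first_rule"] = n
    summary["retained"] = sum(r.passed for r in results)
    return pd.DataFrame([summary]), results


def write_qc_report(results: Sequence[QCResult], path: str | Path) -> None:
    """Write one row per record, one column per flag, as CSV."""
    pd.DataFrame([r.as_dict() for r in results]).to_csv(path, index=False)
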
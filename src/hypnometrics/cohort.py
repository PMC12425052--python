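"""Cohort feature pipeline: per-record metrics, QC, quintiles, correlations.

The feature table is the hand-off boundary to downstream modelling
(survival analysis, gradient boosting, ...), which this package does not
reimplement. Undefined entropies are stored as missing values (NaN),
never 0, and correlations are computed pairwise-complete so that
absent-stage sentinels cannot silently become zeros.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .classic import ArousalEvents, compute_classic
from .entropy import entropy_profile
from .hypnogram import CANONICAL_STAGES, Hypnogram
from .qc import QCThresholds, apply_qc
from .segmentation import NoSleepError

#: Fixed column set of the feature table, in order.
FEATURE_COLUMNS: tuple[str, ...] = (
    "record_id",
    "tst_min",
    "tib_min",
    "se_fraction",
    "sol_sec",
    "waso_min",
    "n_awakenings",
    "sfi_per_hour",
    "rem_latency_min",
    "ari_per_hour",
    *(f"min_{s.lower()}" for s in CANONICAL_STAGES),
    "overall_ste",
    "wake_te",
    "n1_ste",
    "n2_ste",
    "n3_ste",
    "rem_ste",
    "nrem_ste",
    "qc_pass",
    "error",
)

#: Numeric metric columns considered by metric_correlations.
NUMERIC_COLUMNS: tuple[str, ...] = tuple(
    c for c in FEATURE_COLUMNS if c not in ("record_id", "qc_pass", "error")
)


def compute_features(
    records: Sequence[Hypnogram],
    events: Mapping[str, ArousalEvents] | None = None,
    thresholds: QCThresholds | None = None,
) -> pd.DataFrame:
    """Compute the full per-record feature table.

    Every record yields a row. QC flags are included but nothing is
    filtered — retention is the caller's choice. A record that fails to
    process (e.g. no sleep period) gets a row with its error message and
    missing metrics rather than aborting the batch.
    """
    rows: list[dict] = []
    for h in records:
        row: dict = {c: np.nan for c in FEATURE_COLUMNS}
        row["record_id"] = h.record_id
        row["error"] = ""
        try:
            ev = events.get(h.record_id) if events else None
            metrics = compute_classic(h, ev)
            profile = entropy_profile(h)
        except NoSleepError as exc:
            row["qc_pass"] = False
            row["error"] = str(exc)
            rows.append(row)
            continue
        for key, val in metrics.as_dict().items():
            row[key] = np.nan if val is None else val
        for key, val in profile.as_dict().items():
            row[key] = np.nan if val is None else val
        row["qc_pass"] = apply_qc(metrics, profile, thresholds).passed
        rows.append(row)
    return pd.DataFrame(rows, columns=list(FEATURE_COLUMNS))


@dataclass(frozen=True)
class QuintileAssignment:
    """Quintile labels Q1..Q5 for one metric, plus the cut points used.

    Ties at a cut point fall in the lower quintile (type-1 empirical
    quantiles); missing values stay unassigned (None).
    """

    labels: tuple[str | None, ...]
    cut_points: tuple[float, ...]
    metric: str = ""


def assign_quintiles(values: Sequence[float], k: int = 5,
                     metric: str = "") -> QuintileAssignment:
    """Split values at the 20/40/60/80th percentiles into Q1..Q5.

    Cut points are type-1 (inverted-CDF) empirical quantiles of the
    non-missing values; a value equal to a cut point is assigned to the
    lower quintile. Requires at least ``k`` non-missing values.
    """
    arr = np.asarray(values, dtype=float)
    finite = arr[np.isfinite(arr)]
    if finite.size < k:
        raise ValueError(f"need at least {k} non-missing values, got {finite.size}")
    qs = np.arange(1, k) / k
    cuts = np.quantile(finite, qs, method="inverted_cdf")
    labels: list[str | None] = []
    for v in arr:
        if not np.isfinite(v):
            labels.append(None)
        else:
            # v == cut -> side="left" places it below the cut (lower quintile)
            labels.append(f"Q{int(np.searchsorted(cuts, v, side='left')) + 1}")
    return QuintileAssignment(tuple(labels), tuple(float(c) for c in cuts), metric)


def metric_correlations(table: pd.DataFrame, method: str = "pearson") -> pd.DataFrame:
    """Pairwise-complete Pearson correlation matrix over metric columns.

    Columns with zero variance get missing correlations with every other
    column; the diagonal is 1 for any column with at least one value.
    """
    if method != "pearson":
        raise ValueError("only pearson correlations are supported")
    if len(table) < 3:
        raise ValueError("need at least 3 rows for a correlation matrix")
    cols = [c for c in NUMERIC_COLUMNS if c in table.columns]
    num = table[cols].astype(float)
    corr = num.corr(method="pearson", min_periods=2)
    # zero-variance columns: pandas yields NaN off-diagonal already; force
    # the diagonal to 1 wherever the column has data at all
    for c in cols:
        if num[c].notna().any():
            corr.loc[c, c] = 1.0
    return corr
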
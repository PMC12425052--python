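"""Classic polysomnography architecture and fragmentation summaries.

These are the traditional comparator metrics: total sleep time (TST),
time in bed (TIB), sleep efficiency (SE), sleep-onset latency (SOL), wake
after sleep onset (WASO), number of awakenings, sleep fragmentation index
(SFI), per-stage minutes, REM latency, and — when an external arousal
event list is supplied — the arousal index (ArI).

Conventions:

* TIB is the full record span (the supported inputs carry no lights-off
  annotation), so SE = TST / TIB is interpretable only under that reading.
* WASO counts wake inside the sleep period only; latency and terminal
  wake are excluded, so WASO + TST equals the sleep-period duration.
* SFI counts awakenings plus episode shifts into a lighter stage per hour
  of TST, with depth order W > N1 > N2 > N3 and REM as its own class, so a
  shift into W or N1 from any other stage counts. SFI has no single
  agreed definition in the literature; the one implemented here is
  recorded in output metadata.
* Arousals are sub-epoch EEG events and are never inferred from the
  hypnogram; ArI is undefined (``None``) without an event list.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .hypnogram import CANONICAL_STAGES, Hypnogram
from .segmentation import detect_sleep_period, episodes_in_period, run_length_encode

#: Metadata tag: the SFI formula is a package convention, stated above.
SFI_DEFINITION = "awakenings + shifts into W or N1 per hour of TST"


@dataclass(frozen=True)
class ArousalEvents:
    """Scored arousal onsets, in seconds from record start, strictly increasing."""

    start_sec: tuple[float, ...]

    def __post_init__(self) -> None:
        starts = tuple(float(t) for t in self.start_sec)
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise ValueError("arousal onsets must be strictly increasing")
        if any(t < 0 for t in starts):
            raise ValueError("arousal onsets must be non-negative")
        object.__setattr__(self, "start_sec", starts)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ArousalEvents":
        """Read a single-column CSV of onset seconds (header optional)."""
        col = pd.read_csv(path, header=None).iloc[:, 0]
        vals = pd.to_numeric(col, errors="coerce")
        if vals.isna().iloc[0] and len(vals) > 1:  # first row was a header
            vals = vals.iloc[1:]
        return cls(tuple(vals.astype(float)))

    def __len__(self) -> int:
        return len(self.start_sec)


@dataclass(frozen=True)
class ClassicMetrics:
    """Traditional architecture/fragmentation summaries for one record."""

    record_id: str
    tst_min: float
    tib_min: float
    se_fraction: float
    sol_sec: float
    waso_min: float
    n_awakenings: int
    sfi_per_hour: float
    stage_minutes: Mapping[str, float]
    rem_latency_min: float | None
    ari_per_hour: float | None

    def as_dict(self) -> dict[str, float | None]:
        d: dict[str, float | None] = {
            "tst_min": self.tst_min,
            "tib_min": self.tib_min,
            "se_fraction": self.se_fraction,
            "sol_sec": self.sol_sec,
            "waso_min": self.waso_min,
            "n_awakenings": float(self.n_awakenings),
            "sfi_per_hour": self.sfi_per_hour,
            "rem_latency_min": self.rem_latency_min,
            "ari_per_hour": self.ari_per_hour,
        }
        for stage in CANONICAL_STAGES:
            d[f"min_{stage.lower()}"] = float(self.stage_minutes.get(stage, 0.0))
        return d


# depth order W > N1 > N2 > N3, REM its own class: a shift into W or N1
# from any other stage counts toward SFI
_LIGHT_TARGETS = frozenset({"W", "N1"})


def compute_classic(h: Hypnogram, events: ArousalEvents | None = None) -> ClassicMetrics:
    """Compute all classic metrics for one record.

    Raises :class:`hypnometrics.segmentation.NoSleepError` when the record
    has no sleep period.
    """
    period = detect_sleep_period(h)
    epm = h.epoch_seconds / 60.0  # minutes per epoch

    tib_min = h.n_epochs * epm
    n_sleep = sum(1 for s in h.stages if s != "W")
    tst_min = n_sleep * epm
    sol_sec = period.onset_epoch * h.epoch_seconds
    se_fraction = tst_min / tib_min

    episodes = run_length_encode(h)
    in_period = episodes_in_period(episodes, period)

    waso_min = sum(ep.length_epochs for ep in in_period if ep.stage == "W") * epm
    n_awakenings = sum(1 for ep in in_period if ep.stage == "W")

    # SFI: transitions into W or N1 from any other stage, inside the period
    n_light_shifts = sum(
        1
        for a, b in zip(in_period, in_period[1:])
        if b.stage in _LIGHT_TARGETS and a.stage != b.stage
    )
    tst_hours = tst_min / 60.0
    sfi_per_hour = n_light_shifts / tst_hours

    stage_minutes = {stage: 0.0 for stage in CANONICAL_STAGES}
    for s in h.stages:
        stage_minutes[s] += epm

    first_rem = next((i for i, s in enumerate(h.stages) if s == "R"), None)
    rem_latency_min = (
        (first_rem - period.onset_epoch) * epm if first_rem is not None else None
    )

    ari_per_hour = len(events) / tst_hours if events is not None else None

    return ClassicMetrics(
        record_id=h.record_id,
        tst_min=tst_min,
        tib_min=tib_min,
        se_fraction=se_fraction,
        sol_sec=sol_sec,
        waso_min=waso_min,
        n_awakenings=n_awakenings,
        sfi_per_hour=sfi_per_hour,
        stage_minutes=stage_minutes,
        rem_latency_min=rem_latency_min,
        ari_per_hour=ari_per_hour,
    )
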
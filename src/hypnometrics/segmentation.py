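"""Episode segmentation and sleep-period location.

An *episode* is a maximal run of consecutive epochs in one stage — the
unit on which temporal-entropy metrics are computed. The *sleep period*
runs from sleep onset (first non-wake epoch) to the final awakening (last
non-wake epoch), both inclusive; wake before onset (latency) and after the
final awakening is outside the period.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .hypnogram import Hypnogram


class NoSleepError(ValueError):
    """The record contains no non-wake epoch, so no sleep period exists."""


@dataclass(frozen=True)
class Episode:
    """A maximal same-stage run: epochs [start_epoch, start_epoch + length_epochs)."""

    stage: str
    start_epoch: int
    length_epochs: int

    def __post_init__(self) -> None:
        if self.length_epochs < 1:
            raise ValueError("episode length must be >= 1 epoch")
        if self.start_epoch < 0:
            raise ValueError("episode start must be >= 0")

    @property
    def end_epoch(self) -> int:
        """One past the last epoch (half-open)."""
        return self.start_epoch + self.length_epochs


@dataclass(frozen=True)
class SleepPeriod:
    """Inclusive epoch span from sleep onset to the final awakening."""

    onset_epoch: int
    final_sleep_epoch: int

    def __post_init__(self) -> None:
        if self.onset_epoch > self.final_sleep_epoch:
            raise ValueError("onset must not exceed final sleep epoch")

    @property
    def n_epochs(self) -> int:
        return self.final_sleep_epoch - self.onset_epoch + 1


def run_length_encode(h: Hypnogram) -> list[Episode]:
    """Segment a hypnogram into its maximal same-stage episodes.

    The result partitions [0, n_epochs): concatenating the episodes
    reconstructs the stage sequence exactly.
    """
    episodes: list[Episode] = []
    start = 0
    for i in range(1, h.n_epochs + 1):
        if i == h.n_epochs or h.stages[i] != h.stages[start]:
            episodes.append(Episode(h.stages[start], start, i - start))
            start = i
    return episodes


def reconstruct(episodes: Iterable[Episode]) -> list[str]:
    """Expand episodes back to an epoch-wise stage sequence."""
    out: list[str] = []
    for ep in episodes:
        out.extend([ep.stage] * ep.length_epochs)
    return out


def detect_sleep_period(h: Hypnogram) -> SleepPeriod:
    """Locate sleep onset and the final awakening.

    Raises :class:`NoSleepError` for an all-wake record (such records are
    expected to fail QC upstream).
    """
    non_w = [i for i, s in enumerate(h.stages) if s != "W"]
    if not non_w:
        raise NoSleepError(f"{h.record_id}: no non-wake epoch; no sleep period")
    return SleepPeriod(non_w[0], non_w[-1])


def episodes_in_period(
    episodes: Sequence[Episode],
    period: SleepPeriod,
    stage_filter: set[str] | frozenset[str] | None = None,
) -> list[Episode]:
    """Clip episodes to the sleep period, optionally filtering by stage.

    Episodes straddling a period boundary are truncated (they keep their
    stage with an adjusted start/length), so the unfiltered result still
    partitions the period's epochs exactly.
    """
    lo, hi = period.onset_epoch, period.final_sleep_epoch + 1  # half-open
    out: list[Episode] = []
    for ep in episodes:
        start = max(ep.start_epoch, lo)
        end = min(ep.end_epoch, hi)
        if end <= start:
            continue
        if stage_filter is not None and ep.stage not in stage_filter:
            continue
        out.append(Episode(ep.stage, start, end - start))
    return out


def sleep_period_episodes(h: Hypnogram) -> list[Episode]:
    """Convenience: segment and clip to the sleep period in one call."""
    return episodes_in_period(run_length_encode(h), detect_sleep_period(h))
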
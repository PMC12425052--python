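"""Shannon-entropy fragmentation biomarkers from episode lists.

Sleep Temporal Entropy (STE) is the Shannon entropy, in bits, of the
distribution of episode-duration proportions:

    H = -sum_j p_j * log2(p_j)

where p_j is the duration of the j-th episode divided by the total
duration of the episodes considered. Overall STE uses every episode
within the sleep period (wake included); a stage-specific STE restricts
to one stage's episodes and normalizes by that stage's total time; Wake
TE is the wake-stage variant (awakenings); NREM STE pools N1/N2/N3.

A consolidated night (few long episodes) has low entropy; a fragmented
night (many episodes of varying length) has high entropy. A stage with a
single episode scores exactly 0 bits; a stage with no episodes at all is
*undefined* (``None``), never 0 — the two must not be conflated.

Two comparator entropies over the episode sequence are also provided:
transition entropy (entropy of the empirical distribution of ordered
stage pairs between consecutive episodes) and semi-Markov entropy
(transition entropy plus the episode-frequency-weighted entropy of each
stage's empirical duration distribution). These comparators are
reconstructed definitions and are labelled as such in output metadata.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .hypnogram import CANONICAL_STAGES, NREM_STAGES, Hypnogram
from .segmentation import Episode, sleep_period_episodes

#: Metadata tag for the comparator entropies, whose published definitions
#: are not public; the formulations implemented here are stated in the docs.
COMPARATOR_LABEL = "comparator (reconstructed definition)"


def shannon_entropy_bits(proportions: Sequence[float], *, sum_tol: float = 1e-3) -> float:
    """Shannon entropy, in bits, of a duration-proportion distribution.

    Every proportion must be strictly positive and the vector must sum to
    1 within ``sum_tol``. The default tolerance admits proportions printed
    to a few decimal places; distributions built internally from episode
    durations are exact fractions and sum to 1 to machine precision.
    A single-element distribution has entropy 0.
    """
    p = np.asarray(proportions, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("proportions must be a non-empty 1-D vector")
    if np.any(p <= 0):
        raise ValueError("all proportions must be > 0 (zero-duration episodes cannot occur)")
    total = p.sum()
    if abs(total - 1.0) > sum_tol:
        raise ValueError(f"proportions sum to {total!r}, outside 1 +/- {sum_tol}")
    h = float(-(p * np.log2(p)).sum())
    return 0.0 if h == 0.0 else h  # normalize -0.0


def _durations(episodes: Sequence[Episode]) -> np.ndarray:
    return np.array([ep.length_epochs for ep in episodes], dtype=float)


def stage_ste(episodes: Sequence[Episode], stage: str) -> float | None:
    """STE of one stage's episodes, or ``None`` if the stage is absent.

    ``episodes`` should be the within-sleep-period episodes of a single
    record (see :func:`hypnometrics.segmentation.sleep_period_episodes`).
    """
    durs = _durations([ep for ep in episodes if ep.stage == stage])
    if durs.size == 0:
        return None
    return shannon_entropy_bits(durs / durs.sum())


def overall_ste(episodes: Sequence[Episode]) -> float:
    """STE over all episodes (every stage, wake included) in the period."""
    durs = _durations(episodes)
    if durs.size == 0:
        raise ValueError("overall STE needs at least one episode")
    return shannon_entropy_bits(durs / durs.sum())


def nrem_ste(episodes: Sequence[Episode]) -> float | None:
    """STE pooling N1, N2 and N3 episodes, normalized by total NREM time."""
    durs = _durations([ep for ep in episodes if ep.stage in NREM_STAGES])
    if durs.size == 0:
        return None
    return shannon_entropy_bits(durs / durs.sum())


def wake_te(episodes: Sequence[Episode]) -> float | None:
    """Wake Temporal Entropy: STE of awakenings inside the sleep period.

    Latency wake and terminal wake lie outside the period by construction,
    so every W episode seen here is an awakening. ``None`` when the night
    has no awakenings.
    """
    return stage_ste(episodes, "W")


@dataclass(frozen=True)
class EntropyProfile:
    """All temporal-entropy variants for one night, in bits.

    ``None`` marks an undefined value (the stage had zero episodes inside
    the sleep period); 0.0 means a single consolidated episode.
    """

    overall_ste: float
    wake_te: float | None
    n1_ste: float | None
    n2_ste: float | None
    n3_ste: float | None
    rem_ste: float | None
    nrem_ste: float | None

    def as_dict(self) -> dict[str, float | None]:
        return {
            "overall_ste": self.overall_ste,
            "wake_te": self.wake_te,
            "n1_ste": self.n1_ste,
            "n2_ste": self.n2_ste,
            "n3_ste": self.n3_ste,
            "rem_ste": self.rem_ste,
            "nrem_ste": self.nrem_ste,
        }


def entropy_profile(h: Hypnogram) -> EntropyProfile:
    """Compute every STE variant for one record's sleep period."""
    eps = sleep_period_episodes(h)
    return EntropyProfile(
        overall_ste=overall_ste(eps),
        wake_te=wake_te(eps),
        n1_ste=stage_ste(eps, "N1"),
        n2_ste=stage_ste(eps, "N2"),
        n3_ste=stage_ste(eps, "N3"),
        rem_ste=stage_ste(eps, "R"),
        nrem_ste=nrem_ste(eps),
    )


# ---------------------------------------------------------------------------
# comparator entropies over the episode sequence
# ---------------------------------------------------------------------------

def _transition_pairs(episodes: Sequence[Episode]) -> list[tuple[str, str]]:
    if len(episodes) < 2:
        raise ValueError("need at least 2 episodes to observe a transition")
    return [
        (episodes[i].stage, episodes[i + 1].stage) for i in range(len(episodes) - 1)
    ]


def transition_entropy(episodes: Sequence[Episode]) -> float:
    """Entropy (bits) of the empirical distribution of ordered stage pairs
    between consecutive episodes."""
    counts = Counter(_transition_pairs(episodes))
    p = np.array(list(counts.values()), dtype=float)
    return shannon_entropy_bits(p / p.sum())


def semi_markov_entropy(episodes: Sequence[Episode]) -> float:
    """Transition entropy plus frequency-weighted duration entropies.

    H = H_trans + sum_s f_s * H_dur(s), where f_s is the fraction of
    episodes in stage s and H_dur(s) the entropy of the empirical
    distribution of that stage's episode durations (binned by exact epoch
    count). Degenerate durations contribute 0, reducing the value to the
    transition entropy alone.
    """
    h_trans = transition_entropy(episodes)
    n = len(episodes)
    total = 0.0
    for stage in CANONICAL_STAGES:
        durs = [ep.length_epochs for ep in episodes if ep.stage == stage]
        if not durs:
            continue
        counts = np.array(list(Counter(durs).values()), dtype=float)
        h_dur = shannon_entropy_bits(counts / counts.sum())
        total += (len(durs) / n) * h_dur
    return h_trans + total


# ---------------------------------------------------------------------------
# transition matrix of the embedded stage chain
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TransitionMatrix:
    """Row-stochastic matrix of episode-to-episode stage transitions.

    Because episodes are maximal runs, self-transitions cannot occur and
    the diagonal is exactly zero. Rows without observed transitions are
    flagged via ``observed`` and left as zeros.
    """

    stages: tuple[str, ...]
    probs: np.ndarray  # shape (k, k), rows sum to 1 where observed
    observed: np.ndarray  # shape (k,), bool
    counts: np.ndarray | None = None  # raw transition counts when estimated

    def __post_init__(self) -> None:
        k = len(self.stages)
        p = np.asarray(self.probs, dtype=float)
        if p.shape != (k, k):
            raise ValueError(f"probs must be {k}x{k}")
        if np.any(p < 0) or np.any(p > 1):
            raise ValueError("transition probabilities must lie in [0, 1]")
        if np.any(np.abs(np.diag(p)) > 0):
            raise ValueError("diagonal must be exactly 0 (episodes are maximal runs)")
        obs = np.asarray(self.observed, dtype=bool)
        row_sums = p.sum(axis=1)
        if np.any(np.abs(row_sums[obs] - 1.0) > 1e-9):
            raise ValueError("observed rows must sum to 1")
        object.__setattr__(self, "probs", p)
        object.__setattr__(self, "observed", obs)

    def prob(self, src: str, dst: str) -> float:
        return float(self.probs[self.stages.index(src), self.stages.index(dst)])


def estimate_transition_matrix(
    episodes: Sequence[Episode] | Sequence[Sequence[Episode]],
    stages: tuple[str, ...] = CANONICAL_STAGES,
) -> TransitionMatrix:
    """Maximum-likelihood transition matrix of the embedded stage chain.

    Accepts a single episode list or a list of per-record episode lists
    (pooled counts; transitions never cross record boundaries).
    """
    if len(episodes) and isinstance(episodes[0], Episode):
        records: list[Sequence[Episode]] = [episodes]  # type: ignore[list-item]
    else:
        records = list(episodes)  # type: ignore[arg-type]
    idx = {s: i for i, s in enumerate(stages)}
    k = len(stages)
    counts = np.zeros((k, k), dtype=float)
    n_pairs = 0
    for rec in records:
        if len(rec) < 2:
            continue
        for a, b in _transition_pairs(rec):
            counts[idx[a], idx[b]] += 1
            n_pairs += 1
    if n_pairs == 0:
        raise ValueError("need at least 2 episodes to estimate transitions")
    row_sums = counts.sum(axis=1)
    observed = row_sums > 0
    probs = np.zeros_like(counts)
    probs[observed] = counts[observed] / row_sums[observed, None]
    return TransitionMatrix(tuple(stages), probs, observed, counts=counts)
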
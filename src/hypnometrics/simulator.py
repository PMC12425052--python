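"""Semi-Markov hypnogram simulator.

A night is generated by alternating two draws: a holding time from the
current stage's duration model (its mean divided by the fragmentation
factor kappa, rounded up to at least one epoch), then a jump to the next
stage from the transition matrix of the embedded chain (zero diagonal —
episodes are maximal runs by construction). The sequence is truncated at
the requested night length.

The fragmentation factor kappa shortens every stage's mean episode
duration by 1/kappa without touching the transition structure, so raising
kappa packs more, shorter episodes into the same night — the mechanism by
which fragmented sleep raises temporal entropy. Lengthening all means at
kappa = 1 (see :func:`config_for_cycles`) yields fewer NREM->REM cycles
and lower entropy.

Defaults emulate a consolidated 8-hour adult night: mean episode
durations W 4, N1 2, N2 25, N3 20, R 20 epochs (30-s epochs), geometric
holding times (memoryless, the simplest family), and a transition matrix
favouring the canonical W -> N1 -> N2 -> N3 -> N2 -> R cycle. These
produce roughly 4-6 cycles per night and overall STE in the 4-6 bit
range typical of adult polysomnography.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .entropy import TransitionMatrix
from .hypnogram import CANONICAL_STAGES, Hypnogram

DURATION_FAMILIES = ("geometric_epochs", "lognormal_minutes")


@dataclass(frozen=True)
class DurationModel:
    """Holding-time distribution for one stage.

    ``geometric_epochs``: support {1, 2, ...} with the given mean in
    epochs (means <= 1 degenerate to constant 1).
    ``lognormal_minutes``: log-normal episode length in minutes with the
    given arithmetic mean and log-scale sd ``sigma``, converted to whole
    epochs by ceiling.
    """

    family: str
    mean: float  # epochs (geometric_epochs) or minutes (lognormal_minutes)
    sigma: float = 0.5  # lognormal only

    def __post_init__(self) -> None:
        if self.family not in DURATION_FAMILIES:
            raise ValueError(f"unknown duration family {self.family!r}")
        if self.mean <= 0:
            raise ValueError("mean duration must be positive")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")

    def sample_epochs(self, rng: np.random.Generator, kappa: float,
                      epoch_seconds: float) -> int:
        if self.family == "geometric_epochs":
            mean = self.mean / kappa
            if mean <= 1.0:
                return 1
            return int(rng.geometric(1.0 / mean))
        # lognormal_minutes
        mean_min = self.mean / kappa
        mu = math.log(mean_min) - self.sigma**2 / 2.0
        minutes = rng.lognormal(mu, self.sigma)
        return max(1, math.ceil(minutes * 60.0 / epoch_seconds))

    def mean_epochs(self, kappa: float, epoch_seconds: float) -> float:
        """Analytic mean holding time in epochs (geometric family only)."""
        if self.family == "geometric_epochs":
            return max(1.0, self.mean / kappa)
        raise NotImplementedError(
            "analytic mean not available for lognormal_minutes (ceiling of a "
            "lognormal); use long_run_proportions as the oracle"
        )


_DEFAULT_MEANS = {"W": 4.0, "N1": 2.0, "N2": 25.0, "N3": 20.0, "R": 20.0}

# hand-set embedded chain favouring the canonical W->N1->N2->N3->N2->R cycle,
# with occasional awakenings and lighter-stage regressions; rows sum to 1
_DEFAULT_Q = np.array(
    [
        # W     N1    N2    N3    R
        [0.00, 0.80, 0.20, 0.00, 0.00],  # W
        [0.10, 0.00, 0.85, 0.00, 0.05],  # N1
        [0.15, 0.10, 0.00, 0.53, 0.22],  # N2
        [0.20, 0.10, 0.70, 0.00, 0.00],  # N3
        [0.30, 0.20, 0.50, 0.00, 0.00],  # R
    ]
)


@dataclass(frozen=True)
class SimulatorConfig:
    """Ground truth for synthetic nights."""

    transition_matrix: TransitionMatrix
    duration_models: Mapping[str, DurationModel]
    fragmentation_factor: float = 1.0
    night_epochs: int = 960  # 8 h at 30-s epochs
    epoch_seconds: float = 30.0
    initial_stage: str = "W"
    seed: int = 0

    def __post_init__(self) -> None:
        q = self.transition_matrix
        if not q.observed.all():
            raise ValueError("simulator requires every transition row to be specified")
        missing = set(q.stages) - set(self.duration_models)
        if missing:
            raise ValueError(f"duration model missing for stages {sorted(missing)}")
        if self.fragmentation_factor <= 0:
            raise ValueError("fragmentation factor must be positive")
        if self.night_epochs < 1:
            raise ValueError("night must be at least one epoch")
        if self.initial_stage not in q.stages:
            raise ValueError(f"initial stage {self.initial_stage!r} not in stage set")

    @property
    def stages(self) -> tuple[str, ...]:
        return self.transition_matrix.stages

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulatorConfig":
        """Load a config whose keys mirror the dataclass fields.

        ``transition_matrix`` is a nested mapping stage -> {stage: prob};
        ``duration_models`` maps stage -> {family, mean[, sigma]}.
        Omitted scalar fields fall back to the defaults.
        """
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        stages = tuple(raw.get("stages", CANONICAL_STAGES))
        qdict = raw["transition_matrix"]
        k = len(stages)
        probs = np.zeros((k, k))
        for i, src in enumerate(stages):
            for j, dst in enumerate(stages):
                probs[i, j] = float(qdict.get(src, {}).get(dst, 0.0))
        q = TransitionMatrix(stages, probs, np.ones(k, dtype=bool))
        dms = {
            stage: DurationModel(**{str(k_): v for k_, v in spec.items()})
            for stage, spec in raw["duration_models"].items()
        }
        scalars = {
            key: raw[key]
            for key in (
                "fragmentation_factor",
                "night_epochs",
                "epoch_seconds",
                "initial_stage",
                "seed",
            )
            if key in raw
        }
        return cls(transition_matrix=q, duration_models=dms, **scalars)

    def to_yaml(self, path: str | Path) -> None:
        q = self.transition_matrix
        raw = {
            "stages": list(q.stages),
            "transition_matrix": {
                src: {
                    dst: float(q.probs[i, j])
                    for j, dst in enumerate(q.stages)
                    if q.probs[i, j] > 0
                }
                for i, src in enumerate(q.stages)
            },
            "duration_models": {
                stage: (
                    {"family": dm.family, "mean": dm.mean}
                    | ({"sigma": dm.sigma} if dm.family == "lognormal_minutes" else {})
                )
                for stage, dm in self.duration_models.items()
            },
            "fragmentation_factor": self.fragmentation_factor,
            "night_epochs": self.night_epochs,
            "epoch_seconds": self.epoch_seconds,
            "initial_stage": self.initial_stage,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


def default_config(
    fragmentation_factor: float = 1.0,
    night_epochs: int = 960,
    seed: int = 0,
) -> SimulatorConfig:
    """The realistic default night (see module docstring)."""
    q = TransitionMatrix(CANONICAL_STAGES, _DEFAULT_Q, np.ones(5, dtype=bool))
    dms = {
        stage: DurationModel("geometric_epochs", mean)
        for stage, mean in _DEFAULT_MEANS.items()
    }
    return SimulatorConfig(
        transition_matrix=q,
        duration_models=dms,
        fragmentation_factor=fragmentation_factor,
        night_epochs=night_epochs,
        seed=seed,
    )


def embedded_stationary(q: TransitionMatrix) -> np.ndarray:
    """Stationary distribution of the embedded (episode-to-episode) chain."""
    vals, vecs = np.linalg.eig(q.probs.T)
    i = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


def expected_stage_proportions(config: SimulatorConfig) -> dict[str, float]:
    """Long-run expected fraction of epochs per stage.

    Semi-Markov stationary occupancy: pi_s * m_s / sum_t pi_t * m_t, with
    pi the embedded-chain stationary distribution and m_s the mean holding
    time. Analytic means exist for the geometric family only.
    """
    pi = embedded_stationary(config.transition_matrix)
    m = np.array(
        [
            config.duration_models[s].mean_epochs(
                config.fragmentation_factor, config.epoch_seconds
            )
            for s in config.stages
        ]
    )
    w = pi * m
    w /= w.sum()
    return dict(zip(config.stages, w))


def expected_cycles(config: SimulatorConfig) -> float:
    """Expected number of REM entries (NREM->REM cycles) per night."""
    pi = embedded_stationary(config.transition_matrix)
    m = np.array(
        [
            config.duration_models[s].mean_epochs(
                config.fragmentation_factor, config.epoch_seconds
            )
            for s in config.stages
        ]
    )
    mean_epochs_per_episode = float(pi @ m)
    rem_rate = pi[config.stages.index("R")] / mean_epochs_per_episode  # per epoch
    return config.night_epochs * rem_rate


def config_for_cycles(n_cycles: float, night_epochs: int = 960,
                      seed: int = 0) -> SimulatorConfig:
    """Default architecture rescaled to an expected NREM->REM cycle count.

    All stage mean durations are multiplied by a common factor so that the
    expected number of REM entries per night equals ``n_cycles``; the
    transition structure and kappa = 1 are unchanged. Fewer cycles means
    longer episodes, hence lower overall temporal entropy.
    """
    base = default_config(night_epochs=night_epochs, seed=seed)
    scale = expected_cycles(base) / n_cycles
    dms = {
        stage: replace(dm, mean=dm.mean * scale)
        for stage, dm in base.duration_models.items()
    }
    return replace(base, duration_models=dms)


def simulate_night(config: SimulatorConfig, record_id: str = "sim",
                   seed: int | None = None) -> Hypnogram:
    """Generate one night; deterministic given the seed.

    ``seed`` overrides ``config.seed`` when given (used by cohort spawning).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    q = config.transition_matrix
    idx = {s: i for i, s in enumerate(q.stages)}
    stages: list[str] = []
    current = config.initial_stage
    while len(stages) < config.night_epochs:
        dur = config.duration_models[current].sample_epochs(
            rng, config.fragmentation_factor, config.epoch_seconds
        )
        stages.extend([current] * dur)
        nxt = rng.choice(len(q.stages), p=q.probs[idx[current]])
        current = q.stages[int(nxt)]
    return Hypnogram(record_id, tuple(stages[: config.night_epochs]),
                     config.epoch_seconds)


def _spawn_seed(master_seed: int, index: int) -> int:
    """Deterministic per-record seed: first word of SeedSequence([master, i])."""
    return int(np.random.SeedSequence([master_seed, index]).generate_state(1)[0])


@dataclass(frozen=True)
class SyntheticCohort:
    """A batch of simulated nights with their generating configuration."""

    hypnograms: tuple[Hypnogram, ...]
    config: SimulatorConfig
    record_seeds: tuple[int, ...]

    def __len__(self) -> int:
        return len(self.hypnograms)


def simulate_cohort(config: SimulatorConfig, n: int, master_seed: int) -> SyntheticCohort:
    """Simulate ``n`` independent nights with seeds spawned from ``master_seed``.

    Per-record seeds derive deterministically from (master_seed, index),
    so the cohort is reproducible regardless of execution order.
    """
    if n <= 0:
        raise ValueError("cohort size must be positive")
    seeds = tuple(_spawn_seed(master_seed, i) for i in range(n))
    nights = tuple(
        simulate_night(config, record_id=f"sim{i:05d}", seed=s)
        for i, s in enumerate(seeds)
    )
    return SyntheticCohort(nights, config, seeds)


def empirical_stage_proportions(
    cohort: SyntheticCohort, burn_in_episodes: int = 10
) -> tuple[dict[str, float], int]:
    """Pooled epoch fraction per stage across a cohort, with burn-in.

    Nights start deterministically in the initial stage, so the first few
    episodes over-represent it relative to the stationary occupancy; the
    default discards each night's first 10 episodes before pooling.
    Returns the proportions and the number of episodes pooled (a rough
    effective sample size for binomial standard errors).
    """
    from .segmentation import run_length_encode

    totals = {s: 0 for s in cohort.config.stages}
    n_eps = 0
    for h in cohort.hypnograms:
        eps = run_length_encode(h)[burn_in_episodes:]
        n_eps += len(eps)
        for ep in eps:
            totals[ep.stage] += ep.length_epochs
    grand = sum(totals.values())
    if grand == 0:
        raise ValueError("burn-in consumed every episode; use a smaller value")
    return {s: totals[s] / grand for s in totals}, n_eps


def long_run_proportions(config: SimulatorConfig, n_episodes: int = 50_000,
                         seed: int = 12345) -> dict[str, float]:
    """Empirical stage occupancy from one long simulated trajectory.

    Serves as a family-agnostic oracle for the semi-Markov stationary
    occupancy (no night-length truncation; initial-state bias washes out
    over tens of thousands of episodes).
    """
    rng = np.random.default_rng(seed)
    q = config.transition_matrix
    idx = {s: i for i, s in enumerate(q.stages)}
    totals = {s: 0 for s in q.stages}
    current = config.initial_stage
    for _ in range(n_episodes):
        dur = config.duration_models[current].sample_epochs(
            rng, config.fragmentation_factor, config.epoch_seconds
        )
        totals[current] += dur
        nxt = rng.choice(len(q.stages), p=q.probs[idx[current]])
        current = q.stages[int(nxt)]
    grand = sum(totals.values())
    return {s: totals[s] / grand for s in q.stages}
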
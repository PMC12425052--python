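# Methods

## The metric

Sleep Temporal Entropy (STE) treats a night as a partition of time into
stage episodes and asks how evenly that time is spread. For episodes with
durations d_1..d_k (of the whole period, or of one stage) the proportions
p_j = d_j / Σd give

    H = −Σ_j p_j log2 p_j   [bits].

Properties the implementation guarantees and the tests enforce:

* 0 ≤ H ≤ log2(k), with equality at a single episode and at k equal
  episodes respectively;
* scale invariance — doubling every duration (or changing the epoch
  length) leaves H unchanged, because only proportions enter;
* permutation invariance — episode order does not matter to H (order
  sensitivity is the comparators' job, below);
* merge monotonicity — merging two episodes of a stage at fixed total
  stage time strictly lowers that stage's H. This is the sense in which H
  measures fragmentation.

Overall STE is the entropy of **all** episodes within the sleep period,
wake included, normalized by the period duration — not the sum of the six
stage entropies. The two readings differ by >10 bits on typical nights;
the all-episode reading is the one consistent with overall values sitting
in the 4–6 bit range while stage values sum far higher. Stage-specific
STE normalizes by that stage's total time only. Wake TE applies the same
formula to awakenings: wake episodes inside the sleep period. Latency and
terminal wake are outside the period by construction (see Conventions).

**Undefined vs zero.** A stage with one episode scores exactly 0 bits — a
meaningful, maximally consolidated value. A stage with no episodes has no
distribution; it is reported as `None`/NaN and propagates as missing into
feature tables and pairwise-complete correlations. Conflating the two
would bias any downstream model toward "absent stage = consolidated".

**Numerics.** Proportions built internally are exact fractions of epoch
counts and sum to 1 to machine precision. `shannon_entropy_bits` accepts
externally supplied proportions with a sum tolerance of 1e-3 so that
vectors printed to 3–4 decimal places remain usable; anything looser is
rejected. Zero or negative proportions are rejected outright — 0·log 0
never arises because episodes have positive duration. Entropy of a
single-element distribution returns +0.0 (the sign of the float is
normalized).

## Comparator entropies (reconstructed definitions)

Two sequence-sensitive comparators are included for correlation studies.
Their published definitions are not publicly available, so the package
states its own and labels outputs "comparator (reconstructed definition)":

* **Transition entropy** — Shannon entropy of the empirical distribution
  of ordered stage pairs (s_i → s_{i+1}) between consecutive episodes.
* **Semi-Markov entropy** — transition entropy plus
  Σ_s f_s · H_dur(s), where f_s is the fraction of episodes in stage s and
  H_dur(s) the entropy of that stage's empirical duration distribution,
  durations binned by exact epoch count. With degenerate durations it
  reduces to the transition entropy.

No bit-exact agreement with any other implementation of these two is
claimed.

## Conventions

* Epochs are 0-based; an episode over epochs [s, s+L) is half-open;
  default epoch length 30 s (configurable).
* Sleep period: first to last non-wake epoch, both inclusive. Wake before
  onset and after the final awakening is excluded from every STE and from
  WASO; episodes straddling a boundary are truncated so the in-period
  episodes still partition the period exactly. Whether pre-onset wake
  should enter overall STE is not settled in the literature; the exclusive
  convention is the package's choice and `episodes_in_period` accepts any
  period, so the inclusive variant is one call away.
* Unscored/movement epochs: carry-forward by default (inherit the previous
  epoch's stage), which preserves episode structure with minimal
  invention; records with an unscored first epoch or >10% unscored epochs
  are rejected, and a strict `reject` policy is available. Real cohorts
  rarely document their handling, which is why it is configurable.
* Legacy R&K stage 4 merges into N3.
* TIB = full record span (the supported formats carry no lights-off
  annotation), so SE = TST/TIB is a lower bound on lights-off SE.
* SFI = episode transitions into W or N1 from any other stage, per hour of
  TST. SFI has no canonical formula in the literature; this one is a
  package convention recorded in `classic.SFI_DEFINITION`.
* ArI requires an external arousal-event list (single-column CSV of onset
  seconds); arousals are sub-epoch EEG events and are never inferred from
  the hypnogram.
* QC thresholds (defaults: TST in [180, 720] min, SOL in [60, 18000] s,
  SE ≥ 0.6, overall STE ≥ 1 bit) use strict inequalities: boundary values
  are retained. Rule order TST → SOL → SE → STE affects only first-rule
  attribution in summaries, never the retained set.
* Quintile coding: cut points at the 20/40/60/80th percentiles using
  type-1 (inverted-CDF) quantiles; a value equal to a cut point falls in
  the lower quintile; missing values stay unassigned.

## The simulator

Nights are generated from a semi-Markov model: sample a holding time from
the current stage's duration model, emit that many epochs, then jump
according to a zero-diagonal transition matrix Q of the embedded chain.
Defaults (package choices, not estimates from any dataset):

| parameter | default | why |
|---|---|---|
| night length | 960 epochs (8 h at 30 s) | typical in-lab recording |
| mean durations (epochs) | W 4, N1 2, N2 25, N3 20, R 20 | plausible adult episode scales: brief awakenings, transient N1, consolidated N2/N3/REM |
| duration family | geometric (support ≥ 1 epoch) | memoryless, simplest; a log-normal-minutes family (ceiling to whole epochs) is available for heavier tails |
| Q | hand-set to favour W→N1→N2→N3→N2→R | yields ≈5.5 expected NREM→REM cycles per night and overall STE around 5 bits, matching realistic adult architecture qualitatively |
| fragmentation factor κ | 1 | divides every mean duration; κ→∞ collapses all episodes to single epochs |
| initial stage | W | nights start awake |

Per-record seeds spawn deterministically from `SeedSequence([master_seed,
index])`, so cohorts reproduce regardless of execution order.

`config_for_cycles(n)` rescales all mean durations by a common factor so
the expected number of REM entries per night — night_epochs · π_R / Σ_s
π_s m_s, with π the stationary distribution of Q — equals n, holding κ and
Q fixed. This separates the two mechanisms that move overall STE: episode
shortening (κ) and cycle count.

**What the simulator does and does not emulate.** It reproduces
stage-transition statistics and episode-duration scales, which is all the
entropy and classic metrics consume. It has no circadian modulation (no
REM-late/N3-early asymmetry), no ultradian rhythm beyond what Q induces,
no arousal events, and geometric durations are lighter-tailed than real
episode distributions. Passing tests therefore demonstrate correctness of
the metric computations and the direction of entropy responses under a
controlled architecture — not that the package's outputs on real
polysomnography will match any cohort's published distributions. One
consequence of the defaults worth knowing: ~25% of simulated nights fall
asleep within one epoch (geometric W with mean 4), tripping the SOL < 60 s
QC rule; this is realistic for a model without enforced latency and is why
pipeline examples show a sizeable QC-excluded fraction.

**Stationary occupancy and recovery checks.** The long-run fraction of
epochs in stage s is π_s m_s / Σ_t π_t m_t (analytic for the geometric
family; `long_run_proportions` simulates 50,000 episodes as a
family-agnostic oracle). Because nights start deterministically in W, the
first episodes over-represent wake relative to stationarity (≈ +0.004 on
the W fraction for an 8-h night); `empirical_stage_proportions` therefore
discards each night's first 10 episodes as burn-in before comparing a
cohort to the stationary expectation. Transition-matrix recovery pools
episode transitions across records (never across record boundaries) and
compares each entry to its generating value on binomial standard errors.

## Problem sizes used in checks

Verification workloads were sized for quick iteration while keeping Monte
Carlo noise well below the effects tested: 200 random records per
round-trip property, 1,000 Dirichlet distributions (k = 2..50) for the
entropy oracle, 500 nights for parameter recovery, 200 nights per arm for
the fragmentation (κ ∈ {1, 2, 4}) and cycle-count (3 vs 5) responses, and
200 nights for the correlation structure. At these sizes the κ response
spans ~2 bits against a between-night SD of ~0.3, and recovery z-scores
stay near 2 across seeds.

## Known limitations

* Hypnogram-level only: no EDF/EEG parsing, no signal entropies, no
  arousal detection — macro-architecture, not micro-structure.
* The comparator entropies are reconstructions (above).
* Survival and machine-learning modelling are out of scope by design; the
  feature CSV is the hand-off boundary.
* NSRR XML support covers the stage-event subset only (contiguous,
  non-overlapping events whose durations are multiples of the epoch).
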
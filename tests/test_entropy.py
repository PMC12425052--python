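"""Shannon-entropy fragmentation metrics and comparator entropies."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hypnometrics.entropy import (
    EntropyProfile,
    estimate_transition_matrix,
    entropy_profile,
    nrem_ste,
    overall_ste,
    semi_markov_entropy,
    shannon_entropy_bits,
    stage_ste,
    transition_entropy,
    TransitionMatrix,
    wake_te,
)
from hypnometrics.segmentation import Episode, sleep_period_episodes

from conftest import make_hypnogram


def episodes_from_durations(pairs):
    """Build a contiguous episode list from (stage, length) pairs."""
    out, start = [], 0
    for stage, length in pairs:
        out.append(Episode(stage, start, length))
        start += length
    return out


def fsum_entropy_bits(p):
    """Independent oracle: high-precision term-by-term summation."""
    return -math.fsum(x * math.log2(x) for x in p)


class TestShannonEntropy:
    def test_published_rem_worked_example(self):
        # proportions printed to 4 d.p.; the published value is 1.8856 bits
        h = shannon_entropy_bits([0.1341, 0.1829, 0.2927, 0.3902])
        assert h == pytest.approx(1.8856, abs=5e-4)

    def test_single_segment_is_zero(self):
        assert shannon_entropy_bits([1.0]) == 0.0

    def test_uniform_maximum(self):
        assert shannon_entropy_bits([0.25] * 4) == pytest.approx(2.0, abs=1e-12)

    @pytest.mark.parametrize(
        "bad", [[0.5, 0.5, 0.0], [-0.1, 1.1], [0.2, 0.2], [], [0.7, 0.7]]
    )
    def test_invalid_distributions_rejected(self, bad):
        with pytest.raises(ValueError):
            shannon_entropy_bits(bad)

    def test_oracle_equivalence_on_dirichlet_samples(self, rng):
        # 1,000 random distributions, k in 2..50, vs independent fsum oracle
        worst = 0.0
        for _ in range(1000):
            k = int(rng.integers(2, 51))
            p = rng.dirichlet(np.ones(k))
            p = p / p.sum()
            worst = max(worst, abs(shannon_entropy_bits(p) - fsum_entropy_bits(p)))
        assert worst < 1e-12

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        durs=st.lists(st.integers(1, 10_000), min_size=1, max_size=50),
        data=st.data(),
    )
    def test_bounds_scale_and_permutation_invariance(self, durs, data):
        d = np.array(durs, dtype=float)
        h = shannon_entropy_bits(d / d.sum())
        # bounds: 0 <= H <= log2(k)
        assert -1e-12 <= h <= math.log2(len(d)) + 1e-9
        # scale invariance: multiplying durations by a constant changes nothing
        c = data.draw(st.integers(2, 1000))
        assert shannon_entropy_bits(c * d / (c * d).sum()) == pytest.approx(h, abs=1e-9)
        # permutation invariance
        perm = data.draw(st.permutations(range(len(d))))
        assert shannon_entropy_bits(d[list(perm)] / d.sum()) == pytest.approx(h, abs=1e-9)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(durs=st.lists(st.integers(1, 10_000), min_size=2, max_size=50))
    def test_merging_two_episodes_strictly_decreases_entropy(self, durs):
        # fragmentation monotonicity at fixed total stage time
        d = np.array(durs, dtype=float)
        h_before = shannon_entropy_bits(d / d.sum())
        merged = np.concatenate([[d[0] + d[1]], d[2:]])
        h_after = (
            shannon_entropy_bits(merged / merged.sum()) if merged.size > 1 else 0.0
        )
        assert h_after < h_before


class TestStageSte:
    def test_rem_episode_durations_match_worked_example(self):
        # 11/82, 15/82, 24/82, 32/82 round to the published 4-d.p. proportions
        eps = episodes_from_durations([("R", 11), ("W", 1), ("R", 15), ("W", 1),
                                       ("R", 24), ("W", 1), ("R", 32)])
        expected = fsum_entropy_bits([11 / 82, 15 / 82, 24 / 82, 32 / 82])
        assert stage_ste(eps, "R") == pytest.approx(expected, abs=1e-12)
        assert stage_ste(eps, "R") == pytest.approx(1.8856, abs=5e-4)

    def test_single_episode_scores_zero(self):
        assert stage_ste([Episode("R", 0, 37)], "R") == 0.0

    def test_absent_stage_is_undefined_not_zero(self):
        eps = [Episode("N2", 0, 10)]
        assert stage_ste(eps, "N3") is None


class TestOverallSte:
    def test_equal_durations_hit_uniform_maximum(self):
        eps = episodes_from_durations([("W", 5), ("N2", 5), ("R", 5), ("N3", 5)])
        assert overall_ste(eps) == pytest.approx(2.0, abs=1e-12)

    def test_durations_10_20_30_40(self):
        eps = episodes_from_durations([("N1", 10), ("N2", 20), ("N3", 30), ("R", 40)])
        expected = fsum_entropy_bits([0.1, 0.2, 0.3, 0.4])
        assert overall_ste(eps) == pytest.approx(expected, abs=1e-12)

    def test_single_episode_is_zero_and_empty_errors(self):
        assert overall_ste([Episode("N2", 0, 9)]) == 0.0
        with pytest.raises(ValueError):
            overall_ste([])


class TestPooledVariants:
    def test_nrem_pools_n1_n2_n3(self):
        eps = episodes_from_durations([("N1", 5), ("N2", 10), ("N3", 5), ("R", 7)])
        assert nrem_ste(eps) == pytest.approx(1.5, abs=1e-12)  # H(.25,.5,.25)

    def test_nrem_undefined_without_nrem(self):
        eps = episodes_from_durations([("R", 5), ("W", 2), ("R", 3)])
        assert nrem_ste(eps) is None
        assert nrem_ste([Episode("N2", 0, 8)]) == 0.0

    def test_wake_te_counts_awakenings(self):
        eps = episodes_from_durations(
            [("N2", 5), ("W", 1), ("N2", 5), ("W", 1), ("R", 3), ("W", 2), ("N2", 4)]
        )
        assert wake_te(eps) == pytest.approx(1.5, abs=1e-12)  # H(.25,.25,.5)

    def test_two_equal_awakenings_give_one_bit(self):
        eps = episodes_from_durations([("N2", 5), ("W", 2), ("N2", 5), ("W", 2), ("R", 4)])
        assert wake_te(eps) == pytest.approx(1.0, abs=1e-12)

    def test_no_awakenings_undefined(self):
        assert wake_te([Episode("N2", 0, 10)]) is None


class TestEntropyProfile:
    def test_defined_pattern_matches_stage_presence(self, toy_night):
        prof = entropy_profile(toy_night)
        # toy night has W, N1, N2, N3, R inside the period
        assert prof.overall_ste > 0
        for v in prof.as_dict().values():
            assert v is not None
        # single episodes score zero: one N1 and one N3 episode in the period
        assert prof.n1_ste == 0.0
        assert prof.n3_ste == 0.0

    def test_consolidated_all_n2_night(self):
        h = make_hypnogram(["N2"] * 12)
        prof = entropy_profile(h)
        assert prof.overall_ste == 0.0
        assert prof.wake_te is None
        assert prof.rem_ste is None

    def test_profile_matches_independent_epochwise_recomputation(self):
        from hypnometrics.simulator import default_config, simulate_night

        h = simulate_night(default_config(), seed=424242)
        prof = entropy_profile(h)

        # independent recomputation straight from the epoch string
        s = list(h.stages)
        first = next(i for i, x in enumerate(s) if x != "W")
        last = len(s) - 1 - next(i for i, x in enumerate(reversed(s)) if x != "W")
        s = s[first : last + 1]
        runs = []
        i = 0
        while i < len(s):
            j = i
            while j < len(s) and s[j] == s[i]:
                j += 1
            runs.append((s[i], j - i))
            i = j

        def ent(durs):
            total = sum(durs)
            return fsum_entropy_bits([d / total for d in durs])

        assert prof.overall_ste == pytest.approx(ent([d for _, d in runs]), abs=1e-12)
        for stage, field in (("W", "wake_te"), ("N2", "n2_ste"), ("R", "rem_ste")):
            durs = [d for st_, d in runs if st_ == stage]
            expected = ent(durs) if durs else None
            got = getattr(prof, field)
            if expected is None:
                assert got is None
            else:
                assert got == pytest.approx(expected, abs=1e-12)
        nrem = [d for st_, d in runs if st_ in ("N1", "N2", "N3")]
        assert prof.nrem_ste == pytest.approx(ent(nrem), abs=1e-12)


class TestComparatorEntropies:
    def test_transition_entropy_alternating_pairs(self):
        eps = episodes_from_durations([("N2", 3), ("R", 2), ("N2", 4), ("R", 1)])
        # pairs: N2->R, R->N2, N2->R  => H(2/3, 1/3)
        expected = fsum_entropy_bits([2 / 3, 1 / 3])
        assert transition_entropy(eps) == pytest.approx(expected, abs=1e-12)
        assert transition_entropy(eps) == pytest.approx(0.9183, abs=5e-4)

    def test_identical_transitions_score_zero(self):
        eps = episodes_from_durations([("N2", 3), ("R", 2)] * 3)[:2]
        assert transition_entropy(eps) == 0.0

    def test_four_equally_frequent_transition_types(self):
        eps = episodes_from_durations(
            [("N1", 1), ("N2", 1), ("N3", 1), ("N2", 1), ("N1", 1)]
        )
        # N1->N2, N2->N3, N3->N2, N2->N1: four distinct pairs, once each
        assert transition_entropy(eps) == pytest.approx(2.0, abs=1e-12)

    def test_fewer_than_two_episodes_error(self):
        with pytest.raises(ValueError):
            transition_entropy([Episode("N2", 0, 5)])

    def test_semi_markov_degenerate_record_is_zero(self):
        # one transition type, one duration per stage -> both terms vanish
        eps = episodes_from_durations([("N2", 3), ("R", 3)])
        assert semi_markov_entropy(eps) == 0.0

    def test_semi_markov_two_stages_two_durations(self):
        # equal counts of N2->R and R->N2; each stage has two equiprobable
        # durations -> H_trans = 1 and weighted duration entropy = 1
        eps = episodes_from_durations(
            [("N2", 3), ("R", 5), ("N2", 4), ("R", 6), ("N2", 3)]
        )
        # pairs: N2->R, R->N2, N2->R, R->N2 (2+2); durations N2:{3,4,3}, R:{5,6}
        h_trans = 1.0
        h_n2 = fsum_entropy_bits([2 / 3, 1 / 3])
        h_r = 1.0
        expected = h_trans + (3 / 5) * h_n2 + (2 / 5) * h_r
        assert semi_markov_entropy(eps) == pytest.approx(expected, abs=1e-12)

    def test_duration_degenerate_reduces_to_transition_entropy(self):
        eps = episodes_from_durations(
            [("N2", 4), ("R", 4), ("N2", 4), ("N3", 4), ("N2", 4)]
        )
        assert semi_markov_entropy(eps) == pytest.approx(
            transition_entropy(eps), abs=1e-12
        )


class TestTransitionMatrix:
    def test_deterministic_alternation(self):
        eps = episodes_from_durations([("N2", 1), ("R", 1), ("N2", 1), ("R", 1)])
        tm = estimate_transition_matrix(eps)
        assert tm.prob("N2", "R") == 1.0
        assert tm.prob("R", "N2") == 1.0

    def test_row_normalization(self):
        eps = episodes_from_durations(
            [("N2", 1), ("R", 1), ("N2", 1), ("R", 1), ("N2", 1), ("R", 1),
             ("N2", 1), ("N1", 1)]
        )
        tm = estimate_transition_matrix(eps)
        assert tm.prob("N2", "R") == pytest.approx(0.75)
        assert tm.prob("N2", "N1") == pytest.approx(0.25)

    def test_unobserved_rows_flagged(self):
        eps = episodes_from_durations([("N2", 1), ("R", 1)])
        tm = estimate_transition_matrix(eps)
        assert not tm.observed[tm.stages.index("W")]
        assert tm.observed[tm.stages.index("N2")]

    def test_diagonal_must_be_zero(self):
        with pytest.raises(ValueError, match="diagonal"):
            TransitionMatrix(
                ("A", "B"), np.array([[0.5, 0.5], [1.0, 0.0]]),
                np.array([True, True]),
            )

    def test_too_few_episodes_error(self):
        with pytest.raises(ValueError):
            estimate_transition_matrix([Episode("N2", 0, 5)])
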
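import itertools

import numpy as np
import pytest

from countner import (
    CONLL_SCHEME,
    EMPTY,
    RewardSpec,
    RewardTrace,
    assign_rewards,
    by_action,
    cosine_labels,
    count_reward,
    entity_f1,
    exact_match,
    modified_cosine,
    partition_labels,
    token_accuracy,
)
from countner.rewards import segment_count_vectors
from oracles import oracle_f1, oracle_sigma, random_tags

# label sequences realizing the worked count examples:
# gold mentions (PER, LOC, ORG, MISC) = (3, 0, 2, 2) with 7 O-intervals,
# prediction (3, 2, 2, 0) with 8 O-intervals, same length.
GOLD_E = "O O B-PER O B-PER O B-PER O B-ORG O B-ORG O B-MISC O B-MISC".split()
PRED_E = "O B-PER O B-PER O B-PER O B-LOC O B-LOC O B-ORG O B-ORG O".split()
# identical gold/prediction with counts (2, 1, 2, 0) and 6 O-intervals
BOTH_B = "O B-PER O B-PER O B-LOC O B-ORG O B-ORG O".split()


class TestExactMatchAndAccuracy:
    def test_identical_segments(self):
        assert exact_match(["O", "B-PER"], ["O", "B-PER"]) == 1.0
        assert token_accuracy(["O", "B-PER"], ["O", "B-PER"]) == 1.0

    def test_one_differing_position_zeroes_exact_match(self):
        assert exact_match(["O", "O"], ["O", "B-PER"]) == 0.0

    def test_accuracy_counts_matches(self):
        got = token_accuracy(
            ["O", "O", "B-PER", "I-PER"], ["O", "B-PER", "B-PER", "I-PER"]
        )
        assert got == pytest.approx(0.75)

    def test_single_token_exact_match_equals_accuracy(self):
        for g in CONLL_SCHEME.tags:
            for p in CONLL_SCHEME.tags:
                assert exact_match([g], [p]) == token_accuracy([g], [p])

    def test_accuracy_of_concatenation_is_length_weighted_mean(self, rng):
        for _ in range(100):
            n1, n2 = int(rng.integers(1, 8)), int(rng.integers(1, 8))
            g1, g2 = random_tags(rng, CONLL_SCHEME, n1), random_tags(rng, CONLL_SCHEME, n2)
            p1, p2 = random_tags(rng, CONLL_SCHEME, n1), random_tags(rng, CONLL_SCHEME, n2)
            whole = token_accuracy(g1 + g2, p1 + p2)
            weighted = (n1 * token_accuracy(g1, p1) + n2 * token_accuracy(g2, p2)) / (
                n1 + n2
            )
            assert whole == pytest.approx(weighted)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            token_accuracy([], [])
        with pytest.raises(ValueError):
            exact_match(["O"], ["O", "O"])


class TestEntityF1:
    def test_single_token_f1_cannot_separate_b_from_i(self):
        assert entity_f1(["I-PER"], ["B-PER"], CONLL_SCHEME) == 1.0

    def test_missed_entity_scores_zero(self):
        assert entity_f1(["B-PER"], ["O"], CONLL_SCHEME) == 0.0

    def test_empty_against_empty_is_perfect_abstention(self):
        assert entity_f1(["O", "O"], ["O", "O"], CONLL_SCHEME) == 1.0

    def test_matches_brute_force_matcher(self, rng):
        for _ in range(500):
            n = int(rng.integers(0, 14))
            gold = random_tags(rng, CONLL_SCHEME, n)
            pred = random_tags(rng, CONLL_SCHEME, n)
            assert entity_f1(gold, pred, CONLL_SCHEME) == pytest.approx(
                oracle_f1(gold, pred)
            )


class TestModifiedCosine:
    def test_identical_count_vectors(self):
        assert modified_cosine([2, 1, 2, 0, 6], [2, 1, 2, 0, 6]) == pytest.approx(1.0)

    def test_worked_example_plain_counts(self):
        assert round(modified_cosine([3, 0, 2, 2], [3, 2, 2, 0]), 2) == 0.76

    def test_worked_example_with_o_intervals(self):
        # printed as ~0.89 (truncated); the exact value is 0.89541
        assert modified_cosine([3, 0, 2, 2, 7], [3, 2, 2, 0, 8]) == pytest.approx(
            0.89, abs=0.01
        )

    def test_collinear_scaling_penalty(self, rng):
        # sigma(2A, A) = cos * (1 - 1/3) = 2/3 for any A != 0
        for _ in range(50):
            a = rng.integers(0, 9, size=5).astype(float)
            if not a.any():
                continue
            assert modified_cosine(2 * a, a) == pytest.approx(2 / 3)

    def test_zero_vector_conventions(self):
        assert modified_cosine([0, 0], [0, 0]) == 1.0
        assert modified_cosine([0, 0], [1, 0]) == 0.0
        assert modified_cosine([1, 0], [0, 0]) == 0.0

    def test_symmetry_bounds_and_equality_characterization(self, rng):
        for _ in range(300):
            a = rng.integers(0, 8, size=4).astype(float)
            b = rng.integers(0, 8, size=4).astype(float)
            s = modified_cosine(a, b)
            assert 0.0 <= s <= 1.0
            assert s == pytest.approx(modified_cosine(b, a))
            assert modified_cosine(a, a) == pytest.approx(1.0)
            if np.linalg.norm(a) != np.linalg.norm(b):
                assert s < 1.0  # magnitude deviation always costs reward
            if s == pytest.approx(1.0, abs=1e-12):
                assert np.array_equal(a, b)

    def test_matches_scalar_oracle(self, rng):
        for _ in range(500):
            a = rng.integers(0, 10, size=int(rng.integers(1, 7))).astype(float)
            b = rng.integers(0, 10, size=len(a)).astype(float)
            assert modified_cosine(a, b) == pytest.approx(oracle_sigma(a, b))

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            modified_cosine([1, 2], [1, 2, 3])
        with pytest.raises(ValueError):
            modified_cosine([-1, 0], [1, 0])


class TestCosineLabels:
    def test_identical_segments(self):
        assert cosine_labels(["B-PER", "O"], ["B-PER", "O"], CONLL_SCHEME) == 1.0

    def test_one_dimensional_closed_form(self):
        # sigma([a],[b]) = 2*min(a,b)/(a+b) for positive scalars
        for g in CONLL_SCHEME.tags:
            for p in CONLL_SCHEME.tags:
                a = CONLL_SCHEME.tag_index[g]
                b = CONLL_SCHEME.tag_index[p]
                assert cosine_labels([g], [p], CONLL_SCHEME) == pytest.approx(
                    2 * min(a, b) / (a + b)
                )

    def test_matches_oracle_on_random_pairs(self, rng):
        from countner import encode_labels

        for _ in range(100):
            n = int(rng.integers(1, 10))
            gold = random_tags(rng, CONLL_SCHEME, n)
            pred = random_tags(rng, CONLL_SCHEME, n)
            expected = oracle_sigma(
                encode_labels(gold, CONLL_SCHEME), encode_labels(pred, CONLL_SCHEME)
            )
            assert cosine_labels(gold, pred, CONLL_SCHEME) == pytest.approx(expected)


class TestCountReward:
    def test_identical_counts_reach_full_reward_in_every_variant(self):
        for variant in ("counts", "counts_o", "counts_p", "counts_op"):
            value, overrides = count_reward(BOTH_B, BOTH_B, variant, CONLL_SCHEME)
            assert value == pytest.approx(1.0)
            assert overrides == {}

    def test_worked_example_counts_and_counts_o(self):
        assert segment_count_vectors(GOLD_E, CONLL_SCHEME, True) == [3, 0, 2, 2, 7]
        assert segment_count_vectors(PRED_E, CONLL_SCHEME, True) == [3, 2, 2, 0, 8]
        value, _ = count_reward(GOLD_E, PRED_E, "counts", CONLL_SCHEME)
        assert value == pytest.approx(0.76, abs=0.01)
        value_o, _ = count_reward(GOLD_E, PRED_E, "counts_o", CONLL_SCHEME)
        assert value_o == pytest.approx(0.89, abs=0.01)

    def test_informed_variant_zeroes_impossible_class_positions(self):
        # gold has no LOC mentions; both predicted LOC entities get local 0s
        _, overrides = count_reward(GOLD_E, PRED_E, "counts_p", CONLL_SCHEME)
        loc_positions = {t for t, tag in enumerate(PRED_E) if tag.endswith("LOC")}
        assert set(overrides) == loc_positions
        assert all(v == 0.0 for v in overrides.values())

    def test_informed_variant_caps_surplus_predictions(self):
        gold = ["B-PER", "O", "O"]
        pred = ["B-PER", "O", "B-PER"]  # two PER predicted, one annotated
        value, overrides = count_reward(gold, pred, "counts_p", CONLL_SCHEME)
        assert overrides == {}  # PER does occur in gold: no local punishment
        assert value == pytest.approx(1.0)  # capped at the true-positive count

    def test_plain_counts_do_not_cap(self):
        gold = ["B-PER", "O", "O"]
        pred = ["B-PER", "O", "B-PER"]
        value, _ = count_reward(gold, pred, "counts", CONLL_SCHEME)
        assert value == pytest.approx(oracle_sigma([1, 0, 0, 0], [2, 0, 0, 0]))

    def test_member_boundaries_split_o_runs_and_entities(self):
        # two concatenated sequences; the join sits between positions 1|2
        gold = ["O", "O", "O", "O"]
        assert segment_count_vectors(gold, CONLL_SCHEME, True, boundaries=[2]) == [
            0, 0, 0, 0, 2,
        ]
        spanning = ["B-PER", "I-PER", "I-PER", "O"]
        assert segment_count_vectors(
            spanning, CONLL_SCHEME, False, boundaries=[2]
        ) == [2, 0, 0, 0]

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            count_reward(["O"], ["O"], "counts_x", CONLL_SCHEME)


class TestAssignRewards:
    def test_by_action_accuracy_gives_dense_binary_trace(self):
        spec = RewardSpec("accuracy", "by_action")
        gold = ["O", "B-PER", "O"]
        pred = ["O", "O", "O"]
        trace = assign_rewards(gold, pred, by_action(gold), spec, CONLL_SCHEME)
        assert trace.values == (1.0, 0.0, 1.0)

    def test_sequence_level_trace_has_single_terminal_reward(self):
        spec = RewardSpec("f1", "k_grouped")
        gold = ["O", "B-PER", "I-PER", "O"]
        pred = ["O", "B-PER", "I-PER", "O"]
        part = partition_labels(gold, "k_grouped", CONLL_SCHEME)
        trace = assign_rewards(gold, pred, part, spec, CONLL_SCHEME)
        assert trace.values[:3] == (EMPTY, EMPTY, EMPTY)
        assert trace.values[3] == pytest.approx(1.0)

    def test_numeric_entries_equal_segment_count_without_informed_variants(self, rng):
        for name in ("by_action", "by_region", "by_entity", "k_grouped"):
            for function in ("exact_match", "accuracy", "f1", "cosine_labels",
                             "counts", "counts_o"):
                labels = random_tags(rng, CONLL_SCHEME, int(rng.integers(1, 12)))
                pred = random_tags(rng, CONLL_SCHEME, len(labels))
                part = partition_labels(labels, name, CONLL_SCHEME)
                spec = RewardSpec(function, name)
                trace = assign_rewards(labels, pred, part, spec, CONLL_SCHEME)
                assert len(trace) == len(labels)
                assert len(trace.numeric_positions()) == len(part.segments)
                assert all(0.0 <= v <= 1.0 for v in trace.numeric_values())

    def test_informed_overrides_can_overwrite_empty_and_terminal(self):
        spec = RewardSpec("counts_op", "k_grouped")
        gold = ["O", "O"]
        pred = ["B-LOC", "I-LOC"]
        part = partition_labels(gold, "k_grouped", CONLL_SCHEME)
        trace = assign_rewards(gold, pred, part, spec, CONLL_SCHEME)
        assert trace.values == (0.0, 0.0)  # both positions punished locally

    def test_count_variants_coincide_under_by_action(self):
        """Exhaustive over all (gold, pred) single-tag pairs: with singleton
        segments the four count variants communicate identical traces."""
        spec_of = {v: RewardSpec(v, "by_action") for v in
                   ("counts", "counts_o", "counts_p", "counts_op")}
        for g, p in itertools.product(CONLL_SCHEME.tags, repeat=2):
            traces = {
                v: assign_rewards([g], [p], by_action([g]), spec, CONLL_SCHEME).values
                for v, spec in spec_of.items()
            }
            reference = traces["counts"]
            for v, got in traces.items():
                assert got == pytest.approx(reference), (g, p, v)

    def test_partition_must_cover_sequence(self):
        spec = RewardSpec("accuracy", "by_action")
        with pytest.raises(ValueError):
            assign_rewards(["O", "O"], ["O", "O"], by_action(["O"]), spec, CONLL_SCHEME)


class TestRewardTypes:
    def test_trace_rejects_out_of_range_values(self):
        with pytest.raises(ValueError):
            RewardTrace((0.5, 1.5))
        RewardTrace((EMPTY, 0.0, 1.0))

    def test_empty_sentinel_is_not_zero(self):
        assert EMPTY is not None
        assert EMPTY != 0.0
        assert repr(EMPTY) == "EMPTY"

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            RewardSpec("nonsense")
        with pytest.raises(ValueError):
            RewardSpec("accuracy", "by_nothing")
        with pytest.raises(ValueError):
            RewardSpec("accuracy", "by_action", k=2)
        RewardSpec("counts_op", "k_grouped", k=4)
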
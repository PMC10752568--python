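"""Environment generators: allocation counts, half-rewarding invariant,
sampling distribution, determinism and serialization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import seqrep as s
from seqrep.environments import (
    WILDCARD,
    Environment,
    Stimulus,
    TemplateSequence,
    allocate_counts,
)


class TestAllocateCounts:
    @pytest.mark.parametrize(
        "total, fractions, expected",
        [
            (16, (0.5, 0.25, 0.125, 0.125), [8, 4, 2, 2]),
            (8, (0.5, 0.25, 0.125, 0.125), [4, 2, 1, 1]),
            (12, (0.5, 0.5), [6, 6]),
            (10, (1 / 3, 1 / 3, 1 / 3), [4, 3, 3]),
        ],
    )
    def test_known_splits(self, total, fractions, expected):
        assert allocate_counts(total, fractions) == expected

    @given(
        total=st.integers(0, 200),
        weights=st.lists(st.floats(0.01, 10.0), min_size=1, max_size=6),
    )
    @settings(max_examples=80, deadline=None)
    def test_sums_preserved(self, total, weights):
        norm = sum(weights)
        counts = allocate_counts(total, [w / norm for w in weights])
        assert sum(counts) == total
        assert all(c >= 0 for c in counts)

    def test_rejects_non_distribution(self):
        with pytest.raises(ValueError):
            allocate_counts(4, (0.5, 0.6))


class TestEnvironmentInvariants:
    def test_half_rewarding_enforced(self):
        tpl = TemplateSequence(("x", None, None, None), True)
        with pytest.raises(ValueError):
            Environment(
                alphabet=(Stimulus("x", "informative"), Stimulus("z", "noise")),
                templates=(tpl, tpl),
            )

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError):
            Environment(
                alphabet=(Stimulus("x", "noise"), Stimulus("x", "noise")),
                templates=(),
            )

    @pytest.mark.parametrize(
        "builder",
        [
            lambda: s.build_positional_env(66, 32, (0.25,) * 4),
            lambda: s.build_graded_depth_env(20),
            lambda: s.build_graded_depth_env(500),
            lambda: s.build_order_env(0.5, n_stimuli=34),
            lambda: s.build_order_env(1.0, n_stimuli=66),
        ],
    )
    def test_builders_emit_half_rewarding(self, builder):
        env = builder()
        assert 2 * sum(t.rewarding for t in env.templates) == len(env.templates)


class TestSampling:
    def test_sequences_have_length_and_alphabet(self, tiny_positional_env, rng):
        ids = {st.id for st in tiny_positional_env.alphabet}
        for _ in range(50):
            seq, rewarding = s.sample_sequence(tiny_positional_env, rng)
            assert len(seq) == tiny_positional_env.seq_length
            assert set(seq) <= ids
            assert isinstance(rewarding, bool)

    def test_concrete_positions_copied_verbatim(self, tiny_positional_env, rng):
        # last-position world: the final symbol is always an informative id
        informative = {
            st.id for st in tiny_positional_env.alphabet if st.kind == "informative"
        }
        for _ in range(50):
            seq, _ = s.sample_sequence(tiny_positional_env, rng)
            assert seq[-1] in informative

    def test_wildcard_free_template_reproduced_exactly(self, rng):
        env = Environment(
            alphabet=(
                Stimulus("a", "informative"),
                Stimulus("b", "informative"),
                Stimulus("z", "noise"),
            ),
            templates=(
                TemplateSequence(("a", "b", "a", "b"), True),
                TemplateSequence(("b", "a", "b", "a"), False),
            ),
        )
        for _ in range(20):
            seq, _ = s.sample_sequence(env, rng)
            assert seq in {("a", "b", "a", "b"), ("b", "a", "b", "a")}

    def test_template_frequencies_uniform(self, rng):
        env = s.build_positional_env(66, 32, (0.25,) * 4)
        draws = 10_000
        # identical templates are interchangeable: count by distinct pattern
        pattern_mass = {}
        for t in env.templates:
            key = (t.positions, t.rewarding)
            pattern_mass[key] = pattern_mass.get(key, 0) + 1
        observed = dict.fromkeys(pattern_mass, 0)
        for _ in range(draws):
            seq, rewarding = s.sample_sequence(env, rng)
            for key in observed:
                positions, rew = key
                if rew == rewarding and all(
                    p is WILDCARD or p == q for p, q in zip(positions, seq)
                ):
                    observed[key] += 1
                    break
        for key, mass in pattern_mass.items():
            expected = draws * mass / len(env.templates)
            se = np.sqrt(draws * (mass / len(env.templates)) * (1 - mass / len(env.templates)))
            assert abs(observed[key] - expected) <= 3.5 * se

    def test_empty_template_list_signalled(self, rng):
        env = Environment(alphabet=(Stimulus("z", "noise"),), templates=())
        with pytest.raises(ValueError):
            s.sample_sequence(env, rng)

    def test_wildcard_without_fill_pool_signalled(self, rng):
        env = Environment(
            alphabet=(Stimulus("a", "informative"), Stimulus("b", "informative")),
            templates=(
                TemplateSequence(("a", None, None, None), True),
                TemplateSequence(("b", None, None, None), False),
            ),
        )
        with pytest.raises(ValueError):
            s.sample_sequence(env, rng)

    def test_reproducible_under_fixed_seed(self, tiny_positional_env):
        def draws(seed):
            rng = np.random.default_rng(seed)
            return [s.sample_sequence(tiny_positional_env, rng) for _ in range(30)]

        assert draws(7) == draws(7)
        assert draws(7) != draws(8)


class TestPositionalEnv:
    def test_last_position_only(self):
        env = s.build_positional_env(66, 32, (0, 0, 0, 1.0))
        assert len(env.templates) == 32
        assert sum(t.rewarding for t in env.templates) == 16
        for t in env.templates:
            assert t.positions[3] is not WILDCARD
            assert all(p is WILDCARD for p in t.positions[:3])

    def test_uniform_positions_allocation(self):
        env = s.build_positional_env(66, 32, (0.25,) * 4)
        per_position = [0, 0, 0, 0]
        for t in env.templates:
            (concrete,) = [i for i, p in enumerate(t.positions) if p is not WILDCARD]
            per_position[concrete] += 1
        assert per_position == [8, 8, 8, 8]

    def test_first_position_only(self):
        env = s.build_positional_env(66, 32, (1.0, 0, 0, 0))
        for t in env.templates:
            assert t.positions[0] is not WILDCARD
            assert all(p is WILDCARD for p in t.positions[1:])

    def test_alphabet_size(self):
        assert s.build_positional_env(66, 32, (0.25,) * 4).n_stimuli == 66

    def test_odd_template_count_rejected(self):
        with pytest.raises(ValueError):
            s.build_positional_env(66, 31, (0.25,) * 4)


class TestGradedDepthEnv:
    def test_default_recency_allocation(self):
        env = s.build_graded_depth_env(20)
        recency_counts = {}
        for t in env.templates:
            (concrete,) = [i for i, p in enumerate(t.positions) if p is not WILDCARD]
            k = env.seq_length - concrete
            recency_counts[k] = recency_counts.get(k, 0) + 1
        assert recency_counts == {1: 8, 2: 4, 3: 2, 4: 2}

    def test_degenerate_fractions_reduce_to_last_position(self):
        env = s.build_graded_depth_env(20, depth_fractions=(1.0, 0, 0, 0))
        for t in env.templates:
            assert t.positions[-1] is not WILDCARD

    def test_alphabet_scales(self):
        env = s.build_graded_depth_env(500)
        assert env.n_stimuli == 500
        assert len(env.templates) == 400
        # one distinct informative identity per template
        informative = [p for t in env.templates for p in t.positions if p]
        assert len(set(informative)) == len(env.templates)

    def test_rejects_bad_fractions(self):
        with pytest.raises(ValueError):
            s.build_graded_depth_env(20, depth_fractions=(0.5, 0.25, 0.125, 0.2))


class TestOrderEnv:
    @pytest.mark.parametrize("p", [0.0, 0.25, 0.5, 0.75, 1.0])
    def test_template_count_and_balance(self, p):
        env = s.build_order_env(p, n_stimuli=34)
        assert len(env.templates) == 24
        assert sum(t.rewarding for t in env.templates) == 12

    def test_no_bigrams_at_p_zero(self):
        env = s.build_order_env(0.0, n_stimuli=34)
        for t in env.templates:
            concrete = [p for p in t.positions if p is not WILDCARD]
            assert len(concrete) == 1
            assert concrete[0] not in ("A", "B")

    def test_all_information_sequential_at_p_one(self):
        env = s.build_order_env(1.0, n_stimuli=34)
        for t in env.templates:
            concrete = [p for p in t.positions if p is not WILDCARD]
            assert set(concrete) <= {"A", "B"}
        bigrams = [t for t in env.templates if len(t) - t.n_wildcards == 2]
        assert bigrams, "expected (A,B)/(B,A) bigram templates"
        for t in bigrams:
            pair = tuple(p for p in t.positions if p is not WILDCARD)
            assert (pair == ("A", "B")) == t.rewarding

    def test_presence_of_a_or_b_is_uninformative(self):
        env = s.build_order_env(1.0, n_stimuli=34)
        for symbol in ("A", "B"):
            containing = [t for t in env.templates if symbol in t.positions]
            rewarding = sum(t.rewarding for t in containing)
            assert 0 < rewarding < len(containing)

    def test_no_single_position_rule_is_perfect(self):
        # for every position, some symbol occurs there under both labels
        env = s.build_order_env(1.0, n_stimuli=34)
        for pos in range(env.seq_length):
            by_label = {True: set(), False: set()}
            for t in env.templates:
                sym = t.positions[pos]
                symbols = {sym} if sym is not WILDCARD else set(env.fill_ids)
                by_label[t.rewarding] |= symbols
            assert by_label[True] & by_label[False]

    def test_a_and_b_occur_as_fills(self):
        env = s.build_order_env(0.5, n_stimuli=34)
        assert "A" in env.fill_ids and "B" in env.fill_ids

    def test_rejects_bad_p(self):
        with pytest.raises(ValueError):
            s.build_order_env(1.2)


class TestTestSet:
    def test_size_is_product(self, tiny_positional_env, rng):
        items = s.test_set(tiny_positional_env, 10, rng)
        assert len(items) == len(tiny_positional_env.templates) * 10

    def test_frozen_under_seed(self, tiny_positional_env):
        a = s.test_set(tiny_positional_env, 5, np.random.default_rng(3))
        b = s.test_set(tiny_positional_env, 5, np.random.default_rng(3))
        assert a == b

    def test_wildcard_free_environment_duplicates_templates(self, rng):
        env = Environment(
            alphabet=(Stimulus("a", "informative"), Stimulus("b", "informative")),
            templates=(
                TemplateSequence(("a", "a"), True),
                TemplateSequence(("b", "b"), False),
            ),
            seq_length=2,
        )
        items = s.test_set(env, 3, rng)
        assert items.count((("a", "a"), True)) == 3

    def test_rejects_zero_instantiations(self, tiny_positional_env, rng):
        with pytest.raises(ValueError):
            s.test_set(tiny_positional_env, 0, rng)


def test_json_roundtrip():
    env = s.build_order_env(0.5, n_stimuli=34, name="roundtrip")
    restored = Environment.from_json(env.to_json())
    assert restored == env
    assert restored.fill_ids == env.fill_ids
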
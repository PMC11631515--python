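import itertools
import random

import numpy as np
import pytest

from asr_equity.align import segment_asr_stream
from asr_equity.core_io import ElementAnnotation, Transcript, make_utterance, tokenize
from asr_equity.speech_elements import (
    count_repetitions,
    detect_fillers,
    filler_error_rate,
    filler_outcomes,
    proper_noun_error_rate,
    repetition_error_rate,
    repetition_outcomes,
)
from oracles import element_rate_from_components, repetition_events_oracle


class TestDetectFillers:
    def test_positions(self):
        assert detect_fillers(["um", "i", "uh", "think"]) == [0, 2]

    def test_no_fillers(self):
        assert detect_fillers(["i", "think"]) == []

    def test_oh_oh_is_two_fillers_and_one_repetition(self):
        toks = ["oh", "oh"]
        assert detect_fillers(toks) == [0, 1]
        assert len(count_repetitions(toks)) == 1


class TestCountRepetitions:
    def test_i_know_i_know_is_one_event(self):
        events = count_repetitions(tokenize("I know I know"))
        assert len(events) == 1
        assert events[0].unit == ("i", "know")
        assert events[0].run_length == 2

    def test_double_no_no_sentence_is_two_events(self):
        events = count_repetitions(tokenize("no, no, I forgot the appointment, no, no"))
        assert len(events) == 2
        assert all(e.unit == ("no",) for e in events)

    def test_long_run_is_one_event(self):
        events = count_repetitions(["a", "a", "a"])
        assert len(events) == 1
        assert events[0].run_length == 3

    def test_four_fold_single_word_is_one_primitive_event(self):
        events = count_repetitions(["a", "a", "a", "a"])
        assert len(events) == 1
        assert events[0].unit == ("a",)
        assert events[0].run_length == 4

    def test_exhaustive_enumeration_small_strings(self):
        """Agrees with the candidate-enumeration oracle for every token
        string of length <= 6 over a two-symbol alphabet."""
        for n in range(7):
            for s in itertools.product("ab", repeat=n):
                events = count_repetitions(list(s))
                oracle = repetition_events_oracle(list(s))
                got = [(e.unit, e.run_length, e.position) for e in events]
                assert got == oracle, s

    def test_events_non_overlapping_and_maximal(self):
        rng = random.Random(17)
        for _ in range(200):
            toks = [rng.choice("abc") for _ in range(rng.randint(0, 15))]
            events = count_repetitions(toks)
            spans = []
            for e in events:
                span = range(e.position, e.position + e.run_length * len(e.unit))
                assert list(toks[span.start : span.stop]) == list(e.unit) * e.run_length
                spans.extend(span)
            assert len(spans) == len(set(spans))


def _pairs(gold_asr_texts, group="Black"):
    """Align each (gold, asr) text pair as its own single-utterance stream."""
    out = []
    for i, (g, a) in enumerate(gold_asr_texts):
        t = Transcript(f"e{i}", [make_utterance(f"u{i}", "patient", group, g)], "gold")
        out.extend(segment_asr_stream(t, list(tokenize(a))))
    return out


class TestFillerErrorRate:
    def test_worked_example(self):
        """U1: 2 gold fillers, 1 captured (fraction 1/2); U2: no gold fillers
        but ASR inserts one (counts once); U3 perfect -> 100 x (0.5 + 1)/3."""
        pairs = _pairs(
            [
                ("um i uh think", "um i think"),
                ("the pain is here", "the pain is uh here"),
                ("i feel fine", "i feel fine"),
            ]
        )
        assert filler_error_rate(pairs) == pytest.approx(50.0)

    def test_perfect_transcripts_zero(self):
        pairs = _pairs([("um okay", "um okay"), ("i think uh so", "i think uh so")])
        assert filler_error_rate(pairs) == 0.0

    def test_all_inserted_degenerate_case(self):
        pairs = _pairs(
            [("the pain", "the um pain"), ("i sleep", "i uh sleep"), ("we walk", "oh we walk")]
        )
        assert filler_error_rate(pairs) == pytest.approx(100.0)

    def test_substituted_filler_counts_missed_by_default(self):
        pairs = _pairs([("um i think", "uh i think")])
        assert filler_error_rate(pairs, strict=True) == pytest.approx(100.0)
        # lenient mode accepts any inventory filler in the aligned slot
        assert filler_error_rate(pairs, strict=False) == pytest.approx(0.0)

    def test_omitted_filler_is_missed(self):
        pairs = _pairs([("um i think", "i think")])
        (o,) = filler_outcomes(pairs)
        assert (o.gold_count, o.missed, o.added) == (1, 1, 0)


class TestRepetitionErrorRate:
    def test_worked_example(self):
        """U1: 2 gold events, 1 reproduced; U2: ASR invents an event; U3
        perfect -> 100 x (0.5 + 1)/3."""
        pairs = _pairs(
            [
                (
                    "no no i forgot the appointment no no",
                    "no no i forgot the appointment no",
                ),
                ("i want to go home", "i want want to go home"),
                ("it hurts here", "it hurts here"),
            ]
        )
        assert repetition_error_rate(pairs) == pytest.approx(50.0)

    def test_perfect_transcripts_zero(self):
        pairs = _pairs([("i know i know", "i know i know")])
        assert repetition_error_rate(pairs) == 0.0

    def test_rate_matches_formula_recomputation(self):
        """On random corrupted pairs the rate equals a straight-from-formula
        recomputation from the per-utterance components."""
        rng = random.Random(23)
        vocab = ["no", "i", "know", "go", "home", "pain", "um"]
        texts = []
        for _ in range(200):
            g = [rng.choice(vocab) for _ in range(rng.randint(1, 10))]
            a = [w for w in g if rng.random() > 0.2]
            a += [rng.choice(vocab) for _ in range(rng.randint(0, 3))]
            texts.append((" ".join(g), " ".join(a) if a else "um"))
        pairs = _pairs(texts)
        rate = repetition_error_rate(pairs)
        comps = [
            (o.gold_count, o.missed, o.added) for o in repetition_outcomes(pairs)
        ]
        assert rate == pytest.approx(element_rate_from_components(comps))
        f_rate = filler_error_rate(pairs)
        f_comps = [(o.gold_count, o.missed, o.added) for o in filler_outcomes(pairs)]
        assert f_rate == pytest.approx(element_rate_from_components(f_comps))

    def test_order_invariance(self):
        texts = [
            ("no no i forgot no no", "no no i forgot no"),
            ("um i uh think", "um i think"),
            ("i feel fine", "i feel fine"),
        ]
        pairs = _pairs(texts)
        rev = list(reversed(pairs))
        assert repetition_error_rate(pairs) == pytest.approx(repetition_error_rate(rev))
        assert filler_error_rate(pairs) == pytest.approx(filler_error_rate(rev))


class TestProperNounErrorRate:
    def _segments(self, mapping):
        return {k: tuple(tokenize(v)) for k, v in mapping.items()}

    def test_multi_token_surface_requires_contiguous_match(self):
        anns = [ElementAnnotation("u0", "proper_noun", "duane reade", 1, False)]
        hit = self._segments({"u0": "i went to duane reade today"})
        miss = self._segments({"u0": "i went to duane today reade"})
        assert proper_noun_error_rate(anns, hit)["nonmedical"].rate == 0.0
        assert proper_noun_error_rate(anns, miss)["nonmedical"].rate == 100.0

    def test_missing_utterance_counts_as_missed(self):
        anns = [ElementAnnotation("u0", "proper_noun", "tylenol", 1, True)]
        assert proper_noun_error_rate(anns, {})["medical"].rate == 100.0

    def test_all_correct_is_zero(self):
        anns = [
            ElementAnnotation("u0", "proper_noun", "tylenol", 1, True),
            ElementAnnotation("u1", "proper_noun", "astoria", 1, False),
        ]
        segs = self._segments({"u0": "take tylenol", "u1": "i live in astoria"})
        rates = proper_noun_error_rate(anns, segs)
        assert rates["medical"].rate == 0.0
        assert rates["medical"].rate_truncated == 0
        assert rates["nonmedical"].rate == 0.0

    def test_zero_annotated_terms_undefined(self):
        rates = proper_noun_error_rate([], {})
        with pytest.raises(ValueError):
            _ = rates["medical"].rate

    def test_count_weighted_occurrences(self):
        anns = [ElementAnnotation("u0", "proper_noun", "tylenol", 2, True)]
        segs = self._segments({"u0": "tylenol then more tylenol"})
        assert proper_noun_error_rate(anns, segs)["medical"].correct == 2
        one = self._segments({"u0": "just tylenol today"})
        assert proper_noun_error_rate(anns, one)["medical"].rate == 50.0


class TestGeneratorConvergence:
    def test_filler_rate_matches_closed_form_under_pure_omission(self):
        """With only filler omission at probability q, the filler error rate
        converges to 100 x q x (share of utterances with fillers, weighted
        by the per-utterance expectation), within 3 standard errors."""
        from asr_equity.synthetic_data import (
            CorpusConfig,
            CorruptionConfig,
            GroupCorruption,
            corrupt,
            generate_gold,
        )

        q = 0.5
        cfg = CorpusConfig(seed=314, nurse_utterance_prob=0.0)
        gold, anns = generate_gold(cfg)
        corr = CorruptionConfig(
            groups={
                g: GroupCorruption(filler_omission_prob=q)
                for g in cfg.group_profiles
            },
            seed=42,
        )
        asr, _ = corrupt(gold, corr, anns)
        asr_by_utt = {u.utt_id: u for t in asr for u in t.utterances}
        pairs = []
        gold_filler_counts = []
        for t in gold:
            for u in t.utterances:
                single = Transcript(u.utt_id, [u], "gold")
                hyp = list(asr_by_utt[u.utt_id].tokens)
                pairs.extend(segment_asr_stream(single, hyp))
                gold_filler_counts.append(len(detect_fillers(u.tokens)))
        rate = filler_error_rate(pairs)
        n = len(pairs)
        # expectation and variance of the per-utterance fractional term
        exp_terms = [q for g in gold_filler_counts if g > 0]
        var_terms = [q * (1 - q) / g for g in gold_filler_counts if g > 0]
        expected = 100.0 * sum(exp_terms) / n
        se = 100.0 * np.sqrt(sum(var_terms)) / n
        assert abs(rate - expected) <= 3 * se
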
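import numpy as np
import pytest

from asr_equity.core_io import tokenize
from asr_equity.synthetic_data import (
    CorpusConfig,
    CorruptionConfig,
    GroupCorruption,
    GroupProfile,
    corrupt,
    default_corruption,
    generate_gold,
    log_implied_wer,
)

SMALL = CorpusConfig(
    encounters_per_group=2,
    group_profiles={"Black": GroupProfile(20, 4), "White": GroupProfile(18, 4)},
    seed=7,
)


def _zero_corruption(cfg=SMALL, seed=0):
    return CorruptionConfig(
        groups={g: GroupCorruption() for g in cfg.group_profiles}, seed=seed
    )


class TestGenerateGold:
    def test_reproducible_given_seed(self):
        g1, a1 = generate_gold(SMALL)
        g2, a2 = generate_gold(SMALL)
        assert a1 == a2
        for t1, t2 in zip(g1, g2):
            assert t1.encounter_id == t2.encounter_id
            assert t1.utterances == t2.utterances

    def test_different_seeds_differ(self):
        g1, _ = generate_gold(SMALL)
        g2, _ = generate_gold(CorpusConfig(**{**SMALL.__dict__, "seed": 8}))
        assert any(
            t1.utterances != t2.utterances for t1, t2 in zip(g1, g2)
        )

    def test_tokens_round_trip_through_tokenizer(self):
        gold, _ = generate_gold(SMALL)
        for t in gold:
            for u in t.utterances:
                assert tokenize(u.raw_text) == u.tokens

    def test_filler_probability_zero_and_one(self):
        none, anns0 = generate_gold(
            CorpusConfig(**{**SMALL.__dict__, "filler_utterance_prob": 0.0})
        )
        assert not any(a.kind == "filler" for a in anns0)
        gold1, anns1 = generate_gold(
            CorpusConfig(**{**SMALL.__dict__, "filler_utterance_prob": 1.0})
        )
        filler_utts = {a.utt_id for a in anns1 if a.kind == "filler"}
        patient_utts = {
            u.utt_id for t in gold1 for u in t.utterances if u.speaker == "patient"
        }
        assert filler_utts == patient_utts

    def test_filler_share_matches_binomial_expectation(self):
        """Across seeds, the share of patient utterances carrying fillers
        stays within 3 binomial standard errors of the configured 17%."""
        p = 0.17
        total = with_fillers = 0
        for seed in range(12):
            cfg = CorpusConfig(seed=seed, encounters_per_group=2)
            gold, anns = generate_gold(cfg)
            filler_utts = {a.utt_id for a in anns if a.kind == "filler"}
            n_patient = sum(
                1 for t in gold for u in t.utterances if u.speaker == "patient"
            )
            total += n_patient
            with_fillers += len(filler_utts)
        se = np.sqrt(p * (1 - p) / total)
        assert abs(with_fillers / total - p) <= 3 * se

    def test_annotations_describe_generated_elements(self):
        gold, anns = generate_gold(SMALL)
        tokens_by_utt = {u.utt_id: u.tokens for t in gold for u in t.utterances}
        for a in anns:
            toks = tokens_by_utt[a.utt_id]
            surface = tuple(a.surface.split())
            if a.kind == "filler":
                assert sum(1 for t in toks if t == a.surface) == a.count
            elif a.kind == "proper_noun":
                joined = " ".join(toks)
                assert a.surface in joined
            else:  # repetition: the unit appears at least twice in a row
                n = len(surface)
                assert any(
                    toks[i : i + n] == surface and toks[i + n : i + 2 * n] == surface
                    for i in range(len(toks) - 2 * n + 1)
                )

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            CorpusConfig(filler_utterance_prob=1.5)
        with pytest.raises(ValueError):
            GroupCorruption(substitution_rate=0.7, deletion_rate=0.6)


class TestCorrupt:
    def test_zero_rates_identity(self):
        gold, anns = generate_gold(SMALL)
        asr, logs = corrupt(gold, _zero_corruption(), anns)
        for gt, at in zip(gold, asr):
            assert [u.tokens for u in gt.utterances] == [u.tokens for u in at.utterances]
        assert all(not lg.dropped for lg in logs.values())
        assert all(
            e.op == "keep" for lg in logs.values() for e in lg.entries
        )

    def test_edit_log_replays_to_asr_stream(self):
        gold, anns = generate_gold(SMALL)
        asr, logs = corrupt(gold, default_corruption(), anns)
        asr_by_utt = {u.utt_id: u.tokens for t in asr for u in t.utterances}
        for t in gold:
            for u in t.utterances:
                lg = logs[u.utt_id]
                if lg.dropped:
                    assert u.utt_id not in asr_by_utt
                    assert len(u.tokens) < 5
                else:
                    assert lg.replay(u.tokens) == asr_by_utt[u.utt_id]

    def test_reproducible_given_seed(self):
        gold, anns = generate_gold(SMALL)
        asr1, _ = corrupt(gold, default_corruption(), anns)
        asr2, _ = corrupt(gold, default_corruption(), anns)
        for t1, t2 in zip(asr1, asr2):
            assert t1.utterances == t2.utterances

    def test_unknown_group_rejected(self):
        gold, _ = generate_gold(SMALL)
        with pytest.raises(ValueError, match="group"):
            corrupt(gold, CorruptionConfig(groups={"Other": GroupCorruption()}))

    def test_substitution_only_corruption_has_expected_rate(self):
        """With substitution-only corruption at rate p, the fraction of
        substituted tokens is binomial(p) across the corpus."""
        p = 0.25
        gold, anns = generate_gold(SMALL)
        corr = CorruptionConfig(
            groups={g: GroupCorruption(substitution_rate=p) for g in SMALL.group_profiles},
            seed=11,
        )
        _, logs = corrupt(gold, corr, anns)
        n_tok = sum(len(lg.entries) for lg in logs.values())
        n_sub = sum(1 for lg in logs.values() for e in lg.entries if e.op == "sub")
        se = np.sqrt(p * (1 - p) / n_tok)
        assert abs(n_sub / n_tok - p) <= 3 * se

    def test_pipeline_wer_bounded_by_log_implied_wer(self):
        """The aligner may find a cheaper explanation than the generative
        edit log, never a costlier one: per-utterance pipeline WER is at
        most the log-implied WER."""
        from asr_equity.align import segment_asr_stream
        from asr_equity.core_io import Transcript

        gold, anns = generate_gold(SMALL)
        asr, logs = corrupt(gold, default_corruption(), anns)
        implied = log_implied_wer(logs, gold)
        asr_by_utt = {u.utt_id: u.tokens for t in asr for u in t.utterances}
        for t in gold:
            for u in t.utterances:
                single = Transcript(u.utt_id, [u], "gold")
                hyp = list(asr_by_utt.get(u.utt_id, ()))
                (pair,) = segment_asr_stream(single, hyp)
                pipeline_wer = 100.0 * (pair.S + pair.D + pair.I) / len(u.tokens)
                assert pipeline_wer <= implied[u.utt_id] + 1e-9
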
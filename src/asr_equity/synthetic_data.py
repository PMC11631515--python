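"""Synthetic patient-nurse corpora with a controllable ASR error process.

The study's recordings cannot be shared, so every pipeline stage is
exercised on generated data instead: a gold-standard corpus whose shape
mirrors the published encounter characteristics (about 77-95 patient
utterances per encounter, roughly a thousand words per patient, 17% of
utterances containing fillers, occasional repetitions and proper nouns, two
group labels), and an ASR-corrupted counterpart produced by a per-token
error process with *known, group-conditional* rates.  Because the corruption
parameters are known, downstream estimates (WER, disparity tests, element
error rates) can be checked against closed-form expectations, and the edit
log provides exact ground truth for every injected operation.

Everything is deterministic given the config seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .core_io import ElementAnnotation, Transcript, Utterance
from .normalize import CANONICAL_FILLERS

# Closed vocabulary.  Content words deliberately overlap the synthetic
# lexicon's category lists so category scores are well populated; noise words
# (used for ASR insertions) are kept out of the lexicon so that insertion
# errors dilute rather than inflate category scores.
CONTENT_WORDS: tuple[str, ...] = (
    # negation / articles / function words
    "no", "not", "never", "nothing", "don't", "can't", "the", "a", "an",
    "i", "you", "she", "he", "it", "we", "they", "and", "but", "so", "then",
    "there", "here", "again", "really", "just", "still", "about", "with",
    # assent
    "yeah", "okay", "yes", "right", "sure",
    # affect
    "happy", "glad", "good", "nice", "love", "sad", "bad", "hurt", "angry",
    "afraid", "upset",
    # social / family
    "mother", "sister", "son", "daughter", "family", "friend", "people",
    "neighbor", "visit",
    # cognition
    "think", "know", "believe", "understand", "remember", "forget", "maybe",
    "perhaps", "guess", "might",
    # perception
    "see", "look", "watch", "hear", "listen", "sound", "feel",
    # time orientation
    "was", "were", "did", "yesterday", "ago", "before", "will", "gonna",
    "tomorrow", "soon", "later", "today", "now",
    # health / body
    "doctor", "nurse", "medicine", "pill", "sick", "dizzy", "tired", "pain",
    "arm", "leg", "chest", "heart", "blood", "breath", "sleep",
    # drives
    "risk", "danger", "fall", "worse", "better", "improve", "help", "strong",
    # lifestyle
    "home", "house", "kitchen", "bed", "work", "job", "retire", "walk",
    "eat", "cook", "food", "water", "morning", "night", "week", "appointment",
)

NOISE_WORDS: tuple[str, ...] = (
    "television", "hallway", "buzzing", "static", "echo", "murmur",
    "rustle", "clatter", "distant", "traffic", "doorbell", "radio",
)

MEDICAL_PROPER_NOUNS: tuple[str, ...] = (
    "tylenol", "xanax", "lipitor", "metformin", "advil", "insulin",
    "lasix", "coumadin", "lipid profile", "prednisone",
)

NONMEDICAL_PROPER_NOUNS: tuple[str, ...] = (
    "sandy", "pennsylvania", "astoria", "flushing", "brooklyn", "margaret",
    "duane reade", "manhattan", "harlem", "queens",
)

NURSE_WORDS: tuple[str, ...] = (
    "how", "are", "you", "feeling", "today", "let", "me", "check", "your",
    "pressure", "any", "questions", "take", "the", "medication", "please",
)


def _check_prob(name: str, p: float) -> None:
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"{name} must be a probability in [0, 1], got {p}")


@dataclass(frozen=True)
class GroupProfile:
    """Per-group encounter shape: utterance count is (rounded) normal,
    matching the published per-encounter means and spreads."""

    utterances_mean: float
    utterances_sd: float


@dataclass(frozen=True)
class CorpusConfig:
    """Parameters of the gold-standard generator.

    Defaults reproduce the published corpus shape: two racial group labels
    with 95 (SD 17) and 77 (SD 24) patient utterances per encounter, a
    log-normal utterance length putting roughly a thousand words in each
    patient's mouth per encounter, fillers in 17% of utterances, repetitions
    in about 14%, and proper nouns (29% of them medical) in about 8.5%.
    """

    encounters_per_group: int = 5
    group_profiles: Mapping[str, GroupProfile] = field(
        default_factory=lambda: {
            "Black": GroupProfile(95.0, 17.0),
            "White": GroupProfile(77.0, 24.0),
        }
    )
    words_median: float = 9.0
    words_sigma: float = 0.8
    filler_utterance_prob: float = 0.17
    repetition_utterance_prob: float = 0.14
    proper_noun_utterance_prob: float = 0.085
    medical_fraction: float = 0.29
    nurse_utterance_prob: float = 0.3
    vocabulary: tuple[str, ...] = CONTENT_WORDS
    filler_inventory: tuple[str, ...] = CANONICAL_FILLERS
    medical_nouns: tuple[str, ...] = MEDICAL_PROPER_NOUNS
    nonmedical_nouns: tuple[str, ...] = NONMEDICAL_PROPER_NOUNS
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "filler_utterance_prob",
            "repetition_utterance_prob",
            "proper_noun_utterance_prob",
            "medical_fraction",
            "nurse_utterance_prob",
        ):
            _check_prob(name, getattr(self, name))
        if self.encounters_per_group < 1:
            raise ValueError("encounters_per_group must be >= 1")
        if len(self.vocabulary) < 2:
            raise ValueError("vocabulary must have at least 2 words")


@dataclass(frozen=True)
class GroupCorruption:
    """Per-token ASR error process for one group.

    Generic substitution/deletion/insertion rates apply to every token
    (sub + del must stay below 1); filler omission/insertion, repetition
    collapse, proper-noun corruption, and short-utterance dropping model the
    structured failure modes measured downstream.
    """

    substitution_rate: float = 0.0
    deletion_rate: float = 0.0
    insertion_rate: float = 0.0
    filler_omission_prob: float = 0.0
    filler_insertion_prob: float = 0.0
    repetition_collapse_prob: float = 0.0
    proper_noun_corruption_prob: float = 0.0
    short_utterance_drop_prob: float = 0.0

    def __post_init__(self) -> None:
        for name in (
            "substitution_rate",
            "deletion_rate",
            "insertion_rate",
            "filler_omission_prob",
            "filler_insertion_prob",
            "repetition_collapse_prob",
            "proper_noun_corruption_prob",
            "short_utterance_drop_prob",
        ):
            _check_prob(name, getattr(self, name))
        if self.substitution_rate + self.deletion_rate > 1.0:
            raise ValueError("substitution_rate + deletion_rate must not exceed 1")


@dataclass(frozen=True)
class CorruptionConfig:
    """Group label -> error process, plus the corruption seed."""

    groups: Mapping[str, GroupCorruption]
    seed: int = 0


def default_corruption() -> CorruptionConfig:
    """Study-conditions default: a harsher error process for Black patients
    (substitution 0.35 vs 0.2), mirroring the direction of the published
    disparity; structured error modes on for both groups."""
    return CorruptionConfig(
        groups={
            "Black": GroupCorruption(
                substitution_rate=0.35,
                deletion_rate=0.06,
                insertion_rate=0.04,
                filler_omission_prob=0.6,
                filler_insertion_prob=0.12,
                repetition_collapse_prob=0.55,
                proper_noun_corruption_prob=0.5,
                short_utterance_drop_prob=0.12,
            ),
            "White": GroupCorruption(
                substitution_rate=0.2,
                deletion_rate=0.04,
                insertion_rate=0.03,
                filler_omission_prob=0.5,
                filler_insertion_prob=0.1,
                repetition_collapse_prob=0.45,
                proper_noun_corruption_prob=0.45,
                short_utterance_drop_prob=0.08,
            ),
        },
        seed=0,
    )


# ---------------------------------------------------------------------------
# Gold-standard generation
# ---------------------------------------------------------------------------

def _sample_content(rng: np.random.Generator, vocab: Sequence[str], n: int) -> list[str]:
    """n vocabulary tokens with no immediate duplicates (so the only unit-1
    repetition runs in gold text are the deliberately injected ones)."""
    out: list[str] = []
    for _ in range(n):
        w = vocab[int(rng.integers(len(vocab)))]
        while out and w == out[-1]:
            w = vocab[int(rng.integers(len(vocab)))]
        out.append(w)
    return out


def generate_gold(
    cfg: CorpusConfig,
) -> tuple[list[Transcript], list[ElementAnnotation]]:
    """Generate gold transcripts plus exact speech-element annotations.

    Annotations record what was injected at generation time (ground truth),
    not the output of any detector.  Nurse turns are interleaved but never
    annotated; downstream analysis filters them out.
    """
    rng = np.random.default_rng(cfg.seed)
    transcripts: list[Transcript] = []
    annotations: list[ElementAnnotation] = []

    for group, profile in cfg.group_profiles.items():
        for e in range(cfg.encounters_per_group):
            enc_id = f"{group}-e{e}"
            utts: list[Utterance] = []
            n_utt = max(1, int(round(rng.normal(profile.utterances_mean, profile.utterances_sd))))
            for k in range(n_utt):
                utt_id = f"{enc_id}:p{k:03d}"
                tokens, anns = _generate_utterance(rng, cfg, utt_id)
                utts.append(
                    Utterance(utt_id, "patient", group, tuple(tokens), " ".join(tokens))
                )
                annotations.extend(anns)
                if rng.random() < cfg.nurse_utterance_prob:
                    n_nurse = 1 + int(rng.integers(6))
                    ntoks = _sample_content(rng, NURSE_WORDS, n_nurse)
                    utts.append(
                        Utterance(
                            f"{enc_id}:n{k:03d}", "nurse", group, tuple(ntoks), " ".join(ntoks)
                        )
                    )
            transcripts.append(Transcript(enc_id, utts, "gold"))
    return transcripts, annotations


def _generate_utterance(
    rng: np.random.Generator, cfg: CorpusConfig, utt_id: str
) -> tuple[list[str], list[ElementAnnotation]]:
    n_words = max(1, int(round(rng.lognormal(np.log(cfg.words_median), cfg.words_sigma))))
    tokens = _sample_content(rng, cfg.vocabulary, n_words)
    anns: list[ElementAnnotation] = []

    # proper noun (possibly multi-token surface)
    if rng.random() < cfg.proper_noun_utterance_prob:
        medical = bool(rng.random() < cfg.medical_fraction)
        pool = cfg.medical_nouns if medical else cfg.nonmedical_nouns
        surface = pool[int(rng.integers(len(pool)))]
        pos = int(rng.integers(len(tokens) + 1))
        tokens[pos:pos] = surface.split()
        anns.append(ElementAnnotation(utt_id, "proper_noun", surface, 1, medical))

    # repetition event: a 1- or 2-word unit repeated 2-3 times consecutively
    if rng.random() < cfg.repetition_utterance_prob:
        unit_len = 1 + int(rng.integers(2))
        unit = _sample_content(rng, cfg.vocabulary, unit_len)
        reps = 2 + int(rng.integers(2))
        pos = int(rng.integers(len(tokens) + 1))
        block = unit * reps
        # keep the injected run maximal: neighbors must not extend it
        if (pos > 0 and tokens[pos - 1] == block[0]) or (
            pos < len(tokens) and tokens[pos] == block[-1]
        ):
            # draw a fresh unit that cannot merge with its neighbors
            bad = {tokens[pos - 1] if pos > 0 else None, tokens[pos] if pos < len(tokens) else None}
            choices = [w for w in cfg.vocabulary if w not in bad]
            unit = _sample_content(rng, choices, unit_len)
            block = unit * reps
        tokens[pos:pos] = block
        anns.append(ElementAnnotation(utt_id, "repetition", " ".join(unit), 1, None))

    # fillers: 1-2 canonical fillers at distinct, non-adjacent positions
    if rng.random() < cfg.filler_utterance_prob:
        n_fill = 1 + int(rng.integers(2))
        surfaces: dict[str, int] = {}
        for _ in range(n_fill):
            f = cfg.filler_inventory[int(rng.integers(len(cfg.filler_inventory)))]
            pos = int(rng.integers(len(tokens) + 1))
            if (pos > 0 and tokens[pos - 1] == f) or (pos < len(tokens) and tokens[pos] == f):
                continue  # avoid accidental filler repetition runs
            tokens[pos:pos] = [f]
            surfaces[f] = surfaces.get(f, 0) + 1
        for f, c in surfaces.items():
            anns.append(ElementAnnotation(utt_id, "filler", f, c, None))
    return tokens, anns


# ---------------------------------------------------------------------------
# ASR corruption
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EditLogEntry:
    """One generative edit: keep/sub/del consume gold position ``ref``;
    ins emits ``out`` without consuming."""

    op: str  # keep | sub | del | ins
    ref: int | None
    out: str | None


@dataclass
class UtteranceEditLog:
    utt_id: str
    dropped: bool
    entries: list[EditLogEntry]

    @property
    def counts(self) -> tuple[int, int, int]:
        """Implied (S, D, I); a dropped utterance is all deletions."""
        S = sum(1 for e in self.entries if e.op == "sub")
        D = sum(1 for e in self.entries if e.op == "del")
        I = sum(1 for e in self.entries if e.op == "ins")
        return S, D, I

    def replay(self, gold_tokens: Sequence[str]) -> tuple[str, ...]:
        """Apply the log to the gold tokens; must reproduce the ASR stream."""
        if self.dropped:
            return ()
        out: list[str] = []
        next_ref = 0
        for e in self.entries:
            if e.op == "ins":
                out.append(e.out)
                continue
            if e.ref != next_ref:
                raise ValueError(f"log for {self.utt_id!r} skips ref position {next_ref}")
            next_ref += 1
            if e.op == "keep":
                out.append(gold_tokens[e.ref])
            elif e.op == "sub":
                out.append(e.out)
            # del emits nothing
        if next_ref != len(gold_tokens):
            raise ValueError(f"log for {self.utt_id!r} does not cover all gold tokens")
        return tuple(out)


def corrupt(
    gold: Iterable[Transcript],
    cfg: CorruptionConfig,
    annotations: Iterable[ElementAnnotation] = (),
    noise_pool: Sequence[str] = NOISE_WORDS,
    vocabulary: Sequence[str] = CONTENT_WORDS,
    filler_inventory: Sequence[str] = CANONICAL_FILLERS,
) -> tuple[list[Transcript], dict[str, UtteranceEditLog]]:
    """Apply the group-conditional error process to gold transcripts.

    Returns ASR-source transcripts (dropped utterances are omitted entirely)
    and the per-utterance edit log.  Substituted tokens are drawn from the
    vocabulary excluding the original; inserted tokens come from the
    separate noise pool so lexicon-category effects stay controllable.
    Corruption is per token and independent (no burst errors).
    """
    rng = np.random.default_rng(cfg.seed)
    fillers = frozenset(filler_inventory)
    pn_by_utt: dict[str, list[str]] = {}
    for a in annotations:
        if a.kind == "proper_noun":
            pn_by_utt.setdefault(a.utt_id, []).append(a.surface)

    from .speech_elements import count_repetitions  # cycle-free late import

    asr_transcripts: list[Transcript] = []
    logs: dict[str, UtteranceEditLog] = {}
    for t in gold:
        out_utts: list[Utterance] = []
        for u in t.utterances:
            if u.group not in cfg.groups:
                raise ValueError(f"no corruption profile for group {u.group!r}")
            g = cfg.groups[u.group]
            toks = u.tokens
            if len(toks) < 5 and rng.random() < g.short_utterance_drop_prob:
                logs[u.utt_id] = UtteranceEditLog(u.utt_id, True, [])
                continue

            # structured pre-passes mark positions for targeted edits
            collapse = set()
            for ev in count_repetitions(toks):
                if rng.random() < g.repetition_collapse_prob:
                    unit_len = len(ev.unit)
                    start = ev.position + unit_len  # keep the first occurrence
                    collapse.update(range(start, ev.position + ev.run_length * unit_len))
            pn_positions = set()
            for surface in pn_by_utt.get(u.utt_id, ()):
                stoks = tuple(surface.split())
                for i in range(len(toks) - len(stoks) + 1):
                    if toks[i : i + len(stoks)] == stoks:
                        if rng.random() < g.proper_noun_corruption_prob:
                            pn_positions.update(range(i, i + len(stoks)))
                        break

            entries: list[EditLogEntry] = []
            for i, tok in enumerate(toks):
                if i in collapse:
                    entries.append(EditLogEntry("del", i, None))
                elif tok in fillers and rng.random() < g.filler_omission_prob:
                    entries.append(EditLogEntry("del", i, None))
                elif i in pn_positions:
                    entries.append(EditLogEntry("sub", i, _other_word(rng, vocabulary, tok)))
                else:
                    r = rng.random()
                    if r < g.deletion_rate:
                        entries.append(EditLogEntry("del", i, None))
                    elif r < g.deletion_rate + g.substitution_rate:
                        entries.append(EditLogEntry("sub", i, _other_word(rng, vocabulary, tok)))
                    else:
                        entries.append(EditLogEntry("keep", i, tok))
                if rng.random() < g.insertion_rate:
                    entries.append(
                        EditLogEntry("ins", None, noise_pool[int(rng.integers(len(noise_pool)))])
                    )
            if rng.random() < g.filler_insertion_prob:
                f = filler_inventory[int(rng.integers(len(filler_inventory)))]
                slot = int(rng.integers(len(entries) + 1))
                entries.insert(slot, EditLogEntry("ins", None, f))

            log = UtteranceEditLog(u.utt_id, False, entries)
            logs[u.utt_id] = log
            out_toks = log.replay(toks)
            out_utts.append(
                Utterance(u.utt_id, u.speaker, u.group, out_toks, " ".join(out_toks))
            )
        asr_transcripts.append(Transcript(t.encounter_id, out_utts, "asr"))
    return asr_transcripts, logs


def _other_word(rng: np.random.Generator, vocab: Sequence[str], original: str) -> str:
    w = vocab[int(rng.integers(len(vocab)))]
    while w == original:
        w = vocab[int(rng.integers(len(vocab)))]
    return w


def log_implied_wer(
    logs: Mapping[str, UtteranceEditLog], gold: Iterable[Transcript]
) -> dict[str, float]:
    """Per-utterance WER implied by the generative edit log (the alignment
    may find a cheaper explanation, so pipeline WER <= this)."""
    out: dict[str, float] = {}
    for t in gold:
        for u in t.utterances:
            log = logs.get(u.utt_id)
            if log is None or len(u.tokens) == 0:
                continue
            if log.dropped:
                out[u.utt_id] = 100.0
                continue
            S, D, I = log.counts
            out[u.utt_id] = 100.0 * (S + D + I) / len(u.tokens)
    return out
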
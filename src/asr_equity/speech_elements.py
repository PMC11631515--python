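"""Detection and error scoring of fillers, repetitions, and proper nouns.

Fillers ("um", "uh", "oh", ...) and repetitions are fluency markers used in
cognitive and mental-health assessment, so an ASR system that drops or
invents them distorts clinically relevant signal even when overall WER is
acceptable.  Proper nouns (medication names, places, people) are scored
separately for medical and nonmedical terms.

Error-rate formulas (per element type):

    rate = 100 x [ sum_u (missed_u / gold_u)  +  #utterances with ASR-added
                   elements ] / total utterances reviewed

for fillers and repetitions, where the fractional term is only contributed
by utterances that have gold elements; and

    rate = 100 x (1 - correct / total annotated)

for proper nouns, reported separately per medical flag.  Displayed integer
rates truncate (floor) the exact percentage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .align import DELETION, MATCH, SUBSTITUTION, SegmentedPair
from .core_io import ElementAnnotation, tokenize
from .normalize import (
    CANONICAL_FILLERS,
    NormalizationDictionary,
    load_default_dictionary,
    normalize_tokens,
)

DEFAULT_FILLER_INVENTORY = frozenset(CANONICAL_FILLERS)


@dataclass(frozen=True)
class RepetitionEvent:
    """A maximal consecutive repeat of a primitive word n-gram.

    "I know I know" is one event (unit "i know", run length 2); a run of any
    length is still a single event ("a a a" is one event of run length 3).
    """

    unit: tuple[str, ...]
    run_length: int
    position: int


def detect_fillers(
    tokens: Sequence[str], inventory: frozenset[str] = DEFAULT_FILLER_INVENTORY
) -> list[int]:
    """Positions of filler tokens (variant collapsing is normalization's job)."""
    return [i for i, t in enumerate(tokens) if t in inventory]


def _is_primitive(unit: Sequence[str]) -> bool:
    """A unit is primitive if it is not itself k>=2 copies of a shorter block."""
    n = len(unit)
    for d in range(1, n // 2 + 1):
        if n % d == 0 and all(unit[i] == unit[i % d] for i in range(n)):
            return True if d == n else False
    return True


def count_repetitions(tokens: Sequence[str], max_unit: int = 4) -> list[RepetitionEvent]:
    """Maximal non-overlapping consecutive-repeat events.

    Candidates are maximal runs of a primitive unit (so "a a a a" is one run
    of unit "a", not two of "a a").  Longer units are preferred, then earlier
    positions; accepted events may not overlap.
    """
    n = len(tokens)
    candidates: list[RepetitionEvent] = []
    for u in range(1, min(max_unit, n // 2) + 1):
        for start in range(n - 2 * u + 1):
            unit = tuple(tokens[start : start + u])
            if not _is_primitive(unit):
                continue
            # left-maximality: same unit must not immediately precede
            if start >= u and tuple(tokens[start - u : start]) == unit:
                continue
            reps = 1
            while tuple(tokens[start + reps * u : start + (reps + 1) * u]) == unit:
                reps += 1
            if reps >= 2:
                candidates.append(RepetitionEvent(unit, reps, start))
    candidates.sort(key=lambda e: (-len(e.unit), e.position))
    taken: list[RepetitionEvent] = []
    occupied: set[int] = set()
    for ev in candidates:
        span = range(ev.position, ev.position + ev.run_length * len(ev.unit))
        if any(i in occupied for i in span):
            continue
        taken.append(ev)
        occupied.update(span)
    taken.sort(key=lambda e: e.position)
    return taken


# ---------------------------------------------------------------------------
# Filler error rate
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class UtteranceElementOutcome:
    """Per-utterance components of the filler/repetition error formulas."""

    utt_id: str
    gold_count: int
    correct: int
    missed: int
    added: int

    @property
    def fraction(self) -> float:
        """missed / gold, the formula's fractional term (0 when no gold)."""
        return self.missed / self.gold_count if self.gold_count else 0.0


def _rate(outcomes: Sequence[UtteranceElementOutcome]) -> float:
    if not outcomes:
        raise ValueError("no utterance pairs to review")
    total = len(outcomes)
    frac = sum(o.fraction for o in outcomes)
    inserted = sum(1 for o in outcomes if o.added > 0)
    return 100.0 * (frac + inserted) / total


def filler_outcomes(
    pairs: Sequence[SegmentedPair],
    inventory: frozenset[str] = DEFAULT_FILLER_INVENTORY,
    strict: bool = True,
) -> list[UtteranceElementOutcome]:
    """Per-utterance filler bookkeeping from the word alignment.

    A gold filler counts as captured iff its alignment op is a match (with
    ``strict=False``, a substitution by another inventory filler also
    counts).  An added filler is a hypothesis filler arriving via an
    insertion op or via a substitution of a non-filler gold word.
    """
    out = []
    for p in pairs:
        gold_positions = set(detect_fillers(p.gold_tokens, inventory))
        # ops carry concatenated-stream indices; every ref position of this
        # utterance is consumed exactly once, so the smallest is its offset
        ref_indices = [op.ref_index for op in p.ops if op.ref_index is not None]
        offset = min(ref_indices) if ref_indices else 0
        hyp_tok: dict[int, str] = {}
        k = 0
        for op in p.ops:
            if op.hyp_index is not None:
                hyp_tok[op.hyp_index] = p.asr_tokens[k]
                k += 1
        correct = missed = added = 0
        for op in p.ops:
            if op.kind in (MATCH, SUBSTITUTION):
                gold_is_filler = (op.ref_index - offset) in gold_positions
                tok = hyp_tok[op.hyp_index]
                if gold_is_filler:
                    if op.kind == MATCH or (not strict and tok in inventory):
                        correct += 1
                    else:
                        missed += 1
                elif op.kind == SUBSTITUTION and tok in inventory:
                    added += 1
            elif op.kind == DELETION:
                if (op.ref_index - offset) in gold_positions:
                    missed += 1
            else:  # insertion
                if hyp_tok[op.hyp_index] in inventory:
                    added += 1
        out.append(
            UtteranceElementOutcome(p.utt_id, len(gold_positions), correct, missed, added)
        )
    return out


def filler_error_rate(
    pairs: Sequence[SegmentedPair],
    inventory: frozenset[str] = DEFAULT_FILLER_INVENTORY,
    strict: bool = True,
) -> float:
    """Filler error rate over all reviewed utterance pairs (percentage)."""
    return _rate(filler_outcomes(pairs, inventory, strict))


# ---------------------------------------------------------------------------
# Repetition error rate
# ---------------------------------------------------------------------------

def repetition_outcomes(
    pairs: Sequence[SegmentedPair], max_unit: int = 4
) -> list[UtteranceElementOutcome]:
    """Per-utterance repetition bookkeeping.

    Events are detected independently in the gold tokens and the extracted
    ASR segment and matched as multisets of repeat units: a gold event is
    captured iff the ASR segment contains an event with the same unit
    (surplus ASR events count as added)."""
    out = []
    for p in pairs:
        gold_units: dict[tuple[str, ...], int] = {}
        for ev in count_repetitions(p.gold_tokens, max_unit):
            gold_units[ev.unit] = gold_units.get(ev.unit, 0) + 1
        asr_units: dict[tuple[str, ...], int] = {}
        for ev in count_repetitions(p.asr_tokens, max_unit):
            asr_units[ev.unit] = asr_units.get(ev.unit, 0) + 1
        gold_total = sum(gold_units.values())
        correct = sum(min(c, asr_units.get(u, 0)) for u, c in gold_units.items())
        added = sum(max(0, c - gold_units.get(u, 0)) for u, c in asr_units.items())
        out.append(
            UtteranceElementOutcome(
                p.utt_id, gold_total, correct, gold_total - correct, added
            )
        )
    return out


def repetition_error_rate(pairs: Sequence[SegmentedPair], max_unit: int = 4) -> float:
    """Repetition error rate over all reviewed utterance pairs (percentage)."""
    return _rate(repetition_outcomes(pairs, max_unit))


# ---------------------------------------------------------------------------
# Proper-noun error rate
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProperNounRate:
    total: int
    correct: int

    @property
    def rate(self) -> float:
        if self.total == 0:
            raise ValueError("no annotated terms for this flag")
        return 100.0 * (1.0 - self.correct / self.total)

    @property
    def rate_truncated(self) -> int:
        return math.floor(self.rate)


def _count_subsequence(haystack: Sequence[str], needle: Sequence[str]) -> int:
    """Non-overlapping occurrences of a contiguous token subsequence."""
    if not needle:
        return 0
    count = 0
    i = 0
    n, m = len(haystack), len(needle)
    while i <= n - m:
        if tuple(haystack[i : i + m]) == tuple(needle):
            count += 1
            i += m
        else:
            i += 1
    return count


def proper_noun_error_rate(
    annotations: Iterable[ElementAnnotation],
    asr_segments: Mapping[str, Sequence[str]],
    norm_dict: NormalizationDictionary | None = None,
) -> dict[str, ProperNounRate]:
    """Error rates for annotated proper nouns, split by medical flag.

    A term counts as correctly identified iff its (possibly multi-token)
    normalized surface appears contiguously in the ASR segment of its
    utterance; matching is exact, not fuzzy.  An utterance missing from
    ``asr_segments`` counts all its terms as missed.
    """
    d = norm_dict or load_default_dictionary()
    tallies = {"medical": [0, 0], "nonmedical": [0, 0]}  # [total, correct]
    for a in annotations:
        if a.kind != "proper_noun":
            continue
        flag = "medical" if a.medical else "nonmedical"
        surface = normalize_tokens(tokenize(a.surface), d)
        seg = asr_segments.get(a.utt_id, ())
        found = _count_subsequence(seg, surface)
        tallies[flag][0] += a.count
        tallies[flag][1] += min(found, a.count)
    return {
        flag: ProperNounRate(total=t, correct=c) for flag, (t, c) in tallies.items()
    }
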
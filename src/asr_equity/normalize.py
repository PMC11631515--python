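"""Token-sequence normalization shared by gold and ASR transcripts.

Gold-standard transcription guidelines convert spoken numeric and temporal
expressions to a digit convention ("one hundred and fifty" -> "150",
"a quarter past four" -> "4:15") and collapse lengthened filler variants to a
canonical form ("umm" -> "um").  ASR output is passed through the same rules
so that surface-convention differences never count as word errors.

Rules are applied left to right with longest-match-first semantics and no
overlap, the way a human transcriber applies a conversion table.  The default
dictionary covers English number words 0-9999 (with and without "and", with
hyphenated tens), quarter/half clock phrases, and a filler-variant table; it
is a reconstruction and can be replaced by any CSV rule file.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Sequence

from .core_io import ParseError, Transcript, Utterance

Pattern = tuple[str, ...]

_ONES = (
    "zero one two three four five six seven eight nine ten eleven twelve "
    "thirteen fourteen fifteen sixteen seventeen eighteen nineteen"
).split()
_TENS = ("", "", "twenty", "thirty", "forty", "fifty", "sixty", "seventy", "eighty", "ninety")

#: canonical filler inventory; variants collapse onto these
CANONICAL_FILLERS = ("um", "uh", "oh", "er", "ah", "mm", "hmm")


@dataclass
class NormalizationDictionary:
    """Ordered longest-match rewrite rules over token sequences."""

    rules: dict[Pattern, Pattern] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pat, rep in self.rules.items():
            if not pat:
                raise ValueError("empty rule pattern")
            if pat == rep:
                raise ValueError(f"identity rule {pat!r} would break idempotence checks")
        self._lengths = sorted({len(p) for p in self.rules}, reverse=True)

    def add(self, pattern: Sequence[str], replacement: Sequence[str]) -> None:
        self.rules[tuple(pattern)] = tuple(replacement)
        self._lengths = sorted({len(p) for p in self.rules}, reverse=True)

    def __len__(self) -> int:
        return len(self.rules)

    def lookup(self, pattern: Sequence[str]) -> Pattern | None:
        return self.rules.get(tuple(pattern))


def normalize_tokens(tokens: Sequence[str], d: NormalizationDictionary) -> tuple[str, ...]:
    """Rewrite every maximal left-to-right longest rule match.

    At each position the longest matching pattern wins; the scan resumes
    after the replacement, so rules never apply to their own output within
    a single pass (and the default dictionary's outputs match no rule, which
    makes normalization idempotent).
    """
    out: list[str] = []
    i = 0
    n = len(tokens)
    lengths = d._lengths
    rules = d.rules
    while i < n:
        for L in lengths:
            if L > n - i:
                continue
            rep = rules.get(tuple(tokens[i : i + L]))
            if rep is not None:
                out.extend(rep)
                i += L
                break
        else:
            out.append(tokens[i])
            i += 1
    return tuple(out)


def normalize_utterance(u: Utterance, d: NormalizationDictionary) -> Utterance:
    toks = normalize_tokens(u.tokens, d)
    return Utterance(u.utt_id, u.speaker, u.group, toks, " ".join(toks), u.start_time)


def normalize_transcript(t: Transcript, d: NormalizationDictionary) -> Transcript:
    return Transcript(t.encounter_id, [normalize_utterance(u, d) for u in t.utterances], t.source)


# ---------------------------------------------------------------------------
# Default dictionary construction
# ---------------------------------------------------------------------------

def spell_out_variants(n: int) -> list[Pattern]:
    """All accepted spoken spellings of an integer 0-9999 as token tuples.

    Covers the plain form ("one hundred fifty"), the "and" form
    ("one hundred and fifty"), and hyphenated tens-units ("twenty-one",
    a single token under the tokenizer).
    """
    if not 0 <= n <= 9999:
        raise ValueError("spell-out covers 0-9999")
    return [tuple(v) for v in _spell(n, allow_and=True)]


def _tens_units(n: int) -> list[list[str]]:
    # 20..99 only
    t, u = divmod(n, 10)
    if u == 0:
        return [[_TENS[t]]]
    return [[_TENS[t], _ONES[u]], [f"{_TENS[t]}-{_ONES[u]}"]]


def _below_hundred(n: int) -> list[list[str]]:
    if n < 20:
        return [[_ONES[n]]]
    return _tens_units(n)


def _below_thousand(n: int, allow_and: bool) -> list[list[str]]:
    if n < 100:
        return _below_hundred(n)
    h, rest = divmod(n, 100)
    heads = [[_ONES[h], "hundred"]]
    if rest == 0:
        return heads
    out = []
    for head in heads:
        for tail in _below_hundred(rest):
            out.append(head + tail)
            if allow_and:
                out.append(head + ["and"] + tail)
    return out


def _spell(n: int, allow_and: bool) -> list[list[str]]:
    if n < 1000:
        return _below_thousand(n, allow_and)
    th, rest = divmod(n, 1000)
    heads = [[_ONES[th], "thousand"]]
    if rest == 0:
        return heads
    out = []
    for head in heads:
        for tail in _below_thousand(rest, allow_and):
            out.append(head + tail)
            if allow_and and rest < 100:
                out.append(head + ["and"] + tail)
    return out


def filler_variants(canonical: str, max_extra: int = 5) -> list[str]:
    """Lengthened variants of a filler: the final letter repeated 1..max_extra
    extra times ("um" -> "umm", "ummm", ...)."""
    return [canonical + canonical[-1] * k for k in range(1, max_extra + 1)]


def _number_rules() -> dict[Pattern, Pattern]:
    rules: dict[Pattern, Pattern] = {}
    for n in range(10000):
        rep = (str(n),)
        for pat in spell_out_variants(n):
            rules[pat] = rep
    return rules


def _clock_rules() -> dict[Pattern, Pattern]:
    rules: dict[Pattern, Pattern] = {}
    for h in range(1, 13):
        word = _ONES[h]
        prev = h - 1 if h > 1 else 12
        for lead in ((), ("a",)):
            rules[lead + ("quarter", "past", word)] = (f"{h}:15",)
            rules[lead + ("quarter", "to", word)] = (f"{prev}:45",)
        rules[("half", "past", word)] = (f"{h}:30",)
    return rules


def _filler_rules() -> dict[Pattern, Pattern]:
    rules: dict[Pattern, Pattern] = {}
    for canon in CANONICAL_FILLERS:
        for var in filler_variants(canon):
            rules[(var,)] = (canon,)
    # frequent spelling variants not generated by letter lengthening
    rules[("uhm",)] = ("um",)
    rules[("hm",)] = ("hmm",)
    rules[("erm",)] = ("er",)
    return rules


@lru_cache(maxsize=1)
def load_default_dictionary() -> NormalizationDictionary:
    """Default rule set: numbers 0-9999, quarter/half clock phrases, fillers."""
    rules: dict[Pattern, Pattern] = {}
    rules.update(_number_rules())
    rules.update(_clock_rules())
    rules.update(_filler_rules())
    return NormalizationDictionary(rules)


def load_dictionary(path: str | Path) -> NormalizationDictionary:
    """Load rules from a CSV with header ``pattern,replacement`` (token
    sequences space-joined)."""
    rules: dict[Pattern, Pattern] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        for lineno, row in enumerate(reader, start=1):
            if not row or not "".join(row).strip():
                continue
            if lineno == 1 and [c.strip().lower() for c in row[:2]] == ["pattern", "replacement"]:
                continue
            if len(row) < 2:
                raise ParseError(f"line {lineno}: expected pattern,replacement")
            pat = tuple(row[0].split())
            rep = tuple(row[1].split())
            if not pat:
                raise ParseError(f"line {lineno}: empty pattern")
            rules[pat] = rep
    return NormalizationDictionary(rules)
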
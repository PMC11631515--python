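"""Domain types and file I/O for transcript, annotation, and lexicon data.

Transcripts are JSON Lines, one utterance per record:
``{"utt_id", "speaker", "group", "text", "start_time"?, "encounter_id"?}``.
Speech-element annotations are CSV with header
``utt_id,kind,surface,count,medical``.  Category lexicons are accepted either
in the LIWC-2015 ``.dic`` dialect (category table between ``%`` delimiter
lines) or as a two-column ``word,category`` CSV.
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

SPEAKERS = ("patient", "nurse")
SOURCES = ("gold", "asr")

ANNOTATION_KINDS = ("filler", "repetition", "proper_noun")

# Word tokens keep internal apostrophes/hyphens; clock times (4:15) and bare
# numbers (150) survive as single tokens so normalized digits round-trip.
_TOKEN_RE = re.compile(r"\d+:\d+|[a-z0-9]+(?:['\-][a-z0-9]+)*")


class ParseError(ValueError):
    """Malformed input file (message names the offending line)."""


class ValidationError(ValueError):
    """Structurally valid input that violates a domain invariant."""


def tokenize(text: str) -> tuple[str, ...]:
    """Lowercase word tokenization with ASR-robust punctuation handling.

    Casing and punctuation are stripped because word error rate is computed
    on spoken words and ASR systems differ arbitrarily in both.  Word-internal
    apostrophes ("don't") and hyphens ("twenty-one") are kept, as are clock
    times ("4:15") and digit strings ("150") produced by normalization.
    """
    return tuple(_TOKEN_RE.findall(text.replace("’", "'").lower()))


@dataclass(frozen=True)
class Utterance:
    """One continuous speaker turn — the unit all metrics are computed over."""

    utt_id: str
    speaker: str
    group: str
    tokens: tuple[str, ...]
    raw_text: str
    start_time: float | None = None

    def __post_init__(self) -> None:
        if self.speaker not in SPEAKERS:
            raise ValidationError(
                f"utterance {self.utt_id!r}: speaker must be one of {SPEAKERS}, "
                f"got {self.speaker!r}"
            )


def make_utterance(
    utt_id: str,
    speaker: str,
    group: str,
    text: str,
    start_time: float | None = None,
) -> Utterance:
    """Build an :class:`Utterance` from raw text, applying the tokenizer."""
    return Utterance(utt_id, speaker, group, tokenize(text), text, start_time)


@dataclass
class Transcript:
    """Ordered utterances of one recorded encounter, from one source."""

    encounter_id: str
    utterances: list[Utterance]
    source: str

    def __post_init__(self) -> None:
        if self.source not in SOURCES:
            raise ValidationError(f"source must be one of {SOURCES}, got {self.source!r}")
        seen: set[str] = set()
        for u in self.utterances:
            if u.utt_id in seen:
                raise ValidationError(
                    f"duplicate utt_id {u.utt_id!r} in encounter {self.encounter_id!r}"
                )
            seen.add(u.utt_id)

    def __len__(self) -> int:
        return len(self.utterances)

    def __iter__(self) -> Iterator[Utterance]:
        return iter(self.utterances)


@dataclass(frozen=True)
class ElementAnnotation:
    """Gold annotation of a special speech element within one utterance.

    ``count`` is the number of occurrences (filler tokens, repetition events,
    or proper-noun mentions of this surface).  ``medical`` is meaningful only
    for proper nouns.
    """

    utt_id: str
    kind: str
    surface: str
    count: int
    medical: bool | None = None

    def __post_init__(self) -> None:
        if self.kind not in ANNOTATION_KINDS:
            raise ValidationError(f"unknown annotation kind {self.kind!r}")
        if self.count < 1:
            raise ValidationError(
                f"annotation ({self.utt_id!r}, {self.surface!r}): count must be >= 1"
            )
        if (self.kind == "proper_noun") != (self.medical is not None):
            raise ValidationError(
                f"annotation ({self.utt_id!r}, {self.surface!r}): medical flag is "
                "required for proper_noun and forbidden otherwise"
            )


@dataclass
class Lexicon:
    """Category word lists with optional trailing-wildcard prefix entries.

    Matching lowercases both sides; an entry ``happ*`` matches any token that
    starts with ``happ``.  A token may match several categories (multi-
    membership, as in LIWC-style dictionaries).
    """

    exact: dict[str, frozenset[str]] = field(default_factory=dict)
    prefixes: dict[str, tuple[str, ...]] = field(default_factory=dict)

    @classmethod
    def from_entries(cls, categories: Mapping[str, Iterable[str]]) -> "Lexicon":
        exact: dict[str, frozenset[str]] = {}
        prefixes: dict[str, tuple[str, ...]] = {}
        for cat, entries in categories.items():
            words: set[str] = set()
            pref: list[str] = []
            for e in entries:
                e = e.strip().lower()
                if not e:
                    continue
                if e.endswith("*"):
                    stem = e[:-1]
                    if "*" in stem:
                        raise ValidationError(
                            f"lexicon entry {e!r}: wildcard allowed only at the end"
                        )
                    pref.append(stem)
                elif "*" in e:
                    raise ValidationError(
                        f"lexicon entry {e!r}: wildcard allowed only at the end"
                    )
                else:
                    words.add(e)
            exact[cat] = frozenset(words)
            prefixes[cat] = tuple(sorted(pref))
        return cls(exact, prefixes)

    @property
    def categories(self) -> tuple[str, ...]:
        return tuple(self.exact)

    def matches(self, token: str) -> tuple[str, ...]:
        """All categories the token belongs to."""
        tok = token.lower()
        out = []
        for cat in self.exact:
            if tok in self.exact[cat] or any(tok.startswith(p) for p in self.prefixes[cat]):
                out.append(cat)
        return tuple(out)


@dataclass(frozen=True)
class DimensionMap:
    """Feature (category) -> dimension grouping for dimension-level scores."""

    mapping: Mapping[str, str]

    def __post_init__(self) -> None:
        for feat, dim in self.mapping.items():
            if not isinstance(dim, str) or not dim:
                raise ValidationError(f"feature {feat!r} maps to invalid dimension {dim!r}")

    @property
    def dimensions(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for d in self.mapping.values():
            seen.setdefault(d)
        return tuple(seen)

    def features_of(self, dimension: str) -> tuple[str, ...]:
        return tuple(f for f, d in self.mapping.items() if d == dimension)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

_REQUIRED_FIELDS = ("utt_id", "speaker", "group", "text")


def _utterance_from_record(rec: Mapping, lineno: int) -> tuple[str, Utterance]:
    for f in _REQUIRED_FIELDS:
        if f not in rec:
            raise ParseError(f"line {lineno}: missing required field {f!r}")
    enc = rec.get("encounter_id", "default")
    start = rec.get("start_time")
    utt = Utterance(
        utt_id=str(rec["utt_id"]),
        speaker=str(rec["speaker"]),
        group=str(rec["group"]),
        tokens=tokenize(str(rec["text"])),
        raw_text=str(rec["text"]),
        start_time=None if start is None else float(start),
    )
    return str(enc), utt


def read_corpus(path: str | Path, source: str) -> list[Transcript]:
    """Read a JSON Lines transcript file, grouping records by encounter.

    Encounters are returned in order of first appearance; utterances keep
    document order within each encounter.
    """
    groups: dict[str, list[Utterance]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ParseError(f"line {lineno}: invalid JSON ({exc.msg})") from exc
            if not isinstance(rec, dict):
                raise ParseError(f"line {lineno}: record must be a JSON object")
            enc, utt = _utterance_from_record(rec, lineno)
            groups.setdefault(enc, []).append(utt)
    return [Transcript(enc, utts, source) for enc, utts in groups.items()]


def read_transcript(path: str | Path, source: str) -> Transcript:
    """Read a single-encounter JSON Lines transcript file."""
    transcripts = read_corpus(path, source)
    if not transcripts:
        return Transcript("default", [], source)
    if len(transcripts) > 1:
        raise ValidationError(
            f"{path}: expected one encounter, found {len(transcripts)}; "
            "use read_corpus for multi-encounter files"
        )
    return transcripts[0]


def write_corpus(transcripts: Iterable[Transcript], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for t in transcripts:
            for u in t.utterances:
                rec: dict = {
                    "utt_id": u.utt_id,
                    "speaker": u.speaker,
                    "group": u.group,
                    "text": u.raw_text,
                    "encounter_id": t.encounter_id,
                }
                if u.start_time is not None:
                    rec["start_time"] = u.start_time
                fh.write(json.dumps(rec) + "\n")


def write_transcript(t: Transcript, path: str | Path) -> None:
    write_corpus([t], path)


def filter_speaker(t: Transcript, speaker: str) -> Transcript:
    """Keep only utterances of one speaker role, preserving order.

    Idempotent; used to exclude nurse turns before any patient-side metric.
    """
    if speaker not in SPEAKERS:
        raise ValidationError(f"speaker must be one of {SPEAKERS}, got {speaker!r}")
    return Transcript(
        t.encounter_id, [u for u in t.utterances if u.speaker == speaker], t.source
    )


def read_annotations(path: str | Path) -> list[ElementAnnotation]:
    """Read speech-element annotations from CSV."""
    out: list[ElementAnnotation] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        required = {"utt_id", "kind", "surface", "count", "medical"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ParseError(f"{path}: annotation CSV must have columns {sorted(required)}")
        for lineno, row in enumerate(reader, start=2):
            medical_raw = (row["medical"] or "").strip().lower()
            medical: bool | None
            if medical_raw in ("", "na", "none"):
                medical = None
            elif medical_raw in ("true", "1", "yes"):
                medical = True
            elif medical_raw in ("false", "0", "no"):
                medical = False
            else:
                raise ParseError(f"line {lineno}: bad medical flag {row['medical']!r}")
            try:
                out.append(
                    ElementAnnotation(
                        utt_id=row["utt_id"],
                        kind=row["kind"],
                        surface=row["surface"],
                        count=int(row["count"]),
                        medical=medical,
                    )
                )
            except (ValidationError, ValueError) as exc:
                raise ParseError(f"line {lineno}: {exc}") from exc
    return out


def write_annotations(annotations: Iterable[ElementAnnotation], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["utt_id", "kind", "surface", "count", "medical"])
        for a in annotations:
            medical = "" if a.medical is None else str(a.medical).lower()
            writer.writerow([a.utt_id, a.kind, a.surface, a.count, medical])


def read_lexicon(path: str | Path) -> Lexicon:
    """Read a category lexicon (.dic dialect or word,category CSV)."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    stripped = text.lstrip()
    if stripped.startswith("%"):
        return _read_dic(text, path)
    return _read_lexicon_csv(path)


def _read_dic(text: str, path: Path) -> Lexicon:
    lines = text.splitlines()
    # category header sits between the first two lines that are exactly "%"
    delim = [i for i, ln in enumerate(lines) if ln.strip() == "%"]
    if len(delim) < 2:
        raise ParseError(f"{path}: .dic file needs a %%-delimited category header")
    id_to_cat: dict[str, str] = {}
    for lineno in range(delim[0] + 1, delim[1]):
        ln = lines[lineno].strip()
        if not ln:
            continue
        parts = ln.split()
        if len(parts) < 2:
            raise ParseError(f"line {lineno + 1}: category row needs an id and a name")
        id_to_cat[parts[0]] = parts[1]
    entries: dict[str, list[str]] = {cat: [] for cat in id_to_cat.values()}
    for lineno in range(delim[1] + 1, len(lines)):
        ln = lines[lineno].strip()
        if not ln:
            continue
        parts = ln.split()
        word, ids = parts[0], parts[1:]
        if not ids:
            raise ParseError(f"line {lineno + 1}: word row {word!r} lists no categories")
        for cid in ids:
            if cid not in id_to_cat:
                raise ValidationError(
                    f"line {lineno + 1}: word {word!r} references undeclared category {cid}"
                )
            entries[id_to_cat[cid]].append(word)
    return Lexicon.from_entries(entries)


def _read_lexicon_csv(path: Path) -> Lexicon:
    entries: dict[str, list[str]] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        for lineno, row in enumerate(reader, start=1):
            if not row or not "".join(row).strip():
                continue
            if lineno == 1 and [c.strip().lower() for c in row[:2]] == ["word", "category"]:
                continue
            if len(row) < 2:
                raise ParseError(f"line {lineno}: expected word,category")
            word, cat = row[0].strip(), row[1].strip()
            entries.setdefault(cat, []).append(word)
    return Lexicon.from_entries(entries)


def read_dimension_map(path: str | Path) -> DimensionMap:
    """Read a feature,dimension CSV into a :class:`DimensionMap`."""
    mapping: dict[str, str] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        for lineno, row in enumerate(reader, start=1):
            if not row or not "".join(row).strip():
                continue
            if lineno == 1 and [c.strip().lower() for c in row[:2]] == ["feature", "dimension"]:
                continue
            if len(row) < 2:
                raise ParseError(f"line {lineno}: expected feature,dimension")
            feat, dim = row[0].strip(), row[1].strip()
            if feat in mapping and mapping[feat] != dim:
                raise ValidationError(
                    f"line {lineno}: feature {feat!r} mapped to two dimensions"
                )
            mapping[feat] = dim
    return DimensionMap(mapping)
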
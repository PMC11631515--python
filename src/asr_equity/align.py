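"""Two-step word-level alignment of gold-standard and ASR transcripts.

Step one aligns the concatenated patient word stream of an encounter's gold
transcript against the ASR word stream by minimum word edit distance (unit
costs for substitution, deletion, insertion).  Step two projects the gold
utterance boundaries through that global alignment to extract, for each gold
utterance, its corresponding ASR segment together with per-utterance S/D/I
counts.  This lets every downstream metric operate per utterance even when
the ASR system merged, split, dropped, or hallucinated turns.

ASR words that the alignment places between two gold utterances (insertions
at a boundary) attach to the following utterance by default; ``backward`` and
``drop`` policies are available.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .core_io import Transcript, ValidationError

BoundaryAttach = Literal["forward", "backward", "drop"]

MATCH, SUBSTITUTION, DELETION, INSERTION = "match", "substitution", "deletion", "insertion"


@dataclass(frozen=True)
class EditOp:
    """A single step of the word-level edit alignment.

    Match/substitution consume one reference and one hypothesis word;
    deletion consumes only a reference word, insertion only a hypothesis word.
    """

    kind: str
    ref_index: int | None = None
    hyp_index: int | None = None

    def __post_init__(self) -> None:
        if self.kind in (MATCH, SUBSTITUTION):
            ok = self.ref_index is not None and self.hyp_index is not None
        elif self.kind == DELETION:
            ok = self.ref_index is not None and self.hyp_index is None
        elif self.kind == INSERTION:
            ok = self.ref_index is None and self.hyp_index is not None
        else:
            raise ValueError(f"unknown edit op kind {self.kind!r}")
        if not ok:
            raise ValueError(f"indices inconsistent with op kind {self.kind!r}")


@dataclass
class AlignmentResult:
    """Minimal-cost word alignment with its substitution/deletion/insertion
    counts; ``S + D + I`` is the word edit distance."""

    ops: list[EditOp]
    S: int
    D: int
    I: int
    n_ref: int

    @property
    def distance(self) -> int:
        return self.S + self.D + self.I


@dataclass
class SegmentedPair:
    """One gold utterance with its extracted ASR segment and op counts."""

    utt_id: str
    group: str
    gold_tokens: tuple[str, ...]
    asr_tokens: tuple[str, ...]
    ops: list[EditOp]
    S: int
    D: int
    I: int

    @property
    def n_ref(self) -> int:
        return len(self.gold_tokens)


def word_edit_alignment(ref: Sequence[str], hyp: Sequence[str]) -> AlignmentResult:
    """Minimum word-edit-distance alignment under unit costs.

    The backtrace prefers match > substitution > deletion > insertion so the
    result is deterministic and diagonal-heavy (segments stay contiguous).
    Runs in O(len(ref) x len(hyp)); the inner recurrence is vectorized per
    row, with the in-row insertion dependency resolved as a prefix minimum.
    """
    n, m = len(ref), len(hyp)
    if n == 0 and m == 0:
        return AlignmentResult([], 0, 0, 0, 0)
    if m == 0:
        ops = [EditOp(DELETION, ref_index=i) for i in range(n)]
        return AlignmentResult(ops, 0, n, 0, n)
    if n == 0:
        ops = [EditOp(INSERTION, hyp_index=j) for j in range(m)]
        return AlignmentResult(ops, 0, 0, m, 0)

    hyp_arr = np.array(hyp, dtype=object)
    D = np.empty((n + 1, m + 1), dtype=np.int32)
    D[0, :] = np.arange(m + 1)
    col = np.arange(1, m + 1)
    for i in range(1, n + 1):
        sub = D[i - 1, :-1] + (hyp_arr != ref[i - 1])
        cand = np.minimum(sub, D[i - 1, 1:] + 1)
        # In-row insertion dependency D[i,j] = min(cand[j], D[i,j-1]+1)
        # unrolls to D[i,j] = j + min(i, min_{k<=j}(cand[k]-k)): a prefix min.
        D[i, 0] = i
        D[i, 1:] = np.minimum(np.minimum.accumulate(cand - col), i) + col
    ops = _backtrace(ref, hyp, D)
    S = sum(1 for o in ops if o.kind == SUBSTITUTION)
    Dc = sum(1 for o in ops if o.kind == DELETION)
    I = sum(1 for o in ops if o.kind == INSERTION)
    return AlignmentResult(ops, S, Dc, I, n)


def _backtrace(ref: Sequence[str], hyp: Sequence[str], D: np.ndarray) -> list[EditOp]:
    ops: list[EditOp] = []
    i, j = len(ref), len(hyp)
    while i > 0 or j > 0:
        here = D[i, j]
        if i > 0 and j > 0 and ref[i - 1] == hyp[j - 1] and here == D[i - 1, j - 1]:
            ops.append(EditOp(MATCH, ref_index=i - 1, hyp_index=j - 1))
            i, j = i - 1, j - 1
        elif i > 0 and j > 0 and ref[i - 1] != hyp[j - 1] and here == D[i - 1, j - 1] + 1:
            ops.append(EditOp(SUBSTITUTION, ref_index=i - 1, hyp_index=j - 1))
            i, j = i - 1, j - 1
        elif i > 0 and here == D[i - 1, j] + 1:
            ops.append(EditOp(DELETION, ref_index=i - 1))
            i -= 1
        else:
            ops.append(EditOp(INSERTION, hyp_index=j - 1))
            j -= 1
    ops.reverse()
    return ops


def segment_asr_stream(
    gold: Transcript,
    asr_words: Sequence[str],
    boundary_attach: BoundaryAttach = "forward",
) -> list[SegmentedPair]:
    """Project gold utterance boundaries through the global alignment.

    Each gold utterance receives the ops whose reference index falls inside
    its span of the concatenated gold stream.  Pure-insertion ops between
    utterances follow ``boundary_attach``: forward (default) attaches them to
    the next utterance (end-of-stream insertions to the last), backward to
    the previous, drop discards them (breaking stream conservation).
    """
    if len(gold.utterances) == 0:
        raise ValidationError("cannot segment against an empty gold transcript")
    for u in gold.utterances:
        if len(u.tokens) == 0:
            raise ValidationError(f"gold utterance {u.utt_id!r} has no tokens")

    ref: list[str] = []
    owner: list[int] = []  # utterance index of each concatenated ref position
    for k, u in enumerate(gold.utterances):
        ref.extend(u.tokens)
        owner.extend([k] * len(u.tokens))

    result = word_edit_alignment(ref, list(asr_words))

    n_utts = len(gold.utterances)
    assigned: list[list[EditOp]] = [[] for _ in range(n_utts)]
    pending: list[EditOp] = []  # insertions awaiting an owner under "forward"
    prev_owner: int | None = None
    for op in result.ops:
        if op.ref_index is not None:
            k = owner[op.ref_index]
            if pending:
                if boundary_attach == "forward":
                    target = k
                elif boundary_attach == "backward":
                    target = prev_owner if prev_owner is not None else k
                else:  # drop: keep only insertions interior to an utterance
                    target = k if prev_owner == k else None
                if target is not None:
                    assigned[target].extend(pending)
                pending = []
            assigned[k].append(op)
            prev_owner = k
        else:
            pending.append(op)
    if pending and boundary_attach != "drop":
        # gold is nonempty, so at least one ref-consuming op exists
        assert prev_owner is not None
        assigned[prev_owner].extend(pending)

    out: list[SegmentedPair] = []
    for k, u in enumerate(gold.utterances):
        # assigned ops are already in global alignment order, so hyp-consuming
        # ops appear with strictly increasing hyp_index
        hyp_toks = tuple(
            asr_words[o.hyp_index] for o in assigned[k] if o.hyp_index is not None
        )
        S = sum(1 for o in assigned[k] if o.kind == SUBSTITUTION)
        Dc = sum(1 for o in assigned[k] if o.kind == DELETION)
        I = sum(1 for o in assigned[k] if o.kind == INSERTION)
        out.append(
            SegmentedPair(
                utt_id=u.utt_id,
                group=u.group,
                gold_tokens=u.tokens,
                asr_tokens=hyp_toks,
                ops=list(assigned[k]),
                S=S,
                D=Dc,
                I=I,
            )
        )
    return out


def align_transcripts(
    gold: Transcript,
    asr: Transcript,
    boundary_attach: BoundaryAttach = "forward",
) -> list[SegmentedPair]:
    """Convenience wrapper: concatenate the ASR transcript's tokens and run
    :func:`segment_asr_stream` against the gold transcript."""
    asr_words: list[str] = []
    for u in asr.utterances:
        asr_words.extend(u.tokens)
    return segment_asr_stream(gold, asr_words, boundary_attach)
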
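"""Per-utterance word error rate and its stratified summaries.

WER = 100 x (S + D + I) / N, where S, D, I count word substitutions,
deletions, and insertions against a reference of N words.  Insertions can
push WER above 100%.  Summaries are macro statistics over the per-utterance
WER distribution (mean, median, quartiles, range), stratified by group label
or by reference-length bin; a pooled-word micro WER is also provided for
transparency.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Hashable, Iterable, Sequence

import numpy as np
import pandas as pd

from .align import SegmentedPair

#: default reference-length cut points: N < 5, 5 <= N <= 11, N > 11
DEFAULT_LENGTH_BINS = (5, 12)
LENGTH_BIN_LABELS = ("<5", "5-11", ">11")


@dataclass(frozen=True)
class WERRecord:
    """One utterance's WER with the metadata used for stratification."""

    utt_id: str
    group: str
    n_ref: int
    S: int
    D: int
    I: int

    def __post_init__(self) -> None:
        if self.n_ref < 1:
            raise ValueError(
                f"utterance {self.utt_id!r}: WER undefined for empty reference"
            )

    @property
    def wer(self) -> float:
        return compute_wer(self.S, self.D, self.I, self.n_ref)


def compute_wer(S: int, D: int, I: int, N: int) -> float:
    """WER as a percentage; raises on an empty reference (N = 0)."""
    if N < 1:
        raise ValueError("WER undefined for N = 0 (exclude empty references upstream)")
    if min(S, D, I) < 0:
        raise ValueError("edit-op counts must be nonnegative")
    return 100.0 * (S + D + I) / N


def records_from_segments(pairs: Iterable[SegmentedPair]) -> list[WERRecord]:
    """Turn aligned utterance pairs into WER records (empty references are
    excluded upstream by the aligner, which rejects empty gold utterances)."""
    return [
        WERRecord(p.utt_id, p.group, p.n_ref, p.S, p.D, p.I) for p in pairs
    ]


def _summary_row(label: Hashable, wers: np.ndarray) -> dict:
    q25, med, q75 = np.quantile(wers, [0.25, 0.5, 0.75])  # linear interpolation
    return {
        "stratum": label,
        "n": int(wers.size),
        "mean": float(np.mean(wers)),
        "median": float(med),
        "q25": float(q25),
        "q75": float(q75),
        "min": float(np.min(wers)),
        "max": float(np.max(wers)),
    }


def summarize_wer(
    records: Sequence[WERRecord],
    key: Callable[[WERRecord], Hashable] | None = None,
) -> pd.DataFrame:
    """Macro WER summary per stratum (``key=None`` pools everything).

    Quantiles use the inclusive linear-interpolation convention.  Strata are
    reported in order of first appearance; an empty record set yields an
    empty frame.
    """
    strata: dict[Hashable, list[float]] = {}
    for r in records:
        strata.setdefault("all" if key is None else key(r), []).append(r.wer)
    rows = [_summary_row(label, np.asarray(v, dtype=float)) for label, v in strata.items()]
    return pd.DataFrame(
        rows, columns=["stratum", "n", "mean", "median", "q25", "q75", "min", "max"]
    )


def length_bin(n_ref: int, bins: tuple[int, int] = DEFAULT_LENGTH_BINS) -> str:
    lo, hi = bins
    if n_ref < lo:
        return f"<{lo}"
    if n_ref < hi:
        return f"{lo}-{hi - 1}"
    return f">{hi - 1}"


def wer_by_length_bin(
    records: Sequence[WERRecord], bins: tuple[int, int] = DEFAULT_LENGTH_BINS
) -> pd.DataFrame:
    """WER summary stratified by gold utterance length (default: short
    utterances under 5 words, 5-11 words, over 11 words)."""
    df = summarize_wer(records, key=lambda r: length_bin(r.n_ref, bins))
    order = {f"<{bins[0]}": 0, f"{bins[0]}-{bins[1] - 1}": 1, f">{bins[1] - 1}": 2}
    return df.sort_values("stratum", key=lambda s: s.map(order)).reset_index(drop=True)


def micro_wer(records: Sequence[WERRecord]) -> float:
    """Pooled-word WER: total edit ops over total reference words."""
    total_n = sum(r.n_ref for r in records)
    if total_n == 0:
        raise ValueError("micro WER undefined for an empty record set")
    total_ops = sum(r.S + r.D + r.I for r in records)
    return 100.0 * total_ops / total_n
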
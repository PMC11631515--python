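"""Lexicon-based category scoring and gold-vs-ASR percentage change.

A category score is the percentage of tokens in a text that match the
category's word list (literal entries plus trailing-wildcard prefixes); a
token belonging to several categories contributes to each.  Transcription
fidelity is then measured as the signed percentage change

    100 x (score_ASR - score_gold) / score_gold

per feature, and per dimension after summing feature scores within each
dimension on both sides (sum-then-ratio, not a mean of feature changes).
The change is undefined where the gold score is zero; undefined values are
flagged rather than dropped silently.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .core_io import DimensionMap, Lexicon, Transcript


@dataclass(frozen=True)
class PercentChange:
    """Signed percentage change of a feature or dimension score; ``defined``
    is False when the gold score is zero (division by zero)."""

    name: str
    value: float
    defined: bool
    gs_score: float = 0.0
    asr_score: float = 0.0


def count_matches(tokens: Sequence[str], lex: Lexicon) -> dict[str, int]:
    """Raw per-category match counts (multi-membership allowed)."""
    counts = {cat: 0 for cat in lex.categories}
    for tok in tokens:
        for cat in lex.matches(tok):
            counts[cat] += 1
    return counts


def score_text(tokens: Sequence[str], lex: Lexicon) -> dict[str, float]:
    """Per-category percentage of matching tokens; raises on empty input
    (scores are undefined with no tokens — exclude such texts upstream)."""
    if len(tokens) == 0:
        raise ValueError("category scores undefined for an empty token sequence")
    counts = count_matches(tokens, lex)
    n = len(tokens)
    return {cat: 100.0 * c / n for cat, c in counts.items()}


def percent_change_feature(name: str, gs: float, asr: float) -> PercentChange:
    """100 x (asr - gs) / gs, undefined (flagged) when gs is 0."""
    if gs == 0.0:
        return PercentChange(name, float("nan"), False, gs, asr)
    return PercentChange(name, 100.0 * (asr - gs) / gs, True, gs, asr)


def percent_change_features(
    gs_scores: Mapping[str, float], asr_scores: Mapping[str, float]
) -> list[PercentChange]:
    return [
        percent_change_feature(feat, gs_scores[feat], asr_scores.get(feat, 0.0))
        for feat in gs_scores
    ]


def percent_change_dimension(
    gs_scores: Mapping[str, float],
    asr_scores: Mapping[str, float],
    dmap: DimensionMap,
) -> list[PercentChange]:
    """Dimension-level change: sum feature scores within each dimension on
    both sides, then apply the percent-change formula to the sums."""
    out = []
    for dim in dmap.dimensions:
        feats = dmap.features_of(dim)
        gs_sum = sum(gs_scores.get(f, 0.0) for f in feats)
        asr_sum = sum(asr_scores.get(f, 0.0) for f in feats)
        out.append(percent_change_feature(dim, gs_sum, asr_sum))
    return out


def transcript_tokens(t: Transcript) -> list[str]:
    toks: list[str] = []
    for u in t.utterances:
        toks.extend(u.tokens)
    return toks


def score_encounter_changes(
    gold_tokens: Sequence[str],
    asr_tokens: Sequence[str],
    lex: Lexicon,
    dmap: DimensionMap | None = None,
) -> pd.DataFrame:
    """Feature- and dimension-level percent changes for one encounter's
    pooled patient text.  Returns a tidy frame with columns
    level, name, gs_score, asr_score, pct_change, defined."""
    if len(gold_tokens) == 0 or len(asr_tokens) == 0:
        raise ValueError("encounter has no scorable tokens on one side")
    gs = score_text(gold_tokens, lex)
    asr = score_text(asr_tokens, lex)
    rows = []
    for pc in percent_change_features(gs, asr):
        rows.append(
            {
                "level": "feature",
                "name": pc.name,
                "gs_score": pc.gs_score,
                "asr_score": pc.asr_score,
                "pct_change": pc.value,
                "defined": pc.defined,
            }
        )
    if dmap is not None:
        for pc in percent_change_dimension(gs, asr, dmap):
            rows.append(
                {
                    "level": "dimension",
                    "name": pc.name,
                    "gs_score": pc.gs_score,
                    "asr_score": pc.asr_score,
                    "pct_change": pc.value,
                    "defined": pc.defined,
                }
            )
    return pd.DataFrame(rows)
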
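"""End-to-end orchestration: normalize -> align -> WER -> group comparison
-> lexicon scoring -> speech-element error rates, plus corpus summaries.

The in-memory entry point is :func:`run_analysis`; :func:`run_pipeline`
wraps it with file I/O and writes a report bundle (stage CSVs plus one
machine-readable JSON summary that also records the configuration and every
exclusion count, so each number is recomputable from the stage outputs).
"""

from __future__ import annotations

import importlib.resources
import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import align as _align
from .core_io import (
    DimensionMap,
    ElementAnnotation,
    Lexicon,
    Transcript,
    ValidationError,
    filter_speaker,
    read_annotations,
    read_corpus,
    read_dimension_map,
    read_lexicon,
)
from .disparity_stats import BMTestResult, DegenerateSamplesError, brunner_munzel
from .lexicon_scoring import score_encounter_changes
from .normalize import (
    NormalizationDictionary,
    load_default_dictionary,
    load_dictionary,
    normalize_transcript,
)
from .speech_elements import (
    filler_error_rate,
    proper_noun_error_rate,
    repetition_error_rate,
)
from .wer_metrics import (
    WERRecord,
    micro_wer,
    records_from_segments,
    summarize_wer,
    wer_by_length_bin,
)


def packaged_lexicon() -> Lexicon:
    """The small synthetic category lexicon shipped with the package (a
    stand-in for proprietary dictionaries; 20 features over 10 dimensions)."""
    ref = importlib.resources.files("asr_equity").joinpath("data/synthetic_lexicon.dic")
    with importlib.resources.as_file(ref) as p:
        return read_lexicon(p)


def packaged_dimension_map() -> DimensionMap:
    ref = importlib.resources.files("asr_equity").joinpath("data/dimension_map.csv")
    with importlib.resources.as_file(ref) as p:
        return read_dimension_map(p)


@dataclass
class RunConfig:
    """File-based pipeline configuration; serialized into every output."""

    gold_path: str
    asr_path: str
    annotations_path: str | None = None
    lexicon_path: str | None = None
    dimension_map_path: str | None = None
    norm_dict_path: str | None = None
    speaker: str = "patient"
    boundary_attach: str = "forward"
    length_bins: tuple[int, int] = (5, 12)
    out_dir: str = "results"


def summarize_corpus(gold: Iterable[Transcript]) -> pd.DataFrame:
    """Per-group encounter characteristics: utterances per encounter and
    words per encounter (mean, SD, quartiles), patient turns only.

    SD over a single encounter is reported as NaN (0 degrees of freedom).
    """
    rows = []
    per_group: dict[str, list[tuple[int, int]]] = {}
    for t in gold:
        patient = filter_speaker(t, "patient")
        if not patient.utterances:
            continue
        group = patient.utterances[0].group
        n_utt = len(patient.utterances)
        n_words = sum(len(u.tokens) for u in patient.utterances)
        per_group.setdefault(group, []).append((n_utt, n_words))
    for group, stats in per_group.items():
        for label, values in (
            ("utterances_per_encounter", [s[0] for s in stats]),
            ("words_per_encounter", [s[1] for s in stats]),
        ):
            arr = np.asarray(values, dtype=float)
            q25, med, q75 = np.quantile(arr, [0.25, 0.5, 0.75])
            rows.append(
                {
                    "group": group,
                    "measure": label,
                    "n_encounters": arr.size,
                    "mean": float(arr.mean()),
                    "sd": float(arr.std(ddof=1)) if arr.size > 1 else float("nan"),
                    "q25": float(q25),
                    "median": float(med),
                    "q75": float(q75),
                }
            )
    return pd.DataFrame(
        rows,
        columns=["group", "measure", "n_encounters", "mean", "sd", "q25", "median", "q75"],
    )


@dataclass
class AnalysisResult:
    """Bundle of every stage's outputs for one gold/ASR corpus pair."""

    corpus_summary: pd.DataFrame
    wer_records: list[WERRecord]
    wer_overall: pd.DataFrame
    wer_by_group: pd.DataFrame
    wer_by_length: pd.DataFrame
    micro_wer: float
    bm_test: BMTestResult | None
    bm_groups: tuple[str, str] | None
    lexicon_changes: pd.DataFrame
    element_rates: pd.DataFrame
    diagnostics: dict

    def summary_dict(self) -> dict:
        out = {
            "micro_wer": self.micro_wer,
            "wer_overall": self.wer_overall.to_dict(orient="records"),
            "wer_by_group": self.wer_by_group.to_dict(orient="records"),
            "wer_by_length": self.wer_by_length.to_dict(orient="records"),
            "corpus_summary": self.corpus_summary.to_dict(orient="records"),
            "element_rates": self.element_rates.to_dict(orient="records"),
            "diagnostics": self.diagnostics,
        }
        if self.bm_test is not None:
            out["brunner_munzel"] = {
                "groups": list(self.bm_groups),
                "statistic": self.bm_test.statistic,
                "df": self.bm_test.df,
                "p_value": self.bm_test.p_value,
                "relative_effect": self.bm_test.relative_effect,
                "n_x": self.bm_test.n_x,
                "n_y": self.bm_test.n_y,
            }
        if not self.lexicon_changes.empty:
            dims = self.lexicon_changes[
                (self.lexicon_changes["level"] == "dimension")
                & self.lexicon_changes["defined"]
            ]
            out["dimension_pct_change_mean"] = (
                dims.groupby("name")["pct_change"].mean().to_dict()
            )
        return out


def run_analysis(
    gold: Sequence[Transcript],
    asr: Sequence[Transcript],
    annotations: Sequence[ElementAnnotation] = (),
    lexicon: Lexicon | None = None,
    dmap: DimensionMap | None = None,
    norm_dict: NormalizationDictionary | None = None,
    speaker: str = "patient",
    boundary_attach: str = "forward",
    length_bins: tuple[int, int] = (5, 12),
) -> AnalysisResult:
    """Run every evaluation stage on matched gold/ASR transcript corpora.

    Encounters are matched by ``encounter_id`` (an encounter absent from the
    ASR corpus is treated as fully untranscribed only if present with zero
    utterances; a missing id raises).  Gold utterances with no tokens after
    normalization are excluded from WER and counted in diagnostics.
    """
    d = norm_dict or load_default_dictionary()
    asr_by_enc = {t.encounter_id: t for t in asr}
    missing = [t.encounter_id for t in gold if t.encounter_id not in asr_by_enc]
    if missing:
        raise ValidationError(f"ASR corpus lacks encounters: {missing}")

    all_pairs = []
    lexicon_rows = []
    empty_gold = 0
    for gt in gold:
        g_pat = normalize_transcript(filter_speaker(gt, speaker), d)
        a_pat = normalize_transcript(
            filter_speaker(asr_by_enc[gt.encounter_id], speaker), d
        )
        nonempty = [u for u in g_pat.utterances if len(u.tokens) > 0]
        empty_gold += len(g_pat.utterances) - len(nonempty)
        if not nonempty:
            continue
        g_use = Transcript(g_pat.encounter_id, nonempty, "gold")
        pairs = _align.align_transcripts(g_use, a_pat, boundary_attach)
        all_pairs.extend(pairs)

        if lexicon is not None:
            gold_toks = [tok for u in g_use.utterances for tok in u.tokens]
            asr_toks = [tok for p in pairs for tok in p.asr_tokens]
            if gold_toks and asr_toks:
                df = score_encounter_changes(gold_toks, asr_toks, lexicon, dmap)
                df.insert(0, "encounter_id", gt.encounter_id)
                df.insert(1, "group", nonempty[0].group)
                lexicon_rows.append(df)

    records = records_from_segments(all_pairs)
    wer_overall = summarize_wer(records)
    wer_by_group = summarize_wer(records, key=lambda r: r.group)
    wer_by_len = wer_by_length_bin(records, length_bins)

    groups = list(dict.fromkeys(r.group for r in records))
    bm = None
    bm_groups = None
    if len(groups) == 2:
        x = [r.wer for r in records if r.group == groups[0]]
        y = [r.wer for r in records if r.group == groups[1]]
        if len(x) >= 2 and len(y) >= 2:
            try:
                bm = brunner_munzel(x, y)
                bm_groups = (groups[0], groups[1])
            except DegenerateSamplesError:
                bm = None

    lex_df = (
        pd.concat(lexicon_rows, ignore_index=True)
        if lexicon_rows
        else pd.DataFrame(
            columns=[
                "encounter_id", "group", "level", "name",
                "gs_score", "asr_score", "pct_change", "defined",
            ]
        )
    )

    element_rows = []
    pairs_by_group: dict[str, list] = {}
    for p in all_pairs:
        pairs_by_group.setdefault(p.group, []).append(p)
    scopes = [("all", all_pairs)] + sorted(pairs_by_group.items())
    for label, pairs in scopes:
        if not pairs:
            continue
        element_rows.append(
            {
                "element": "filler",
                "group": label,
                "rate_pct": filler_error_rate(pairs),
                "n_utterances": len(pairs),
            }
        )
        element_rows.append(
            {
                "element": "repetition",
                "group": label,
                "rate_pct": repetition_error_rate(pairs),
                "n_utterances": len(pairs),
            }
        )
    if annotations:
        segments = {p.utt_id: p.asr_tokens for p in all_pairs}
        utt_group = {p.utt_id: p.group for p in all_pairs}
        scoped_annotations = [("all", list(annotations))] + [
            (
                g,
                [a for a in annotations if utt_group.get(a.utt_id) == g],
            )
            for g in sorted(pairs_by_group)
        ]
        for label, anns in scoped_annotations:
            rates = proper_noun_error_rate(anns, segments, d)
            for flag, pr in rates.items():
                if pr.total == 0:
                    continue
                element_rows.append(
                    {
                        "element": f"proper_noun_{flag}",
                        "group": label,
                        "rate_pct": pr.rate,
                        "rate_pct_truncated": pr.rate_truncated,
                        "n_terms": pr.total,
                        "n_correct": pr.correct,
                    }
                )
    element_df = pd.DataFrame(element_rows)

    n_undefined = (
        int((~lex_df["defined"]).sum()) if not lex_df.empty else 0
    )
    diagnostics = {
        "excluded_empty_gold_utterances": empty_gold,
        "undefined_percent_changes": n_undefined,
        "n_utterance_pairs": len(all_pairs),
        "boundary_attach": boundary_attach,
        "groups": groups,
    }

    return AnalysisResult(
        corpus_summary=summarize_corpus(gold),
        wer_records=records,
        wer_overall=wer_overall,
        wer_by_group=wer_by_group,
        wer_by_length=wer_by_len,
        micro_wer=micro_wer(records),
        bm_test=bm,
        bm_groups=bm_groups,
        lexicon_changes=lex_df,
        element_rates=element_df,
        diagnostics=diagnostics,
    )


def run_pipeline(cfg: RunConfig) -> AnalysisResult:
    """File-based pipeline: read inputs, run :func:`run_analysis`, write the
    report bundle (CSVs + summary.json) into ``cfg.out_dir``."""
    gold = read_corpus(cfg.gold_path, "gold")
    asr = read_corpus(cfg.asr_path, "asr")
    annotations = (
        read_annotations(cfg.annotations_path) if cfg.annotations_path else []
    )
    lexicon = read_lexicon(cfg.lexicon_path) if cfg.lexicon_path else packaged_lexicon()
    dmap = (
        read_dimension_map(cfg.dimension_map_path)
        if cfg.dimension_map_path
        else packaged_dimension_map()
    )
    norm = load_dictionary(cfg.norm_dict_path) if cfg.norm_dict_path else None

    result = run_analysis(
        gold,
        asr,
        annotations,
        lexicon,
        dmap,
        norm,
        speaker=cfg.speaker,
        boundary_attach=cfg.boundary_attach,
        length_bins=tuple(cfg.length_bins),
    )

    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.corpus_summary.to_csv(out / "corpus_summary.csv", index=False)
    result.wer_overall.to_csv(out / "wer_overall.csv", index=False)
    result.wer_by_group.to_csv(out / "wer_by_group.csv", index=False)
    result.wer_by_length.to_csv(out / "wer_by_length.csv", index=False)
    result.lexicon_changes.to_csv(out / "lexicon_changes.csv", index=False)
    result.element_rates.to_csv(out / "element_rates.csv", index=False)
    pd.DataFrame(
        [
            {
                "utt_id": r.utt_id,
                "group": r.group,
                "n_ref": r.n_ref,
                "S": r.S,
                "D": r.D,
                "I": r.I,
                "wer": r.wer,
            }
            for r in result.wer_records
        ]
    ).to_csv(out / "wer_records.csv", index=False)
    summary = {"config": asdict(cfg), **result.summary_dict()}
    (out / "summary.json").write_text(json.dumps(summary, indent=2, default=float))
    return result
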
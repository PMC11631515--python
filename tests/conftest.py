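from __future__ import annotations

import sys
from pathlib import Path

import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from asr_equity.core_io import Lexicon, Transcript, make_utterance
from asr_equity.normalize import load_default_dictionary
from asr_equity.report import packaged_dimension_map, packaged_lexicon


@pytest.fixture(scope="session")
def norm_dict():
    return load_default_dictionary()


@pytest.fixture(scope="session")
def lexicon() -> Lexicon:
    return packaged_lexicon()


@pytest.fixture(scope="session")
def dimension_map():
    return packaged_dimension_map()


@pytest.fixture()
def tiny_lexicon() -> Lexicon:
    return Lexicon.from_entries({"negemo": ["sad"], "posemo": ["happy", "happ*"]})


def _utts(texts, speaker="patient", group="Black", prefix="u"):
    return [
        make_utterance(f"{prefix}{i}", speaker, group, t) for i, t in enumerate(texts)
    ]


@pytest.fixture()
def small_gold() -> Transcript:
    """One encounter, patient and nurse turns interleaved."""
    utts = []
    utts.append(make_utterance("p0", "patient", "Black", "i don't feel good today"))
    utts.append(make_utterance("n0", "nurse", "Black", "how are you feeling"))
    utts.append(make_utterance("p1", "patient", "Black", "um the pain is worse"))
    utts.append(make_utterance("p2", "patient", "Black", "okay"))
    utts.append(make_utterance("n1", "nurse", "Black", "let me check"))
    utts.append(make_utterance("p3", "patient", "Black", "i know i know it hurts"))
    return Transcript("enc0", utts, "gold")


def make_transcript(texts, *, speaker="patient", group="Black", source="gold", enc="enc0"):
    return Transcript(enc, _utts(texts, speaker=speaker, group=group), source)


@pytest.fixture()
def make_gold():
    return make_transcript
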
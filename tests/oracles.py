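"""Independent reference implementations used only to check the package.

Each oracle deliberately takes the dumbest correct route (exhaustive
recursion, pairwise counting, straight-from-formula arithmetic) and shares
no code with the implementation under test.
"""

from __future__ import annotations

from functools import lru_cache
from typing import Sequence


def brute_edit_distance(ref: Sequence[str], hyp: Sequence[str]) -> int:
    """Word edit distance by exhaustive memoized recursion."""
    ref = tuple(ref)
    hyp = tuple(hyp)

    @lru_cache(maxsize=None)
    def go(i: int, j: int) -> int:
        if i == len(ref):
            return len(hyp) - j
        if j == len(hyp):
            return len(ref) - i
        best = go(i + 1, j + 1) + (ref[i] != hyp[j])  # match / substitute
        best = min(best, go(i + 1, j) + 1)  # delete ref word
        best = min(best, go(i, j + 1) + 1)  # insert hyp word
        return best

    return go(0, 0)


_ONES = (
    "zero one two three four five six seven eight nine ten eleven twelve "
    "thirteen fourteen fifteen sixteen seventeen eighteen nineteen"
).split()
_TENS_WORDS = {2: "twenty", 3: "thirty", 4: "forty", 5: "fifty",
               6: "sixty", 7: "seventy", 8: "eighty", 9: "ninety"}


def spell_number(n: int) -> list[str]:
    """Canonical spoken spelling (digit-by-digit place values, with "and"
    between hundreds and the remainder), written independently of the
    package's variant generator."""
    assert 0 <= n <= 9999
    if n < 20:
        return [_ONES[n]]
    words: list[str] = []
    thousands, n = divmod(n, 1000)
    if thousands:
        words += [_ONES[thousands], "thousand"]
    hundreds, n = divmod(n, 100)
    if hundreds:
        words += [_ONES[hundreds], "hundred"]
    if n:
        if words:
            words.append("and")
        if n < 20:
            words.append(_ONES[n])
        else:
            tens, units = divmod(n, 10)
            words.append(_TENS_WORDS[tens])
            if units:
                words.append(_ONES[units])
    return words


def pairwise_relative_effect(x: Sequence[float], y: Sequence[float]) -> float:
    """P(X < Y) + 0.5 P(X = Y) by exhaustive pairwise counting."""
    total = 0.0
    for xi in x:
        for yj in y:
            if xi < yj:
                total += 1.0
            elif xi == yj:
                total += 0.5
    return total / (len(x) * len(y))


def element_rate_from_components(
    per_utterance: Sequence[tuple[int, int, int]],
) -> float:
    """Error rate straight from the printed formula.

    Each tuple is (gold_count, missed_count, added_count) for one utterance.
    """
    n = len(per_utterance)
    numer = 0.0
    for gold, missed, added in per_utterance:
        if gold:
            numer += missed / gold
        if added:
            numer += 1.0
    return 100.0 * numer / n


def repetition_events_oracle(tokens: Sequence[str], max_unit: int = 4) -> list[tuple]:
    """Repetition events by explicit candidate enumeration and rule-based
    selection: maximal runs of primitive units, longer units first, then
    earlier position, non-overlapping."""
    tokens = tuple(tokens)
    n = len(tokens)

    def primitive(unit: tuple) -> bool:
        for d in range(1, len(unit)):
            if len(unit) % d == 0 and unit == unit[:d] * (len(unit) // d):
                return False
        return True

    candidates = []
    for u in range(1, max_unit + 1):
        for start in range(n):
            unit = tokens[start : start + u]
            if len(unit) < u or not primitive(unit):
                continue
            reps = 0
            while tokens[start + reps * u : start + (reps + 1) * u] == unit:
                reps += 1
            if reps < 2:
                continue
            left_ok = start < u or tokens[start - u : start] != unit
            if left_ok:
                candidates.append((unit, reps, start))
    chosen = []
    used: set[int] = set()
    for unit, reps, start in sorted(candidates, key=lambda c: (-len(c[0]), c[2])):
        span = set(range(start, start + reps * len(unit)))
        if span & used:
            continue
        chosen.append((unit, reps, start))
        used |= span
    return sorted(chosen, key=lambda c: c[2])
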
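# Methods

This note documents the models, conventions, and design choices behind the
package, in the order the pipeline runs them.

## Unit of analysis

The utterance — one continuous speaker turn — is the unit for every metric.
Nurse turns are filtered out before analysis (the audit concerns patient
speech), and utterances are treated as independent observations. Repeated
utterances from the same patient are *not* modeled with random effects; the
group comparison therefore tests a marginal hypothesis over utterances, and
within-patient clustering, if strong, will make its p-values optimistic.
This is a deliberate simplification, flagged here rather than hidden.

## Tokenization and normalization

Tokens are lowercased words with punctuation stripped, except word-internal
apostrophes (`don't`) and hyphens (`twenty-one`), and except clock-time
(`4:15`) and digit (`150`) tokens, which are preserved whole. Casing and
punctuation never enter WER because ASR systems differ arbitrarily in both
and a word-based error rate should not penalize them.

Normalization rewrites token sequences with an ordered rule table applied
left-to-right, longest match first, no overlap — the way a human
transcriber applies a conversion guideline. The default table is generated
at load time and covers:

- English number spell-outs 0–9999, with and without "and"
  (`one hundred and fifty` → `150`) and hyphenated tens (`twenty-one` → `21`);
- quarter/half clock phrases anchored on an hour word
  (`a quarter past four` → `4:15`, `quarter to one` → `12:45`); unanchored
  fragments (`past four` alone) are left as words;
- filler variants: each canonical filler (`um, uh, oh, er, ah, mm, hmm`)
  plus lengthenings generated by repeating the final letter (`umm`, `uhh`,
  …) and a few attested spellings (`uhm`, `hm`, `erm`).

No rule's output matches another rule's input, which makes normalization
idempotent (property-tested). The table is a reconstruction of common
transcription-guideline conventions and can be replaced wholesale by a
`pattern,replacement` CSV (`--norm-dict`). Dialect forms are never
rewritten: the pipeline evaluates transcription of dialect, it does not
"correct" it.

## Alignment

Per encounter, the concatenated gold patient word stream is aligned to the
concatenated ASR patient word stream by minimum word edit distance with
unit costs (match 0; substitution, deletion, insertion 1) and exact string
equality after normalization — no phonetic similarity. The backtrace
breaks ties in the fixed order match > substitution > deletion > insertion,
which makes results deterministic and keeps alignments diagonal-heavy. The
DP is O(nm) with the in-row insertion recurrence vectorized as a prefix
minimum; encounters of ~1300 words align in well under a second.

Gold utterance boundaries are then projected through the global alignment:
each utterance receives the ops that consume its reference positions. Pure
insertions falling *between* utterances have no natural owner; by default
they attach to the following utterance (hallucinated background words are
most often preamble to the next turn), with `backward` and `drop` policies
available. Under `forward`/`backward`, concatenating the extracted segments
reproduces the ASR stream exactly and per-utterance op counts sum to the
global edit distance (conservation, oracle-tested); `drop` sacrifices
conservation to keep segments clean.

Two consequences worth knowing: a gold utterance wholly missed by the ASR
system becomes a pure-deletion segment with WER 100; and because the global
alignment may explain the data more cheaply than the true generative
process did, pipeline WER is a lower bound on the injected error rate
(property-tested against the simulator's edit log).

## WER summaries

WER is undefined for empty references; utterances with no tokens after
normalization are excluded and counted in the diagnostics table. The
headline statistics are macro (per-utterance distribution: mean, median,
quartiles with the inclusive linear-interpolation convention, min, max); a
pooled-word micro WER is emitted alongside for transparency. Length bins
default to N < 5, 5–11, > 11 reference words.

## Brunner–Munzel test

The two-sample comparison uses the Brunner–Munzel statistic on midranks,
with the placement-based variance estimator, Satterthwaite-type degrees of
freedom, and two-sided t p-values; it estimates the relative effect
P(X < Y) + ½·P(X = Y) directly. Midranks are required because WER values
repeat heavily. Edge cases: jointly constant samples raise a degenerate-
variance error; complete separation yields an infinite statistic with
p = 0 while the relative effect (0 or 1) remains meaningful. For very
small samples a studentized permutation p-value (`method="permutation"`,
seeded) is available. The implementation is cross-checked in the test suite
against an independently coded version to 10⁻¹⁰ and against exhaustive
pairwise counting of the relative effect. Raw p-values are reported with no
multiple-testing correction, and are labeled as such.

## Lexicon scoring

Category scoring is lexicon-agnostic: any mapping of category → word list
with optional trailing-wildcard prefixes, read from a `%`-delimited `.dic`
table or a two-column CSV. A token may belong to several categories; a
category score is the percentage of tokens matching it, so scores depend
only on the bag of words (segmentation-invariant, property-tested).

Percentage change is computed per encounter on the pooled patient text of
each side, then summarized by group — per-encounter granularity matches how
such scores are usually aggregated and keeps denominators large enough to
be stable. Dimension scores sum their features' scores *before* taking the
ratio; this is not equivalent to averaging feature-level changes and the
distinction is enforced by test. Changes with a zero gold score are
undefined: they are flagged and counted, never silently dropped or treated
as zero. The packaged lexicon (20 features over 10 dimensions) is synthetic
— built for the generator's vocabulary — because real psycholinguistic
dictionaries are proprietary; all computations accept a user lexicon.

## Speech elements

**Fillers.** The inventory defaults to the canonical set
`um, uh, oh, er, ah, mm, hmm` (variant collapsing happens during
normalization). A gold filler counts as captured iff its alignment op is a
match; a substitution by a *different* filler counts as missed by default
(`strict=False` relaxes this), and an ASR filler arriving via insertion or
via substitution of a non-filler word counts as "added". An utterance
contributes `missed/gold` to the error numerator plus 1 if it contains any
added filler; the denominator is the number of reviewed utterance pairs.
An utterance can contribute both terms — the added-filler count is about
the utterance containing spurious fillers, not about whether it had gold
fillers at all.

**Repetitions.** A repetition event is a maximal consecutive run (≥2) of a
primitive unit of up to 4 tokens — primitive meaning the unit is not itself
copies of a shorter block, so `a a a a` is one run of unit `a`, not two of
`a a`. Candidate events are selected longest-unit-first, then earliest,
non-overlapping; a run of any length is a single event. Detection runs
independently on the gold tokens and the extracted ASR segment, and events
are matched as multisets of units. The error formula mirrors the filler
one, with events as the counted element.

**Proper nouns.** Gold proper nouns come from annotations (no automatic
NER). A term is correct iff its normalized, possibly multi-token surface
appears contiguously in the ASR segment of its utterance — recognition is
right or wrong, never graded by string similarity. Rates are reported per
medical flag; displayed integers truncate (floor) the exact percentage,
with full precision retained in CSV output.

## Synthetic data generator

The generator emulates the *shape* of recorded home-healthcare encounters,
not their content: two group labels with per-encounter utterance counts of
mean 95 (SD 17) and 77 (SD 24); log-normal utterance lengths (median 9
words, σ = 0.8) putting roughly a thousand words in each patient's mouth
per encounter; fillers in 17% of utterances; repetition events in ~14%;
proper nouns in ~8.5% of utterances, 29% of them medical; and optional
interleaved nurse turns. Content words come from a closed vocabulary that
overlaps the packaged lexicon, so category scores are well populated.
Annotations record exactly what was injected (generation-time ground truth,
no re-detection). Consecutive duplicate content words are avoided so the
only gold repetition runs are deliberate.

The corruption process is per-token and independent, by group: generic
substitution/deletion/insertion rates, filler omission and insertion,
repetition collapse (the run's repeats beyond the first unit are deleted),
proper-noun corruption, and dropping of short (<5 word) utterances.
Substituted tokens are drawn from the vocabulary excluding the original;
inserted tokens come from a disjoint noise pool so insertions dilute rather
than inflate category scores. Every edit is logged, and replaying the log
against the gold tokens must reproduce the ASR stream byte-for-byte
(tested). The default configuration gives the `Black` group a harsher
process (substitution 0.35 vs 0.2, plus slightly higher rates elsewhere),
reproducing the direction of disparities reported for commercial ASR
systems so that the disparity statistics have a known signal to recover.

What the generator does **not** model — and therefore what passing tests do
not establish about real data: acoustics and channel noise, dialect
phonology and morphology (error rates are injected, not caused by
linguistic features), burst/correlated errors (a burst option exists but
defaults off), ASR language-model effects such as semantically plausible
substitutions, and diarization confusion beyond whole-utterance drops.
Recovery results on synthetic corpora validate the *measurement machinery*,
not any claim about a particular ASR system.

## Problem sizes and numerical conventions

Simulation-based tests use study-scale corpora (5 encounters per group,
~800–950 patient utterances total), 5000 null replicates at n = 50/group
for the type-I-error check (band 0.04–0.06 at α = 0.05), 100 seeded
replicates for the power check (substitution 0.2 vs 0.35, rejection in
>90%), and 3-standard-error tolerances for all stochastic recovery checks.
All randomness flows through explicit integer seeds (`numpy` Generators);
identical seeds give byte-identical corpora and report bundles. Quantile
convention, boundary-attach rule, and exclusion counts are recorded in the
report bundle so every summary number can be recomputed from the stage
CSVs.

## Known limitations

- No clustering of utterances within patients (see above).
- Exact-match proper-noun scoring counts near-misses (`tylenol` vs
  `tylenols`) as wrong; fuzzy matching is intentionally out of scope.
- The normalization table covers numbers, anchored clock phrases, and
  filler variants only; domain-specific conventions need a user dictionary.
- The boundary-attach rule for between-utterance insertions is a
  convention; both alternatives are implemented and the choice is recorded
  in the output, but results for insertion-heavy ASR output will depend
  mildly on it.
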
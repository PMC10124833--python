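# Methods

## Model and procedure

The analysis is a lexicon-based, bag-of-words emotion profile at sentence
scope. Its assumptions are those of the NRC EmoLex tradition: a word's
emotional load is context-free, binary per category, and additive across a
sentence. No negation handling, valence shifters, intensity weighting, or
emoji mapping are applied; a sentence's count vector is exactly the sum of
its tokens' association vectors.

The dyad statistic treats the *joint presence* of two basic emotions in
one sentence as evidence of a complex emotion. The per-sentence score is
the minimum of the two constituent counts — the largest number of
co-occurring "pairs" the sentence supports — summed over the corpus. The
min-rule is the only reading consistent with the defining worked example
(sadness 2 with joy 3 gives bittersweetness 2). Dyads are defined over the
8 basic emotions only; the two sentiment polarities are scored alongside
but never enter dyad computation.

Normalization is **within class**: the basic wheel and each of the four
dyad classes are divided by their own maximum, so every wheel has exactly
one unit-length petal (when its class maximum is nonzero). Ratios are kept
exact internally; reports round half-up to 2 decimals.

## Text segmentation

Sentence segmentation is a deterministic rule: split at runs of `. ! ?`
(optionally followed by closing quotes/brackets) at a whitespace boundary,
unless the preceding word is in a fixed abbreviation guard list (dr, mr,
mrs, ms, vs, e.g, i.e, etc). Tokenization lowercases (Unicode-aware) and
splits on any non-alphanumeric character, so clitics split ("don't" → don,
t) and hyphenated compounds decompose. Determinism was chosen over
linguistic fidelity: the reference tooling in this field does not document
its segmenter, and only a deterministic rule makes counts reproducible.
Single-letter fragments produced by apostrophe splitting are harmless: no
EmoLex-style lexicon contains single letters, so they can never alter a
count.

Lexicon matching is exact lowercase equality — no stemming or
lemmatization — mirroring the Syuzhet/EmoLex convention; per-sentence
count tables are only reproducible under exact matching. Duplicate lines
in a long-format lexicon resolve to the last flag, with a logged warning.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| lexicon | built-in 10-word fixture | word → 10-flag association table; any NRC-format lexicon can be substituted (`load_lexicon`, long or wide TSV) |
| keyword patterns | 6 clinical-trial wildcards | `*` matches zero or more **non**-alphanumeric characters, so `clinical*trial` catches "clinical trial"/"clinical-trial"/"clinicaltrial" but never "clinically trialed" |
| inclusion filter | on | restricts scoring to patient/caregiver posts; healthcare-professional and unknown authors are excluded |
| report rounding | half-up, 2 decimals (ratios, M), 1 decimal (percentages) | internal arithmetic is exact |

Deduplication is keyed on post id (keyword downloads of one community
overlap exactly by id), keeping the first occurrence. Kappa treats
"unknown" as a real label, not missing data, and is the standard
unweighted two-rater statistic; disagreements are reported, never
auto-resolved. User-type percentages are taken over corpus size;
post-type percentages over the number of assigned labels.

## Synthetic-data generator

The generator emulates the shape of a keyword-filtered cancer-forum
corpus: 337 posts by default, timestamps uniform over July 2011–November
2021, user types drawn at (patient .383, caregiver .332, hc .021, unknown
.264) and post types at (advice .227, experience .419, both .251, unknown
.103), 3–20 sentences per post and 8–25 words per sentence (≈ 60k tokens
at default size), and a default emotion mixture proportional to the
category prevalences typical of clinical-trial discussions (positive and
fear-heavy, surprise rare). The out-of-vocabulary fraction defaults to
0.7: most running prose in forum posts is function words and
out-of-lexicon content, and a majority-OOV stream is what makes the
exact-match scorer's zero-contamination property worth testing.

Ground truth is recorded from the planted words' *full* lexicon vectors,
not from the sampling intent — a multi-emotion word contributes to every
category it flags — so recovery checks are exact with zero tolerance.
Fillers come from a syllable generator and are screened against the
lexicon; planted words are restricted to single-token, non-abbreviation
lexicon entries so segmentation and tokenization are invertible on
generated text. Generated sentences are word sequences without grammar:
the scorer is bag-of-words at sentence scope, so syntactic realism would
add nothing testable. What passing recovery tests shows is that counting,
segmentation bookkeeping and aggregation are exact; it says nothing about
how well a 10-word or full lexicon captures emotion in real prose.

## Numerical choices and degenerate inputs

- Ratios and means are double precision; only reports round (half-up:
  Python's banker's rounding would disagree with conventionally rounded
  published tables at .5 boundaries).
- A dyad class with maximum frequency 0 gets all-zero ratios (no 0/0).
- An empty sentence matrix makes M undefined: `aggregate` raises rather
  than returning NaNs, and the pipeline reports the failing stage.
- Kappa with expected agreement 1 (both raters constant and identical) is
  undefined and raises.
- Band assignment maps κ ≤ 0 to "no agreement" and uses closed upper
  bounds (0.20/0.40/0.60/0.80/1.00).
- The generator's sampling path uses a single seeded NumPy generator;
  identical seeds give bit-identical corpora, and pipeline reruns give
  byte-identical tabular artifacts.

## Known limitations and documented discrepancies

- Published co-occurrence tables for this statistic are reproducible from
  their printed frequencies under the class-max rule for 26 of 28 dyads;
  two printed ratios (cynicism 325/1322 → 0.25 printed as 0.24;
  aggressiveness 370/813 → 0.46 printed as 0.45) are consistent with
  truncation instead. The package implements the single consistent rule
  and its tests exclude those two rows.
- The per-sentence mean M is reported with the number of sentences as
  denominator. Published N/M pairs in this literature are mostly
  consistent with a constant corpus-level denominator, but not uniformly
  so; the package states its definition and applies it uniformly.
- Full-lexicon per-sentence count tables are NRC-version-dependent: the
  EmoLex has had several releases and bundled copies differ. Counts
  produced with the built-in 10-word fixture are version-independent;
  reproducing any specific published sentence×emotion table requires the
  matching lexicon release.
- The dyad statistic never pairs an emotion with itself; within-emotion
  repetition affects dyad scores only through the min with the partner
  emotion.
- Spelling: the registry's canonical names are `cynicism` and
  `morbidness`; the historic spellings "cynism" and "morbideness" are
  accepted as aliases.
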
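# Methods

This note documents the models implemented in `notescope`, the choices made
where the procedure admits more than one reasonable reading, and what the
synthetic test bed does and does not establish.

## Text normalisation

All analyses consume one fixed pipeline: lowercase → tokenise on any
non-letter character (Unicode letter classes, so diacritics survive) →
drop stop-words → reduce tokens to a base form. Because the tokeniser
splits at digits and punctuation, no retained token can contain them; a
note whose every token is removed is reported with length 0 and excluded
from per-note scores by callers.

The base-form reducer is a pluggable callable (default: identity). The
emotion analysis is usually described with stemming and the topic analysis
with lemmatisation; we deliberately use a *single* shared normaliser for
both paths so that the lexicon, the polarity dictionary and the
term–document matrix agree on vocabulary. No Polish stemmer is hard-coded —
the package is language-agnostic at its core, and any callable
(e.g. a Morfologik- or spaCy-backed lemmatiser) can be injected.

Stop-words default to the empty set and are supplied as a one-word-per-line
UTF-8 file.

## Affective lexicon and embedding-based extension

The lexicon format follows normed affective word lists (one row per word,
five emotion intensities — happiness, sadness, anger, fear, disgust — on a
1–7 base scale). Values outside [1, 7] are a hard error, not clamped.
Standardisation is per-emotion min–max over the lexicon's observed values;
a constant column maps to zeros with a warning. The *dominant emotion* is
the argmax, with ties broken by the fixed order happiness < sadness <
anger < fear < disgust; the same order breaks all later cosine ties.

Extension of out-of-lexicon corpus words is the three-stage procedure:
center construction, cosine matching, neighbour interpolation. Decisions
taken where the procedure is underdetermined:

* **Weights.** The neighbour weighting is shifted cosine, w′ₖ = (cosₖ+1)/2,
  renormalised to Σwₖ = 1. Shifted cosine is bounded, monotone in
  similarity, and defined even for duplicate vectors (where inverse
  distance would divide by zero); the renormalisation keeps every extended
  intensity a convex combination, hence on the standardised scale.
* **Role of the matched center.** The Stage-II match restricts the
  Stage-III neighbour pool to lexicon words with that dominant emotion —
  otherwise the matching step would have no effect on the output. If the
  pool is empty the extension falls back to all embeddable lexicon words,
  with a warning. The center's own coordinates are never blended into the
  result.
* **Neighbour count.** Default n = 5, configurable. With n at least the
  pool size, the result is the similarity-weighted mean of the whole pool.
* **Emotions without members.** An emotion with no embeddable lexicon word
  is omitted from the center set (no unknown word could draw neighbours
  from it); centers are preferentially built from words that occur in the
  corpus, falling back to the whole lexicon∩embeddings intersection.
* **Unscoreable words.** Corpus words with no embedding are reported and
  skipped; in note profiles they contribute zero intensity but still count
  in the length denominator, because the profile is defined as a sum over
  the note divided by the note's length in words.

Embeddings are an input file (word2vec text format, optional header,
duplicate rows keep the first occurrence with a warning). The package does
not train embeddings; any 100-dimensional (or other) vectors trained on the
notes or pre-trained generically can be supplied.

## Hybrid sentiment

The dictionary score is the normalised count difference over
polarity-bearing tokens. Neutral-labelled words count in the denominator —
a note full of explicitly neutral vocabulary is attenuated toward 0 rather
than being indistinguishable from a note with no polarity information; a
note with *no* polarity-bearing words also scores 0. The score maps to
pseudo-probabilities (neg, neu, pos) = (max(−s,0), 1−|s|, max(s,0)), is
blended convexly with classifier probabilities (default α = 0.5 when a
model is present; α forced to 1 otherwise), and the argmax decides with
ties going to neutral — a deliberately conservative rule for a screening
instrument.

The machine-learned component is a contract (``predict_proba`` over the
three classes, probabilities summing to 1 ± 1e-9). The shipped reference
model is a bag-of-embeddings logistic regression, trainable in seconds on
synthetic data; deep sequence models can be plugged in unchanged.

## Difficulty areas

The term × document matrix uses raw counts by default (TF-IDF optional).
The truncated SVD keeps, by default, the smallest k whose components carry
≥ 90 % of the spectral energy (squared singular values). A fixed minimal
geometry of one axis per area and polarity (k = 6 for three areas) was
evaluated and rejected: it blurs the within-area positive/negative
contrast enough that genuinely balanced (mixed-context) notes acquire
spuriously large relative differences, while the energy rule preserves the
contrast and the classifier's decisions stabilise. k remains a parameter.

Document vectors are V·Σ and fold-in is qᵀ·U, so folding in an existing
document's bag reproduces its document vector exactly at full rank.
Affiliation of a note to an area-context is the cosine between the note's
document vector and the folded dictionary pseudo-document, clamped at 0,
and additionally forced to exactly 0 when the note contains no occurrence
of any word of that dictionary. The overlap gate makes "the topic is not
covered ⇔ both affiliations equal 0" a term-level statement; without it a
latent-space cosine is almost never exactly zero and the not-covered
outcome would be a floating-point accident. Pure-cosine behaviour is
available (``require_term_overlap=False``).

The four-way decision uses the relative difference
(W_N − W_P)/max(W_N, W_P)·100 %: negative if > 20, positive if < −20,
mixed if the absolute value is ≤ 20 (a tie at exactly the threshold is
mixed, reading "greater than 20 %" strictly), not covered iff both
affiliations are 0. The threshold is scale-free: multiplying both
affiliations by any positive constant leaves the label unchanged.

Agreement with expert flags (0 not raised, −1 negative, 1 positive,
2 mixed) partitions note×area pairs into four exhaustive categories:
consistent, mixed-detected-as-single, single-detected-as-mixed, and error
(all remaining mismatches); percentages are per area and sum to 100. The
report also gives the expert's context shares among flagged notes.

## Synthetic test bed

The generator emulates the study conditions with known ground truth:

* **Lexicon** — words assigned evenly to the five emotions; the dominant
  intensity is drawn U[5, 7] and the others U[1, 3] (base scale), giving a
  clear but noisy dominant-emotion signal.
* **Embeddings** — one Gaussian cluster per emotion: centers on scaled
  orthogonal axes at mutual distance ≥ the configured separation
  (default 10), isotropic noise σ (default 1). At a 10:1
  separation-to-noise ratio essentially every word's nearest center is its
  own cluster's.
* **Notes** — token streams planting three independent signals per note:
  sentiment (4 tokens of one polarity class, saturating the dictionary
  path: score ±1 or 0), per-area context (6 dictionary tokens of one
  polarity, a 3+3 split for mixed, none for not-covered), plus 3 emotion
  lexicon tokens and 3 filler tokens. Expert flags replicate the planted
  contexts. Defaults mirror the emulated study: 50 notes, stage groups
  11/32/7, sentiment split 29/10/11. Tokens are letter-only synthetic
  strings — no linguistic realism is attempted.
* **POS corpus** — a separate generator plants a corpus-level morphological
  profile exactly (by default 191 adjectives of which 138 negative and 53
  positive; 270 verbs of which 105 copula split 7 past / 89 present /
  9 future and the rest split 25 past / 140 present; 36 possessive-"my"
  tokens) together with the matching dictionary tagger.

Everything is driven by one integer seed through integer-indexed numpy
generators; fixture files are byte-identical across runs.

**What passing tests show — and don't.** Recovery of planted structure
demonstrates that the formulas are implemented correctly and that the
pipeline is internally coherent under favourable, noise-controlled
conditions. Real elicited notes differ in every hard way: inflected
natural language and imperfect normalisation, polarity and affect words
outside any lexicon, areas expressed without dictionary vocabulary, mixed
signals within one sentence, and expert judgements informed by context the
bag-of-words representation cannot see. Agreement percentages on synthetic
corpora therefore say nothing about clinical accuracy; they validate the
bookkeeping and the geometry, not the instrument.

## Problem sizes and numerics

Default experiment sizes (50–60 notes, lexicons of 100–500 words,
100-dimensional embeddings) match the emulated study's scale and keep the
full test suite under a few seconds. Cosines raise an error on zero
vectors where a decision depends on them (centers, matching) and clamp to
0 where they express affiliation. The extension's equality with a
brute-force oracle is asserted to 1e-12 on small instances; SVD
reconstruction to 1e-8. Per-emotion tie-breaks are everywhere the fixed
emotion order, never dictionary insertion order.

## Known limitations

* The tagging contract ships only a dictionary-lookup tagger; real corpora
  need an external morphological tagger for Polish (or any language).
* LSA is transductive here: context labels are defined for the fitted
  corpus; new notes require refitting (or fold-in, which slightly biases
  affiliations toward the fitted geometry).
* The reported copula tense counts omit a residual "other/untensed"
  bucket; tense subcounts need not sum to the verb totals when the tagger
  leaves tenses unknown.
* The hybrid's α is a free parameter with no data-driven calibration; the
  default dictionary-only pipeline (α = 1) is the reproducible baseline.
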
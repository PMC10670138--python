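# notescope

Automated screening of body-image perception from short free-text patient
notes.

Patients undergoing treatment for head-and-neck and upper-gastrointestinal
cancers frequently experience disturbed body image, but psycho-oncological
assessment capacity is scarce. `notescope` analyses a one-paragraph
first-person note (elicited by a prompt such as *"How do you perceive your
body?"*) along four complementary axes, giving clinicians and researchers a
quantitative, repeatable first-pass screen:

1. **Emotion intensity** — a five-emotion profile (happiness, sadness,
   anger, fear, disgust) scored against a normed affective word list
   extended into word-embedding space;
2. **Sentiment** — a three-class attitude toward the body (negative /
   neutral / positive) from a hybrid of a polarity dictionary and an
   optional machine-learned classifier;
3. **Morphological profile** — adjectives by polarity, verbs by copula vs.
   other and by tense, uses of the possessive "my", characteristic terms;
4. **Difficulty areas** — whether the note raises *body image*, *acceptance
   of the environment* or *self-esteem*, and in which context (negative,
   positive, mixed, not covered), via latent semantic analysis, validated
   against expert flags.

## Method

**Lexicon extension.** An affective lexicon assigns each word intensities
for the five basic emotions on a 1–7 scale. Intensities are min–max
standardised per emotion, *f(x) = (x − min x)/(max x − min x)*. Corpus
words absent from the lexicon are interpolated from word embeddings in
three stages: (I) per emotion, a *center* — the mean vector of lexicon
words present in the corpus with that dominant emotion; (II) the unknown
word is matched to the most cosine-similar center; (III) its intensities
become the similarity-weighted average of its *n* nearest lexicon
neighbours with that dominant emotion,
*intensity = Σₖ sₖ·wₖ*, with weights *wₖ ∝ (cos ₖ+1)/2* normalised to sum
to one. A note's emotion profile is the count-weighted mean intensity of
its tokens divided by the note length.

**Sentiment.** The dictionary score is
*s = (#positive − #negative)/#polarity-bearing* ∈ [−1, 1], mapped to
pseudo-probabilities (neg = max(−s, 0), pos = max(s, 0), neu = 1 − |s|) and
blended with classifier probabilities as *α·dict + (1 − α)·model*; argmax
decides, ties resolve to neutral.

**Difficulty areas.** Notes form a term × document frequency matrix,
reduced by truncated SVD (LSA). Each area's positive and negative expert
dictionary is folded in as a pseudo-document; a note's affiliations W_P and
W_N are clamped cosines to those vectors, and the relative difference
*(W_N − W_P)/max(W_N, W_P)·100 %* yields a four-way context decision at a
20 % threshold (both affiliations zero ⇒ topic not covered).

See `docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

The package ships a seeded generator emulating the study conditions
(50 notes split 11/32/7 over diagnosis/treatment/palliative stage groups,
a planted 29/10/11 negative/positive/neutral sentiment split):

```bash
notescope generate --seed 42 --outdir fx
cat > run.yaml <<EOF
notes: fx/notes.jsonl
lexicon: fx/lexicon.tsv
embeddings: fx/embeddings.vec
polarity: fx/polarity.tsv
areas: fx/areas.json
outdir: out
EOF
notescope run --config run.yaml
cat out/report.md
```

prints

```
# notescope report

Notes analysed: 50

## Sentiment toward the body

negative: 29, neutral: 11, positive: 10

## Mean emotion intensity per stage group

- stage I (n=11): anger=0.311, disgust=0.318, fear=0.311, happiness=0.280, sadness=0.286
- stage II (n=32): anger=0.295, disgust=0.302, fear=0.305, happiness=0.295, sadness=0.306
- stage palliative (n=7): anger=0.262, disgust=0.315, fear=0.313, happiness=0.291, sadness=0.325

## Agreement with expert flags

- body_image: 96% consistent, 0% error, 4% mixed→single, 0% single→mixed
- environment_acceptance: 96% consistent, 0% error, 4% mixed→single, 0% single→mixed
- self_esteem: 98% consistent, 0% error, 2% mixed→single, 0% single→mixed
```

The sentiment block recovers the planted 29/10/11 split exactly (the
dictionary path is decisive on this corpus); the per-stage emotion means
are flat because the generator plants no stage–emotion association; the
agreement block scores the LSA context classifier against the generated
expert flags. `out/report.json` holds the same content machine-readably,
including per-note emotion profiles and per-area affiliations. The same
stages are available individually (`notescope emotions`, `sentiment`,
`pos-profile`, `topics`, `agreement`, `extend-lexicon`) and as a library —
`EmotionIntensityScorer`, `HybridSentimentClassifier`, `LsaContextClassifier`
and `PosProfiler` are scikit-learn-style estimators.

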
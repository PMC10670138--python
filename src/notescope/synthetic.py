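"""Seeded synthetic study generator.

Real elicited patient notes are not distributable, so this module generates
a complete, ground-truthed stand-in for the whole study: an affective
lexicon with the five-emotion layout of normed word lists (dominant-emotion
intensity drawn uniform on [5, 7], the others on [1, 3], base scale 1–7),
cluster-structured word embeddings (one Gaussian cluster per emotion),
positive/negative area dictionaries, a polarity lexicon, and short
token-stream notes with planted sentiment, planted per-area context, and
matching expert flags.  Everything is driven by one integer seed and is
byte-reproducible.

Tokens are synthetic letter-only strings (e.g. ``fearab``,
``bodyimagenegac``) that survive the corpus tokeniser unchanged, not natural
language: correctness of the numerical pipeline does not depend on any
language resource.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .affect import BASE_MAX, BASE_MIN, EMOTIONS, AffectiveEntry, AffectiveLexicon, EmbeddingSpace
from .corpus import RawNote
from .pos import DictionaryTagger
from .sentiment import PolarityLexicon
from .topics import AREAS, AreaDictionaries

CONTEXT_FLAGS = {"negative": -1, "positive": 1, "mixed": 2, "not_covered": 0}


def _alpha(i: int) -> str:
    """Letter-only index suffix (0 → 'aa', 1 → 'ab', …): generated tokens
    must contain no digits or punctuation to survive tokenisation."""
    if i < 0:
        raise ValueError("index must be nonnegative")
    letters = []
    i += 26  # at least two letters
    while i:
        i, r = divmod(i, 26)
        letters.append(chr(ord("a") + r))
    return "".join(reversed(letters))


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic study.

    Defaults mirror the emulated study design: 50 notes split 11 / 32 / 7
    over the diagnosis (I), treatment (II) and palliative stage groups, a
    29 / 10 / 11 negative–positive–neutral sentiment split, 100-dimensional
    embeddings, and emotion clusters separated by 10 with unit noise.
    """

    seed: int = 0
    n_lexicon_words: int = 100
    n_notes: int = 50
    embed_dim: int = 100
    cluster_separation: float = 10.0
    noise_sigma: float = 1.0
    stage_sizes: dict[str, int] = field(
        default_factory=lambda: {"I": 11, "II": 32, "palliative": 7}
    )
    sentiment_counts: dict[str, int] = field(
        default_factory=lambda: {"negative": 29, "positive": 10, "neutral": 11}
    )
    context_probs: dict[str, float] = field(
        default_factory=lambda: {
            "negative": 0.35,
            "positive": 0.25,
            "mixed": 0.2,
            "not_covered": 0.2,
        }
    )
    min_area_tokens: int = 6
    n_area_words: int = 12  # per area and polarity
    n_polarity_words: int = 20  # per polarity class
    n_filler_words: int = 30
    n_emotion_tokens: int = 3  # lexicon tokens sampled into each note
    n_sentiment_tokens: int = 4  # polarity tokens planted per note
    n_filler_tokens: int = 3
    planted_sentiment: list[str] | None = None  # explicit per-note labels
    planted_context: dict[str, dict[str, str]] | None = None  # note→area→label

    def __post_init__(self) -> None:
        if self.cluster_separation <= 0:
            raise ValueError("cluster_separation must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be nonnegative")
        if sum(self.stage_sizes.values()) != self.n_notes:
            raise ValueError("stage sizes must sum to n_notes")


def generate_affective_lexicon(config: GeneratorConfig) -> AffectiveLexicon:
    """Base-scale lexicon: words cycle through the five emotions; the
    dominant intensity is U[5, 7], the others U[1, 3]."""
    if config.n_lexicon_words < len(EMOTIONS):
        raise ValueError("need at least one lexicon word per emotion")
    rng = np.random.default_rng(config.seed)
    entries: dict[str, AffectiveEntry] = {}
    for i in range(config.n_lexicon_words):
        emotion_idx = i % len(EMOTIONS)
        word = f"{EMOTIONS[emotion_idx]}{_alpha(i // len(EMOTIONS))}"
        intensities = rng.uniform(1.0, 3.0, size=len(EMOTIONS))
        intensities[emotion_idx] = rng.uniform(5.0, 7.0)
        assert np.all((intensities >= BASE_MIN) & (intensities <= BASE_MAX))
        entries[word] = AffectiveEntry(word, intensities)
    return AffectiveLexicon(entries=entries, scale="base")


def _cluster_centers(config: GeneratorConfig) -> np.ndarray:
    # scaled orthonormal axes: mutual distance = separation * sqrt(2) >= separation
    centers = np.zeros((len(EMOTIONS), config.embed_dim))
    for i in range(len(EMOTIONS)):
        centers[i, i] = config.cluster_separation
    return centers


def generate_embeddings(
    lexicon: AffectiveLexicon,
    config: GeneratorConfig,
    extra_word_emotions: Mapping[str, str] | None = None,
) -> EmbeddingSpace:
    """One Gaussian cluster per emotion; a word's vector is its dominant
    emotion's center plus isotropic noise.  ``extra_word_emotions`` assigns
    clusters to non-lexicon words (corpus words to be interpolated)."""
    if config.embed_dim < len(EMOTIONS):
        raise ValueError("embed_dim must be at least the number of emotions")
    rng = np.random.default_rng(config.seed + 1)
    centers = _cluster_centers(config)
    emotion_of: dict[str, str] = {
        word: entry.dominant_emotion for word, entry in lexicon.entries.items()
    }
    if extra_word_emotions:
        emotion_of.update(extra_word_emotions)
    vectors = {}
    for word in sorted(emotion_of):
        center = centers[EMOTIONS.index(emotion_of[word])]
        vectors[word] = center + rng.normal(
            0.0, config.noise_sigma, size=config.embed_dim
        )
    return EmbeddingSpace(dimension=config.embed_dim, vectors=vectors)


def generate_area_dictionaries(config: GeneratorConfig) -> dict[str, AreaDictionaries]:
    """Disjoint synthetic vocabularies per area and polarity."""
    return {
        area: AreaDictionaries(
            area=area,
            positive_words=[
                f"{area.replace('_', '')}pos{_alpha(i)}"
                for i in range(config.n_area_words)
            ],
            negative_words=[
                f"{area.replace('_', '')}neg{_alpha(i)}"
                for i in range(config.n_area_words)
            ],
        )
        for area in AREAS
    }


def generate_polarity_lexicon(config: GeneratorConfig) -> PolarityLexicon:
    """Synthetic polarity lexicon, disjoint from the area dictionaries so
    that planted sentiment and planted area context stay independent."""
    entries: dict[str, str] = {}
    for polarity in ("positive", "negative", "neutral"):
        for i in range(config.n_polarity_words):
            entries[f"pol{polarity}{_alpha(i)}"] = polarity
    return PolarityLexicon(entries)


def _planted_sentiments(config: GeneratorConfig, rng: np.random.Generator) -> list[str]:
    if config.planted_sentiment is not None:
        if len(config.planted_sentiment) != config.n_notes:
            raise ValueError("planted_sentiment must have one label per note")
        return list(config.planted_sentiment)
    labels = []
    for label, count in sorted(config.sentiment_counts.items()):
        labels.extend([label] * count)
    if len(labels) != config.n_notes:
        raise ValueError("sentiment counts must sum to n_notes")
    return [labels[i] for i in rng.permutation(len(labels))]


def _planted_contexts(
    config: GeneratorConfig, note_ids: Sequence[str], rng: np.random.Generator
) -> dict[str, dict[str, str]]:
    if config.planted_context is not None:
        return {n: dict(config.planted_context[n]) for n in note_ids}
    labels = sorted(config.context_probs)
    probs = np.array([config.context_probs[l] for l in labels])
    probs = probs / probs.sum()
    return {
        note_id: {
            area: labels[rng.choice(len(labels), p=probs)] for area in AREAS
        }
        for note_id in note_ids
    }


def _sample(words: Sequence[str], k: int, rng: np.random.Generator) -> list[str]:
    return [words[i] for i in rng.integers(0, len(words), size=k)]


def generate_notes(
    config: GeneratorConfig,
    area_dicts: Mapping[str, AreaDictionaries],
    polarity_lexicon: PolarityLexicon,
    lexicon: AffectiveLexicon,
) -> tuple[list[RawNote], dict]:
    """Notes with planted sentiment and per-area context, plus the ground
    truth (also emitted as each note's expert flags).

    Sentiment planting saturates the dictionary path: a negative note
    carries only negative polarity tokens (score −1), a positive note only
    positive ones (+1), a neutral note only neutral-labelled ones (0).
    Context planting places ``min_area_tokens`` dictionary tokens of one
    polarity (single context), an even split (mixed), or none (not covered).
    """
    for area, dicts in area_dicts.items():
        if not dicts.positive_words or not dicts.negative_words:
            raise ValueError(f"area {area!r}: empty dictionary")
    rng = np.random.default_rng(config.seed + 2)
    note_ids = [f"note{i:03d}" for i in range(config.n_notes)]
    sentiments = _planted_sentiments(config, rng)
    contexts = _planted_contexts(config, note_ids, rng)

    area_vocab = {
        w for d in area_dicts.values() for w in d.positive_words + d.negative_words
    }
    pol_words = {
        polarity: sorted(
            w for w, p in polarity_lexicon.entries.items()
            if p == polarity and w not in area_vocab
        )
        for polarity in ("positive", "negative", "neutral")
    }
    lex_words = sorted(lexicon.entries)
    filler = [f"filler{_alpha(i)}" for i in range(config.n_filler_words)]

    stages = []
    for stage, count in sorted(config.stage_sizes.items()):
        stages.extend([stage] * count)
    stages = [stages[i] for i in rng.permutation(len(stages))]

    notes: list[RawNote] = []
    for note_id, sentiment, stage in zip(note_ids, sentiments, stages):
        tokens: list[str] = []
        tokens += _sample(pol_words[sentiment], config.n_sentiment_tokens, rng)
        for area in AREAS:
            label = contexts[note_id][area]
            dicts = area_dicts[area]
            if label == "negative":
                tokens += _sample(dicts.negative_words, config.min_area_tokens, rng)
            elif label == "positive":
                tokens += _sample(dicts.positive_words, config.min_area_tokens, rng)
            elif label == "mixed":
                half = max(1, config.min_area_tokens // 2)
                tokens += _sample(dicts.negative_words, half, rng)
                tokens += _sample(dicts.positive_words, half, rng)
            elif label != "not_covered":
                raise ValueError(f"unknown planted context {label!r}")
        tokens += _sample(lex_words, config.n_emotion_tokens, rng)
        tokens += _sample(filler, config.n_filler_tokens, rng)
        tokens = [tokens[i] for i in rng.permutation(len(tokens))]
        flags = {area: CONTEXT_FLAGS[contexts[note_id][area]] for area in AREAS}
        notes.append(
            RawNote(id=note_id, text=" ".join(tokens), stage=stage, expert_flags=flags)
        )

    truth = {
        "sentiment": dict(zip(note_ids, sentiments)),
        "context": contexts,
        "stage": dict(zip(note_ids, stages)),
    }
    return notes, truth


#: Morphological counts planted by default into the synthetic POS corpus.
#: The copula and non-copula tense splits are internally consistent
#: (105 = 7+89+9 and 165 = 25+140).
DEFAULT_POS_COUNTS = {
    "adj_negative": 138,
    "adj_positive": 53,
    "verb_tobe_past": 7,
    "verb_tobe_present": 89,
    "verb_tobe_future": 9,
    "verb_other_past": 25,
    "verb_other_present": 140,
    "my_count": 36,
}


def generate_pos_corpus(
    counts: Mapping[str, int] | None = None,
    n_notes: int = 50,
    seed: int = 0,
) -> tuple[list[RawNote], DictionaryTagger, PolarityLexicon]:
    """Notes whose corpus-level morphological profile equals ``counts``
    exactly, together with the matching dictionary tagger and adjective
    polarity lexicon."""
    counts = dict(DEFAULT_POS_COUNTS if counts is None else counts)
    rng = np.random.default_rng(seed)
    stream: list[str] = []
    stream += ["adjneg"] * counts.get("adj_negative", 0)
    stream += ["adjpos"] * counts.get("adj_positive", 0)
    stream += ["tobepast"] * counts.get("verb_tobe_past", 0)
    stream += ["tobepres"] * counts.get("verb_tobe_present", 0)
    stream += ["tobefut"] * counts.get("verb_tobe_future", 0)
    stream += ["verbpast"] * counts.get("verb_other_past", 0)
    stream += ["verbpres"] * counts.get("verb_other_present", 0)
    stream += ["moje"] * counts.get("my_count", 0)
    stream += ["fillertok"] * n_notes  # at least one plain token per note
    stream = [stream[i] for i in rng.permutation(len(stream))]

    notes = []
    for i in range(n_notes):
        chunk = stream[i::n_notes]
        notes.append(RawNote(id=f"pos{i:03d}", text=" ".join(chunk)))

    tagger = DictionaryTagger(
        {
            "adjneg": ("adjective", "adjneg", None),
            "adjpos": ("adjective", "adjpos", None),
            "tobepast": ("verb", "być", "past"),
            "tobepres": ("verb", "być", "present"),
            "tobefut": ("verb", "być", "future"),
            "verbpast": ("verb", "robić", "past"),
            "verbpres": ("verb", "robić", "present"),
            "fillertok": ("other", "fillertok", None),
        }
    )
    polarity = PolarityLexicon({"adjneg": "negative", "adjpos": "positive"})
    return notes, tagger, polarity


class SyntheticStudy:
    """Bundle of all synthetic inputs for one seeded study.

    Attributes are built lazily-once at construction: ``lexicon`` (base
    scale), ``embeddings`` (covering the lexicon and every note token, so
    the extension stage has vectors for all corpus words), ``area_dicts``,
    ``polarity``, ``notes`` and ``truth``.
    """

    def __init__(self, config: GeneratorConfig | None = None):
        self.config = config or GeneratorConfig()
        self.lexicon = generate_affective_lexicon(self.config)
        self.area_dicts = generate_area_dictionaries(self.config)
        self.polarity = generate_polarity_lexicon(self.config)
        self.notes, self.truth = generate_notes(
            self.config, self.area_dicts, self.polarity, self.lexicon
        )
        extra = {}
        all_tokens = sorted({t for n in self.notes for t in n.text.split()})
        for i, token in enumerate(all_tokens):
            if token not in self.lexicon.entries:
                extra[token] = EMOTIONS[i % len(EMOTIONS)]
        self.embeddings = generate_embeddings(self.lexicon, self.config, extra)

    def write_fixtures(self, outdir: str | Path) -> dict[str, Path]:
        """Write notes.jsonl, lexicon.tsv, embeddings.vec, polarity.tsv,
        areas.json, flags.csv and truth.json; returns the path map."""
        from .affect import write_affective_lexicon, write_embeddings

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {name: outdir / name for name in (
            "notes.jsonl", "lexicon.tsv", "embeddings.vec", "polarity.tsv",
            "areas.json", "flags.csv", "truth.json",
        )}
        with open(paths["notes.jsonl"], "w", encoding="utf-8") as handle:
            for note in self.notes:
                handle.write(json.dumps({
                    "id": note.id,
                    "text": note.text,
                    "stage": note.stage,
                    "flags": note.expert_flags,
                }, sort_keys=True) + "\n")
        write_affective_lexicon(self.lexicon, paths["lexicon.tsv"])
        write_embeddings(self.embeddings, paths["embeddings.vec"])
        with open(paths["polarity.tsv"], "w", encoding="utf-8") as handle:
            for word in sorted(self.polarity.entries):
                handle.write(f"{word}\t{self.polarity.entries[word]}\n")
        with open(paths["areas.json"], "w", encoding="utf-8") as handle:
            json.dump(
                {
                    area: {
                        "positive": d.positive_words,
                        "negative": d.negative_words,
                    }
                    for area, d in self.area_dicts.items()
                },
                handle, indent=2, sort_keys=True,
            )
        with open(paths["flags.csv"], "w", encoding="utf-8") as handle:
            handle.write("note_id,area,flag\n")
            for note in self.notes:
                for area in sorted(note.expert_flags):
                    handle.write(f"{note.id},{area},{note.expert_flags[area]}\n")
        with open(paths["truth.json"], "w", encoding="utf-8") as handle:
            json.dump(self.truth, handle, indent=2, sort_keys=True)
        return paths
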
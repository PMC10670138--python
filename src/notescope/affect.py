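"""Affective-lexicon standardisation, embedding-based extension, and
per-note emotion profiles.

The lexicon assigns each word an intensity for the five basic emotions —
happiness, sadness, anger, fear, disgust — on a 1–7 base scale (the layout of
normed affective word lists such as the Nencki Affective Word List).  Base
intensities are min–max standardised per emotion,

    f(x) = (x - min x) / (max x - min x),

so every emotion column spans [0, 1] over the lexicon.  Corpus words missing
from the lexicon ("indefinite" words) are then interpolated from their
position in a word-embedding space in three stages:

I.   per emotion, a *center*: the mean vector of lexicon words occurring in
     the corpus whose dominant emotion is that emotion;
II.  the indefinite word is matched to the center with the highest cosine
     similarity;
III. its intensities become a similarity-weighted average over its n nearest
     lexicon neighbours with that dominant emotion,

         intensity_e = sum_k s_k * w_k,

     where s_k is neighbour k's intensity for emotion e and the weights
     w_k ∝ (cos_k + 1)/2 are normalised to sum to one, keeping the result a
     convex combination on the standardised scale.

A note's emotion profile is the count-weighted mean intensity of its tokens,
divided by the note length; tokens absent from even the extended lexicon
contribute zero but still count toward the length.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .corpus import ProcessedNote, build_vocabulary

#: Fixed emotion order; also the tie-break order for dominant emotions.
EMOTIONS = ("happiness", "sadness", "anger", "fear", "disgust")

BASE_MIN, BASE_MAX = 1.0, 7.0


@dataclass(frozen=True)
class AffectiveEntry:
    """One lexicon word with its five-emotion intensity vector."""

    word: str
    intensities: np.ndarray  # shape (5,), ordered as EMOTIONS
    origin: str = "original"  # or "extended"

    @property
    def dominant_emotion(self) -> str:
        # np.argmax returns the first maximum, matching the fixed tie order
        return EMOTIONS[int(np.argmax(self.intensities))]


@dataclass
class AffectiveLexicon:
    """Word → :class:`AffectiveEntry` map on one scale (``base`` 1–7 or
    ``standardized`` [0, 1])."""

    entries: dict[str, AffectiveEntry]
    scale: str = "base"
    # per-emotion (min, max) observed at standardisation time
    minmax: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __contains__(self, word: str) -> bool:
        return word in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def intensity(self, word: str, emotion: str) -> float:
        return float(self.entries[word].intensities[EMOTIONS.index(emotion)])

    def to_frame(self) -> pd.DataFrame:
        data = {
            word: list(entry.intensities) + [entry.origin]
            for word, entry in self.entries.items()
        }
        frame = pd.DataFrame.from_dict(
            data, orient="index", columns=list(EMOTIONS) + ["origin"]
        )
        frame.index.name = "word"
        return frame


@dataclass
class EmbeddingSpace:
    """Vocabulary → fixed-dimension real vectors."""

    dimension: int
    vectors: dict[str, np.ndarray]

    def __contains__(self, word: str) -> bool:
        return word in self.vectors

    def __getitem__(self, word: str) -> np.ndarray:
        return self.vectors[word]


@dataclass
class EmotionCenter:
    """Centroid of same-dominant-emotion words in embedding space."""

    emotion: str
    centroid: np.ndarray
    member_words: list[str]


@dataclass
class EmotionProfile:
    """Per-note mean emotion intensity (standardised scale)."""

    note_id: str
    intensity: dict[str, float]

    def as_array(self) -> np.ndarray:
        return np.array([self.intensity[e] for e in EMOTIONS])


def read_affective_lexicon(path: str | Path, scale: str = "auto") -> AffectiveLexicon:
    """Read a lexicon from TSV with header
    ``word happiness sadness anger fear disgust`` (+ optional ``origin``).

    ``scale="auto"`` treats a file whose values all lie in [0, 1] (e.g. a
    written-back extended lexicon) as standardized, anything else as base
    scale; base-scale values must lie in [1, 7].
    """
    frame = pd.read_csv(path, sep="\t")
    missing = [c for c in ("word",) + EMOTIONS if c not in frame.columns]
    if missing:
        raise ValueError(f"lexicon file missing columns: {missing}")
    if frame["word"].duplicated().any():
        dupes = frame.loc[frame["word"].duplicated(), "word"].tolist()
        raise ValueError(f"duplicate lexicon words: {dupes}")
    values = frame[list(EMOTIONS)].to_numpy(dtype=float)
    if scale == "auto":
        scale = "standardized" if np.all((values >= 0.0) & (values <= 1.0)) else "base"
    if scale == "base" and (np.any(values < BASE_MIN) or np.any(values > BASE_MAX)):
        raise ValueError(
            f"base-scale intensities must lie in [{BASE_MIN}, {BASE_MAX}]"
        )
    if scale == "standardized" and (np.any(values < 0.0) or np.any(values > 1.0)):
        raise ValueError("standardized intensities must lie in [0, 1]")
    origins = (
        frame["origin"].astype(str).tolist()
        if "origin" in frame.columns
        else ["original"] * len(frame)
    )
    entries = {
        str(row.word): AffectiveEntry(str(row.word), values[i].copy(), origins[i])
        for i, row in enumerate(frame.itertuples(index=False))
    }
    return AffectiveLexicon(entries=entries, scale=scale)


def write_affective_lexicon(lexicon: AffectiveLexicon, path: str | Path) -> None:
    """Write back in the input TSV dialect plus an ``origin`` column."""
    lexicon.to_frame().to_csv(path, sep="\t")


def standardize_weights(lexicon: AffectiveLexicon) -> AffectiveLexicon:
    """Min–max standardise each emotion column over the lexicon's observed
    values; a constant column maps to all zeros with a warning."""
    if lexicon.scale != "base":
        raise ValueError("lexicon is already standardized")
    words = list(lexicon.entries)
    matrix = np.array([lexicon.entries[w].intensities for w in words], float)
    minmax: dict[str, tuple[float, float]] = {}
    out = np.zeros_like(matrix)
    for j, emotion in enumerate(EMOTIONS):
        lo, hi = matrix[:, j].min(), matrix[:, j].max()
        minmax[emotion] = (float(lo), float(hi))
        if hi > lo:
            out[:, j] = (matrix[:, j] - lo) / (hi - lo)
        else:
            warnings.warn(
                f"emotion {emotion!r} has a constant column; standardised to 0"
            )
    entries = {
        w: AffectiveEntry(w, out[i].copy(), lexicon.entries[w].origin)
        for i, w in enumerate(words)
    }
    return AffectiveLexicon(entries=entries, scale="standardized", minmax=minmax)


def read_embeddings(path: str | Path) -> EmbeddingSpace:
    """Read word2vec text format; an initial ``count dim`` header line is
    tolerated.  Duplicate words keep the first occurrence with a warning."""
    vectors: dict[str, np.ndarray] = {}
    dimension: int | None = None
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, 1):
            parts = line.rstrip("\n").split()
            if not parts:
                continue
            if lineno == 1 and len(parts) == 2:
                try:
                    int(parts[0]), int(parts[1])
                    continue  # header line
                except ValueError:
                    pass
            word, values = parts[0], parts[1:]
            if dimension is None:
                dimension = len(values)
                if dimension == 0:
                    raise ValueError(f"line {lineno}: no vector components")
            elif len(values) != dimension:
                raise ValueError(
                    f"line {lineno}: expected {dimension} components, "
                    f"got {len(values)}"
                )
            if word in vectors:
                warnings.warn(f"duplicate embedding for {word!r}; keeping first")
                continue
            vectors[word] = np.asarray(values, dtype=float)
    if not vectors:
        raise ValueError(f"no embeddings found in {path}")
    return EmbeddingSpace(dimension=dimension, vectors=vectors)


def write_embeddings(space: EmbeddingSpace, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        handle.write(f"{len(space.vectors)} {space.dimension}\n")
        for word, vec in space.vectors.items():
            handle.write(word + " " + " ".join(repr(float(v)) for v in vec) + "\n")


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(np.dot(u, v) / (nu * nv))


def compute_emotion_centers(
    lexicon: AffectiveLexicon,
    space: EmbeddingSpace,
    note_vocab: Iterable[str],
) -> dict[str, EmotionCenter]:
    """Stage I: per emotion, the mean vector of lexicon∩embeddings∩corpus
    words with that dominant emotion.

    An emotion with no member in the triple intersection falls back to the
    lexicon∩embeddings intersection with a warning; an emotion with no
    embeddable lexicon member at all is omitted from the result (no
    indefinite word could draw neighbours from it anyway).  A zero centroid,
    or no center at all, is an error.
    """
    if lexicon.scale != "standardized":
        raise ValueError("centers require a standardized lexicon")
    vocab = set(note_vocab)
    centers: dict[str, EmotionCenter] = {}
    for emotion in EMOTIONS:
        members = [
            w
            for w, entry in lexicon.entries.items()
            if entry.dominant_emotion == emotion and w in space and w in vocab
        ]
        if not members:
            members = [
                w
                for w, entry in lexicon.entries.items()
                if entry.dominant_emotion == emotion and w in space
            ]
            if members:
                warnings.warn(
                    f"emotion {emotion!r}: no member word occurs in the corpus; "
                    "falling back to the full lexicon∩embeddings intersection"
                )
        if not members:
            warnings.warn(f"emotion {emotion!r} has no embeddable member word")
            continue
        centroid = np.mean([space[w] for w in members], axis=0)
        if np.linalg.norm(centroid) == 0.0:
            raise ValueError(f"emotion {emotion!r}: zero centroid, cosine undefined")
        centers[emotion] = EmotionCenter(emotion, centroid, sorted(members))
    if not centers:
        raise ValueError("no emotion has an embeddable lexicon member")
    return centers


def match_word_to_center(
    word: str, space: EmbeddingSpace, centers: Mapping[str, EmotionCenter]
) -> str:
    """Stage II: the emotion whose center is most cosine-similar to the word
    (ties broken by the fixed emotion order)."""
    if word not in space:
        raise KeyError(f"word {word!r} has no embedding")
    vec = space[word]
    best_emotion, best_sim = None, -np.inf
    for emotion in EMOTIONS:  # fixed order makes the argmax tie-break stable
        if emotion not in centers:
            continue
        sim = cosine_similarity(vec, centers[emotion].centroid)
        if sim > best_sim:
            best_emotion, best_sim = emotion, sim
    if best_emotion is None:
        raise ValueError("no emotion centers available")
    return best_emotion


@dataclass
class NeighborSet:
    """The neighbours backing one extended entry (diagnostic record)."""

    query_word: str
    matched_emotion: str
    neighbors: list[tuple[str, float, np.ndarray, float]]  # word, cos, s_k, w_k


def _nearest_neighbors(
    word: str,
    lexicon: AffectiveLexicon,
    space: EmbeddingSpace,
    emotion: str,
    n: int,
) -> NeighborSet:
    pool = [
        w
        for w, entry in lexicon.entries.items()
        if entry.dominant_emotion == emotion and w in space
    ]
    if not pool:
        warnings.warn(
            f"no lexicon word with dominant emotion {emotion!r} is embeddable; "
            "falling back to the whole lexicon∩embeddings pool"
        )
        pool = [w for w in lexicon.entries if w in space]
    if not pool:
        raise ValueError("no embeddable lexicon word available as a neighbour")
    vec = space[word]
    sims = [(w, cosine_similarity(vec, space[w])) for w in sorted(pool)]
    sims.sort(key=lambda pair: (-pair[1], pair[0]))
    chosen = sims[: max(1, n)]
    raw = np.array([(sim + 1.0) / 2.0 for _, sim in chosen])
    if raw.sum() == 0.0:  # every neighbour exactly antipodal; weight uniformly
        raw = np.ones_like(raw)
    weights = raw / raw.sum()
    neighbors = [
        (w, sim, lexicon.entries[w].intensities, float(weight))
        for (w, sim), weight in zip(chosen, weights)
    ]
    return NeighborSet(word, emotion, neighbors)


def extend_word(
    word: str,
    lexicon: AffectiveLexicon,
    space: EmbeddingSpace,
    centers: Mapping[str, EmotionCenter],
    n: int = 5,
) -> AffectiveEntry:
    """Stage III: interpolate an indefinite word's intensities from its n
    most-similar lexicon neighbours with the Stage-II matched emotion.

    A word already in the lexicon is returned unchanged; a word without an
    embedding raises ``KeyError`` (callers skip it).
    """
    if word in lexicon.entries:
        return lexicon.entries[word]
    if word not in space:
        raise KeyError(f"word {word!r} has no embedding")
    emotion = match_word_to_center(word, space, centers)
    nbrs = _nearest_neighbors(word, lexicon, space, emotion, n)
    intensities = np.zeros(len(EMOTIONS))
    for _, _, s_k, w_k in nbrs.neighbors:
        intensities += s_k * w_k
    return AffectiveEntry(word, intensities, origin="extended")


def extend_lexicon(
    vocab: Iterable[str],
    lexicon: AffectiveLexicon,
    space: EmbeddingSpace,
    n: int = 5,
    centers: Mapping[str, EmotionCenter] | None = None,
) -> tuple[AffectiveLexicon, list[str]]:
    """Extend the lexicon to every embeddable vocabulary word; returns the
    extended lexicon and the list of skipped (unembeddable) words."""
    if lexicon.scale != "standardized":
        raise ValueError("extension requires a standardized lexicon")
    vocab = sorted(set(vocab))
    if centers is None:
        centers = compute_emotion_centers(lexicon, space, vocab)
    entries = dict(lexicon.entries)
    skipped: list[str] = []
    for word in vocab:
        if word in entries:
            continue
        if word not in space:
            skipped.append(word)
            continue
        entries[word] = extend_word(word, lexicon, space, centers, n)
    return (
        AffectiveLexicon(entries=entries, scale="standardized", minmax=dict(lexicon.minmax)),
        skipped,
    )


def note_emotion_profile(
    note: ProcessedNote, lexicon: AffectiveLexicon
) -> EmotionProfile:
    """Count-weighted mean intensity per emotion, divided by note length.

    Stems absent from the (extended) lexicon contribute zero intensity but
    still count in the denominator.
    """
    if note.length_N == 0:
        raise ValueError(f"empty note {note.id!r}: emotion profile undefined")
    if lexicon.scale != "standardized":
        raise ValueError("profiles require a standardized lexicon")
    total = np.zeros(len(EMOTIONS))
    for stem, count in note.counts.items():
        entry = lexicon.entries.get(stem)
        if entry is not None:
            total += count * entry.intensities
    total /= note.length_N
    return EmotionProfile(note.id, dict(zip(EMOTIONS, total)))


def group_emotion_profile(
    profiles: Sequence[EmotionProfile], grouping: Mapping[str, str]
) -> pd.DataFrame:
    """Arithmetic-mean profile per stage group, with group sizes.

    ``grouping`` maps note id → stage label; empty groups are omitted.
    """
    rows = []
    for profile in profiles:
        if profile.note_id not in grouping:
            raise KeyError(f"no stage for note {profile.note_id!r}")
        rows.append(
            {"stage": grouping[profile.note_id], **profile.intensity}
        )
    frame = pd.DataFrame(rows)
    grouped = frame.groupby("stage", sort=True)[list(EMOTIONS)].mean()
    grouped["n"] = frame.groupby("stage", sort=True).size()
    return grouped


class EmotionIntensityScorer(TransformerMixin, BaseEstimator):
    """Transform processed notes into five-emotion intensity profiles.

    ``fit`` standardises the affective lexicon (if given on the base scale),
    computes the emotion centers against the fitted corpus vocabulary, and
    extends the lexicon to every embeddable corpus word; ``transform`` scores
    notes against the extended lexicon.

    Parameters
    ----------
    lexicon : AffectiveLexicon
        Base- or standardised-scale affective lexicon.
    embeddings : EmbeddingSpace
        Word vectors covering (part of) the corpus vocabulary.
    n_neighbors : int, default 5
        Neighbour count for intensity interpolation.

    Attributes
    ----------
    lexicon_ : AffectiveLexicon
        The standardised, corpus-extended lexicon.
    centers_ : dict of emotion → EmotionCenter
    skipped_words_ : list of corpus words with no embedding (left unscored).
    """

    def __init__(
        self,
        lexicon: AffectiveLexicon,
        embeddings: EmbeddingSpace,
        n_neighbors: int = 5,
    ):
        self.lexicon = lexicon
        self.embeddings = embeddings
        self.n_neighbors = n_neighbors

    def fit(self, X: Sequence[ProcessedNote], y=None):
        if self.n_neighbors < 1:
            raise ValueError("n_neighbors must be >= 1")
        lexicon = self.lexicon
        if lexicon.scale == "base":
            lexicon = standardize_weights(lexicon)
        vocab = build_vocabulary(X)
        self.centers_ = compute_emotion_centers(lexicon, self.embeddings, vocab)
        self.lexicon_, self.skipped_words_ = extend_lexicon(
            vocab, lexicon, self.embeddings, self.n_neighbors, self.centers_
        )
        return self

    def transform(self, X: Sequence[ProcessedNote]) -> np.ndarray:
        check_is_fitted(self, "lexicon_")
        return np.array(
            [note_emotion_profile(note, self.lexicon_).as_array() for note in X]
        )

    def profile_frame(self, X: Sequence[ProcessedNote]) -> pd.DataFrame:
        """Per-note profiles as a DataFrame indexed by note id."""
        values = self.transform(X)
        return pd.DataFrame(
            values, index=[note.id for note in X], columns=list(EMOTIONS)
        )

    def get_feature_names_out(self, input_features=None):
        return np.asarray(EMOTIONS, dtype=object)
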
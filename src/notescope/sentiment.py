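"""Hybrid three-class sentiment of a note's attitude toward the body.

Two signals are blended: a polarity dictionary (word → positive / negative /
neutral, in the style of the ~8000-term Wilson–Wiebe–Hoffman subjectivity
lexicon) and an optional machine-learned classifier supplied through a
predict-probabilities contract.  The dictionary score

    s = (count(positive) - count(negative)) / count(polarity-bearing)

lies in [-1, 1] (0 when no token carries polarity) and is mapped to
pseudo-probabilities (negative=max(-s,0), positive=max(s,0), neutral=1-|s|);
the final class probabilities are alpha·dictionary + (1-alpha)·model, with
argmax decision and ties resolved to neutral.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.utils.validation import check_is_fitted

from .corpus import Normalizer, ProcessedNote, identity_normalizer

#: Fixed class order used for every probability vector in this module.
SENTIMENT_CLASSES = ("negative", "neutral", "positive")

POLARITIES = ("positive", "negative", "neutral")


@dataclass
class PolarityLexicon:
    """Word → polarity map, stored in normalised (lowercase/stemmed) form."""

    entries: dict[str, str]

    def __contains__(self, word: str) -> bool:
        return word in self.entries

    def polarity(self, word: str) -> str | None:
        return self.entries.get(word)


def read_polarity_lexicon(
    path: str | Path, normalizer: Normalizer | None = None
) -> PolarityLexicon:
    """Read TSV ``word<TAB>polarity``; duplicate consistent rows are merged,
    conflicting duplicates and unknown polarity labels are errors."""
    normalizer = normalizer or identity_normalizer
    entries: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text("utf-8").splitlines(), 1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"line {lineno}: expected 'word<TAB>polarity'")
        word, polarity = normalizer(parts[0].strip().lower()), parts[1].strip()
        if polarity not in POLARITIES:
            raise ValueError(f"line {lineno}: unknown polarity {polarity!r}")
        if word in entries and entries[word] != polarity:
            raise ValueError(f"word {word!r} has conflicting polarities")
        entries[word] = polarity
    return PolarityLexicon(entries)


def dictionary_polarity_score(note: ProcessedNote, lexicon: PolarityLexicon) -> float:
    """Normalised count difference in [-1, 1]; 0 without polarity-bearing
    words.  Neutral-labelled words count in the denominator and attenuate the
    score toward 0."""
    pos = neg = bearing = 0
    for stem, count in note.counts.items():
        polarity = lexicon.polarity(stem)
        if polarity is None:
            continue
        bearing += count
        if polarity == "positive":
            pos += count
        elif polarity == "negative":
            neg += count
    if bearing == 0:
        return 0.0
    return (pos - neg) / bearing


def dict_score_to_probs(score: float) -> np.ndarray:
    """Map a dictionary score to (negative, neutral, positive) probabilities."""
    if not -1.0 <= score <= 1.0:
        raise ValueError("dictionary score must lie in [-1, 1]")
    return np.array([max(-score, 0.0), 1.0 - abs(score), max(score, 0.0)])


def validate_probabilities(probs: Sequence[float]) -> np.ndarray:
    """Enforce the classifier contract: three nonnegative values, sum 1±1e-9."""
    probs = np.asarray(probs, dtype=float)
    if probs.shape != (3,):
        raise ValueError("expected probabilities over the 3 sentiment classes")
    if np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError(f"invalid probability vector {probs!r}")
    return probs


def classifier_probabilities(
    note: ProcessedNote, model
) -> np.ndarray | None:
    """Query a pluggable model for (negative, neutral, positive) probabilities;
    ``None`` signals that the model is unavailable and the hybrid should fall
    back to the dictionary path."""
    if model is None:
        return None
    probs = model.predict_proba([note])
    return validate_probabilities(np.asarray(probs).reshape(-1))


def _argmax_label(probs: np.ndarray) -> str:
    top = probs.max()
    winners = [c for c, p in zip(SENTIMENT_CLASSES, probs) if p == top]
    return winners[0] if len(winners) == 1 else "neutral"


def hybrid_label(
    dict_score: float,
    ml_probs: Sequence[float] | None = None,
    alpha: float = 0.5,
) -> str:
    """Blend dictionary pseudo-probabilities with model probabilities and
    return the argmax class (ties → neutral).  Without model probabilities the
    mixing weight is forced to 1 (pure dictionary path)."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    dict_probs = dict_score_to_probs(dict_score)
    if ml_probs is None:
        blended = dict_probs
    else:
        blended = alpha * dict_probs + (1.0 - alpha) * validate_probabilities(ml_probs)
    return _argmax_label(blended)


@dataclass
class SentimentResult:
    note_id: str
    dict_score: float
    ml_probs: np.ndarray | None
    hybrid_label: str
    alpha: float


def sentiment_summary(results: Sequence[SentimentResult | str]) -> dict[str, int]:
    """Label counts over a result collection (accepts results or bare labels)."""
    counts = Counter(
        r if isinstance(r, str) else r.hybrid_label for r in results
    )
    return {label: counts.get(label, 0) for label in SENTIMENT_CLASSES}


class UniformSentimentModel:
    """Untrained stub honouring the classifier contract: uniform probabilities."""

    def predict_proba(self, notes):
        return np.full((len(list(notes)), 3), 1.0 / 3.0)


class BagOfEmbeddingsClassifier(ClassifierMixin, BaseEstimator):
    """Reference machine-learned sentiment model: logistic regression over
    the mean embedding vector of a note's tokens.

    Stands behind the pluggable classifier contract; any estimator exposing
    ``predict_proba`` over processed notes can replace it.

    Parameters
    ----------
    embeddings : EmbeddingSpace
        Token vectors; tokens without a vector are ignored, an all-unknown
        note maps to the zero vector.
    C : float, default 1.0
        Inverse regularisation strength of the logistic model.
    """

    def __init__(self, embeddings, C: float = 1.0):
        self.embeddings = embeddings
        self.C = C

    def _featurize(self, notes: Sequence[ProcessedNote]) -> np.ndarray:
        rows = []
        for note in notes:
            vecs = [self.embeddings[t] for t in note.tokens if t in self.embeddings]
            rows.append(
                np.mean(vecs, axis=0) if vecs else np.zeros(self.embeddings.dimension)
            )
        return np.array(rows)

    def fit(self, X: Sequence[ProcessedNote], y):
        from sklearn.linear_model import LogisticRegression

        y = np.asarray(y)
        unknown = set(y) - set(SENTIMENT_CLASSES)
        if unknown:
            raise ValueError(f"unknown sentiment labels: {sorted(unknown)}")
        self.model_ = LogisticRegression(C=self.C, max_iter=1000)
        self.model_.fit(self._featurize(X), y)
        self.classes_ = self.model_.classes_
        return self

    def predict_proba(self, X: Sequence[ProcessedNote]) -> np.ndarray:
        check_is_fitted(self, "model_")
        raw = self.model_.predict_proba(self._featurize(X))
        # re-order to the fixed (negative, neutral, positive) convention,
        # padding classes unseen in training with probability 0
        out = np.zeros((len(raw), 3))
        for j, cls in enumerate(self.model_.classes_):
            out[:, SENTIMENT_CLASSES.index(cls)] = raw[:, j]
        return out

    def predict(self, X: Sequence[ProcessedNote]) -> np.ndarray:
        probs = self.predict_proba(X)
        return np.array([_argmax_label(p) for p in probs])


class HybridSentimentClassifier(ClassifierMixin, BaseEstimator):
    """Dictionary + machine-learning hybrid sentiment classifier.

    Parameters
    ----------
    polarity_lexicon : PolarityLexicon
    alpha : float, default 0.5
        Weight of the dictionary path; forced to 1 when no model is available.
    ml_model : estimator or None, default None
        Pluggable model with ``predict_proba`` over processed notes (e.g.
        :class:`BagOfEmbeddingsClassifier`).  If it is unfitted and labels are
        passed to ``fit``, a clone is trained.
    """

    def __init__(self, polarity_lexicon: PolarityLexicon, alpha: float = 0.5,
                 ml_model=None):
        self.polarity_lexicon = polarity_lexicon
        self.alpha = alpha
        self.ml_model = ml_model

    def fit(self, X: Sequence[ProcessedNote], y=None):
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        self.classes_ = np.asarray(SENTIMENT_CLASSES, dtype=object)
        model = self.ml_model
        if model is not None and y is not None and hasattr(model, "fit"):
            model = clone(model) if isinstance(model, BaseEstimator) else model
            model.fit(X, y)
        self.ml_model_ = model
        return self

    def _blended(self, note: ProcessedNote) -> tuple[float, np.ndarray | None, np.ndarray]:
        score = dictionary_polarity_score(note, self.polarity_lexicon)
        dict_probs = dict_score_to_probs(score)
        if self.ml_model_ is None:
            return score, None, dict_probs
        ml = validate_probabilities(
            np.asarray(self.ml_model_.predict_proba([note])).reshape(-1)
        )
        return score, ml, self.alpha * dict_probs + (1.0 - self.alpha) * ml

    def predict_proba(self, X: Sequence[ProcessedNote]) -> np.ndarray:
        check_is_fitted(self, "classes_")
        return np.array([self._blended(note)[2] for note in X])

    def predict(self, X: Sequence[ProcessedNote]) -> np.ndarray:
        check_is_fitted(self, "classes_")
        return np.array([_argmax_label(self._blended(n)[2]) for n in X], dtype=object)

    def score_notes(self, X: Sequence[ProcessedNote]) -> list[SentimentResult]:
        """Full per-note results (dictionary score, model probabilities,
        hybrid label)."""
        check_is_fitted(self, "classes_")
        out = []
        for note in X:
            score, ml, blended = self._blended(note)
            out.append(
                SentimentResult(
                    note_id=note.id,
                    dict_score=score,
                    ml_probs=ml,
                    hybrid_label=_argmax_label(blended),
                    alpha=1.0 if ml is None else self.alpha,
                )
            )
        return out

    def result_frame(self, X: Sequence[ProcessedNote]) -> pd.DataFrame:
        rows = []
        for res in self.score_notes(X):
            ml = res.ml_probs if res.ml_probs is not None else [np.nan] * 3
            rows.append(
                {
                    "note_id": res.note_id,
                    "dict_score": res.dict_score,
                    "ml_neg": ml[0],
                    "ml_neu": ml[1],
                    "ml_pos": ml[2],
                    "label": res.hybrid_label,
                }
            )
        return pd.DataFrame(rows).set_index("note_id")
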
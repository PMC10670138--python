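"""Difficulty-area detection via latent semantic analysis.

Each note becomes a bag-of-words column of a term × document frequency
matrix, reduced by truncated singular value decomposition (LSA).  Every
difficulty area — body image, acceptance of the environment, self-esteem —
carries an expert-built dictionary of positive and of negative words; each
dictionary is folded into the latent space as a pseudo-document, and a note's
affiliation to the area in the positive (W_P) and negative (W_N) context is
its cosine similarity to the folded dictionary, clamped at zero.  The
relative difference

    rel_diff = (W_N - W_P) / max(W_N, W_P) * 100%

drives a four-way context decision at a 20% threshold: negative when
rel_diff > 20, positive when rel_diff < -20, mixed when |rel_diff| <= 20,
and "not covered" when both affiliations are exactly zero.  Predictions are
scored against expert flags (0 not raised, -1 negative, 1 positive,
2 mixed).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .corpus import ProcessedNote

AREAS = ("body_image", "environment_acceptance", "self_esteem")

CONTEXTS = ("negative", "positive", "mixed", "not_covered")

#: Expert flag value → context label.
FLAG_LABELS = {0: "not_covered", -1: "negative", 1: "positive", 2: "mixed"}


@dataclass
class FrequencyMatrix:
    """Term × document raw-count matrix with deterministic orders
    (terms lexicographic, documents in input order)."""

    terms: list[str]
    doc_ids: list[str]
    counts: np.ndarray  # shape (n_terms, n_docs)

    def term_index(self, term: str) -> int:
        return self.terms.index(term)


def build_frequency_matrix(notes: Sequence[ProcessedNote]) -> FrequencyMatrix:
    if not notes or all(n.length_N == 0 for n in notes):
        raise ValueError("cannot build a frequency matrix from empty notes")
    terms = sorted({stem for note in notes for stem in note.counts})
    index = {t: i for i, t in enumerate(terms)}
    counts = np.zeros((len(terms), len(notes)))
    for j, note in enumerate(notes):
        for stem, count in note.counts.items():
            counts[index[stem], j] = count
    return FrequencyMatrix(terms=terms, doc_ids=[n.id for n in notes], counts=counts)


@dataclass
class LsaModel:
    """Truncated SVD of the frequency matrix: X ≈ U_k Σ_k V_kᵀ.

    ``term_vectors`` = U_k·Σ_k and ``doc_vectors`` = V_k·Σ_k, so folding in an
    existing document's bag (qᵀ·U_k) reproduces its document vector exactly at
    full rank.
    """

    k: int
    terms: list[str]
    doc_ids: list[str]
    u: np.ndarray  # (n_terms, k)
    singular_values: np.ndarray  # (k,), non-increasing
    term_vectors: np.ndarray  # (n_terms, k)
    doc_vectors: np.ndarray  # (n_docs, k)

    def doc_vector(self, note_id: str) -> np.ndarray:
        return self.doc_vectors[self.doc_ids.index(note_id)]


def fit_lsa(matrix: FrequencyMatrix, k: int) -> LsaModel:
    """Truncated SVD of the (term × document) count matrix."""
    n_terms, n_docs = matrix.counts.shape
    if not 1 <= k <= min(n_terms, n_docs):
        raise ValueError(f"k={k} out of range [1, {min(n_terms, n_docs)}]")
    u, s, vt = np.linalg.svd(matrix.counts, full_matrices=False)
    u_k, s_k, v_k = u[:, :k], s[:k], vt[:k].T
    return LsaModel(
        k=k,
        terms=list(matrix.terms),
        doc_ids=list(matrix.doc_ids),
        u=u_k,
        singular_values=s_k,
        term_vectors=u_k * s_k,
        doc_vectors=v_k * s_k,
    )


def fold_in(
    words: Iterable[str],
    model: LsaModel,
    return_missing: bool = False,
):
    """Project a pseudo-document (one count per word occurrence) into the
    latent space as qᵀ·U_k; words outside the fitted vocabulary are ignored
    (and reported when ``return_missing``)."""
    index = {t: i for i, t in enumerate(model.terms)}
    q = np.zeros(len(model.terms))
    missing = []
    for word in words:
        i = index.get(word)
        if i is None:
            missing.append(word)
        else:
            q[i] += 1.0
    vec = q @ model.u
    return (vec, missing) if return_missing else vec


@dataclass
class AreaDictionaries:
    """Positive and negative vocabulary depicting one difficulty area."""

    area: str
    positive_words: list[str]
    negative_words: list[str]

    def __post_init__(self) -> None:
        if not self.positive_words or not self.negative_words:
            raise ValueError(f"area {self.area!r}: both word lists must be non-empty")
        if set(self.positive_words) & set(self.negative_words):
            raise ValueError(f"area {self.area!r}: word lists must be disjoint")


def load_area_dictionaries(mapping: Mapping[str, Mapping[str, list[str]]]) -> dict[str, AreaDictionaries]:
    """Build area dictionaries from the JSON layout
    ``{area: {"positive": [...], "negative": [...]}}``."""
    return {
        area: AreaDictionaries(area, list(d["positive"]), list(d["negative"]))
        for area, d in mapping.items()
    }


def _clamped_cosine(u: np.ndarray, v: np.ndarray) -> float:
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        return 0.0
    return max(0.0, float(np.dot(u, v) / (nu * nv)))


def area_affiliation(
    note_id: str,
    model: LsaModel,
    dicts: AreaDictionaries,
    note_counts: Mapping[str, int] | None = None,
) -> tuple[float, float]:
    """(W_P, W_N): clamped cosine between the note's document vector and the
    folded positive / negative dictionary pseudo-documents.

    When ``note_counts`` is given, a context whose dictionary shares no term
    with the note has affiliation exactly 0, making "the value of belonging
    equals 0" an attainable, term-level statement rather than a numerical
    accident of the latent geometry.
    """
    doc = model.doc_vector(note_id)

    def _w(words: list[str]) -> float:
        if note_counts is not None and not any(w in note_counts for w in words):
            return 0.0
        return _clamped_cosine(doc, fold_in(words, model))

    return _w(dicts.positive_words), _w(dicts.negative_words)


def relative_difference(w_n: float, w_p: float) -> float:
    """((W_N − W_P) / max(W_N, W_P)) · 100, in percent."""
    if w_n < 0 or w_p < 0:
        raise ValueError("affiliations must be nonnegative")
    top = max(w_n, w_p)
    if top == 0.0:
        raise ValueError("relative difference undefined when both affiliations are 0")
    return (w_n - w_p) / top * 100.0


def classify_context(w_n: float, w_p: float, threshold: float = 20.0) -> str:
    """Four-way context decision; a tie at exactly the threshold is mixed."""
    if w_n < 0 or w_p < 0:
        raise ValueError("affiliations must be nonnegative")
    if w_n == 0.0 and w_p == 0.0:
        return "not_covered"
    diff = relative_difference(w_n, w_p)
    if diff > threshold:
        return "negative"
    if diff < -threshold:
        return "positive"
    return "mixed"


@dataclass
class TopicAffiliation:
    """Per note × area affiliation and context decision."""

    note_id: str
    area: str
    w_p: float
    w_n: float
    rel_diff: float | None
    context: str


def affiliations_for_corpus(
    model: LsaModel,
    area_dicts: Mapping[str, AreaDictionaries],
    threshold: float = 20.0,
    note_counts: Mapping[str, Mapping[str, int]] | None = None,
) -> list[TopicAffiliation]:
    out = []
    for note_id in model.doc_ids:
        counts = note_counts.get(note_id) if note_counts is not None else None
        for area in sorted(area_dicts):
            w_p, w_n = area_affiliation(note_id, model, area_dicts[area], counts)
            rel = relative_difference(w_n, w_p) if max(w_n, w_p) > 0 else None
            out.append(
                TopicAffiliation(
                    note_id, area, w_p, w_n, rel,
                    classify_context(w_n, w_p, threshold),
                )
            )
    return out


@dataclass
class AgreementReport:
    """Per-area agreement of predicted contexts with expert flags."""

    per_area: dict[str, dict[str, float]]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.per_area).T


def evaluate_agreement(
    predicted: Sequence[TopicAffiliation],
    flags: Mapping[str, Mapping[str, int]],
) -> AgreementReport:
    """Score predictions against expert flags per area.

    Each note × area falls into exactly one of four categories: consistent
    (label match), mixed_detected_as_single (expert flag 2, single-context
    prediction), single_detected_as_mixed (expert flag ±1, mixed prediction),
    or error (all remaining mismatches).  Percentages are over notes per area
    and sum to 100.  Context shares among expert-flagged notes (flag ≠ 0) are
    reported alongside.
    """
    missing = [
        f"{p.note_id}/{p.area}"
        for p in predicted
        if p.note_id not in flags or p.area not in flags[p.note_id]
    ]
    if missing:
        raise ValueError(f"missing expert flags for: {missing}")

    per_area: dict[str, dict[str, float]] = {}
    areas = sorted({p.area for p in predicted})
    for area in areas:
        preds = [p for p in predicted if p.area == area]
        n = len(preds)
        consistent = error = mixed_as_single = single_as_mixed = 0
        flagged = []
        for p in preds:
            flag = flags[p.note_id][p.area]
            if flag not in FLAG_LABELS:
                raise ValueError(f"invalid expert flag {flag!r}")
            expert = FLAG_LABELS[flag]
            if flag != 0:
                flagged.append(expert)
            if p.context == expert:
                consistent += 1
            elif expert == "mixed" and p.context in ("negative", "positive"):
                mixed_as_single += 1
            elif expert in ("negative", "positive") and p.context == "mixed":
                single_as_mixed += 1
            else:
                error += 1
        shares = {
            f"expert_share_{c}": (100.0 * flagged.count(c) / len(flagged))
            if flagged else 0.0
            for c in ("negative", "positive", "mixed")
        }
        per_area[area] = {
            "n_notes": n,
            "pct_consistent": 100.0 * consistent / n,
            "pct_error": 100.0 * error / n,
            "pct_mixed_detected_as_single": 100.0 * mixed_as_single / n,
            "pct_single_detected_as_mixed": 100.0 * single_as_mixed / n,
            **shares,
        }
    return AgreementReport(per_area=per_area)


class LsaContextClassifier(BaseEstimator):
    """LSA-based four-way context classifier over the difficulty areas.

    ``fit`` builds the frequency matrix from the processed notes, runs the
    truncated SVD and folds each area dictionary into the latent space;
    ``predict`` returns a note × area frame of context labels for the fitted
    corpus (LSA is transductive: affiliations are defined for fitted
    documents).

    Parameters
    ----------
    area_dicts : mapping area → AreaDictionaries (or the JSON-style nested
        mapping accepted by :func:`load_area_dictionaries`).
    k : int or None, default None
        Retained latent dimensions; ``None`` keeps the smallest k whose
        components carry at least ``energy`` of the spectral energy
        (squared singular values) — the usual scree/energy criterion.
    threshold : float, default 20.0
        Relative-difference threshold in percent.
    energy : float, default 0.9
        Spectral-energy fraction retained when ``k`` is None.
    tfidf : bool, default False
        Apply TF-IDF weighting to the frequency matrix before the SVD.
    require_term_overlap : bool, default True
        Force an affiliation to 0 when the note contains no dictionary term
        of that context (makes "not covered" exact).
    """

    def __init__(
        self,
        area_dicts,
        k: int | None = None,
        threshold: float = 20.0,
        tfidf: bool = False,
        require_term_overlap: bool = True,
        energy: float = 0.9,
    ):
        self.area_dicts = area_dicts
        self.k = k
        self.threshold = threshold
        self.tfidf = tfidf
        self.require_term_overlap = require_term_overlap
        self.energy = energy

    def _dicts(self) -> dict[str, AreaDictionaries]:
        first = next(iter(self.area_dicts.values()))
        if isinstance(first, AreaDictionaries):
            return dict(self.area_dicts)
        return load_area_dictionaries(self.area_dicts)

    def fit(self, X: Sequence[ProcessedNote], y=None):
        if not 0.0 < self.threshold < 100.0:
            raise ValueError("threshold must lie in (0, 100)")
        dicts = self._dicts()
        matrix = build_frequency_matrix(X)
        if self.tfidf:
            from sklearn.feature_extraction.text import TfidfTransformer

            weighted = TfidfTransformer().fit_transform(matrix.counts.T).toarray().T
            matrix = FrequencyMatrix(matrix.terms, matrix.doc_ids, weighted)
        k = self.k
        if k is None:
            if not 0.0 < self.energy <= 1.0:
                raise ValueError("energy must lie in (0, 1]")
            s = np.linalg.svd(matrix.counts, compute_uv=False)
            cumulative = np.cumsum(s**2) / np.sum(s**2)
            k = int(np.searchsorted(cumulative, self.energy) + 1)
            k = min(k, len(matrix.doc_ids), len(matrix.terms))
        self.matrix_ = matrix
        self.model_ = fit_lsa(matrix, k)
        self.area_dicts_ = dicts
        self.note_counts_ = {n.id: dict(n.counts) for n in X}
        return self

    def affiliations(self) -> list[TopicAffiliation]:
        check_is_fitted(self, "model_")
        counts = self.note_counts_ if self.require_term_overlap else None
        return affiliations_for_corpus(
            self.model_, self.area_dicts_, self.threshold, counts
        )

    def affiliation_frame(self) -> pd.DataFrame:
        rows = [
            {
                "note_id": a.note_id,
                "area": a.area,
                "W_P": a.w_p,
                "W_N": a.w_n,
                "rel_diff": a.rel_diff,
                "context": a.context,
            }
            for a in self.affiliations()
        ]
        return pd.DataFrame(rows)

    def predict(self, X: Sequence[ProcessedNote] | None = None) -> pd.DataFrame:
        """Context labels as a note × area frame.  ``X`` defaults to the
        fitted corpus; passing notes re-checks they were fitted."""
        check_is_fitted(self, "model_")
        if X is not None:
            unseen = [n.id for n in X if n.id not in self.model_.doc_ids]
            if unseen:
                raise ValueError(f"notes not in the fitted corpus: {unseen}")
        frame = self.affiliation_frame()
        wide = frame.pivot(index="note_id", columns="area", values="context")
        if X is not None:
            wide = wide.loc[[n.id for n in X]]
        else:
            wide = wide.loc[self.model_.doc_ids]
        return wide

    def score(self, flags: Mapping[str, Mapping[str, int]]) -> AgreementReport:
        """Agreement of the fitted corpus's predictions with expert flags."""
        return evaluate_agreement(self.affiliations(), flags)
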
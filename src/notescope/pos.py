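"""Morphological (part-of-speech) profiling of the note corpus.

Counts adjectives split by polarity, verbs split into the copula "to be"
versus other verbs and by tense, and occurrences of the possessive "my"
(for Polish: mój/moja/moje/…), plus a frequency ranking of characteristic
terms.  Tagging itself is a pluggable contract — any callable mapping a text
to :class:`TaggedToken` objects; a deterministic dictionary-lookup tagger is
provided for reproducible runs and tests.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Sequence

import pandas as pd
from sklearn.base import BaseEstimator

from .corpus import Normalizer, ProcessedNote, RawNote, identity_normalizer, tokenize
from .sentiment import PolarityLexicon

POS_TAGS = ("adjective", "verb", "possessive_my", "other")
TENSES = ("past", "present", "future")

#: Default surface forms of the Polish possessive "my" (mój).
DEFAULT_MY_FORMS = frozenset(
    {
        "mój", "moja", "moje", "mojego", "mojej", "mojemu", "moim", "moją",
        "moi", "moich", "moimi", "mych", "mym", "mymi", "ma", "me", "mej",
        "my",  # English fallback
    }
)


@dataclass
class TaggedToken:
    """One token with its part-of-speech annotation."""

    surface: str
    lemma: str
    pos: str
    tense: str | None = None  # verbs only
    polarity: str | None = None  # adjectives only

    def __post_init__(self) -> None:
        if self.pos not in POS_TAGS:
            raise ValueError(f"unknown pos tag {self.pos!r}")
        if self.tense is not None and self.pos != "verb":
            raise ValueError("tense is only defined for verbs")
        if self.tense is not None and self.tense not in TENSES:
            raise ValueError(f"unknown tense {self.tense!r}")
        if self.polarity is not None and self.pos != "adjective":
            raise ValueError("polarity is only defined for adjectives")


Tagger = Callable[[str], list[TaggedToken]]


class DictionaryTagger:
    """Deterministic tagger backed by a word-form table.

    The table maps a lowercase surface form to (pos, lemma, tense).  Unknown
    forms tag as ``other`` with the surface as lemma.  Loadable from TSV
    ``wordform<TAB>pos<TAB>lemma<TAB>tense`` (tense column may be empty or
    absent).
    """

    def __init__(self, table: dict[str, tuple[str, str, str | None]]):
        self.table = dict(table)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DictionaryTagger":
        table: dict[str, tuple[str, str, str | None]] = {}
        for lineno, line in enumerate(Path(path).read_text("utf-8").splitlines(), 1):
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"line {lineno}: expected wordform, pos, lemma")
            form, pos, lemma = parts[0].lower(), parts[1], parts[2]
            tense = parts[3] if len(parts) > 3 and parts[3] else None
            table[form] = (pos, lemma, tense)
        return cls(table)

    def __call__(self, text: str) -> list[TaggedToken]:
        tokens = []
        for surface in tokenize(text):
            pos, lemma, tense = self.table.get(surface, ("other", surface, None))
            tokens.append(
                TaggedToken(
                    surface=surface,
                    lemma=lemma,
                    pos=pos,
                    tense=tense if pos == "verb" else None,
                )
            )
        return tokens


def tag_tokens(
    note: RawNote,
    tagger: Tagger,
    polarity_lexicon: PolarityLexicon | None = None,
    my_forms: Iterable[str] = DEFAULT_MY_FORMS,
    normalizer: Normalizer | None = None,
) -> list[TaggedToken]:
    """Tag one note; adjective polarity is looked up in the polarity lexicon
    (by normalised lemma) and possessive-"my" surface forms override the
    tagger's part of speech."""
    normalizer = normalizer or identity_normalizer
    my_forms = {f.lower() for f in my_forms}
    tagged = tagger(note.text)
    out = []
    for token in tagged:
        if token.surface.lower() in my_forms:
            token = TaggedToken(token.surface, token.lemma, "possessive_my")
        elif token.pos == "adjective" and polarity_lexicon is not None:
            polarity = polarity_lexicon.polarity(normalizer(token.lemma.lower()))
            if polarity in ("positive", "negative"):
                token = TaggedToken(
                    token.surface, token.lemma, "adjective", polarity=polarity
                )
        out.append(token)
    return out


_COUNT_FIELDS = (
    "adj_total", "adj_negative", "adj_positive",
    "verb_total", "verb_tobe_total", "verb_tobe_past", "verb_tobe_present",
    "verb_tobe_future", "verb_other_total", "verb_other_past",
    "verb_other_present", "my_count",
)


@dataclass
class PosProfile:
    """Corpus-level morphological counts."""

    adj_total: int = 0
    adj_negative: int = 0
    adj_positive: int = 0
    verb_total: int = 0
    verb_tobe_total: int = 0
    verb_tobe_past: int = 0
    verb_tobe_present: int = 0
    verb_tobe_future: int = 0
    verb_other_total: int = 0
    verb_other_past: int = 0
    verb_other_present: int = 0
    my_count: int = 0

    def __add__(self, other: "PosProfile") -> "PosProfile":
        return PosProfile(
            **{f: getattr(self, f) + getattr(other, f) for f in _COUNT_FIELDS}
        )

    def as_dict(self) -> dict[str, int]:
        return {f: getattr(self, f) for f in _COUNT_FIELDS}


#: Lemmas treated as the copula "to be".
DEFAULT_TOBE_LEMMAS = frozenset({"być", "be"})


def pos_statistics(
    tagged_notes: Iterable[Sequence[TaggedToken]],
    tobe_lemmas: Iterable[str] = DEFAULT_TOBE_LEMMAS,
) -> PosProfile:
    """Fold tagged notes into a corpus :class:`PosProfile` (a pure sum, so
    the result is independent of note order)."""
    tobe = {l.lower() for l in tobe_lemmas}
    profile = PosProfile()
    for tokens in tagged_notes:
        for token in tokens:
            if token.pos == "adjective":
                profile.adj_total += 1
                if token.polarity == "negative":
                    profile.adj_negative += 1
                elif token.polarity == "positive":
                    profile.adj_positive += 1
            elif token.pos == "verb":
                profile.verb_total += 1
                if token.lemma.lower() in tobe:
                    profile.verb_tobe_total += 1
                    if token.tense == "past":
                        profile.verb_tobe_past += 1
                    elif token.tense == "present":
                        profile.verb_tobe_present += 1
                    elif token.tense == "future":
                        profile.verb_tobe_future += 1
                else:
                    profile.verb_other_total += 1
                    if token.tense == "past":
                        profile.verb_other_past += 1
                    elif token.tense == "present":
                        profile.verb_other_present += 1
            elif token.pos == "possessive_my":
                profile.my_count += 1
    return profile


def characteristic_terms(
    notes: Sequence[ProcessedNote],
    stopwords: Iterable[str] = (),
    top_k: int = 20,
) -> list[tuple[str, int]]:
    """Most frequent corpus terms (stop-words excluded), ties broken
    lexicographically."""
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    stop = {w.lower() for w in stopwords}
    counts: Counter = Counter()
    for note in notes:
        for stem, count in note.counts.items():
            if stem not in stop:
                counts[stem] += count
    ranked = sorted(counts.items(), key=lambda item: (-item[1], item[0]))
    return ranked[:top_k]


class PosProfiler(BaseEstimator):
    """Corpus morphological profiler over a pluggable tagger.

    Parameters
    ----------
    tagger : callable text → list of TaggedToken
    polarity_lexicon : PolarityLexicon or None
        Source of adjective polarity; adjectives absent from it stay untyped.
    my_forms : iterable of str
        Surface forms counted as the possessive "my".
    tobe_lemmas : iterable of str
        Lemmas identifying the copula.
    """

    def __init__(
        self,
        tagger: Tagger,
        polarity_lexicon: PolarityLexicon | None = None,
        my_forms: Iterable[str] = DEFAULT_MY_FORMS,
        tobe_lemmas: Iterable[str] = DEFAULT_TOBE_LEMMAS,
    ):
        self.tagger = tagger
        self.polarity_lexicon = polarity_lexicon
        self.my_forms = my_forms
        self.tobe_lemmas = tobe_lemmas

    def fit(self, X=None, y=None):
        return self

    def tag(self, notes: Sequence[RawNote]) -> list[list[TaggedToken]]:
        tagged = []
        for note in notes:
            try:
                tagged.append(
                    tag_tokens(note, self.tagger, self.polarity_lexicon, self.my_forms)
                )
            except Exception as exc:  # tagger failure skips the note
                warnings.warn(f"tagger failed on note {note.id!r}: {exc}")
        return tagged

    def corpus_profile(self, notes: Sequence[RawNote]) -> PosProfile:
        return pos_statistics(self.tag(notes), self.tobe_lemmas)

    def transform(self, X: Sequence[RawNote]) -> pd.DataFrame:
        """Per-note count rows (one PosProfile per note)."""
        rows = [
            pos_statistics([tokens], self.tobe_lemmas).as_dict()
            for tokens in self.tag(X)
        ]
        return pd.DataFrame(rows, index=[n.id for n in X])
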
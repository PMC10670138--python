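"""Reading and normalising free-text notes.

Every downstream analysis consumes :class:`ProcessedNote` objects produced by
one fixed normalisation pipeline: lowercase, tokenise on non-letter
boundaries (Unicode letters, so diacritics survive), drop stop-words, then
reduce each token to a base form with a pluggable normaliser (stemmer or
lemmatiser — the package does not hard-code a language-specific algorithm).
"""

from __future__ import annotations

import csv
import json
import re
import unicodedata
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

from sklearn.base import BaseEstimator, TransformerMixin

STAGES = ("I", "II", "III_convalescent", "palliative", "unknown")

# Unicode letter runs; digits and punctuation act as separators, so no
# retained token can contain them.
_TOKEN_RE = re.compile(r"[^\W\d_]+", re.UNICODE)

Normalizer = Callable[[str], str]


def identity_normalizer(token: str) -> str:
    """Default normaliser: the lowercase token is its own base form."""
    return token


@dataclass
class RawNote:
    """One patient note as read from disk, before any processing."""

    id: str
    text: str
    stage: str = "unknown"
    expert_flags: dict[str, int] | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("note id must be non-empty")
        if not self.text.strip():
            raise ValueError(f"note {self.id!r}: text empty after stripping")
        if self.stage not in STAGES:
            raise ValueError(f"note {self.id!r}: unknown stage {self.stage!r}")


@dataclass
class ProcessedNote:
    """Ordered retained stems of one note plus their multiplicities."""

    id: str
    tokens: list[str]
    counts: Counter = field(init=False)

    def __post_init__(self) -> None:
        self.counts = Counter(self.tokens)

    @property
    def length_N(self) -> int:
        return len(self.tokens)


def _parse_stage(value) -> str:
    if value is None or value == "":
        return "unknown"
    value = str(value)
    if value not in STAGES:
        raise ValueError(f"unknown stage label {value!r}")
    return value


def _parse_flags(record: Mapping) -> dict[str, int] | None:
    flags = record.get("flags") or record.get("expert_flags")
    if flags is None:
        # flat CSV columns like flags.body_image
        flat = {
            key.split(".", 1)[1]: record[key]
            for key in record
            if key.startswith("flags.") and record[key] not in (None, "")
        }
        flags = flat or None
    if flags is None:
        return None
    return {area: int(value) for area, value in flags.items()}


def read_notes(path: str | Path, format: str = "jsonl") -> list[RawNote]:
    """Read a note collection from ``jsonl``, ``csv`` or a ``txt_dir``.

    Raises on duplicate ids and on empty inputs; a missing stage becomes
    ``unknown`` and missing expert flags stay absent.
    """
    path = Path(path)
    notes: list[RawNote] = []
    if format == "jsonl":
        with open(path, encoding="utf-8") as handle:
            for line in handle:
                line = line.strip()
                if not line:
                    continue
                record = json.loads(line)
                notes.append(
                    RawNote(
                        id=str(record["id"]),
                        text=record["text"],
                        stage=_parse_stage(record.get("stage")),
                        expert_flags=_parse_flags(record),
                    )
                )
    elif format == "csv":
        with open(path, encoding="utf-8", newline="") as handle:
            for record in csv.DictReader(handle):
                notes.append(
                    RawNote(
                        id=str(record["id"]),
                        text=record["text"],
                        stage=_parse_stage(record.get("stage")),
                        expert_flags=_parse_flags(record),
                    )
                )
    elif format == "txt_dir":
        for file in sorted(path.glob("*.txt")):
            notes.append(RawNote(id=file.stem, text=file.read_text("utf-8")))
    else:
        raise ValueError(f"unknown notes format {format!r}")

    if not notes:
        raise ValueError(f"no notes found in {path}")
    seen: set[str] = set()
    for note in notes:
        if note.id in seen:
            raise ValueError(f"duplicate note id {note.id!r}")
        seen.add(note.id)
    return notes


def read_stopwords(path: str | Path) -> frozenset[str]:
    """One word per line, UTF-8; blank lines ignored."""
    words = {
        line.strip().lower()
        for line in Path(path).read_text("utf-8").splitlines()
        if line.strip()
    }
    return frozenset(words)


def tokenize(text: str) -> list[str]:
    """Lowercase and split on any non-letter character."""
    return _TOKEN_RE.findall(unicodedata.normalize("NFC", text).lower())


def preprocess_note(
    note: RawNote,
    stopwords: Iterable[str] = (),
    stemmer: Normalizer | None = None,
) -> ProcessedNote:
    """Apply the fixed pipeline: lowercase → tokenise → drop stop-words → stem.

    A note whose every token is removed yields ``length_N == 0``; callers
    decide whether that is an error for their analysis.
    """
    stemmer = stemmer or identity_normalizer
    stop = {word.lower() for word in stopwords}
    stems = []
    for token in tokenize(note.text):
        if token in stop:
            continue
        stem = stemmer(token)
        if not stem:
            raise ValueError(f"normaliser produced an empty stem for {token!r}")
        stems.append(stem)
    return ProcessedNote(id=note.id, tokens=stems)


def build_vocabulary(notes: Sequence[ProcessedNote]) -> list[str]:
    """Sorted, deduplicated union of stems over the collection."""
    if not notes:
        raise ValueError("cannot build a vocabulary from an empty collection")
    vocab: set[str] = set()
    for note in notes:
        vocab.update(note.counts)
    return sorted(vocab)


class TextPreprocessor(TransformerMixin, BaseEstimator):
    """Stateless transformer from raw notes (or strings) to processed notes.

    Parameters
    ----------
    stopwords : iterable of str, default ()
        Words removed before stemming (compared lowercase).
    stemmer : callable or None, default None
        Token → base-form mapping; ``None`` keeps tokens verbatim.
    """

    def __init__(self, stopwords: Iterable[str] = (), stemmer: Normalizer | None = None):
        self.stopwords = stopwords
        self.stemmer = stemmer

    def fit(self, X=None, y=None):
        self.n_features_in_ = 0  # text input; kept for sklearn compatibility
        return self

    def transform(self, X: Iterable[RawNote | str]) -> list[ProcessedNote]:
        out = []
        for i, item in enumerate(X):
            note = item if isinstance(item, RawNote) else RawNote(id=f"n{i}", text=item)
            out.append(preprocess_note(note, self.stopwords, self.stemmer))
        return out
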
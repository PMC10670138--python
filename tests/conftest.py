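import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from notescope import (
    AffectiveLexicon,
    EmbeddingSpace,
    GeneratorConfig,
    SyntheticStudy,
    TextPreprocessor,
)
from notescope.affect import AffectiveEntry, standardize_weights


@pytest.fixture(scope="session")
def study():
    """Default 50-note synthetic study (stage groups 11/32/7, sentiment
    29/10/11)."""
    return SyntheticStudy(GeneratorConfig(seed=1))


@pytest.fixture(scope="session")
def processed(study):
    return TextPreprocessor().fit().transform(study.notes)


def make_lexicon(rows: dict[str, list[float]], scale: str = "base") -> AffectiveLexicon:
    """Build a lexicon directly from word → five base-scale intensities."""
    lex = AffectiveLexicon(
        entries={
            w: AffectiveEntry(w, np.asarray(v, dtype=float)) for w, v in rows.items()
        },
        scale="base",
    )
    return standardize_weights(lex) if scale == "standardized" else lex


def make_std_lexicon(rows: dict[str, list[float]]) -> AffectiveLexicon:
    """Build a standardized-scale lexicon verbatim (values already in [0,1])."""
    return AffectiveLexicon(
        entries={
            w: AffectiveEntry(w, np.asarray(v, dtype=float)) for w, v in rows.items()
        },
        scale="standardized",
    )


def make_space(vectors: dict[str, list[float]]) -> EmbeddingSpace:
    arrays = {w: np.asarray(v, dtype=float) for w, v in vectors.items()}
    dim = len(next(iter(arrays.values())))
    return EmbeddingSpace(dimension=dim, vectors=arrays)
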
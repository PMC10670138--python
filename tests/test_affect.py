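import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from notescope import (
    EMOTIONS,
    compute_emotion_centers,
    extend_lexicon,
    extend_word,
    group_emotion_profile,
    match_word_to_center,
    note_emotion_profile,
    read_affective_lexicon,
    read_embeddings,
    standardize_weights,
)
from notescope.affect import EmotionIntensityScorer, write_affective_lexicon
from notescope.corpus import ProcessedNote
from conftest import make_lexicon, make_space, make_std_lexicon


# --- independent brute-force oracle for the extension formula -------------

def _cos(u, v):
    num = sum(a * b for a, b in zip(u, v))
    return num / (math.sqrt(sum(a * a for a in u)) * math.sqrt(sum(b * b for b in v)))


def oracle_extend(word, lexicon, space, n):
    """Direct evaluation of the three-stage interpolation with plain loops:
    centroid matching, same-dominant-emotion neighbour pool, shifted-cosine
    weights, weighted average."""
    dominant = {
        w: max(range(5), key=lambda j: (e.intensities[j], -j))
        for w, e in lexicon.entries.items()
    }
    # Stage I: centers over lexicon∩space (note_vocab = lexicon words here)
    best_emotion, best_sim = None, -2.0
    for j in range(5):
        members = [w for w in lexicon.entries if dominant[w] == j and w in space]
        if not members:
            continue
        centroid = [
            sum(space[w][d] for w in members) / len(members)
            for d in range(space.dimension)
        ]
        sim = _cos(list(space[word]), centroid)
        if sim > best_sim:
            best_emotion, best_sim = j, sim
    # Stage III: n most similar same-emotion lexicon words
    pool = [w for w in lexicon.entries if dominant[w] == best_emotion and w in space]
    sims = sorted(
        ((_cos(list(space[word]), list(space[w])), w) for w in pool),
        key=lambda t: (-t[0], t[1]),
    )[:n]
    weights = [(s + 1.0) / 2.0 for s, _ in sims]
    total = sum(weights)
    weights = [w / total for w in weights]
    out = [0.0] * 5
    for (s, w), weight in zip(sims, weights):
        for j in range(5):
            out[j] += lexicon.entries[w].intensities[j] * weight
    return np.array(out)


def random_instance(rng, n_words, dim=6):
    rows = {
        f"w{i}": list(rng.uniform(1.0, 7.0, size=5)) for i in range(n_words)
    }
    lexicon = make_lexicon(rows, scale="standardized")
    vectors = {w: list(rng.normal(size=dim)) for w in rows}
    vectors["query"] = list(rng.normal(size=dim))
    return lexicon, make_space(vectors)


class TestLexiconIO:
    def test_dominant_emotion_is_argmax(self, tmp_path):
        path = tmp_path / "lex.tsv"
        path.write_text(
            "word\thappiness\tsadness\tanger\tfear\tdisgust\n"
            "strach\t1.2\t2.0\t1.5\t6.8\t1.1\n"
        )
        lex = read_affective_lexicon(path)
        assert lex.entries["strach"].dominant_emotion == "fear"

    def test_tie_breaks_by_fixed_emotion_order(self):
        lex = make_lexicon({"x": [3, 3, 3, 3, 3]})
        assert lex.entries["x"].dominant_emotion == "happiness"

    def test_out_of_range_weight_rejected(self, tmp_path):
        path = tmp_path / "lex.tsv"
        path.write_text(
            "word\thappiness\tsadness\tanger\tfear\tdisgust\n"
            "zly\t9.0\t2.0\t1.5\t6.8\t1.1\n"
        )
        with pytest.raises(ValueError, match=r"\[1.0, 7.0\]"):
            read_affective_lexicon(path)

    def test_duplicate_word_rejected(self, tmp_path):
        path = tmp_path / "lex.tsv"
        path.write_text(
            "word\thappiness\tsadness\tanger\tfear\tdisgust\n"
            "a\t1\t1\t1\t1\t1\na\t2\t2\t2\t2\t2\n"
        )
        with pytest.raises(ValueError, match="duplicate"):
            read_affective_lexicon(path)

    def test_roundtrip_with_origin_column(self, tmp_path):
        lex = make_lexicon({"a": [1, 2, 3, 4, 5], "b": [5, 4, 3, 2, 1]})
        path = tmp_path / "out.tsv"
        write_affective_lexicon(lex, path)
        text = path.read_text()
        assert "origin" in text.splitlines()[0]
        assert "original" in text

    def test_written_back_standardized_lexicon_reads_as_standardized(self, tmp_path):
        std = standardize_weights(
            make_lexicon({"a": [1, 2, 3, 4, 5], "b": [5, 4, 3, 2, 1]})
        )
        path = tmp_path / "std.tsv"
        write_affective_lexicon(std, path)
        back = read_affective_lexicon(path)
        assert back.scale == "standardized"
        assert np.allclose(
            back.entries["a"].intensities, std.entries["a"].intensities
        )
        assert back.entries["a"].origin == "original"


class TestStandardize:
    def test_full_range_maps_to_unit_interval(self):
        lex = make_lexicon({"lo": [1, 1, 1, 1, 1], "mid": [4, 4, 4, 4, 4],
                            "hi": [7, 7, 7, 7, 7]})
        std = standardize_weights(lex)
        assert np.allclose(std.entries["lo"].intensities, 0.0)
        assert np.allclose(std.entries["mid"].intensities, 0.5)
        assert np.allclose(std.entries["hi"].intensities, 1.0)

    def test_constant_column_maps_to_zero_with_warning(self):
        lex = make_lexicon({"a": [2, 1, 1, 1, 1], "b": [2, 3, 3, 3, 3]})
        with pytest.warns(UserWarning, match="constant"):
            std = standardize_weights(lex)
        assert std.entries["a"].intensities[0] == 0.0
        assert std.entries["b"].intensities[0] == 0.0

    @given(
        st.lists(
            st.lists(st.floats(1.0, 7.0), min_size=5, max_size=5),
            min_size=2,
            max_size=12,
        )
    )
    @settings(deadline=None, max_examples=50)
    def test_minmax_invariants_hold_for_any_base_lexicon(self, rows):
        lex = make_lexicon({f"w{i}": row for i, row in enumerate(rows)})
        with pytest.warns() if _has_constant_column(rows) else _nullcontext():
            std = standardize_weights(lex)
        matrix = np.array([e.intensities for e in std.entries.values()])
        assert np.all((matrix >= 0.0) & (matrix <= 1.0))
        for j in range(5):
            column = matrix[:, j]
            if len(set(r[j] for r in rows)) >= 2:
                assert column.min() == 0.0 and column.max() == 1.0

    def test_standardizing_twice_rejected(self):
        std = make_lexicon({"a": [1, 2, 3, 4, 5], "b": [5, 4, 3, 2, 1]},
                           scale="standardized")
        with pytest.raises(ValueError):
            standardize_weights(std)


def _has_constant_column(rows):
    return any(len({r[j] for r in rows}) == 1 for j in range(5))


class _nullcontext:
    def __enter__(self):
        return self

    def __exit__(self, *exc):
        return False


class TestEmbeddingsIO:
    def test_word2vec_text_with_header(self, tmp_path):
        path = tmp_path / "e.vec"
        path.write_text("2 3\nfoo 1 2 3\nbar 4 5 6\n")
        space = read_embeddings(path)
        assert space.dimension == 3
        assert np.allclose(space["bar"], [4, 5, 6])

    def test_ragged_rows_rejected(self, tmp_path):
        path = tmp_path / "e.vec"
        path.write_text("foo 1 2 3\nbar 4 5\n")
        with pytest.raises(ValueError, match="expected 3"):
            read_embeddings(path)

    def test_duplicate_word_keeps_first_with_warning(self, tmp_path):
        path = tmp_path / "e.vec"
        path.write_text("foo 1 2\nfoo 9 9\n")
        with pytest.warns(UserWarning, match="duplicate"):
            space = read_embeddings(path)
        assert np.allclose(space["foo"], [1, 2])

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "e.vec"
        path.write_text("")
        with pytest.raises(ValueError):
            read_embeddings(path)


class TestCentersAndMatching:
    def _five_word_setup(self):
        rows = {}
        vectors = {}
        for j, emotion in enumerate(EMOTIONS):
            row = [1.0] * 5
            row[j] = 7.0
            rows[f"{emotion}w"] = row
            vec = [0.0] * 5
            vec[j] = 1.0
            vectors[f"{emotion}w"] = vec
        return make_lexicon(rows, scale="standardized"), make_space(vectors)

    def test_single_member_centroid_is_its_vector(self):
        lex, space = self._five_word_setup()
        centers = compute_emotion_centers(lex, space, list(lex.entries))
        assert np.allclose(centers["anger"].centroid, space["angerw"])
        assert centers["anger"].member_words == ["angerw"]

    def test_fallback_to_lexicon_when_corpus_misses_an_emotion(self):
        lex, space = self._five_word_setup()
        with pytest.warns(UserWarning, match="falling back"):
            centers = compute_emotion_centers(lex, space, ["happinessw"])
        assert set(centers) == set(EMOTIONS)

    def test_zero_centroid_rejected(self):
        rows = {"a": [7, 1, 1, 1, 1], "b": [7, 1, 1, 1, 1],
                "c": [1, 7, 1, 1, 1]}
        vectors = {"a": [1.0, 0.0], "b": [-1.0, 0.0], "c": [0.0, 1.0]}
        lex = make_lexicon(rows, scale="standardized")
        with pytest.raises(ValueError, match="zero centroid"):
            compute_emotion_centers(lex, make_space(vectors), list(rows))

    def test_match_prefers_highest_cosine(self):
        lex, space = self._five_word_setup()
        centers = compute_emotion_centers(lex, space, list(lex.entries))
        space.vectors["query"] = np.array([0.0, 0.0, 0.0, 0.9, 0.0])
        assert match_word_to_center("query", space, centers) == "fear"

    def test_equidistant_tie_goes_to_happiness(self):
        lex, space = self._five_word_setup()
        centers = compute_emotion_centers(lex, space, list(lex.entries))
        space.vectors["query"] = np.ones(5)
        assert match_word_to_center("query", space, centers) == "happiness"

    def test_unembeddable_word_signalled(self):
        lex, space = self._five_word_setup()
        centers = compute_emotion_centers(lex, space, list(lex.entries))
        with pytest.raises(KeyError):
            match_word_to_center("ghost", space, centers)


class TestExtendWord:
    def test_in_lexicon_word_is_identity(self):
        rng = np.random.default_rng(0)
        lex, space = random_instance(rng, 8)
        entry = extend_word("w3", lex, space, centers=None, n=3)
        assert entry is lex.entries["w3"]

    def test_constant_neighbour_intensity_is_fixed_point(self):
        # every neighbour has fear intensity 0.6 → extension returns 0.6
        # regardless of the distances, because the weights sum to one
        rows = {f"w{i}": [0.1, 0.0, 0.2, 0.6, 0.1] for i in range(4)}
        lex = make_std_lexicon(rows)
        rng = np.random.default_rng(1)
        vectors = {w: list(rng.normal(size=4)) for w in rows}
        vectors["query"] = list(rng.normal(size=4))
        space = make_space(vectors)
        centers = compute_emotion_centers(lex, space, list(rows))
        entry = extend_word("query", lex, space, centers, n=3)
        assert entry.intensities[3] == pytest.approx(0.6, abs=1e-12)

    def test_equal_cosine_neighbours_average_evenly(self):
        rows = {"a": [0.1, 0.0, 0.0, 0.2, 0.0], "b": [0.3, 0.0, 0.0, 0.8, 0.0]}
        lex = make_std_lexicon(rows)
        space = make_space({
            "a": [1.0, 1.0], "b": [1.0, -1.0], "query": [1.0, 0.0],
        })
        centers = compute_emotion_centers(lex, space, list(rows))
        entry = extend_word("query", lex, space, centers, n=2)
        # fear intensities 0.2 and 0.8 at equal similarity → 0.5
        assert entry.intensities[3] == pytest.approx(0.5, abs=1e-12)

    def test_matches_brute_force_oracle_on_random_instances(self):
        rng = np.random.default_rng(42)
        for case in range(200):
            n_words = int(rng.integers(5, 11))
            n = int(rng.integers(1, 6))
            lex, space = random_instance(rng, n_words)
            centers = compute_emotion_centers(lex, space, list(lex.entries))
            got = extend_word("query", lex, space, centers, n=n)
            expected = oracle_extend("query", lex, space, n)
            assert np.allclose(got.intensities, expected, atol=1e-12), case
            assert got.origin == "extended"

    def test_extension_stays_in_neighbour_convex_hull(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            lex, space = random_instance(rng, 10)
            centers = compute_emotion_centers(lex, space, list(lex.entries))
            got = extend_word("query", lex, space, centers, n=4)
            matrix = np.array([e.intensities for e in lex.entries.values()])
            assert np.all(got.intensities >= matrix.min(axis=0) - 1e-12)
            assert np.all(got.intensities <= matrix.max(axis=0) + 1e-12)

    def test_full_pool_equals_similarity_weighted_pool_mean(self):
        rng = np.random.default_rng(11)
        lex, space = random_instance(rng, 9)
        centers = compute_emotion_centers(lex, space, list(lex.entries))
        got = extend_word("query", lex, space, centers, n=100)
        assert np.allclose(
            got.intensities, oracle_extend("query", lex, space, 100), atol=1e-12
        )


class TestExtendLexicon:
    def test_vocab_inside_lexicon_is_identity(self):
        rng = np.random.default_rng(3)
        lex, space = random_instance(rng, 6)
        out, skipped = extend_lexicon(["w0", "w1"], lex, space, n=3)
        assert out.entries.keys() == lex.entries.keys()
        assert skipped == []

    def test_one_new_word_gains_one_extended_entry(self):
        rng = np.random.default_rng(4)
        lex, space = random_instance(rng, 6)
        out, skipped = extend_lexicon(["query"], lex, space, n=3)
        assert len(out) == len(lex) + 1
        assert out.entries["query"].origin == "extended"

    def test_unembeddable_word_reported_not_added(self):
        rng = np.random.default_rng(5)
        lex, space = random_instance(rng, 6)
        out, skipped = extend_lexicon(["ghost"], lex, space, n=3)
        assert len(out) == len(lex)
        assert skipped == ["ghost"]


class TestNoteProfile:
    def test_single_token_profile_is_word_intensity(self):
        lex = make_lexicon({"a": [7, 1, 1, 1, 1], "b": [1, 7, 1, 1, 1]},
                           scale="standardized")
        profile = note_emotion_profile(ProcessedNote("n", ["a"]), lex)
        assert profile.as_array() == pytest.approx(lex.entries["a"].intensities)

    def test_count_weighted_mean(self):
        # fear(w)=0.6, fear(u)=0.3, counts 2 and 1 → (2·0.6+1·0.3)/3 = 0.5
        lex = make_lexicon(
            {"w": [1, 1, 1, 1 + 0.6 * 6, 1], "u": [1, 1, 1, 1 + 0.3 * 6, 1],
             "lo": [1, 1, 1, 1, 1], "hi": [7, 7, 7, 7, 7]},
            scale="standardized",
        )
        profile = note_emotion_profile(ProcessedNote("n", ["w", "w", "u"]), lex)
        assert profile.intensity["fear"] == pytest.approx(0.5)

    def test_unknown_tokens_contribute_zero_but_count(self):
        lex = make_lexicon({"a": [7, 1, 1, 1, 1], "z": [1, 1, 1, 1, 1]},
                           scale="standardized")
        profile = note_emotion_profile(ProcessedNote("n", ["a", "x", "y"]), lex)
        assert profile.intensity["happiness"] == pytest.approx(1.0 / 3.0)

    def test_all_unknown_tokens_give_zero_profile(self):
        lex = make_lexicon({"a": [7, 1, 1, 1, 1], "z": [1, 1, 1, 1, 1]},
                           scale="standardized")
        profile = note_emotion_profile(ProcessedNote("n", ["x", "y", "q"]), lex)
        assert np.allclose(profile.as_array(), 0.0)

    def test_empty_note_rejected(self):
        lex = make_lexicon({"a": [7, 1, 1, 1, 1], "z": [1, 1, 1, 1, 1]},
                           scale="standardized")
        with pytest.raises(ValueError, match="empty note"):
            note_emotion_profile(ProcessedNote("n", []), lex)

    @given(st.lists(st.sampled_from(["a", "z", "x"]), min_size=1, max_size=12))
    @settings(deadline=None)
    def test_duplicating_every_token_preserves_profile(self, tokens):
        lex = make_lexicon({"a": [7, 1, 3, 1, 1], "z": [1, 5, 1, 2, 1]},
                           scale="standardized")
        single = note_emotion_profile(ProcessedNote("n", tokens), lex)
        double = note_emotion_profile(ProcessedNote("n", tokens * 2), lex)
        assert single.as_array() == pytest.approx(double.as_array())


class TestGroupProfile:
    def test_singleton_groups_pass_through(self):
        lex = make_lexicon({"a": [7, 1, 1, 1, 1], "z": [1, 1, 1, 1, 1]},
                           scale="standardized")
        p1 = note_emotion_profile(ProcessedNote("n1", ["a"]), lex)
        p2 = note_emotion_profile(ProcessedNote("n2", ["z"]), lex)
        frame = group_emotion_profile([p1, p2], {"n1": "I", "n2": "II"})
        assert frame.loc["I", "happiness"] == pytest.approx(1.0)
        assert frame.loc["I", "n"] == 1

    def test_study_design_group_sizes(self, study, processed):
        lexicon = standardize_weights(study.lexicon)
        profiles = [note_emotion_profile(p, lexicon) for p in processed]
        grouping = {n.id: n.stage for n in study.notes}
        frame = group_emotion_profile(profiles, grouping)
        assert frame["n"].to_dict() == {"I": 11, "II": 32, "palliative": 7}


class TestScorer:
    def test_scorer_profiles_are_five_dimensional_and_bounded(self, study, processed):
        scorer = EmotionIntensityScorer(study.lexicon, study.embeddings)
        values = scorer.fit(processed).transform(processed)
        assert values.shape == (len(processed), 5)
        assert np.all((values >= 0.0) & (values <= 1.0))
        assert list(scorer.get_feature_names_out()) == list(EMOTIONS)

    def test_every_corpus_word_becomes_scoreable(self, study, processed):
        scorer = EmotionIntensityScorer(study.lexicon, study.embeddings)
        scorer.fit(processed)
        assert scorer.skipped_words_ == []
        vocab = {t for p in processed for t in p.tokens}
        assert vocab <= set(scorer.lexicon_.entries)
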
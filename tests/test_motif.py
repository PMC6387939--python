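from __future__ import annotations

import pytest
from hypothesis import given
from hypothesis import strategies as st

from fmotif.corpus_io import ConsistencyError, EmptyInputError, TokenSequence
from fmotif.examples import worked_table
from fmotif.motif import (
    FMotif,
    annotate_frequencies,
    classify_function_content,
    extract_fmotifs,
    length_spectrum,
    motif_str,
    position_grid,
    rank_frequency_spectrum,
    short_long_counts,
)

value_lists = st.lists(st.integers(min_value=1, max_value=9), max_size=50)


def brute_force_motifs(values):
    """Independent splitter: from each start, extend the run while the next
    value does not drop; restart at the first drop."""
    runs = []
    start = 0
    while start < len(values):
        end = start
        while end + 1 < len(values) and values[end + 1] >= values[end]:
            end += 1
        runs.append(tuple(values[start : end + 1]))
        start = end + 1
    return runs


class TestAnnotate:
    def test_simple(self):
        ts = TokenSequence("c", ["a", "b", "a"], [0])
        from fmotif.corpus_io import FrequencyTable

        assert annotate_frequencies(ts, FrequencyTable("c", {"a": 2, "b": 1})) == [2, 1, 2]

    def test_worked_sentence(self, worked_chunk):
        vals = annotate_frequencies(worked_chunk, worked_table())
        assert vals == [23, 14, 6, 44, 29, 3, 1, 70, 14, 1, 8, 24, 1, 3, 3]

    def test_empty(self):
        from fmotif.corpus_io import FrequencyTable

        assert annotate_frequencies(TokenSequence("c", [], []), FrequencyTable("c", {})) == []

    def test_missing_token_is_consistency_error(self):
        from fmotif.corpus_io import FrequencyTable

        ts = TokenSequence("c", ["a", "zz"], [0])
        with pytest.raises(ConsistencyError):
            annotate_frequencies(ts, FrequencyTable("other", {"a": 1}))


class TestExtract:
    def test_printed_motif_string_first_eight(self):
        vals = [23, 14, 6, 44, 29, 3, 1, 70, 14, 1, 8, 24]
        got = [m.values for m in extract_fmotifs(vals)]
        assert got == [(23,), (14,), (6, 44), (29,), (3,), (1, 70), (14,), (1, 8, 24)]

    def test_full_worked_sequence_has_nine_motifs_ending_133(self, worked_values):
        motifs = extract_fmotifs(worked_values)
        assert len(motifs) == 9
        assert motifs[-1].values == (1, 3, 3)

    @pytest.mark.parametrize(
        "values, expected",
        [
            ([5, 5, 5], [(5, 5, 5)]),
            ([3, 2, 1], [(3,), (2,), (1,)]),
            ([], []),
            ([7], [(7,)]),
        ],
    )
    def test_small_cases(self, values, expected):
        assert [m.values for m in extract_fmotifs(values)] == expected

    def test_rejects_nonpositive_values(self):
        with pytest.raises(ValueError):
            extract_fmotifs([1, 0, 2])

    @given(value_lists)
    def test_agrees_with_brute_force_and_conserves(self, values):
        motifs = extract_fmotifs(values)
        assert [m.values for m in motifs] == brute_force_motifs(values)
        flat = [v for m in motifs for v in m.values]
        assert flat == list(values)

    @given(value_lists)
    def test_maximality_at_boundaries(self, values):
        motifs = extract_fmotifs(values)
        for prev, nxt in zip(motifs, motifs[1:]):
            assert nxt.values[0] < prev.values[-1]

    def test_word_slices_follow_values(self, worked_values, worked_chunk):
        motifs = extract_fmotifs(worked_values, worked_chunk.tokens)
        assert motifs[7].words == ("disputes", "should", "be")
        assert motifs[7].start == 9


class TestSpectra:
    def test_rank_frequency_basic(self):
        motifs = [FMotif((1, 2)), FMotif((1, 2)), FMotif((3,))]
        spec = rank_frequency_spectrum(motifs)
        assert spec.entries == [((1, 2), 2), ((3,), 1)]
        assert (spec.N, spec.V) == (3, 2)

    def test_all_distinct(self):
        motifs = [FMotif((i,)) for i in range(1, 6)]
        spec = rank_frequency_spectrum(motifs)
        assert all(f == 1 for f in spec.frequencies)

    def test_empty_errors(self):
        with pytest.raises(EmptyInputError):
            rank_frequency_spectrum([])

    @given(st.lists(value_lists.filter(bool), min_size=1, max_size=40))
    def test_matches_hash_count_oracle(self, runs):
        from collections import Counter

        motifs = [FMotif(tuple(sorted(r))) for r in runs]
        spec = rank_frequency_spectrum(motifs)
        oracle = Counter(m.values for m in motifs)
        assert dict(spec.entries) == dict(oracle)
        assert sum(spec.frequencies) == spec.N == len(motifs)
        # deterministic tie-break: descending frequency then lexicographic
        assert spec.entries == sorted(spec.entries, key=lambda kv: (-kv[1], kv[0]))

    def test_length_spectrum(self, worked_values):
        motifs = extract_fmotifs(worked_values)
        assert length_spectrum(motifs).counts == {1: 5, 2: 2, 3: 2}

    def test_length_spectrum_conserves(self):
        motifs = [FMotif((1, 2)), FMotif((1, 2)), FMotif((3,))]
        ls = length_spectrum(motifs)
        assert ls.counts == {2: 2, 1: 1}
        assert ls.N == 3


class TestPositionGrid:
    def test_worked_example_L3P3(self, worked_motifs):
        grid = position_grid(worked_motifs)
        assert grid.mean_freq[(3, 3)] == pytest.approx(13.5)
        assert grid.n_motifs[3] == 2

    def test_last_position_holds_run_maximum(self, worked_motifs):
        grid = position_grid(worked_motifs)
        for L in grid.n_motifs:
            if L >= 2:
                assert grid.mean_freq[(L, L)] >= grid.mean_freq[(L, 1)]

    def test_lengths_above_max_excluded(self):
        motifs = [FMotif(tuple(range(1, 10))), FMotif((2,))]
        grid = position_grid(motifs, max_len=7)
        assert grid.n_motifs == {1: 1}

    def test_all_singletons(self):
        grid = position_grid([FMotif((4,)), FMotif((2,))])
        assert set(grid.mean_freq) == {(1, 1)}


class TestWordClasses:
    def test_worked_sentence_six_function_nine_content(self, worked_chunk):
        tally = classify_function_content(worked_chunk)
        assert (tally.function_count, tally.content_count) == (6, 9)

    def test_max_content_frequency_is_14(self, worked_chunk, worked_values):
        tally = classify_function_content(worked_chunk)
        content = [
            v
            for v, lab in zip(worked_values, tally.labels)
            if lab == "CONTENT"
        ]
        assert max(content) == 14

    def test_all_stoplist(self):
        tally = classify_function_content(["the", "of", "and"])
        assert (tally.function_count, tally.content_count) == (3, 0)

    def test_empty(self):
        tally = classify_function_content([])
        assert (tally.function_count, tally.content_count) == (0, 0)

    def test_custom_stoplist(self):
        tally = classify_function_content(["alpha", "beta"], stoplist={"alpha"})
        assert tally.labels == ["FUNCTION", "CONTENT"]


class TestShortLong:
    def test_basic_partition(self):
        motifs = [FMotif((1,)), FMotif((1, 2)), FMotif((1, 2, 3)), FMotif((1, 2, 3, 4))]
        assert short_long_counts(motifs) == (3, 1)

    def test_empty(self):
        assert short_long_counts([]) == (0, 0)

    @given(st.lists(st.integers(min_value=1, max_value=10), max_size=30))
    def test_partition_with_overflow(self, lengths):
        motifs = [FMotif(tuple(range(1, L + 1))) for L in lengths]
        short, long_ = short_long_counts(motifs)
        overflow = sum(1 for L in lengths if L > 7)
        assert short + long_ + overflow == len(motifs)


def test_motif_str_hyphen_notation():
    assert motif_str((1, 8, 24)) == "1-8-24"
    assert motif_str((7,)) == "7"


def test_fmotif_rejects_decreasing_values():
    with pytest.raises(ValueError):
        FMotif((3, 1))
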
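"""Median splits, realizable cuts, gap-rank scores, and pool assembly."""

import statistics

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aaopt.aaindex_io import CANONICAL_ALPHABET, FeatureTable
from aaopt.separations import (
    SeparationError,
    candidate_pool,
    deduplicate_pool,
    default_size_bounds,
    enumerate_cuts,
    median_separation,
    median_value,
    score_cuts,
    sorted_profile,
)
from aaopt.synthetic import generate_random_table

from conftest import record_from_values

N = len(CANONICAL_ALPHABET)


def random_record(seed, tie_fraction=0.0):
    table = generate_random_table(
        n_residues=N, n_features=1, seed=seed, tie_fraction=tie_fraction
    )
    return table.records[0]


class TestSortedProfile:
    def test_descending_values_reverse_alphabet(self):
        rec = record_from_values(range(20, 0, -1))
        prof = sorted_profile(rec, CANONICAL_ALPHABET)
        assert [r for r, _ in prof] == list(reversed(CANONICAL_ALPHABET))

    def test_ties_keep_alphabet_adjacency(self):
        values = list(range(1, 21))
        values[1] = values[5] = 0  # R and Q tied at the minimum
        rec = record_from_values(values)
        prof = sorted_profile(rec, CANONICAL_ALPHABET)
        assert [r for r, _ in prof[:2]] == ["R", "Q"]  # alphabet order R < Q

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_independent_sort(self, seed):
        rec = random_record(seed, tie_fraction=0.3)
        prof = sorted_profile(rec, CANONICAL_ALPHABET)
        assert [v for _, v in prof] == sorted(rec.values.values())


class TestMedianValue:
    def test_one_to_twenty(self):
        assert median_value(range(1, 21)) == 10.5

    def test_tied_middle_order_statistics(self):
        assert median_value([0.0] * 11 + [1.0] * 9) == 0.0

    @given(st.lists(st.integers(-1000, 1000), min_size=1, max_size=40))
    @settings(derandomize=True, max_examples=60)
    def test_agrees_with_stdlib_median(self, values):
        assert median_value(values) == pytest.approx(
            float(statistics.median(values))
        )

    def test_empty_rejected(self):
        with pytest.raises(SeparationError):
            median_value([])


class TestMedianSeparation:
    def test_distinct_values_split_ten_ten(self, ascending_record):
        sep = median_separation(ascending_record, CANONICAL_ALPHABET)
        assert sep.membership == (0,) * 10 + (1,) * 10
        assert sep.cut_size == 10
        assert sep.threshold == 10.0
        assert sep.is_median and sep.gap == 1.0

    def test_median_ties_never_split(self):
        # eleven residues tied at the minimum: all stay in the low set
        rec = record_from_values([0.0] * 11 + list(range(1, 10)))
        sep = median_separation(rec, CANONICAL_ALPHABET)
        assert sep.cut_size == 11

    def test_constant_feature_has_no_median_split(self):
        rec = record_from_values([3.0] * 20)
        with pytest.raises(SeparationError, match="no realizable median"):
            median_separation(rec, CANONICAL_ALPHABET)


class TestEnumerateCuts:
    def test_twenty_distinct_values_give_19_cuts(self, ascending_record):
        assert len(enumerate_cuts(ascending_record, CANONICAL_ALPHABET)) == 19

    def test_constant_feature_gives_no_cuts(self):
        rec = record_from_values([1.0] * 20)
        assert enumerate_cuts(rec, CANONICAL_ALPHABET) == []

    @pytest.mark.parametrize("seed", range(8))
    def test_cut_count_equals_strict_increases(self, seed):
        rec = random_record(seed, tie_fraction=0.4)
        ordered = sorted(rec.values.values())
        expected = sum(
            1 for a, b in zip(ordered, ordered[1:]) if b > a
        )
        assert len(enumerate_cuts(rec, CANONICAL_ALPHABET)) == expected

    @pytest.mark.parametrize("seed", range(8))
    def test_cuts_are_realizable_and_thresholds_monotone(self, seed):
        rec = random_record(seed, tie_fraction=0.3)
        cuts = enumerate_cuts(rec, CANONICAL_ALPHABET)
        thresholds = []
        for cut in cuts:
            low = [rec.values[r] for r, b in zip(CANONICAL_ALPHABET, cut.membership) if b == 0]
            high = [rec.values[r] for r, b in zip(CANONICAL_ALPHABET, cut.membership) if b == 1]
            assert min(high) > max(low)
            assert cut.threshold == max(low)
            assert cut.gap == pytest.approx(min(high) - max(low))
            assert len(low) == cut.cut_size
            thresholds.append(cut.threshold)
        assert thresholds == sorted(thresholds)


class TestScoreCuts:
    def test_distinct_gaps_score_zero_to_eighteen(self):
        # gaps 2**i are all distinct: scores must be exactly {0..18}
        values = [float(sum(2**j for j in range(i))) for i in range(20)]
        cuts = score_cuts(enumerate_cuts(record_from_values(values), CANONICAL_ALPHABET))
        assert sorted(c.score for c in cuts) == list(range(19))
        top = max(cuts, key=lambda c: c.gap)
        assert top.score == 18

    def test_equal_gaps_all_score_zero(self, ascending_record):
        cuts = score_cuts(enumerate_cuts(ascending_record, CANONICAL_ALPHABET))
        assert {c.score for c in cuts} == {0}

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_pairwise_counting_oracle(self, seed):
        rec = random_record(seed, tie_fraction=0.25)
        cuts = score_cuts(enumerate_cuts(rec, CANONICAL_ALPHABET))
        for c in cuts:
            oracle = sum(1 for other in cuts if other.gap < c.gap)
            assert c.score == oracle
            assert 0 <= c.score <= len(cuts) - 1

    def test_mixed_accessions_rejected(self, ascending_record):
        a = enumerate_cuts(ascending_record, CANONICAL_ALPHABET)
        b = enumerate_cuts(
            record_from_values(range(1, 21), accession="OTHER0001"),
            CANONICAL_ALPHABET,
        )
        with pytest.raises(SeparationError):
            score_cuts(a + b)


class TestCandidatePool:
    def test_size_filter_keeps_13_of_19(self, single_record_table):
        pool = candidate_pool(single_record_table, mode="cuts", k=19)
        assert len(pool) == 13
        assert {c.cut_size for c in pool} == set(range(4, 17))

    def test_top_k_bound_per_feature(self):
        table = generate_random_table(n_residues=N, n_features=2, seed=5)
        pool = candidate_pool(table, mode="cuts", k=3)
        assert len(pool) <= 6
        per_feature = {}
        for sep in pool:
            per_feature[sep.accession] = per_feature.get(sep.accession, 0) + 1
        assert all(v <= 3 for v in per_feature.values())

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_filter_then_sort_oracle(self, seed):
        table = generate_random_table(n_residues=N, n_features=5, seed=seed)
        k, (lo, hi) = 3, default_size_bounds(N, 5)
        expected = []
        for rec in table.records:
            cuts = score_cuts(enumerate_cuts(rec, table.alphabet))
            ok = [c for c in cuts if lo <= c.cut_size <= hi and lo <= N - c.cut_size <= hi]
            ok.sort(key=lambda c: (-c.gap, -c.score, c.cut_size))
            expected.extend(ok[:k])
        expected = deduplicate_pool(expected)
        assert candidate_pool(table, mode="cuts", k=k) == expected

    def test_median_mode_one_separation_per_feature(self):
        table = generate_random_table(n_residues=N, n_features=4, seed=2)
        pool = candidate_pool(table, mode="median")
        assert len(pool) == 4
        assert all(s.is_median for s in pool)

    def test_median_mode_skips_degenerate_features(self, planted):
        table, _ = planted  # includes constant-ish NOISE features
        pool = candidate_pool(table, mode="median")
        assert {s.accession for s in pool} == set(
            a for a in table.accessions if a.startswith("PLANT")
        )

    def test_median_cut_flag_survives_cuts_mode(self, planted):
        table, _ = planted
        pool = candidate_pool(table, mode="cuts", k=3)
        flagged = [s for s in pool if s.is_median]
        # balanced planted planes: the band cut is the median cut and has
        # the top gap, so it must appear flagged in the pool
        assert len(flagged) == 5

    def test_include_median_forces_median_cut(self):
        # median cut has a tiny gap here, so top-1 would normally drop it
        values = list(range(1, 21))
        values[-1] = 100.0
        table = FeatureTable(
            alphabet=CANONICAL_ALPHABET, records=[record_from_values(values)]
        )
        bare = candidate_pool(table, mode="cuts", k=1)
        assert not any(s.is_median for s in bare)
        forced = candidate_pool(table, mode="cuts", k=1, include_median=True)
        assert any(s.is_median for s in forced)

    def test_empty_pool_is_an_error(self):
        table = FeatureTable(
            alphabet=CANONICAL_ALPHABET,
            records=[record_from_values([1.0] * 20)],
        )
        with pytest.raises(SeparationError, match="empty candidate pool"):
            candidate_pool(table, mode="cuts", k=3)


class TestDeduplicatePool:
    def test_identical_vectors_keep_highest_score(self, ascending_record):
        a = score_cuts(enumerate_cuts(ascending_record, CANONICAL_ALPHABET))
        doubled = record_from_values(
            [2 * v for v in range(1, 21)], accession="ZOTHER001"
        )
        b = score_cuts(enumerate_cuts(doubled, CANONICAL_ALPHABET))
        # same rankings -> identical membership vectors pairwise
        out = deduplicate_pool([a[9], b[9]])
        assert len(out) == 1
        # equal scores: tie broken by lexicographically smaller accession
        assert out[0].accession == "TEST00001"

    def test_distinct_vectors_unchanged(self, ascending_record):
        cuts = score_cuts(enumerate_cuts(ascending_record, CANONICAL_ALPHABET))
        assert deduplicate_pool(cuts) == sorted(cuts, key=lambda s: s.key)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_group_by_vector_oracle(self, seed):
        rng = np.random.default_rng(seed)
        table = generate_random_table(n_residues=N, n_features=4, seed=seed)
        pool = []
        for rec in table.records:
            pool.extend(score_cuts(enumerate_cuts(rec, table.alphabet)))
        pool = [pool[i] for i in rng.choice(len(pool), size=30)]
        groups = {}
        for sep in pool:
            groups.setdefault(sep.membership, []).append(sep)
        expected = {
            min(g, key=lambda s: (-s.score, s.accession, s.cut_size)).key
            for g in groups.values()
        }
        assert {s.key for s in deduplicate_pool(pool)} == expected
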
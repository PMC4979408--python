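"""Weighted-KS enrichment, combined scores, ranking and leading edges."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from diffconnect import (
    FixtureSpec,
    GeneSignature,
    RankedGeneList,
    connectivity,
    enrichment_score,
    gen_compound_instances,
    leading_edge,
    null_distribution,
    rank_instances,
    results_table,
)
from diffconnect.connectivity import ConnectivityResult, read_scores_tsv, write_scores_tsv
from diffconnect.errors import (
    DegenerateQueryError,
    EmptyOverlapError,
    ValidationError,
)
from conftest import make_ranked


class TestEnrichmentScore:
    def test_hand_stepped_five_gene_walk(self, es_oracle):
        # g1..g5 with metrics 3,2,1,-1,-2; query {g2, g5}; p=1:
        # steps -1/3, +1/2, -1/3, -1/3, +1/2 -> extreme -1/2 at position 4
        ranked = RankedGeneList(["g1", "g2", "g3", "g4", "g5"], [3, 2, 1, -1, -2])
        result = enrichment_score(ranked, {"g2", "g5"}, p=1)
        expected_es, expected_peak = es_oracle(
            ranked.gene_symbols, ranked.metric_values, {"g2", "g5"}, p=1
        )
        assert expected_es == pytest.approx(-0.5, abs=1e-15)
        assert result.es == pytest.approx(expected_es, abs=1e-15)
        assert result.peak_position == expected_peak == 4

    @pytest.mark.parametrize("p", [0, 1])
    def test_top_k_query_scores_exactly_one(self, ranked_factory, p):
        ranked = ranked_factory(200)
        result = enrichment_score(ranked, ranked.gene_symbols[:20], p=p)
        assert result.es == 1.0
        assert result.hits_found == 20 and result.hits_missing == 0

    @pytest.mark.parametrize("p", [0, 1])
    def test_bottom_k_query_scores_exactly_minus_one(self, ranked_factory, p):
        ranked = ranked_factory(200)
        assert enrichment_score(ranked, ranked.gene_symbols[-20:], p=p).es == -1.0

    def test_absent_query_genes_dropped_and_counted(self, ranked_factory):
        ranked = ranked_factory(50)
        query = set(ranked.gene_symbols[:5]) | {"NOT_THERE_1", "NOT_THERE_2"}
        result = enrichment_score(ranked, query)
        assert result.hits_found == 5 and result.hits_missing == 2

    def test_empty_overlap_is_an_error(self, ranked_factory):
        with pytest.raises(EmptyOverlapError):
            enrichment_score(ranked_factory(10), {"nope"})

    def test_query_covering_whole_list_is_degenerate(self, ranked_factory):
        ranked = ranked_factory(10)
        with pytest.raises(DegenerateQueryError):
            enrichment_score(ranked, set(ranked.gene_symbols))

    @given(
        n=st.integers(5, 50),
        seed=st.integers(0, 10_000),
        p=st.sampled_from([0, 1]),
    )
    def test_streaming_matches_bruteforce_oracle(self, n, seed, p):
        from conftest import es_running_sum_oracle as es_oracle

        rng = np.random.default_rng(seed)
        ranked = make_ranked(n, seed=seed)
        k = int(rng.integers(1, n))
        query = set(rng.choice(ranked.gene_symbols, size=k, replace=False))
        result = enrichment_score(ranked, query, p=p)
        expected_es, expected_peak = es_oracle(
            ranked.gene_symbols, ranked.metric_values, query, p
        )
        assert result.es == pytest.approx(expected_es, abs=1e-12)
        assert result.peak_position == expected_peak
        assert -1.0 <= result.es <= 1.0

    def test_all_zero_hit_metrics_fall_back_to_equal_weights(self):
        # hits sit where the metric is exactly zero; p=1 weights all vanish
        ranked = RankedGeneList(list("abcdef"), [2, 1, 0, 0, -1, -2])
        result = enrichment_score(ranked, {"c", "d"}, p=1)
        assert -1.0 <= result.es <= 1.0


class TestLeadingEdge:
    def test_query_at_top_returns_whole_query(self, ranked_factory):
        ranked = ranked_factory(100)
        query = ranked.gene_symbols[:10]
        assert leading_edge(ranked, query) == query

    def test_single_gene_query(self, ranked_factory):
        ranked = ranked_factory(50)
        g = ranked.gene_symbols[7]
        assert leading_edge(ranked, {g}) == [g]

    def test_planted_overlap_recovered(self, ranked_factory):
        # 12 query genes in the top 15 positions drive a positive peak; the
        # remaining 8 query genes sit mid-list, after the peak
        ranked = ranked_factory(100)
        planted = [ranked.gene_symbols[i] for i in range(12)]
        stragglers = [ranked.gene_symbols[i] for i in range(55, 63)]
        got = leading_edge(ranked, set(planted) | set(stragglers))
        assert got == planted

    def test_negative_es_takes_tail_genes(self, ranked_factory):
        ranked = ranked_factory(100)
        query = ranked.gene_symbols[-10:]
        assert leading_edge(ranked, query) == query


class TestConnectivity:
    def test_combined_is_half_the_score_difference(self, ranked_factory):
        ranked = ranked_factory(200)
        sig = GeneSignature(
            tuple(ranked.gene_symbols[:20]), tuple(ranked.gene_symbols[-20:]), x=20,
            source_id="mimic",
        )
        result = connectivity(ranked, sig)
        assert result.score_up == 1.0 and result.score_down == -1.0
        assert result.combined == 1.0
        assert not result.same_sign

    def test_equal_scores_combine_to_zero(self, ranked_factory):
        ranked = ranked_factory(200)
        genes = ranked.gene_symbols
        # both sets interleaved identically around the top
        sig = GeneSignature(tuple(genes[0:20:2]), tuple(genes[1:21:2]), x=10)
        result = connectivity(ranked, sig)
        assert result.combined == pytest.approx(
            (result.score_up - result.score_down) / 2, abs=0
        )

    def test_swapping_sets_negates_combined(self, ranked_factory):
        ranked = ranked_factory(300)
        rng = np.random.default_rng(99)
        for _ in range(100):
            both = rng.choice(ranked.gene_symbols, size=40, replace=False)
            sig = GeneSignature(tuple(both[:20]), tuple(both[20:]), x=20)
            fwd = connectivity(ranked, sig)
            rev = connectivity(ranked, sig.swapped())
            assert rev.combined == -fwd.combined

    def test_error_names_the_failing_set(self, ranked_factory):
        ranked = ranked_factory(50)
        sig = GeneSignature(("missing1", "missing2"), tuple(ranked.gene_symbols[:2]),
                            x=2, source_id="bad")
        with pytest.raises(EmptyOverlapError, match="up set of bad"):
            connectivity(ranked, sig)


def _result(source_id, combined):
    return ConnectivityResult(
        source_id=source_id, score_up=0.0, score_down=0.0, combined=combined,
        leading_edge_up=(), leading_edge_down=(), n_hits_up=1, n_hits_down=1,
    )


class TestRankInstances:
    def test_ranks_follow_combined_score(self):
        results = [_result("a", 0.9), _result("b", -0.9), _result("c", 0.1)]
        ranked = {r.source_id: r for r in rank_instances(results)}
        assert [ranked[s].rank_positive for s in "abc"] == [1, 3, 2]
        assert [ranked[s].rank_negative for s in "abc"] == [3, 1, 2]

    def test_ties_resolved_by_source_id_in_both_directions(self):
        results = [_result(s, 0.5) for s in ("z", "a", "m")]
        ranked = rank_instances(results)
        assert [r.source_id for r in ranked] == ["a", "m", "z"]
        assert [r.rank_positive for r in ranked] == [1, 2, 3]
        assert [r.rank_negative for r in ranked] == [1, 2, 3]

    def test_ranks_are_a_permutation(self):
        rng = np.random.default_rng(1)
        results = [_result(f"i{k}", float(c)) for k, c in enumerate(rng.normal(size=40))]
        ranked = rank_instances(results)
        assert sorted(r.rank_positive for r in ranked) == list(range(1, 41))
        assert sorted(r.rank_negative for r in ranked) == list(range(1, 41))

    def test_per_compound_collapse_keeps_extreme_instance(self):
        results = [_result("i1", 0.2), _result("i2", 0.8), _result("i3", -0.5)]
        per_compound = {"i1": "cpdA", "i2": "cpdA", "i3": "cpdB"}
        ranked = rank_instances(results, per_compound=per_compound)
        assert {r.source_id for r in ranked} == {"i2", "i3"}

    def test_large_cohort_planted_mimic_attains_rank_one(self, ranked1000):
        # cohort cardinality mirrors an instance-level compound collection
        spec = FixtureSpec(seed=17, n_instances=6100)
        inst = gen_compound_instances(spec, ranked1000)
        results = rank_instances([connectivity(ranked1000, s) for s in inst.signatures])
        assert inst.truth[results[0].source_id] == "mimic"


class TestNullDistribution:
    def test_deterministic_under_seed(self, ranked1000):
        a = null_distribution(ranked1000, 50, 20, seed=5)
        b = null_distribution(ranked1000, 50, 20, seed=5)
        np.testing.assert_array_equal(a, b)

    def test_bounded(self, ranked1000):
        scores = null_distribution(ranked1000, 50, 50, seed=2)
        assert np.all(scores >= -1.0) and np.all(scores <= 1.0)

    def test_set_size_must_be_smaller_than_list(self, ranked_factory):
        with pytest.raises(ValidationError):
            null_distribution(ranked_factory(10), 10, 5, seed=0)


def test_scores_tsv_round_trip(tmp_path, ranked_factory):
    ranked = ranked_factory(200)
    sigs = [
        GeneSignature(tuple(ranked.gene_symbols[:10]), tuple(ranked.gene_symbols[-10:]),
                      x=10, source_id="s1"),
        GeneSignature(tuple(ranked.gene_symbols[20:30]), tuple(ranked.gene_symbols[50:60]),
                      x=10, source_id="s2"),
    ]
    results = rank_instances([connectivity(ranked, s) for s in sigs])
    f = tmp_path / "scores.tsv"
    write_scores_tsv(results, f)
    back = read_scores_tsv(f)
    assert back == results
    table = results_table(results)
    assert list(table["source_id"]) == [r.source_id for r in results]
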
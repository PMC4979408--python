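"""Ranked-list construction and signature extraction."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from diffconnect import (
    ExpressionProfile,
    PhenotypeAssignment,
    ProbeMap,
    RankedGeneList,
    collapse_probes,
    compound_ranked_profile,
    differential_ranking,
    extract_signature,
)
from diffconnect.errors import ClassCountError, SignatureSizeError, ValidationError
from diffconnect.signatures import read_rnk, write_rnk


def profile(probes, values, samples=None):
    values = np.asarray(values, dtype=float)
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return ExpressionProfile(list(probes), samples, values)


class TestCollapseProbes:
    def test_max_of_two_probes(self):
        p = profile(["p1", "p2"], [[1.0, 5.0], [3.0, 2.0]])
        pm = ProbeMap({"p1": "G", "p2": "G"})
        collapsed, n_dropped = collapse_probes(p, pm, mode="max")
        assert collapsed.probe_ids == ["G"]
        np.testing.assert_array_equal(collapsed.values, [[3.0, 5.0]])
        assert n_dropped == 0

    def test_one_to_one_map_relabels_rows(self):
        p = profile(["p1", "p2"], [[1.0, 2.0], [3.0, 4.0]])
        pm = ProbeMap({"p1": "A", "p2": "B"})
        collapsed, _ = collapse_probes(p, pm)
        assert collapsed.probe_ids == ["A", "B"]
        np.testing.assert_array_equal(collapsed.values, p.values)

    def test_unmapped_probes_dropped_and_counted(self):
        # 5 probes: p1,p2 -> G1; p3 -> G2; p4,p5 unmapped
        p = profile(
            ["p1", "p2", "p3", "p4", "p5"],
            [[1], [2], [3], [4], [5]],
        )
        pm = ProbeMap({"p1": "G1", "p2": "G1", "p3": "G2"})
        collapsed, n_dropped = collapse_probes(p, pm)
        assert n_dropped == 2
        assert collapsed.probe_ids == ["G1", "G2"]

    def test_max_collapse_idempotent_on_collapsed_input(self):
        p = profile(["p1", "p2"], [[1.0, 5.0], [3.0, 2.0]])
        pm = ProbeMap({"p1": "G1", "p2": "G2"})
        once, _ = collapse_probes(p, pm)
        identity = ProbeMap({g: g for g in once.probe_ids})
        twice, _ = collapse_probes(once, identity)
        np.testing.assert_array_equal(once.values, twice.values)
        assert once.probe_ids == twice.probe_ids

    def test_mean_mode(self):
        p = profile(["p1", "p2"], [[1.0], [3.0]])
        pm = ProbeMap({"p1": "G", "p2": "G"})
        collapsed, _ = collapse_probes(p, pm, mode="mean")
        assert collapsed.values[0, 0] == 2.0

    def test_zero_mappable_probes_error(self):
        p = profile(["p1"], [[1.0]])
        with pytest.raises(ValidationError, match="no probe maps"):
            collapse_probes(p, ProbeMap({"q": "G"}))


class TestDifferentialRanking:
    def test_log2_ratio_on_prelogged_data_is_mean_difference(self):
        p = profile(["G1"], [[4.0, 4.0, 2.0, 2.0]])
        phen = PhenotypeAssignment(["A", "B"], [0, 0, 1, 1])
        ranked = differential_ranking(p, phen, "log2_ratio_of_classes", pre_logged=True)
        assert ranked.metric_values[0] == 2.0

    def test_identical_classes_give_zero_metrics_in_tie_order(self):
        values = np.tile([[5.0], [3.0], [4.0]], (1, 6))
        p = profile(["gB", "gA", "gC"], values)
        phen = PhenotypeAssignment(["x", "y"], [0, 0, 0, 1, 1, 1])
        ranked = differential_ranking(p, phen, "signal2noise")
        assert np.all(ranked.metric_values == 0.0)
        assert ranked.gene_symbols == ["gA", "gB", "gC"]  # symbol tie-break

    def test_signal2noise_matches_per_gene_recomputation(self):
        rng = np.random.default_rng(11)
        values = rng.lognormal(3, 0.5, size=(10, 8))
        genes = [f"g{i}" for i in range(10)]
        p = profile(genes, values)
        phen = PhenotypeAssignment(["A", "B"], [0] * 4 + [1] * 4)
        ranked = differential_ranking(p, phen, "signal2noise")
        # independent per-gene recomputation with the GSEA variance floor
        expected = {}
        for i, g in enumerate(genes):
            a, b = values[i, :4], values[i, 4:]
            ma, mb = a.mean(), b.mean()
            sa = max(a.std(ddof=1), 0.2 * abs(ma) if ma != 0 else 0.2)
            sb = max(b.std(ddof=1), 0.2 * abs(mb) if mb != 0 else 0.2)
            expected[g] = (ma - mb) / (sa + sb)
        for g, v in zip(ranked.gene_symbols, ranked.metric_values):
            assert v == pytest.approx(expected[g], abs=1e-12)
        assert list(ranked.metric_values) == sorted(expected.values(), reverse=True)

    def test_metric_values_non_increasing(self):
        rng = np.random.default_rng(3)
        p = profile([f"g{i}" for i in range(50)], rng.lognormal(3, 1, size=(50, 6)))
        phen = PhenotypeAssignment(["A", "B"], [0, 0, 0, 1, 1, 1])
        ranked = differential_ranking(p, phen, "signal2noise")
        assert np.all(np.diff(ranked.metric_values) <= 0)

    def test_swapping_classes_negates_metrics_and_reverses_order(self):
        rng = np.random.default_rng(5)
        p = profile([f"g{i}" for i in range(30)], rng.lognormal(3, 1, size=(30, 6)))
        fwd = PhenotypeAssignment(["A", "B"], [0, 0, 0, 1, 1, 1])
        rev = PhenotypeAssignment(["B", "A"], [1, 1, 1, 0, 0, 0])
        r1 = differential_ranking(p, fwd, "signal2noise")
        r2 = differential_ranking(p, rev, "signal2noise")
        m1 = dict(zip(r1.gene_symbols, r1.metric_values))
        m2 = dict(zip(r2.gene_symbols, r2.metric_values))
        for g in m1:
            assert m2[g] == pytest.approx(-m1[g], abs=1e-15)
        assert r2.gene_symbols == list(reversed(r1.gene_symbols))  # no ties here

    def test_more_than_two_classes_rejected(self):
        p = profile(["g"], [[1, 2, 3]])
        phen = PhenotypeAssignment(["A", "B", "C"], [0, 1, 2])
        with pytest.raises(ClassCountError):
            differential_ranking(p, phen)

    def test_signal2noise_needs_three_per_class(self):
        p = profile(["g"], [[1, 2, 3, 4]])
        phen = PhenotypeAssignment(["A", "B"], [0, 0, 1, 1])
        with pytest.raises(ValidationError, match=">= 3"):
            differential_ranking(p, phen, "signal2noise")


class TestCompoundRankedProfile:
    def test_log2_of_fourfold_change(self):
        t = profile(["G"], [[8.0, 8.0]])
        v = profile(["G"], [[2.0, 2.0]])
        result = compound_ranked_profile(t, v)
        assert result.ranked.metric_values[0] == 2.0

    def test_equal_profiles_give_zero_metrics(self):
        t = profile(["G1", "G2"], [[4.0], [6.0]])
        result = compound_ranked_profile(t, t)
        assert np.all(result.ranked.metric_values == 0.0)

    def test_matches_per_gene_recomputation(self):
        rng = np.random.default_rng(8)
        genes = [f"g{i}" for i in range(20)]
        tv = rng.lognormal(3, 0.5, size=(20, 3))
        vv = rng.lognormal(3, 0.5, size=(20, 3))
        result = compound_ranked_profile(profile(genes, tv), profile(genes, vv))
        expected = {g: math.log2(tv[i].mean() / vv[i].mean()) for i, g in enumerate(genes)}
        for g, m in zip(result.ranked.gene_symbols, result.ranked.metric_values):
            assert m == pytest.approx(expected[g], abs=1e-12)

    def test_nonpositive_vehicle_mean_excluded_and_counted(self):
        t = profile(["G1", "G2"], [[4.0], [4.0]])
        v = profile(["G1", "G2"], [[2.0], [0.0]])
        result = compound_ranked_profile(t, v)
        assert result.n_excluded == 1
        assert result.ranked.gene_symbols == ["G1"]

    def test_different_universes_rejected(self):
        with pytest.raises(ValidationError, match="universe"):
            compound_ranked_profile(profile(["A"], [[1.0]]), profile(["B"], [[1.0]]))


class TestExtractSignature:
    def test_default_size_yields_50_up_50_down(self, ranked_factory):
        sig = extract_signature(ranked_factory(1000))
        assert len(sig.up_genes) == 50 and len(sig.down_genes) == 50
        assert not set(sig.up_genes) & set(sig.down_genes)

    def test_boundary_list_of_exactly_2x(self, ranked_factory):
        ranked = ranked_factory(10)
        sig = extract_signature(ranked, x=5)
        assert sig.up_genes == tuple(ranked.gene_symbols[:5])
        assert sig.down_genes == tuple(ranked.gene_symbols[5:])

    def test_too_short_list_names_required_minimum(self, ranked_factory):
        with pytest.raises(SignatureSizeError, match="100"):
            extract_signature(ranked_factory(99))

    @given(n=st.integers(2, 400), frac=st.floats(0.01, 0.5), seed=st.integers(0, 99))
    def test_sets_disjoint_and_of_size_x(self, n, frac, seed):
        from conftest import make_ranked

        x = max(1, int(n * frac))
        if n < 2 * x:
            return
        sig = extract_signature(make_ranked(n, seed=seed), x=x)
        assert len(sig.up_genes) == x == len(sig.down_genes)
        assert not set(sig.up_genes) & set(sig.down_genes)


def test_rnk_round_trip(tmp_path, ranked_factory):
    ranked = ranked_factory(20)
    f = tmp_path / "list.rnk"
    write_rnk(ranked, f)
    back = read_rnk(f)
    assert back.gene_symbols == ranked.gene_symbols
    np.testing.assert_array_equal(back.metric_values, ranked.metric_values)
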
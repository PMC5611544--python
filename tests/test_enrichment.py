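import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from coexnet.clustering import ClusterSet
from coexnet.enrichment import (
    GeneSetCollection, annotate_clusters, best_terms, bh_adjust,
    enrichment_score, filter_genesets, hypergeom_overlap,
    identify_responsive_clusters, motif_presence_filter, read_gmt,
    read_motif_hits, write_gmt,
)


def enumerate_tail(N, n_i, n_j, m):
    """Oracle: P(overlap >= m) by enumerating all C(N, n_j) draws."""
    universe = range(N)
    set_i = set(range(n_i))
    hits = total = 0
    for draw in itertools.combinations(universe, n_j):
        total += 1
        if len(set_i & set(draw)) >= m:
            hits += 1
    return hits / total


class TestHypergeomOverlap:
    def test_zero_overlap_is_certain(self):
        assert hypergeom_overlap(100, 10, 5, 0) == 1.0

    def test_small_worked_example_matches_enumeration(self):
        p = hypergeom_overlap(10, 5, 4, 4)
        assert p == pytest.approx(5 / 210)
        assert p == pytest.approx(enumerate_tail(10, 5, 4, 4))

    def test_forced_complete_overlap(self):
        assert hypergeom_overlap(7, 7, 7, 7) == pytest.approx(1.0)

    @pytest.mark.parametrize("N", range(2, 13))
    def test_matches_enumeration_for_all_small_universes(self, N):
        for n_i in range(N + 1):
            for n_j in range(N + 1):
                for m in range(min(n_i, n_j) + 1):
                    expected = enumerate_tail(N, n_i, n_j, m)
                    assert hypergeom_overlap(N, n_i, n_j, m) == \
                        pytest.approx(expected, abs=1e-12)

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            hypergeom_overlap(10, 5, 4, 5)

    def test_growing_overlap_never_increases_p(self):
        ps = [hypergeom_overlap(1000, 50, 40, m) for m in range(0, 41)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))


class TestBhAdjust:
    def test_hand_computed_step_up(self):
        # min over j >= i of p_j * n / j, all equal 0.04
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.3])[0] == pytest.approx(0.3)

    def test_all_ones_stay_ones(self):
        np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_empty_input(self):
        assert len(bh_adjust([])) == 0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=2,
                    max_size=30))
    def test_order_preserving_under_permutation(self, pvalues):
        q = bh_adjust(pvalues)
        perm = np.random.default_rng(0).permutation(len(pvalues))
        q_perm = bh_adjust(np.asarray(pvalues)[perm])
        np.testing.assert_allclose(q_perm, q[perm], atol=1e-12)


def test_es_threshold_matches_q_threshold():
    # ES > 1.3 <=> q < 10^-1.3 (about 0.05)
    assert enrichment_score(10 ** -1.3) == pytest.approx(1.3)
    assert enrichment_score(0.049) > 1.3 > enrichment_score(0.051)


class TestFilterGenesets:
    def _coll(self, sizes):
        return GeneSetCollection(
            {f"s{k}": frozenset(f"g{k}_{i}" for i in range(n))
             for k, n in enumerate(sizes)})

    def test_boundary_sizes(self):
        coll = filter_genesets(self._coll([9, 10, 1500, 1501]))
        kept_sizes = sorted(len(s) for s in coll.sets.values())
        assert kept_sizes == [10, 1500]

    def test_empty_collection(self):
        assert len(filter_genesets(GeneSetCollection({}))) == 0

    def test_sweep_preset_is_strictly_below_500(self):
        coll = filter_genesets(self._coll([499, 500]), min_size=0,
                               max_size=500, strict_max=True)
        assert sorted(len(s) for s in coll.sets.values()) == [499]

    def test_sizes_computed_within_universe(self):
        coll = GeneSetCollection({"s": frozenset(["a", "b", "out"])},
                                 universe=frozenset("ab"))
        assert len(filter_genesets(coll, min_size=3).sets) == 0
        assert len(filter_genesets(coll, min_size=2).sets) == 1


class TestAnnotateClusters:
    def test_perfect_overlap_is_best_term(self):
        clusters = ClusterSet([("a", "b", "c")], ["d", "e", "f"], 0.5)
        genesets = GeneSetCollection({"match": frozenset("abc"),
                                      "other": frozenset("def")})
        results = annotate_clusters(clusters, genesets)
        assert best_terms(results) == {"Cluster0001": "match"}

    def test_zero_overlap_yields_no_annotations(self):
        clusters = ClusterSet([("a", "b", "c")], ["d", "e", "f"], 0.5)
        genesets = GeneSetCollection({"other": frozenset("def")})
        results = annotate_clusters(clusters, genesets)
        assert not results["annotated"].any()

    def test_matches_independent_oracle(self):
        """3 clusters x 4 sets with planted overlaps vs a from-scratch
        reimplementation of the tail probability and step-up correction."""
        rng = np.random.default_rng(13)
        universe = [f"g{i}" for i in range(60)]
        members = [tuple(universe[0:10]), tuple(universe[10:25]),
                   tuple(universe[25:33])]
        clusters = ClusterSet(list(members),
                              [g for g in universe
                               if g not in set().union(*map(set, members))],
                              0.5)
        sets = {f"S{k}": frozenset(rng.choice(universe, size=12, replace=False))
                for k in range(4)}
        genesets = GeneSetCollection(sets)
        results = annotate_clusters(clusters, genesets,
                                    universe=universe).set_index(
                                        ["cluster_id", "set_name"])

        def oracle_tail(N, K, n, m):
            denom = math.comb(N, n)
            return sum(math.comb(K, x) * math.comb(N - K, n - x)
                       for x in range(m, min(K, n) + 1)) / denom

        raw = {}
        for cid, cgenes in clusters.as_dict().items():
            for name, sgenes in sets.items():
                m = len(set(cgenes) & sgenes)
                raw[(cid, name)] = oracle_tail(60, len(cgenes), len(sgenes), m)
        # hand step-up BH
        items = sorted(raw.items(), key=lambda kv: kv[1])
        n = len(items)
        qs = {}
        running = 1.0
        for rank in range(n, 0, -1):
            key, p = items[rank - 1]
            running = min(running, p * n / rank)
            qs[key] = running
        for key, p in raw.items():
            assert results.loc[key, "p"] == pytest.approx(p, abs=1e-12)
            assert results.loc[key, "q"] == pytest.approx(qs[key], abs=1e-12)

    def test_cluster_gene_outside_universe_is_an_error(self):
        clusters = ClusterSet([("a", "b", "c")], [], 0.5)
        genesets = GeneSetCollection({"s": frozenset("ab")})
        with pytest.raises(ValueError, match="absent from the universe"):
            annotate_clusters(clusters, genesets, universe=["a", "b"])


class TestResponsiveClusters:
    def test_strongly_overlapping_up_list_scores_positive(self):
        universe = [f"g{i}" for i in range(20000)]
        cluster_genes = tuple(universe[:20])
        clusters = ClusterSet([cluster_genes], universe[20:120], 0.5)
        de_lists = {"seedling_up": universe[:200]}
        result = identify_responsive_clusters(
            clusters, de_lists, {"seedling_up": "up"}, universe,
            q_cutoff=0.001)
        row = result.iloc[0]
        assert row["q"] < 1e-10
        assert row["score"] > 0
        assert row["responsive"]

    def test_disjoint_lists_score_zero(self):
        universe = [f"g{i}" for i in range(100)]
        clusters = ClusterSet([tuple(universe[:5])], universe[5:50], 0.5)
        result = identify_responsive_clusters(
            clusters, {"up": universe[50:60]}, {"up": "up"}, universe, 0.001)
        assert (result["score"] == 0).all()
        assert not result["responsive"].any()

    def test_down_direction_flips_sign_only(self):
        universe = [f"g{i}" for i in range(20000)]
        clusters = ClusterSet([tuple(universe[:20])], universe[20:120], 0.5)
        kwargs = dict(universe=universe, q_cutoff=0.001)
        up = identify_responsive_clusters(
            clusters, {"L": universe[:200]}, {"L": "up"}, **kwargs)
        down = identify_responsive_clusters(
            clusters, {"L": universe[:200]}, {"L": "down"}, **kwargs)
        assert down.iloc[0]["score"] == pytest.approx(-up.iloc[0]["score"])

    def test_unknown_direction_label_rejected(self):
        universe = ["a", "b", "c"]
        clusters = ClusterSet([], universe, 0.5)
        with pytest.raises(ValueError, match="direction"):
            identify_responsive_clusters(clusters, {"L": ["a"]},
                                         {"L": "sideways"}, universe, 0.01)


class TestMotifPresence:
    def _clusters(self):
        return ClusterSet([("g1", "g2", "g3", "g4", "g5")], [], 0.5)

    def test_sixty_percent_kept(self):
        hits = {g: {"M1"} for g in ("g1", "g2", "g3")}
        assert motif_presence_filter(self._clusters(), hits) == \
            {"Cluster0001": ["M1"]}

    def test_exactly_half_dropped(self):
        clusters = ClusterSet([("g1", "g2", "g3", "g4")], [], 0.5)
        hits = {g: {"M1"} for g in ("g1", "g2")}
        assert motif_presence_filter(clusters, hits) == {"Cluster0001": []}

    def test_empty_hit_table(self):
        assert motif_presence_filter(self._clusters(), {}) == \
            {"Cluster0001": []}


def test_gmt_round_trip_and_motif_reader(tmp_path):
    coll = GeneSetCollection({"setA": frozenset("abc"), "setB": frozenset("bcd")},
                             {"setA": "first", "setB": "second"})
    path = tmp_path / "sets.gmt"
    write_gmt(coll, path)
    back = read_gmt(path)
    assert back.sets == coll.sets
    assert back.descriptions["setA"] == "first"

    hits_path = tmp_path / "hits.tsv"
    hits_path.write_text("gene_id\tmotif_id\ng1\tM1\ng1\tM2\ng2\tM1\n")
    assert read_motif_hits(hits_path) == {"g1": {"M1", "M2"}, "g2": {"M1"}}
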
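"""Cluster parsing, pair enumeration, closest outparalogs, aggregation."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from domarch.pairs import (
    ClusterTableError,
    HomologPair,
    OrthologCluster,
    OutparalogCutoffs,
    ScoreTable,
    closest_outparalogs,
    enumerate_within_cluster_pairs,
    mean_of_cluster_means,
    parse_clusters,
    split_one_to_one,
)


def cluster(cid, n_a, n_b, prefix=""):
    members = tuple(
        [(f"{prefix}a{i}", "spA") for i in range(n_a)]
        + [(f"{prefix}b{i}", "spB") for i in range(n_b)]
    )
    return OrthologCluster(cid, members)


def write_clusters_file(tmp_path, rows):
    path = tmp_path / "clusters.tsv"
    lines = ["cluster_id\tspecies\tprotein_id\tis_seed"]
    lines += ["\t".join(map(str, r)) for r in rows]
    path.write_text("\n".join(lines) + "\n")
    return path


class TestParseClusters:
    def test_one_to_one_cluster(self, tmp_path):
        path = write_clusters_file(
            tmp_path, [("c1", "spA", "a1", 1), ("c1", "spB", "b1", 1)]
        )
        (c,) = parse_clusters(path)
        assert c.is_one_to_one
        assert c.seed_pair == ("a1", "b1")

    def test_duplicated_cluster(self, tmp_path):
        path = write_clusters_file(
            tmp_path,
            [("c1", "spA", "a1", 1), ("c1", "spA", "a2", 0), ("c1", "spB", "b1", 1)],
        )
        (c,) = parse_clusters(path)
        assert not c.is_one_to_one
        assert sorted(c.members_of("spA")) == ["a1", "a2"]

    def test_single_species_cluster_is_error(self, tmp_path):
        path = write_clusters_file(tmp_path, [("c1", "spA", "a1", 1)])
        with pytest.raises(ClusterTableError, match="exactly 2"):
            parse_clusters(path)

    def test_protein_in_two_clusters_is_error(self, tmp_path):
        path = write_clusters_file(
            tmp_path,
            [
                ("c1", "spA", "a1", 1), ("c1", "spB", "b1", 1),
                ("c2", "spA", "a1", 1), ("c2", "spB", "b2", 1),
            ],
        )
        with pytest.raises(ClusterTableError, match="a1"):
            parse_clusters(path)


class TestEnumeratePairs:
    @pytest.mark.parametrize(
        "n_a,n_b,n_o,n_ip",
        [(2, 2, 4, 2), (1, 1, 1, 0), (3, 1, 3, 3)],
    )
    def test_pair_counts(self, n_a, n_b, n_o, n_ip):
        orth, inp = enumerate_within_cluster_pairs(cluster("c1", n_a, n_b))
        assert len(orth) == n_o
        assert len(inp) == n_ip
        assert all(p.pair_type == "O" for p in orth)
        assert all(p.pair_type == "iP" for p in inp)

    @settings(derandomize=True, max_examples=50)
    @given(st.integers(1, 6), st.integers(1, 6))
    def test_counts_match_combinatorics_and_are_unique(self, n_a, n_b):
        orth, inp = enumerate_within_cluster_pairs(cluster("c1", n_a, n_b))
        assert len(orth) == n_a * n_b
        assert len(inp) == math.comb(n_a, 2) + math.comb(n_b, 2)
        keys = [p.key for p in orth + inp]
        assert len(keys) == len(set(keys))


class TestClosestOutparalogs:
    def setup_method(self):
        self.clusters = [
            cluster("c1", 1, 1, prefix="x"),
            cluster("c2", 1, 1, prefix="y"),
        ]
        self.species = {"xa0": "spA", "xb0": "spB", "ya0": "spA", "yb0": "spB",
                        "za0": "spA"}

    def test_argmax_partner(self):
        scores = ScoreTable()
        scores.add("xa0", "ya0", 50.0)
        scores.add("xa0", "za0", 45.0)
        ops, _ = closest_outparalogs(self.clusters, scores, self.species)
        ops_for_x = [p for p in ops if "xa0" in (p.protein_1, p.protein_2)]
        assert {p.key for p in ops_for_x} == {("xa0", "ya0")}

    def test_below_bit_cutoff_yields_no_pair(self):
        scores = ScoreTable()
        scores.add("xa0", "za0", 35.0)
        ops, opx = closest_outparalogs(self.clusters, scores, self.species)
        assert not any("xa0" in p.key for p in ops)

    def test_exactly_at_cutoff_passes(self):
        scores = ScoreTable()
        scores.add("xa0", "za0", 40.0)
        ops, _ = closest_outparalogs(self.clusters, scores, self.species)
        assert any(p.key == ("xa0", "za0") for p in ops)

    def test_member_of_other_cluster_is_valid_partner(self):
        scores = ScoreTable()
        scores.add("xa0", "ya0", 60.0)  # ya0 sits in cluster c2
        ops, _ = closest_outparalogs(self.clusters, scores, self.species)
        assert any(p.key == ("xa0", "ya0") for p in ops)

    def test_same_cluster_member_excluded(self):
        scores = ScoreTable()
        scores.add("xa0", "xb0", 500.0)
        ops, opx = closest_outparalogs(self.clusters, scores, self.species)
        assert not any(p.key == ("xa0", "xb0") for p in ops + opx)

    def test_cross_species_partner_is_opx(self):
        scores = ScoreTable()
        scores.add("xa0", "yb0", 60.0)
        _, opx = closest_outparalogs(self.clusters, scores, self.species)
        assert any(p.key == ("xa0", "yb0") and p.pair_type == "oPx" for p in opx)

    def test_tie_breaks_to_lexicographically_smaller_id(self):
        scores = ScoreTable()
        scores.add("xa0", "za0", 50.0)
        scores.add("xa0", "ya0", 50.0)
        ops, _ = closest_outparalogs(self.clusters, scores, self.species)
        assert any(p.key == ("xa0", "ya0") for p in ops)

    def test_partner_choice_invariant_to_insertion_order(self):
        s1, s2 = ScoreTable(), ScoreTable()
        s1.add("xa0", "za0", 50.0)
        s1.add("xa0", "ya0", 55.0)
        s2.add("xa0", "ya0", 55.0)
        s2.add("xa0", "za0", 50.0)
        r1 = closest_outparalogs(self.clusters, s1, self.species)
        r2 = closest_outparalogs(self.clusters, s2, self.species)
        assert [p.key for p in r1[0]] == [p.key for p in r2[0]]

    def test_mutually_closest_pair_credits_both_clusters(self):
        scores = ScoreTable()
        scores.add("xa0", "ya0", 90.0)
        ops, _ = closest_outparalogs(self.clusters, scores, self.species)
        (pair,) = [p for p in ops if p.key == ("xa0", "ya0")]
        assert pair.cluster_ids == ("c1", "c2")

    def test_coverage_cutoffs_applied_when_present(self):
        scores = ScoreTable()
        scores.add("xa0", "za0", 80.0, overlap_frac=0.3, segment_frac=0.9)
        ops, _ = closest_outparalogs(self.clusters, scores, self.species)
        assert not any("za0" in p.key for p in ops)


def test_split_one_to_one():
    ones, dups = split_one_to_one([cluster("c1", 1, 1), cluster("c2", 2, 1)])
    assert [c.cluster_id for c in ones] == ["c1"]
    assert [c.cluster_id for c in dups] == ["c2"]
    assert split_one_to_one([]) == ([], [])


class TestMeanOfClusterMeans:
    def pair(self, cids, da):
        return HomologPair("p", "q", "O", tuple(cids), da_score=da)

    def test_simple_mean_of_means(self):
        agg, means = mean_of_cluster_means(
            [self.pair(["c1"], 0.75), self.pair(["c2"], 0.5)]
        )
        assert agg == pytest.approx(0.625)

    def test_equal_cluster_weighting(self):
        pairs = [self.pair(["c1"], 1.0), self.pair(["c1"], 0.0), self.pair(["c2"], 1.0)]
        agg, _ = mean_of_cluster_means(pairs)
        assert agg == pytest.approx(0.75)  # not the pair mean 0.666...

    def test_dual_cluster_pair_contributes_to_both(self):
        pairs = [
            self.pair(["c1"], 0.4),
            self.pair(["c2"], 0.8),
            self.pair(["c1", "c2"], 1.0),
        ]
        agg, means = mean_of_cluster_means(pairs)
        assert means["c1"] == pytest.approx(0.7)
        assert means["c2"] == pytest.approx(0.9)
        assert agg == pytest.approx(0.8)

    def test_aggregate_equals_inverse_size_weighted_pair_mean(self):
        pairs = [
            self.pair(["c1"], 0.2), self.pair(["c1"], 0.6),
            self.pair(["c2"], 1.0), self.pair(["c2"], 0.8), self.pair(["c2"], 0.9),
        ]
        agg, _ = mean_of_cluster_means(pairs)
        weights = {"c1": 1 / 2, "c2": 1 / 3}
        manual = sum(weights[p.cluster_ids[0]] * p.da_score for p in pairs) / 2
        assert agg == pytest.approx(manual)

    def test_missing_values_dropped(self):
        agg, _ = mean_of_cluster_means([self.pair(["c1"], 0.5), self.pair(["c1"], None)])
        assert agg == pytest.approx(0.5)

    def test_empty_input(self):
        assert mean_of_cluster_means([]) == (None, {})
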
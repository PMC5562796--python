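"""High-expression calling, communication edges, exclusiveness ranking."""

import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

import crosstalk as ct
from crosstalk.scnet import (
    build_network,
    call_high,
    edge_counts,
    exclusiveness,
    export_graphml,
    filter_involving,
    max_standardized_deviation_bound,
    rank_edges,
    type_profiles,
)


def _matrix(data, types):
    """genes x cells matrix with cells named <type>_<i> and annotations."""
    cells = []
    ann = []
    for t, n in types:
        cells += [f"{t}_{i}" for i in range(n)]
        ann += [t] * n
    m = pd.DataFrame(data, index=[f"g{i}" for i in range(len(data))], columns=cells)
    return m, pd.Series(ann, index=cells)


class TestTypeProfiles:
    def test_hand_computed_means(self):
        m, ann = _matrix([[1, 3, 10, 20], [0, 0, 4, 4]], [("A", 2), ("B", 2)])
        profiles, counts = type_profiles(m, ann)
        assert profiles.loc["g0", "A"] == 2.0
        assert profiles.loc["g0", "B"] == 15.0
        assert profiles.loc["g1", "B"] == 4.0
        assert counts["A"] == counts["B"] == 2

    def test_unannotated_cell_rejected(self):
        m, ann = _matrix([[1, 2, 3, 4]], [("A", 2), ("B", 2)])
        with pytest.raises(ValueError, match="unannotated"):
            type_profiles(m, ann.drop("B_0"))


class TestCallHigh:
    def test_constant_gene_never_high(self, sc_dataset):
        matrix, ann, _ = sc_dataset
        const = matrix.copy()
        const.loc["CONST"] = 5.0
        for scope in ("rest", "pooled", "type-means"):
            calls = call_high(const, ann, k=3, stat_scope=scope)
            assert not calls.loc["CONST"].any()

    def test_planted_types_called_exclusively(self, sc_dataset):
        matrix, ann, truth = sc_dataset
        calls = call_high(matrix, ann, k=3)
        for sender, receiver, ligand, receptor in truth.edges:
            assert calls.loc[ligand, sender]
            assert calls.loc[ligand].sum() == 1
            assert calls.loc[receptor, receiver]

    def test_invariant_under_global_rescaling(self, sc_dataset):
        matrix, ann, _ = sc_dataset
        for scope in ("rest", "pooled", "type-means"):
            a = call_high(matrix, ann, k=3, stat_scope=scope)
            b = call_high(matrix * 7.3, ann, k=3, stat_scope=scope)
            assert a.equals(b)

    def test_lowering_k_never_removes_a_call(self, sc_dataset):
        matrix, ann, _ = sc_dataset
        strict = call_high(matrix, ann, k=3).to_numpy()
        loose = call_high(matrix, ann, k=1.5).to_numpy()
        assert (loose | strict).sum() == loose.sum()

    def test_type_mean_statistics_can_never_fire_at_k3(self):
        """With moments over the 7 type means, no value can exceed
        mean + 3 sd: the largest standardized deviation among n values is
        (n-1)/sqrt(n) ~ 2.27 for n = 7."""
        assert max_standardized_deviation_bound(7) < 3
        rng = np.random.default_rng(2)
        for trial in range(20):
            data = rng.gamma(1.0, 50.0, size=(30, 70))
            m, ann = _matrix(data, [(f"T{i}", 10) for i in range(7)])
            profiles, _ = type_profiles(m, ann)
            vals = profiles.to_numpy()
            z = (vals - vals.mean(1, keepdims=True)) / vals.std(1, ddof=1, keepdims=True)
            assert z.max() <= max_standardized_deviation_bound(7) + 1e-9
            calls = call_high(m, ann, k=3, stat_scope="type-means")
            assert not calls.to_numpy().any()

    def test_validation(self, sc_dataset):
        matrix, ann, _ = sc_dataset
        with pytest.raises(ValueError, match="stat_scope"):
            call_high(matrix, ann, stat_scope="bogus")
        with pytest.raises(ValueError, match="k must"):
            call_high(matrix, ann, k=0)


class TestBuildNetwork:
    def test_no_calls_empty_network(self, demo_db):
        calls = pd.DataFrame(
            False, index=["LB1", "RB1"], columns=["A", "B"]
        )
        assert build_network(calls, demo_db).empty

    def test_single_directed_edge(self, demo_db):
        calls = pd.DataFrame(False, index=["LB1", "RB1"], columns=["A", "B"])
        calls.loc["LB1", "A"] = True
        calls.loc["RB1", "B"] = True
        edges = build_network(calls, demo_db)
        assert edges.to_numpy().tolist() == [["A", "B", "LB1", "RB1"]]

    def test_planted_edges_recovered_exactly(self, sc_dataset, bijective_db):
        matrix, ann, truth = sc_dataset
        calls = call_high(matrix, ann, k=3)
        edges = build_network(calls, bijective_db)
        assert set(map(tuple, edges.to_numpy())) == set(truth.edges)

    def test_autocrine_edge_supported(self, demo_db):
        calls = pd.DataFrame(False, index=["LB1", "RB1"], columns=["A"])
        calls.loc[["LB1", "RB1"], "A"] = True
        edges = build_network(calls, demo_db)
        assert edges.iloc[0]["sender"] == edges.iloc[0]["receiver"] == "A"


class TestEdgeCounts:
    def test_empty_edge_set(self):
        edges = pd.DataFrame(columns=["sender", "receiver", "ligand", "receptor"])
        counts = edge_counts(edges, types=["A", "B"])
        assert counts.to_numpy().sum() == 0

    def test_hand_counts(self):
        edges = pd.DataFrame(
            [("A", "B", "l", "r")] * 3 + [("B", "A", "l", "r")],
            columns=["sender", "receiver", "ligand", "receptor"],
        )
        counts = edge_counts(edges)
        assert counts.loc["A", "B"] == 3
        assert counts.loc["B", "A"] == 1
        assert counts.to_numpy().sum() == len(edges)

    def test_matches_truth_record(self, sc_dataset, bijective_db):
        matrix, ann, truth = sc_dataset
        edges = build_network(call_high(matrix, ann), bijective_db)
        counts = edge_counts(edges)
        for sender, receiver, _, _ in truth.edges:
            assert counts.loc[sender, receiver] >= 1
        assert counts.to_numpy().sum() == len(truth.edges)


class TestExclusiveness:
    @staticmethod
    def _profiles(rows):
        return pd.DataFrame(
            rows, index=[f"g{i}" for i in range(len(rows))],
            columns=[f"T{i}" for i in range(len(rows[0]))],
        )

    def test_uniform_gene_scores_one(self):
        p = self._profiles([[4.0] * 7])
        for t in p.columns:
            assert exclusiveness(p, t, "g0") == 1.0

    def test_single_type_gene_scores_type_count(self):
        p = self._profiles([[0, 0, 0, 9.0, 0, 0, 0]])
        assert np.isclose(exclusiveness(p, "T3", "g0"), 7.0)
        assert exclusiveness(p, "T0", "g0") == 0.0

    def test_silent_gene_warns_nan(self):
        p = self._profiles([[0.0, 0.0]])
        with pytest.warns(UserWarning, match="zero mean"):
            assert np.isnan(exclusiveness(p, "T0", "g0"))


class TestRankEdges:
    def test_single_edge_always_kept(self):
        edges = pd.DataFrame(
            [("A", "B", "g0", "g1")],
            columns=["sender", "receiver", "ligand", "receptor"],
        )
        p = pd.DataFrame([[9.0, 0.0], [0.0, 9.0]], index=["g0", "g1"], columns=["A", "B"])
        ranked = rank_edges(edges, p, top_fraction=0.02)
        assert len(ranked) == 1  # ceil(0.02 * 1) = 1

    def test_highest_scoring_edge_wins(self):
        edges = pd.DataFrame(
            [("A", "B", "g0", "g1"), ("B", "A", "g2", "g3")],
            columns=["sender", "receiver", "ligand", "receptor"],
        )
        p = pd.DataFrame(
            [[14.0, 0.0], [0.0, 14.0], [7.0, 7.0], [7.0, 7.0]],
            index=["g0", "g1", "g2", "g3"], columns=["A", "B"],
        )
        ranked = rank_edges(edges, p, top_fraction=0.5)
        assert len(ranked) == 1
        assert ranked.iloc[0]["ligand"] == "g0"
        assert np.isclose(ranked.iloc[0]["score"], 2.0)  # sqrt(2 * 2)

    def test_top_set_matches_bruteforce_sort(self):
        rng = np.random.default_rng(5)
        genes = [f"g{i}" for i in range(40)]
        types = ["A", "B", "C", "D"]
        p = pd.DataFrame(rng.gamma(2, 3, size=(40, 4)), index=genes, columns=types)
        rows = [
            (types[rng.integers(4)], types[rng.integers(4)],
             genes[rng.integers(40)], genes[rng.integers(40)])
            for _ in range(100)
        ]
        edges = pd.DataFrame(rows, columns=["sender", "receiver", "ligand", "receptor"])
        ranked = rank_edges(edges, p, top_fraction=0.02)
        assert len(ranked) == 2
        brute = sorted(
            (
                math.sqrt(
                    exclusiveness(p, s, l) * exclusiveness(p, r, c)
                )
                for s, r, l, c in rows
            ),
            reverse=True,
        )
        np.testing.assert_allclose(sorted(ranked["score"], reverse=True), brute[:2])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            rank_edges(pd.DataFrame(columns=["sender", "receiver", "ligand", "receptor"]),
                       pd.DataFrame())


class TestFilterInvolving:
    EDGES = pd.DataFrame(
        [("A", "B", "l", "r"), ("B", "C", "l", "r"), ("A", "A", "l", "r")],
        columns=["sender", "receiver", "ligand", "receptor"],
    )

    def test_absent_type_empty(self):
        assert filter_involving(self.EDGES, "Z").empty

    def test_autocrine_retained(self):
        kept = filter_involving(self.EDGES, "A")
        assert len(kept) == 2
        assert (kept["sender"] == "A").all()

    def test_predicate_scan(self):
        kept = filter_involving(self.EDGES, "B")
        mask = (self.EDGES["sender"] == "B") | (self.EDGES["receiver"] == "B")
        assert len(kept) == mask.sum()


def test_graphml_round_trip(tmp_path, sc_dataset, bijective_db):
    matrix, ann, truth = sc_dataset
    edges = build_network(call_high(matrix, ann), bijective_db)
    path = tmp_path / "net.graphml"
    export_graphml(edges, path)
    g = nx.read_graphml(path)
    assert g.number_of_edges() == len(truth.edges)
    assert set(g.nodes) == {e[0] for e in truth.edges} | {e[1] for e in truth.edges}
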
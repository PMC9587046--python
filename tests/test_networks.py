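import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from msgnet.data import ValidationError
from msgnet.networks import (
    AssociationNetwork,
    aggregated_measures,
    compare_networks,
    dice_network,
    export_dot,
    match_sample_size,
    network_from_matrix,
    node_measures,
    subsample_replicates,
    welch_log_test,
)

from conftest import make_group


def net_from_weights(w, species=None, occurrences=None, cooccur=None):
    w = np.asarray(w, dtype=float)
    n = w.shape[0]
    species = species or [f"sp{i}" for i in range(n)]
    return AssociationNetwork(
        species=list(species),
        weights=w,
        occurrences=np.asarray(occurrences if occurrences is not None else np.full(n, 5)),
        cooccurrences=np.asarray(cooccur if cooccur is not None else (w > 0) * 5),
    )


class TestDiceNetwork:
    def test_never_cooccur_weight_zero(self):
        groups = [make_group("1", ["a"]), make_group("2", ["b"])]
        assert dice_network(groups, ["a", "b"]).weight("a", "b") == 0.0

    def test_always_together_weight_one(self):
        groups = [make_group(str(i), ["a", "b"]) for i in range(5)]
        assert dice_network(groups, ["a", "b"]).weight("a", "b") == 1.0

    def test_direct_arithmetic(self):
        # N_a = 10, N_b = 6, N_ab = 3 -> w = 2*3/16 = 0.375
        groups = (
            [make_group(f"ab{i}", ["a", "b"]) for i in range(3)]
            + [make_group(f"a{i}", ["a"]) for i in range(7)]
            + [make_group(f"b{i}", ["b"]) for i in range(3)]
        )
        net = dice_network(groups, ["a", "b"])
        assert net.weight("a", "b") == pytest.approx(0.375)
        assert net.occurrences.tolist() == [10, 6]

    def test_empty_species_set_rejected(self):
        with pytest.raises(ValidationError):
            dice_network([make_group("1", ["a"])], [])

    def test_matches_matrix_route(self, tiny_groups):
        from msgnet.data import OccurrenceMatrix

        a = dice_network(tiny_groups, ["a", "b", "c"])
        b = network_from_matrix(OccurrenceMatrix.from_groups(tiny_groups))
        assert np.allclose(a.weights, b.weights)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_bounds_and_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        m = (rng.random((20, 6)) < 0.3).astype(np.int8)
        m = m[m.sum(axis=1) > 0]
        if not len(m):
            return
        net = network_from_matrix(m)
        assert np.allclose(net.weights, net.weights.T)
        assert net.weights.max() <= 1.0
        s = net.weights.sum(axis=1)
        assert (s <= len(net.species) - 1 + 1e-12).all()
        assert (net.cooccurrences <= np.minimum.outer(net.occurrences, net.occurrences)).all()

    def test_relabeling_permutes_outputs(self, rng):
        m = (rng.random((30, 5)) < 0.4).astype(np.int8)
        m = m[m.sum(axis=1) > 0]
        net = network_from_matrix(m)
        perm = rng.permutation(5)
        net_p = network_from_matrix(m[:, perm])
        assert np.allclose(net_p.weights, net.weights[np.ix_(perm, perm)])
        nm, nm_p = node_measures(net), node_measures(net_p)
        for j, pj in enumerate(perm):
            row = nm.iloc[pj][["strength", "y_measure"]]
            row_p = nm_p.iloc[j][["strength", "y_measure"]]
            assert np.allclose(row.to_numpy(dtype=float), row_p.to_numpy(dtype=float), equal_nan=True)


class TestNodeMeasures:
    def test_four_equal_edges_y(self):
        w = np.zeros((5, 5))
        w[0, 1:] = w[1:, 0] = 0.5
        nm = node_measures(net_from_weights(w))
        assert nm.loc["sp0", "y_measure"] == pytest.approx(0.25)
        assert nm.loc["sp0", "strength"] == pytest.approx(2.0)

    def test_single_edge_y_is_one(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 0.7
        nm = node_measures(net_from_weights(w))
        assert nm.loc["sp0", "y_measure"] == pytest.approx(1.0)
        assert np.isnan(nm.loc["sp2", "y_measure"])  # isolated node

    def test_complete_unit_triangle_closed_form(self):
        w = 1.0 - np.eye(3)
        nm = node_measures(net_from_weights(w))
        assert np.allclose(nm["strength"], 2.0)
        assert np.allclose(nm["y_measure"], 0.5)
        assert np.allclose(nm["wcc"], 1.0)

    def test_open_triplet_has_zero_clustering(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 0.5
        w[1, 2] = w[2, 1] = 0.5
        nm = node_measures(net_from_weights(w))
        assert nm.loc["sp1", "wcc"] == pytest.approx(0.0)
        assert np.isnan(nm.loc["sp0", "wcc"])  # degree 1

    def test_geometric_variant_unit_triangle(self):
        w = 1.0 - np.eye(3)
        nm = node_measures(net_from_weights(w), variant="geometric")
        assert np.allclose(nm["wcc"], 1.0)

    def test_y_minimised_by_equal_weights(self, rng):
        k = 6
        w = np.zeros((k + 1, k + 1))
        w[0, 1:] = w[1:, 0] = rng.uniform(0.1, 1.0, size=k)
        y_uneven = node_measures(net_from_weights(w)).loc["sp0", "y_measure"]
        w[0, 1:] = w[1:, 0] = 0.4
        y_even = node_measures(net_from_weights(w)).loc["sp0", "y_measure"]
        assert y_even == pytest.approx(1.0 / k)
        assert y_uneven >= y_even - 1e-12


class TestSubsampling:
    def test_balanced_partition_sizes(self, rng):
        groups = [make_group(f"g{i}", ["a"]) for i in range(10)]
        reps = subsample_replicates(groups, k=3, seed=0)
        assert sorted(len(r) for r in reps) == [3, 3, 4]
        ids = [g.group_id for r in reps for g in r]
        assert sorted(ids) == sorted(g.group_id for g in groups)

    def test_exact_split(self):
        groups = [make_group(f"g{i}", ["a"]) for i in range(9)]
        assert [len(r) for r in subsample_replicates(groups, k=3, seed=1)] == [3, 3, 3]

    def test_seed_determinism(self):
        groups = [make_group(f"g{i}", ["a"]) for i in range(10)]
        a = subsample_replicates(groups, k=3, seed=7)
        b = subsample_replicates(groups, k=3, seed=7)
        assert [[g.group_id for g in r] for r in a] == [[g.group_id for g in r] for r in b]

    def test_k_too_small(self):
        with pytest.raises(ValidationError):
            subsample_replicates([make_group("g", ["a"])] * 5, k=1)

    def test_match_sample_size(self):
        a = [make_group(f"a{i}", ["a"]) for i in range(100)]
        b = [make_group(f"b{i}", ["b"]) for i in range(400)]
        sub = match_sample_size(a, b, seed=0)
        assert len(sub) == 100
        assert all(g.group_id.startswith("b") for g in sub)
        sub2 = match_sample_size(a, b, seed=1)
        assert [g.group_id for g in sub] != [g.group_id for g in sub2]
        with pytest.raises(ValidationError):
            match_sample_size(b, a)


class TestWelch:
    def test_hand_computed_example(self):
        # log-scale samples {1,2,3} vs {4,5,6}: t = -3/sqrt(2/3), df = 4
        res = welch_log_test(np.exp([1.0, 2.0, 3.0]), np.exp([4.0, 5.0, 6.0]))
        assert res.t == pytest.approx(-3.6742, abs=1e-4)
        assert res.df == pytest.approx(4.0)
        assert res.p == pytest.approx(0.0213, abs=1e-4)

    def test_nonpositive_values_reported(self):
        with pytest.raises(ValidationError, match="replicate"):
            welch_log_test([1.0, 0.0, 2.0], [1.0, 1.0, 1.0])

    def test_identical_samples_null(self):
        res = welch_log_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == 0.0 and res.p == 1.0


class TestCompareNetworks:
    def _groups(self, rng, n=120, tag=""):
        out = []
        for i in range(n):
            members = ["zebra"] if rng.random() < 0.5 else ["zebra", "wildebeest"]
            if rng.random() < 0.4:
                members.append("impala")
            out.append(make_group(f"{tag}{i}", members))
        return out

    def test_identical_inputs_are_null(self, rng):
        groups = self._groups(rng)
        res = compare_networks(groups, groups, ["zebra", "wildebeest", "impala"],
                               focal_species=["zebra", "wildebeest"], seed=3)
        for r in res.values():
            assert r.t == 0.0 and r.p == 1.0

    def test_matches_larger_side_down(self, rng):
        a = self._groups(rng, 60, "a")
        b = self._groups(rng, 240, "b")
        res = compare_networks(a, b, ["zebra", "wildebeest", "impala"],
                               focal_species=["zebra", "wildebeest"], seed=3)
        assert set(res) == {"strength", "y_measure", "wcc"}
        for r in res.values():
            assert 0.0 <= r.p <= 1.0

    def test_aggregation_averages_focal_species(self, rng):
        groups = self._groups(rng, 60)
        reps = subsample_replicates(groups, k=3, seed=0)
        agg = aggregated_measures(reps, ["zebra", "wildebeest", "impala"],
                                  focal_species=["zebra", "wildebeest"])
        net0 = dice_network(reps[0], ["zebra", "wildebeest", "impala"])
        nm0 = node_measures(net0)
        expect = nm0.loc[["zebra", "wildebeest"], "strength"].mean()
        assert agg.loc[0, "strength"] == pytest.approx(expect)


class TestExportDot:
    def test_weight_filter(self):
        w = np.zeros((2, 2))
        w[0, 1] = w[1, 0] = 0.04
        dot = export_dot(net_from_weights(w, cooccur=np.full((2, 2), 5)))
        assert "--" not in dot

    def test_cooccurrence_filter(self):
        w = np.zeros((2, 2))
        w[0, 1] = w[1, 0] = 0.2
        dot = export_dot(net_from_weights(w, cooccur=np.ones((2, 2), dtype=int)))
        assert "--" not in dot

    def test_empty_network_still_valid(self):
        dot = export_dot(net_from_weights(np.zeros((3, 3))))
        assert dot.startswith("graph") and dot.rstrip().endswith("}")
        assert dot.count('"sp') >= 3

    def test_highlight_styles(self):
        w = np.zeros((2, 2))
        w[0, 1] = w[1, 0] = 0.3
        net = net_from_weights(w, cooccur=np.full((2, 2), 5))
        dot = export_dot(net, highlight={("sp0", "sp1"): "significant"})
        assert "penwidth=3" in dot and "color=black" in dot
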
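import numpy as np
import pytest

from multifvs import (
    FunctionWeights,
    Layer,
    MultilayerNetwork,
    compare_methods,
    dominated_rank,
    enumerate_cycles,
    iisg,
    iisg_duplex,
    is_fvs,
    isg,
    min_union_oracle,
    sg_mfvs,
)

from conftest import random_layer


def random_duplex(rng, n, p, correlation=0.3):
    ids = [f"v{i:02d}" for i in range(n)]
    base = random_layer(rng, n, p, layer_id="1")
    edges2 = []
    for u in ids:
        for v in ids:
            if u == v:
                continue
            if rng.random() < correlation:
                if (u, v) in base.edges:
                    edges2.append((u, v))
            elif rng.random() < p:
                edges2.append((u, v))
    lay2 = Layer.from_edges(edges2, layer_id="2", extra_nodes=ids)
    return MultilayerNetwork((base, lay2))


class TestDominatedRank:
    def test_worked_example_top_two(self, worked_example):
        _, study = worked_example
        F_r = {"2", "5"}
        L = enumerate_cycles(study).restrict_through(F_r)
        ranked = dominated_rank({n for c in L for n in c}, L, F_r)
        assert [s.node_id for s in ranked[:2]] == ["2", "5"]

    def test_loop_count_orders_without_reference(self):
        lay = Layer.from_edges(
            [("a", "b"), ("b", "a"), ("b", "c"), ("c", "b")]
        )
        L = enumerate_cycles(lay)
        ranked = dominated_rank(lay.nodes, L, F_r=set())
        assert ranked[0].node_id == "b"  # b lies on both 2-cycles

    def test_tie_breaks_on_node_id(self, triangle):
        L = enumerate_cycles(triangle)
        ranked = dominated_rank(triangle.nodes, L, F_r=set())
        assert [s.node_id for s in ranked] == ["a", "b", "c"]

    def test_function_weight_breaks_loop_tie(self, triangle):
        L = enumerate_cycles(triangle)
        w = FunctionWeights({"c": 5.0})
        ranked = dominated_rank(triangle.nodes, L, F_r=set(), w=w)
        assert ranked[0].node_id == "c"

    def test_nodes_off_all_cycles_ineligible(self):
        lay = Layer.from_edges([("a", "b"), ("b", "a"), ("b", "x")])
        ranked = dominated_rank(lay.nodes, enumerate_cycles(lay), F_r=set())
        assert "x" not in [s.node_id for s in ranked]


class TestIisgDuplex:
    def test_worked_example(self, worked_example):
        reference, study = worked_example
        res = iisg_duplex(reference, study)
        assert res.size == 3
        assert {"2", "5"} <= res.driver_nodes
        assert res.driver_nodes - {"2", "5"} <= {"3", "4"}
        assert res.all_valid
        # published tie-break: node 3 is chosen from the residual circle
        assert res.driver_nodes == frozenset({"2", "5", "3"})

    def test_identical_three_cycles_share_one_driver(self, triangle):
        ref = Layer(layer_id="ref", nodes=triangle.nodes, edges=triangle.edges)
        res = iisg_duplex(ref, triangle)
        assert res.size == 1 and res.all_valid

    def test_mismatched_universes_rejected(self, triangle):
        other = Layer.from_edges([("x", "y"), ("y", "x")])
        with pytest.raises(ValueError):
            iisg_duplex(triangle, other)

    @pytest.mark.parametrize("seed", range(25))
    def test_random_duplex_sound_and_bounded(self, seed):
        rng = np.random.default_rng(1000 + seed)
        net = random_duplex(rng, 10, 0.25)
        res = iisg_duplex(net.layers[0], net.layers[1])
        assert res.all_valid
        assert res.size >= min_union_oracle(net).size

    def test_exact_residual_mode_valid(self, worked_example):
        reference, study = worked_example
        res = iisg_duplex(reference, study, exact_residual=True)
        assert res.all_valid and res.size == 3


class TestIsgAndFold:
    def test_identical_layers_union_equals_single(self, triangle):
        dup = Layer(layer_id="2", nodes=triangle.nodes, edges=triangle.edges)
        net = MultilayerNetwork((triangle, dup))
        assert isg(net).size == sg_mfvs(triangle).size

    def test_disjoint_cycle_systems_add(self):
        a = Layer.from_edges([("a", "b"), ("b", "a")], layer_id="1",
                             extra_nodes=["c", "d"])
        b = Layer.from_edges([("c", "d"), ("d", "c")], layer_id="2",
                             extra_nodes=["a", "b"])
        net = MultilayerNetwork((a, b))
        assert isg(net).size == 2
        assert min_union_oracle(net).size == 2

    def test_single_layer_fold_equals_sg(self, worked_example):
        _, study = worked_example
        net = MultilayerNetwork((study,))
        assert iisg(net).driver_nodes == sg_mfvs(study).fvs

    def test_two_layer_fold_equals_duplex(self, worked_example):
        reference, study = worked_example
        net = MultilayerNetwork((reference, study))
        assert iisg(net).driver_nodes == iisg_duplex(reference, study).driver_nodes

    def test_reference_index_out_of_range(self, worked_net):
        with pytest.raises(IndexError):
            iisg(worked_net, reference_index=5)

    def test_three_layer_fold_valid_and_bounded(self):
        rng = np.random.default_rng(10)
        ids = [f"v{i:02d}" for i in range(12)]
        layers = [
            random_layer(np.random.default_rng(s), 12, 0.18, layer_id=str(s))
            for s in (10, 11, 12)
        ]
        net = MultilayerNetwork.from_layers(layers)
        res = iisg(net)
        assert res.all_valid
        assert res.size >= min_union_oracle(net).size

    def test_dag_layer_contributes_nothing(self, worked_example):
        _, study = worked_example
        dag = Layer.from_edges(
            [("1", "2"), ("2", "3"), ("3", "4")], layer_id="dag",
            extra_nodes=study.nodes,
        )
        net = MultilayerNetwork((dag, study))
        res = iisg(net)
        alone = iisg(MultilayerNetwork((study,)))
        assert res.driver_nodes == alone.driver_nodes

    def test_reference_swap_preserves_validity(self, worked_net):
        for idx in range(worked_net.S):
            assert iisg(worked_net, reference_index=idx).all_valid

    def test_determinism(self, worked_net):
        assert iisg(worked_net).driver_nodes == iisg(worked_net).driver_nodes


class TestOracleAndCompare:
    def test_identical_triangles_min_union_one(self, triangle):
        dup = Layer(layer_id="2", nodes=triangle.nodes, edges=triangle.edges)
        net = MultilayerNetwork((triangle, dup))
        assert min_union_oracle(net).size == 1

    def test_worked_example_min_union_three(self, worked_net):
        assert min_union_oracle(worked_net).size == 3

    def test_oracle_refuses_large(self):
        rng = np.random.default_rng(0)
        net = MultilayerNetwork((random_layer(rng, 20, 0.1),))
        with pytest.raises(ValueError, match="max_n"):
            min_union_oracle(net)

    def test_compare_table_worked_example(self, worked_net):
        table = compare_methods(worked_net)
        by_method = table.set_index("method")
        assert by_method.loc["SG(layer reference)", "size"] == 2
        assert by_method.loc["IISG", "size"] == 3
        assert by_method.loc["oracle", "size"] == 3
        assert by_method.loc["IISG", "size"] <= by_method.loc["ISG", "size"]

    def test_compare_identical_layers(self, triangle):
        dup = Layer(layer_id="2", nodes=triangle.nodes, edges=triangle.edges)
        table = compare_methods(MultilayerNetwork((triangle, dup)))
        by_method = table.set_index("method")
        assert by_method.loc["ISG", "size"] == by_method.loc["IISG", "size"]

    def test_cicc_shaped_duplex(self):
        from multifvs.synthgen import cicc_shaped_duplex

        net = cicc_shaped_duplex(seed=0)
        i1, i2 = isg(net), iisg(net)
        assert i1.all_valid and i2.all_valid
        assert i2.size <= i1.size
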
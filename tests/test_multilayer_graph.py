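import numpy as np
import pytest

from multifvs import (
    Layer,
    MultilayerNetwork,
    read_edge_list,
    read_multiplex,
    read_node_weights,
    validate_network,
)
from multifvs.multilayer_graph import (
    FunctionWeights,
    ParseError,
    write_edge_list,
    write_multiplex,
)
from multifvs.synthgen import GeneratorSpec, random_multilayer


class TestReadEdgeList:
    def test_two_cycle(self, tmp_path):
        p = tmp_path / "e.tsv"
        p.write_text("a\tb\nb\ta\n")
        lay = read_edge_list(p)
        assert lay.n_nodes == 2 and lay.n_edges == 2

    def test_duplicate_lines_collapse(self, tmp_path):
        p = tmp_path / "e.tsv"
        p.write_text("a b\na b\n")
        assert read_edge_list(p).n_edges == 1

    def test_comments_and_weight_column_ignored(self, tmp_path):
        p = tmp_path / "e.tsv"
        p.write_text("# header\na\tb\t0.5\n")
        lay = read_edge_list(p)
        assert lay.edges == frozenset({("a", "b")})

    def test_malformed_line_names_lineno(self, tmp_path):
        p = tmp_path / "e.tsv"
        p.write_text("a b\nc\n")
        with pytest.raises(ParseError, match=":2"):
            read_edge_list(p)

    def test_empty_file_warns(self, tmp_path):
        p = tmp_path / "e.tsv"
        p.write_text("")
        with pytest.warns(UserWarning):
            lay = read_edge_list(p)
        assert lay.n_nodes == 0

    def test_worked_study_file_roundtrip(self, worked_example, tmp_path):
        # the study layer file carries 10 edges; its endpoints span 6
        # ids (node 6 is isolated and lives only in the shared universe)
        _, study = worked_example
        p = tmp_path / "study.tsv"
        write_edge_list(study, p)
        back = read_edge_list(p)
        assert back.n_edges == 10
        assert back.nodes == study.nodes - {"6"}
        assert back.edges == study.edges


class TestReadMultiplex:
    def test_two_layers_shared_universe(self, tmp_path):
        p = tmp_path / "m.edges"
        p.write_text("1 a b 1\n2 b a 1\n")
        net = read_multiplex(p)
        assert net.S == 2
        assert net.node_universe == frozenset({"a", "b"})

    def test_self_loop_roundtrip(self, tmp_path):
        p = tmp_path / "m.edges"
        p.write_text("1 a a 1\n")
        net = read_multiplex(p)
        assert net.layers[0].self_loops == frozenset({"a"})

    def test_bad_layer_id(self, tmp_path):
        p = tmp_path / "m.edges"
        p.write_text("x a b 1\n")
        with pytest.raises(ParseError, match="layer id"):
            read_multiplex(p)

    def test_wrong_column_count(self, tmp_path):
        p = tmp_path / "m.edges"
        p.write_text("1 a b\n")
        with pytest.raises(ParseError, match=":1"):
            read_multiplex(p)

    def test_generator_roundtrip(self, tmp_path):
        net = random_multilayer(GeneratorSpec(n=20, S=3, edge_prob=0.1, seed=7))
        assert net.S == 3 and net.N == 20
        p = tmp_path / "m.edges"
        write_multiplex(net, p)
        back = read_multiplex(p)
        assert back.node_universe == net.node_universe
        assert [l.edges for l in back.layers] == [l.edges for l in net.layers]

    def test_read_is_deterministic(self, tmp_path):
        p = tmp_path / "m.edges"
        p.write_text("1 a b 1\n1 b c 1\n2 c a 1\n")
        assert read_multiplex(p) == read_multiplex(p)


class TestNodeWeights:
    def test_lookup_and_default(self, tmp_path):
        p = tmp_path / "w.tsv"
        p.write_text("AKT\t3\nP53\t5\n")
        w = read_node_weights(p)
        assert w["AKT"] == 3 and w["P53"] == 5 and w["JAK"] == 0

    def test_empty_file_all_zero(self, tmp_path):
        p = tmp_path / "w.tsv"
        p.write_text("")
        w = read_node_weights(p)
        assert len(w) == 0 and w["anything"] == 0

    def test_negative_weight_rejected(self, tmp_path):
        p = tmp_path / "w.tsv"
        p.write_text("x\t-1\n")
        with pytest.raises(ParseError, match="negative"):
            read_node_weights(p)

    def test_non_numeric_weight_rejected(self, tmp_path):
        p = tmp_path / "w.tsv"
        p.write_text("x\tabc\n")
        with pytest.raises(ParseError):
            read_node_weights(p)


class TestDataModel:
    def test_edge_outside_nodes_rejected(self):
        with pytest.raises(ValueError):
            Layer(layer_id="1", nodes=frozenset({"a"}), edges=frozenset({("a", "b")}))

    def test_hyphenated_ids_preserved(self):
        lay = Layer.from_edges([("GAG-POL", "Env")])
        assert "GAG-POL" in lay.nodes and "Env" in lay.nodes

    def test_mismatched_universe_rejected(self):
        a = Layer.from_edges([("a", "b")])
        b = Layer.from_edges([("b", "c")])
        with pytest.raises(ValueError):
            MultilayerNetwork((a, b))
        # from_layers expands instead
        net = MultilayerNetwork.from_layers([a, b])
        assert net.node_universe == frozenset({"a", "b", "c"})

    def test_validate_report(self, worked_net):
        report = validate_network(worked_net)
        assert report["n_layers"] == 2 and report["n_nodes"] == 7
        by_id = {l["layer_id"]: l for l in report["layers"]}
        assert by_id["study"]["n_self_loops"] == 1
        assert by_id["study"]["isolated_nodes"] == ["6"]
        assert by_id["reference"]["isolated_nodes"] == ["7"]
        assert report["universe_expanded"]

    def test_validate_counts_echoed(self):
        net = random_multilayer(
            GeneratorSpec(n=14, S=2, seed=1, edges_per_layer=(38, 42))
        )
        report = validate_network(net)
        assert [l["n_edges"] for l in report["layers"]] == [38, 42]
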
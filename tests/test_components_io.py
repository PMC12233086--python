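"""Payload loaders: tables, graphs, plot dialects, text passthrough."""

import json

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from scireport.components_io import (
    Graph,
    LoadError,
    detect_plot_dialect,
    graph_to_edge_list_text,
    load_graph,
    load_table,
    load_text_component,
    probe_delimiter,
)
from scireport.config_model import PlotDialect


class TestLoadTable:
    def test_small_csv(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("a,b\n1,2\n3,4\n")
        t = load_table(p)
        assert t.column_names == ["a", "b"]
        assert t.n_rows == 2 and t.n_cols == 2
        assert t.rows == [(1, 2), (3, 4)]

    def test_probe_selects_tab(self, tmp_path):
        p = tmp_path / "t.txt"
        p.write_text("a\tb\n1\t2\n3\t4\n")
        t = load_table(p)
        assert t.column_names == ["a", "b"]
        assert t.rows == [(1, 2), (3, 4)]

    def test_configured_delimiter_wins_over_probe(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("a;b\n1;2\n")
        t = load_table(p, delimiter=";")
        assert t.column_names == ["a", "b"]

    def test_same_logical_table_loads_equal_across_formats(self, tmp_path):
        from scireport.fixtures import _write_xlsx

        df = pd.DataFrame({"x": [1, 2, 3], "y": [0.5, 1.5, 2.5], "label": list("abc")})
        df.to_csv(tmp_path / "t.csv", index=False)
        df.to_csv(tmp_path / "t.txt", sep="\t", index=False)
        df.to_parquet(tmp_path / "t.parquet", index=False)
        _write_xlsx(df, tmp_path / "t.xlsx")
        tables = [
            load_table(tmp_path / f"t.{ext}") for ext in ("csv", "txt", "parquet", "xlsx")
        ]
        for t in tables[1:]:
            assert t.column_names == tables[0].column_names
            assert t.rows == tables[0].rows

    def test_ragged_file_cites_line(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("a,b\n1,2\n3,4,5\n")
        with pytest.raises(LoadError, match="line"):
            load_table(p)

    def test_empty_file_errors(self, tmp_path):
        p = tmp_path / "empty.csv"
        p.write_text("")
        with pytest.raises(LoadError, match="empty"):
            load_table(p)

    def test_xlsx_first_sheet_only_warns(self, tmp_path, caplog):
        p = tmp_path / "multi.xlsx"
        with pd.ExcelWriter(p) as xw:
            pd.DataFrame({"a": [1]}).to_excel(xw, sheet_name="first", index=False)
            pd.DataFrame({"b": [2]}).to_excel(xw, sheet_name="second", index=False)
        with caplog.at_level("WARNING"):
            t = load_table(p)
        assert t.column_names == ["a"]
        assert any("first" in r.message for r in caplog.records)


class TestProbeDelimiter:
    @pytest.mark.parametrize(
        "text,expected",
        [("a,b\n1,2", ","), ("a\tb\n1\t2", "\t"), ("a;b\n1;2", ";"), ("plain", ",")],
    )
    def test_majority_vote(self, text, expected):
        assert probe_delimiter(text) == expected


class TestLoadGraph:
    def test_symmetric_adjacency_two_edges(self, tmp_path):
        p = tmp_path / "adjacency.csv"
        p.write_text(",A,B,C\nA,0,1,0\nB,1,0,2\nC,0,2,0\n")
        g = load_graph(p, "adjacency")
        assert g.n_nodes == 3
        assert g.n_edges == 2
        assert not g.directed

    def test_asymmetric_adjacency_is_directed(self, tmp_path):
        p = tmp_path / "adjacency.csv"
        p.write_text(",A,B\nA,0,1\nB,0,0\n")
        g = load_graph(p, "adjacency")
        assert g.directed
        assert g.edges == [("A", "B", 1.0)]

    def test_diagonal_is_ignored(self, tmp_path):
        p = tmp_path / "adjacency.csv"
        p.write_text(",A,B\nA,5,0\nB,0,5\n")
        g = load_graph(p, "adjacency")
        assert g.n_edges == 0

    def test_non_square_adjacency_errors(self, tmp_path):
        p = tmp_path / "adjacency.csv"
        p.write_text(",A,B,C\nA,0,1,0\nB,1,0,2\n")
        with pytest.raises(LoadError, match="square"):
            load_graph(p, "adjacency")

    def test_edge_list_basic(self, tmp_path):
        p = tmp_path / "edges.csv"
        p.write_text("source,target\nA,B\nB,C\n")
        g = load_graph(p, "edge_list")
        assert g.n_nodes == 3 and g.n_edges == 2

    def test_edge_list_single_column_errors(self, tmp_path):
        p = tmp_path / "edges.csv"
        p.write_text("source\nA\nB\n")
        with pytest.raises(LoadError, match="2 columns"):
            load_graph(p, "edge_list")

    def test_third_numeric_column_is_weight(self, tmp_path):
        p = tmp_path / "edges.csv"
        p.write_text("source,target,weight,kind\nA,B,0.5,pos\n")
        g = load_graph(p, "edge_list")
        assert g.edges == [("A", "B", 0.5)]
        assert g.edge_attrs[0] == {"kind": "pos"}

    def test_graphml_counts_verified_against_networkx(self, tmp_path):
        gx = nx.gnm_random_graph(5, 4, seed=1)
        p = tmp_path / "g.graphml"
        nx.write_graphml(gx, p)
        g = load_graph(p)
        # independent oracle: networkx's own reader
        ref = nx.read_graphml(p)
        assert g.n_nodes == ref.number_of_nodes() == 5
        assert g.n_edges == ref.number_of_edges() == 4

    @pytest.mark.parametrize("fmt", ["gml", "gexf", "cyjs"])
    def test_exchange_formats_round_node_edge_counts(self, tmp_path, fmt):
        gx = nx.gnm_random_graph(6, 7, seed=3)
        p = tmp_path / f"g.{fmt}"
        if fmt == "gml":
            nx.write_gml(gx, p, stringizer=str)
        elif fmt == "gexf":
            nx.write_gexf(gx, p)
        else:
            p.write_text(json.dumps(nx.cytoscape_data(gx)))
        g = load_graph(p)
        assert g.n_nodes == 6 and g.n_edges == 7

    def test_html_embed_passes_through_raw(self, tmp_path):
        p = tmp_path / "network_view.html"
        p.write_text("<html><body>net</body></html>")
        assert load_graph(p, "html_embed") == "<html><body>net</body></html>"

    def test_symmetric_adjacency_edge_count_property(self):
        # edge count == nonzero upper-triangle count, over random matrices
        rng = np.random.default_rng(2024)
        for trial in range(50):
            n = int(rng.integers(2, 8))
            upper = rng.random((n, n)) < 0.4
            mat = np.triu(upper, k=1).astype(float) * rng.random((n, n))
            mat = mat + mat.T
            expected = int(np.count_nonzero(np.triu(mat, k=1)))
            labels = [f"n{i}" for i in range(n)]
            df = pd.DataFrame(mat, index=labels, columns=labels)
            import io

            text = df.to_csv()
            path = None
            # write to a temp file for the loader
            import tempfile, os

            fd, path = tempfile.mkstemp(suffix=".csv")
            with os.fdopen(fd, "w") as fh:
                fh.write(text)
            try:
                g = load_graph(path, "adjacency")
            finally:
                os.unlink(path)
            assert g.n_edges == expected, f"trial {trial}"
            assert not g.directed

    def test_edge_list_round_trip_is_isomorphic(self, tmp_path):
        g = Graph(
            nodes=["a", "b", "c", "d"],
            edges=[("a", "b", 1.0), ("b", "c", 0.5), ("c", "d", 2.0)],
        )
        p = tmp_path / "edges.csv"
        p.write_text(graph_to_edge_list_text(g))
        g2 = load_graph(p, "edge_list")
        assert set(g2.nodes) == set(g.nodes)
        assert sorted(map(tuple, g2.edges)) == sorted(map(tuple, g.edges))


class TestPlotDialect:
    @pytest.mark.parametrize(
        "payload,expected",
        [
            (
                {"$schema": "https://vega.github.io/schema/vega-lite/v5.json"},
                PlotDialect.VEGA_FAMILY,
            ),
            ({"data": [], "layout": {}}, PlotDialect.FIGURE_OBJECT),
            ({"foo": 1}, PlotDialect.UNKNOWN),
            ([1, 2, 3], PlotDialect.UNKNOWN),
            ({"data": []}, PlotDialect.UNKNOWN),
        ],
    )
    def test_detection_rule(self, payload, expected):
        assert detect_plot_dialect(payload) is expected


class TestTextComponents:
    def test_markdown_passthrough_is_byte_identical(self, tmp_path):
        content = "## Heading\n\n$E = mc^2$\n\n| a | b |\n|---|---|\n"
        p = tmp_path / "notes.md"
        p.write_text(content)
        assert load_text_component(p, "markdown") == content

    def test_empty_file_warns(self, tmp_path, caplog):
        p = tmp_path / "empty.md"
        p.write_text("")
        with caplog.at_level("WARNING"):
            assert load_text_component(p) == ""
        assert any("empty" in r.message for r in caplog.records)

    def test_non_utf8_replacement_decoded_with_warning(self, tmp_path, caplog):
        p = tmp_path / "latin.md"
        p.write_bytes(b"caf\xe9")
        with caplog.at_level("WARNING"):
            text = load_text_component(p)
        assert "caf" in text and "�" in text
        assert any("UTF-8" in r.message for r in caplog.records)

    def test_missing_file_errors(self, tmp_path):
        with pytest.raises(LoadError):
            load_text_component(tmp_path / "nope.md")
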
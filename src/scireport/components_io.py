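"""Load and normalize component payloads: tables, graphs, plot specs, text.

Tables come from CSV/TXT (with a delimiter probe), Parquet, or XLSX and
are normalized to a simple header + rows container. Graphs come from
edge lists, labeled adjacency matrices, or the standard graph-exchange
formats (GraphML/GML/GEXF/CYJS); symmetric adjacency matrices give an
undirected graph with each pair emitted once, asymmetric ones a directed
graph, and the diagonal is ignored. Interactive plot JSON is classified
by dialect: Plotly-style figure objects versus the Vega family.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional, Union

import networkx as nx
import numpy as np
import pandas as pd

from .config_model import NetworkFormat, PlotDialect, TableFormat

logger = logging.getLogger(__name__)

__all__ = [
    "Table",
    "Graph",
    "PlotSpec",
    "LoadError",
    "probe_delimiter",
    "load_table",
    "load_graph",
    "graph_to_edge_list_text",
    "detect_plot_dialect",
    "load_plot_spec",
    "load_text_component",
]


class LoadError(ValueError):
    """Raised when a component payload cannot be loaded."""


@dataclass
class Table:
    column_names: list[str]
    rows: list[tuple]

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.column_names)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "Table":
        return cls(
            column_names=[str(c) for c in df.columns],
            rows=[tuple(r) for r in df.itertuples(index=False, name=None)],
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=self.column_names)


@dataclass
class Graph:
    nodes: list
    edges: list[tuple]  # (source, target) or (source, target, weight)
    directed: bool = False
    edge_attrs: list[dict] = field(default_factory=list)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def to_networkx(self) -> Union[nx.Graph, nx.DiGraph]:
        g = nx.DiGraph() if self.directed else nx.Graph()
        g.add_nodes_from(self.nodes)
        for i, e in enumerate(self.edges):
            attrs = dict(self.edge_attrs[i]) if i < len(self.edge_attrs) else {}
            if len(e) > 2 and e[2] is not None:
                attrs.setdefault("weight", e[2])
            g.add_edge(e[0], e[1], **attrs)
        return g


@dataclass
class PlotSpec:
    dialect: PlotDialect
    json_payload: Any


# --------------------------------------------------------------------------
# Tables
# --------------------------------------------------------------------------

_PROBE_CANDIDATES = (",", "\t", ";")


def probe_delimiter(text: str, n_lines: int = 10) -> str:
    """Pick the delimiter by majority vote over the first ``n_lines`` lines.

    Each line votes for the candidate (comma, tab, semicolon) it contains
    most occurrences of; ties and blank lines abstain. Falls back to comma.
    """
    votes = {c: 0 for c in _PROBE_CANDIDATES}
    for line in text.splitlines()[:n_lines]:
        counts = {c: line.count(c) for c in _PROBE_CANDIDATES}
        best = max(counts.values())
        if best == 0:
            continue
        winners = [c for c, n in counts.items() if n == best]
        if len(winners) == 1:
            votes[winners[0]] += 1
    best = max(votes.values())
    if best == 0:
        return ","
    for c in _PROBE_CANDIDATES:  # fixed preference order on overall ties
        if votes[c] == best:
            return c
    return ","


def load_table(
    path: Union[str, Path],
    file_format: Optional[Union[str, TableFormat]] = None,
    delimiter: Optional[str] = None,
) -> Table:
    """Load a tabular component into a :class:`Table`.

    For delimited text the header row supplies column names and an
    unconfigured delimiter is probed; a configured delimiter always wins.
    XLSX reads the first sheet only (a warning is logged if there are
    more). Empty and ragged files raise :class:`LoadError`.
    """
    path = Path(path)
    if not path.is_file():
        raise LoadError(f"table file not found: {path}")
    fmt = (
        TableFormat(file_format)
        if file_format is not None
        else TableFormat(path.suffix.lstrip(".").lower())
    )

    if fmt in (TableFormat.CSV, TableFormat.TXT):
        text = path.read_text(encoding="utf-8", errors="replace")
        if not text.strip():
            raise LoadError(f"empty table file: {path}")
        sep = delimiter if delimiter is not None else probe_delimiter(text)
        try:
            df = pd.read_csv(path, sep=sep)
        except pd.errors.ParserError as exc:
            raise LoadError(f"ragged delimited file {path}: {exc}") from exc
        # pandas tolerates short rows by filling NaN; enforce rectangularity.
        widths = {
            len(line.split(sep))
            for line in text.splitlines()
            if line.strip()
        }
        if len(widths) > 1:
            bad = next(
                i + 1
                for i, line in enumerate(text.splitlines())
                if line.strip() and len(line.split(sep)) != len(df.columns)
            )
            raise LoadError(f"ragged delimited file {path}: line {bad}")
        return Table.from_dataframe(df)

    if fmt is TableFormat.PARQUET:
        return Table.from_dataframe(pd.read_parquet(path))

    if fmt is TableFormat.XLSX:
        xl = pd.ExcelFile(path)
        if len(xl.sheet_names) > 1:
            logger.warning(
                "%s has %d sheets; reading the first only", path, len(xl.sheet_names)
            )
        df = xl.parse(xl.sheet_names[0])
        if df.empty and df.columns.empty:
            raise LoadError(f"empty table file: {path}")
        return Table.from_dataframe(df)

    raise LoadError(f"unsupported table format: {fmt}")


# --------------------------------------------------------------------------
# Graphs
# --------------------------------------------------------------------------


def _graph_from_networkx(g) -> Graph:
    directed = g.is_directed()
    edges = []
    attrs = []
    for u, v, data in g.edges(data=True):
        w = data.get("weight")
        edges.append((u, v, w) if w is not None else (u, v))
        attrs.append({k: val for k, val in data.items() if k != "weight"})
    return Graph(nodes=list(g.nodes), edges=edges, directed=directed, edge_attrs=attrs)


def _load_edge_list(path: Path, delimiter: Optional[str]) -> Graph:
    text = path.read_text(encoding="utf-8", errors="replace")
    if not text.strip():
        raise LoadError(f"empty edge list: {path}")
    sep = delimiter if delimiter is not None else probe_delimiter(text)
    df = pd.read_csv(path, sep=sep)
    if df.shape[1] < 2:
        raise LoadError(f"edge list {path} needs at least 2 columns, got {df.shape[1]}")
    nodes: list = []
    seen = set()
    edges = []
    attrs = []
    extra_cols = list(df.columns[3:])
    weight_col = df.columns[2] if df.shape[1] >= 3 else None
    if weight_col is not None and not pd.api.types.is_numeric_dtype(df[weight_col]):
        extra_cols = [weight_col] + extra_cols
        weight_col = None
    for row in df.itertuples(index=False):
        u, v = row[0], row[1]
        for n in (u, v):
            if n not in seen:
                seen.add(n)
                nodes.append(n)
        if weight_col is not None:
            edges.append((u, v, row[2]))
        else:
            edges.append((u, v))
        attrs.append({c: getattr(row, c) for c in extra_cols if hasattr(row, c)})
    return Graph(nodes=nodes, edges=edges, directed=False, edge_attrs=attrs)


def _load_adjacency(path: Path, delimiter: Optional[str]) -> Graph:
    text = path.read_text(encoding="utf-8", errors="replace")
    sep = delimiter if delimiter is not None else probe_delimiter(text)
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.shape[0] != df.shape[1]:
        raise LoadError(
            f"adjacency matrix {path} is not square: {df.shape[0]}x{df.shape[1]}"
        )
    labels = [str(c) for c in df.columns]
    mat = df.to_numpy(dtype=float)
    symmetric = np.allclose(mat, mat.T)
    edges = []
    n = len(labels)
    for i in range(n):
        rng = range(i + 1, n) if symmetric else range(n)
        for j in rng:
            if i == j:
                continue  # diagonal ignored
            w = mat[i, j]
            if w != 0:
                edges.append((labels[i], labels[j], float(w)))
    return Graph(
        nodes=labels,
        edges=edges,
        directed=not symmetric,
        edge_attrs=[{} for _ in edges],
    )


def _load_cyjs(path: Path) -> Graph:
    payload = json.loads(path.read_text(encoding="utf-8"))
    g = nx.cytoscape_graph(payload)
    return _graph_from_networkx(g)


def load_graph(
    path: Union[str, Path],
    net_format: Optional[Union[str, NetworkFormat]] = None,
    delimiter: Optional[str] = None,
) -> Union[Graph, str]:
    """Load a network component.

    Edge lists and adjacency matrices come from delimited text; the
    exchange formats are parsed with networkx. ``html_embed`` payloads are
    returned as raw text, unparsed, for direct embedding.
    """
    path = Path(path)
    if not path.is_file():
        raise LoadError(f"network file not found: {path}")
    if net_format is None:
        net_format = NetworkFormat(path.suffix.lstrip(".").lower())
    fmt = NetworkFormat(net_format)

    if fmt is NetworkFormat.EDGE_LIST:
        return _load_edge_list(path, delimiter)
    if fmt is NetworkFormat.ADJACENCY:
        return _load_adjacency(path, delimiter)
    if fmt is NetworkFormat.GRAPHML:
        return _graph_from_networkx(nx.read_graphml(path))
    if fmt is NetworkFormat.GML:
        return _graph_from_networkx(nx.read_gml(path))
    if fmt is NetworkFormat.GEXF:
        return _graph_from_networkx(nx.read_gexf(path))
    if fmt is NetworkFormat.CYJS:
        return _load_cyjs(path)
    if fmt is NetworkFormat.HTML_EMBED:
        return path.read_text(encoding="utf-8", errors="replace")
    raise LoadError(f"unsupported network format: {fmt}")


def graph_to_edge_list_text(graph: Graph, delimiter: str = ",") -> str:
    """Serialize a graph to edge-list text (source, target[, weight])."""
    weighted = any(len(e) > 2 for e in graph.edges)
    header = ["source", "target"] + (["weight"] if weighted else [])
    lines = [delimiter.join(header)]
    for e in graph.edges:
        row = [str(e[0]), str(e[1])]
        if weighted:
            row.append(str(e[2]) if len(e) > 2 else "1")
        lines.append(delimiter.join(row))
    return "\n".join(lines) + "\n"


# --------------------------------------------------------------------------
# Plot specs and text components
# --------------------------------------------------------------------------


def detect_plot_dialect(json_payload: Any) -> PlotDialect:
    """Classify a parsed plot-JSON payload.

    A top-level ``$schema`` string containing "vega" marks the Vega
    family (Vega / Vega-Lite, as written by Altair); top-level ``data``
    plus ``layout`` keys mark a Plotly-style figure object; anything else
    is unknown and will be shown as a code block rather than a chart.
    """
    if isinstance(json_payload, dict):
        schema = json_payload.get("$schema")
        if isinstance(schema, str) and "vega" in schema.lower():
            return PlotDialect.VEGA_FAMILY
        if "data" in json_payload and "layout" in json_payload:
            return PlotDialect.FIGURE_OBJECT
    return PlotDialect.UNKNOWN


def load_plot_spec(path: Union[str, Path]) -> PlotSpec:
    path = Path(path)
    try:
        payload = json.loads(path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise LoadError(f"invalid plot JSON {path}: {exc}") from exc
    return PlotSpec(dialect=detect_plot_dialect(payload), json_payload=payload)


def load_text_component(path: Union[str, Path], kind: str = "markdown") -> str:
    """Return a Markdown/HTML component's raw text, unmodified.

    Inputs are trusted local files, so no sanitization is applied.
    Non-UTF-8 bytes are replacement-decoded with a warning; an empty file
    is allowed but warned about.
    """
    path = Path(path)
    if not path.exists():
        raise LoadError(f"{kind} file not found: {path}")
    data = path.read_bytes()
    try:
        text = data.decode("utf-8")
    except UnicodeDecodeError:
        logger.warning("%s is not valid UTF-8; using replacement decoding", path)
        text = data.decode("utf-8", errors="replace")
    if not text:
        logger.warning("%s is empty", path)
    return text
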
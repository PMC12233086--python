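"""Deterministic synthetic example directories for demos and tests.

Two generators produce small results directories of the kind the tool
ingests, together with a ground-truth manifest of what was written:

* :func:`make_basic_fixture` — a general tree covering every component
  subtype at least once (static images, interactive plot JSON in both
  dialects, all four table formats, an edge-list CSV, GraphML, Markdown,
  HTML) with numeric name suffixes exercising the ordering rules.
* :func:`make_emp_style_fixture` — a microbiome-survey-shaped tree with
  sections on exploratory data analysis, metagenomics, and network
  analysis (ordination scatter, abundance tables, a co-occurrence
  graph). The contents are synthetic stand-ins, not real survey data.

All content is a pure function of the seed — no timestamps, no
filesystem ordering effects — so regenerating a fixture yields a
byte-identical tree. Charts are tiny (≤ 20 points) so static export is
fast.
"""

from __future__ import annotations

import datetime
import io
import json
import re
import zipfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import networkx as nx
import numpy as np
import openpyxl
import pandas as pd

from .config_model import (
    Component,
    ComponentKind,
    DataFrameAttrs,
    NetworkAttrs,
    NetworkFormat,
    PlotAttrs,
    PlotFormat,
    ReportSpec,
    Section,
    Subsection,
    TableFormat,
)

__all__ = ["FixtureManifest", "make_basic_fixture", "make_emp_style_fixture"]


@dataclass
class FixtureManifest:
    """Ground truth for a generated fixture directory.

    ``file_list`` holds (relative path, kind, subtype) for every file
    written; ``expected`` aggregates counts; :meth:`expected_spec`
    rebuilds the report structure the scanner must infer, written out by
    hand so it is independent of the scanner.
    """

    root: Path
    seed: int
    file_list: list[tuple[str, str, str]]
    _spec_builder: object = field(default=None, repr=False, compare=False)

    @property
    def expected(self) -> dict:
        spec = self.expected_spec()
        kinds: dict[str, int] = {}
        for _, kind, _ in self.file_list:
            kinds[kind] = kinds.get(kind, 0) + 1
        return {
            "sections": len(spec.sections),
            "subsections": sum(len(s.subsections) for s in spec.sections),
            "components": len(self.file_list),
            "kinds": kinds,
        }

    def expected_spec(self) -> ReportSpec:
        return self._spec_builder(self.root)


# --------------------------------------------------------------------------
# Deterministic file writers
# --------------------------------------------------------------------------

_FIXED_DATE = datetime.datetime(2000, 1, 1)


def _write_png_bar(path: Path, rng: np.random.Generator, labels, title: str) -> None:
    values = rng.integers(5, 60, size=len(labels))
    fig, ax = plt.subplots(figsize=(5, 3), dpi=100)
    ax.bar(labels, values, color="#4c78a8")
    ax.set_title(title)
    ax.set_ylabel("relative abundance (%)")
    fig.tight_layout()
    fig.savefig(path, format="png", metadata={"Software": None})
    plt.close(fig)


def _write_svg_heatmap(path: Path, rng: np.random.Generator, n: int = 4) -> None:
    # Hand-built SVG: a small colored grid; byte-stable by construction.
    cell = 40
    values = rng.random((n, n))
    rects = []
    for i in range(n):
        for j in range(n):
            shade = int(255 * (1 - values[i, j]))
            rects.append(
                f'<rect x="{j * cell}" y="{i * cell}" width="{cell}" '
                f'height="{cell}" fill="rgb({shade},{shade},255)"/>'
            )
    svg = (
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{n * cell}" '
        f'height="{n * cell}">' + "".join(rects) + "</svg>\n"
    )
    path.write_text(svg, encoding="utf-8")


def _write_vega_scatter(path: Path, rng: np.random.Generator, xf: str, yf: str) -> None:
    values = [
        {xf: round(float(x), 3), yf: round(float(y), 3)}
        for x, y in rng.random((12, 2))
    ]
    spec = {
        "$schema": "https://vega.github.io/schema/vega-lite/v5.json",
        "mark": "point",
        "data": {"values": values},
        "encoding": {
            "x": {"field": xf, "type": "quantitative"},
            "y": {"field": yf, "type": "quantitative"},
        },
    }
    path.write_text(json.dumps(spec, indent=2, sort_keys=True) + "\n", encoding="utf-8")


def _write_plotly_scatter(path: Path, rng: np.random.Generator, title: str) -> None:
    xs = list(range(1, 11))
    ys = [round(float(v), 3) for v in np.cumsum(rng.normal(1.0, 0.4, size=10))]
    fig = {
        "data": [{"type": "scatter", "mode": "lines+markers", "x": xs, "y": ys,
                  "name": "series 1"}],
        "layout": {"title": {"text": title}},
    }
    path.write_text(json.dumps(fig, indent=2, sort_keys=True) + "\n", encoding="utf-8")


def _random_table(rng: np.random.Generator, n: int = 6) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample": [f"S{i + 1}" for i in range(n)],
            "reads": rng.integers(1_000, 50_000, size=n),
            "richness": np.round(rng.uniform(10, 200, size=n), 1),
        }
    )


def _write_xlsx(df: pd.DataFrame, path: Path) -> None:
    """Write an xlsx whose bytes depend only on the data.

    openpyxl stamps the save time into the document properties and the
    zip entry headers; both are normalized away here.
    """
    wb = openpyxl.Workbook()
    ws = wb.active
    ws.title = "data"
    ws.append(list(df.columns))
    for row in df.itertuples(index=False, name=None):
        ws.append([v.item() if hasattr(v, "item") else v for v in row])
    wb.properties.created = _FIXED_DATE
    wb.properties.modified = _FIXED_DATE
    buf = io.BytesIO()
    wb.save(buf)
    out = io.BytesIO()
    with zipfile.ZipFile(buf) as zin, zipfile.ZipFile(
        out, "w", zipfile.ZIP_DEFLATED
    ) as zout:
        for name in sorted(zin.namelist()):
            data = zin.read(name)
            if name == "docProps/core.xml":
                data = re.sub(
                    rb"(<dcterms:modified[^>]*>)[^<]*(</dcterms:modified>)",
                    rb"\g<1>2000-01-01T00:00:00Z\g<2>",
                    data,
                )
            info = zipfile.ZipInfo(name, date_time=(1980, 1, 1, 0, 0, 0))
            info.compress_type = zipfile.ZIP_DEFLATED
            zout.writestr(info, data)
    path.write_bytes(out.getvalue())


def _random_graph(rng: np.random.Generator, n: int = 5, m: int = 4) -> nx.Graph:
    g = nx.gnm_random_graph(n, m, seed=int(rng.integers(0, 2**31 - 1)))
    return nx.relabel_nodes(g, {i: f"taxon_{i + 1}" for i in g.nodes})


def _write_graphml(g: nx.Graph, path: Path) -> None:
    nx.write_graphml(g, path)


def _write_edge_list(g: nx.Graph, path: Path, rng: np.random.Generator) -> None:
    lines = ["source,target,weight"]
    for u, v in g.edges:
        lines.append(f"{u},{v},{round(float(rng.uniform(0.1, 1.0)), 3)}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


_MARKDOWN_BODY = """\
### About this {what}

This {what} was produced by the synthetic fixture generator. It stands in
for free-form notes an analyst would drop next to their results:

- seeded content, identical across runs
- a little *formatting* and an equation: $H' = -\\sum_i p_i \\ln p_i$
"""

_HTML_BODY = """\
<div class="summary">
  <h3>Run summary</h3>
  <p>Synthetic HTML component; {n_samples} samples processed.</p>
  <table><tr><th>metric</th><th>value</th></tr>
  <tr><td>mean depth</td><td>{depth}</td></tr></table>
</div>
"""


# --------------------------------------------------------------------------
# Basic fixture
# --------------------------------------------------------------------------


def _basic_expected_spec(root: Path) -> ReportSpec:
    def plot(title, path, fmt):
        return Component(
            title=title, kind=ComponentKind.PLOT, file_path=path,
            attrs=PlotAttrs(plot_format=PlotFormat(fmt)),
        )

    def table(title, path, fmt):
        return Component(
            title=title, kind=ComponentKind.DATAFRAME, file_path=path,
            attrs=DataFrameAttrs(file_format=TableFormat(fmt)),
        )

    def net(title, path, fmt):
        return Component(
            title=title, kind=ComponentKind.NETWORK, file_path=path,
            attrs=NetworkAttrs(net_format=NetworkFormat(fmt)),
        )

    def text(title, path, kind):
        return Component(title=title, kind=ComponentKind(kind), file_path=path)

    return ReportSpec(
        title="Basic Example Report",
        base_dir=root,
        sections=[
            Section(
                title="Exploratory Data Analysis",
                subsections=[
                    Subsection(
                        title="Summary Figures",
                        components=[
                            plot("Phylum Barplot",
                                 "exploratory_data_analysis_1/summary_figures_1/phylum_barplot_2.png",
                                 "static_image"),
                            plot("Alpha Diversity",
                                 "exploratory_data_analysis_1/summary_figures_1/alpha_diversity_10.json",
                                 "interactive_json"),
                            text("Intro",
                                 "exploratory_data_analysis_1/summary_figures_1/intro.md",
                                 "markdown"),
                        ],
                    ),
                    Subsection(
                        title="Statistics",
                        components=[
                            table("Abundance Table",
                                  "exploratory_data_analysis_1/statistics_2/abundance_table_1.csv",
                                  "csv"),
                            table("Sample Metadata",
                                  "exploratory_data_analysis_1/statistics_2/sample_metadata_2.txt",
                                  "txt"),
                            table("Read Counts",
                                  "exploratory_data_analysis_1/statistics_2/read_counts_3.parquet",
                                  "parquet"),
                            table("Measurements",
                                  "exploratory_data_analysis_1/statistics_2/measurements_4.xlsx",
                                  "xlsx"),
                        ],
                    ),
                ],
            ),
            Section(
                title="Network Analysis",
                subsections=[
                    Subsection(
                        title="Cooccurrence Networks",
                        components=[
                            net("Cooccurrence",
                                "network_analysis_2/cooccurrence_networks_1/cooccurrence.graphml",
                                "graphml"),
                            net("Taxa Edge List",
                                "network_analysis_2/cooccurrence_networks_1/taxa_edge_list.csv",
                                "edge_list"),
                        ],
                    ),
                    Subsection(
                        title="Notes",
                        components=[
                            text("Methods",
                                 "network_analysis_2/notes_2/methods.md", "markdown"),
                            text("Summary",
                                 "network_analysis_2/notes_2/summary.html", "html"),
                        ],
                    ),
                ],
            ),
            Section(
                title="Appendix",
                components=[
                    text("Readme", "appendix/readme.md", "markdown"),
                ],
                subsections=[
                    Subsection(
                        title="Extra Figures",
                        components=[
                            plot("Overview Heatmap",
                                 "appendix/extra_figures/overview_heatmap.svg",
                                 "static_image"),
                            plot("Scatter Interactive",
                                 "appendix/extra_figures/scatter_interactive.json",
                                 "interactive_json"),
                        ],
                    ),
                ],
            ),
        ],
    )


def make_basic_fixture(outdir: Union[str, Path], seed: int = 7) -> FixtureManifest:
    """Write the general example directory under ``outdir`` and return
    its manifest. ``outdir`` itself is the report root (3 sections, 5
    subsections, 14 component files). Deterministic for a given seed."""
    root = Path(outdir)
    root.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    eda = root / "exploratory_data_analysis_1"
    figs = eda / "summary_figures_1"
    stats = eda / "statistics_2"
    netsec = root / "network_analysis_2"
    coocc = netsec / "cooccurrence_networks_1"
    notes = netsec / "notes_2"
    appendix = root / "appendix"
    extra = appendix / "extra_figures"
    for d in (figs, stats, coocc, notes, extra):
        d.mkdir(parents=True, exist_ok=True)

    phyla = ["Proteo", "Firmi", "Actino", "Bactero"]
    _write_png_bar(figs / "phylum_barplot_2.png", rng, phyla, "Phylum composition")
    _write_vega_scatter(figs / "alpha_diversity_10.json", rng, "depth", "shannon")
    (figs / "intro.md").write_text(
        _MARKDOWN_BODY.format(what="figure set"), encoding="utf-8"
    )

    df = _random_table(rng)
    df.to_csv(stats / "abundance_table_1.csv", index=False)
    df.assign(group=["A", "B"] * 3).to_csv(
        stats / "sample_metadata_2.txt", sep="\t", index=False
    )
    df.to_parquet(stats / "read_counts_3.parquet", index=False)
    _write_xlsx(df, stats / "measurements_4.xlsx")

    g = _random_graph(rng)
    _write_graphml(g, coocc / "cooccurrence.graphml")
    _write_edge_list(g, coocc / "taxa_edge_list.csv", rng)

    (notes / "methods.md").write_text(
        _MARKDOWN_BODY.format(what="analysis"), encoding="utf-8"
    )
    (notes / "summary.html").write_text(
        _HTML_BODY.format(n_samples=6, depth=round(float(rng.uniform(20, 80)), 1)),
        encoding="utf-8",
    )

    _write_svg_heatmap(extra / "overview_heatmap.svg", rng)
    _write_plotly_scatter(
        extra / "scatter_interactive.json", rng, "Cumulative signal"
    )
    (appendix / "readme.md").write_text(
        _MARKDOWN_BODY.format(what="appendix"), encoding="utf-8"
    )

    spec = _basic_expected_spec(root)
    file_list = []
    for _, _, comp in spec.iter_components():
        cls_sub = {
            ComponentKind.PLOT: lambda c: c.attrs.plot_format.value,
            ComponentKind.DATAFRAME: lambda c: c.attrs.file_format.value,
            ComponentKind.NETWORK: lambda c: c.attrs.net_format.value,
            ComponentKind.MARKDOWN: lambda c: "md",
            ComponentKind.HTML: lambda c: "html",
        }[comp.kind](comp)
        file_list.append((comp.file_path, comp.kind.value, cls_sub))

    return FixtureManifest(
        root=root, seed=seed, file_list=file_list, _spec_builder=_basic_expected_spec
    )


# --------------------------------------------------------------------------
# Microbiome-survey-style fixture
# --------------------------------------------------------------------------


def _emp_expected_spec(root: Path) -> ReportSpec:
    return ReportSpec(
        title="Microbiome Survey Report",
        base_dir=root,
        sections=[
            Section(
                title="Exploratory Data Analysis",
                subsections=[
                    Subsection(
                        title="Sample Overview",
                        components=[
                            Component(
                                title="Ordination Scatter",
                                kind=ComponentKind.PLOT,
                                file_path="exploratory_data_analysis_1/sample_overview_1/ordination_scatter.json",
                                attrs=PlotAttrs(plot_format=PlotFormat.INTERACTIVE_JSON),
                            ),
                            Component(
                                title="Sample Metadata",
                                kind=ComponentKind.DATAFRAME,
                                file_path="exploratory_data_analysis_1/sample_overview_1/sample_metadata.csv",
                                attrs=DataFrameAttrs(file_format=TableFormat.CSV),
                            ),
                        ],
                    ),
                ],
            ),
            Section(
                title="Metagenomics",
                subsections=[
                    Subsection(
                        title="Taxonomy",
                        components=[
                            Component(
                                title="Phylum Abundance",
                                kind=ComponentKind.DATAFRAME,
                                file_path="metagenomics_2/taxonomy_1/phylum_abundance.csv",
                                attrs=DataFrameAttrs(file_format=TableFormat.CSV),
                            ),
                            Component(
                                title="Taxa Barplot",
                                kind=ComponentKind.PLOT,
                                file_path="metagenomics_2/taxonomy_1/taxa_barplot.png",
                                attrs=PlotAttrs(plot_format=PlotFormat.STATIC_IMAGE),
                            ),
                        ],
                    ),
                    Subsection(
                        title="Diversity",
                        components=[
                            Component(
                                title="Alpha Diversity Trend",
                                kind=ComponentKind.PLOT,
                                file_path="metagenomics_2/diversity_2/alpha_diversity_trend.json",
                                attrs=PlotAttrs(plot_format=PlotFormat.INTERACTIVE_JSON),
                            ),
                            Component(
                                title="Diversity Summary",
                                kind=ComponentKind.MARKDOWN,
                                file_path="metagenomics_2/diversity_2/diversity_summary.md",
                            ),
                        ],
                    ),
                ],
            ),
            Section(
                title="Network Analysis",
                subsections=[
                    Subsection(
                        title="Cooccurrence",
                        components=[
                            Component(
                                title="Cooccurrence Network",
                                kind=ComponentKind.NETWORK,
                                file_path="network_analysis_3/cooccurrence_1/cooccurrence_network.graphml",
                                attrs=NetworkAttrs(net_format=NetworkFormat.GRAPHML),
                            ),
                            Component(
                                title="Taxa Edge List",
                                kind=ComponentKind.NETWORK,
                                file_path="network_analysis_3/cooccurrence_1/taxa_edge_list.csv",
                                attrs=NetworkAttrs(net_format=NetworkFormat.EDGE_LIST),
                            ),
                        ],
                    ),
                ],
            ),
        ],
    )


def make_emp_style_fixture(outdir: Union[str, Path], seed: int = 7) -> FixtureManifest:
    """Write a microbiome-survey-shaped example directory: sections on
    exploratory data analysis, metagenomics, and network analysis."""
    root = Path(outdir)
    root.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    overview = root / "exploratory_data_analysis_1" / "sample_overview_1"
    taxonomy = root / "metagenomics_2" / "taxonomy_1"
    diversity = root / "metagenomics_2" / "diversity_2"
    coocc = root / "network_analysis_3" / "cooccurrence_1"
    for d in (overview, taxonomy, diversity, coocc):
        d.mkdir(parents=True, exist_ok=True)

    _write_vega_scatter(overview / "ordination_scatter.json", rng, "PC1", "PC2")
    _random_table(rng).to_csv(overview / "sample_metadata.csv", index=False)

    phyla = ["Proteo", "Firmi", "Actino", "Bactero", "Cyano"]
    abundance = pd.DataFrame(
        {
            "phylum": phyla,
            "mean_abundance": np.round(rng.dirichlet(np.ones(5)) * 100, 2),
        }
    )
    abundance.to_csv(taxonomy / "phylum_abundance.csv", index=False)
    _write_png_bar(taxonomy / "taxa_barplot.png", rng, phyla, "Taxa composition")

    _write_plotly_scatter(
        diversity / "alpha_diversity_trend.json", rng, "Alpha diversity by depth"
    )
    (diversity / "diversity_summary.md").write_text(
        _MARKDOWN_BODY.format(what="diversity analysis"), encoding="utf-8"
    )

    g = _random_graph(rng, n=6, m=7)
    _write_graphml(g, coocc / "cooccurrence_network.graphml")
    _write_edge_list(g, coocc / "taxa_edge_list.csv", rng)

    spec = _emp_expected_spec(root)
    file_list = []
    for _, _, comp in spec.iter_components():
        sub = {
            ComponentKind.PLOT: lambda c: c.attrs.plot_format.value,
            ComponentKind.DATAFRAME: lambda c: c.attrs.file_format.value,
            ComponentKind.NETWORK: lambda c: c.attrs.net_format.value,
            ComponentKind.MARKDOWN: lambda c: "md",
            ComponentKind.HTML: lambda c: "html",
        }[comp.kind](comp)
        file_list.append((comp.file_path, comp.kind.value, sub))

    return FixtureManifest(
        root=root, seed=seed, file_list=file_list, _spec_builder=_emp_expected_spec
    )
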
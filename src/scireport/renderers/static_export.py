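"""Static export: turn interactive charts and networks into PNG images.

Static report formats (PDF, DOCX, ODT, PPTX) cannot host interactive
widgets, so plot-JSON payloads and networks are rasterized first. The
exporter renders the two supported chart dialects with matplotlib:
Plotly-style figure objects (scatter/line/bar traces) and Vega-Lite
specs (point/circle/line/bar marks with inline data values). Networks
are drawn with a spring layout under a fixed seed so repeated exports
are byte-identical. Anything the exporter cannot draw raises
:class:`StaticizeError` naming the unsupported feature — never a silent
blank image.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Union

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import networkx as nx

from ..components_io import Graph, PlotSpec
from ..config_model import PlotDialect

__all__ = [
    "StaticizeError",
    "DEFAULT_SIZE_PX",
    "DEFAULT_LAYOUT_SEED",
    "render_plot_png",
    "render_graph_png",
]


class StaticizeError(RuntimeError):
    """Raised when an interactive payload cannot be exported to an image."""


#: Default export size in pixels (width, height); fits A4 and slide layouts.
DEFAULT_SIZE_PX = (1000, 600)
#: Fixed seed for network layouts, for reproducible drawings.
DEFAULT_LAYOUT_SEED = 42

_DPI = 100


def _new_figure(size_px: tuple[int, int]):
    w, h = size_px
    return plt.subplots(figsize=(w / _DPI, h / _DPI), dpi=_DPI)


def _save(fig, out: Path) -> None:
    out.parent.mkdir(parents=True, exist_ok=True)
    # Drop the Software metadata chunk so repeated exports are byte-identical
    # across matplotlib point releases too.
    fig.savefig(out, format="png", metadata={"Software": None})
    plt.close(fig)


def _title_text(raw) -> Optional[str]:
    if isinstance(raw, dict):
        return raw.get("text")
    if isinstance(raw, str):
        return raw
    return None


def _render_figure_object(payload: dict, ax) -> None:
    traces = payload.get("data") or []
    if not isinstance(traces, list) or not traces:
        raise StaticizeError("figure object has no data traces")
    for trace in traces:
        ttype = trace.get("type", "scatter")
        x, y = trace.get("x"), trace.get("y")
        if x is None or y is None:
            raise StaticizeError(f"trace of type {ttype!r} lacks x/y data")
        label = trace.get("name")
        if ttype == "scatter":
            mode = trace.get("mode", "lines")
            if "lines" in mode:
                ax.plot(x, y, marker="o" if "markers" in mode else None, label=label)
            else:
                ax.scatter(x, y, label=label)
        elif ttype == "bar":
            ax.bar(x, y, label=label)
        else:
            raise StaticizeError(f"no static export support for trace type {ttype!r}")
    layout = payload.get("layout") or {}
    title = _title_text(layout.get("title"))
    if title:
        ax.set_title(title)
    xaxis = layout.get("xaxis") or {}
    yaxis = layout.get("yaxis") or {}
    if _title_text(xaxis.get("title")):
        ax.set_xlabel(_title_text(xaxis.get("title")))
    if _title_text(yaxis.get("title")):
        ax.set_ylabel(_title_text(yaxis.get("title")))
    if any(t.get("name") for t in traces):
        ax.legend()


def _render_vega(payload: dict, ax) -> None:
    data = payload.get("data")
    values = data.get("values") if isinstance(data, dict) else None
    if not values:
        raise StaticizeError("vega spec without inline data.values")
    mark = payload.get("mark")
    if isinstance(mark, dict):
        mark = mark.get("type")
    encoding = payload.get("encoding") or {}
    xf = (encoding.get("x") or {}).get("field")
    yf = (encoding.get("y") or {}).get("field")
    if xf is None or yf is None:
        raise StaticizeError("vega spec without x/y field encoding")
    x = [row.get(xf) for row in values]
    y = [row.get(yf) for row in values]
    if mark in ("point", "circle", "square", "tick"):
        ax.scatter(x, y)
    elif mark == "line":
        ax.plot(x, y)
    elif mark == "bar":
        ax.bar(x, y)
    else:
        raise StaticizeError(f"no static export support for vega mark {mark!r}")
    ax.set_xlabel(xf)
    ax.set_ylabel(yf)
    title = _title_text(payload.get("title"))
    if title:
        ax.set_title(title)


def render_plot_png(
    spec: PlotSpec,
    out: Union[str, Path],
    size_px: tuple[int, int] = DEFAULT_SIZE_PX,
) -> Path:
    """Rasterize an interactive plot spec to a PNG at ``out``."""
    out = Path(out)
    fig, ax = _new_figure(size_px)
    try:
        if spec.dialect is PlotDialect.FIGURE_OBJECT:
            _render_figure_object(spec.json_payload, ax)
        elif spec.dialect is PlotDialect.VEGA_FAMILY:
            _render_vega(spec.json_payload, ax)
        else:
            raise StaticizeError(
                "cannot export a plot JSON of unknown dialect to an image"
            )
    except Exception:
        plt.close(fig)
        raise
    _save(fig, out)
    return out


def render_graph_png(
    graph: Graph,
    out: Union[str, Path],
    size_px: tuple[int, int] = DEFAULT_SIZE_PX,
    layout_seed: int = DEFAULT_LAYOUT_SEED,
    title: Optional[str] = None,
) -> Path:
    """Draw a network with a seeded spring layout and save it as PNG."""
    out = Path(out)
    g = graph.to_networkx()
    fig, ax = _new_figure(size_px)
    pos = nx.spring_layout(g, seed=layout_seed)
    nx.draw_networkx(
        g,
        pos=pos,
        ax=ax,
        node_color="#4c78a8",
        edge_color="#999999",
        font_size=8,
        node_size=300,
    )
    if title:
        ax.set_title(title)
    ax.set_axis_off()
    _save(fig, out)
    return out
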
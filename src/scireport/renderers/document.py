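"""Quarto Markdown (qmd) document writer for the non-webapp report types.

One qmd file structures the entire report: sections become level-1 and
subsections level-2 headings (presentation formats start a new slide per
subsection); components are embedded in order. For the static formats
(PDF, DOCX, ODT, PPTX) every interactive plot or network is first
converted to a PNG, so the document source carries no interactive JSON.
API-call and chatbot components only make sense in the web application
and are skipped here with a warning.

Every component block begins with an HTML comment marker naming its
source file, so the mapping from spec to document is auditable.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional, Union

from ..components_io import (
    Graph,
    load_graph,
    load_plot_spec,
    load_table,
    load_text_component,
)
from ..config_model import (
    Component,
    ComponentKind,
    DataFrameAttrs,
    FILELESS_KINDS,
    NetworkAttrs,
    NetworkFormat,
    PlotAttrs,
    PlotDialect,
    PlotFormat,
    ReportSpec,
    ReportType,
    Section,
    Subsection,
)
from .bundle import (
    AssetStore,
    ReportBundle,
    RenderError,
    StaticizedAsset,
    check_renderable,
    is_interactive_payload,
    slugify,
)
from .static_export import (
    DEFAULT_LAYOUT_SEED,
    DEFAULT_SIZE_PX,
    StaticizeError,
    render_graph_png,
    render_plot_png,
)

logger = logging.getLogger(__name__)

__all__ = ["generate_document", "staticize"]

_QUARTO_FORMAT = {
    ReportType.HTML: "html",
    ReportType.PDF: "pdf",
    ReportType.DOCX: "docx",
    ReportType.ODT: "odt",
    ReportType.REVEALJS: "revealjs",
    ReportType.PPTX: "pptx",
    ReportType.NOTEBOOK: "ipynb",
}

#: Formats whose output can host live JS/HTML widgets.
_EMBED_INTERACTIVE = {ReportType.HTML, ReportType.REVEALJS}


def staticize(
    component: Component,
    outdir: Union[str, Path],
    base_dir: Optional[Path] = None,
    size_px: tuple[int, int] = DEFAULT_SIZE_PX,
    layout_seed: int = DEFAULT_LAYOUT_SEED,
) -> StaticizedAsset:
    """Convert an interactive plot/network component into a PNG asset.

    Static-image plot components pass through unchanged (no new file is
    written). The PNG lands in ``outdir`` under a name derived from the
    component's file path, at ``size_px`` resolution; network layouts use
    ``layout_seed`` so repeated runs are byte-identical.
    """
    outdir = Path(outdir)
    if component.kind not in (ComponentKind.PLOT, ComponentKind.NETWORK):
        raise StaticizeError(
            f"cannot staticize a {component.kind.value} component"
        )
    src = Path(component.file_path) if component.file_path else None
    if src is not None and not src.is_absolute() and base_dir is not None:
        src = base_dir / src

    if component.kind is ComponentKind.PLOT:
        attrs = component.attrs
        assert isinstance(attrs, PlotAttrs)
        if attrs.plot_format is PlotFormat.STATIC_IMAGE:
            return StaticizedAsset(source=component, image_path=src)
        name = slugify(Path(component.file_path).with_suffix("").as_posix()) + ".png"
        spec = load_plot_spec(src)
        out = render_plot_png(spec, outdir / name, size_px=size_px)
        return StaticizedAsset(source=component, image_path=out)

    attrs = component.attrs
    assert isinstance(attrs, NetworkAttrs)
    if attrs.net_format is NetworkFormat.HTML_EMBED:
        raise StaticizeError(
            "an HTML network embed has no parseable structure to rasterize"
        )
    graph = load_graph(src, attrs.net_format, attrs.delimiter)
    assert isinstance(graph, Graph)
    name = slugify(Path(component.file_path).with_suffix("").as_posix()) + ".png"
    out = render_graph_png(
        graph, outdir / name, size_px=size_px, layout_seed=layout_seed,
        title=component.title,
    )
    return StaticizedAsset(source=component, image_path=out)


def _front_matter(spec: ReportSpec, report_type: ReportType) -> str:
    fmt = _QUARTO_FORMAT[report_type]
    lines = ["---", f"title: {json.dumps(spec.title)}"]
    if spec.description:
        lines.append(f"subtitle: {json.dumps(spec.description)}")
    lines.append(f"format: {fmt}")
    if report_type in _EMBED_INTERACTIVE:
        lines.append("embed-resources: true")
    lines += ["---", ""]
    return "\n".join(lines)


def _marker(comp: Component) -> str:
    ident = comp.file_path if comp.file_path else f"{comp.kind.value}:{comp.title}"
    return f"<!-- component: {ident} -->"


def _table_markdown(comp: Component, path: Path, max_rows: int = 50) -> str:
    attrs = comp.attrs
    assert isinstance(attrs, DataFrameAttrs)
    table = load_table(path, attrs.file_format, attrs.delimiter)
    df = table.to_dataframe()
    truncated = len(df) > max_rows
    shown = df.head(max_rows)
    header = "| " + " | ".join(str(c) for c in shown.columns) + " |"
    rule = "|" + "|".join(" --- " for _ in shown.columns) + "|"
    body = [
        "| " + " | ".join(str(v) for v in row) + " |"
        for row in shown.itertuples(index=False, name=None)
    ]
    note = (
        f"\n\n_{len(df)} rows total; first {max_rows} shown._" if truncated else ""
    )
    return "\n".join([header, rule, *body]) + note


def _interactive_table_html(comp: Component, path: Path, rel: Path, idx: int) -> str:
    """HTML table wired to DataTables (filtering, sorting, pagination)."""
    attrs = comp.attrs
    assert isinstance(attrs, DataFrameAttrs)
    table = load_table(path, attrs.file_format, attrs.delimiter)
    df = table.to_dataframe()
    tid = f"tbl_{idx}_{slugify(comp.title)}"
    html = df.to_html(index=False, table_id=tid, border=0)
    script = (
        '<link rel="stylesheet" href="https://cdn.datatables.net/2.0.8/css/'
        'dataTables.dataTables.min.css">\n'
        '<script src="https://code.jquery.com/jquery-3.7.1.min.js"></script>\n'
        '<script src="https://cdn.datatables.net/2.0.8/js/'
        'dataTables.min.js"></script>\n'
        f'<script>new DataTable("#{tid}", {{paging: true, searching: true, '
        "ordering: true}});</script>"
    )
    return "```{=html}\n" + html + "\n" + script + "\n```"


def _interactive_plot_html(comp: Component, payload, dialect: PlotDialect, idx: int) -> str:
    div = f"plot_{idx}_{slugify(comp.title)}"
    blob = json.dumps(payload)
    if dialect is PlotDialect.VEGA_FAMILY:
        body = (
            f'<div id="{div}"></div>\n'
            '<script src="https://cdn.jsdelivr.net/npm/vega@5"></script>\n'
            '<script src="https://cdn.jsdelivr.net/npm/vega-lite@5"></script>\n'
            '<script src="https://cdn.jsdelivr.net/npm/vega-embed@6"></script>\n'
            f'<script>vegaEmbed("#{div}", {blob});</script>'
        )
    else:
        body = (
            f'<div id="{div}"></div>\n'
            '<script src="https://cdn.plot.ly/plotly-2.32.0.min.js"></script>\n'
            f'<script>Plotly.newPlot("{div}", {blob}["data"], {blob}["layout"]);'
            "</script>"
        )
    return "```{=html}\n" + body + "\n```"


def _emit_component(
    comp: Component,
    idx: int,
    spec: ReportSpec,
    report_type: ReportType,
    bundle: ReportBundle,
    assets: AssetStore,
    assets_dir: Path,
    heading_level: int,
    failures: list[str],
) -> list[str]:
    lines: list[str] = [_marker(comp)]
    title_line = "#" * heading_level + f" {comp.title}"

    if comp.kind in FILELESS_KINDS:
        logger.warning(
            "%s component %r is applicable only to webapp reports; skipped "
            "for %s output",
            comp.kind.value,
            comp.title,
            report_type.value,
        )
        lines.append(f"_{comp.kind.value} component {comp.title!r} is only "
                     "available in the web application; skipped._")
        return lines

    rel = assets.place(comp)
    src = assets.root / rel

    def image_ref(path_rel: Path) -> str:
        alt = comp.caption or comp.title
        return f"![{alt}]({path_rel.as_posix()})"

    needs_static = report_type.is_static or (
        report_type is ReportType.NOTEBOOK and is_interactive_payload(comp)
    )

    if comp.kind is ComponentKind.PLOT:
        attrs = comp.attrs
        assert isinstance(attrs, PlotAttrs)
        lines.append(title_line)
        if attrs.plot_format is PlotFormat.STATIC_IMAGE:
            lines.append(image_ref(rel))
        else:
            plot = load_plot_spec(src)
            if report_type in _EMBED_INTERACTIVE and plot.dialect is not PlotDialect.UNKNOWN:
                lines.append(_interactive_plot_html(comp, plot.json_payload, plot.dialect, idx))
            elif plot.dialect is PlotDialect.UNKNOWN:
                logger.warning(
                    "plot %r has an unknown JSON dialect; shown as code", comp.title
                )
                lines.append("```json\n" + json.dumps(plot.json_payload, indent=2) + "\n```")
            else:
                lines.append(
                    _staticized_image(comp, spec, bundle, assets_dir, image_ref, failures)
                )
    elif comp.kind is ComponentKind.NETWORK:
        attrs = comp.attrs
        assert isinstance(attrs, NetworkAttrs)
        lines.append(title_line)
        if attrs.net_format is NetworkFormat.HTML_EMBED:
            if report_type in _EMBED_INTERACTIVE:
                text = load_text_component(src, "html")
                lines.append("```{=html}\n" + text + "\n```")
            else:
                lines.append(f"_Interactive network view: see [{rel.name}]({rel.as_posix()})._")
        else:
            lines.append(
                _staticized_image(comp, spec, bundle, assets_dir, image_ref, failures)
            )
    elif comp.kind is ComponentKind.DATAFRAME:
        lines.append(title_line)
        if report_type in _EMBED_INTERACTIVE:
            lines.append(_interactive_table_html(comp, src, rel, idx))
        else:
            lines.append(_table_markdown(comp, src))
        lines.append(f"\n_Source: `{rel.as_posix()}`_")
    elif comp.kind is ComponentKind.MARKDOWN:
        lines.append(title_line)
        lines.append(load_text_component(src, "markdown"))
    elif comp.kind is ComponentKind.HTML:
        lines.append(title_line)
        if report_type in _EMBED_INTERACTIVE:
            lines.append("```{=html}\n" + load_text_component(src, "html") + "\n```")
        else:
            lines.append(f"_HTML component: see [{rel.name}]({rel.as_posix()})._")

    if comp.caption and comp.kind is not ComponentKind.PLOT:
        lines.append(f"\n_{comp.caption}_")
    return lines


def _staticized_image(comp, spec, bundle, assets_dir, image_ref, failures) -> str:
    try:
        asset = staticize(comp, assets_dir, base_dir=spec.base_dir)
    except StaticizeError as exc:
        failures.append(f"{comp.title}: {exc}")
        logger.error("staticize failed for %r: %s", comp.title, exc)
        return f"_[static export failed for {comp.title!r}: {exc}]_"
    rel = asset.image_path.relative_to(assets_dir.parent)
    bundle.add(rel, "static_image")
    return image_ref(rel)


def generate_document(
    spec: ReportSpec,
    report_type: Union[str, ReportType],
    outdir: Union[str, Path],
) -> ReportBundle:
    """Compile a spec into a qmd document bundle for a non-webapp format.

    Returns the bundle; ``bundle.entry`` is the qmd file, ready for
    ``quarto render``. Raises :class:`RenderError` if validation finds
    errors or if any required static export fails.
    """
    report_type = ReportType(report_type)
    if report_type is ReportType.WEBAPP:
        raise RenderError("use generate_webapp for webapp reports")
    if report_type not in _QUARTO_FORMAT:
        raise RenderError(f"unknown report type: {report_type}")
    outdir = Path(outdir)
    check_renderable(spec, report_type)
    outdir.mkdir(parents=True, exist_ok=True)

    bundle = ReportBundle(
        report_type=report_type,
        root=outdir,
        render_command=f"quarto render {outdir / 'report.qmd'}",
    )
    assets = AssetStore(spec, outdir, bundle)
    assets_dir = outdir / "assets"
    failures: list[str] = []

    parts: list[str] = [_front_matter(spec, report_type)]
    if spec.graphical_abstract:
        ga = spec.resolve_path(spec.graphical_abstract)
        if ga.is_file():
            rel = _place_extra(assets, spec.graphical_abstract, outdir)
            parts.append(f"![Graphical abstract]({rel.as_posix()})\n")
    idx = 0
    for section in spec.sections:
        parts.append(f"# {section.title}")
        if section.description:
            parts.append(section.description)
        if not section.subsections and not section.components:
            parts.append("_This section has no content yet._")
        for comp in section.components:
            parts.append(
                "\n".join(
                    _emit_component(
                        comp, idx, spec, report_type, bundle, assets,
                        assets_dir, 3, failures,
                    )
                )
            )
            idx += 1
        for sub in section.subsections:
            parts.append(f"## {sub.title}")
            if sub.description:
                parts.append(sub.description)
            if not sub.components:
                parts.append("_This subsection has no content yet._")
            for comp in sub.components:
                parts.append(
                    "\n".join(
                        _emit_component(
                            comp, idx, spec, report_type, bundle, assets,
                            assets_dir, 3, failures,
                        )
                    )
                )
                idx += 1

    doc_path = outdir / "report.qmd"
    doc_path.write_text("\n\n".join(parts) + "\n", encoding="utf-8")
    bundle.add(Path("report.qmd"), "document_source")
    if failures:
        raise RenderError(
            f"{len(failures)} component(s) failed static export: "
            + "; ".join(failures)
        )
    return bundle


def _place_extra(assets: AssetStore, file_path: str, outdir: Path) -> Path:
    comp = Component(
        title="Graphical Abstract",
        kind=ComponentKind.PLOT,
        file_path=file_path,
        attrs=PlotAttrs(plot_format=PlotFormat.STATIC_IMAGE),
    )
    return assets.place(comp)
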
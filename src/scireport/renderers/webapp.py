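"""Multi-page web application writer.

Emits a Streamlit source bundle: an entry script with the navigation
across all pages, one subfolder per section, and one page script per
subsection (plus an overview page for sections holding components
directly). Pages render components in order — interactive charts,
sortable/filterable table widgets, network views, markdown and HTML
blocks, API-call and chatbot panels. The emitted scripts are plain
Python text; Streamlit is needed only to *run* the app, not to write it.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Union

from ..config_model import (
    ApiCallAttrs,
    ChatbotAttrs,
    ChatMode,
    Component,
    ComponentKind,
    DataFrameAttrs,
    NetworkAttrs,
    NetworkFormat,
    PlotAttrs,
    PlotFormat,
    ReportSpec,
    ReportType,
    TableFormat,
)
from .bundle import AssetStore, ReportBundle, RenderError, check_renderable, slugify

logger = logging.getLogger(__name__)

__all__ = ["generate_webapp"]

_PAGE_PRELUDE = '''\
from pathlib import Path

import streamlit as st

BASE = Path(__file__).resolve().parents[2]
'''


def _py(value) -> str:
    """A Python literal for embedding in generated source."""
    return repr(value)


def _emit_plot(comp: Component, rel: Path, key: str) -> list[str]:
    attrs = comp.attrs
    assert isinstance(attrs, PlotAttrs)
    if attrs.plot_format is PlotFormat.STATIC_IMAGE:
        return [f"st.image(str(BASE / {_py(rel.as_posix())}), "
                f"caption={_py(comp.caption or comp.title)})"]
    return [
        "import json as _json",
        f"_payload = _json.loads((BASE / {_py(rel.as_posix())}).read_text())",
        'if isinstance(_payload, dict) and "vega" in str(_payload.get("$schema", "")).lower():',
        "    st.vega_lite_chart(_payload, use_container_width=True)",
        'elif isinstance(_payload, dict) and "data" in _payload and "layout" in _payload:',
        "    import plotly.io as _pio",
        "    st.plotly_chart(_pio.from_json(_json.dumps(_payload)), use_container_width=True)",
        "else:",
        "    st.warning('Unknown plot JSON dialect; showing raw payload')",
        "    st.json(_payload)",
    ]


_TABLE_READERS = {
    TableFormat.CSV: "pd.read_csv(_path, sep={sep})",
    TableFormat.TXT: "pd.read_csv(_path, sep={sep})",
    TableFormat.PARQUET: "pd.read_parquet(_path)",
    TableFormat.XLSX: "pd.read_excel(_path)",
}


def _emit_table(comp: Component, rel: Path, key: str) -> list[str]:
    attrs = comp.attrs
    assert isinstance(attrs, DataFrameAttrs)
    sep = _py(attrs.delimiter) if attrs.delimiter else "None"
    if attrs.file_format in (TableFormat.CSV, TableFormat.TXT) and not attrs.delimiter:
        sep = "None"  # pandas sniffs when sep=None with engine='python'
        reader = "pd.read_csv(_path, sep=None, engine='python')"
    else:
        reader = _TABLE_READERS[attrs.file_format].format(sep=sep)
    return [
        "import pandas as pd",
        f"_path = BASE / {_py(rel.as_posix())}",
        f"_df = {reader}",
        f"st.dataframe(_df, use_container_width=True, key={_py(key)})",
    ]


_NETWORK_READERS = {
    NetworkFormat.GRAPHML: "nx.read_graphml(_path)",
    NetworkFormat.GML: "nx.read_gml(_path)",
    NetworkFormat.GEXF: "nx.read_gexf(_path)",
}


def _emit_network(comp: Component, rel: Path, key: str) -> list[str]:
    attrs = comp.attrs
    assert isinstance(attrs, NetworkAttrs)
    if attrs.net_format is NetworkFormat.HTML_EMBED:
        return [
            "import streamlit.components.v1 as _components",
            f"_components.html((BASE / {_py(rel.as_posix())}).read_text(), "
            "height=620, scrolling=True)",
        ]
    lines = ["import networkx as nx", f"_path = BASE / {_py(rel.as_posix())}"]
    if attrs.net_format in _NETWORK_READERS:
        lines.append(f"_G = {_NETWORK_READERS[attrs.net_format]}")
    elif attrs.net_format is NetworkFormat.CYJS:
        lines += [
            "import json as _json",
            "_G = nx.cytoscape_graph(_json.loads(_path.read_text()))",
        ]
    elif attrs.net_format is NetworkFormat.ADJACENCY:
        sep = _py(attrs.delimiter or ",")
        lines += [
            "import pandas as pd",
            f"_adj = pd.read_csv(_path, sep={sep}, index_col=0)",
            "_G = nx.from_pandas_adjacency(_adj)",
        ]
    else:  # edge list
        sep = _py(attrs.delimiter or ",")
        lines += [
            "import pandas as pd",
            f"_edges = pd.read_csv(_path, sep={sep})",
            "_G = nx.from_pandas_edgelist(_edges, source=_edges.columns[0], "
            "target=_edges.columns[1])",
        ]
    lines += [
        "try:",
        "    from pyvis.network import Network as _PyvisNetwork",
        "    import streamlit.components.v1 as _components",
        "    _net = _PyvisNetwork(height='600px', width='100%', notebook=False)",
        "    _net.from_nx(_G)",
        "    _components.html(_net.generate_html(), height=620, scrolling=True)",
        "except ImportError:",
        "    import matplotlib.pyplot as _plt",
        "    _fig, _ax = _plt.subplots(figsize=(8, 6))",
        "    nx.draw_networkx(_G, pos=nx.spring_layout(_G, seed=42), ax=_ax, "
        "node_size=300, font_size=8)",
        "    _ax.set_axis_off()",
        "    st.pyplot(_fig)",
    ]
    return lines


def _emit_apicall(comp: Component, key: str) -> list[str]:
    attrs = comp.attrs
    assert isinstance(attrs, ApiCallAttrs)
    headers = dict(attrs.headers) if attrs.headers else {}
    body = attrs.request_body
    return [
        "import requests",
        f"st.caption('API endpoint: ' + {_py(attrs.api_url)})",
        f"if st.button('Send request', key={_py(key)}):",
        f"    _resp = requests.request(",
        f"        {_py(attrs.method.value)},",
        f"        {_py(attrs.api_url)},",
        f"        data={_py(body)},",
        f"        headers={_py(headers)},",
        f"        timeout=30,",
        f"    )",
        "    st.write(f'Status: {_resp.status_code}')",
        "    try:",
        "        st.json(_resp.json())",
        "    except ValueError:",
        "        st.text(_resp.text)",
    ]


def _emit_chatbot(comp: Component, key: str) -> list[str]:
    attrs = comp.attrs
    assert isinstance(attrs, ChatbotAttrs)
    headers = dict(attrs.headers) if attrs.headers else {}
    streaming = attrs.mode is ChatMode.STREAMING
    lines = [
        "import requests",
        f"_history_key = {_py(key + '_history')}",
        "if _history_key not in st.session_state:",
        "    st.session_state[_history_key] = []",
        "for _msg in st.session_state[_history_key]:",
        "    with st.chat_message(_msg['role']):",
        "        st.markdown(_msg['content'])",
        f"_prompt = st.chat_input('Ask the model...', key={_py(key)})",
        "if _prompt:",
        "    st.session_state[_history_key].append({'role': 'user', 'content': _prompt})",
        "    with st.chat_message('user'):",
        "        st.markdown(_prompt)",
        "    _payload = {",
        f"        'model': {_py(attrs.model)},",
        "        'messages': st.session_state[_history_key],",
        f"        'stream': {streaming},",
        "    }",
        "    with st.chat_message('assistant'):",
    ]
    if streaming:
        lines += [
            f"        _resp = requests.post({_py(attrs.api_url)}, json=_payload, "
            f"headers={_py(headers)}, stream=True, timeout=120)",
            "        _chunks = []",
            "        _box = st.empty()",
            "        for _line in _resp.iter_lines():",
            "            if _line:",
            "                _chunks.append(_line.decode('utf-8', 'replace'))",
            "                _box.markdown(''.join(_chunks))",
            "        _answer = ''.join(_chunks)",
        ]
    else:
        lines += [
            f"        _resp = requests.post({_py(attrs.api_url)}, json=_payload, "
            f"headers={_py(headers)}, timeout=120)",
            "        _data = _resp.json()",
            "        _answer = _data.get('choices', [{}])[0].get('message', {})"
            ".get('content', str(_data))",
            "        st.markdown(_answer)",
        ]
    lines += [
        "    st.session_state[_history_key].append("
        "{'role': 'assistant', 'content': _answer})",
    ]
    return lines


def _component_block(
    comp: Component, idx: int, assets: AssetStore
) -> list[str]:
    ident = comp.file_path if comp.file_path else f"{comp.kind.value}:{comp.title}"
    key = f"c{idx}_{slugify(comp.title)}"
    lines = [f"# component: {ident}", f"st.subheader({_py(comp.title)})"]
    if comp.kind is ComponentKind.APICALL:
        lines += _emit_apicall(comp, key)
    elif comp.kind is ComponentKind.CHATBOT:
        lines += _emit_chatbot(comp, key)
    else:
        rel = assets.place(comp)
        if comp.kind is ComponentKind.PLOT:
            lines += _emit_plot(comp, rel, key)
        elif comp.kind is ComponentKind.DATAFRAME:
            lines += _emit_table(comp, rel, key)
        elif comp.kind is ComponentKind.NETWORK:
            lines += _emit_network(comp, rel, key)
        elif comp.kind is ComponentKind.MARKDOWN:
            lines.append(
                f"st.markdown((BASE / {_py(rel.as_posix())}).read_text(encoding='utf-8'))"
            )
        elif comp.kind is ComponentKind.HTML:
            lines += [
                "import streamlit.components.v1 as _components",
                f"_components.html((BASE / {_py(rel.as_posix())})"
                ".read_text(encoding='utf-8'), height=620, scrolling=True)",
            ]
    if comp.caption:
        lines.append(f"st.caption({_py(comp.caption)})")
    return lines


def _page_source(title: str, description, blocks: list[list[str]]) -> str:
    parts = [_PAGE_PRELUDE, f"st.header({_py(title)})"]
    if description:
        parts.append(f"st.markdown({_py(description)})")
    if not blocks:
        parts.append("st.info('This page has no content yet.')")
    for block in blocks:
        parts.append("\n".join(block))
    return "\n\n".join(parts) + "\n"


def generate_webapp(spec: ReportSpec, outdir: Union[str, Path]) -> ReportBundle:
    """Compile a spec into a multi-page Streamlit app source bundle.

    Layout: ``app.py`` (entry, builds the navigation), one
    ``sections/<section>/`` folder per section, one page script per
    subsection; a section holding components directly (or nothing at
    all) additionally gets an ``overview.py`` page. Run with
    ``streamlit run app.py``.
    """
    outdir = Path(outdir)
    check_renderable(spec, ReportType.WEBAPP)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle = ReportBundle(
        report_type=ReportType.WEBAPP,
        root=outdir,
        render_command=f"streamlit run {outdir / 'app.py'}",
    )
    assets = AssetStore(spec, outdir, bundle)

    nav_entries: list[tuple[str, list[tuple[str, str]]]] = []
    idx = 0
    for section in spec.sections:
        sec_slug = slugify(section.title)
        sec_dir = outdir / "sections" / sec_slug
        sec_dir.mkdir(parents=True, exist_ok=True)
        pages: list[tuple[str, str]] = []

        if section.components or not section.subsections:
            blocks = []
            for comp in section.components:
                blocks.append(_component_block(comp, idx, assets))
                idx += 1
            page_rel = Path("sections") / sec_slug / "overview.py"
            (outdir / page_rel).write_text(
                _page_source(section.title, section.description, blocks),
                encoding="utf-8",
            )
            bundle.add(page_rel, "page")
            pages.append(("Overview", page_rel.as_posix()))

        for sub in section.subsections:
            blocks = []
            for comp in sub.components:
                blocks.append(_component_block(comp, idx, assets))
                idx += 1
            page_rel = Path("sections") / sec_slug / f"{slugify(sub.title)}.py"
            (outdir / page_rel).write_text(
                _page_source(sub.title, sub.description, blocks), encoding="utf-8"
            )
            bundle.add(page_rel, "page")
            pages.append((sub.title, page_rel.as_posix()))

        nav_entries.append((section.title, pages))

    entry_lines = [
        "import streamlit as st",
        "",
        f"st.set_page_config(page_title={_py(spec.title)}, layout='wide')",
    ]
    if spec.logo:
        logo_comp = Component(
            title="Logo", kind=ComponentKind.PLOT, file_path=spec.logo,
            attrs=PlotAttrs(plot_format=PlotFormat.STATIC_IMAGE),
        )
        if spec.resolve_path(spec.logo).is_file():
            rel = assets.place(logo_comp)
            entry_lines.append(f"st.logo({_py(rel.as_posix())})")
    entry_lines += ["", "pages = {"]
    for sec_title, pages in nav_entries:
        page_items = ", ".join(
            f"st.Page({_py(path)}, title={_py(title)})" for title, path in pages
        )
        entry_lines.append(f"    {_py(sec_title)}: [{page_items}],")
    entry_lines += [
        "}",
        "",
        f"st.sidebar.title({_py(spec.title)})",
    ]
    if spec.description:
        entry_lines.append(f"st.sidebar.markdown({_py(spec.description)})")
    entry_lines += ["", "nav = st.navigation(pages)", "nav.run()", ""]

    (outdir / "app.py").write_text("\n".join(entry_lines), encoding="utf-8")
    bundle.add(Path("app.py"), "entry")
    return bundle
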
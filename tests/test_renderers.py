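"""Bundle writers: webapp structure, document structure, static export."""

import ast
import copy
import re
import shutil

import pytest
from PIL import Image

from scireport.config_model import (
    ApiCallAttrs,
    ChatbotAttrs,
    Component,
    ComponentKind,
    PlotAttrs,
    ReportSpec,
    Section,
)
from scireport.renderers.bundle import is_interactive_payload
from scireport.renderers import (
    DEFAULT_SIZE_PX,
    ExternalToolMissing,
    RenderError,
    StaticizeError,
    generate_document,
    generate_webapp,
    render_external,
    staticize,
)

from .conftest import tree_hash

DOCUMENT_TYPES = ["html", "pdf", "docx", "odt", "revealjs", "pptx", "notebook"]

COMPONENT_MARKER = re.compile(r"^<!-- component: (.+) -->$", re.M)
PAGE_MARKER = re.compile(r"^# component: (.+)$", re.M)


def spec_with_panels(base_spec) -> ReportSpec:
    """The fixture spec extended with an API-call and a chatbot panel."""
    spec = copy.deepcopy(base_spec)
    spec.sections[0].subsections[0].components.append(
        Component(
            title="Annotation Lookup",
            kind=ComponentKind.APICALL,
            attrs=ApiCallAttrs(
                api_url="https://api.example.org/annotate",
                method="POST",
                request_body='{"ids": [1, 2]}',
            ),
        )
    )
    spec.sections[1].subsections[1].components.append(
        Component(
            title="Results Assistant",
            kind=ComponentKind.CHATBOT,
            attrs=ChatbotAttrs(
                api_url="https://llm.example.org/v1/chat", model="demo-model"
            ),
        )
    )
    return spec


class TestWebapp:
    def test_bundle_structure_law(self, basic_spec, tmp_path):
        bundle = generate_webapp(basic_spec, tmp_path / "web")
        n_sections = len(basic_spec.sections)
        n_subsections = sum(len(s.subsections) for s in basic_spec.sections)
        n_direct = sum(1 for s in basic_spec.sections if s.components)
        section_dirs = [
            d for d in (bundle.root / "sections").iterdir() if d.is_dir()
        ]
        assert len(section_dirs) == n_sections
        assert len(bundle.with_role("page")) == n_subsections + n_direct
        assert len(bundle.with_role("entry")) == 1

    def test_every_page_parses_as_python(self, basic_spec, tmp_path):
        bundle = generate_webapp(basic_spec, tmp_path / "web")
        for f in bundle.with_role("page") + bundle.with_role("entry"):
            ast.parse((bundle.root / f.path).read_text(), filename=str(f.path))

    def test_every_component_on_exactly_one_page(self, basic_spec, tmp_path):
        bundle = generate_webapp(basic_spec, tmp_path / "web")
        seen: dict[str, int] = {}
        for f in bundle.with_role("page"):
            for ident in PAGE_MARKER.findall((bundle.root / f.path).read_text()):
                seen[ident] = seen.get(ident, 0) + 1
        expected = {
            c.file_path for _, _, c in basic_spec.iter_components()
        }
        assert seen == {p: 1 for p in expected}

    def test_apicall_panel_uses_configured_request(self, basic_spec, tmp_path):
        spec = spec_with_panels(basic_spec)
        bundle = generate_webapp(spec, tmp_path / "web")
        hits = [
            f
            for f in bundle.with_role("page")
            if "https://api.example.org/annotate" in (bundle.root / f.path).read_text()
        ]
        assert len(hits) == 1
        src = (bundle.root / hits[0].path).read_text()
        assert "'POST'" in src and '{"ids": [1, 2]}' in src

    def test_chatbot_panel_emitted(self, basic_spec, tmp_path):
        spec = spec_with_panels(basic_spec)
        bundle = generate_webapp(spec, tmp_path / "web")
        sources = "".join(
            (bundle.root / f.path).read_text() for f in bundle.with_role("page")
        )
        assert "st.chat_input" in sources
        assert "demo-model" in sources

    def test_empty_section_gets_placeholder_page(self, tmp_path):
        spec = ReportSpec(title="T", sections=[Section(title="Empty")])
        bundle = generate_webapp(spec, tmp_path / "web")
        pages = bundle.with_role("page")
        assert len(pages) == 1
        assert "no content" in (bundle.root / pages[0].path).read_text()

    def test_validation_errors_refuse_render(self, basic_spec, tmp_path):
        spec = copy.deepcopy(basic_spec)
        spec.sections[0].subsections[0].components[0].file_path = "gone.png"
        with pytest.raises(RenderError, match="gone.png"):
            generate_webapp(spec, tmp_path / "web")

    def test_regeneration_is_byte_identical(self, basic_spec, tmp_path):
        generate_webapp(basic_spec, tmp_path / "a")
        generate_webapp(basic_spec, tmp_path / "b")
        assert tree_hash(tmp_path / "a") == tree_hash(tmp_path / "b")


class TestDocument:
    @pytest.mark.parametrize("report_type", DOCUMENT_TYPES)
    def test_single_source_and_heading_counts(self, basic_spec, tmp_path, report_type):
        bundle = generate_document(basic_spec, report_type, tmp_path / report_type)
        sources = bundle.with_role("document_source")
        assert len(sources) == 1
        doc = (bundle.root / sources[0].path).read_text()
        body = doc.split("---", 2)[2]  # skip front matter
        h1 = sum(1 for line in body.splitlines() if re.match(r"^# \S", line))
        h2 = sum(1 for line in body.splitlines() if re.match(r"^## \S", line))
        assert h1 == len(basic_spec.sections)
        assert h2 == sum(len(s.subsections) for s in basic_spec.sections)

    @pytest.mark.parametrize("report_type", DOCUMENT_TYPES)
    def test_component_conservation(self, basic_spec, tmp_path, report_type):
        spec = spec_with_panels(basic_spec)
        bundle = generate_document(spec, report_type, tmp_path / report_type)
        doc = (bundle.root / "report.qmd").read_text()
        markers = COMPONENT_MARKER.findall(doc)
        expected = []
        for _, _, c in spec.iter_components():
            expected.append(
                c.file_path if c.file_path else f"{c.kind.value}:{c.title}"
            )
        assert sorted(markers) == sorted(expected)
        for m in set(markers):
            assert markers.count(m) == 1

    @pytest.mark.parametrize("report_type", ["pdf", "docx", "odt", "pptx"])
    def test_static_purity(self, basic_spec, tmp_path, report_type):
        bundle = generate_document(basic_spec, report_type, tmp_path / report_type)
        doc = (bundle.root / "report.qmd").read_text()
        assert "$schema" not in doc
        assert '"layout"' not in doc
        assert "vegaEmbed" not in doc and "Plotly.newPlot" not in doc
        n_interactive = sum(
            1
            for _, _, c in basic_spec.iter_components()
            if is_interactive_payload(c)
        )
        assert len(bundle.with_role("static_image")) == n_interactive

    def test_static_regeneration_byte_identical(self, basic_spec, tmp_path):
        generate_document(basic_spec, "pdf", tmp_path / "a")
        generate_document(basic_spec, "pdf", tmp_path / "b")
        assert tree_hash(tmp_path / "a") == tree_hash(tmp_path / "b")

    def test_html_embeds_interactive_payloads(self, basic_spec, tmp_path):
        bundle = generate_document(basic_spec, "html", tmp_path / "html")
        doc = (bundle.root / "report.qmd").read_text()
        assert "vegaEmbed" in doc
        assert "Plotly.newPlot" in doc

    def test_fileless_components_skipped_with_warning(self, basic_spec, tmp_path, caplog):
        spec = spec_with_panels(basic_spec)
        with caplog.at_level("WARNING"):
            bundle = generate_document(spec, "docx", tmp_path / "docx")
        doc = (bundle.root / "report.qmd").read_text()
        assert "Send request" not in doc
        skip_msgs = [r.message for r in caplog.records if "skipped" in r.message]
        assert len(skip_msgs) == 2

    def test_markdown_included_verbatim(self, basic_spec, tmp_path):
        bundle = generate_document(basic_spec, "html", tmp_path / "html")
        doc = (bundle.root / "report.qmd").read_text()
        md_comp = next(
            c for _, _, c in basic_spec.iter_components()
            if c.kind is ComponentKind.MARKDOWN
        )
        content = basic_spec.resolve_path(md_comp.file_path).read_text()
        assert content.strip() in doc

    def test_webapp_type_refused(self, basic_spec, tmp_path):
        with pytest.raises(RenderError, match="generate_webapp"):
            generate_document(basic_spec, "webapp", tmp_path / "x")


class TestStaticize:
    def _component(self, spec, title):
        return next(c for _, _, c in spec.iter_components() if c.title == title)

    def test_static_image_identity(self, basic_spec, tmp_path):
        comp = self._component(basic_spec, "Phylum Barplot")
        asset = staticize(comp, tmp_path, base_dir=basic_spec.base_dir)
        assert asset.image_path == basic_spec.resolve_path(comp.file_path)
        assert list(tmp_path.iterdir()) == []  # no new file

    def test_vega_spec_renders_png_at_default_size(self, basic_spec, tmp_path):
        comp = self._component(basic_spec, "Alpha Diversity")
        asset = staticize(comp, tmp_path, base_dir=basic_spec.base_dir)
        assert asset.image_path.is_file()
        assert asset.image_path.stat().st_size > 0
        assert Image.open(asset.image_path).size == DEFAULT_SIZE_PX

    def test_network_render_is_byte_stable(self, basic_spec, tmp_path):
        comp = self._component(basic_spec, "Cooccurrence")
        a = staticize(comp, tmp_path / "a", base_dir=basic_spec.base_dir)
        b = staticize(comp, tmp_path / "b", base_dir=basic_spec.base_dir)
        assert a.image_path.read_bytes() == b.image_path.read_bytes()

    def test_unknown_dialect_raises_explicitly(self, tmp_path):
        payload = tmp_path / "odd.json"
        payload.write_text('{"foo": 1}')
        comp = Component(
            title="Odd",
            kind=ComponentKind.PLOT,
            file_path="odd.json",
            attrs=PlotAttrs(plot_format="interactive_json"),
        )
        with pytest.raises(StaticizeError, match="unknown dialect"):
            staticize(comp, tmp_path / "out", base_dir=tmp_path)

    def test_markdown_cannot_be_staticized(self, basic_spec, tmp_path):
        comp = self._component(basic_spec, "Intro")
        with pytest.raises(StaticizeError):
            staticize(comp, tmp_path, base_dir=basic_spec.base_dir)


class TestRenderExternal:
    def test_webapp_smoke_check(self, basic_spec, tmp_path):
        bundle = generate_webapp(basic_spec, tmp_path / "web")
        artifacts = render_external(bundle)
        assert artifacts == [bundle.root / "app.py"]

    def test_document_contract_with_or_without_compiler(self, basic_spec, tmp_path):
        bundle = generate_document(basic_spec, "html", tmp_path / "html")
        if shutil.which("quarto") is None:
            with pytest.raises(ExternalToolMissing, match="quarto"):
                render_external(bundle)
        else:
            artifacts = render_external(bundle)
            assert artifacts and artifacts[0].suffix == ".html"
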
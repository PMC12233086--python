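"""Report data model and its YAML serialization.

A report is a tree: report metadata at the top, then ordered sections,
each holding ordered subsections and/or components placed directly under
the section. A component is one renderable unit — a plot, a dataframe
(table), a network, a block of Markdown or HTML, an API-call panel, or a
chatbot panel — with kind-specific attributes such as the file format and
delimiter of a table or the URL and method of an API call.

The YAML schema uses lowercase snake_case keys. The component kind is
always written explicitly (``component_type``) so hand-written configs are
unambiguous even where it could be inferred from the file extension.
Unset optional fields are omitted on write; ``null`` and omitted are
equivalent on read. Relative ``file_path`` values are interpreted
relative to the directory of the config file they came from.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional, Union

import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "ComponentKind",
    "ReportType",
    "PlotAttrs",
    "DataFrameAttrs",
    "NetworkAttrs",
    "ApiCallAttrs",
    "ChatbotAttrs",
    "Component",
    "Subsection",
    "Section",
    "ReportSpec",
    "ValidationIssue",
    "ConfigError",
    "parse_config",
    "load_config",
    "serialize_config",
    "write_config",
    "validate",
]


class ConfigError(ValueError):
    """Raised for malformed or schema-invalid configuration input."""


class ComponentKind(str, enum.Enum):
    PLOT = "plot"
    DATAFRAME = "dataframe"
    NETWORK = "network"
    MARKDOWN = "markdown"
    HTML = "html"
    APICALL = "apicall"
    CHATBOT = "chatbot"


class ReportType(str, enum.Enum):
    """The eight supported output formats.

    ``webapp`` is a multi-page Streamlit application; the rest are
    compiled from a single Quarto Markdown document. PDF, DOCX, ODT and
    PPTX are static — they cannot host interactive widgets, so
    interactive plots and networks are converted to images for them.
    """

    WEBAPP = "webapp"
    HTML = "html"
    PDF = "pdf"
    DOCX = "docx"
    ODT = "odt"
    REVEALJS = "revealjs"
    PPTX = "pptx"
    NOTEBOOK = "notebook"

    @property
    def is_static(self) -> bool:
        return self in STATIC_TYPES

    @property
    def is_interactive(self) -> bool:
        return self in INTERACTIVE_TYPES


STATIC_TYPES = frozenset(
    {ReportType.PDF, ReportType.DOCX, ReportType.ODT, ReportType.PPTX}
)
INTERACTIVE_TYPES = frozenset(
    {ReportType.WEBAPP, ReportType.HTML, ReportType.REVEALJS, ReportType.NOTEBOOK}
)

#: CLI/user-facing aliases, resolved case-insensitively.
REPORT_TYPE_ALIASES = {"streamlit": ReportType.WEBAPP, "jupyter": ReportType.NOTEBOOK}


def coerce_report_type(value: Union[str, ReportType]) -> ReportType:
    """Resolve a user-supplied report type name, honouring aliases."""
    if isinstance(value, ReportType):
        return value
    key = str(value).strip().lower()
    if key in REPORT_TYPE_ALIASES:
        return REPORT_TYPE_ALIASES[key]
    try:
        return ReportType(key)
    except ValueError:
        legal = ", ".join(t.value for t in ReportType)
        raise ConfigError(
            f"unknown report type {value!r}; expected one of: {legal}"
        ) from None


# --------------------------------------------------------------------------
# Kind-specific attribute records
# --------------------------------------------------------------------------


class PlotFormat(str, enum.Enum):
    INTERACTIVE_JSON = "interactive_json"
    STATIC_IMAGE = "static_image"


class PlotDialect(str, enum.Enum):
    """JSON chart dialects: Plotly-style figure objects or the Vega family."""

    FIGURE_OBJECT = "figure_object"
    VEGA_FAMILY = "vega_family"
    UNKNOWN = "unknown"


class TableFormat(str, enum.Enum):
    CSV = "csv"
    TXT = "txt"
    PARQUET = "parquet"
    XLSX = "xlsx"


class NetworkFormat(str, enum.Enum):
    EDGE_LIST = "edge_list"
    ADJACENCY = "adjacency"
    GRAPHML = "graphml"
    GML = "gml"
    GEXF = "gexf"
    CYJS = "cyjs"
    HTML_EMBED = "html_embed"


class HttpMethod(str, enum.Enum):
    GET = "GET"
    POST = "POST"
    PUT = "PUT"


class ChatMode(str, enum.Enum):
    STANDARD = "standard"
    STREAMING = "streaming"


def _coerce(obj, field_name: str, enum_cls) -> None:
    value = getattr(obj, field_name)
    if not isinstance(value, enum_cls):
        object.__setattr__(obj, field_name, enum_cls(value))


@dataclass(frozen=True)
class PlotAttrs:
    plot_format: PlotFormat = PlotFormat.STATIC_IMAGE
    json_dialect: PlotDialect = PlotDialect.UNKNOWN

    def __post_init__(self) -> None:
        _coerce(self, "plot_format", PlotFormat)
        _coerce(self, "json_dialect", PlotDialect)


@dataclass(frozen=True)
class DataFrameAttrs:
    file_format: TableFormat = TableFormat.CSV
    delimiter: Optional[str] = None

    def __post_init__(self) -> None:
        _coerce(self, "file_format", TableFormat)


@dataclass(frozen=True)
class NetworkAttrs:
    net_format: NetworkFormat = NetworkFormat.EDGE_LIST
    delimiter: Optional[str] = None

    def __post_init__(self) -> None:
        _coerce(self, "net_format", NetworkFormat)


@dataclass(frozen=True)
class ApiCallAttrs:
    api_url: str = ""
    method: HttpMethod = HttpMethod.GET
    request_body: Optional[str] = None
    headers: Optional[tuple[tuple[str, str], ...]] = None

    def __post_init__(self) -> None:
        _coerce(self, "method", HttpMethod)


@dataclass(frozen=True)
class ChatbotAttrs:
    api_url: str = ""
    model: str = ""
    mode: ChatMode = ChatMode.STANDARD
    headers: Optional[tuple[tuple[str, str], ...]] = None

    def __post_init__(self) -> None:
        _coerce(self, "mode", ChatMode)


Attrs = Union[PlotAttrs, DataFrameAttrs, NetworkAttrs, ApiCallAttrs, ChatbotAttrs, None]

_ATTR_CLASSES: dict[ComponentKind, Optional[type]] = {
    ComponentKind.PLOT: PlotAttrs,
    ComponentKind.DATAFRAME: DataFrameAttrs,
    ComponentKind.NETWORK: NetworkAttrs,
    ComponentKind.MARKDOWN: None,
    ComponentKind.HTML: None,
    ComponentKind.APICALL: ApiCallAttrs,
    ComponentKind.CHATBOT: ChatbotAttrs,
}

#: Kinds that carry no payload file in the config.
FILELESS_KINDS = frozenset({ComponentKind.APICALL, ComponentKind.CHATBOT})


# --------------------------------------------------------------------------
# The report tree
# --------------------------------------------------------------------------


@dataclass
class Component:
    title: str
    kind: ComponentKind
    file_path: Optional[str] = None
    caption: Optional[str] = None
    attrs: Attrs = None
    extras: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.title:
            raise ConfigError("component title must be non-empty")
        expected = _ATTR_CLASSES[self.kind]
        if expected is None:
            if self.attrs is not None:
                raise ConfigError(
                    f"{self.kind.value} components take no attribute record"
                )
        elif self.attrs is None:
            self.attrs = expected()
        elif not isinstance(self.attrs, expected):
            raise ConfigError(
                f"attributes {type(self.attrs).__name__} do not match "
                f"component kind {self.kind.value!r}"
            )


@dataclass
class Subsection:
    title: str
    description: Optional[str] = None
    components: list[Component] = field(default_factory=list)
    extras: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.title:
            raise ConfigError("subsection title must be non-empty")


@dataclass
class Section:
    title: str
    description: Optional[str] = None
    subsections: list[Subsection] = field(default_factory=list)
    components: list[Component] = field(default_factory=list)
    extras: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.title:
            raise ConfigError("section title must be non-empty")


@dataclass
class ReportSpec:
    title: str
    description: Optional[str] = None
    graphical_abstract: Optional[str] = None
    logo: Optional[str] = None
    sections: list[Section] = field(default_factory=list)
    extras: dict[str, Any] = field(default_factory=dict)
    #: Directory against which relative file paths resolve. Not part of
    #: structural equality: the same report moved elsewhere is the same report.
    base_dir: Optional[Path] = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not self.title:
            raise ConfigError("report title must be non-empty")

    def iter_components(self):
        """Yield (section, subsection_or_None, component) in render order."""
        for sec in self.sections:
            for comp in sec.components:
                yield sec, None, comp
            for sub in sec.subsections:
                for comp in sub.components:
                    yield sec, sub, comp

    def resolve_path(self, file_path: str) -> Path:
        p = Path(file_path)
        if p.is_absolute() or self.base_dir is None:
            return p
        return self.base_dir / p


@dataclass(frozen=True)
class ValidationIssue:
    severity: str  # "error" | "warning"
    path: str  # config location, e.g. sections[1].components[0].file_path
    message: str


# --------------------------------------------------------------------------
# Parsing
# --------------------------------------------------------------------------

_COMPONENT_KEYS = {"title", "caption", "component_type", "file_path"}
_ATTR_KEYS = {
    ComponentKind.PLOT: {"plot_format", "json_dialect"},
    ComponentKind.DATAFRAME: {"file_format", "delimiter"},
    ComponentKind.NETWORK: {"net_format", "delimiter"},
    ComponentKind.APICALL: {"api_url", "method", "request_body", "headers"},
    ComponentKind.CHATBOT: {"api_url", "model", "mode", "headers"},
    ComponentKind.MARKDOWN: set(),
    ComponentKind.HTML: set(),
}


def _require(mapping: dict, key: str, where: str) -> Any:
    value = mapping.get(key)
    if value in (None, ""):
        raise ConfigError(f"missing required key {key!r} at {where}")
    return value


def _headers_tuple(raw: Any) -> Optional[tuple[tuple[str, str], ...]]:
    if raw is None:
        return None
    if not isinstance(raw, dict):
        raise ConfigError("headers must be a mapping")
    return tuple(sorted((str(k), str(v)) for k, v in raw.items()))


def _parse_attrs(kind: ComponentKind, raw: dict, where: str) -> Attrs:
    try:
        if kind is ComponentKind.PLOT:
            return PlotAttrs(
                plot_format=PlotFormat(raw.get("plot_format", "static_image")),
                json_dialect=PlotDialect(raw.get("json_dialect", "unknown")),
            )
        if kind is ComponentKind.DATAFRAME:
            delim = raw.get("delimiter")
            if delim is not None and len(str(delim)) != 1:
                raise ConfigError(f"delimiter must be a single character at {where}")
            return DataFrameAttrs(
                file_format=TableFormat(raw.get("file_format", "csv")),
                delimiter=None if delim is None else str(delim),
            )
        if kind is ComponentKind.NETWORK:
            delim = raw.get("delimiter")
            return NetworkAttrs(
                net_format=NetworkFormat(raw.get("net_format", "edge_list")),
                delimiter=None if delim is None else str(delim),
            )
        if kind is ComponentKind.APICALL:
            return ApiCallAttrs(
                api_url=str(_require(raw, "api_url", where)),
                method=HttpMethod(str(raw.get("method", "GET")).upper()),
                request_body=raw.get("request_body"),
                headers=_headers_tuple(raw.get("headers")),
            )
        if kind is ComponentKind.CHATBOT:
            return ChatbotAttrs(
                api_url=str(_require(raw, "api_url", where)),
                model=str(raw.get("model", "")),
                mode=ChatMode(raw.get("mode", "standard")),
                headers=_headers_tuple(raw.get("headers")),
            )
    except ValueError as exc:
        raise ConfigError(f"bad attribute value at {where}: {exc}") from None
    return None


def _parse_component(raw: Any, where: str) -> Component:
    if not isinstance(raw, dict):
        raise ConfigError(f"component at {where} must be a mapping")
    kind_raw = raw.get("component_type")
    if kind_raw is None:
        raise ConfigError(
            f"cannot resolve component kind at {where}: key 'component_type' missing"
        )
    try:
        kind = ComponentKind(str(kind_raw).lower())
    except ValueError:
        raise ConfigError(
            f"unknown component_type {kind_raw!r} at {where}"
        ) from None

    file_path = raw.get("file_path")
    if kind not in FILELESS_KINDS and not file_path:
        raise ConfigError(f"missing required key 'file_path' at {where}")

    known = _COMPONENT_KEYS | _ATTR_KEYS[kind]
    extras = {k: v for k, v in raw.items() if k not in known}
    for key in extras:
        logger.warning("unknown key %r at %s preserved in extras", key, where)

    return Component(
        title=str(_require(raw, "title", where)),
        kind=kind,
        file_path=None if file_path is None else str(file_path),
        caption=raw.get("caption"),
        attrs=_parse_attrs(kind, raw, where),
        extras=extras,
    )


def _parse_subsection(raw: Any, where: str) -> Subsection:
    if not isinstance(raw, dict):
        raise ConfigError(f"subsection at {where} must be a mapping")
    known = {"title", "description", "components"}
    extras = {k: v for k, v in raw.items() if k not in known}
    for key in extras:
        logger.warning("unknown key %r at %s preserved in extras", key, where)
    return Subsection(
        title=str(_require(raw, "title", where)),
        description=raw.get("description"),
        components=[
            _parse_component(c, f"{where}.components[{i}]")
            for i, c in enumerate(raw.get("components") or [])
        ],
        extras=extras,
    )


def _parse_section(raw: Any, where: str) -> Section:
    if not isinstance(raw, dict):
        raise ConfigError(f"section at {where} must be a mapping")
    known = {"title", "description", "subsections", "components"}
    extras = {k: v for k, v in raw.items() if k not in known}
    for key in extras:
        logger.warning("unknown key %r at %s preserved in extras", key, where)
    return Section(
        title=str(_require(raw, "title", where)),
        description=raw.get("description"),
        subsections=[
            _parse_subsection(s, f"{where}.subsections[{i}]")
            for i, s in enumerate(raw.get("subsections") or [])
        ],
        components=[
            _parse_component(c, f"{where}.components[{i}]")
            for i, c in enumerate(raw.get("components") or [])
        ],
        extras=extras,
    )


def parse_config(yaml_text: str, base_dir: Optional[Path] = None) -> ReportSpec:
    """Parse a YAML report configuration into a :class:`ReportSpec`.

    ``base_dir`` is the directory relative file paths resolve against
    (normally the directory of the config file; see :func:`load_config`).
    Unknown keys are kept in ``extras`` and logged as warnings. Malformed
    YAML raises :class:`ConfigError` carrying the parser's line number.
    """
    try:
        raw = yaml.safe_load(yaml_text)
    except yaml.YAMLError as exc:
        mark = getattr(exc, "problem_mark", None)
        loc = f" (line {mark.line + 1})" if mark is not None else ""
        raise ConfigError(f"malformed YAML{loc}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")

    report = raw.get("report")
    if not isinstance(report, dict):
        raise ConfigError("missing required key 'report'")
    known = {"title", "description", "graphical_abstract", "logo"}
    extras = {k: v for k, v in report.items() if k not in known}
    top_extras = {k: v for k, v in raw.items() if k not in {"report", "sections"}}
    extras.update(top_extras)
    for key in extras:
        logger.warning("unknown key %r at report preserved in extras", key)

    return ReportSpec(
        title=str(_require(report, "title", "report")),
        description=report.get("description"),
        graphical_abstract=report.get("graphical_abstract"),
        logo=report.get("logo"),
        sections=[
            _parse_section(s, f"sections[{i}]")
            for i, s in enumerate(raw.get("sections") or [])
        ],
        extras=extras,
        base_dir=base_dir,
    )


def load_config(path: Union[str, Path]) -> ReportSpec:
    """Read a config file; relative paths resolve against its directory."""
    path = Path(path)
    return parse_config(path.read_text(encoding="utf-8"), base_dir=path.parent)


# --------------------------------------------------------------------------
# Serialization
# --------------------------------------------------------------------------


def _put(d: dict, key: str, value: Any) -> None:
    """Emit a key only when set — unset optionals are omitted, not null."""
    if value is not None:
        d[key] = value


def _attrs_to_dict(comp: Component) -> dict:
    a = comp.attrs
    out: dict[str, Any] = {}
    if isinstance(a, PlotAttrs):
        out["plot_format"] = a.plot_format.value
        if a.plot_format is PlotFormat.INTERACTIVE_JSON:
            out["json_dialect"] = a.json_dialect.value
    elif isinstance(a, DataFrameAttrs):
        out["file_format"] = a.file_format.value
        _put(out, "delimiter", a.delimiter)
    elif isinstance(a, NetworkAttrs):
        out["net_format"] = a.net_format.value
        _put(out, "delimiter", a.delimiter)
    elif isinstance(a, ApiCallAttrs):
        out["api_url"] = a.api_url
        out["method"] = a.method.value
        _put(out, "request_body", a.request_body)
        if a.headers:
            out["headers"] = dict(a.headers)
    elif isinstance(a, ChatbotAttrs):
        out["api_url"] = a.api_url
        out["model"] = a.model
        out["mode"] = a.mode.value
        if a.headers:
            out["headers"] = dict(a.headers)
    return out


def _component_to_dict(comp: Component) -> dict:
    out: dict[str, Any] = {"title": comp.title}
    _put(out, "caption", comp.caption)
    out["component_type"] = comp.kind.value
    _put(out, "file_path", comp.file_path)
    out.update(_attrs_to_dict(comp))
    out.update(comp.extras)
    return out


def _subsection_to_dict(sub: Subsection) -> dict:
    out: dict[str, Any] = {"title": sub.title}
    _put(out, "description", sub.description)
    if sub.components:
        out["components"] = [_component_to_dict(c) for c in sub.components]
    out.update(sub.extras)
    return out


def _section_to_dict(sec: Section) -> dict:
    out: dict[str, Any] = {"title": sec.title}
    _put(out, "description", sec.description)
    if sec.components:
        out["components"] = [_component_to_dict(c) for c in sec.components]
    if sec.subsections:
        out["subsections"] = [_subsection_to_dict(s) for s in sec.subsections]
    out.update(sec.extras)
    return out


def serialize_config(spec: ReportSpec) -> str:
    """Serialize a spec to YAML, deterministically.

    Key order is fixed (report metadata, then sections in order), so two
    serializations of an equal spec are byte-identical, and
    ``parse_config(serialize_config(s)) == s``.
    """
    report: dict[str, Any] = {"title": spec.title}
    _put(report, "description", spec.description)
    _put(report, "graphical_abstract", spec.graphical_abstract)
    _put(report, "logo", spec.logo)
    report.update(spec.extras)
    doc = {"report": report, "sections": [_section_to_dict(s) for s in spec.sections]}
    return yaml.safe_dump(
        doc, sort_keys=False, allow_unicode=True, default_flow_style=False, width=100
    )


def write_config(spec: ReportSpec, out: Union[str, Path]) -> Path:
    out = Path(out)
    out.parent.mkdir(parents=True, exist_ok=True)
    out.write_text(serialize_config(spec), encoding="utf-8")
    return out


# --------------------------------------------------------------------------
# Validation
# --------------------------------------------------------------------------


def validate(spec: ReportSpec, report_type: ReportType) -> list[ValidationIssue]:
    """Check a spec against a target report type.

    Returns every issue found; an empty list means the spec is renderable.
    Errors (missing component files) block rendering; warnings (web-app-only
    components in another format, content-less sections) do not.
    """
    issues: list[ValidationIssue] = []

    def check_components(comps: list[Component], where: str) -> None:
        for i, comp in enumerate(comps):
            loc = f"{where}.components[{i}]"
            if comp.kind in FILELESS_KINDS:
                if report_type is not ReportType.WEBAPP:
                    issues.append(
                        ValidationIssue(
                            "warning",
                            loc,
                            f"{comp.kind.value} components are applicable only to "
                            f"webapp reports; skipped for {report_type.value}",
                        )
                    )
                continue
            if comp.file_path is None:
                issues.append(
                    ValidationIssue("error", f"{loc}.file_path", "file_path missing")
                )
                continue
            resolved = spec.resolve_path(comp.file_path)
            if not resolved.is_file():
                issues.append(
                    ValidationIssue(
                        "error",
                        f"{loc}.file_path",
                        f"component file not found: {resolved}",
                    )
                )

    for si, sec in enumerate(spec.sections):
        where = f"sections[{si}]"
        if not sec.subsections and not sec.components:
            issues.append(
                ValidationIssue("warning", where, f"section {sec.title!r} has no content")
            )
        check_components(sec.components, where)
        for gi, sub in enumerate(sec.subsections):
            sub_where = f"{where}.subsections[{gi}]"
            if not sub.components:
                issues.append(
                    ValidationIssue(
                        "warning", sub_where, f"subsection {sub.title!r} has no content"
                    )
                )
            check_components(sub.components, sub_where)
    if not spec.sections:
        issues.append(ValidationIssue("warning", "sections", "report has no sections"))
    return issues


def has_errors(issues: list[ValidationIssue]) -> bool:
    return any(i.severity == "error" for i in issues)
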
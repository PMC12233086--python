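"""Infer a report structure from a results directory.

First-level folders become sections, second-level folders become
subsections, and files become typed components. Titles come from folder
and file names; explicit ordering comes from numeric tokens in those
names (a trailing ``_2`` or a leading ``2_``), which are stripped from
the title. Component kinds are inferred from file extensions, with a
name-based hint for CSV/TXT/HTML files that actually hold networks.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Union

from .config_model import (
    Component,
    ComponentKind,
    DataFrameAttrs,
    NetworkAttrs,
    NetworkFormat,
    PlotAttrs,
    PlotDialect,
    PlotFormat,
    ReportSpec,
    Section,
    Subsection,
    TableFormat,
    serialize_config,
)

logger = logging.getLogger(__name__)

__all__ = [
    "NameParse",
    "ComponentClassification",
    "IngestError",
    "DEFAULT_NETWORK_HINT_TOKENS",
    "parse_name",
    "order_key",
    "classify_file",
    "scan_directory",
    "directory_to_config",
]


class IngestError(ValueError):
    """Raised when a directory cannot be turned into a report."""


#: Basename tokens that flag a CSV/TXT/HTML file as a network payload.
DEFAULT_NETWORK_HINT_TOKENS = ("edge_list", "edgelist", "adjacency", "network", "graph")


@dataclass(frozen=True)
class NameParse:
    raw: str
    order: Optional[int]
    title: str


@dataclass(frozen=True)
class ComponentClassification:
    kind: Optional[ComponentKind]
    subtype: Optional[str]
    confident: bool


_SUFFIX_RE = re.compile(r"^(?P<stem>.+?)[_-](?P<num>\d+)$")
_PREFIX_RE = re.compile(r"^(?P<num>\d+)[_-](?P<stem>.+)$")


def parse_name(raw: str) -> NameParse:
    """Split a folder/file name (extension already removed) into order + title.

    A trailing ``_<n>`` (or ``-<n>``) token is the explicit order; a leading
    ``<n>_`` prefix is accepted too, with the suffix winning if both are
    present. Remaining underscores and hyphens become spaces and each word
    is capitalized. The title never ends up empty: a name that is nothing
    but an order token falls back to the raw text.
    """
    stem = raw
    order: Optional[int] = None
    m = _SUFFIX_RE.match(stem)
    if m:
        order = int(m.group("num"))
        stem = m.group("stem")
    m = _PREFIX_RE.match(stem)
    if m:
        if order is None:  # suffix wins when both are present
            order = int(m.group("num"))
        stem = m.group("stem")
    words = [w for w in re.split(r"[_\-\s]+", stem) if w]
    title = " ".join(w[:1].upper() + w[1:] for w in words)
    if not title:
        title = raw
    return NameParse(raw=raw, order=order, title=title)


def order_key(parse: NameParse):
    """Sort key: explicitly ordered items first (numeric, ascending), then
    unordered ones alphabetically, case-insensitive. Stable under equal keys."""
    if parse.order is not None:
        return (0, parse.order, parse.title.lower())
    return (1, 0, parse.title.lower())


_IMAGE_EXTS = {".png", ".svg", ".jpg", ".jpeg"}
_GRAPH_EXTS = {".graphml": "graphml", ".gml": "gml", ".gexf": "gexf", ".cyjs": "cyjs"}


def _has_hint(stem: str, tokens: Iterable[str]) -> bool:
    low = stem.lower()
    return any(tok in low for tok in tokens)


def classify_file(
    path: Union[str, Path],
    network_hint_tokens: Iterable[str] = DEFAULT_NETWORK_HINT_TOKENS,
) -> ComponentClassification:
    """Infer (component kind, format subtype) from a file's extension and name.

    Images are static plots, JSON files interactive plots, tabular formats
    dataframes, graph-exchange formats networks. CSV/TXT/HTML files whose
    basename contains a network hint token are treated as networks
    (adjacency if the name says so, edge list otherwise). Unknown
    extensions yield an unconfident classification and are skipped upstream.
    """
    path = Path(path)
    ext = path.suffix.lower()
    stem = path.stem
    tokens = tuple(network_hint_tokens)

    if ext in _IMAGE_EXTS:
        return ComponentClassification(ComponentKind.PLOT, "static_image", True)
    if ext == ".json":
        return ComponentClassification(ComponentKind.PLOT, "interactive_json", True)
    if ext in (".csv", ".txt"):
        if _has_hint(stem, tokens):
            sub = "adjacency" if "adjacency" in stem.lower() else "edge_list"
            return ComponentClassification(ComponentKind.NETWORK, sub, True)
        return ComponentClassification(ComponentKind.DATAFRAME, ext[1:], True)
    if ext == ".parquet":
        return ComponentClassification(ComponentKind.DATAFRAME, "parquet", True)
    if ext == ".xlsx":
        return ComponentClassification(ComponentKind.DATAFRAME, "xlsx", True)
    if ext == ".md":
        return ComponentClassification(ComponentKind.MARKDOWN, "md", True)
    if ext in _GRAPH_EXTS:
        return ComponentClassification(ComponentKind.NETWORK, _GRAPH_EXTS[ext], True)
    if ext in (".html", ".htm"):
        if _has_hint(stem, tokens):
            return ComponentClassification(ComponentKind.NETWORK, "html_embed", True)
        return ComponentClassification(ComponentKind.HTML, "html", True)
    return ComponentClassification(None, None, False)


def _component_from_classification(
    cls: ComponentClassification, title: str, rel_path: str
) -> Component:
    if cls.kind is ComponentKind.PLOT:
        fmt = PlotFormat(cls.subtype)
        attrs = PlotAttrs(plot_format=fmt)
    elif cls.kind is ComponentKind.DATAFRAME:
        attrs = DataFrameAttrs(file_format=TableFormat(cls.subtype))
    elif cls.kind is ComponentKind.NETWORK:
        attrs = NetworkAttrs(net_format=NetworkFormat(cls.subtype))
    else:
        attrs = None
    return Component(title=title, kind=cls.kind, file_path=rel_path, attrs=attrs)


def _is_hidden(p: Path) -> bool:
    return p.name.startswith(".")


def _iter_entries(folder: Path, seen: set[Path]) -> list[Path]:
    """Children of ``folder``, with hidden entries dropped and symlink
    cycles broken via the resolved-path set (at most one level followed)."""
    out = []
    for child in sorted(folder.iterdir(), key=lambda p: p.name):
        if _is_hidden(child):
            logger.warning("skipping hidden entry %s", child)
            continue
        resolved = child.resolve()
        if child.is_symlink():
            if resolved in seen:
                logger.warning("skipping symlink cycle at %s", child)
                continue
            seen.add(resolved)
        out.append(child)
    return out


def _collect_files(
    folder: Path, seen: set[Path], flatten_warn: bool = True
) -> list[Path]:
    """All files under ``folder``, flattening deeper directories into it."""
    files: list[Path] = []
    for child in _iter_entries(folder, seen):
        if child.is_file():
            files.append(child)
        elif child.is_dir():
            if flatten_warn:
                logger.warning(
                    "folder %s is deeper than the two-level hierarchy; "
                    "flattening its contents into %s",
                    child,
                    folder,
                )
            files.extend(_collect_files(child, seen, flatten_warn=False))
    return files


def _build_components(
    files: list[Path],
    root: Path,
    tokens: Iterable[str],
    skipped: list[str],
) -> list[Component]:
    entries = []
    for f in files:
        if f.stat().st_size == 0:
            logger.warning("skipping zero-byte file %s", f)
            skipped.append(str(f))
            continue
        cls = classify_file(f, tokens)
        if not cls.confident:
            logger.warning("skipping unclassifiable file %s", f)
            skipped.append(str(f))
            continue
        parse = parse_name(f.stem)
        entries.append((parse, cls, f))
    entries.sort(key=lambda e: order_key(e[0]))
    return [
        _component_from_classification(
            cls, parse.title, f.relative_to(root).as_posix()
        )
        for parse, cls, f in entries
    ]


def scan_directory(
    root: Union[str, Path],
    report_title: Optional[str] = None,
    network_hint_tokens: Iterable[str] = DEFAULT_NETWORK_HINT_TOKENS,
) -> ReportSpec:
    """Walk a results directory and build the report structure it implies.

    One section per first-level folder and one subsection per second-level
    folder; files inside a subsection folder become its components, files
    directly inside a section folder become that section's direct
    components. Files at the root itself are ignored with a warning.
    Everything is sorted by the explicit numeric order, then title, so the
    result is independent of filesystem enumeration order. Component
    ``file_path`` values are stored relative to ``root`` and the returned
    spec's ``base_dir`` is ``root``.
    """
    root = Path(root)
    if not root.is_dir():
        raise IngestError(f"input directory does not exist: {root}")

    seen: set[Path] = {root.resolve()}
    skipped: list[str] = []
    sections: list[tuple[NameParse, Section]] = []

    for entry in _iter_entries(root, seen):
        if entry.is_file():
            logger.warning("ignoring file at report root: %s", entry)
            skipped.append(str(entry))
            continue
        sec_parse = parse_name(entry.name)
        direct_files: list[Path] = []
        subsections: list[tuple[NameParse, Subsection]] = []
        for child in _iter_entries(entry, seen):
            if child.is_file():
                direct_files.append(child)
            elif child.is_dir():
                sub_parse = parse_name(child.name)
                comps = _build_components(
                    _collect_files(child, seen), root, network_hint_tokens, skipped
                )
                subsections.append(
                    (sub_parse, Subsection(title=sub_parse.title, components=comps))
                )
        subsections.sort(key=lambda t: order_key(t[0]))
        section = Section(
            title=sec_parse.title,
            components=_build_components(
                direct_files, root, network_hint_tokens, skipped
            ),
            subsections=[s for _, s in subsections],
        )
        sections.append((sec_parse, section))

    sections.sort(key=lambda t: order_key(t[0]))
    spec = ReportSpec(
        title=report_title or parse_name(root.name).title,
        sections=[s for _, s in sections],
        base_dir=root,
    )
    if not any(True for _ in spec.iter_components()):
        raise IngestError(f"nothing to report: no classifiable content under {root}")
    return spec


def directory_to_config(
    root: Union[str, Path],
    out: Union[str, Path],
    report_title: Optional[str] = None,
    network_hint_tokens: Iterable[str] = DEFAULT_NETWORK_HINT_TOKENS,
) -> Path:
    """Scan ``root`` and write the inferred config as YAML to ``out``.

    File paths in the config are written relative to ``out``'s directory,
    so the file remains valid wherever it is placed. The output is
    deterministic: running twice on an unchanged tree gives identical files.
    """
    root = Path(root)
    out = Path(out)
    spec = scan_directory(root, report_title, network_hint_tokens)
    out.parent.mkdir(parents=True, exist_ok=True)
    base = out.parent.resolve()
    import os

    for _, _, comp in spec.iter_components():
        absolute = (root / comp.file_path).resolve()
        comp.file_path = Path(os.path.relpath(absolute, base)).as_posix()
    spec.base_dir = base
    out.write_text(serialize_config(spec), encoding="utf-8")
    return out
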
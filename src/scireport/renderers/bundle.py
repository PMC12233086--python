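"""Bundle bookkeeping shared by the webapp and document writers."""

from __future__ import annotations

import re
import shutil
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from ..config_model import (
    Component,
    ComponentKind,
    FILELESS_KINDS,
    NetworkAttrs,
    NetworkFormat,
    PlotAttrs,
    PlotFormat,
    ReportSpec,
    ReportType,
    ValidationIssue,
    has_errors,
    validate,
)

__all__ = ["BundleFile", "ReportBundle", "StaticizedAsset", "RenderError", "slugify"]


class RenderError(RuntimeError):
    """Raised when a report bundle cannot be generated."""


@dataclass(frozen=True)
class BundleFile:
    path: Path  # relative to the bundle root
    role: str  # entry | page | asset | static_image | document_source


@dataclass
class ReportBundle:
    report_type: ReportType
    root: Path
    files: list[BundleFile] = field(default_factory=list)
    render_command: str = ""

    def add(self, path: Path, role: str) -> None:
        self.files.append(BundleFile(path=path, role=role))

    def with_role(self, role: str) -> list[BundleFile]:
        return [f for f in self.files if f.role == role]

    @property
    def entry(self) -> Optional[Path]:
        entries = self.with_role("entry") + self.with_role("document_source")
        return self.root / entries[0].path if entries else None


@dataclass(frozen=True)
class StaticizedAsset:
    source: Component
    image_path: Path


def slugify(text: str) -> str:
    slug = re.sub(r"[^a-z0-9]+", "_", text.lower()).strip("_")
    return slug or "untitled"


def check_renderable(spec: ReportSpec, report_type: ReportType) -> list[ValidationIssue]:
    issues = validate(spec, report_type)
    if has_errors(issues):
        errors = "; ".join(i.message for i in issues if i.severity == "error")
        raise RenderError(f"spec is not renderable for {report_type.value}: {errors}")
    return issues


def is_interactive_payload(comp: Component) -> bool:
    """True for components whose payload is interactive: plot JSON or any
    network format short of a prerendered HTML embed."""
    if comp.kind is ComponentKind.PLOT and isinstance(comp.attrs, PlotAttrs):
        return comp.attrs.plot_format is PlotFormat.INTERACTIVE_JSON
    if comp.kind is ComponentKind.NETWORK and isinstance(comp.attrs, NetworkAttrs):
        return comp.attrs.net_format is not NetworkFormat.HTML_EMBED
    return False


class AssetStore:
    """Copies component payloads into ``<bundle root>/static`` exactly once,
    preserving relative layout, and hands back bundle-relative paths."""

    def __init__(self, spec: ReportSpec, root: Path, bundle: ReportBundle):
        self.spec = spec
        self.root = root
        self.bundle = bundle
        self._placed: dict[Path, Path] = {}

    def place(self, comp: Component) -> Path:
        if comp.kind in FILELESS_KINDS or comp.file_path is None:
            raise RenderError(f"component {comp.title!r} has no payload file")
        src = self.spec.resolve_path(comp.file_path)
        if not src.is_file():
            raise RenderError(f"component file not found: {src}")
        key = src.resolve()
        if key in self._placed:
            return self._placed[key]
        rel_src = Path(comp.file_path)
        if rel_src.is_absolute() or ".." in rel_src.parts:
            # keep at most the three trailing path parts so the bundle layout
            # stays self-contained and independent of where the inputs live
            parts = [p for p in rel_src.parts if p not in ("..", "/", "\\")]
            rel = Path("static") / Path(*parts[-3:])
        else:
            rel = Path("static") / rel_src
        dest = self.root / rel
        i = 1
        while dest.exists() and dest.read_bytes() != src.read_bytes():
            rel = rel.with_name(f"{rel.stem}_{i}{rel.suffix}")
            dest = self.root / rel
            i += 1
        dest.parent.mkdir(parents=True, exist_ok=True)
        shutil.copyfile(src, dest)
        self.bundle.add(rel, "asset")
        self._placed[key] = rel
        return rel
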
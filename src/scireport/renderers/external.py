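"""Optional integration with the external rendering tools.

The generated bundles are complete on their own; turning a qmd bundle
into the final artifact needs the ``quarto`` CLI and running a webapp
bundle needs ``streamlit``. This step is deliberately optional — when
the tool is missing a clear error says what to install, and everything
else in the package works without it.
"""

from __future__ import annotations

import ast
import logging
import shutil
import subprocess
from pathlib import Path

from ..config_model import ReportType
from .bundle import RenderError, ReportBundle

logger = logging.getLogger(__name__)

__all__ = ["ExternalToolMissing", "render_external"]


class ExternalToolMissing(RenderError):
    """The external renderer needed for this bundle is not installed."""


def render_external(bundle: ReportBundle) -> list[Path]:
    """Render a bundle with its external tool, returning final artifacts.

    For webapp bundles this is a smoke check: every emitted script must
    parse as valid Python (launching a server is the user's call). For
    the document formats it invokes ``quarto render`` and returns the
    produced artifact paths. Raises :class:`ExternalToolMissing` with an
    install hint when the tool is absent, and :class:`RenderError`
    carrying the tool's log when it exits nonzero.
    """
    if bundle.report_type is ReportType.WEBAPP:
        for f in bundle.with_role("page") + bundle.with_role("entry"):
            src = (bundle.root / f.path).read_text(encoding="utf-8")
            try:
                ast.parse(src, filename=str(f.path))
            except SyntaxError as exc:  # pragma: no cover - generator bug guard
                raise RenderError(f"emitted script {f.path} does not parse: {exc}")
        if shutil.which("streamlit") is None:
            logger.info(
                "streamlit is not installed; bundle verified but not launched "
                "(install streamlit and run: %s)",
                bundle.render_command,
            )
        return [bundle.root / "app.py"]

    if shutil.which("quarto") is None:
        raise ExternalToolMissing(
            "the 'quarto' CLI is required to compile document reports; "
            "install it from https://quarto.org and re-run: "
            + bundle.render_command
        )
    entry = bundle.entry
    proc = subprocess.run(
        ["quarto", "render", str(entry)],
        capture_output=True,
        text=True,
    )
    if proc.returncode != 0:
        raise RenderError(
            f"quarto render failed (exit {proc.returncode}):\n{proc.stderr}"
        )
    suffix = {
        ReportType.HTML: ".html",
        ReportType.PDF: ".pdf",
        ReportType.DOCX: ".docx",
        ReportType.ODT: ".odt",
        ReportType.REVEALJS: ".html",
        ReportType.PPTX: ".pptx",
        ReportType.NOTEBOOK: ".ipynb",
    }[bundle.report_type]
    return sorted(bundle.root.glob(f"report{suffix}"))
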
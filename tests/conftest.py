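"""Shared fixtures: generated example directories and spec builders."""

from __future__ import annotations

import hashlib
import random
from pathlib import Path

import pytest

from scireport.config_model import (
    ApiCallAttrs,
    ChatbotAttrs,
    Component,
    ComponentKind,
    HttpMethod,
    ReportSpec,
    Section,
    Subsection,
)
from scireport.fixtures import make_basic_fixture, make_emp_style_fixture
from scireport.ingest import scan_directory


@pytest.fixture(scope="session")
def basic_fixture(tmp_path_factory):
    root = tmp_path_factory.mktemp("fixtures") / "basic_example_report"
    manifest = make_basic_fixture(root, seed=7)
    return manifest


@pytest.fixture(scope="session")
def emp_fixture(tmp_path_factory):
    root = tmp_path_factory.mktemp("fixtures_emp") / "microbiome_survey_report"
    manifest = make_emp_style_fixture(root, seed=7)
    return manifest


@pytest.fixture(scope="session")
def basic_spec(basic_fixture):
    return scan_directory(
        basic_fixture.root, report_title=basic_fixture.expected_spec().title
    )


@pytest.fixture(scope="session")
def emp_spec(emp_fixture):
    return scan_directory(
        emp_fixture.root, report_title=emp_fixture.expected_spec().title
    )


def tree_hash(root: Path) -> str:
    """Order-independent digest of a file tree (paths + contents)."""
    root = Path(root)
    h = hashlib.sha256()
    for p in sorted(root.rglob("*")):
        if p.is_file():
            h.update(p.relative_to(root).as_posix().encode())
            h.update(p.read_bytes())
    return h.hexdigest()


def make_random_spec(rng: random.Random) -> ReportSpec:
    """A small random report spec over fileless/markdown-free structure.

    Used for round-trip properties, so it only needs structural variety,
    not real payload files. Components are apicall/chatbot (fileless) or
    carry arbitrary path strings that are never resolved.
    """

    def component(i: int) -> Component:
        kind = rng.choice(
            [ComponentKind.MARKDOWN, ComponentKind.APICALL, ComponentKind.CHATBOT]
        )
        if kind is ComponentKind.APICALL:
            return Component(
                title=f"Call {i}",
                kind=kind,
                attrs=ApiCallAttrs(
                    api_url=f"https://api.example.org/v{i}",
                    method=rng.choice(list(HttpMethod)),
                    request_body='{"q": 1}' if rng.random() < 0.5 else None,
                    headers=(("x-key", "abc"),) if rng.random() < 0.5 else None,
                ),
            )
        if kind is ComponentKind.CHATBOT:
            return Component(
                title=f"Chat {i}",
                kind=kind,
                attrs=ChatbotAttrs(
                    api_url="https://llm.example.org/chat", model=f"model-{i}"
                ),
            )
        return Component(
            title=f"Notes {i}",
            kind=kind,
            file_path=f"notes/part_{i}.md",
            caption=f"caption {i}" if rng.random() < 0.5 else None,
        )

    idx = 0
    sections = []
    for s in range(rng.randint(1, 3)):
        subsections = []
        for t in range(rng.randint(0, 2)):
            comps = []
            for _ in range(rng.randint(1, 3)):
                comps.append(component(idx))
                idx += 1
            subsections.append(
                Subsection(
                    title=f"Subsection {s}.{t}",
                    description=f"desc {t}" if rng.random() < 0.5 else None,
                    components=comps,
                )
            )
        direct = []
        if rng.random() < 0.4 or not subsections:
            direct = [component(idx)]
            idx += 1
        sections.append(
            Section(
                title=f"Section {s}",
                subsections=subsections,
                components=direct,
            )
        )
    return ReportSpec(
        title="Random Report",
        description="generated for round-trip testing" if rng.random() < 0.5 else None,
        sections=sections,
    )
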
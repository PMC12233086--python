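# scireport

Bioinformatics and other data-heavy analyses leave behind a scatter of
output files — plots, tables, networks, notes — and turning those into a
shareable report usually means hand-writing a document or a web app.
`scireport` automates that step: point it at a directory of results (or
at a YAML configuration describing the report) and pick an output
format, and it compiles a structured report with no coding required.

Supported outputs: a multi-page **Streamlit web application**, and —
via Quarto Markdown — **HTML, PDF, DOCX, ODT, PPTX, Reveal.js slides,
and Jupyter notebooks**.

## How it works

A report is a three-level hierarchy: *sections* → *subsections* →
*components*. When given a directory, the tool infers that hierarchy:

- first-level folders become sections, second-level folders become
  subsections, and files become components;
- titles come from folder and file names (`alpha_diversity_10.json` →
  "Alpha Diversity"), and numeric name tokens fix the ordering
  (`_2` sorts before `_10`, numerically);
- component types are inferred from extensions and names: images are
  static plots; JSON files are interactive charts (Plotly-style figure
  objects or Vega-Lite, auto-detected); CSV/TXT/Parquet/XLSX are tables;
  GraphML/GML/GEXF/CYJS are networks, as are CSV/TXT files whose name
  contains a token like `edge_list` or `adjacency`; Markdown and HTML
  are included as text blocks.

The inferred structure is written out as an editable YAML configuration
(see `docs/config_schema.md`), so you can add descriptions and captions,
reorder content, or add API-call and chatbot panels (web app only) and
re-render. The same configuration drives every output format. For the
static formats (PDF, DOCX, ODT, PPTX), interactive charts and networks
are automatically converted to 1000×600 px PNG images.

## Worked example

Generate a small example results directory and build two reports:

```sh
python -c "from scireport.fixtures import make_basic_fixture; \
           make_basic_fixture('demo/basic_example_report', seed=7)"
scireport --directory demo/basic_example_report --report_type html --output-dir demo/reports
scireport --directory demo/basic_example_report --report_type webapp --output-dir demo/reports
```

which prints:

```
report bundle written to demo/reports/html
editable configuration saved to demo/reports/report_config.yaml
render with: quarto render demo/reports/html/report.qmd
report bundle written to demo/reports/webapp
editable configuration saved to demo/reports/report_config.yaml
render with: streamlit run demo/reports/webapp/app.py
```

The example directory has 3 sections, 5 subsections, and 14 components
(4 plots, 4 tables, 2 networks, 3 Markdown, 1 HTML). The HTML bundle is
a single `report.qmd` with one level-1 heading per section and one
level-2 heading per subsection; the webapp bundle contains `app.py`
plus one page script per subsection (and an overview page for the
section that holds components directly — 6 pages here), each rendering
its components with interactive widgets. `report_config.yaml` is the
inferred configuration; edit it and re-run with `--config` to customize
the report:

```sh
scireport --config demo/reports/report_config.yaml --report_type pdf --output-dir demo/reports
```

The same works as a library:

```python
from scireport import scan_directory, generate_document

spec = scan_directory("demo/basic_example_report")
bundle = generate_document(spec, "pdf", "demo/reports/pdf")
print(bundle.render_command)
```

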
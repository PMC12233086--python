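# Methods

This note documents how `scireport` turns a directory of analysis
outputs into multi-format reports: the structure-inference rules, the
component model, the rendering pipeline, the numerical and formatting
choices that were genuinely open, and what the synthetic fixtures do
and do not exercise.

## The report model

A report is `ReportSpec(title, description?, graphical_abstract?,
logo?, sections)`, where each `Section` holds ordered `Subsection`s
and, optionally, components placed directly under the section; each
`Subsection` holds ordered `Component`s. A component is one renderable
unit with a kind (`plot`, `dataframe`, `network`, `markdown`, `html`,
`apicall`, `chatbot`) and kind-specific attributes (table format and
delimiter, network encoding, chart dialect, API endpoint details).
Equality is structural and order-sensitive: the YAML serialization has
a fixed key order and omits unset optionals, so
`parse(serialize(spec)) == spec` and repeated serialization is
byte-identical. `apicall` and `chatbot` are the only fileless kinds;
they are rendered only in the web application and skipped with a
warning elsewhere, so one configuration can drive all formats.

## Directory inference

Given a results directory, first-level folders map to sections and
second-level folders to subsections; files become components. Rules
that the directory layout alone does not determine are fixed as
follows:

- **Titles and order.** A trailing `_<n>` (or `-<n>`) token on a name
  stem is the explicit order and is stripped from the title; a leading
  `<n>_` prefix is accepted too, with the suffix winning when both are
  present. Ordered items sort first (numerically — `_2` before `_10`),
  then unordered items case-insensitively alphabetically; equal orders
  tie-break alphabetically. This makes the scan independent of
  filesystem enumeration order.
- **Type inference.** By extension: images → static plots; `.json` →
  interactive plots; `.csv`/`.txt` → tables; `.parquet`/`.xlsx` →
  tables; `.md` → markdown; `.graphml`/`.gml`/`.gexf`/`.cyjs` →
  networks; `.html` → HTML. A `.csv`/`.txt`/`.html` file whose basename
  contains one of the tokens `edge_list`, `edgelist`, `adjacency`,
  `network`, `graph` (case-insensitive, configurable via
  `--network-hint-token`) is treated as a network instead — adjacency
  if the name says so, edge list otherwise.
- **Edge cases.** Files at the directory root, hidden (dot-prefixed)
  entries, zero-byte files, and files with unknown extensions are
  skipped with warnings. Folders deeper than two levels are flattened
  into their second-level ancestor, with a warning, since the report
  model has exactly two hierarchy levels. Symlinks are followed with
  cycle detection on resolved paths. A directory with no classifiable
  content is an error ("nothing to report"), not an empty report.

## Payload loading

- **Tables** load through pandas. For delimited text, an unset
  delimiter is chosen by majority vote over the first 10 lines among
  comma, tab, and semicolon; a configured delimiter always wins. The
  header row supplies column names; ragged files and empty files are
  errors naming the first bad line. XLSX reads the first sheet only
  (warning if more exist).
- **Networks**: edge lists take one edge per data row, a third numeric
  column as weight, and further columns as edge attributes. Adjacency
  matrices must be square and labeled; the diagonal is ignored; a
  symmetric matrix yields an undirected graph with each pair emitted
  once (so the edge count equals the nonzero upper-triangle count), an
  asymmetric one a directed graph. GraphML/GML/GEXF/CYJS parse via
  networkx. `html_embed` payloads pass through unparsed.
- **Plot JSON dialect**: a top-level `$schema` containing "vega" marks
  the Vega family; top-level `data` plus `layout` keys mark a
  Plotly-style figure object; anything else is `unknown` and is shown
  as a pretty-printed code block with a warning rather than aborting
  the report.
- **Markdown/HTML** are returned verbatim, unsanitized: inputs are the
  user's own local analysis outputs, not untrusted uploads. Non-UTF-8
  bytes are replacement-decoded with a warning.

## Rendering

**Web application.** The writer emits Streamlit *source text*: an
`app.py` entry with the navigation, one folder per section, one page
script per subsection, and an overview page for sections with direct
components; an empty section still gets a visible placeholder page so
the report mirrors the configuration. Pages use interactive widgets
(chart objects, sortable/filterable dataframes, network views with a
pyvis embed and a drawn fallback, chat panels). The emitted scripts are
validated by parsing them as Python; running the app requires
Streamlit, which is deliberately not a dependency of the generator
itself.

**Documents.** The other seven formats produce one Quarto Markdown file
with format-specific front matter. Sections are level-1 headings and
subsections level-2 (component titles are level-3, so heading counts
track the hierarchy); the presentation formats start a new slide per
subsection through the same mapping. Interactive charts are embedded as
HTML/JS blocks in HTML and Reveal.js output and staticized for the
static formats; notebooks also use staticized images, keeping the
generated notebook executable-free. Tables render as DataTables-backed
HTML tables in interactive formats and as pipe tables (first 50 rows)
otherwise. Each component block starts with an HTML comment naming its
source file, which makes component conservation — every component
referenced exactly once — mechanically checkable.

**Static export.** The package ships its own matplotlib-based exporter
for the two chart dialects: Plotly-style scatter/line/bar traces and
Vega-Lite point/circle/line/bar marks with inline data values. Anything
outside that envelope raises an explicit error naming the unsupported
feature — never a silent blank image. Networks are drawn with a
networkx spring layout under a fixed seed (42). Defaults: 1000×600 px
at 100 dpi, chosen to fit A4 pages and 16:9 slides; PNG metadata that
would vary between runs is stripped, so regenerating a bundle is
byte-identical.

**External tools.** `render_external` invokes `quarto render` (or, for
the webapp, re-parses the emitted scripts as a smoke check). It is an
optional integration layer: when the tool is missing the error names it
and shows the command to run, and no other functionality depends on it.

## Synthetic fixtures

Two seeded generators make the package fully testable offline. The
basic fixture is a 3-section / 5-subsection / 14-component tree
covering every classifiable subtype at least once, with numeric name
suffixes exercising the 2-before-10 ordering case. The survey-style
fixture mimics the structure of a large microbiome survey report —
sections on exploratory data analysis, metagenomics, and network
analysis, with an ordination scatter, abundance tables, and a
co-occurrence graph. Both return a manifest listing every file with its
expected kind and subtype plus a hand-written expected `ReportSpec`,
which serves as the independent oracle for the scanner.

All fixture content is a pure function of the seed: charts have ≤ 20
points so static export is fast; XLSX output is normalized (fixed
document-property dates and zip timestamps) because the spreadsheet
writer otherwise stamps save time into the bytes. The fixtures emulate
the *shape* of real results directories, not their content: passing
tests demonstrate correct structure inference, loading, and rendering,
but say nothing about the scientific validity of any particular
analysis output, about very large tables/graphs, or about malformed
files beyond the error cases tested explicitly.

## Known limitations

- The static chart exporter covers the common trace/mark types, not the
  full Plotly/Vega grammars; unsupported specs fail loudly and can be
  pre-rendered to PNG upstream instead.
- Interactive network views exist only in the web application; document
  formats always use the static drawing (or link an `html_embed`).
- Multi-sheet workbooks, file-content sniffing beyond the delimiter
  probe, config migration, and theming beyond logo/graphical abstract
  are out of scope.
- The chatbot panel emits a generic chat-completion request/response
  loop; it does not implement any provider-specific protocol.
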
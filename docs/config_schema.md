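# Report configuration schema

A report configuration is a UTF-8 YAML file with two top-level keys:
`report` (metadata) and `sections` (the ordered content hierarchy).
Unset optional fields are simply omitted; writing `null` is equivalent.
Relative `file_path` values are resolved against the directory that
contains the config file; absolute paths are used as-is. Unknown keys
are preserved and reported as warnings, never errors.

```yaml
report:
  title: My Analysis Report          # required
  description: One-line summary.     # optional
  graphical_abstract: figs/ga.png    # optional, shown on the title page
  logo: figs/logo.png                # optional, shown in the webapp sidebar

sections:                            # ordered; order is meaningful
- title: Exploratory Data Analysis   # required
  description: What this section covers.   # optional
  components: []                     # optional: components directly under
                                     # the section, without a subsection
  subsections:
  - title: Summary Figures
    description: ...                 # optional
    components:
    - ...                            # see component examples below
```

Every component needs `title` and `component_type` (one of `plot`,
`dataframe`, `network`, `markdown`, `html`, `apicall`, `chatbot`), plus
`file_path` for all kinds except `apicall`/`chatbot`. An optional
`caption` is shown under the rendered component.

## One example per component kind

### plot

```yaml
- title: Alpha Diversity
  caption: Shannon index against sequencing depth.
  component_type: plot
  file_path: eda/alpha_diversity.json
  plot_format: interactive_json      # or static_image (PNG/SVG/JPG)
  json_dialect: vega_family          # vega_family | figure_object | unknown;
                                     # auto-detected from the payload when unknown
```

### dataframe

```yaml
- title: Abundance Table
  component_type: dataframe
  file_path: eda/abundance.csv
  file_format: csv                   # csv | txt | parquet | xlsx
  delimiter: ";"                     # optional, csv/txt only; probed when unset
```

### network

```yaml
- title: Cooccurrence Network
  component_type: network
  file_path: networks/cooccurrence.graphml
  net_format: graphml                # edge_list | adjacency | graphml | gml |
                                     # gexf | cyjs | html_embed
  # delimiter: ","                   # optional, edge_list/adjacency only
```

### markdown

```yaml
- title: Methods
  component_type: markdown
  file_path: notes/methods.md        # included verbatim
```

### html

```yaml
- title: QC Summary
  component_type: html
  file_path: qc/multiqc_report.html  # embedded raw in HTML-capable outputs
```

### apicall (webapp reports only)

```yaml
- title: Annotation Lookup
  component_type: apicall
  api_url: https://api.example.org/annotate
  method: POST                       # GET | POST | PUT
  request_body: '{"ids": [1, 2]}'    # optional JSON text
  headers:                           # optional
    x-api-key: abc123
```

### chatbot (webapp reports only)

```yaml
- title: Results Assistant
  component_type: chatbot
  api_url: https://llm.example.org/v1/chat
  model: my-model
  mode: standard                     # standard | streaming
```

`apicall` and `chatbot` panels are rendered only in the web
application; in every other format they are skipped with a warning, so
one configuration can drive all eight report types.
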
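# File formats

All tabular inputs are tab-separated with a mandatory header row, UTF-8,
gzip-transparent (a `.gz` suffix is decompressed on the fly).  Empty
fields may be written as `` (empty), `-`, `na` or `none`.

## BioGRID-like interactions (`biogrid.tsv`)

| column | type | notes |
|---|---|---|
| `gene_a` | string | first interactor symbol |
| `gene_b` | string | second interactor symbol |
| `taxid_a` | int | NCBI taxon of interactor A |
| `taxid_b` | int | NCBI taxon of interactor B |
| `interaction_label` | `physical` \| `genetic` \| empty | explicit type; when empty the type is deduced from the experiment system |
| `experiment_system` | string | e.g. `two hybrid`, `dosage lethality` |
| `direction` | `a_to_b` \| `b_to_a` \| `unknown` | genetic rows are unidirectional A→B regardless |

## STRING-like links (`string_links.tsv`)

`gene_a  gene_b  taxid_a  taxid_b  neighborhood  coexpression  experimental  database  textmining`

Channel columns are non-negative scores.  A pair is kept only if at least
one *evidence channel* (default `experimental`, `database`) is positive.

## STRING-like actions (`string_actions.tsv`)

`gene_a  gene_b  direction` with direction `a_to_b` or `b_to_a`.  Pairs
without an action record are treated as bidirectional.  Actions
referencing pairs absent from the links file are logged and ignored.

## Text-mining output (`ppaxe.tsv`)

`gene_a  gene_b  score  pmid` — score in [0, 1], PMID optional.

## Alias table (`aliases.tsv`)

`alias  official_symbol`.  A row mapping a symbol to itself declares it
canonical.  Matching is case-insensitive; an alias mapping to two
different official symbols is an error.

## Driver table (`drivers.tsv`)

`symbol  driver_class` with class `SYNDROMIC`, `NON_SYNDROMIC` or `BOTH`.

## Annotation layer (`expression.tsv` etc.)

`symbol  value` — finite numbers; missing symbols take the layer default.

## Outputs

* Edge list: `src  dst  itype  n_evidences  sources` (sorted; `sources`
  is a comma-joined list of source databases).
* Level table: `symbol  level  is_driver  driver_class` (level is an
  integer or `whole`).
* Level summary: `level  new_nodes  new_edges  total_nodes  total_edges`.
* Session: versioned JSON, see `session.schema.json`.
* Cytoscape.js JSON, GraphML, Neo4j bulk CSVs (`nodes.csv`,
  `relationships.csv`).
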
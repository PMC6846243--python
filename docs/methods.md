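# Methods

## Model

The interactome is a directed multigraph over official gene symbols.  An
edge is an ordered pair (src, dst) with an interaction type —
`PHYSICAL` (protein contact), `GENETIC` (phenotype-level interaction), or
`UNKNOWN` (typically text-mining derived, where the extractor cannot tell
the two apart) — and a non-empty list of evidence records (source
database, experiment system or evidence channel, optional reference such
as a PubMed id, optional score).  Parallel edges between the same ordered
pair are permitted only with distinct types; duplicate same-typed edges
merge with evidence union, so evidence counts are conserved by
construction.  Self-loops are allowed and are common in practice
(autoregulation, text-mined self-references).

Directionality is handled at ingestion.  Undirected physical or untyped
records are assumed bidirectional and expanded into both directed edges;
genetic records are taken as unidirectional in listed order; explicit
direction tags (from STRING-style action records, or a direction column)
orient the pair.  Consequence: an undirected kept record contributes
exactly 2 directed edges and a directed record exactly 1, an identity the
tests exercise on every generated dataset.

## Skeleton

Given driver set D, the skeleton is the union over every ordered pair
(a, b), a ≠ b, of all minimal-length directed paths a → b.  Each pair is
computed independently (no Steiner-style global approximation): a forward
BFS from a and a reverse BFS from b give distances d_a and d_b; a node v
is on some shortest a→b path iff d_a(v) + d_b(v) = d_a(b), and an edge
(u, v) iff d_a(u) + 1 + d_b(v) = d_a(b).  This marks the complete
shortest-path DAG without enumerating paths, so skeleton construction is
O(|D| · (V + E)) for the BFS sweeps plus the per-pair marking, and keeps
*every* tied path — the point of the reduction is that tied connectors are
equally interesting candidates.

A driver with no path to or from any other driver is *unconnected*: it is
excluded from the skeleton and reported separately.  It still receives a
level label later if some expansion shell reaches it; an edgeless driver
ends in the whole-graph remainder.

Path enumeration (for queries) walks the same DAG depth-first with
successors in sorted order, which yields the complete path list in
lexicographic order deterministically; a result cap (default 1000, with an
explicit truncation flag) guards against combinatorial blow-up on dense
graphs.  Paths are node sequences: parallel typed edges between
consecutive nodes never multiply paths, their types are annotated on the
step instead.

## Levels

Level 0 is the skeleton node set with its induced edges.  Level k adds all
parents and children of level-(k−1) nodes — the neighborhood relation in
both orientations — and the level-k edge set is *all* edges induced among
the accumulated nodes, so an interaction between two genes that both
arrive at level k is tallied at level k ("within-shell" links).  Expansion
stops at the first step adding no node; that last growing level is the
saturation level.  The per-level table records new/total node and edge
counts; totals are non-decreasing and the saturation set is a fixed point
of expansion.  Nodes never reached are labelled `whole` and appear only in
the whole graph, whose node and edge sets are by definition the full
graph's; the difference between whole-graph and saturation-level tallies
is exactly the `whole`-labelled remainder.

## Ingestion rules and parameters

| parameter | default | meaning |
|---|---|---|
| `taxid` | 9606 | organism filter; rows with any other taxid on either side are dropped, which also removes artificial trans-species constructs |
| `type_map` | bundled | experiment-system → physical/genetic deduction for curated rows lacking an explicit label; unmapped systems stay `UNKNOWN` rather than being guessed |
| `evidence_channels` | {experimental, database} | STRING-style channels that count as actual evidence; pairs with no positive score in any of these are prediction-only and dropped |
| `ppaxe_threshold` | 0.5 | text-mining classifier score cut-off, midpoint of the score range; the filter principle matters more than the exact value and it is configurable |
| `drop_unknown` | true | unaliasing policy for symbols absent from the nomenclature table; driver symbols failing to resolve are a hard error instead |

Alias matching is case-insensitive (text-mining output is mixed-case).
The merge key after unaliasing is (src, dst, itype): the same ordered pair
legitimately carries parallel physical and genetic edges, so type is part
of edge identity.  Unaliasing is idempotent and conserves evidence over
non-dropped edges.

Column layouts of the three dialects are frozen in `docs/formats.md`; the
fixture generator and the parsers share those definitions.  Real-world
BioGRID/STRING exports have different column orders — adapting them is a
one-off reshaping exercise, deliberately out of scope here.

## Statistics

Each directed edge contributes one out-degree at its source and one
in-degree at its target; a self-loop contributes one of each to the same
node.  Hence avg_degree = 2E/N and avg_in = avg_out = E/N, identities the
suite asserts on every fixture.  *Non-redundant interactions* are distinct
unordered endpoint pairs, collapsing direction and parallel types; a
self-loop counts as the single pair {A}.  This makes avg_degree/2 the
per-orientation average the way interactome papers usually quote it.

## Synthetic data

The generator emulates the three source dialects with known ground truth:
a directed Erdős–Rényi backbone over unordered gene pairs (default
n_genes 30, n_drivers 5, p_edge 0.05, 15 % genetic, 15 % untyped — sparse
enough that shortest paths are non-trivial, dense enough that the driver
set usually connects), *planted* unidirectional genetic chains of chosen
lengths between consecutive drivers (so known shortest paths and direction
asymmetries exist by construction), alias spellings injected at a
configurable rate, and deliberate junk the parsers must drop: non-human
rows, evidence-free STRING-style pairs, sub-threshold and
non-nomenclature text-mining rows.  The manifest records the expected
parser output plus skeleton/level ground truth computed through networkx
(an independent route from the package's own BFS machinery).  Output is
byte-identical for identical seeds.

What it does **not** emulate: scale-free degree distributions, realistic
evidence-score distributions, biased database overlap, or real gene
nomenclature.  Passing tests therefore demonstrate algorithmic
correctness and bookkeeping identities, not biological fidelity of any
particular interactome release; headline figures of real builds depend on
the database versions ingested.

The bundled worked example is a hand-crafted 22-gene dataset using real
retinal gene symbols: a six-gene skeleton over four connected drivers, two
expansion shells with within-shell links, a two-gene island, a
self-referencing island and an edgeless driver.  Its expected level table
is part of the fixture and asserted in the smoke tests.

## Numerical and design choices

* Shortest paths are unweighted BFS; evidence scores never weight edges.
* Deterministic ordering everywhere: paths lexicographic, exports sorted
  by symbol, parsers preserve file order — identical inputs give
  byte-identical outputs.
* Degenerate queries are defined, not errors: a path query from a gene to
  itself returns the single zero-length path; an empty path result carries
  a reverse-direction hint; an isolated gene connects to nothing in either
  direction.
* The connect-to-level query reports OUTBOUND and INBOUND path sets
  separately and never merges them: the engine is directed while the
  question ("is it connected?") is not, and collapsing the orientations
  would hide which way the evidence points.
* Sessions serialize positions as JSON numbers via Python float repr,
  which round-trips IEEE doubles bit-exactly; loading validates structure
  field by field and fills defaults for fields missing from older minor
  versions.  A JSON-schema document (`docs/session.schema.json`) describes
  the format.
* Test scale: graph-algorithm oracles run on 200 random digraphs of 4–12
  nodes (edge probability 0.2, drivers 2–5) against brute-force
  depth-first path enumeration — small enough that exhaustive enumeration
  is exact and fast, large enough to cover self-loops, parallel types,
  unreachable pairs and tied paths.  Parser and bookkeeping properties run
  on 50 generated datasets of 24 genes.

## Known limitations

* Real BioGRID/STRING column layouts must be reshaped to the documented
  dialects before ingestion; no release downloader is included.
* The level-k edge tally counts all induced edges, including within-shell
  links; pipelines counting only edges incident to new nodes will report
  smaller per-level increments.
* Whether non-redundant pair counting should ignore self-loops is
  convention; here {A} is one pair.
* The edge-list TSV keeps only evidence tallies, so re-importing it
  reconstructs topology and provenance sources but not per-evidence
  detail; use sessions or GraphML for richer round-trips.
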
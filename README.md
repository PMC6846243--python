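# skelenet

Disease-gene interactome skeleton networks: build, reduce, expand and query.

## The problem

Inherited retinal dystrophies (and Mendelian diseases generally) have many
clinically validated *driver genes*, yet a large fraction of patients carry
variants in genes not yet linked to the disease.  Interaction networks help:
a candidate gene sitting on a path between two known drivers is a much
stronger lead than one floating in the bulk interactome.  The raw
interactome, however, is enormous and noisy — far too large to inspect.

`skelenet` implements the reduction that makes this tractable.  Given a
directed, typed interaction multigraph *G* = (*V*, *E*) and a driver set
*D* ⊆ *V*:

* **Skeleton** — the subgraph formed by the union, over every ordered pair
  (*a*, *b*) ∈ *D* × *D*, *a* ≠ *b*, of **all** minimal-length directed
  paths *a* → … → *b*.  Every tied shortest path is kept, computed per pair
  on the BFS shortest-path DAG (an edge (*u*, *v*) is on a shortest *a*→*b*
  path iff *d*(*a*,*u*) + 1 + *d*(*v*,*b*) = *d*(*a*,*b*)).  Drivers with
  no path to or from any other driver are reported as *unconnected*.
* **Levels** — level 0 is the skeleton; level *k* adds every parent
  (in-neighbor) and child (out-neighbor) of a level-(*k*−1) node, plus all
  edges induced among the accumulated nodes.  Expansion stops at
  *saturation*, the first level adding no new node.  Unreached nodes —
  isolated genes and interaction islands — carry the `whole` label and
  appear only in the whole graph.
* **Queries** — (1) direct interactors of a gene within a level cap,
  (2) all shortest directed paths between two genes (direction matters;
  swap the genes for the reverse question), (3) shortest connections from
  a gene to any node of a given level, searched and reported in both
  orientations.

Edges are typed `PHYSICAL` / `GENETIC` / `UNKNOWN` and carry provenance
(`Evidence`: source database, experiment or channel, reference, score).
Three source dialects are ingested — BioGRID-style curated interactions,
STRING-style scored channels with optional direction tags, and
text-mining (PPaxe-style) output — with the standard filters: non-human
pairs out, prediction-only associations out, sub-threshold and
non-nomenclature text-mining hits out, undirected records expanded to both
directions, genetic records kept unidirectional.  All identifiers are
unaliased to official symbols before merging.

## Worked example

The package bundles a hand-crafted 22-gene dataset with a known
decomposition (`skelenet.worked_example_graph`):

```python
import skelenet as sk

graph, example = sk.worked_example_graph()
skeleton, levels = sk.decompose(graph, example.drivers)
stats = sk.compute_stats(graph)

print(f"whole graph: {stats.n_nodes} nodes, {stats.n_edges} edges "
      f"({stats.n_nonredundant} non-redundant)")
print(f"skeleton: {sorted(skeleton.nodes)}")
print(f"saturation at level {levels.saturation_level}; "
      f"unconnected drivers: {levels.unconnected_drivers}")
for row in levels.per_level:
    print(f"level {row.level}: +{row.new_nodes} nodes, +{row.new_edges} edges "
          f"(totals {row.total_nodes}/{row.total_edges})")

result = sk.query_paths_between(graph, "CERKL", "NRL")
print(f"CERKL -> NRL: {result.n_paths} shortest path(s) of length {result.length}")
for p in result.paths:
    print("  " + " -> ".join(p.nodes))
```

prints

```
whole graph: 22 nodes, 23 edges (22 non-redundant)
skeleton: ['CERKL', 'CRX', 'NRL', 'RHO', 'SIRT1', 'SMAD4']
saturation at level 2; unconnected drivers: ['MT-ND4']
level 0: +6 nodes, +8 edges (totals 6/8)
level 1: +6 nodes, +7 edges (totals 12/15)
level 2: +5 nodes, +6 edges (totals 17/21)
CERKL -> NRL: 1 shortest path(s) of length 4
  CERKL -> SIRT1 -> CRX -> SMAD4 -> NRL
```

Reading: of the five drivers, four are linked by shortest paths through two
connector genes (SIRT1, SMAD4) — those six genes are the skeleton.  Two
expansion shells absorb every other connected gene by level 2; the
mitochondrially encoded driver MT-ND4 has no curated interactions, so it is
unconnected and stays in the whole graph, as do an opsin island and a
self-referencing kinase.  The 23 directed typed edges collapse to 22
distinct unordered pairs because NRL→RHO carries parallel genetic and
physical edges.

## Command line

```sh
skelenet fixtures generate --seed 7 --out data/       # synthetic dataset
skelenet build --data data/ --out build/ --graphml    # parse → graph → levels
skelenet stats --graph build/edges.tsv
skelenet query paths  --graph build/edges.tsv --drivers data/drivers.tsv GEN001 GEN002
skelenet query direct --graph build/edges.tsv --drivers data/drivers.tsv --level 1 GEN003
skelenet query connect --graph build/edges.tsv --drivers data/drivers.tsv --target-level 0 GEN010
```

Annotation layers (expression values per gene), session save/restore with
exact layout positions, Cytoscape.js JSON, GraphML and Neo4j bulk-import
CSV exports live in `skelenet.annotate`.  File formats are documented in
`docs/formats.md`; the science and design choices in `docs/methods.md`.

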
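# Methods

## Data model and storage

The registry keeps every source record verbatim: databases (name,
version, promiscuous flag), entities with an attribute multimap, and
relations as entity subtypes with ordered participants that may carry
their own attributes (role, cardinality). Persistence is a versioned
JSON document rather than a database server; at the tens-of-thousands of
records this package targets, an in-memory dict plus an inverted
attribute index answers every query in microseconds and keeps the whole
artifact installable with `pip` alone. Entity and database ids are dense
integers assigned in registration order, so identical inputs produce
byte-identical saved registries.

Attribute values are compared after normalization, controlled by a
per-attribute *kind*: identifiers are trimmed and casefolded (source
casing is inconsistent across databases), `taxID`/`GeneID` parse as
integers, protein sequences are whitespace-stripped and upper-cased, and
sequences longer than 24 residues are indexed by their SHA-256 digest
plus length instead of the literal string. Digest+length equality is
treated as sequence equality; at these scales an accidental collision is
not a realistic failure mode. Raw values are retained alongside the
normalized keys so backtracking reports show what the source actually
said. Participant-level attributes describe membership in a relation,
not the participant molecule, so they are excluded from unification.

## Unification semantics

A protocol atom `(dbA, dbB, {attrs})` declares two records equivalent
iff they come from that (unordered) database pair — `(A, A)` compares
within one database — and share at least one normalized value for
*every* attribute in the set (AND within an atom). Atoms are OR-ed: the
union of their pairs feeds a transitive closure. A missing attribute
never matches (no wildcard), and relation records never pair.

Promiscuous sources get asymmetric treatment:

- connected components are computed over non-promiscuous records using
  only pairs whose both endpoints are non-promiscuous;
- a promiscuous record then attaches to every component containing a
  record it paired with, and may therefore sit in several user entities;
- promiscuous–promiscuous pairs are discarded, and a promiscuous record
  with no anchor appears in no user entity.

The non-transitivity is deliberate: a shared SCOP/Pfam domain entry must
annotate the proteins that carry it, not fuse unrelated proteins into
one node. Without it, a single common domain record would collapse large
parts of the proteome. Component discovery delegates to
`networkx.connected_components`; user-entity ids are ordered by the
smallest member id so partitions are reproducible. Unification is a full
recompute each time — at desk scale that costs milliseconds and avoids
the bookkeeping of incremental merges.

Backtracking inverts the process: for any user entity it reports each
member's source database and raw attributes, and every rule firing
(atom, entity pair, shared values) internal to the group, which is
exactly the audit trail needed to decide whether a merge was justified.

## Networks

Networks live over user entities. Expansion is breadth-first from the
seed set: seeds are level 0 and a node's level is its BFS distance; the
depth-`d` network contains nodes up to level `d` and *all* edges among
them (edges between two final-level nodes cost no further expansion and
make the output self-contained), while edges reaching level `d+1` are
excluded. N-ary relations (complexes, pathways) lift to the clique of
their participants' user entities, each resulting edge citing the same
source relation; promiscuous members can carry relation participation
into every user entity that holds them, but never merge nodes. Edges
record provenance (source relation ids), an inferred flag, free-form
tags and evidence strings. Restrictions are pure predicates on relation
type and relation attributes, applied before lifting, so tightening a
restriction can only shrink the result.

Randomization uses `networkx.double_edge_swap` (10 swaps per edge by
default) on the simple undirected view, which preserves the degree
sequence exactly and introduces no self-loops or multi-edges; provenance
is dropped because randomized edges assert nothing about sources. Union
and intersection combine node and edge sets, union provenance on shared
edges, and recompute levels from the combined seed sets. Anything
classical (shortest paths, components, centralities) is reached through
`UnifiedNetwork.to_networkx()` rather than re-implemented.

## Edge transfer (generalized interologs)

Templates are observed edges only: for each observed edge (x, z), both
orientations are tried, and every user entity y matching the template
endpoint z under the criterion contributes an inferred edge (x, y)
citing the observed edge's provenance plus the matching evidence.
Observed edges are never overwritten, and inference does not chain
through inferred edges in one call — iterating is an explicit user
decision, since each round compounds the error rate.

Matching criteria:

- **shared_attribute** — y shares at least one normalized value with z
  for every listed attribute (existential per attribute, conjunctive
  across attributes);
- **sequence_similarity** — some member sequence of y aligns to some
  member sequence of z above the cutoffs (existential over member
  pairs). Similarity is the percent of alignment columns with a positive
  substitution score; identity percent is also available as the metric.
  Coverage defaults to the template (z) side — "90% of the template's
  residues are inside the alignment" — with an option to require both
  sides. Defaults are 90% similarity and 90% coverage.

The aligner is an affine-gap Smith–Waterman (Gotoh) with substitution
matrices loaded from Biopython (BLOSUM62 default, gap open 11 / extend
1, plus a ±1 identity scheme). It is written here so that tie-breaking
is fully specified — diagonal over gaps, restart at non-positive scores,
traceback from the first maximal cell in row-major order — which makes
reported statistics reproducible and directly checkable against
enumeration oracles. Percentages use the full alignment length
(gap columns included) as denominator. E-value-based cutoffs from an
external search tool can be supplied as precomputed tabular hits instead
of using the built-in aligner; building a proteome-scale homolog index
is out of scope.

## Synthetic data

The generators emulate the structural features unification actually
exercises: the same molecule appearing in several databases under
different identifier systems, identity recoverable via shared accession,
shared sequence+taxon, or shared gene symbol, and promiscuous annotation
records pointing at several proteins. The two worked fixtures encode the
canonical scenarios (a twin-record pair mergeable by accession but not
by sequence+taxon, a four-record chain merged by accession-or-symbol,
and a four-database accession group). Random registries plant
equivalence classes of size 1–4 spread over three non-promiscuous
databases plus one promiscuous source whose records attach to 0–3
classes; class sequences are independent uniform 40-mers, long enough
for the aligner defaults to be meaningful and short enough that the
exhaustive test oracles stay fast. Random interactomes draw each
user-entity pair independently (Erdős–Rényi at the chosen density) and
realize it between random members, recording the ground-truth node-level
edge set.

What the generators do *not* emulate: real identifier syntax and
curation noise (obsolete accessions, isoform suffixes, wrong taxa),
skewed degree distributions of real interactomes, and sequence evolution
(mutated homolog fixtures use uniform random substitutions). Passing
tests therefore demonstrate the *semantics* — partitioning, promiscuity
handling, level bookkeeping, transfer logic — not robustness to dirty
real-world inputs, which remains the user's responsibility at import
time.

## Numerical and design choices

- Alignment scores are plain floats; score comparisons in tests use
  exact equality against the oracle since both sides add the same
  quantities.
- Degenerate inputs: empty registries unify to an empty partition; a
  protocol with no atoms yields all-singleton user entities; empty
  networks write header-only files; `randomize_network` returns the
  graph unchanged when it has fewer than two usable edges.
- The MITAB reader requires the 15-column PSI-MI TAB 2.5 core, ignores
  extra columns, merges repeated interactors by primary id, keeps
  unknown namespaces as raw attributes, and stores column 15 verbatim
  under `Confidence`; n-ary expansion never applies to MITAB because its
  rows are binary by construction.
- PDB values (and all identifier attributes) are compared verbatim after
  casefolding; no chain-id parsing is attempted.
- Problem sizes in the test suite and acceptance script (registries up
  to ~200 records, 100 replicates per property, 40-mer sequences) were
  chosen so each brute-force oracle — O(n²) pair checks, closure by DFS,
  exhaustive alignment enumeration — remains exact rather than sampled.

## Known limitations

Single-process, full-recompute design: no incremental re-unification,
no concurrent writers, no merge confidence scores. The generic tabular
reader stands in for database-specific parsers; importing a real
resource means flattening it to the entity/relation table formats first.
Inferred edges carry evidence but no calibrated reliability estimate.
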
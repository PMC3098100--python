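# entityfuse

`entityfuse` is a desk-scale toolkit for integrating biological records
from heterogeneous databases. Protein-centric resources disagree about
identity: the same yeast protein is `P12385` in one source, `EBI-6533`
in another, `MINT-560710` and `REACT_1034` elsewhere. Rather than baking
one mapping into the data, `entityfuse` keeps every source record verbatim
and lets the *user* decide what counts as "the same molecule" through an
explicit, auditable rule set. It is aimed at bioinformaticians who build
and analyse protein–protein interaction networks from several interaction
databases at once and need to control — and later inspect — how records
were merged.

## The model

- An **external database** is a registered source (name + version). A
  source may be flagged **promiscuous** (e.g. a structural-domain
  classification): its records annotate proteins but should never define
  protein identity.
- An **external entity** is one source record (protein, gene, compound)
  carrying a multimap of **attributes** (`UniprotAccession`,
  `ProteinSequence`, `taxID`, `GeneID`, `geneSymbol`, `Pfam`, ...).
  Relations between records (interactions, complexes, pathways,
  regulation) are themselves entities with participants.
- A **unification protocol** is a set of rule atoms, OR-ed together. Each
  atom names a pair of databases and a set of attributes: two records
  from those databases are equivalent iff they share a value for *every*
  attribute in the atom. The transitive closure of these equivalences
  partitions the records into **user entities** — the nodes of all
  downstream networks. Promiscuous records attach to the user entities
  they match but never form or bridge one, and may belong to several.
- Networks are built breadth-first from **seed** user entities (seeds are
  level 0, their partners level 1, and so on), optionally restricted by
  relation type or relation attributes. Sessions support tagging, linker
  degree (tagged-neighbour counts), degree-preserving randomization, and
  network union/intersection.
- New edges are predicted by a generalized **interolog** transfer: an
  edge x–y is inferred when x is observed to interact with z and y
  matches z, either by sharing user-chosen attributes (e.g. Pfam domains)
  or by local sequence alignment above similarity and coverage cutoffs
  (default 90% / 90%).
- Every merge and every edge is **backtrackable** to the source records,
  the rule atoms that fired, and the shared values that justified them.

## Worked example

```python
from entityfuse import compute_user_entities, backtrack_user_entity, select_seeds
from entityfuse.synthetic import make_unification_example_fixture

registry, protocol, names = make_unification_example_fixture()
partition = compute_user_entities(registry, protocol)
print(len(partition))                       # 1
ue = partition.user_entities[0]
print(sorted(ue.members))                   # [0, 1, 2, 3]
report = backtrack_user_entity(partition, ue.ue_id)
print(sorted(m["database"] for m in report["members"]))
# ['intact', 'mint', 'reactome', 'swissprot']
print(select_seeds(partition, [("UniprotEntry", "ERF1_YEAST")]))
# {0}
```

Four records — a Swiss-Prot entry, an IntAct interactor, a MINT
interactor and a Reactome participant — all annotate the same accession,
so the recommended identifier protocol (accession OR sequence+taxon OR
gene id) fuses them into a single user entity; the backtracking report
lists the four source records and the rule firings behind each merge.
Querying the Uniprot entry code then finds that one node, exactly as a
seed query would during network construction.

The same workflow is available from the shell:

```sh
entityfuse fixtures export --name unification-example --dir fix/
entityfuse unify --registry fix/registry.json \
    --protocol fix/protocol_recommended.json --out partition.tsv
entityfuse backtrack --registry fix/registry.json \
    --protocol fix/protocol_recommended.json --query UniprotEntry=ERF1_YEAST
```

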
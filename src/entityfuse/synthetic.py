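"""Deterministic fixture and random-instance generators.

Everything here is synthetic: the fixtures emulate the canonical
multi-database overlap situations (shared accession, shared
sequence+taxon, shared gene symbol, promiscuous domain annotations) at
toy scale so every other module can be tested without downloading any
real database.  Same spec + seed always yields the identical registry.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from .registry import Registry
from .unification import (
    Partition,
    UnificationProtocol,
    UserEntity,
    cross_all,
)

_AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


def random_protein_sequence(rng: random.Random, length: int = 40) -> str:
    return "".join(rng.choice(_AMINO_ACIDS) for _ in range(length))


# -- worked-example fixtures ----------------------------------------------


def make_protocol_triplet_fixture():
    """Two protein databases plus a promiscuous domain database, arranged
    so three protocols behave differently.

    Returns (registry, protocols, names) where ``protocols`` maps
    P1 (accession), P2 (sequence AND taxon), P3 (accession OR gene
    symbol) — each additionally crossing the domain database on Pfam so
    the promiscuous annotation record attaches — and ``names`` maps the
    protein labels to entity ids.
    """
    reg = Registry()
    db_a = reg.register_database("dbA", "1.0")
    db_b = reg.register_database("dbB", "1.0")
    db_dom = reg.register_database("domdb", "1.0", promiscuous=True)

    rng = random.Random(55901)
    seqs = {label: random_protein_sequence(rng) for label in "1234"}
    names = {
        "Prot1A": reg.register_entity(
            db_a,
            "protein",
            {
                "SourceID": ["Prot1A"],
                "UniprotAccession": ["U1"],
                "geneSymbol": ["G1"],
                "ProteinSequence": [seqs["1"]],
                "taxID": [9606],
                "Pfam": ["PF001"],
            },
        ),
        "Prot1B": reg.register_entity(
            db_b,
            "protein",
            {
                "SourceID": ["Prot1B"],
                "UniprotAccession": ["U1"],
                "geneSymbol": ["G2"],
                "ProteinSequence": [seqs["2"]],
                "taxID": [9606],
            },
        ),
        "Prot2A": reg.register_entity(
            db_a,
            "protein",
            {
                "SourceID": ["Prot2A"],
                "UniprotAccession": ["U2"],
                "geneSymbol": ["G2"],
                "ProteinSequence": [seqs["3"]],
                "taxID": [9606],
            },
        ),
        "Prot2B": reg.register_entity(
            db_b,
            "protein",
            {
                "SourceID": ["Prot2B"],
                "UniprotAccession": ["U2"],
                "geneSymbol": ["G3"],
                "ProteinSequence": [seqs["4"]],
                "taxID": [9606],
                "Pfam": ["PF001"],
            },
        ),
        "Dom1": reg.register_entity(
            db_dom, "other", {"SourceID": ["Dom1"], "Pfam": ["PF001"]}
        ),
    }

    def with_domain_atoms(protocol: UnificationProtocol) -> UnificationProtocol:
        extra = cross_all(reg, [{"Pfam"}], id="pfam").atoms
        dom_atoms = [a for a in extra if db_dom in (a.db_a, a.db_b) and a.db_a != a.db_b]
        protocol.atoms.extend(dom_atoms)
        return protocol

    protocols = {
        "P1": with_domain_atoms(cross_all(reg, [{"UniprotAccession"}], id="P1")),
        "P2": with_domain_atoms(
            cross_all(reg, [{"ProteinSequence", "taxID"}], id="P2")
        ),
        "P3": with_domain_atoms(
            cross_all(reg, [{"UniprotAccession"}, {"geneSymbol"}], id="P3")
        ),
    }
    return reg, protocols, names


def make_unification_example_fixture():
    """Four databases each contributing one record for the same yeast
    translation-termination protein, plus the recommended identifier
    protocol (accession OR sequence+taxon OR gene id) that fuses them.

    Returns (registry, protocol, names)."""
    reg = Registry()
    rng = random.Random(12385)
    seq = random_protein_sequence(rng, 48)
    db_sp = reg.register_database("swissprot", "14.1")
    db_ia = reg.register_database("intact", "2009")
    db_mi = reg.register_database("mint", "2009")
    db_re = reg.register_database("reactome", "2009")
    names = {
        "P12385": reg.register_entity(
            db_sp,
            "protein",
            {
                "SourceID": ["P12385"],
                "UniprotAccession": ["P12385"],
                "UniprotEntry": ["ERF1_YEAST"],
                "ProteinSequence": [seq],
                "taxID": [4932],
                "GeneID": [852896],
            },
        ),
        "EBI-6533": reg.register_entity(
            db_ia,
            "protein",
            {"SourceID": ["EBI-6533"], "UniprotAccession": ["P12385"]},
        ),
        "MINT-560710": reg.register_entity(
            db_mi,
            "protein",
            {
                "SourceID": ["MINT-560710"],
                "UniprotAccession": ["P12385"],
                "ProteinSequence": [seq],
                "taxID": [4932],
            },
        ),
        "REACT_1034": reg.register_entity(
            db_re,
            "protein",
            {
                "SourceID": ["REACT_1034"],
                "UniprotAccession": ["P12385"],
                "GeneID": [852896],
            },
        ),
    }
    protocol = cross_all(
        reg,
        [{"UniprotAccession"}, {"ProteinSequence", "taxID"}, {"GeneID"}],
        id="recommended",
    )
    return reg, protocol, names


# -- random instances ------------------------------------------------------


@dataclass
class FixtureSpec:
    """Plan for a random multi-database registry with planted equivalence
    classes (records sharing one accession per class)."""

    rng_seed: int = 0
    n_databases: int = 4
    n_promiscuous_databases: int = 1
    n_classes: int = 20
    class_size_range: tuple[int, int] = (1, 4)
    n_promiscuous_entities: int = 5
    promiscuous_attach_range: tuple[int, int] = (0, 3)
    sequence_length: int = 40
    extra_attributes: bool = True

    def __post_init__(self):
        if self.n_promiscuous_databases >= self.n_databases:
            raise ValueError("need at least one non-promiscuous database")
        lo, hi = self.class_size_range
        if not (1 <= lo <= hi):
            raise ValueError("invalid class_size_range")


@dataclass
class PlantedTruth:
    """Ground-truth partition a generated registry realizes."""

    classes: list[frozenset[int]]
    attachments: list[frozenset[int]]  # parallel to classes
    orphan_promiscuous: frozenset[int]

    def as_user_entities(self) -> list[UserEntity]:
        paired = sorted(
            zip(self.classes, self.attachments), key=lambda cp: min(cp[0])
        )
        return [
            UserEntity(ue_id=i, members=members, promiscuous_members=prom)
            for i, (members, prom) in enumerate(paired)
        ]


def random_registry(spec: FixtureSpec):
    """Generate a registry realizing planted classes via shared accessions.

    Returns (registry, protocol, truth): the protocol crosses every
    database pair on UniprotAccession, and ``truth`` is the partition
    that protocol must recover."""
    rng = random.Random(spec.rng_seed)
    reg = Registry()
    plain_dbs = [
        reg.register_database(f"db{i}", "1.0")
        for i in range(spec.n_databases - spec.n_promiscuous_databases)
    ]
    prom_dbs = [
        reg.register_database(f"promdb{i}", "1.0", promiscuous=True)
        for i in range(spec.n_promiscuous_databases)
    ]

    classes: list[frozenset[int]] = []
    accessions: list[str] = []
    for c in range(spec.n_classes):
        acc = f"ACC{spec.rng_seed}_{c}"
        accessions.append(acc)
        size = rng.randint(*spec.class_size_range)
        seq = random_protein_sequence(rng, spec.sequence_length)
        members = []
        for m in range(size):
            attrs = {
                "SourceID": [f"rec_{c}_{m}"],
                "UniprotAccession": [acc],
                "ProteinSequence": [seq],
                "taxID": [rng.choice((9606, 10090, 4932))],
            }
            if spec.extra_attributes:
                attrs["geneSymbol"] = [f"SYM{c}_{m}"]
            members.append(
                reg.register_entity(rng.choice(plain_dbs), "protein", attrs)
            )
        classes.append(frozenset(members))

    attachments = [set() for _ in classes]
    orphans = set()
    for p in range(spec.n_promiscuous_entities):
        k = rng.randint(*spec.promiscuous_attach_range)
        targets = rng.sample(range(spec.n_classes), min(k, spec.n_classes))
        attrs = {
            "SourceID": [f"prom_{p}"],
            "UniprotAccession": [accessions[t] for t in targets],
        }
        eid = reg.register_entity(rng.choice(prom_dbs), "other", attrs)
        if targets:
            for t in targets:
                attachments[t].add(eid)
        else:
            orphans.add(eid)

    protocol = cross_all(reg, [{"UniprotAccession"}], id=f"planted-{spec.rng_seed}")
    truth = PlantedTruth(
        classes=classes,
        attachments=[frozenset(a) for a in attachments],
        orphan_promiscuous=frozenset(orphans),
    )
    return reg, protocol, truth


@dataclass
class InteractomeTruth:
    db_id: int
    ue_edges: frozenset[tuple[int, int]]
    relation_ids: tuple[int, ...] = ()


def random_interactome(
    partition: Partition, edge_density: float, rng_seed: int
) -> InteractomeTruth:
    """Sample binary interactions over user entities' members.

    Each unordered pair of user entities independently gets an
    interaction with probability ``edge_density``, realized between one
    random (non-promiscuous) member of each.  The ue-level ground-truth
    edge set is returned for oracle tests."""
    if not 0 <= edge_density <= 1:
        raise ValueError("edge_density must be in [0, 1]")
    rng = random.Random(rng_seed)
    reg = partition.registry
    db_id = reg.register_database(f"interactome-{rng_seed}", "synthetic")
    ues = sorted(partition, key=lambda ue: ue.ue_id)
    edges = set()
    relation_ids = []
    for i in range(len(ues)):
        for j in range(i + 1, len(ues)):
            if rng.random() >= edge_density:
                continue
            a = rng.choice(sorted(ues[i].members))
            b = rng.choice(sorted(ues[j].members))
            relation_ids.append(
                reg.register_relation(db_id, "interaction", [a, b])
            )
            edges.add((ues[i].ue_id, ues[j].ue_id))
    return InteractomeTruth(
        db_id=db_id,
        ue_edges=frozenset(edges),
        relation_ids=tuple(relation_ids),
    )
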
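"""Partition external entities into user entities under a rule protocol.

A protocol is a set of atoms OR-ed together; each atom names a pair of
databases and a set of attributes that must ALL share at least one value
for two records to be equivalent.  Records from promiscuous databases may
be attached to several user entities but never form or bridge one:
equivalence pairs with a promiscuous endpoint annotate components, pairs
between two promiscuous records are ignored entirely.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import networkx as nx

from .registry import Registry, RegistryError


@dataclass(frozen=True)
class UnificationAtom:
    """One rule: cross two databases on a conjunction of attributes."""

    db_a: int
    db_b: int
    attribute_names: frozenset[str]

    def __post_init__(self):
        if not self.attribute_names:
            raise ValueError("an atom needs at least one attribute name")

    def covers(self, da: int, db: int) -> bool:
        return {da, db} == {self.db_a, self.db_b} or (
            da == db == self.db_a == self.db_b
        )


@dataclass
class UnificationProtocol:
    atoms: list[UnificationAtom] = field(default_factory=list)
    id: str = "protocol"

    @classmethod
    def from_dict(cls, data: dict, registry: Registry) -> "UnificationProtocol":
        """Build from the JSON form; database names are resolved against
        ``registry`` and promiscuous flags are checked for consistency."""
        for name in data.get("promiscuous", []):
            db = registry.database_by_name(name)
            if not db.promiscuous:
                raise RegistryError(
                    f"protocol expects database {name!r} to be promiscuous"
                )
        atoms = []
        for a in data["atoms"]:
            dbs = a["dbs"]
            if len(dbs) not in (1, 2):
                raise ValueError("atom 'dbs' must list one or two databases")
            ids = [registry.database_by_name(n).db_id for n in dbs]
            if len(ids) == 1:
                ids = ids * 2
            atoms.append(UnificationAtom(ids[0], ids[1], frozenset(a["attributes"])))
        return cls(atoms=atoms, id=data.get("id", "protocol"))

    def to_dict(self, registry: Registry) -> dict:
        return {
            "id": self.id,
            "promiscuous": sorted(
                d.name for d in registry.databases.values() if d.promiscuous
            ),
            "atoms": [
                {
                    "dbs": sorted(
                        {registry.databases[a.db_a].name, registry.databases[a.db_b].name}
                    ),
                    "attributes": sorted(a.attribute_names),
                }
                for a in self.atoms
            ],
        }

    @classmethod
    def load(cls, path, registry: Registry) -> "UnificationProtocol":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh), registry)

    def save(self, path, registry: Registry) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(registry), fh, indent=1, sort_keys=True)
            fh.write("\n")


def cross_all(registry: Registry, attribute_sets, id: str = "protocol") -> UnificationProtocol:
    """Convenience: atoms for every unordered database pair (incl. self)
    for each attribute-name set in ``attribute_sets``."""
    db_ids = sorted(registry.databases)
    atoms = []
    for names in attribute_sets:
        for da, db in itertools.combinations_with_replacement(db_ids, 2):
            atoms.append(UnificationAtom(da, db, frozenset(names)))
    return UnificationProtocol(atoms=atoms, id=id)


@dataclass(frozen=True)
class UserEntity:
    """An equivalence class of external entities under a protocol."""

    ue_id: int
    members: frozenset[int]
    promiscuous_members: frozenset[int] = frozenset()

    def all_members(self) -> frozenset[int]:
        return self.members | self.promiscuous_members


@dataclass
class Partition:
    """The full outcome of unifying a registry under a protocol."""

    registry: Registry
    protocol: UnificationProtocol
    user_entities: list[UserEntity]
    #: pair evidence: frozenset({e,f}) -> list of (atom, {attr: shared norm values})
    evidence: dict[frozenset, list]

    def __post_init__(self):
        self._member_to_ue: dict[int, int] = {}
        self._prom_to_ues: dict[int, set[int]] = {}
        self._by_id = {ue.ue_id: ue for ue in self.user_entities}
        for ue in self.user_entities:
            for m in ue.members:
                self._member_to_ue[m] = ue.ue_id
            for p in ue.promiscuous_members:
                self._prom_to_ues.setdefault(p, set()).add(ue.ue_id)

    def __iter__(self):
        return iter(self.user_entities)

    def __len__(self):
        return len(self.user_entities)

    def get(self, ue_id: int) -> UserEntity:
        try:
            return self._by_id[ue_id]
        except KeyError:
            raise RegistryError(f"unknown user entity id {ue_id}") from None

    def ues_of(self, entity_id: int) -> frozenset[int]:
        """User entities an external entity belongs to (0, 1 or several)."""
        if entity_id in self._member_to_ue:
            return frozenset({self._member_to_ue[entity_id]})
        return frozenset(self._prom_to_ues.get(entity_id, ()))

    def attribute_norm_values(self, ue_id: int, name: str) -> frozenset[str]:
        """Union of members' normalized values — user entities inherit all
        attributes of their included records (promiscuous ones too)."""
        out: set[str] = set()
        for eid in self.get(ue_id).all_members():
            out |= self.registry.get(eid).norm_values(name)
        return frozenset(out)

    def attribute_values(self, ue_id: int, name: str) -> tuple[str, ...]:
        out: set[str] = set()
        for eid in self.get(ue_id).all_members():
            out.update(self.registry.get(eid).values(name))
        return tuple(sorted(out))

    def as_rows(self):
        """(ue_id, entity_id, db name, db version, membership) rows."""
        for ue in self.user_entities:
            for eid in sorted(ue.members):
                db = self.registry.databases[self.registry.get(eid).db_id]
                yield ue.ue_id, eid, db.name, db.version, "member"
            for eid in sorted(ue.promiscuous_members):
                db = self.registry.databases[self.registry.get(eid).db_id]
                yield ue.ue_id, eid, db.name, db.version, "promiscuous"


def _atom_pairs(registry: Registry, atom: UnificationAtom):
    """Yield (pair, shared-values dict) for one atom.

    Candidates are drawn from the inverted index on the atom's first
    attribute, then filtered by the remaining attributes (AND semantics).
    Relations never pair.
    """
    names = sorted(atom.attribute_names)
    first = names[0]
    index = registry._index.get(first, {})
    db_pair = {atom.db_a, atom.db_b}
    for norm_value, holders in index.items():
        cands = [
            e
            for e in holders
            if registry.entities[e].entity_type != "relation"
            and registry.entities[e].db_id in db_pair
        ]
        if len(cands) < 2:
            continue
        for e, f in itertools.combinations(sorted(cands), 2):
            de, df = registry.entities[e].db_id, registry.entities[f].db_id
            if not atom.covers(de, df):
                continue
            shared = {first: frozenset({norm_value})}
            ok = True
            for name in names[1:]:
                common = registry.entities[e].norm_values(name) & registry.entities[
                    f
                ].norm_values(name)
                if not common:
                    ok = False
                    break
                shared[name] = common
            if ok:
                # re-derive the full shared set for the first attribute too
                shared[first] = registry.entities[e].norm_values(first) & registry.entities[
                    f
                ].norm_values(first)
                yield frozenset({e, f}), shared


def build_equivalence_pairs(
    registry: Registry, protocol: UnificationProtocol
) -> set[frozenset]:
    """All unordered entity pairs equivalent under some atom (OR of atoms)."""
    return set(build_equivalence_evidence(registry, protocol))


def build_equivalence_evidence(
    registry: Registry, protocol: UnificationProtocol
) -> dict[frozenset, list]:
    evidence: dict[frozenset, list] = {}
    for atom in protocol.atoms:
        if atom.db_a not in registry.databases or atom.db_b not in registry.databases:
            raise RegistryError("protocol atom references an unknown database")
        for pair, shared in _atom_pairs(registry, atom):
            evidence.setdefault(pair, []).append((atom, shared))
    return evidence


def compute_user_entities(
    registry: Registry, protocol: UnificationProtocol
) -> Partition:
    """Partition the registry's non-relation entities into user entities.

    Components are formed over non-promiscuous records only; promiscuous
    records are then attached to every component they pair with, and are
    dropped when attached to none.  ue_ids follow the smallest member id.
    """
    evidence = build_equivalence_evidence(registry, protocol)
    non_prom = [
        e.entity_id
        for e in registry.iter_entities()
        if not registry.databases[e.db_id].promiscuous
    ]
    graph = nx.Graph()
    graph.add_nodes_from(non_prom)
    prom_links: dict[int, set[int]] = {}
    for pair in evidence:
        e, f = sorted(pair)
        pe, pf = registry.is_promiscuous(e), registry.is_promiscuous(f)
        if not pe and not pf:
            graph.add_edge(e, f)
        elif pe and not pf:
            prom_links.setdefault(e, set()).add(f)
        elif pf and not pe:
            prom_links.setdefault(f, set()).add(e)
        # promiscuous-promiscuous pairs contribute nothing

    components = sorted(
        (sorted(c) for c in nx.connected_components(graph)), key=lambda c: c[0]
    )
    member_to_comp = {
        eid: idx for idx, comp in enumerate(components) for eid in comp
    }
    prom_members: dict[int, set[int]] = {i: set() for i in range(len(components))}
    for p, anchors in prom_links.items():
        for a in anchors:
            prom_members[member_to_comp[a]].add(p)

    user_entities = [
        UserEntity(
            ue_id=idx,
            members=frozenset(comp),
            promiscuous_members=frozenset(prom_members[idx]),
        )
        for idx, comp in enumerate(components)
    ]
    return Partition(registry, protocol, user_entities, evidence)


def backtrack_user_entity(partition: Partition, ue_id: int) -> dict:
    """Report the source records fused into one user entity and the rule
    firings that justify each merge."""
    ue = partition.get(ue_id)
    registry = partition.registry
    members = []
    for eid in sorted(ue.all_members()):
        entity = registry.get(eid)
        db = registry.databases[entity.db_id]
        members.append(
            {
                "entity_id": eid,
                "database": db.name,
                "version": db.version,
                "promiscuous": db.promiscuous,
                "entity_type": entity.entity_type,
                "attributes": {
                    name: list(entity.values(name))
                    for name in entity.attribute_names()
                },
            }
        )
    merges = []
    all_members = ue.all_members()
    for pair, firings in sorted(
        partition.evidence.items(), key=lambda kv: sorted(kv[0])
    ):
        if not pair <= all_members:
            continue
        if not pair & ue.members:
            continue  # promiscuous-promiscuous pairs justify nothing
        for atom, shared in firings:
            merges.append(
                {
                    "entities": sorted(pair),
                    "atom": {
                        "dbs": sorted(
                            {
                                registry.databases[atom.db_a].name,
                                registry.databases[atom.db_b].name,
                            }
                        ),
                        "attributes": sorted(atom.attribute_names),
                    },
                    "shared_values": {k: sorted(v) for k, v in shared.items()},
                }
            )
    return {"ue_id": ue_id, "members": members, "merges": merges}
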
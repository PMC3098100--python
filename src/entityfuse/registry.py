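"""In-memory store of external databases, entities and relations.

The registry is the substrate every other module queries: it owns the
attribute catalog (which controls value normalization), an inverted index
from (attribute name, normalized value) to entity ids, and per-entity
relation adjacency.  Identifiers are dense integers assigned in
registration order, so two registries built from the same records in the
same order are identical, and save/load round-trips are byte-stable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field

logger = logging.getLogger(__name__)

ENTITY_TYPES = frozenset({"protein", "gene", "compound", "relation", "other"})
RELATION_TYPES = frozenset(
    {"interaction", "reaction", "complex", "pathway", "regulation", "other"}
)

#: attribute kinds control how values are normalized before comparison
ATTRIBUTE_KINDS = frozenset({"identifier", "integer", "sequence", "text"})

# Seed catalog: the attribute names most cross-references use.  Users can
# register further names at runtime (see AttributeCatalog.register).
DEFAULT_CATALOG: dict[str, str] = {
    "UniprotAccession": "identifier",
    "UniprotEntry": "identifier",
    "GeneID": "integer",
    "taxID": "integer",
    "geneSymbol": "identifier",
    "PDB": "identifier",
    "Pfam": "identifier",
    "SCOP": "identifier",
    "SourceID": "identifier",
    "ProteinSequence": "sequence",
    "Description": "text",
    "Name": "text",
    "DetectionMethod": "text",
    "InteractionType": "text",
    "Confidence": "text",
    "Reliability": "text",
    "Role": "text",
    "Cardinality": "text",
}

# Sequences longer than this are indexed by digest rather than verbatim.
_SEQ_DIGEST_THRESHOLD = 24


class RegistryError(ValueError):
    """Raised on contract violations (duplicates, dangling ids, ...)."""


class AttributeCatalog:
    """Registered attribute names and their normalization kinds."""

    def __init__(self, names: dict[str, str] | None = None) -> None:
        self._kinds: dict[str, str] = dict(DEFAULT_CATALOG if names is None else names)

    def register(self, name: str, kind: str = "identifier") -> None:
        if kind not in ATTRIBUTE_KINDS:
            raise RegistryError(f"unknown attribute kind {kind!r}")
        existing = self._kinds.get(name)
        if existing is not None and existing != kind:
            raise RegistryError(
                f"attribute {name!r} already registered with kind {existing!r}"
            )
        self._kinds[name] = kind

    def __contains__(self, name: str) -> bool:
        return name in self._kinds

    def kind(self, name: str) -> str:
        try:
            return self._kinds[name]
        except KeyError:
            raise RegistryError(f"attribute {name!r} is not in the catalog") from None

    def normalize(self, name: str, value) -> str:
        """Return the comparison key for a raw attribute value.

        identifier: trimmed + casefolded; integer: parsed to int (ValueError
        propagates); sequence: whitespace stripped, upper-cased, long
        sequences replaced by sha256 digest + length; text: trimmed.
        """
        kind = self.kind(name)
        s = str(value).strip()
        if kind == "identifier":
            return s.casefold()
        if kind == "integer":
            return str(int(s))
        if kind == "sequence":
            seq = "".join(s.split()).upper()
            if len(seq) > _SEQ_DIGEST_THRESHOLD:
                digest = hashlib.sha256(seq.encode()).hexdigest()
                return f"sha256:{digest}:{len(seq)}"
            return seq
        return s

    def to_dict(self) -> dict[str, str]:
        return dict(self._kinds)


@dataclass(frozen=True)
class ExternalDatabase:
    db_id: int
    name: str
    version: str
    promiscuous: bool = False


@dataclass
class ExternalEntity:
    """One record from an external database, with a multimap of attributes.

    ``attributes`` maps name -> {normalized value -> raw value}; the
    normalized key deduplicates, the raw value is what backtracking shows.
    """

    entity_id: int
    db_id: int
    entity_type: str
    attributes: dict[str, dict[str, str]] = field(default_factory=dict)

    def attribute_names(self) -> tuple[str, ...]:
        return tuple(sorted(self.attributes))

    def values(self, name: str) -> tuple[str, ...]:
        """Raw values stored under ``name`` (sorted, possibly empty)."""
        return tuple(sorted(self.attributes.get(name, {}).values()))

    def norm_values(self, name: str) -> frozenset[str]:
        return frozenset(self.attributes.get(name, ()))


@dataclass
class ExternalEntityRelation(ExternalEntity):
    relation_type: str = "interaction"
    #: ordered (entity_id, per-participant attribute multimap) pairs
    participants: list[tuple[int, dict[str, dict[str, str]]]] = field(
        default_factory=list
    )

    def participant_ids(self) -> tuple[int, ...]:
        return tuple(pid for pid, _ in self.participants)


class Registry:
    """Databases + entities + relations + inverted attribute index."""

    SCHEMA_VERSION = 1

    def __init__(self, catalog: AttributeCatalog | None = None) -> None:
        self.catalog = catalog or AttributeCatalog()
        self.databases: dict[int, ExternalDatabase] = {}
        self.entities: dict[int, ExternalEntity] = {}
        self._db_keys: set[tuple[str, str]] = set()
        self._index: dict[str, dict[str, set[int]]] = {}
        self._adjacency: dict[int, set[int]] = {}
        self._next_db_id = 0
        self._next_entity_id = 0

    # -- databases ---------------------------------------------------------

    def register_database(
        self, name: str, version: str = "", promiscuous: bool = False
    ) -> int:
        if not name:
            raise RegistryError("database name must be non-empty")
        key = (name, version)
        if key in self._db_keys:
            raise RegistryError(
                f"database {name!r} version {version!r} is already registered"
            )
        db_id = self._next_db_id
        self._next_db_id += 1
        self.databases[db_id] = ExternalDatabase(db_id, name, version, promiscuous)
        self._db_keys.add(key)
        return db_id

    def database_by_name(self, name: str, version: str | None = None) -> ExternalDatabase:
        for db in self.databases.values():
            if db.name == name and (version is None or db.version == version):
                return db
        raise RegistryError(f"no database named {name!r}")

    def is_promiscuous(self, entity_id: int) -> bool:
        return self.databases[self.entities[entity_id].db_id].promiscuous

    # -- entities ----------------------------------------------------------

    def _normalize_attributes(self, attributes) -> dict[str, dict[str, str]]:
        out: dict[str, dict[str, str]] = {}
        for name, values in (attributes or {}).items():
            if name not in self.catalog:
                raise RegistryError(
                    f"attribute {name!r} is not in the catalog; register it first"
                )
            if isinstance(values, (str, int)):
                values = [values]
            norm_map: dict[str, str] = {}
            for raw in values:
                norm_map.setdefault(self.catalog.normalize(name, raw), str(raw).strip())
            if norm_map:
                out[name] = norm_map
        return out

    def register_entity(
        self, db_id: int, entity_type: str = "protein", attributes=None
    ) -> int:
        if db_id not in self.databases:
            raise RegistryError(f"unknown database id {db_id}")
        if entity_type not in ENTITY_TYPES:
            raise RegistryError(f"unknown entity type {entity_type!r}")
        entity = ExternalEntity(
            entity_id=self._next_entity_id,
            db_id=db_id,
            entity_type=entity_type,
            attributes=self._normalize_attributes(attributes),
        )
        self._next_entity_id += 1
        self._store(entity)
        return entity.entity_id

    def register_relation(
        self,
        db_id: int,
        relation_type: str,
        participants,
        attributes=None,
    ) -> int:
        if db_id not in self.databases:
            raise RegistryError(f"unknown database id {db_id}")
        if relation_type not in RELATION_TYPES:
            raise RegistryError(f"unknown relation type {relation_type!r}")
        parts: list[tuple[int, dict[str, dict[str, str]]]] = []
        for item in participants:
            if isinstance(item, tuple):
                pid, pattrs = item
            else:
                pid, pattrs = item, None
            if pid not in self.entities:
                raise RegistryError(f"participant entity {pid} does not exist")
            parts.append((int(pid), self._normalize_attributes(pattrs)))
        if len(parts) < 2:
            raise RegistryError("a relation needs at least 2 participants")
        relation = ExternalEntityRelation(
            entity_id=self._next_entity_id,
            db_id=db_id,
            entity_type="relation",
            attributes=self._normalize_attributes(attributes),
            relation_type=relation_type,
            participants=parts,
        )
        self._next_entity_id += 1
        self._store(relation)
        for pid, _ in parts:
            self._adjacency.setdefault(pid, set()).add(relation.entity_id)
        return relation.entity_id

    def add_attribute(self, entity_id: int, name: str, value) -> None:
        """Attach one more (name, value) pair to an existing entity."""
        entity = self.entities[entity_id]
        if name not in self.catalog:
            raise RegistryError(
                f"attribute {name!r} is not in the catalog; register it first"
            )
        norm = self.catalog.normalize(name, value)
        entity.attributes.setdefault(name, {}).setdefault(norm, str(value).strip())
        self._index.setdefault(name, {}).setdefault(norm, set()).add(entity_id)

    def _store(self, entity: ExternalEntity) -> None:
        self.entities[entity.entity_id] = entity
        for name, norm_map in entity.attributes.items():
            bucket = self._index.setdefault(name, {})
            for norm in norm_map:
                bucket.setdefault(norm, set()).add(entity.entity_id)

    # -- queries -----------------------------------------------------------

    def get(self, entity_id: int) -> ExternalEntity:
        return self.entities[entity_id]

    def query_by_attribute(
        self, name: str, value, dbs: set[int] | None = None
    ) -> set[int]:
        """Ids of entities holding (name, value); empty set when absent."""
        if name not in self.catalog:
            logger.warning("query on unregistered attribute %r", name)
            return set()
        try:
            norm = self.catalog.normalize(name, value)
        except ValueError:
            return set()
        hits = self._index.get(name, {}).get(norm, set())
        if dbs is None:
            return set(hits)
        return {e for e in hits if self.entities[e].db_id in dbs}

    def relations_of(self, entity_id: int) -> set[int]:
        if entity_id not in self.entities:
            raise RegistryError(f"unknown entity id {entity_id}")
        return set(self._adjacency.get(entity_id, set()))

    def iter_entities(self, include_relations: bool = False):
        for e in self.entities.values():
            if include_relations or e.entity_type != "relation":
                yield e

    def iter_relations(self):
        for e in self.entities.values():
            if isinstance(e, ExternalEntityRelation):
                yield e

    def entity_ids(self, db_id: int | None = None) -> list[int]:
        return sorted(
            e.entity_id
            for e in self.iter_entities()
            if db_id is None or e.db_id == db_id
        )

    # -- persistence -------------------------------------------------------

    def to_dict(self) -> dict:
        def attrs(a: dict[str, dict[str, str]]):
            return {n: [m[k] for k in sorted(m)] for n, m in sorted(a.items())}

        entities = []
        for e in sorted(self.entities.values(), key=lambda e: e.entity_id):
            rec = {
                "entity_id": e.entity_id,
                "db_id": e.db_id,
                "entity_type": e.entity_type,
                "attributes": attrs(e.attributes),
            }
            if isinstance(e, ExternalEntityRelation):
                rec["relation_type"] = e.relation_type
                rec["participants"] = [
                    {"entity_id": pid, "attributes": attrs(pattrs)}
                    for pid, pattrs in e.participants
                ]
            entities.append(rec)
        return {
            "schema_version": self.SCHEMA_VERSION,
            "catalog": self.catalog.to_dict(),
            "databases": [
                {
                    "db_id": d.db_id,
                    "name": d.name,
                    "version": d.version,
                    "promiscuous": d.promiscuous,
                }
                for d in sorted(self.databases.values(), key=lambda d: d.db_id)
            ],
            "entities": entities,
        }

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_dict(cls, data: dict) -> "Registry":
        if data.get("schema_version") != cls.SCHEMA_VERSION:
            raise RegistryError(
                f"unsupported registry schema {data.get('schema_version')!r}"
            )
        reg = cls(AttributeCatalog(data["catalog"]))
        for d in data["databases"]:
            db_id = reg.register_database(d["name"], d["version"], d["promiscuous"])
            if db_id != d["db_id"]:
                raise RegistryError("non-contiguous database ids in saved registry")
        for rec in data["entities"]:
            if "participants" in rec:
                eid = reg.register_relation(
                    rec["db_id"],
                    rec["relation_type"],
                    [
                        (p["entity_id"], p["attributes"])
                        for p in rec["participants"]
                    ],
                    rec["attributes"],
                )
            else:
                eid = reg.register_entity(
                    rec["db_id"], rec["entity_type"], rec["attributes"]
                )
            if eid != rec["entity_id"]:
                raise RegistryError("non-contiguous entity ids in saved registry")
        return reg

    @classmethod
    def load(cls, path) -> "Registry":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))
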
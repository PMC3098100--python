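"""Readers and writers for the supported plain-text formats.

Covered: a generic tabular external-database format (entity and relation
tables), PSI-MI TAB 2.5 interaction files, FASTA sequence attachment, and
network export as SIF or an edge TSV that keeps provenance and (in
comment lines) node levels, tags and seeds so a session can be resumed
from files.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field

import pandas as pd
from Bio import SeqIO

from .network import UnifiedNetwork
from .registry import Registry, RegistryError

logger = logging.getLogger(__name__)


@dataclass
class EntityTableDialect:
    """Column conventions of the generic entity table.

    The header names every column; ``id_column`` holds the source record
    id (stored under ``id_attribute``), ``type_column`` the entity type
    (optional — ``default_type`` applies when absent).  Every other column
    is an attribute column; cells may hold several values joined by
    ``separator``.
    """

    id_column: str = "external_id"
    type_column: str = "type"
    id_attribute: str = "SourceID"
    default_type: str = "protein"
    separator: str = "|"
    comment: str = "#"


@dataclass
class RelationTableDialect:
    id_column: str = "relation_id"
    type_column: str = "relation_type"
    participants_column: str = "participants"
    id_attribute: str = "SourceID"
    separator: str = "|"
    comment: str = "#"


def _read_table(path, comment: str) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", comment=comment, dtype=str, keep_default_na=False
    )


def _register_unknown_columns(registry: Registry, columns) -> None:
    for name in columns:
        if name not in registry.catalog:
            logger.info("registering attribute %r from table header", name)
            registry.catalog.register(name, "identifier")


def read_entity_table(
    path, registry: Registry, db_id: int, dialect: EntityTableDialect | None = None
) -> int:
    """Register one entity per data row; returns the number registered.

    Rows whose integer-kind attributes fail to parse are skipped and
    logged, never half-registered.
    """
    dialect = dialect or EntityTableDialect()
    df = _read_table(path, dialect.comment)
    if dialect.id_column not in df.columns:
        raise RegistryError(
            f"entity table {path} lacks required column {dialect.id_column!r}"
        )
    attr_cols = [
        c for c in df.columns if c not in (dialect.id_column, dialect.type_column)
    ]
    _register_unknown_columns(registry, [dialect.id_attribute, *attr_cols])
    count = 0
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        rec = dict(zip(df.columns, row))
        attributes = {dialect.id_attribute: [rec[dialect.id_column]]}
        for col in attr_cols:
            values = [v for v in rec[col].split(dialect.separator) if v.strip()]
            if values:
                attributes.setdefault(col, []).extend(values)
        etype = rec.get(dialect.type_column, "") or dialect.default_type
        try:
            registry.register_entity(db_id, etype, attributes)
        except ValueError as exc:
            logger.warning("skipping row %d of %s: %s", row_no, path, exc)
            continue
        count += 1
    return count


def read_relation_table(
    path, registry: Registry, db_id: int, dialect: RelationTableDialect | None = None
) -> int:
    """Register relations whose participant ids resolve (via the id
    attribute) against entities already in the registry."""
    dialect = dialect or RelationTableDialect()
    df = _read_table(path, dialect.comment)
    for col in (dialect.id_column, dialect.type_column, dialect.participants_column):
        if col not in df.columns:
            raise RegistryError(f"relation table {path} lacks column {col!r}")
    attr_cols = [
        c
        for c in df.columns
        if c
        not in (dialect.id_column, dialect.type_column, dialect.participants_column)
    ]
    _register_unknown_columns(registry, [dialect.id_attribute, *attr_cols])
    count = 0
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        rec = dict(zip(df.columns, row))
        participant_ids = []
        ok = True
        for token in rec[dialect.participants_column].split(","):
            token = token.strip()
            hits = sorted(registry.query_by_attribute(dialect.id_attribute, token))
            if not hits:
                logger.warning(
                    "skipping row %d of %s: participant %r not found", row_no, path, token
                )
                ok = False
                break
            participant_ids.append(hits[0])
        if not ok:
            continue
        attributes = {dialect.id_attribute: [rec[dialect.id_column]]}
        for col in attr_cols:
            values = [v for v in rec[col].split(dialect.separator) if v.strip()]
            if values:
                attributes[col] = values
        try:
            registry.register_relation(
                db_id, rec[dialect.type_column], participant_ids, attributes
            )
        except ValueError as exc:
            logger.warning("skipping row %d of %s: %s", row_no, path, exc)
            continue
        count += 1
    return count


# -- PSI-MI TAB 2.5 --------------------------------------------------------

#: namespace -> catalog attribute; config-extensible via read_mitab(...)
MITAB_NAMESPACES: dict[str, str] = {
    "uniprotkb": "UniprotAccession",
    "entrez gene/locuslink": "GeneID",
    "entrezgene/locuslink": "GeneID",
}

_MITAB_MIN_COLUMNS = 15


def _parse_mitab_field(field_text: str):
    """Split a MITAB multi-value field into (namespace, value) pairs."""
    out = []
    if field_text.strip() in ("", "-"):
        return out
    for item in field_text.split("|"):
        item = item.strip()
        if not item or item == "-":
            continue
        if ":" in item:
            ns, value = item.split(":", 1)
        else:
            ns, value = "", item
        # drop a trailing "(description)" qualifier
        if value.endswith(")") and "(" in value:
            value = value[: value.rindex("(")]
        value = value.strip().strip('"')
        if value:
            out.append((ns.strip().casefold(), value))
    return out


def read_mitab(
    path, registry: Registry, db_id: int, namespaces: dict[str, str] | None = None
) -> tuple[int, int]:
    """Import a PSI-MI TAB 2.5 file as binary interaction relations.

    Interactor ids (columns 1-2) and alt-ids (3-4) become attributes per
    the namespace map; unknown namespaces are kept as raw attributes named
    after the namespace.  Columns 10-11 give taxID, 7 the detection
    method, 12 the interaction type and 15 the confidence.  Interactors
    repeated across rows are merged by primary id.  Returns
    (entities registered, relations registered); short rows are skipped.
    """
    ns_map = dict(MITAB_NAMESPACES)
    if namespaces:
        ns_map.update(namespaces)
    interactors: dict[str, int] = {}
    n_entities = n_relations = 0

    def attribute_for(ns: str) -> str:
        name = ns_map.get(ns)
        if name is None:
            name = ns if ns else "RawID"
            if name not in registry.catalog:
                registry.catalog.register(name, "identifier")
        return name

    def interactor(primary_field: str, alt_field: str, taxid_field: str) -> int | None:
        nonlocal n_entities
        primary = _parse_mitab_field(primary_field)
        if not primary:
            return None
        key = f"{primary[0][0]}:{primary[0][1]}".casefold()
        attributes: dict[str, list] = {}
        for ns, value in primary + _parse_mitab_field(alt_field):
            attributes.setdefault(attribute_for(ns), []).append(value)
        for ns, value in _parse_mitab_field(taxid_field):
            if ns == "taxid":
                try:
                    attributes.setdefault("taxID", []).append(int(value))
                except ValueError:
                    logger.warning("unparseable taxid %r", value)
        if key in interactors:
            eid = interactors[key]
            for name, values in attributes.items():
                for v in values:
                    registry.add_attribute(eid, name, v)
            return eid
        eid = registry.register_entity(db_id, "protein", attributes)
        interactors[key] = eid
        n_entities += 1
        return eid

    with open(path, encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < _MITAB_MIN_COLUMNS:
                logger.warning(
                    "skipping line %d of %s: %d columns < %d",
                    line_no, path, len(cols), _MITAB_MIN_COLUMNS,
                )
                continue
            a = interactor(cols[0], cols[2], cols[9])
            b = interactor(cols[1], cols[3], cols[10])
            if a is None or b is None:
                logger.warning("skipping line %d of %s: missing interactor", line_no, path)
                continue
            rel_attrs: dict[str, list] = {}
            for field_text, name in (
                (cols[6], "DetectionMethod"),
                (cols[11], "InteractionType"),
                (cols[14], "Confidence"),
            ):
                values = [v for _, v in _parse_mitab_field(field_text)]
                if field_text.strip() not in ("", "-") and not values:
                    values = [field_text.strip()]
                if values:
                    rel_attrs[name] = values
            registry.register_relation(db_id, "interaction", [a, b], rel_attrs)
            n_relations += 1
    return n_entities, n_relations


# -- FASTA -----------------------------------------------------------------


def read_fasta_attributes(
    path, registry: Registry, db_id: int, id_attribute_name: str = "UniprotAccession"
) -> int:
    """Attach ProteinSequence attributes from a FASTA file.

    The header token up to the first whitespace is matched against
    existing entities' ``id_attribute_name`` values; on a hit the sequence
    is attached, otherwise a new protein entity is created.  Returns the
    number of records applied; empty sequences are skipped."""
    count = 0
    for record in SeqIO.parse(str(path), "fasta"):
        seq = str(record.seq).strip()
        if not seq:
            logger.warning("skipping FASTA record %r: empty sequence", record.id)
            continue
        hits = sorted(registry.query_by_attribute(id_attribute_name, record.id))
        if hits:
            for eid in hits:
                registry.add_attribute(eid, "ProteinSequence", seq)
        else:
            registry.register_entity(
                db_id,
                "protein",
                {id_attribute_name: [record.id], "ProteinSequence": [seq]},
            )
        count += 1
    return count


# -- network export / import ----------------------------------------------

NETWORK_FORMATS = ("sif", "tsv")
_EDGE_COLUMNS = [
    "source",
    "target",
    "relation_type",
    "source_databases",
    "source_relations",
    "inferred",
    "evidence",
    "tags",
]


def write_network(
    network: UnifiedNetwork, path, fmt: str = "tsv", registry: Registry | None = None
) -> None:
    """Write a network as SIF or provenance-keeping edge TSV.

    The TSV keeps node levels/tags and the seed set in ``#!`` comment
    lines so ``read_network_tsv`` restores the full session object; SIF is
    a lossy one-line-per-edge export for downstream viewers."""
    if fmt not in NETWORK_FORMATS:
        raise ValueError(f"unknown network format {fmt!r}")
    edges = sorted(network.edges.items())
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if fmt == "sif":
            for (u, v, rtype), _ in edges:
                fh.write(f"{u}\t{rtype}\t{v}\n")
            return
        fh.write(f"#!partition_id\t{network.partition_id}\n")
        fh.write("#!seeds\t" + ",".join(str(s) for s in sorted(network.seeds)) + "\n")
        for n in sorted(network.nodes):
            nd = network.nodes[n]
            level = "" if nd.level is None else str(nd.level)
            fh.write(f"#!node\t{n}\t{level}\t{','.join(sorted(nd.tags))}\n")
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_EDGE_COLUMNS)
        for (u, v, rtype), ed in edges:
            dbs = ""
            if registry is not None:
                names = {
                    registry.databases[registry.get(r).db_id].name
                    for r in ed.provenance
                    if r in registry.entities
                }
                dbs = ",".join(sorted(names))
            writer.writerow(
                [
                    u,
                    v,
                    rtype,
                    dbs,
                    ",".join(str(r) for r in sorted(ed.provenance)),
                    "1" if ed.inferred else "0",
                    "|".join(sorted(ed.evidence)),
                    ",".join(sorted(ed.tags)),
                ]
            )


def read_network_tsv(path) -> UnifiedNetwork:
    """Rebuild a UnifiedNetwork from the edge-TSV written above."""
    net = UnifiedNetwork()
    header: list[str] | None = None
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#!"):
                parts = line[2:].split("\t")
                if parts[0] == "partition_id":
                    net.partition_id = parts[1] if len(parts) > 1 else ""
                elif parts[0] == "seeds" and len(parts) > 1 and parts[1]:
                    net.seeds = {int(s) for s in parts[1].split(",")}
                elif parts[0] == "node":
                    node = int(parts[1])
                    level = int(parts[2]) if len(parts) > 2 and parts[2] else None
                    net.add_node(node, level=level)
                    if len(parts) > 3 and parts[3]:
                        net.nodes[node].tags.update(parts[3].split(","))
                continue
            if line.startswith("#"):
                continue
            cols = line.split("\t")
            if header is None:
                header = cols
                continue
            rec = dict(zip(header, cols))
            key = net.add_edge(
                int(rec["source"]),
                int(rec["target"]),
                rec["relation_type"],
                provenance={int(r) for r in rec["source_relations"].split(",") if r},
                inferred=rec["inferred"] == "1",
                evidence={e for e in rec["evidence"].split("|") if e},
            )
            if rec.get("tags"):
                net.edges[key].tags.update(rec["tags"].split(","))
    return net


# -- partition TSV ---------------------------------------------------------


def write_partition(partition, path) -> None:
    """ue_id / entity_id / database / version / membership rows."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["ue_id", "entity_id", "database", "version", "membership"])
        for row in partition.as_rows():
            writer.writerow(row)


def write_entity_table(
    registry: Registry, db_id: int, path, dialect: EntityTableDialect | None = None
) -> int:
    """Inverse of read_entity_table for one database (round-trip export)."""
    dialect = dialect or EntityTableDialect()
    entities = [registry.get(e) for e in registry.entity_ids(db_id)]
    attr_names = sorted(
        {n for e in entities for n in e.attribute_names() if n != dialect.id_attribute}
    )
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow([dialect.id_column, dialect.type_column, *attr_names])
        for e in entities:
            ids = e.values(dialect.id_attribute)
            ext_id = ids[0] if ids else str(e.entity_id)
            row = [ext_id, e.entity_type]
            for name in attr_names:
                row.append(dialect.separator.join(e.values(name)))
            writer.writerow(row)
    return len(entities)
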
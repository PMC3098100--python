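"""Networks of user entities: seed-based expansion, tagging, linker
degree, degree-preserving randomization and set-algebra combination.

Nodes are user-entity ids; each node carries the breadth-first level from
the seed set (seeds are level 0) and a tag set.  Edges are undirected,
keyed by (u, v, relation_type), and carry provenance (the source relation
record ids), an inferred flag, evidence strings and tags.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass, field

import networkx as nx

from .registry import Registry
from .unification import Partition

logger = logging.getLogger(__name__)


@dataclass
class NodeData:
    level: int | None = None
    tags: set[str] = field(default_factory=set)


@dataclass
class EdgeData:
    provenance: set[int] = field(default_factory=set)
    inferred: bool = False
    tags: set[str] = field(default_factory=set)
    evidence: set[str] = field(default_factory=set)


@dataclass
class EdgeRestriction:
    """Filter on relations during network expansion.

    ``allowed_types`` limits relation types (None = all).  ``require``
    maps attribute name -> allowed value set: the relation must hold at
    least one of the values for every named attribute.  ``forbid`` maps
    attribute name -> banned value set.  Values are compared after the
    catalog's normalization.
    """

    allowed_types: frozenset[str] | None = None
    require: dict[str, frozenset[str]] = field(default_factory=dict)
    forbid: dict[str, frozenset[str]] = field(default_factory=dict)

    def passes(self, relation, registry: Registry) -> bool:
        if self.allowed_types is not None and relation.relation_type not in self.allowed_types:
            return False
        for name, allowed in self.require.items():
            norm_allowed = {registry.catalog.normalize(name, v) for v in allowed}
            if not relation.norm_values(name) & norm_allowed:
                return False
        for name, banned in self.forbid.items():
            norm_banned = {registry.catalog.normalize(name, v) for v in banned}
            if relation.norm_values(name) & norm_banned:
                return False
        return True

    @classmethod
    def from_dict(cls, data: dict) -> "EdgeRestriction":
        return cls(
            allowed_types=(
                frozenset(data["relation_types"]) if data.get("relation_types") else None
            ),
            require={k: frozenset(v) for k, v in data.get("require", {}).items()},
            forbid={k: frozenset(v) for k, v in data.get("forbid", {}).items()},
        )


def edge_key(u: int, v: int, relation_type: str) -> tuple[int, int, str]:
    a, b = (u, v) if u <= v else (v, u)
    return (a, b, relation_type)


class UnifiedNetwork:
    """Undirected network over user entities with levels and provenance."""

    def __init__(self, partition_id: str = "") -> None:
        self.partition_id = partition_id
        self.seeds: set[int] = set()
        self.nodes: dict[int, NodeData] = {}
        self.edges: dict[tuple[int, int, str], EdgeData] = {}

    # -- construction ------------------------------------------------------

    def add_node(self, ue_id: int, level: int | None = None) -> None:
        self.nodes.setdefault(ue_id, NodeData(level=level))

    def add_edge(
        self,
        u: int,
        v: int,
        relation_type: str,
        provenance=(),
        inferred: bool = False,
        evidence=(),
    ) -> tuple[int, int, str]:
        self.add_node(u)
        self.add_node(v)
        key = edge_key(u, v, relation_type)
        data = self.edges.setdefault(key, EdgeData(inferred=inferred))
        data.provenance.update(provenance)
        data.evidence.update(evidence)
        if not inferred:
            data.inferred = False
        return key

    def copy(self) -> "UnifiedNetwork":
        out = UnifiedNetwork(self.partition_id)
        out.seeds = set(self.seeds)
        for n, nd in self.nodes.items():
            out.nodes[n] = NodeData(level=nd.level, tags=set(nd.tags))
        for k, ed in self.edges.items():
            out.edges[k] = EdgeData(
                provenance=set(ed.provenance),
                inferred=ed.inferred,
                tags=set(ed.tags),
                evidence=set(ed.evidence),
            )
        return out

    # -- queries -----------------------------------------------------------

    def neighbors(self, ue_id: int) -> set[int]:
        if ue_id not in self.nodes:
            raise KeyError(f"unknown node {ue_id}")
        out: set[int] = set()
        for u, v, _ in self.edges:
            if u == ue_id:
                out.add(v)
            elif v == ue_id:
                out.add(u)
        out.discard(ue_id)
        return out

    def degree(self, ue_id: int) -> int:
        return len(self.neighbors(ue_id))

    def edge_set(self) -> set[tuple[int, int, str]]:
        return set(self.edges)

    def simple_edges(self) -> set[tuple[int, int]]:
        """Undirected simple view: relation types collapsed, self-loops kept
        out."""
        return {(u, v) for u, v, _ in self.edges if u != v}

    def to_networkx(self) -> nx.Graph:
        """Export hook: shortest paths, components, centralities etc. are
        delegated to networkx on this view."""
        g = nx.Graph()
        for n, nd in self.nodes.items():
            g.add_node(n, level=nd.level, tags=frozenset(nd.tags))
        for (u, v, rtype), ed in self.edges.items():
            if g.has_edge(u, v):
                g[u][v]["relation_types"] = g[u][v]["relation_types"] | {rtype}
            else:
                g.add_edge(u, v, relation_types={rtype}, inferred=ed.inferred)
        return g

    def recompute_levels(self) -> None:
        """BFS levels from the seed set; unreachable nodes get level None."""
        for nd in self.nodes.values():
            nd.level = None
        adj: dict[int, set[int]] = {n: set() for n in self.nodes}
        for u, v, _ in self.edges:
            if u != v:
                adj[u].add(v)
                adj[v].add(u)
        queue = deque()
        for s in sorted(self.seeds & set(self.nodes)):
            self.nodes[s].level = 0
            queue.append(s)
        while queue:
            u = queue.popleft()
            for w in sorted(adj[u]):
                if self.nodes[w].level is None:
                    self.nodes[w].level = self.nodes[u].level + 1
                    queue.append(w)


# -- session operations ----------------------------------------------------


def select_seeds(partition: Partition, queries) -> set[int]:
    """User entities owning at least one member matching at least one
    (attribute, value) query."""
    out: set[int] = set()
    for name, value in queries:
        for eid in partition.registry.query_by_attribute(name, value):
            out |= partition.ues_of(eid)
    return out


def _lifted_relation_edges(partition: Partition, registry: Registry, restriction):
    """Yield (u, v, relation_type, relation_id) for every surviving
    relation, lifted to user entities as the clique of its participants."""
    for rel in registry.iter_relations():
        if restriction is not None and not restriction.passes(rel, registry):
            continue
        pids = rel.participant_ids()
        # participant slots map to ue sets; promiscuous members may carry
        # relation participation into several user entities
        slot_ues = [partition.ues_of(pid) for pid in pids]
        seen: set[tuple[int, int]] = set()
        for i in range(len(pids)):
            for j in range(i + 1, len(pids)):
                for u in slot_ues[i]:
                    for v in slot_ues[j]:
                        a, b = (u, v) if u <= v else (v, u)
                        if (a, b) in seen:
                            continue
                        seen.add((a, b))
                        yield a, b, rel.relation_type, rel.entity_id


def expand_network(
    partition: Partition,
    registry: Registry,
    seeds,
    depth: int,
    restriction: EdgeRestriction | None = None,
) -> UnifiedNetwork:
    """Breadth-first expansion from seed user entities.

    Nodes up to level ``depth`` are included; edges whose both endpoints
    are included are retained (so edges among final-level nodes survive,
    edges reaching into level depth+1 do not).
    """
    if depth < 0:
        raise ValueError("depth must be >= 0")
    seeds = set(seeds)
    lifted = list(_lifted_relation_edges(partition, registry, restriction))
    adj: dict[int, set[int]] = {}
    for u, v, _, _ in lifted:
        adj.setdefault(u, set()).add(v)
        adj.setdefault(v, set()).add(u)

    level = {s: 0 for s in seeds}
    frontier = sorted(seeds)
    d = 0
    while frontier and d < depth:
        nxt = []
        for u in frontier:
            for w in sorted(adj.get(u, ())):
                if w not in level:
                    level[w] = d + 1
                    nxt.append(w)
        frontier = sorted(nxt)
        d += 1

    net = UnifiedNetwork(partition_id=partition.protocol.id)
    net.seeds = set(seeds)
    for n, lv in level.items():
        net.add_node(n, level=lv)
    for u, v, rtype, rel_id in lifted:
        if u in level and v in level:
            net.add_edge(u, v, rtype, provenance={rel_id})
    return net


def tag(network: UnifiedNetwork, selector, tag_name: str) -> UnifiedNetwork:
    """Tag a node (int selector) or edge ((u, v, relation_type) selector);
    retagging is idempotent."""
    if isinstance(selector, tuple):
        key = edge_key(*selector)
        if key not in network.edges:
            raise KeyError(f"unknown edge {selector}")
        network.edges[key].tags.add(tag_name)
    else:
        if selector not in network.nodes:
            raise KeyError(f"unknown node {selector}")
        network.nodes[selector].tags.add(tag_name)
    return network


def linker_degree(network: UnifiedNetwork, ue_id: int, tag_name: str) -> int:
    """Number of distinct neighbors of ``ue_id`` carrying ``tag_name``."""
    return sum(
        1 for n in network.neighbors(ue_id) if tag_name in network.nodes[n].tags
    )


def randomize_network(
    network: UnifiedNetwork, rng_seed: int, n_swaps: int | None = None
) -> UnifiedNetwork:
    """Degree-preserving double-edge-swap randomization of the simple
    undirected view.  Provenance is dropped; same seed, same result."""
    g = nx.Graph()
    g.add_nodes_from(network.nodes)
    g.add_edges_from(network.simple_edges())
    n_edges = g.number_of_edges()
    if n_edges >= 2 and g.number_of_nodes() >= 4:
        if n_swaps is None:
            n_swaps = 10 * n_edges
        try:
            nx.double_edge_swap(
                g, nswap=n_swaps, max_tries=max(100, 100 * n_swaps), seed=rng_seed
            )
        except nx.NetworkXAlgorithmError:
            logger.debug("randomization hit max_tries; degrees still preserved")
    out = UnifiedNetwork(network.partition_id)
    out.seeds = set(network.seeds)
    for n, nd in network.nodes.items():
        out.nodes[n] = NodeData(level=nd.level, tags=set(nd.tags))
    for u, v in g.edges():
        out.add_edge(u, v, "randomized")
    return out


def combine(networks, mode: str) -> UnifiedNetwork:
    """Set-algebra combination of networks built over the same partition.

    ``union`` merges nodes and edges (provenance unioned on shared edges);
    ``intersection`` keeps shared ones only.  Levels are recomputed from
    the combined seed sets.
    """
    networks = list(networks)
    if mode not in {"union", "intersection"}:
        raise ValueError(f"unknown combine mode {mode!r}")
    if not networks:
        raise ValueError("need at least one network")
    pid = networks[0].partition_id
    if any(n.partition_id != pid for n in networks):
        raise ValueError("networks were built over different partitions")

    out = UnifiedNetwork(pid)
    if mode == "union":
        out.seeds = set().union(*(n.seeds for n in networks))
        node_ids = set().union(*(set(n.nodes) for n in networks))
        edge_keys = set().union(*(set(n.edges) for n in networks))
    else:
        out.seeds = set.intersection(*(set(n.seeds) for n in networks))
        node_ids = set.intersection(*(set(n.nodes) for n in networks))
        edge_keys = set.intersection(*(set(n.edges) for n in networks))

    for n in sorted(node_ids):
        out.add_node(n)
        for net in networks:
            if n in net.nodes:
                out.nodes[n].tags |= net.nodes[n].tags
    for key in sorted(edge_keys, key=lambda k: (k[0], k[1], k[2])):
        data = EdgeData(inferred=True)
        for net in networks:
            if key in net.edges:
                ed = net.edges[key]
                data.provenance |= ed.provenance
                data.tags |= ed.tags
                data.evidence |= ed.evidence
                if not ed.inferred:
                    data.inferred = False
        out.edges[key] = data
    out.recompute_levels()
    return out
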
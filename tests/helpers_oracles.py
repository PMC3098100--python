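"""Independent brute-force oracles used by the test suite.

Everything here recomputes expected answers from first principles
(linear scans, O(n^2) pair checks, transitive closure by DFS, exhaustive
alignment enumeration) without touching the package's own index or
partitioning code paths.
"""

from __future__ import annotations

import itertools


# -- registry oracles ------------------------------------------------------


def scan_query(registry, name, value, dbs=None):
    """Linear-scan equivalent of Registry.query_by_attribute."""
    if name not in registry.catalog:
        return set()
    try:
        norm = registry.catalog.normalize(name, value)
    except ValueError:
        return set()
    out = set()
    for e in registry.entities.values():
        if norm in e.attributes.get(name, {}):
            if dbs is None or e.db_id in dbs:
                out.add(e.entity_id)
    return out


def scan_relations_of(registry, entity_id):
    out = set()
    for e in registry.entities.values():
        if getattr(e, "participants", None) is not None:
            if entity_id in e.participant_ids():
                out.add(e.entity_id)
    return out


# -- unification oracles ---------------------------------------------------


def brute_force_pairs(registry, protocol):
    """O(n^2) re-derivation of the equivalence pairs."""
    entities = [e for e in registry.entities.values() if e.entity_type != "relation"]
    pairs = set()
    for e, f in itertools.combinations(entities, 2):
        for atom in protocol.atoms:
            if not atom.covers(e.db_id, f.db_id):
                continue
            if all(
                e.norm_values(name) & f.norm_values(name)
                for name in atom.attribute_names
            ):
                pairs.add(frozenset({e.entity_id, f.entity_id}))
                break
    return pairs


def closure_partition(registry, pairs):
    """Transitive closure over non-promiscuous entities (DFS), then
    promiscuous attachment — the reference semantics for user entities.

    Returns a set of (frozenset members, frozenset promiscuous_members).
    """
    non_prom = {
        e.entity_id
        for e in registry.entities.values()
        if e.entity_type != "relation"
        and not registry.databases[e.db_id].promiscuous
    }
    adj = {e: set() for e in non_prom}
    prom_links = {}
    for pair in pairs:
        e, f = sorted(pair)
        pe, pf = e in non_prom, f in non_prom
        if pe and pf:
            adj[e].add(f)
            adj[f].add(e)
        elif pe and not pf:
            prom_links.setdefault(f, set()).add(e)
        elif pf and not pe:
            prom_links.setdefault(e, set()).add(f)
    seen = set()
    components = []
    for start in sorted(non_prom):
        if start in seen:
            continue
        stack, comp = [start], set()
        while stack:
            u = stack.pop()
            if u in comp:
                continue
            comp.add(u)
            stack.extend(adj[u] - comp)
        seen |= comp
        components.append(frozenset(comp))
    out = set()
    for comp in components:
        proms = {p for p, anchors in prom_links.items() if anchors & comp}
        out.add((comp, frozenset(proms)))
    return out


def partition_as_sets(partition):
    return {(ue.members, ue.promiscuous_members) for ue in partition}


# -- network oracles -------------------------------------------------------


def bfs_levels(nodes, simple_edges, seeds):
    """Plain BFS distances from a seed set."""
    adj = {n: set() for n in nodes}
    for u, v in simple_edges:
        if u != v:
            adj[u].add(v)
            adj[v].add(u)
    level = {s: 0 for s in seeds if s in adj}
    frontier = sorted(level)
    d = 0
    while frontier:
        nxt = []
        for u in frontier:
            for w in adj[u]:
                if w not in level:
                    level[w] = d + 1
                    nxt.append(w)
        frontier = sorted(nxt)
        d += 1
    return level


# -- alignment oracles -----------------------------------------------------


def enumerate_local_alignments(a, b, sub, gap_open=11.0, gap_extend=1.0):
    """All local alignments of a vs b as (score, columns) tuples.

    Exhaustive: for every substring pair, every global alignment of the
    two substrings (no terminal gap columns).  Only usable for very short
    sequences.
    """
    results = []

    def extend(i, i1, j, j1, columns, score, prev_gap):
        if i == i1 and j == j1:
            if columns and columns[0][0] is not None and columns[0][1] is not None \
               and columns[-1][0] is not None and columns[-1][1] is not None:
                results.append((score, tuple(columns)))
            return
        if i < i1 and j < j1:
            extend(i + 1, i1, j + 1, j1, columns + [(i, j)],
                   score + sub(a[i], b[j]), None)
        if i < i1:
            pen = gap_extend if prev_gap == "b" else gap_open
            extend(i + 1, i1, j, j1, columns + [(i, None)], score - pen, "b")
        if j < j1:
            pen = gap_extend if prev_gap == "a" else gap_open
            extend(i, i1, j + 1, j1, columns + [(None, j)], score - pen, "a")

    for i0 in range(len(a)):
        for i1 in range(i0 + 1, len(a) + 1):
            for j0 in range(len(b)):
                for j1 in range(j0 + 1, len(b) + 1):
                    extend(i0, i1, j0, j1, [], 0.0, None)
    return results


def best_local_score(a, b, sub, gap_open=11.0, gap_extend=1.0):
    """Score-only affine Smith-Waterman, written independently (dict-based)."""
    neg = float("-inf")
    prev_m = [0.0] * (len(b) + 1)
    prev_x = [neg] * (len(b) + 1)
    prev_y = [neg] * (len(b) + 1)
    best = 0.0
    for i in range(1, len(a) + 1):
        cur_m = [0.0] * (len(b) + 1)
        cur_x = [neg] * (len(b) + 1)
        cur_y = [neg] * (len(b) + 1)
        for j in range(1, len(b) + 1):
            cur_x[j] = max(prev_m[j] - gap_open, prev_x[j] - gap_extend)
            cur_y[j] = max(cur_m[j - 1] - gap_open, cur_y[j - 1] - gap_extend)
            diag = max(prev_m[j - 1], prev_x[j - 1], prev_y[j - 1], 0.0)
            cur_m[j] = diag + sub(a[i - 1], b[j - 1])
            best = max(best, cur_m[j])
        prev_m, prev_x, prev_y = cur_m, cur_x, cur_y
    return best


# -- transfer oracle -------------------------------------------------------


def brute_force_transfer(observed_edges, partners_of):
    """Expected inferred simple-edge set from triple enumeration.

    observed_edges: set of (u, v) simple pairs (u <= v).
    partners_of: callable ue -> set of partner ues.
    Returns the set of (a, b) inferred pairs (a <= b) not observed.
    """
    inferred = set()
    for u, v in observed_edges:
        for anchor, template in ((u, v), (v, u)):
            for y in partners_of(template):
                a, b = (anchor, y) if anchor <= y else (y, anchor)
                if (a, b) not in observed_edges:
                    inferred.add((a, b))
    return inferred
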
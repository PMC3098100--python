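"""Edge inference by attribute/similarity transfer (generalized interologs).

An edge x–y is predicted whenever x is observed to interact with z and y
matches z under a transfer criterion: either y shares a value for every
listed attribute with z (e.g. Pfam or SCOP domains), or some member
sequence of y aligns to a member sequence of z above similarity and
coverage cutoffs.  Both endpoints of an observed edge serve as templates;
observed edges are never overwritten.

The aligner is an affine-gap Smith-Waterman (Gotoh) with a deterministic
traceback (diagonal preferred over gaps, earliest maximal cell), scored
with Biopython substitution matrices.  Similarity is the percent of
alignment columns with a positive substitution score; coverage is the
fraction of a sequence's residues inside the local alignment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache

from Bio.Align import substitution_matrices

from .network import UnifiedNetwork
from .unification import Partition

logger = logging.getLogger(__name__)

DEFAULT_GAP_OPEN = 11.0
DEFAULT_GAP_EXTEND = 1.0


@lru_cache(maxsize=None)
def _scheme(name: str):
    """Substitution scoring function for a named scheme."""
    if name == "identity":
        return lambda a, b: 1.0 if a == b else -1.0
    try:
        matrix = substitution_matrices.load(name.upper())
    except FileNotFoundError:
        raise ValueError(f"unknown scoring scheme {name!r}") from None

    def score(a, b, m=matrix):
        try:
            return float(m[a, b])
        except (KeyError, IndexError):
            return float(m["X", "X"]) if ("X", "X") in m else 0.0

    return score


@dataclass(frozen=True)
class AlignmentStats:
    """Summary of one local alignment.

    Percentages use the full alignment length (gap columns included) as
    denominator; coverage_pct_query / coverage_pct_target are the percent
    of each sequence's residues inside the aligned region.
    """

    score: float
    identity_pct: float
    similarity_pct: float
    coverage_pct_query: float
    coverage_pct_target: float
    aligned_length: int

    def __post_init__(self):
        assert 0.0 <= self.identity_pct <= self.similarity_pct <= 100.0
        assert 0.0 <= self.coverage_pct_query <= 100.0
        assert 0.0 <= self.coverage_pct_target <= 100.0


def align_pair(seq_a: str, seq_b: str, scheme: str = "blosum62") -> AlignmentStats:
    """Best local alignment of ``seq_a`` (query) vs ``seq_b`` (target).

    Affine gap penalties (open 11, extend 1).  Deterministic: ties in the
    dynamic program are broken diagonal > gap-in-target > gap-in-query,
    and the traceback starts at the first maximal cell in row-major order.
    """
    a = "".join(seq_a.split()).upper()
    b = "".join(seq_b.split()).upper()
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    sub = _scheme(scheme)
    columns = _gotoh_local(a, b, sub, DEFAULT_GAP_OPEN, DEFAULT_GAP_EXTEND)
    return stats_from_columns(a, b, columns, sub)


def stats_from_columns(a: str, b: str, columns, sub) -> AlignmentStats:
    """AlignmentStats for an explicit list of alignment columns.

    ``columns`` is a list of (i, j) with i/j the 0-based residue index or
    None for a gap in that sequence.
    """
    if not columns:
        return AlignmentStats(0.0, 0.0, 0.0, 0.0, 0.0, 0)
    length = len(columns)
    ident = simil = a_cols = b_cols = 0
    score = 0.0
    gap_open, gap_extend = DEFAULT_GAP_OPEN, DEFAULT_GAP_EXTEND
    prev_gap = None
    for i, j in columns:
        if i is not None:
            a_cols += 1
        if j is not None:
            b_cols += 1
        if i is not None and j is not None:
            s = sub(a[i], b[j])
            score += s
            if a[i] == b[j]:
                ident += 1
            if s > 0:
                simil += 1
            prev_gap = None
        else:
            which = "a" if i is None else "b"
            score -= gap_extend if prev_gap == which else gap_open
            prev_gap = which
    return AlignmentStats(
        score=score,
        identity_pct=100.0 * ident / length,
        similarity_pct=100.0 * simil / length,
        coverage_pct_query=100.0 * a_cols / len(a),
        coverage_pct_target=100.0 * b_cols / len(b),
        aligned_length=length,
    )


def _gotoh_local(a: str, b: str, sub, gap_open: float, gap_extend: float):
    """Smith-Waterman with affine gaps; returns alignment columns.

    State M aligns a[i-1] with b[j-1]; Ix has a gap in b (consumes a);
    Iy has a gap in a (consumes b).  Local: M floors at 0.
    """
    n, m = len(a), len(b)
    neg = float("-inf")
    M = [[0.0] * (m + 1) for _ in range(n + 1)]
    Ix = [[neg] * (m + 1) for _ in range(n + 1)]
    Iy = [[neg] * (m + 1) for _ in range(n + 1)]
    # pointers: 0 start-fresh, 1 from M, 2 from Ix, 3 from Iy
    ptr_m = [[0] * (m + 1) for _ in range(n + 1)]
    ptr_x = [[0] * (m + 1) for _ in range(n + 1)]
    ptr_y = [[0] * (m + 1) for _ in range(n + 1)]

    best, bi, bj = 0.0, 0, 0
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            # gap states first (they read row i-1 / column j-1 of M)
            open_x = M[i - 1][j] - gap_open
            ext_x = Ix[i - 1][j] - gap_extend
            if open_x >= ext_x:
                Ix[i][j], ptr_x[i][j] = open_x, 1
            else:
                Ix[i][j], ptr_x[i][j] = ext_x, 2
            open_y = M[i][j - 1] - gap_open
            ext_y = Iy[i][j - 1] - gap_extend
            if open_y >= ext_y:
                Iy[i][j], ptr_y[i][j] = open_y, 1
            else:
                Iy[i][j], ptr_y[i][j] = ext_y, 3

            s = sub(ai, b[j - 1])
            diag_m = M[i - 1][j - 1]
            diag_x = Ix[i - 1][j - 1]
            diag_y = Iy[i - 1][j - 1]
            # tie-break: continue from M, then Ix, then Iy; restart at <= 0
            # (restarting on exact zeros keeps tracebacks off the boundary)
            val, p = diag_m, 1
            if diag_x > val:
                val, p = diag_x, 2
            if diag_y > val:
                val, p = diag_y, 3
            if val <= 0.0:
                val, p = 0.0, 0
            M[i][j] = val + s
            ptr_m[i][j] = p
            if M[i][j] > best:
                best, bi, bj = M[i][j], i, j

    if best <= 0.0:
        return []

    columns: list[tuple[int | None, int | None]] = []
    i, j, state = bi, bj, "M"
    while True:
        if state == "M":
            p = ptr_m[i][j]
            columns.append((i - 1, j - 1))
            i, j = i - 1, j - 1
            if p == 0:
                break
            state = ("M", "X", "Y")[p - 1]
        elif state == "X":
            p = ptr_x[i][j]
            columns.append((i - 1, None))
            i -= 1
            state = "M" if p == 1 else "X"
        else:
            p = ptr_y[i][j]
            columns.append((None, j - 1))
            j -= 1
            state = "M" if p == 1 else "Y"
    columns.reverse()
    return columns


@dataclass(frozen=True)
class TransferCriterion:
    """How a third node y qualifies as equivalent to template z."""

    mode: str  # "shared_attribute" | "sequence_similarity"
    attribute_names: frozenset[str] = frozenset()
    min_similarity_pct: float = 90.0
    min_coverage_pct: float = 90.0
    scheme: str = "blosum62"
    metric: str = "similarity"  # or "identity"
    require_both_coverage: bool = False

    def __post_init__(self):
        if self.mode not in {"shared_attribute", "sequence_similarity"}:
            raise ValueError(f"unknown transfer mode {self.mode!r}")
        if self.mode == "shared_attribute" and not self.attribute_names:
            raise ValueError("shared_attribute mode needs attribute names")
        if not (0 <= self.min_similarity_pct <= 100):
            raise ValueError("min_similarity_pct must be in [0, 100]")
        if not (0 <= self.min_coverage_pct <= 100):
            raise ValueError("min_coverage_pct must be in [0, 100]")
        if self.metric not in {"similarity", "identity"}:
            raise ValueError(f"unknown metric {self.metric!r}")


def _ue_sequences(partition: Partition, ue_id: int) -> tuple[str, ...]:
    return partition.attribute_values(ue_id, "ProteinSequence")


def _passes(stats: AlignmentStats, criterion: TransferCriterion) -> bool:
    value = (
        stats.similarity_pct if criterion.metric == "similarity" else stats.identity_pct
    )
    if value < criterion.min_similarity_pct:
        return False
    # coverage applies to the template (target) sequence by default
    if stats.coverage_pct_target < criterion.min_coverage_pct:
        return False
    if criterion.require_both_coverage and (
        stats.coverage_pct_query < criterion.min_coverage_pct
    ):
        return False
    return True


def find_partners(
    partition: Partition, ue_id: int, criterion: TransferCriterion
) -> dict[int, tuple]:
    """User entities equivalent to ``ue_id`` under the criterion.

    Returns {partner ue_id: evidence}; ``ue_id`` itself is excluded.
    shared_attribute evidence is a tuple of (name, shared values); sequence
    evidence is the first passing AlignmentStats.
    """
    out: dict[int, tuple] = {}
    if criterion.mode == "shared_attribute":
        names = sorted(criterion.attribute_names)
        mine = {n: partition.attribute_norm_values(ue_id, n) for n in names}
        if not all(mine.values()):
            return out
        for other in partition:
            if other.ue_id == ue_id:
                continue
            shared = []
            for n in names:
                common = mine[n] & partition.attribute_norm_values(other.ue_id, n)
                if not common:
                    break
                shared.append((n, tuple(sorted(common))))
            else:
                out[other.ue_id] = tuple(shared)
        return out

    template_seqs = _ue_sequences(partition, ue_id)
    if not template_seqs:
        logger.warning("user entity %d has no ProteinSequence values", ue_id)
        return out
    for other in partition:
        if other.ue_id == ue_id:
            continue
        for cand in _ue_sequences(partition, other.ue_id):
            done = False
            for tmpl in template_seqs:
                stats = align_pair(cand, tmpl, scheme=criterion.scheme)
                if _passes(stats, criterion):
                    out[other.ue_id] = (stats,)
                    done = True
                    break
            if done:
                break
    return out


def transfer_edges(
    network: UnifiedNetwork,
    partition: Partition,
    registry,
    criterion: TransferCriterion,
) -> UnifiedNetwork:
    """One round of interolog-style transfer over observed edges.

    For every observed edge (x, z) and both orientations, each partner y
    of the template endpoint contributes an inferred edge (anchor, y)
    citing the observed edge's provenance.  Observed edges are untouched;
    templates are observed edges only (no chaining through predictions).
    """
    out = network.copy()
    observed_simple = {
        (u, v) for (u, v, _), ed in network.edges.items() if not ed.inferred
    }
    partners_cache: dict[int, dict[int, tuple]] = {}

    def partners(z: int) -> dict[int, tuple]:
        if z not in partners_cache:
            partners_cache[z] = find_partners(partition, z, criterion)
        return partners_cache[z]

    for (u, v, rtype), ed in sorted(network.edges.items()):
        if ed.inferred:
            continue
        for anchor, template in ((u, v), (v, u)):
            for y, evidence in sorted(partners(template).items()):
                a, b = (anchor, y) if anchor <= y else (y, anchor)
                if (a, b) in observed_simple:
                    continue
                evid_strings = {_format_evidence(template, evidence)}
                key = (a, b, rtype)
                if key in out.edges and not out.edges[key].inferred:
                    continue
                out.add_edge(
                    a,
                    b,
                    rtype,
                    provenance=ed.provenance,
                    inferred=True,
                    evidence=evid_strings,
                )
    return out


def _format_evidence(template: int, evidence: tuple) -> str:
    parts = []
    for item in evidence:
        if isinstance(item, AlignmentStats):
            parts.append(
                f"sim={item.similarity_pct:.1f}%,id={item.identity_pct:.1f}%,"
                f"cov={item.coverage_pct_target:.1f}%"
            )
        else:
            name, values = item
            parts.append(f"{name}={'|'.join(values)}")
    return f"template=ue{template};" + ";".join(parts)
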
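import itertools
import random

import pytest
from Bio import Align

from entityfuse import (
    Registry,
    TransferCriterion,
    align_pair,
    compute_user_entities,
    cross_all,
    expand_network,
    find_partners,
    transfer_edges,
)
from entityfuse.inference import _scheme
from entityfuse.synthetic import random_protein_sequence
from helpers_oracles import (
    best_local_score,
    brute_force_transfer,
    enumerate_local_alignments,
)


class TestAlignPair:
    def test_identical_sequences_are_perfect(self):
        s = "MKTAYIAKQRQISFVKSHFSRQ"
        stats = align_pair(s, s)
        assert stats.identity_pct == 100.0
        assert stats.similarity_pct == 100.0
        assert stats.coverage_pct_query == 100.0
        assert stats.coverage_pct_target == 100.0
        assert stats.aligned_length == len(s)

    def test_disjoint_sequences_have_no_coverage(self):
        stats = align_pair("AAAAAA", "WWWWWW", scheme="identity")
        assert stats.coverage_pct_query == 0.0
        assert stats.coverage_pct_target == 0.0

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            align_pair("", "MKT")

    def test_unknown_scheme_rejected(self):
        with pytest.raises(ValueError):
            align_pair("MKT", "MKT", scheme="nosuchmatrix")

    def test_partial_coverage_of_longer_target(self):
        query = "MKTAYIAKQR"
        target = query + "W" * 10
        stats = align_pair(query, target)
        assert stats.coverage_pct_query == 100.0
        assert stats.coverage_pct_target == 50.0

    @pytest.mark.parametrize("scheme", ["blosum62", "identity"])
    def test_score_matches_independent_dp_oracle(self, scheme):
        """Optimal score equals a score-only affine SW written separately,
        on random toy pairs up to length 12."""
        rng = random.Random(77)
        sub = _scheme(scheme)
        for _ in range(40):
            a = random_protein_sequence(rng, rng.randint(1, 12))
            b = random_protein_sequence(rng, rng.randint(1, 12))
            stats = align_pair(a, b, scheme=scheme)
            assert stats.score == pytest.approx(best_local_score(a, b, sub))

    def test_score_matches_biopython_local_aligner(self):
        """Cross-check against an independent implementation of the same
        scoring model."""
        aligner = Align.PairwiseAligner()
        aligner.mode = "local"
        aligner.substitution_matrix = Align.substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = -11
        aligner.extend_gap_score = -1
        rng = random.Random(101)
        for _ in range(25):
            a = random_protein_sequence(rng, rng.randint(3, 12))
            b = random_protein_sequence(rng, rng.randint(3, 12))
            stats = align_pair(a, b)
            expected = aligner.score(a, b) if aligner.score(a, b) > 0 else 0.0
            assert stats.score == pytest.approx(max(expected, 0.0))

    def test_stats_match_exhaustive_enumeration(self):
        """On very short pairs, the reported stats coincide with those of
        an optimal alignment found by brute-force enumeration."""
        rng = random.Random(5)
        sub = _scheme("blosum62")
        for _ in range(6):
            a = random_protein_sequence(rng, rng.randint(2, 5))
            b = random_protein_sequence(rng, rng.randint(2, 5))
            stats = align_pair(a, b)
            alignments = enumerate_local_alignments(a, b, sub)
            best = max((s for s, _ in alignments), default=0.0)
            best = max(best, 0.0)
            assert stats.score == pytest.approx(best)
            if best == 0.0:
                assert stats.aligned_length == 0
                continue
            optimal = {
                (len(cols),
                 sum(1 for i, j in cols if i is not None and j is not None
                     and a[i] == b[j]))
                for s, cols in alignments if s == pytest.approx(best)
            }
            assert (
                stats.aligned_length,
                round(stats.identity_pct * stats.aligned_length / 100),
            ) in optimal

    def test_stats_invariants_hold(self):
        rng = random.Random(9)
        for _ in range(30):
            a = random_protein_sequence(rng, rng.randint(1, 20))
            b = random_protein_sequence(rng, rng.randint(1, 20))
            stats = align_pair(a, b)
            assert 0 <= stats.identity_pct <= stats.similarity_pct <= 100
            assert 0 <= stats.coverage_pct_query <= 100
            assert 0 <= stats.coverage_pct_target <= 100


def build_sequence_partition(seqs):
    """One singleton user entity per sequence (plus one accession each)."""
    reg = Registry()
    db = reg.register_database("db", "1")
    for i, seq in enumerate(seqs):
        attrs = {"UniprotAccession": [f"P{i}"]}
        if seq is not None:
            attrs["ProteinSequence"] = [seq]
        reg.register_entity(db, "protein", attrs)
    part = compute_user_entities(reg, cross_all(reg, [{"UniprotAccession"}]))
    return reg, part


class TestFindPartners:
    def test_no_shared_domain_means_no_partner(self):
        reg = Registry()
        db = reg.register_database("db", "1")
        reg.register_entity(db, "protein", {"UniprotAccession": ["P0"], "Pfam": ["PF1"]})
        reg.register_entity(db, "protein", {"UniprotAccession": ["P1"], "Pfam": ["PF2"]})
        part = compute_user_entities(reg, cross_all(reg, [{"UniprotAccession"}]))
        criterion = TransferCriterion(
            mode="shared_attribute", attribute_names=frozenset({"Pfam"})
        )
        assert find_partners(part, 0, criterion) == {}

    def test_shared_attribute_conjunction(self):
        reg = Registry()
        db = reg.register_database("db", "1")
        reg.register_entity(
            db, "protein",
            {"UniprotAccession": ["P0"], "Pfam": ["PF1"], "taxID": [9606]},
        )
        reg.register_entity(
            db, "protein",
            {"UniprotAccession": ["P1"], "Pfam": ["PF1"], "taxID": [9606]},
        )
        reg.register_entity(
            db, "protein",
            {"UniprotAccession": ["P2"], "Pfam": ["PF1"], "taxID": [10090]},
        )
        part = compute_user_entities(reg, cross_all(reg, [{"UniprotAccession"}]))
        criterion = TransferCriterion(
            mode="shared_attribute", attribute_names=frozenset({"Pfam", "taxID"})
        )
        assert set(find_partners(part, 0, criterion)) == {1}

    def test_verbatim_sequence_copy_passes_90_90(self):
        rng = random.Random(1)
        s = random_protein_sequence(rng, 50)
        reg, part = build_sequence_partition([s, s, random_protein_sequence(rng, 50)])
        criterion = TransferCriterion(
            mode="sequence_similarity", min_similarity_pct=90, min_coverage_pct=90
        )
        partners = find_partners(part, 0, criterion)
        assert set(partners) == {1}
        (stats,) = partners[1]
        assert stats.similarity_pct == 100.0

    def test_entity_without_sequence_yields_empty(self):
        reg, part = build_sequence_partition([None, "MKTAYIAKQR"])
        criterion = TransferCriterion(mode="sequence_similarity")
        assert find_partners(part, 0, criterion) == {}

    def test_matches_brute_force_attribute_check(self, small_random):
        reg, protocol, _ = small_random
        part = compute_user_entities(reg, protocol)
        criterion = TransferCriterion(
            mode="shared_attribute", attribute_names=frozenset({"ProteinSequence"})
        )
        for ue in part:
            got = set(find_partners(part, ue.ue_id, criterion))
            expected = {
                other.ue_id
                for other in part
                if other.ue_id != ue.ue_id
                and part.attribute_norm_values(ue.ue_id, "ProteinSequence")
                & part.attribute_norm_values(other.ue_id, "ProteinSequence")
            }
            assert got == expected


def mutate(rng, seq, n_subs):
    out = list(seq)
    for pos in rng.sample(range(len(seq)), n_subs):
        out[pos] = rng.choice([c for c in "ACDEFGHIKLMNPQRSTVWY" if c != out[pos]])
    return "".join(out)


@pytest.fixture(scope="module")
def homolog_partition():
    """Eight singleton user entities: two homolog families + noise."""
    rng = random.Random(4242)
    base1 = random_protein_sequence(rng, 40)
    base2 = random_protein_sequence(rng, 40)
    seqs = [
        base1,
        mutate(rng, base1, 2),
        mutate(rng, base1, 8),
        base2,
        mutate(rng, base2, 3),
        random_protein_sequence(rng, 40),
        random_protein_sequence(rng, 40),
        base1[:20],
    ]
    return build_sequence_partition(seqs)


class TestTransferEdges:
    def make_network(self, reg, part, pairs):
        db = reg.register_database(f"rels-{len(reg.databases)}", "1")
        for a, b in pairs:
            reg.register_relation(db, "interaction", [a, b])
        return expand_network(part, reg, {ue.ue_id for ue in part}, depth=1)

    def test_criterion_matching_nothing_changes_nothing(self, homolog_partition):
        reg, part = homolog_partition
        net = self.make_network(reg, part, [(0, 5)])
        criterion = TransferCriterion(
            mode="sequence_similarity", min_similarity_pct=100, min_coverage_pct=100,
            metric="identity",
        )
        out = transfer_edges(net, part, reg, criterion)
        assert out.edge_set() == net.edge_set()

    def test_twin_template_produces_inferred_triangle_edge(self):
        rng = random.Random(2)
        s = random_protein_sequence(rng, 45)
        reg, part = build_sequence_partition(
            [random_protein_sequence(rng, 45), s, s]
        )
        net = self.make_network(reg, part, [(0, 1)])  # x=0 observed with z=1
        criterion = TransferCriterion(mode="sequence_similarity")
        out = transfer_edges(net, part, reg, criterion)
        key = (0, 2, "interaction")
        assert key in out.edges and out.edges[key].inferred
        assert out.edges[key].provenance == net.edges[(0, 1, "interaction")].provenance

    def test_observed_edges_conserved_and_never_overwritten(self, homolog_partition):
        reg, part = homolog_partition
        net = self.make_network(reg, part, [(0, 3), (1, 3)])
        criterion = TransferCriterion(mode="sequence_similarity", min_similarity_pct=80)
        out = transfer_edges(net, part, reg, criterion)
        for key, ed in net.edges.items():
            assert key in out.edges
            assert out.edges[key].inferred == ed.inferred
            assert out.edges[key].provenance >= ed.provenance
        observed = {k for k, ed in out.edges.items() if not ed.inferred}
        assert observed == set(net.edges)

    def test_matches_triple_enumeration_oracle(self, homolog_partition):
        reg, part = homolog_partition
        net = self.make_network(reg, part, [(0, 3), (2, 4), (5, 6)])
        criterion = TransferCriterion(
            mode="sequence_similarity", min_similarity_pct=70, min_coverage_pct=70
        )
        out = transfer_edges(net, part, reg, criterion)
        partners = {
            ue.ue_id: set(find_partners(part, ue.ue_id, criterion))
            for ue in part
        }
        expected = brute_force_transfer(
            {(u, v) for u, v, _ in net.edges}, lambda z: partners[z]
        )
        got = {(u, v) for (u, v, _), ed in out.edges.items() if ed.inferred}
        assert got == expected

    def test_symmetry_of_template_choice(self, homolog_partition):
        """Transferring over edge (x,z) equals transferring over (z,x)."""
        reg, part = homolog_partition
        criterion = TransferCriterion(mode="sequence_similarity", min_similarity_pct=80)
        n1 = self.make_network(reg, part, [(0, 3)])
        n2 = self.make_network(reg, part, [(3, 0)])
        o1 = transfer_edges(n1, part, reg, criterion)
        o2 = transfer_edges(n2, part, reg, criterion)
        assert {(u, v) for (u, v, _), ed in o1.edges.items() if ed.inferred} == {
            (u, v) for (u, v, _), ed in o2.edges.items() if ed.inferred
        }

    def test_threshold_monotonicity_over_cutoff_grid(self, homolog_partition):
        reg, part = homolog_partition
        net = self.make_network(reg, part, [(0, 4), (1, 3)])
        grid = [50, 70, 90, 100]
        counts = {}
        for sim, cov in itertools.product(grid, grid):
            criterion = TransferCriterion(
                mode="sequence_similarity",
                min_similarity_pct=sim,
                min_coverage_pct=cov,
            )
            out = transfer_edges(net, part, reg, criterion)
            counts[(sim, cov)] = {
                k for k, ed in out.edges.items() if ed.inferred
            }
        for sim, cov in itertools.product(grid, grid):
            for sim2, cov2 in itertools.product(grid, grid):
                if sim2 >= sim and cov2 >= cov:
                    assert counts[(sim2, cov2)] <= counts[(sim, cov)]

    def test_self_transfer_is_identity(self):
        """If nothing matches anything else, transfer changes nothing."""
        rng = random.Random(8)
        reg, part = build_sequence_partition(
            [random_protein_sequence(rng, 30) for _ in range(4)]
        )
        net = self.make_network(reg, part, [(0, 1), (2, 3)])
        criterion = TransferCriterion(mode="sequence_similarity")
        out = transfer_edges(net, part, reg, criterion)
        assert out.edge_set() == net.edge_set()
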
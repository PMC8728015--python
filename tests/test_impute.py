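"""Emission model, diploid Viterbi (vs enumeration), genotype extraction."""

import math

import numpy as np
import pytest

from haplograph.genome_model import GenomicInterval, VariantSite
from haplograph.graph import HaplotypeGraph, transition_probs
from haplograph.haplotype_db import ConsensusHaplotype
from haplograph.impute import (
    DiploidPath,
    DiploidState,
    EmissionParams,
    ReadObservation,
    assign_read,
    emission_loglik,
    emission_matrix,
    impute_taxa,
    path_to_genotypes,
    path_to_haplotypes,
    read_reads_tsv,
    viterbi_diploid,
    write_reads_tsv,
)
from haplograph.range_builder import ReferenceRange

from _oracles import enumerate_diploid_paths


def make_graph(node_alleles_per_range, edge_counts=None, member_counts=None, rng=None):
    """Assemble a single-chromosome trellis from explicit allele vectors."""
    ranges, sites, nodes = [], [], []
    for i, vectors in enumerate(node_alleles_per_range):
        n_sites = len(vectors[0])
        idx = np.arange(len(sites), len(sites) + n_sites)
        for p in range(n_sites):
            sites.append(VariantSite("chr1", i * 1000 + 10 * p, "A", "T"))
        ranges.append(ReferenceRange(i, GenomicInterval("chr1", i * 1000, (i + 1) * 1000), idx))
        mc = member_counts[i] if member_counts else [1] * len(vectors)
        nodes.append(
            [
                ConsensusHaplotype(i, j, np.array(v, dtype=np.int8), [f"t{i}_{j}"], int(m))
                for j, (v, m) in enumerate(zip(vectors, mc))
            ]
        )
    edges = {}
    for i in range(len(ranges) - 1):
        k, k2 = len(nodes[i]), len(nodes[i + 1])
        if edge_counts is not None:
            edges[i] = np.asarray(edge_counts[i], dtype=float)
        else:
            edges[i] = (rng or np.random.default_rng(0)).gamma(1.0, 2.0, (k, k2))
    return HaplotypeGraph(ranges, sites, nodes, edges)


def random_instance(rng):
    """Random trellis + reads with continuous transitions (no score ties)."""
    n_ranges = int(rng.integers(2, 6))
    node_sets = []
    for _ in range(n_ranges):
        k = int(rng.integers(1, 5))
        node_sets.append([rng.integers(0, 2, 4).tolist() for _ in range(k)])
    members = [[int(rng.integers(1, 5)) for _ in vs] for vs in node_sets]
    graph = make_graph(node_sets, member_counts=members, rng=rng)
    obs = []
    for i in range(n_ranges):
        for _ in range(int(rng.integers(0, 4))):
            start = int(rng.integers(0, 3))
            obs.append(
                ReadObservation(i, np.arange(start, start + 2), rng.integers(0, 2, 2))
            )
    return graph, obs


class TestAssignRead:
    def _nodes(self):
        return [
            ConsensusHaplotype(0, 0, np.array([1, 0, 0, 1], dtype=np.int8), ["a"], 1),
            ConsensusHaplotype(0, 1, np.array([0, 0, 0, 1], dtype=np.int8), ["b"], 1),
        ]

    def test_consistency_at_covered_sites_only(self):
        read = ReadObservation(0, np.array([0, 3]), np.array([1, 1]))
        assert assign_read(read, self._nodes()) == {0}

    def test_mismatch_tolerance(self):
        read = ReadObservation(0, np.array([0, 3]), np.array([1, 1]))
        assert assign_read(read, self._nodes(), mismatch_tol=1) == {0, 1}

    def test_read_consistent_with_no_node(self):
        read = ReadObservation(0, np.array([2, 3]), np.array([1, 0]))
        assert assign_read(read, self._nodes()) == set()


class TestEmission:
    def _setup(self):
        nodes = [
            ConsensusHaplotype(0, 0, np.zeros(4, dtype=np.int8), ["a"], 1),
            ConsensusHaplotype(0, 1, np.ones(4, dtype=np.int8), ["b"], 1),
        ]
        return nodes, EmissionParams(epsilon=0.01)

    def test_diploid_mixture_closed_forms(self):
        """Per read: both haps consistent -> 1-eps; one -> 1/2; none -> eps."""
        nodes, params = self._setup()
        ref_read = ReadObservation(0, np.arange(4), np.zeros(4, dtype=np.int8))
        alt_read = ReadObservation(0, np.arange(4), np.ones(4, dtype=np.int8))
        E = emission_matrix(nodes, [ref_read] * 3, params)
        assert E[0, 0] == pytest.approx(3 * math.log(0.99))
        assert E[0, 1] == pytest.approx(3 * math.log(0.5))
        assert E[1, 1] == pytest.approx(3 * math.log(0.01))
        E2 = emission_matrix(nodes, [ref_read, ref_read, alt_read], params)
        assert E2[0, 0] == pytest.approx(2 * math.log(0.99) + math.log(0.01))
        assert E2[0, 1] == pytest.approx(3 * math.log(0.5))

    def test_no_reads_uniform(self):
        nodes, params = self._setup()
        np.testing.assert_array_equal(emission_matrix(nodes, [], params), np.zeros((2, 2)))
        state = DiploidState(0, (0, 1))
        assert emission_loglik(state, [], nodes, params) == 0.0

    def test_symmetry(self):
        nodes, params = self._setup()
        read = ReadObservation(0, np.arange(4), np.zeros(4, dtype=np.int8))
        E = emission_matrix(nodes, [read], params)
        np.testing.assert_allclose(E, E.T)

    def test_consistent_read_never_hurts_relative_standing(self):
        """Adding a read consistent with a state never lowers that state's
        advantage over a state the read is inconsistent with."""
        rng = np.random.default_rng(3)
        nodes = [
            ConsensusHaplotype(0, j, rng.integers(0, 2, 6).astype(np.int8), [f"t{j}"], 1)
            for j in range(4)
        ]
        params = EmissionParams(epsilon=0.05)
        base = [
            ReadObservation(0, np.arange(2), rng.integers(0, 2, 2)) for _ in range(3)
        ]
        new = ReadObservation(0, np.arange(6), nodes[1].alleles.copy())
        E0 = emission_matrix(nodes, base, params)
        E1 = emission_matrix(nodes, base + [new], params)
        consistent = assign_read(new, nodes)
        assert 1 in consistent
        for a, b in [(1, 1), (1, 0), (1, 2)]:
            for c, d in [(c, d) for c in range(4) for d in range(4)]:
                if c in consistent or d in consistent:
                    continue
                assert E1[a, b] - E1[c, d] >= E0[a, b] - E0[c, d] - 1e-12

    def test_read_cap_deterministic(self):
        nodes, params = self._setup()
        params = EmissionParams(epsilon=0.01, max_reads_per_range=2)
        reads = [
            ReadObservation(0, np.array([s]), np.array([1])) for s in (3, 0, 2, 1)
        ]
        E1 = emission_matrix(nodes, reads, params)
        E2 = emission_matrix(nodes, list(reversed(reads)), params)
        np.testing.assert_array_equal(E1, E2)  # cap after stable sort, order-free
        # only 2 reads scored
        assert E1[1, 1] == pytest.approx(2 * math.log(0.99))

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            EmissionParams(epsilon=0.6)
        with pytest.raises(ValueError):
            EmissionParams(max_reads_per_range=0)


class TestViterbi:
    def test_dominant_evidence_single_range(self):
        graph = make_graph([[[0, 0, 0, 0], [1, 1, 1, 1]]])
        tm = transition_probs(graph)
        reads = [ReadObservation(0, np.arange(4), np.zeros(4, dtype=np.int8))] * 4
        path = viterbi_diploid(graph, tm, reads, EmissionParams())
        assert path.states[0].nodes == (0, 0)

    def test_no_reads_maximizes_prior_and_transitions(self):
        rng = np.random.default_rng(12)
        graph, _ = random_instance(rng)
        tm = transition_probs(graph, 0.3)
        params = EmissionParams()
        lp, states = enumerate_diploid_paths(graph, tm, [], params)
        path = viterbi_diploid(graph, tm, [], params)
        assert path.log_prob == pytest.approx(lp, abs=1e-9)
        assert [s.nodes for s in path.states] == states

    @pytest.mark.parametrize("seed", range(40))
    def test_matches_exhaustive_enumeration(self, seed):
        """Path and log-probability equal brute-force enumeration over all
        diploid paths (<=5 ranges, <=4 nodes/range)."""
        rng = np.random.default_rng(1000 + seed)
        graph, obs = random_instance(rng)
        tm = transition_probs(graph, 0.5)
        params = EmissionParams(epsilon=0.05)
        lp, states = enumerate_diploid_paths(graph, tm, obs, params)
        path = viterbi_diploid(graph, tm, obs, params)
        assert path.log_prob == pytest.approx(lp, abs=1e-9)
        assert [s.nodes for s in path.states] == states

    def test_determinism(self):
        rng = np.random.default_rng(77)
        graph, obs = random_instance(rng)
        tm = transition_probs(graph)
        p1 = viterbi_diploid(graph, tm, obs, EmissionParams())
        p2 = viterbi_diploid(graph, tm, obs, EmissionParams())
        assert p1.log_prob == p2.log_prob
        assert [s.nodes for s in p1.states] == [s.nodes for s in p2.states]

    def test_unordered_reporting_label_symmetry(self):
        """The reported pair is unordered: reads supporting (a,b) and (b,a)
        give the same state."""
        graph = make_graph([[[0, 0, 0, 0], [1, 1, 1, 1]]] * 2)
        tm = transition_probs(graph)
        ref = ReadObservation(0, np.arange(4), np.zeros(4, dtype=np.int8))
        alt = ReadObservation(0, np.arange(4), np.ones(4, dtype=np.int8))
        p1 = viterbi_diploid(graph, tm, [ref, alt], EmissionParams())
        p2 = viterbi_diploid(graph, tm, [alt, ref], EmissionParams())
        assert p1.states[0].nodes == p2.states[0].nodes == (0, 1)


class TestGenotypeExtraction:
    def test_het_hom_and_dosage_sum(self):
        rng = np.random.default_rng(5)
        graph = make_graph([[rng.integers(0, 2, 4).tolist() for _ in range(3)] for _ in range(3)])
        states = [DiploidState(i, (int(rng.integers(3)), int(rng.integers(3)))) for i in range(3)]
        path = DiploidPath("x", states, -1.0)
        dosage = path_to_genotypes(path, graph)
        hap = path_to_haplotypes(path, graph)
        np.testing.assert_array_equal(dosage, hap.sum(axis=0))
        for i, st in enumerate(states):
            a = graph.nodes[i][st.nodes[0]].alleles
            b = graph.nodes[i][st.nodes[1]].alleles
            np.testing.assert_array_equal(dosage[graph.ranges[i].site_indices], a + b)

    def test_all_ref_all_alt_pair_is_het_everywhere(self):
        graph = make_graph([[[0, 0, 0], [1, 1, 1]]])
        path = DiploidPath("x", [DiploidState(0, (0, 1))], -1.0)
        assert path_to_genotypes(path, graph).tolist() == [1, 1, 1]


class TestImputeTaxa:
    def test_zero_read_taxon_warns_but_imputes(self, caplog):
        graph = make_graph([[[0, 0], [1, 1]], [[0, 0], [1, 1]]])
        tm = transition_probs(graph)
        with caplog.at_level("WARNING", logger="haplograph.impute"):
            matrix, paths = impute_taxa(graph, tm, {"empty": []})
        assert "no reads" in caplog.text
        assert matrix.n_taxa == 1 and matrix.n_sites == 4
        assert (matrix.calls >= 0).all()

    def test_identical_read_sets_identical_rows(self):
        rng = np.random.default_rng(8)
        graph, obs = random_instance(rng)
        tm = transition_probs(graph)
        matrix, _ = impute_taxa(graph, tm, {"a": obs, "b": list(obs)})
        np.testing.assert_array_equal(matrix.calls[0], matrix.calls[1])


def test_reads_tsv_round_trip(tmp_path):
    rng = np.random.default_rng(9)
    reads = {
        "t1": [ReadObservation(0, np.array([0, 1]), np.array([1, 0]))],
        "t2": [
            ReadObservation(2, np.array([3]), np.array([1])),
            ReadObservation(1, np.array([0, 1, 2]), np.array([0, 0, 1])),
        ],
    }
    path = tmp_path / "reads.tsv"
    write_reads_tsv(reads, path)
    back = read_reads_tsv(path)
    assert set(back) == {"t1", "t2"}
    for t in reads:
        got = [(r.range_id, r.site_indices.tolist(), r.alleles.tolist()) for r in back[t]]
        want = [(r.range_id, r.site_indices.tolist(), r.alleles.tolist()) for r in reads[t]]
        assert got == want
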
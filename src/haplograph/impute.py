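"""Diploid Viterbi imputation over the haplotype trellis.

The hidden state at each reference range is an *ordered pair* of consensus
haplotype nodes (k^2 states for k nodes), reported as an unordered pair.
Emissions come from read observations via the standard diploid read
likelihood: a read drawn from an unknown one of the two genome copies has
P(read | h_a, h_b) = (f(read|h_a) + f(read|h_b)) / 2, where f(read|h) is
(1 - eps) when the read matches h at all covered sites and eps otherwise.
So a read consistent with both haplotypes contributes (1 - eps), with
exactly one ~1/2, with neither eps — which is what lets read depth separate
homozygous from heterozygous states.  Pair transition
probabilities factor as the product of the two per-haplotype transition
probabilities, which lets the max-plus recursion run in O(k^3) per boundary
instead of O(k^4).  Chromosomes are imputed independently, starting from
member-count-proportional node priors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .genome_model import GenotypeMatrix, VariantSite
from .graph import HaplotypeGraph, TransitionModel
from .haplotype_db import ConsensusHaplotype

logger = logging.getLogger(__name__)


@dataclass
class ReadObservation:
    """One read's evidence in variant space: covered sites + observed alleles.

    ``site_indices`` index into the *range's* site list (local indices).
    """

    range_id: int
    site_indices: np.ndarray
    alleles: np.ndarray

    def __post_init__(self) -> None:
        self.site_indices = np.asarray(self.site_indices, dtype=np.int64)
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if len(self.site_indices) == 0:
            raise ValueError("empty read observation")
        if self.site_indices.shape != self.alleles.shape:
            raise ValueError("site_indices and alleles must align")

    def sort_key(self) -> tuple:
        return (self.range_id, tuple(self.site_indices), tuple(self.alleles))


@dataclass
class EmissionParams:
    """Emission model knobs.

    epsilon: probability a read is inconsistent with the true haplotype pair
        (absorbs sequencing error, misassignment, divergence).
    max_reads_per_range: deterministic cap on reads scored per range
        (guards against over-confident deep ranges).
    mismatch_tol: allowed per-read mismatches for consistency.
    """

    epsilon: float = 0.01
    max_reads_per_range: int = 50
    mismatch_tol: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.epsilon < 0.5:
            raise ValueError("epsilon must be in (0, 0.5)")
        if self.max_reads_per_range < 1:
            raise ValueError("max_reads_per_range must be >= 1")


@dataclass(frozen=True)
class DiploidState:
    """Unordered pair of node indices at one range."""

    range_id: int
    nodes: tuple[int, int]  # stored sorted

    def __post_init__(self) -> None:
        object.__setattr__(self, "nodes", tuple(sorted(self.nodes)))


@dataclass
class DiploidPath:
    """Two haplotype choices per range for one taxon, with the path score."""

    taxon: str
    states: list[DiploidState]
    log_prob: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.log_prob):
            raise ValueError("path log-probability must be finite")


def assign_read(
    observation: ReadObservation,
    nodes: Sequence[ConsensusHaplotype],
    mismatch_tol: int = 0,
) -> set[int]:
    """Node indices whose alleles match the read at all covered sites
    (allowing up to ``mismatch_tol`` mismatches)."""
    out = set()
    for idx, node in enumerate(nodes):
        mism = int(
            (node.alleles[observation.site_indices] != observation.alleles).sum()
        )
        if mism <= mismatch_tol:
            out.add(idx)
    return out


def _capped(observations: Sequence[ReadObservation], cap: int) -> list[ReadObservation]:
    """Deterministic subsample: first ``cap`` after a stable sort."""
    if len(observations) <= cap:
        return sorted(observations, key=ReadObservation.sort_key)
    return sorted(observations, key=ReadObservation.sort_key)[:cap]


def _consistency_matrix(
    nodes: Sequence[ConsensusHaplotype],
    observations: Sequence[ReadObservation],
    mismatch_tol: int,
) -> np.ndarray:
    """(n_reads, k) boolean read-vs-node consistency."""
    k = len(nodes)
    alleles = np.stack([n.alleles for n in nodes]) if k else np.empty((0, 0))
    C = np.zeros((len(observations), k), dtype=bool)
    for r, obs in enumerate(observations):
        mism = (alleles[:, obs.site_indices] != obs.alleles[None, :]).sum(axis=1)
        C[r] = mism <= mismatch_tol
    return C


def emission_matrix(
    nodes: Sequence[ConsensusHaplotype],
    observations: Sequence[ReadObservation],
    params: EmissionParams,
) -> np.ndarray:
    """(k, k) log-likelihood of each ordered node pair given the reads.

    Per read, the diploid mixture factor (f_a + f_b)/2 with f_h = (1 - eps)
    if the read is consistent with node h, eps otherwise; reads beyond the
    cap are dropped after a stable sort.  With no reads the emission is
    uniform (all zeros in log space).
    """
    k = len(nodes)
    if not observations:
        return np.zeros((k, k))
    obs = _capped(observations, params.max_reads_per_range)
    C = _consistency_matrix(nodes, obs, params.mismatch_tol)
    F = np.where(C, 1.0 - params.epsilon, params.epsilon)
    return np.log(0.5 * (F[:, :, None] + F[:, None, :])).sum(axis=0)


def emission_loglik(
    state: DiploidState,
    observations: Sequence[ReadObservation],
    nodes: Sequence[ConsensusHaplotype],
    params: EmissionParams,
) -> float:
    """Log-likelihood of one diploid state given that range's reads."""
    for obs in observations:
        if obs.range_id != state.range_id:
            raise ValueError("observation range does not match state range")
    E = emission_matrix(nodes, observations, params)
    a, b = state.nodes
    return float(E[a, b])


def viterbi_diploid(
    graph: HaplotypeGraph,
    transitions: TransitionModel,
    observations: Iterable[ReadObservation],
    params: EmissionParams | None = None,
    taxon: str = "",
) -> DiploidPath:
    """Exact Viterbi over ordered haplotype pairs, per chromosome.

    Initial distribution is the product of member-count-proportional node
    frequencies; pair transitions are products of per-haplotype transitions.
    Ties resolve deterministically toward smaller node indices.  Returns the
    argmax path (states reported as unordered pairs) and its log-probability
    summed over chromosomes.
    """
    params = params or EmissionParams()
    obs_by_idx: dict[int, list[ReadObservation]] = {}
    for obs in observations:
        obs_by_idx.setdefault(graph.range_index(obs.range_id), []).append(obs)

    states: list[DiploidState] = [None] * graph.n_ranges  # type: ignore[list-item]
    total_lp = 0.0
    with np.errstate(divide="ignore"):
        for s, e in graph.chrom_blocks():
            pair, lp = _viterbi_block(graph, transitions, obs_by_idx, params, s, e)
            total_lp += lp
            for i in range(s, e):
                states[i] = DiploidState(graph.ranges[i].id, pair[i - s])
    return DiploidPath(taxon, states, total_lp)


def _viterbi_block(
    graph: HaplotypeGraph,
    transitions: TransitionModel,
    obs_by_idx: Mapping[int, Sequence[ReadObservation]],
    params: EmissionParams,
    s: int,
    e: int,
) -> tuple[list[tuple[int, int]], float]:
    """Viterbi over ranges [s, e) (one chromosome)."""
    if len(graph.nodes[s]) == 0:
        raise ValueError(f"range index {s} has zero nodes")
    log_pi = np.log(graph.node_priors(s))
    V = log_pi[:, None] + log_pi[None, :] + emission_matrix(
        graph.nodes[s], obs_by_idx.get(s, ()), params
    )
    back: list[tuple[np.ndarray, np.ndarray]] = []
    for i in range(s, e - 1):
        if len(graph.nodes[i + 1]) == 0:
            raise ValueError(f"range index {i + 1} has zero nodes")
        L = np.log(transitions.probs[i])
        # step 1: maximize over a.  t1[a, b, a'] = V[a, b] + L[a, a']
        t1 = V[:, :, None] + L[:, None, :]
        A1 = t1.argmax(axis=0)  # (b, a')
        M1 = t1.max(axis=0)
        # step 2: maximize over b.  t2[b, a', b'] = M1[b, a'] + L[b, b']
        t2 = M1[:, :, None] + L[:, None, :]
        B = t2.argmax(axis=0)  # (a', b')
        V = t2.max(axis=0) + emission_matrix(
            graph.nodes[i + 1], obs_by_idx.get(i + 1, ()), params
        )
        back.append((A1, B))
    flat = int(V.argmax())  # row-major: lexicographically smallest tied pair
    a, b = np.unravel_index(flat, V.shape)
    lp = float(V[a, b])
    pairs = [(int(a), int(b))]
    for A1, B in reversed(back):
        b_prev = int(B[a, b])
        a_prev = int(A1[b_prev, a])
        pairs.append((a_prev, b_prev))
        a, b = a_prev, b_prev
    pairs.reverse()
    return pairs, lp


def path_to_haplotypes(path: DiploidPath, graph: HaplotypeGraph) -> np.ndarray:
    """(2, n_sites) phased allele array implied by a diploid path."""
    hap = np.zeros((2, len(graph.sites)), dtype=np.int8)
    for state in path.states:
        i = graph.range_index(state.range_id)
        r = graph.ranges[i]
        if r.n_sites == 0:
            continue
        for h, node_idx in enumerate(state.nodes):
            hap[h, r.site_indices] = graph.nodes[i][node_idx].alleles
    return hap


def path_to_genotypes(path: DiploidPath, graph: HaplotypeGraph) -> np.ndarray:
    """Unphased dosage vector over the graph's sites (sum of the two nodes)."""
    return path_to_haplotypes(path, graph).sum(axis=0).astype(np.int8)


def impute_taxa(
    graph: HaplotypeGraph,
    transitions: TransitionModel,
    reads_by_taxon: Mapping[str, Sequence[ReadObservation]],
    params: EmissionParams | None = None,
) -> tuple[GenotypeMatrix, dict[str, DiploidPath]]:
    """Impute every taxon: Viterbi per chromosome, concatenated.

    Taxa with zero reads are still imputed (priors + transitions alone) with
    a warning.  Returns the imputed dosage matrix (sites in graph order, with
    the graph's panel frequencies) and the per-taxon paths.
    """
    params = params or EmissionParams()
    taxa = list(reads_by_taxon)
    calls = np.zeros((len(taxa), len(graph.sites)), dtype=np.int8)
    paths: dict[str, DiploidPath] = {}
    n_ranges = max(graph.n_ranges, 1)
    for i, taxon in enumerate(taxa):
        reads = list(reads_by_taxon[taxon])
        if not reads:
            logger.warning("impute_taxa: %s has no reads; imputing from priors", taxon)
        path = viterbi_diploid(graph, transitions, reads, params, taxon=taxon)
        paths[taxon] = path
        calls[i] = path_to_genotypes(path, graph)
        logger.debug(
            "impute_taxa: %s log-prob %.2f, %.2f reads/range",
            taxon, path.log_prob, len(reads) / n_ranges,
        )
    matrix = GenotypeMatrix(list(graph.sites), taxa, calls)
    return matrix, paths


def write_imputed_vcf(
    matrix: GenotypeMatrix,
    paths: Mapping[str, DiploidPath],
    graph: HaplotypeGraph,
    path: str | Path,
) -> None:
    """Write the imputed matrix as a phased VCF (phase from the paths)."""
    from .genome_model import write_vcf

    phased = {t: path_to_haplotypes(p, graph) for t, p in paths.items()}
    write_vcf(matrix, path, phased=phased)


# ---------------------------------------------------------------------------
# Read observation I/O
# ---------------------------------------------------------------------------

def write_reads_tsv(
    reads_by_taxon: Mapping[str, Sequence[ReadObservation]], path: str | Path
) -> None:
    """TSV dialect: taxon, range_id, comma-joined site indices, allele string."""
    with open(path, "w") as fh:
        fh.write("taxon\trange_id\tsite_indices\talleles\n")
        for taxon, reads in reads_by_taxon.items():
            for r in reads:
                idx = ",".join(str(i) for i in r.site_indices)
                al = "".join(str(int(a)) for a in r.alleles)
                fh.write(f"{taxon}\t{r.range_id}\t{idx}\t{al}\n")


def read_reads_tsv(path: str | Path) -> dict[str, list[ReadObservation]]:
    out: dict[str, list[ReadObservation]] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("taxon"):
            raise ValueError(f"unexpected reads TSV header in {path}")
        for line in fh:
            taxon, rid, idx, al = line.rstrip("\n").split("\t")
            out.setdefault(taxon, []).append(
                ReadObservation(
                    int(rid),
                    np.array([int(i) for i in idx.split(",")]),
                    np.array([int(c) for c in al]),
                )
            )
    return out


def pileup_to_observations(
    pileup, graph: HaplotypeGraph
) -> dict[str, list[ReadObservation]]:
    """Convert a per-site pileup table to single-site read observations.

    ``pileup`` is a DataFrame with columns (taxon, chrom, pos, allele, count);
    ``allele`` is 0 (ref) or 1 (alt); each unit of ``count`` becomes one
    single-site observation.  Sites outside the graph are dropped (counted).
    """
    site_lookup: dict[tuple[str, int], tuple[int, int]] = {}
    for i, r in enumerate(graph.ranges):
        for local, j in enumerate(r.site_indices):
            s = graph.sites[j]
            site_lookup[(s.chrom, s.pos)] = (r.id, local)
    out: dict[str, list[ReadObservation]] = {}
    n_dropped = 0
    for row in pileup.itertuples(index=False):
        key = (str(row.chrom), int(row.pos))
        if key not in site_lookup:
            n_dropped += 1
            continue
        rid, local = site_lookup[key]
        for _ in range(int(row.count)):
            out.setdefault(str(row.taxon), []).append(
                ReadObservation(rid, np.array([local]), np.array([int(row.allele)]))
            )
    if n_dropped:
        logger.info("pileup_to_observations: %d pileup rows outside graph", n_dropped)
    return out


def observations_from_genotypes(
    matrix: GenotypeMatrix, graph: HaplotypeGraph
) -> dict[str, list[ReadObservation]]:
    """Turn panel genotype calls into per-site observations (for augmentation).

    Hom calls yield one observation of their allele; het calls yield one of
    each allele; missing calls yield nothing.  This emulates re-aligning the
    panel's own sequence to the graph to harvest adjacency information.
    """
    out: dict[str, list[ReadObservation]] = {t: [] for t in matrix.taxa}
    for r in graph.ranges:
        for local, j in enumerate(r.site_indices):
            col = matrix.calls[:, j]
            for i, taxon in enumerate(matrix.taxa):
                c = int(col[i])
                if c < 0:
                    continue
                alleles = [0] if c == 0 else [1] if c == 2 else [0, 1]
                for a in alleles:
                    out[taxon].append(
                        ReadObservation(r.id, np.array([local]), np.array([a]))
                    )
    return out
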
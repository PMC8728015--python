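"""The haplotype trellis graph and its transition model.

Each reference range is a trellis column whose nodes are that range's
consensus haplotypes.  Directed edges connect nodes of adjacent ranges on the
same chromosome; the edge weight c(h -> h') counts sampled genome copies that
carry haplotype h in one range and h' in the next.  For IBD-sampled
haplotypes this means a taxon homozygous in *both* adjacent ranges (only
consecutive homozygous ranges yield phase-certain adjacency evidence); for
fully phased genomes each phase contributes independently.

Transition probabilities are smoothed edge-count fractions; inferred
whole-genome paths can later be folded back in ("augmentation") to enrich the
adjacency information without adding any haplotype nodes.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, TYPE_CHECKING

import numpy as np

from .genome_model import GenomicInterval, VariantSite
from .haplotype_db import ConsensusHaplotype, Haplotype, _allele_string, _parse_allele_string
from .range_builder import ReferenceRange

if TYPE_CHECKING:  # pragma: no cover
    from .impute import DiploidPath

logger = logging.getLogger(__name__)


@dataclass
class HaplotypeGraph:
    """Trellis of consensus haplotype nodes with adjacency edge counts.

    ``nodes[i]`` lists the consensus haplotypes of ``ranges[i]``;
    ``edges[i]`` is the (k_i, k_{i+1}) count matrix for the boundary between
    ranges i and i+1, present only when both lie on the same chromosome
    (chromosome breaks carry no edge and reset the HMM).
    """

    ranges: list[ReferenceRange]
    sites: list[VariantSite]
    nodes: list[list[ConsensusHaplotype]]
    edges: dict[int, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.nodes) != len(self.ranges):
            raise ValueError("one node list required per range")
        for i, mat in self.edges.items():
            if mat.shape != (len(self.nodes[i]), len(self.nodes[i + 1])):
                raise ValueError(f"edge matrix {i} has wrong shape")
            if (mat < 0).any():
                raise ValueError("edge counts must be >= 0")

    @property
    def n_ranges(self) -> int:
        return len(self.ranges)

    def range_index(self, range_id: int) -> int:
        if not hasattr(self, "_rid_to_idx"):
            self._rid_to_idx = {r.id: i for i, r in enumerate(self.ranges)}
        return self._rid_to_idx[range_id]

    def chrom_blocks(self) -> list[tuple[int, int]]:
        """Half-open index runs [s, e) of consecutive same-chromosome ranges."""
        blocks: list[tuple[int, int]] = []
        s = 0
        for i in range(1, len(self.ranges) + 1):
            if i == len(self.ranges) or (
                self.ranges[i].interval.chrom != self.ranges[s].interval.chrom
            ):
                blocks.append((s, i))
                s = i
        return blocks

    def node_priors(self, i: int) -> np.ndarray:
        """Member-count-proportional node frequencies at range index i."""
        counts = np.array([n.member_count for n in self.nodes[i]], dtype=float)
        return counts / counts.sum()


@dataclass
class TransitionModel:
    """Row-stochastic transition matrices per same-chromosome boundary."""

    probs: dict[int, np.ndarray]  # boundary left-index -> (k_i, k_{i+1})
    pseudocount: float

    def __post_init__(self) -> None:
        for i, mat in self.probs.items():
            rowsum = mat.sum(axis=1)
            if not np.allclose(rowsum, 1.0, atol=1e-12):
                raise ValueError(f"transition rows at boundary {i} do not sum to 1")


def build_graph(
    consensus: Mapping[int, Sequence[ConsensusHaplotype]],
    haplotypes: Iterable[Haplotype],
    ranges: Sequence[ReferenceRange],
    sites: Sequence[VariantSite],
) -> HaplotypeGraph:
    """Assemble the trellis and count adjacency evidence.

    An edge count c(h -> h') is incremented once per sample label (taxon, or
    taxon|phase) that contributed a haplotype to cluster h at range i *and*
    to cluster h' at range i+1 on the same chromosome.
    """
    nodes: list[list[ConsensusHaplotype]] = []
    for r in ranges:
        if r.id not in consensus:
            raise ValueError(f"consensus set missing range {r.id}")
        nodes.append(list(consensus[r.id]))
    known = {r.id for r in ranges}
    for rid in consensus:
        if rid not in known:
            raise ValueError(f"consensus references unknown range {rid}")

    # (range_id -> sample label -> node index)
    membership: dict[int, dict[str, int]] = {r.id: {} for r in ranges}
    for r in ranges:
        for idx, node in enumerate(consensus[r.id]):
            for taxon in node.member_taxa:
                membership[r.id][taxon] = idx

    graph = HaplotypeGraph(list(ranges), list(sites), nodes)
    for i in range(len(ranges) - 1):
        left, right = ranges[i], ranges[i + 1]
        if left.interval.chrom != right.interval.chrom:
            continue
        mat = np.zeros((len(nodes[i]), len(nodes[i + 1])), dtype=float)
        ml, mr = membership[left.id], membership[right.id]
        for taxon, h in ml.items():
            h2 = mr.get(taxon)
            if h2 is not None:
                mat[h, h2] += 1
        graph.edges[i] = mat
    n_edges = sum(int((m > 0).sum()) for m in graph.edges.values())
    logger.info("build_graph: %d ranges, %d nonzero edges", len(ranges), n_edges)
    return graph


def transition_probs(graph: HaplotypeGraph, pseudocount: float = 0.5) -> TransitionModel:
    """Smoothed row-stochastic transition matrices from edge counts.

    The pseudocount is a *total* Dirichlet mass spread over the next range's
    nodes: P(h'|h) = (c(h->h') + a/k') / (sum_h'' c(h->h'') + a), k' being
    the node count of the next range.  ``a`` is therefore the weight, in
    observation units, given to "jump to an unobserved track" — roughly the
    per-boundary recombination mass — and does not grow with graph density
    (a per-cell pseudocount would add a*k' phantom transitions per row and
    swamp the 1-2 genome copies of evidence a sparse panel provides).  With
    all-zero counts this is uniform; with a = 0 it is the bare count
    fraction (rows with zero total would be undefined, so a > 0 is required
    then).
    """
    probs: dict[int, np.ndarray] = {}
    for i, counts in graph.edges.items():
        k_next = counts.shape[1]
        denom = counts.sum(axis=1, keepdims=True) + pseudocount
        if (denom == 0).any():
            raise ValueError(
                f"boundary {i} has a node with zero outgoing counts and "
                "pseudocount 0; use a positive pseudocount"
            )
        probs[i] = (counts + pseudocount / k_next) / denom
    return TransitionModel(probs, pseudocount)


def augment_transitions(
    graph: HaplotypeGraph, paths: Sequence["DiploidPath"]
) -> HaplotypeGraph:
    """Fold inferred diploid paths back into the edge counts.

    Each path increments, at every same-chromosome boundary, the edge of each
    of its two haplotypes by 1 (2 increments per boundary per path).  Node
    sets are never changed.  Mutates and returns ``graph``.
    """
    for path in paths:
        for state in path.states:
            i = graph.range_index(state.range_id)
            k = len(graph.nodes[i])
            if not all(0 <= h < k for h in state.nodes):
                raise ValueError(
                    f"path for {path.taxon} references unknown node at range "
                    f"{state.range_id}"
                )
        for a, b in zip(path.states[:-1], path.states[1:]):
            i = graph.range_index(a.range_id)
            if i not in graph.edges:
                continue  # chromosome break
            for h, h2 in zip(a.nodes, b.nodes):
                graph.edges[i][h, h2] += 1
    return graph


# ---------------------------------------------------------------------------
# JSON serialization (imputation does not need the panel VCF)
# ---------------------------------------------------------------------------

def graph_to_json(graph: HaplotypeGraph, path: str | Path) -> None:
    doc = {
        "format": "haplograph-graph-v1",
        "sites": [
            {
                "chrom": s.chrom, "pos": s.pos, "ref": s.ref_allele,
                "alt": s.alt_allele, "alt_freq": None
                if np.isnan(s.panel_alt_freq) else s.panel_alt_freq,
            }
            for s in graph.sites
        ],
        "ranges": [
            {
                "id": r.id, "chrom": r.interval.chrom,
                "start": r.interval.start, "end": r.interval.end,
                "site_indices": r.site_indices.tolist(),
            }
            for r in graph.ranges
        ],
        "nodes": [
            [
                {
                    "consensus_id": n.consensus_id,
                    "alleles": _allele_string(n.alleles),
                    "member_taxa": n.member_taxa,
                    "member_count": n.member_count,
                }
                for n in node_list
            ]
            for node_list in graph.nodes
        ],
        "edges": [
            {"left": i, "counts": mat.tolist()} for i, mat in sorted(graph.edges.items())
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def graph_from_json(path: str | Path) -> HaplotypeGraph:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("format") != "haplograph-graph-v1":
        raise ValueError(f"{path} is not a haplograph graph JSON")
    sites = [
        VariantSite(
            s["chrom"], s["pos"], s["ref"], s["alt"],
            float("nan") if s["alt_freq"] is None else s["alt_freq"],
        )
        for s in doc["sites"]
    ]
    ranges = [
        ReferenceRange(
            r["id"],
            GenomicInterval(r["chrom"], r["start"], r["end"]),
            np.array(r["site_indices"], dtype=np.int64),
        )
        for r in doc["ranges"]
    ]
    nodes = [
        [
            ConsensusHaplotype(
                r.id, n["consensus_id"], _parse_allele_string(n["alleles"]),
                list(n["member_taxa"]), n["member_count"],
            )
            for n in node_list
        ]
        for r, node_list in zip(ranges, doc["nodes"])
    ]
    edges = {e["left"]: np.array(e["counts"], dtype=float) for e in doc["edges"]}
    return HaplotypeGraph(ranges, sites, nodes, edges)
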
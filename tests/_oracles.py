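"""Independent oracles used by the test suite.

These deliberately avoid the implementation's recursions: the Viterbi oracle
materializes the score of *every* diploid path as a dense tensor; the UPGMA
oracle is scipy's average-linkage on the condensed distance matrix.
"""

from __future__ import annotations

import numpy as np

from haplograph.graph import HaplotypeGraph, TransitionModel
from haplograph.impute import EmissionParams, ReadObservation, emission_matrix


def enumerate_diploid_paths(
    graph: HaplotypeGraph,
    transitions: TransitionModel,
    observations: list[ReadObservation],
    params: EmissionParams,
) -> tuple[float, list[tuple[int, int]]]:
    """Brute-force argmax over all ordered-pair paths (single chromosome).

    Builds the full (k0^2, k1^2, ..., k_{n-1}^2) score tensor and takes its
    argmax, so it is exact by construction.  States are reported as unordered
    pairs like the implementation.
    """
    blocks = graph.chrom_blocks()
    assert len(blocks) == 1, "oracle handles single-chromosome graphs"
    n = graph.n_ranges
    obs_by: dict[int, list[ReadObservation]] = {}
    for o in observations:
        obs_by.setdefault(graph.range_index(o.range_id), []).append(o)
    with np.errstate(divide="ignore"):
        k2 = [len(graph.nodes[i]) ** 2 for i in range(n)]
        pi0 = np.log(graph.node_priors(0))
        E0 = emission_matrix(graph.nodes[0], obs_by.get(0, ()), params)
        full = (pi0[:, None] + pi0[None, :] + E0).reshape(k2[0])
        for i in range(n - 1):
            L = np.log(transitions.probs[i])
            pairL = (L[:, None, :, None] + L[None, :, None, :]).reshape(k2[i], k2[i + 1])
            em = emission_matrix(
                graph.nodes[i + 1], obs_by.get(i + 1, ()), params
            ).reshape(k2[i + 1])
            full = (
                full[..., None]
                + pairL.reshape((1,) * (full.ndim - 1) + (k2[i], k2[i + 1]))
                + em
            )
    best = np.unravel_index(np.argmax(full), full.shape)
    states = []
    for i, flat in enumerate(best):
        k = len(graph.nodes[i])
        states.append(tuple(sorted((int(flat) // k, int(flat) % k))))
    return float(full[best]), states


def scipy_upgma(distances: np.ndarray) -> np.ndarray:
    """Reference UPGMA linkage via scipy average-linkage."""
    from scipy.cluster.hierarchy import linkage
    from scipy.spatial.distance import squareform

    return linkage(squareform(np.asarray(distances), checks=False), method="average")


def cophenetic_matrix(Z: np.ndarray, n: int) -> np.ndarray:
    """Pairwise cophenetic distances from a linkage table."""
    from scipy.cluster.hierarchy import cophenet
    from scipy.spatial.distance import squareform

    if n == 1:
        return np.zeros((1, 1))
    return squareform(cophenet(Z))
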
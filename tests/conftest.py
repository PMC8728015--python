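"""Shared fixtures: a hand-computed toy panel and cached closed-loop runs."""

from __future__ import annotations

import numpy as np
import pytest

from haplograph.genome_model import GenomicInterval, GenotypeMatrix, VariantSite
from haplograph.graph import build_graph, transition_probs
from haplograph.haplotype_db import collapse_consensus, haplotypes_from_phased
from haplograph.impute import impute_taxa
from haplograph.range_builder import assign_sites, build_reference_ranges
from haplograph.simulate import (
    SimConfig,
    random_mating,
    simulate_founders,
    simulate_read_sets,
)

# ---------------------------------------------------------------------------
# Toy panel: 5 taxa x 6 ranges x 4 sites, every quantity hand-checkable.
#
# Ranges are 1000 bp, so the 0.001 het/bp threshold admits at most one het
# call per range.  Designed calls (dosages; -1 missing), per range:
#   T1: 0000 | 2222 | 0022 | 2000 | 0202 | 2220      (homozygous everywhere)
#   T2: 1100 | 2222 | 0022 | 0000 | 0202 | 2220      (2 hets in r0 -> fails r0)
#   T3: 0000 | 2212 | 2200 | 2000 | 1111 | 0000      (1 het in r1 -> passes,
#                                                      4 hets in r4 -> fails)
#   T4: 000. | 0000 | 0022 | 2000 | 0202 | 2220      (1 missing call in r0)
#   T5: 2222 | 2222 | 0022 | 0222 | 0202 | ....      (r5 all missing -> no hap)
#
# Hand-derived truths (see test_acceptance / test_haplotype_db):
#   haplotypes sampled: T1 6, T2 5, T3 5, T4 6, T5 5 = 27
#   het rates: T2/r0 = 0.002, T3/r1 = 0.001 (inclusive boundary), T3/r4 = 0.004
#   panel alt freq at r1 site 2 = 7/10 -> T3's tolerated het becomes allele 1
#   consensus nodes per range: 2,2,2,3,1,2 = 12, member counts
#     r0 [3,1], r1 [4,1], r2 [4,1], r3 [3,1,1], r4 [4], r5 [3,1]
#   edge-count totals per boundary: 4,5,5,4,3 (taxa IBD in both flanks)
# ---------------------------------------------------------------------------

_TOY_CALLS = {
    "T1": [0, 0, 0, 0, 2, 2, 2, 2, 0, 0, 2, 2, 2, 0, 0, 0, 0, 2, 0, 2, 2, 2, 2, 0],
    "T2": [1, 1, 0, 0, 2, 2, 2, 2, 0, 0, 2, 2, 0, 0, 0, 0, 0, 2, 0, 2, 2, 2, 2, 0],
    "T3": [0, 0, 0, 0, 2, 2, 1, 2, 2, 2, 0, 0, 2, 0, 0, 0, 1, 1, 1, 1, 0, 0, 0, 0],
    "T4": [0, 0, 0, -1, 0, 0, 0, 0, 0, 0, 2, 2, 2, 0, 0, 0, 0, 2, 0, 2, 2, 2, 2, 0],
    "T5": [2, 2, 2, 2, 2, 2, 2, 2, 0, 0, 2, 2, 0, 2, 2, 2, 0, 2, 0, 2, -1, -1, -1, -1],
}

TOY_EXPECT = {
    "n_haplotypes": 27,
    "haps_per_taxon": {"T1": 6, "T2": 5, "T3": 5, "T4": 6, "T5": 5},
    "failing_pairs": {("T2", 0), ("T3", 4), ("T5", 5)},
    "het_rates": {("T2", 0): 0.002, ("T3", 1): 0.001, ("T3", 4): 0.004},
    "n_consensus": 12,
    "nodes_per_range": [2, 2, 2, 3, 1, 2],
    "member_counts": {0: [3, 1], 1: [4, 1], 2: [4, 1], 3: [3, 1, 1], 4: [4], 5: [3, 1]},
    "boundary_totals": [4, 5, 5, 4, 3],
}


def make_toy_panel():
    genes = [GenomicInterval("chr1", 2000 * r, 2000 * r + 1000) for r in range(6)]
    ranges = build_reference_ranges(genes, {"chr1": 12000}, flank_bp=0)
    sites = [
        VariantSite("chr1", 2000 * r + off, "A", "T")
        for r in range(6)
        for off in (100, 300, 500, 700)
    ]
    taxa = list(_TOY_CALLS)
    calls = np.array([_TOY_CALLS[t] for t in taxa], dtype=np.int8)
    matrix = GenotypeMatrix(sites, taxa, calls).with_computed_freqs()
    ranges, n_unassigned = assign_sites(ranges, matrix.sites)
    assert n_unassigned == 0
    return matrix, ranges


@pytest.fixture
def toy_panel():
    return make_toy_panel()


# ---------------------------------------------------------------------------
# Closed-loop simulation runs (founders fully loaded, offspring imputed).
# Cached per (seed, coverages) at session scope since several acceptance
# checks share them.
# ---------------------------------------------------------------------------

_CLOSED_LOOP_CACHE: dict = {}


def closed_loop_run(seed: int, coverages: tuple[float, ...], **overrides):
    """Simulate, build the founder-loaded graph, impute offspring.

    Returns a dict with the config, truth dosages, panel frequencies and
    imputed matrices per coverage.  Noiseless reads: the regime isolates the
    graph/HMM stages from base-error modelling.
    """
    key = (seed, coverages, tuple(sorted(overrides.items())))
    if key in _CLOSED_LOOP_CACHE:
        return _CLOSED_LOOP_CACHE[key]
    cfg = SimConfig(seed=seed, seq_error=0.0, **overrides)
    panel = simulate_founders(cfg)
    offspring, origins = random_mating(panel.founders, panel.ranges, cfg)
    haps = haplotypes_from_phased(panel.founders, panel.ranges)
    consensus = collapse_consensus(haps, panel.ranges)
    graph = build_graph(consensus, haps, panel.ranges, panel.matrix.sites)
    trans = transition_probs(graph)
    truth = np.stack([o.dosages() for o in offspring])
    imputed = {}
    for cov in coverages:
        reads = simulate_read_sets(offspring, panel.ranges, cov, cfg)
        matrix, _ = impute_taxa(graph, trans, reads)
        assert matrix.taxa == [o.taxon for o in offspring]
        imputed[cov] = matrix
    result = {
        "config": cfg,
        "panel": panel,
        "offspring": offspring,
        "origins": origins,
        "graph": graph,
        "transitions": trans,
        "truth": truth,
        "freqs": panel.matrix.alt_freqs(),
        "imputed": imputed,
    }
    _CLOSED_LOOP_CACHE[key] = result
    return result


@pytest.fixture(scope="session")
def closed_loop_main():
    """The principal closed-loop run: 20 founders, 100 offspring, 5 generations."""
    return closed_loop_run(11, (0.5, 1.0, 5.0, 10.0))


@pytest.fixture
def small_sim():
    """A miniature simulation for fast unit-level checks."""
    cfg = SimConfig(
        seed=7, n_founders=6, pop_size=12, generations=2, n_chrom=2,
        ranges_per_chrom=5, sites_per_range=8, seq_error=0.0, n_qtl=10,
    )
    panel = simulate_founders(cfg)
    offspring, origins = random_mating(panel.founders, panel.ranges, cfg)
    return cfg, panel, offspring, origins
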
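"""Forward simulator: founder panels, random mating, skim-sequencing reads.

The simulator emulates the validation design of the closed-loop experiment:
a small set of fully phased founders populates the graph, descendants are
produced by several generations of random mating with recombination, and
read evidence is drawn at skim-sequencing coverages.  Recombination is
modelled at reference-range boundaries only (the trellis is the unit of
inference, so finer-scale crossovers are invisible to it), and there is no
mutation, so every offspring haplotype is a mosaic of founder haplotypes —
the closed-system assumption under which the graph contains every truth
haplotype.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .genome_model import GenomicInterval, GenotypeMatrix, PhasedGenome, VariantSite
from .impute import ReadObservation
from .range_builder import ReferenceRange, assign_sites, build_reference_ranges

logger = logging.getLogger(__name__)

_DEFAULT_COVERAGES = (0.1, 0.5, 1.0, 5.0, 10.0)


@dataclass
class SimConfig:
    """Study-condition knobs for the forward simulation.

    Defaults follow the validation design: 20 founders, constant population
    size 100, five generations of random mating, and the coverage grid
    0.1/0.5/1/5/10x.  Genome layout (chromosome and range counts, sites per
    range) and the recombination/error rates are desk-scale choices
    documented in docs/methods.md.
    """

    n_founders: int = 20
    pop_size: int = 100
    generations: int = 5
    n_chrom: int = 2
    ranges_per_chrom: int = 30
    sites_per_range: int = 80
    alt_freq_range: tuple[float, float] = (0.05, 0.5)
    switch_prob: float = 0.01  # recombination per range boundary
    coverages: tuple[float, ...] = _DEFAULT_COVERAGES
    read_len_sites: int = 3
    seq_error: float = 0.002
    heritability: float = 0.5
    n_qtl: int = 50
    seed: int = 0
    gene_len_bp: int = 2000
    gene_gap_bp: int = 4000
    flank_bp: int = 1000

    def __post_init__(self) -> None:
        for p in (self.switch_prob, self.seq_error, self.heritability, *self.alt_freq_range):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability out of [0,1]: {p}")
        for c in (self.n_founders, self.pop_size, self.n_chrom,
                  self.ranges_per_chrom, self.sites_per_range, self.read_len_sites):
            if c < 1:
                raise ValueError("counts must be positive")

    def rng(self, salt: int | tuple[int, ...] = 0) -> np.random.Generator:
        extra = tuple(salt) if isinstance(salt, tuple) else (salt,)
        return np.random.default_rng(np.random.SeedSequence((self.seed, *extra)))


@dataclass
class SimulatedPanel:
    """Founders plus the genome layout they segregate on."""

    founders: list[PhasedGenome]
    matrix: GenotypeMatrix  # collapsed unphased founder calls, freqs filled
    ranges: list[ReferenceRange]
    genes: list[GenomicInterval]
    chrom_lengths: dict[str, int]


def _layout(config: SimConfig, rng: np.random.Generator):
    """Genes, ranges and site positions for the synthetic genome.

    Genes are spaced so that flank-expanded ranges neither merge nor clip:
    the range structure is exactly one range per gene.
    """
    pitch = config.gene_len_bp + config.gene_gap_bp
    genes: list[GenomicInterval] = []
    chrom_lengths: dict[str, int] = {}
    for c in range(config.n_chrom):
        chrom = f"chr{c + 1}"
        for g in range(config.ranges_per_chrom):
            start = config.flank_bp + 1000 + g * pitch
            genes.append(GenomicInterval(chrom, start, start + config.gene_len_bp))
        chrom_lengths[chrom] = config.flank_bp + 2000 + config.ranges_per_chrom * pitch
    ranges = build_reference_ranges(genes, chrom_lengths, config.flank_bp)
    sites: list[VariantSite] = []
    bases = np.array(list("ACGT"))
    for r in ranges:
        pos = np.sort(
            rng.choice(
                np.arange(r.interval.start, r.interval.end),
                size=config.sites_per_range,
                replace=False,
            )
        )
        for p in pos:
            ref, alt = rng.choice(4, size=2, replace=False)
            sites.append(
                VariantSite(r.interval.chrom, int(p), str(bases[ref]), str(bases[alt]))
            )
    ranges, n_un = assign_sites(ranges, sites)
    assert n_un == 0
    return genes, ranges, sites, chrom_lengths


def simulate_founders(config: SimConfig) -> SimulatedPanel:
    """Draw founder genomes: per-site alt frequency, then Bernoulli alleles.

    Alt frequencies are uniform on ``alt_freq_range``; each founder haplotype
    allele is an independent Bernoulli draw, so founders are in
    Hardy-Weinberg proportions at the drawn frequencies.
    """
    rng = config.rng(salt=1)
    genes, ranges, sites, chrom_lengths = _layout(config, rng)
    lo, hi = config.alt_freq_range
    freqs = rng.uniform(lo, hi, size=len(sites)) if hi > lo else np.full(len(sites), lo)
    founders = []
    for f in range(config.n_founders):
        hap = (rng.random((2, len(sites))) < freqs[None, :]).astype(np.int8)
        founders.append(PhasedGenome(f"F{f:02d}", hap))
    calls = np.stack([g.dosages() for g in founders])
    matrix = GenotypeMatrix(sites, [g.taxon for g in founders], calls).with_computed_freqs()
    return SimulatedPanel(founders, matrix, ranges, genes, chrom_lengths)


def _chrom_block_bounds(ranges: Sequence[ReferenceRange]) -> list[tuple[int, int]]:
    blocks, s = [], 0
    for i in range(1, len(ranges) + 1):
        if i == len(ranges) or ranges[i].interval.chrom != ranges[s].interval.chrom:
            blocks.append((s, i))
            s = i
    return blocks


def _gamete(
    parent: PhasedGenome,
    ranges: Sequence[ReferenceRange],
    origin: np.ndarray,
    switch_prob: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """One recombinant haplotype: a Markov walk over the parent's two copies.

    Returns (allele vector over all sites, founder-haplotype origin per range).
    """
    n_sites = parent.haplotypes.shape[1]
    hap = np.zeros(n_sites, dtype=np.int8)
    gorigin = np.zeros(len(ranges), dtype=np.int32)
    for s, e in _chrom_block_bounds(ranges):
        h = int(rng.integers(2))  # chromosome start: fresh draw
        for i in range(s, e):
            if i > s and rng.random() < switch_prob:
                h = 1 - h
            idx = ranges[i].site_indices
            hap[idx] = parent.haplotypes[h, idx]
            gorigin[i] = origin[h, i]
    return hap, gorigin


def random_mating(
    founders: Sequence[PhasedGenome],
    ranges: Sequence[ReferenceRange],
    config: SimConfig,
) -> tuple[list[PhasedGenome], np.ndarray]:
    """Evolve the population by random mating at constant size.

    Each offspring draws two distinct parents uniformly; each gamete starts
    on a random parental copy per chromosome and switches copies at each
    range boundary with probability ``switch_prob``.  Returns the final
    generation and a ``(n, 2, n_ranges)`` array tracing each genome copy back
    to a founder haplotype index (2*f + phase) for lineage bookkeeping.
    """
    if len(founders) < 2:
        raise ValueError("random mating requires at least 2 founders")
    rng = config.rng(salt=2)
    pop = list(founders)
    origins = np.stack(
        [
            np.stack([np.full(len(ranges), 2 * f + h, dtype=np.int32) for h in range(2)])
            for f in range(len(founders))
        ]
    )
    if config.generations == 0:
        return pop, origins
    for gen in range(config.generations):
        new_pop: list[PhasedGenome] = []
        new_origins = np.zeros((config.pop_size, 2, len(ranges)), dtype=np.int32)
        for i in range(config.pop_size):
            pa, pb = rng.choice(len(pop), size=2, replace=False)
            hap_a, or_a = _gamete(pop[pa], ranges, origins[pa], config.switch_prob, rng)
            hap_b, or_b = _gamete(pop[pb], ranges, origins[pb], config.switch_prob, rng)
            new_pop.append(
                PhasedGenome(f"G{gen + 1}_{i:03d}", np.stack([hap_a, hap_b]))
            )
            new_origins[i] = np.stack([or_a, or_b])
        pop, origins = new_pop, new_origins
    return pop, origins


def simulate_reads(
    genome: PhasedGenome,
    ranges: Sequence[ReferenceRange],
    coverage: float,
    config: SimConfig,
    rng: np.random.Generator,
) -> list[ReadObservation]:
    """Skim-sequencing reads in variant space for one genome.

    Per range, the read count is Poisson(coverage * n_sites / read_len);
    each read picks one of the two true haplotypes at random, covers a
    contiguous window of ``read_len_sites`` sites, and flips each observed
    allele independently with probability ``seq_error``.
    """
    if coverage < 0:
        raise ValueError("coverage must be >= 0")
    out: list[ReadObservation] = []
    if coverage == 0:
        return out
    for r in ranges:
        n_sites = r.n_sites
        if n_sites == 0:
            continue
        read_len = min(config.read_len_sites, n_sites)
        n_reads = rng.poisson(coverage * n_sites / read_len)
        for _ in range(n_reads):
            h = int(rng.integers(2))
            start = int(rng.integers(0, n_sites - read_len + 1))
            local = np.arange(start, start + read_len)
            alleles = genome.haplotypes[h, r.site_indices[local]].copy()
            if config.seq_error > 0:
                flip = rng.random(read_len) < config.seq_error
                alleles[flip] = 1 - alleles[flip]
            out.append(ReadObservation(r.id, local, alleles))
    return out


def simulate_read_sets(
    genomes: Sequence[PhasedGenome],
    ranges: Sequence[ReferenceRange],
    coverage: float,
    config: SimConfig,
    salt: int = 3,
) -> dict[str, list[ReadObservation]]:
    """Reads for a whole population at one coverage, reproducibly seeded."""
    rng = config.rng(salt=(salt, int(round(coverage * 1000))))
    return {
        g.taxon: simulate_reads(g, ranges, coverage, config, rng) for g in genomes
    }


def simulate_phenotypes(
    matrix: GenotypeMatrix, config: SimConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Additive phenotypes: y = g + e with Var(g)/Var(y) ~ heritability.

    ``n_qtl`` sites are drawn without replacement with standard-normal
    additive effects; the noise is rescaled (and decorrelated from g) so the
    realized heritability matches the configured value in-sample.  Returns
    (phenotypes, qtl site indices, effects).
    """
    if config.n_qtl > matrix.n_sites:
        raise ValueError("n_qtl exceeds site count")
    rng = config.rng(salt=4)
    qtl = rng.choice(matrix.n_sites, size=config.n_qtl, replace=False)
    effects = rng.normal(size=config.n_qtl)
    dos = matrix.calls[:, qtl].astype(float)
    dos[dos < 0] = np.nan
    g = np.nansum(dos * effects[None, :], axis=1)
    g = g - g.mean()
    h2 = config.heritability
    n = len(g)
    if h2 >= 1.0:
        return g, qtl, effects
    e = rng.normal(size=n)
    if h2 <= 0.0:
        return e, qtl, effects
    var_g = g.var()
    # decorrelate noise from g in-sample, then scale to the exact variance
    if var_g > 0:
        e = e - (e @ g) / (g @ g) * g
    e = e / e.std() * np.sqrt(var_g * (1 - h2) / h2)
    return g + e, qtl, effects
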
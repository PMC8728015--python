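"""Haplotype sampling from runs of homozygosity and consensus collapsing.

In a heterozygous diploid panel, a reference range in which a taxon is
(nearly) homozygous carries two identical-by-descent genome copies, so the
haplotype can be read directly off the genotype calls without statistical
phasing.  A taxon passes for a range when its heterozygosity rate — het calls
per base pair of the range — is at or below a threshold (default 0.001/bp,
tolerating de-novo mutations and call errors).  Sampled haplotypes are then
clustered per range with UPGMA on pairwise mismatch distances and collapsed
into consensus haplotypes at a maximum divergence (default 0.001).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .genome_model import MISSING, GenotypeMatrix, PhasedGenome
from .range_builder import ReferenceRange

logger = logging.getLogger(__name__)

#: allele sentinel for a missing call inside a sampled haplotype
HAP_MISSING: int = -1


@dataclass
class Haplotype:
    """One sampled allele vector over a range's sites, with its origin."""

    range_id: int
    taxon: str
    alleles: np.ndarray  # int8, entries in {0, 1, HAP_MISSING}

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int8)


@dataclass
class HetRateTable:
    """Heterozygous-call counts and per-bp rates per (taxon, range)."""

    taxa: list[str]
    range_ids: list[int]
    het_counts: np.ndarray  # (n_taxa, n_ranges) int
    nonmissing_counts: np.ndarray  # (n_taxa, n_ranges) int
    range_len_bp: np.ndarray  # (n_ranges,) int

    @property
    def rates(self) -> np.ndarray:
        return self.het_counts / self.range_len_bp[None, :].astype(float)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.rates, index=self.taxa, columns=self.range_ids)


@dataclass
class ConsensusHaplotype:
    """Representative allele vector of a cluster of near-identical haplotypes."""

    range_id: int
    consensus_id: int
    alleles: np.ndarray  # int8, entries in {0, 1}; no missing after collapse
    member_taxa: list[str]
    member_count: int

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if self.member_count < 1:
            raise ValueError("member_count must be >= 1")


def het_rate(matrix: GenotypeMatrix, ranges: Sequence[ReferenceRange]) -> HetRateTable:
    """Count het calls per (taxon, range); rate uses the range's bp length."""
    n_taxa = matrix.n_taxa
    het = np.zeros((n_taxa, len(ranges)), dtype=np.int64)
    nonmiss = np.zeros_like(het)
    lens = np.zeros(len(ranges), dtype=np.int64)
    for k, r in enumerate(ranges):
        lens[k] = r.length_bp
        if r.n_sites:
            block = matrix.calls[:, r.site_indices]
            het[:, k] = (block == 1).sum(axis=1)
            nonmiss[:, k] = (block != MISSING).sum(axis=1)
    return HetRateTable(list(matrix.taxa), [r.id for r in ranges], het, nonmiss, lens)


def sample_ibd_haplotypes(
    matrix: GenotypeMatrix,
    ranges: Sequence[ReferenceRange],
    threshold: float = 0.001,
) -> list[Haplotype]:
    """Sample one haplotype per (taxon, range) classified as IBD.

    A (taxon, range) passes when its het rate is <= ``threshold`` (inclusive)
    and it has at least one non-missing call.  Alleles follow the homozygous
    calls; tolerated sub-threshold het calls take the panel major allele
    (they are treated as noise, not signal); missing calls stay missing and
    are filled with the cluster majority at collapse time.  Deterministic.
    """
    table = het_rate(matrix, ranges)
    rates = table.rates
    freqs = matrix.alt_freqs()
    major_is_alt = freqs > 0.5  # exactly 0.5 -> ref, consistent with class convention
    out: list[Haplotype] = []
    n_het_filled = 0
    for k, r in enumerate(ranges):
        if r.n_sites == 0:
            continue
        block = matrix.calls[:, r.site_indices]
        major = np.where(major_is_alt[r.site_indices], 1, 0).astype(np.int8)
        for i, taxon in enumerate(matrix.taxa):
            if rates[i, k] > threshold or table.nonmissing_counts[i, k] == 0:
                continue
            calls = block[i]
            alleles = np.full(r.n_sites, HAP_MISSING, dtype=np.int8)
            alleles[calls == 0] = 0
            alleles[calls == 2] = 1
            het_mask = calls == 1
            alleles[het_mask] = major[het_mask]
            n_het_filled += int(het_mask.sum())
            out.append(Haplotype(r.id, taxon, alleles))
    if n_het_filled:
        logger.info(
            "sample_ibd_haplotypes: %d tolerated het sites set to panel major allele",
            n_het_filled,
        )
    logger.info("sample_ibd_haplotypes: %d haplotypes sampled", len(out))
    return out


def haplotypes_from_phased(
    genomes: Sequence[PhasedGenome], ranges: Sequence[ReferenceRange]
) -> list[Haplotype]:
    """Load both phases of fully phased genomes as haplotypes.

    Each phase is entered under its own sample label (``taxon|h1``/``|h2``)
    so adjacent-range co-occurrence — and hence graph edge evidence — is
    tracked per genome copy.
    """
    out: list[Haplotype] = []
    for g in genomes:
        for h, suffix in enumerate(("h1", "h2")):
            label = f"{g.taxon}|{suffix}"
            for r in ranges:
                if r.n_sites == 0:
                    continue
                out.append(Haplotype(r.id, label, g.haplotypes[h, r.site_indices]))
    return out


def haplotype_distance(h1: Haplotype, h2: Haplotype) -> float:
    """Mismatch proportion over sites non-missing in both haplotypes."""
    if h1.range_id != h2.range_id:
        raise ValueError(
            f"haplotypes from different ranges: {h1.range_id} vs {h2.range_id}"
        )
    comparable = (h1.alleles != HAP_MISSING) & (h2.alleles != HAP_MISSING)
    n = int(comparable.sum())
    if n == 0:
        logger.debug("haplotype_distance: no comparable sites, returning 0")
        return 0.0
    return float((h1.alleles[comparable] != h2.alleles[comparable]).mean())


def pairwise_distances(haps: Sequence[Haplotype]) -> np.ndarray:
    n = len(haps)
    d = np.zeros((n, n), dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = haplotype_distance(haps[i], haps[j])
    return d


def upgma_cluster(distances: np.ndarray) -> np.ndarray:
    """UPGMA agglomeration of a square symmetric distance matrix.

    Returns a scipy-style linkage array ``(n-1, 4)``: each row is
    ``[id_a, id_b, merge_height, cluster_size]`` with new clusters numbered
    ``n, n+1, ...``.  New distances are size-weighted arithmetic means, so
    merge heights are non-decreasing.  When several pairs tie at the minimum
    distance, the pair whose smallest original member ids are lexicographically
    least is merged — a reproducibility rule.
    """
    d = np.asarray(distances, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if np.isnan(d).any():
        raise ValueError("NaN in distance matrix")
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    n = d.shape[0]
    if n == 1:
        return np.empty((0, 4), dtype=float)

    # active cluster id -> (size, smallest original leaf id)
    active: dict[int, tuple[int, int]] = {i: (1, i) for i in range(n)}
    dist: dict[tuple[int, int], float] = {
        (i, j): d[i, j] for i in range(n) for j in range(i + 1, n)
    }
    Z = np.zeros((n - 1, 4), dtype=float)
    next_id = n
    for step in range(n - 1):
        best = None
        for (i, j), v in dist.items():
            key = (v, min(active[i][1], active[j][1]), max(active[i][1], active[j][1]))
            if best is None or key < best[0]:
                best = (key, i, j)
        (_, _, _), i, j = best
        h = dist[(i, j)]
        si, mi = active[i]
        sj, mj = active[j]
        Z[step] = (i, j, h, si + sj)
        new = next_id
        next_id += 1
        del dist[(i, j)]
        for k in list(active):
            if k in (i, j):
                continue
            dik = dist.pop((min(i, k), max(i, k)))
            djk = dist.pop((min(j, k), max(j, k)))
            dist[(min(new, k), max(new, k))] = (si * dik + sj * djk) / (si + sj)
        del active[i], active[j]
        active[new] = (si + sj, min(mi, mj))
    return Z


def _flat_clusters(Z: np.ndarray, n: int, max_height: float) -> np.ndarray:
    """Cut a linkage so clusters contain only merges at height <= max_height."""
    from scipy.cluster.hierarchy import fcluster

    if n == 1:
        return np.array([1])
    return fcluster(Z, t=max_height, criterion="distance")


def collapse_consensus(
    haplotypes: Iterable[Haplotype],
    ranges: Sequence[ReferenceRange],
    max_divergence: float = 0.001,
) -> dict[int, list[ConsensusHaplotype]]:
    """Collapse sampled haplotypes into per-range consensus haplotypes.

    Per range: UPGMA on pairwise distances, cut so every within-cluster merge
    is at height <= ``max_divergence``; the consensus allele at each site is
    the majority over members' non-missing alleles, ties going to the
    reference allele (0).  Ranges with no sampled haplotype (including
    zero-site ranges) get a single all-reference placeholder node so path
    continuity is preserved.  Returned per-range lists are ordered by
    consensus_id.
    """
    by_range: dict[int, list[Haplotype]] = {}
    for h in haplotypes:
        by_range.setdefault(h.range_id, []).append(h)

    out: dict[int, list[ConsensusHaplotype]] = {}
    for r in ranges:
        haps = by_range.get(r.id, [])
        if not haps:
            n_sites = max(r.n_sites, 0)
            out[r.id] = [
                ConsensusHaplotype(
                    r.id, 0, np.zeros(n_sites, dtype=np.int8), [], 1
                )
            ]
            continue
        # stable order: by taxon label, for deterministic clustering input
        haps = sorted(haps, key=lambda h: h.taxon)
        d = pairwise_distances(haps)
        Z = upgma_cluster(d)
        labels = _flat_clusters(Z, len(haps), max_divergence)
        clusters: dict[int, list[int]] = {}
        for idx, lab in enumerate(labels):
            clusters.setdefault(int(lab), []).append(idx)
        nodes: list[ConsensusHaplotype] = []
        # deterministic node order: by smallest member index
        for cid, members in enumerate(sorted(clusters.values(), key=min)):
            stack = np.stack([haps[m].alleles for m in members])
            alt_votes = (stack == 1).sum(axis=0)
            ref_votes = (stack == 0).sum(axis=0)
            consensus = (alt_votes > ref_votes).astype(np.int8)  # tie -> ref
            node = ConsensusHaplotype(
                r.id,
                cid,
                consensus,
                sorted(haps[m].taxon for m in members),
                len(members),
            )
            for m in members:
                dmc = haplotype_distance(haps[m], Haplotype(r.id, "_c", consensus))
                if dmc > max_divergence and len(members) > 1:
                    logger.warning(
                        "range %d: member %s diverges %.4g from consensus",
                        r.id, haps[m].taxon, dmc,
                    )
            nodes.append(node)
        out[r.id] = nodes
    return out


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def _allele_string(alleles: np.ndarray) -> str:
    return "".join("." if a == HAP_MISSING else str(int(a)) for a in alleles)


def _parse_allele_string(s: str) -> np.ndarray:
    return np.array([HAP_MISSING if c == "." else int(c) for c in s], dtype=np.int8)


def write_haplotypes_tsv(haplotypes: Iterable[Haplotype], path: str | Path) -> None:
    """Serialize haplotypes as TSV: range_id, taxon, allele string."""
    with open(path, "w") as fh:
        fh.write("range_id\ttaxon\talleles\n")
        for h in haplotypes:
            fh.write(f"{h.range_id}\t{h.taxon}\t{_allele_string(h.alleles)}\n")


def read_haplotypes_tsv(path: str | Path) -> list[Haplotype]:
    out: list[Haplotype] = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("range_id"):
            raise ValueError(f"unexpected haplotype TSV header in {path}")
        for line in fh:
            rid, taxon, alleles = line.rstrip("\n").split("\t")
            out.append(Haplotype(int(rid), taxon, _parse_allele_string(alleles)))
    return out
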
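"""Reference-range construction: genes + flanks, merged, with sites assigned.

A reference range is one column of the haplotype trellis.  Ranges are genic
intervals expanded by a flank, clipped to the chromosome, with overlapping or
abutting intervals merged; ids are consecutive in genomic order.
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .genome_model import GenomicInterval, VariantSite

logger = logging.getLogger(__name__)


@dataclass
class ReferenceRange:
    """A trellis column: an interval plus the indices of the sites inside it."""

    id: int
    interval: GenomicInterval
    site_indices: np.ndarray = field(default_factory=lambda: np.array([], dtype=np.int64))

    def __post_init__(self) -> None:
        self.site_indices = np.asarray(self.site_indices, dtype=np.int64)

    @property
    def n_sites(self) -> int:
        return len(self.site_indices)

    @property
    def length_bp(self) -> int:
        return self.interval.length


def build_reference_ranges(
    genes: Sequence[GenomicInterval],
    chrom_lengths: Mapping[str, int],
    flank_bp: int = 1000,
) -> list[ReferenceRange]:
    """Expand genes by ``flank_bp``, clip to the chromosome, merge, number.

    Overlapping *or abutting* expanded intervals are merged (abutting merges
    avoid zero-gap ranges with no inter-range sites).  Ids are assigned in
    (chrom, start) order.
    """
    if flank_bp < 0:
        raise ValueError("flank_bp must be >= 0")
    expanded: list[GenomicInterval] = []
    for g in genes:
        if g.chrom not in chrom_lengths:
            raise ValueError(f"gene on unknown chromosome: {g.chrom}")
        start = max(0, g.start - flank_bp)
        end = min(chrom_lengths[g.chrom], g.end + flank_bp)
        expanded.append(GenomicInterval(g.chrom, start, end))
    expanded.sort()

    merged: list[GenomicInterval] = []
    for iv in expanded:
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
            last = merged[-1]
            merged[-1] = GenomicInterval(last.chrom, last.start, max(last.end, iv.end))
        else:
            merged.append(iv)
    return [ReferenceRange(i, iv) for i, iv in enumerate(merged)]


def assign_sites(
    ranges: Sequence[ReferenceRange], sites: Sequence[VariantSite]
) -> tuple[list[ReferenceRange], int]:
    """Assign each site to the (unique) range containing it.

    Ranges are half-open, so a site at a range's end coordinate is outside it.
    Sites falling between ranges are counted as unassigned and logged; ranges
    with zero sites are retained (they become placeholder trellis columns).
    Returns the ranges (with ``site_indices`` filled) and the unassigned count.
    """
    by_chrom: dict[str, list[ReferenceRange]] = {}
    for r in ranges:
        by_chrom.setdefault(r.interval.chrom, []).append(r)
    starts = {c: [r.interval.start for r in rs] for c, rs in by_chrom.items()}

    assigned: dict[int, list[int]] = {r.id: [] for r in ranges}
    n_unassigned = 0
    for j, site in enumerate(sites):
        rs = by_chrom.get(site.chrom)
        if not rs:
            n_unassigned += 1
            continue
        k = bisect_right(starts[site.chrom], site.pos) - 1
        if k >= 0 and site.pos < rs[k].interval.end:
            assigned[rs[k].id].append(j)
        else:
            n_unassigned += 1
    if n_unassigned:
        logger.info("assign_sites: %d sites fall outside all ranges", n_unassigned)
    out = [
        ReferenceRange(r.id, r.interval, np.array(assigned[r.id], dtype=np.int64))
        for r in ranges
    ]
    return out, n_unassigned


def ranges_to_bed(ranges: Sequence[ReferenceRange], path: str | Path) -> None:
    """Export ranges as BED4 with the range id in column 4."""
    with open(path, "w") as fh:
        for r in ranges:
            iv = r.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{r.id}\n")
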
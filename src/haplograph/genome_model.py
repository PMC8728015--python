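"""Core domain types and standard-format I/O (VCF, BED/GFF3).

Coordinates are 0-based half-open everywhere inside the package; conversion
to/from 1-based happens only at the VCF and GFF3 boundaries.  Genotypes are
stored as alternate-allele dosages (0 = hom-ref, 1 = het, 2 = hom-alt) with
``MISSING`` (-1) as the sentinel for no-calls.  Only biallelic SNPs enter the
model; everything else is skipped and counted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: dosage sentinel for a missing diploid call
MISSING: int = -1

_BASES = frozenset("ACGT")


class EmptyInputError(ValueError):
    """Raised when an input file yields no usable records."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval ``[start, end)`` on ``chrom``."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.end <= self.start:
            raise ValueError(f"empty/inverted interval: {self.start}..{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end


@dataclass(frozen=True)
class VariantSite:
    """A biallelic SNP with its alternate-allele frequency in the panel."""

    chrom: str
    pos: int  # 0-based
    ref_allele: str
    alt_allele: str
    panel_alt_freq: float = float("nan")

    def __post_init__(self) -> None:
        if self.ref_allele not in _BASES or self.alt_allele not in _BASES:
            raise ValueError(
                f"non-SNP alleles {self.ref_allele}/{self.alt_allele} at "
                f"{self.chrom}:{self.pos}"
            )
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"ref == alt at {self.chrom}:{self.pos}")


@dataclass
class GenotypeMatrix:
    """Unphased diploid calls for ``taxa`` over ``sites``.

    ``calls`` is an ``(n_taxa, n_sites)`` int8 array of dosages with
    ``MISSING`` for no-calls.
    """

    sites: list[VariantSite]
    taxa: list[str]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.taxa), len(self.sites)):
            raise ValueError(
                f"calls shape {self.calls.shape} inconsistent with "
                f"{len(self.taxa)} taxa x {len(self.sites)} sites"
            )
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("calls must be in {0,1,2,MISSING}")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def positions(self) -> np.ndarray:
        return np.array([s.pos for s in self.sites], dtype=np.int64)

    def chroms(self) -> np.ndarray:
        return np.array([s.chrom for s in self.sites])

    def alt_freqs(self) -> np.ndarray:
        return np.array([s.panel_alt_freq for s in self.sites], dtype=float)

    def compute_alt_freqs(self) -> np.ndarray:
        """Alt-allele frequency per site over non-missing calls.

        freq = (het + 2*hom_alt) / (2 * non_missing); NaN if all missing.
        """
        obs = self.calls != MISSING
        n_obs = obs.sum(axis=0)
        alt = np.where(obs, self.calls, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = alt / (2.0 * n_obs)
        return np.where(n_obs > 0, freq, np.nan)

    def with_computed_freqs(self) -> "GenotypeMatrix":
        freqs = self.compute_alt_freqs()
        sites = [
            VariantSite(s.chrom, s.pos, s.ref_allele, s.alt_allele, float(f))
            for s, f in zip(self.sites, freqs)
        ]
        return GenotypeMatrix(sites, list(self.taxa), self.calls.copy())


@dataclass
class PhasedGenome:
    """Truth object: two genome-wide haplotype allele vectors for one taxon.

    ``haplotypes`` has shape ``(2, n_sites)`` with entries in {0, 1}; per-range
    vectors are obtained by slicing with a range's ``site_indices``.
    """

    taxon: str
    haplotypes: np.ndarray

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        if self.haplotypes.ndim != 2 or self.haplotypes.shape[0] != 2:
            raise ValueError("haplotypes must have shape (2, n_sites)")
        if not np.isin(self.haplotypes, (0, 1)).all():
            raise ValueError("haplotype alleles must be 0 (ref) or 1 (alt)")

    def range_haplotypes(self, site_indices: np.ndarray) -> np.ndarray:
        return self.haplotypes[:, site_indices]

    def dosages(self) -> np.ndarray:
        return self.haplotypes.sum(axis=0).astype(np.int8)


# ---------------------------------------------------------------------------
# VCF I/O
# ---------------------------------------------------------------------------

def read_vcf(path: str | Path, max_missing_frac: float = 0.5) -> GenotypeMatrix:
    """Read a VCF 4.x into a :class:`GenotypeMatrix`.

    Multiallelic records and non-SNPs are skipped (counted to the log).
    Sites missing in more than ``max_missing_frac`` of taxa are dropped with a
    warning.  Alternate-allele frequencies are computed over non-missing
    calls.  Non-diploid GT fields are an input error.
    """
    from cyvcf2 import VCF

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)

    vcf = VCF(str(path))
    taxa = list(vcf.samples)
    records: list[tuple[str, int, str, str, np.ndarray]] = []
    n_skipped = 0
    for rec in vcf:
        if not rec.is_snp or len(rec.ALT) != 1:
            n_skipped += 1
            continue
        gts = rec.genotypes
        for g in gts:
            if len(g) != 3:  # [allele_a, allele_b, phased]
                raise ValueError(
                    f"non-diploid genotype at {rec.CHROM}:{rec.POS}"
                )
        gt_types = rec.gt_types  # 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
        dosage = np.select(
            [gt_types == 0, gt_types == 1, gt_types == 3],
            [0, 1, 2],
            default=MISSING,
        ).astype(np.int8)
        records.append((rec.CHROM, rec.POS - 1, rec.REF, rec.ALT[0], dosage))
    if n_skipped:
        logger.info("read_vcf: skipped %d non-biallelic-SNP records", n_skipped)
    if not records:
        raise EmptyInputError(f"no biallelic SNPs in {path}")

    records.sort(key=lambda r: (r[0], r[1]))
    calls = np.stack([r[4] for r in records], axis=1)
    sites = [VariantSite(c, p, ref, alt) for c, p, ref, alt, _ in records]
    matrix = GenotypeMatrix(sites, taxa, calls)

    miss_frac = (matrix.calls == MISSING).mean(axis=0)
    keep = miss_frac <= max_missing_frac
    if not keep.all():
        logger.warning(
            "read_vcf: dropped %d sites missing in >%.0f%% of taxa",
            int((~keep).sum()), 100 * max_missing_frac,
        )
        matrix = GenotypeMatrix(
            [s for s, k in zip(matrix.sites, keep) if k],
            taxa,
            matrix.calls[:, keep],
        )
    return matrix.with_computed_freqs()


_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(
    matrix: GenotypeMatrix,
    path: str | Path,
    phased: Mapping[str, np.ndarray] | None = None,
    chrom_lengths: Mapping[str, int] | None = None,
) -> None:
    """Write a VCF 4.2 (positions emitted 1-based).

    ``phased`` maps taxon name to a ``(2, n_sites)`` haplotype-allele array;
    such taxa get ``|``-separated GTs, all others ``/``-separated dosage GTs.
    """
    if matrix.n_sites == 0:
        raise ValueError("cannot write an empty site list")
    phased = phased or {}
    path = Path(path)
    chrom_order: list[str] = []
    for s in matrix.sites:
        if s.chrom not in chrom_order:
            chrom_order.append(s.chrom)
    lengths = {
        c: (chrom_lengths or {}).get(
            c, max(s.pos for s in matrix.sites if s.chrom == c) + 1
        )
        for c in chrom_order
    }
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=haplograph\n")
        for c in chrom_order:
            fh.write(f"##contig=<ID={c},length={lengths[c]}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
        fh.write("\t".join(cols + matrix.taxa) + "\n")
        for j, site in enumerate(matrix.sites):
            fields = [
                site.chrom, str(site.pos + 1), ".", site.ref_allele,
                site.alt_allele, ".", "PASS",
                "." if np.isnan(site.panel_alt_freq) else f"AF={site.panel_alt_freq:.6g}",
                "GT",
            ]
            for i, taxon in enumerate(matrix.taxa):
                hap = phased.get(taxon)
                if hap is not None:
                    a, b = hap[0, j], hap[1, j]
                    fmt = lambda x: "." if x < 0 else str(int(x))
                    fields.append(f"{fmt(a)}|{fmt(b)}")
                else:
                    fields.append(_GT_STRINGS[int(matrix.calls[i, j])])
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# Annotation I/O
# ---------------------------------------------------------------------------

def read_annotations(path: str | Path, format: str) -> list[GenomicInterval]:
    """Read gene intervals from BED (0-based half-open) or GFF3 (1-based).

    For GFF3 only records with feature type ``gene`` are used.  Output is in
    the internal 0-based half-open convention, sorted by (chrom, start).
    """
    import pyranges as pr

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format.lower()
    try:
        if fmt == "bed":
            gr = pr.read_bed(str(path))
            df = gr.df
        elif fmt == "gff3":
            gr = pr.read_gff3(str(path))  # pyranges converts to 0-based starts
            df = gr.df
            df = df[df["Feature"] == "gene"]
        else:
            raise ValueError(f"unknown annotation format: {format!r}")
    except ValueError:
        raise
    except Exception as exc:  # pragma: no cover - parser internals vary
        raise ValueError(f"failed to parse {path} as {fmt}: {exc}") from exc
    intervals = [
        GenomicInterval(str(c), int(s), int(e))
        for c, s, e in zip(df["Chromosome"], df["Start"], df["End"])
    ]
    intervals.sort()
    logger.info("read_annotations: %d gene intervals from %s", len(intervals), path)
    return intervals
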
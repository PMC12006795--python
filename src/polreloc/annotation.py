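"""Genome annotation, interval arithmetic, binning, and promoter windows.

All coordinates are 0-based half-open internally. GFF3 input (1-based,
closed) is converted exactly once on read by :mod:`polreloc.io`.

The genome is tiled into fixed-width bins (200 bp by default) after
trimming a 200 bp end region from each chromosome. For the S. cerevisiae
R64-1-1 assembly (nuclear chromosomes only, one-end trim, partial terminal
bins dropped) this yields 60,333 bins; the trim convention is configurable
and :func:`calibrate_tiling_convention` searches the small space of
variants for the one matching a required total.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

logger = logging.getLogger(__name__)

#: R64-1-1 (sacCer3) chromosome lengths in bp.
R64_CHROM_LENGTHS: dict[str, int] = {
    "chrI": 230218,
    "chrII": 813184,
    "chrIII": 316620,
    "chrIV": 1531933,
    "chrV": 576874,
    "chrVI": 270161,
    "chrVII": 1090940,
    "chrVIII": 562643,
    "chrIX": 439888,
    "chrX": 745751,
    "chrXI": 666816,
    "chrXII": 1078177,
    "chrXIII": 924431,
    "chrXIV": 784333,
    "chrXV": 1091291,
    "chrXVI": 948066,
    "chrM": 85779,
}

MITO_CHROMS = frozenset({"chrM", "chrMT", "chrmt", "MT", "Mito", "chrMito"})


@dataclass(frozen=True, order=True)
class Interval:
    """Half-open genomic interval [start, end) on a chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap_len(self, other: "Interval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def overlaps(self, other: "Interval") -> bool:
        return self.overlap_len(other) > 0

    def contains(self, other: "Interval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass(frozen=True)
class FlaggedInterval:
    """An interval that may have been truncated at a chromosome boundary.

    ``empty`` marks windows that fell entirely off the chromosome; such
    windows carry a zero-length placeholder coordinate pair instead of an
    :class:`Interval` (which forbids start == end).
    """

    chrom: str
    start: int
    end: int
    truncated: bool = False

    @property
    def empty(self) -> bool:
        return self.start >= self.end

    @property
    def length(self) -> int:
        return max(0, self.end - self.start)

    def to_interval(self) -> Interval:
        if self.empty:
            raise ValueError("empty window has no interval representation")
        return Interval(self.chrom, self.start, self.end)


POL2_BIOTYPES = frozenset({"mRNA", "snRNA", "ncRNA"})


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    interval: Interval
    strand: str
    biotype: str = "mRNA"
    cds: Interval | None = None
    is_rp: bool = False

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        if self.cds is not None and not self.interval.contains(self.cds):
            raise ValueError(f"{self.gene_id}: CDS not contained in gene interval")

    @property
    def tss(self) -> int:
        """Transcription start site (strand-aware)."""
        return self.interval.start if self.strand == "+" else self.interval.end

    @property
    def tes(self) -> int:
        """Transcription end site (strand-aware)."""
        return self.interval.end if self.strand == "+" else self.interval.start

    @property
    def cds_interval(self) -> Interval:
        """CDS, defaulting to the whole gene interval (yeast convention)."""
        return self.cds if self.cds is not None else self.interval

    @property
    def is_pol2(self) -> bool:
        return self.biotype in POL2_BIOTYPES


@dataclass
class GenomeAnnotation:
    chrom_lengths: dict[str, int]
    genes: list[GeneModel] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for g in self.genes:
            if g.gene_id in seen:
                raise ValueError(f"duplicate gene_id {g.gene_id!r}")
            seen.add(g.gene_id)
            L = self.chrom_lengths.get(g.interval.chrom)
            if L is None:
                raise ValueError(
                    f"{g.gene_id}: unknown chromosome {g.interval.chrom!r}"
                )
            if g.interval.end > L:
                raise ValueError(
                    f"{g.gene_id}: interval extends past end of {g.interval.chrom}"
                )

    def gene(self, gene_id: str) -> GeneModel:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    @property
    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]

    def genes_by_biotype(self, biotype: str) -> list[GeneModel]:
        return [g for g in self.genes if g.biotype == biotype]

    @property
    def rp_genes(self) -> list[GeneModel]:
        return [g for g in self.genes if g.is_rp]


@dataclass(frozen=True)
class Bin:
    interval: Interval
    index: int


@dataclass(frozen=True)
class TilingConvention:
    """End-trim convention for genome tiling.

    trim_both: trim ``end_trim`` from both chromosome ends (else one end).
    include_mito: tile the mitochondrial genome as well.
    """

    trim_both: bool = False
    include_mito: bool = False


DEFAULT_TILING = TilingConvention(trim_both=False, include_mito=False)


def flag_rp_genes(
    genes: Iterable[GeneModel], rp_gene_ids: Iterable[str]
) -> list[GeneModel]:
    """Set ``is_rp`` on the listed genes; warn about ids absent from the set."""
    rp = set(rp_gene_ids)
    out = []
    seen = set()
    for g in genes:
        if g.gene_id in rp:
            g = replace(g, is_rp=True)
            seen.add(g.gene_id)
        out.append(g)
    missing = rp - seen
    if missing:
        warnings.warn(
            f"{len(missing)} RP gene id(s) not found in annotation: "
            + ", ".join(sorted(missing)[:5])
            + ("..." if len(missing) > 5 else ""),
            stacklevel=2,
        )
    return out


def tile_genome(
    annotation_or_lengths: GenomeAnnotation | Mapping[str, int],
    bin_size: int = 200,
    end_trim: int = 200,
    convention: TilingConvention = DEFAULT_TILING,
) -> list[Bin]:
    """Tile chromosomes into consecutive non-overlapping bins.

    Each chromosome loses an ``end_trim`` bp end region (one end by
    default, both under ``convention.trim_both``); the remainder is tiled
    into bins of exactly ``bin_size`` and partial terminal bins are
    dropped. Chromosomes too short to hold one bin yield none. Bins get a
    global index in (chrom, start) order of the input mapping.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    if end_trim < 0:
        raise ValueError("end_trim must be non-negative")
    lengths = (
        annotation_or_lengths.chrom_lengths
        if isinstance(annotation_or_lengths, GenomeAnnotation)
        else dict(annotation_or_lengths)
    )
    bins: list[Bin] = []
    idx = 0
    for chrom, length in lengths.items():
        if not convention.include_mito and chrom in MITO_CHROMS:
            continue
        if convention.trim_both:
            start, stop = end_trim, length - end_trim
        else:
            start, stop = 0, length - end_trim
        n = max(0, (stop - start)) // bin_size
        for i in range(n):
            s = start + i * bin_size
            bins.append(Bin(Interval(chrom, s, s + bin_size), idx))
            idx += 1
    return bins


def calibrate_tiling_convention(
    chrom_lengths: Mapping[str, int],
    target_bins: int,
    bin_size: int = 200,
    end_trim: int = 200,
) -> list[TilingConvention]:
    """Search the end-trim convention variants for a given bin total.

    Returns every convention whose tiling of ``chrom_lengths`` produces
    exactly ``target_bins`` bins. For R64-1-1 and a target of 60,333 the
    unique answer is one-end trim with the mitochondrial genome excluded.
    """
    hits = []
    for trim_both in (False, True):
        for include_mito in (False, True):
            conv = TilingConvention(trim_both, include_mito)
            n = len(tile_genome(chrom_lengths, bin_size, end_trim, conv))
            if n == target_bins:
                hits.append(conv)
    return hits


def _clip_window(chrom: str, chrom_len: int, start: int, end: int) -> FlaggedInterval:
    cs, ce = max(0, start), min(chrom_len, end)
    if cs >= ce:
        return FlaggedInterval(chrom, 0, 0, truncated=True)
    return FlaggedInterval(chrom, cs, ce, truncated=(cs != start or ce != end))


def upstream_subregions(
    gene: GeneModel,
    annotation: GenomeAnnotation,
    upstream: int = 1000,
    n_subregions: int = 5,
) -> list[FlaggedInterval]:
    """Split the 1 kb upstream of the TSS into five 200-bp subregions.

    Subregions are ordered from -upstream to -1 relative to the TSS on the
    gene's strand; for minus-strand genes they lie at genomic coordinates
    TSS..TSS+upstream. Windows running off the chromosome are truncated
    and flagged, never dropped.
    """
    width = upstream // n_subregions
    chrom = gene.interval.chrom
    chrom_len = annotation.chrom_lengths[chrom]
    out = []
    for k in range(n_subregions):
        # offsets of subregion k: [-upstream + k*width, -upstream + (k+1)*width)
        lo = -upstream + k * width
        hi = lo + width
        if gene.strand == "+":
            s, e = gene.tss + lo, gene.tss + hi
        else:
            s, e = gene.tss - hi, gene.tss - lo
        out.append(_clip_window(chrom, chrom_len, s, e))
    return out


def tss_relative_window(
    gene: GeneModel, annotation: GenomeAnnotation, lo: int, hi: int
) -> FlaggedInterval:
    """Genomic window for TSS-relative offsets [lo, hi) (negative = upstream)."""
    chrom_len = annotation.chrom_lengths[gene.interval.chrom]
    if gene.strand == "+":
        s, e = gene.tss + lo, gene.tss + hi
    else:
        s, e = gene.tss - hi, gene.tss - lo
    return _clip_window(gene.interval.chrom, chrom_len, s, e)


def urs_window(
    gene: GeneModel,
    annotation: GenomeAnnotation,
    window: tuple[int, int] = (-600, -100),
) -> FlaggedInterval:
    """Upstream regulatory sequence window, TSS-relative (default -600..-100)."""
    return tss_relative_window(gene, annotation, window[0], window[1])
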
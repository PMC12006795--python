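"""Positional analyses: metagene matrices, URS Poisson enrichment, and
IUPAC consensus motif scanning with local positional enrichment.

The URS enrichment test asks whether Pol II-independent Hda1 peaks pile
up in particular TSS-relative windows of the RP genes: the observed
statistic is the number of genes whose window overlaps a peak, compared
under a Poisson null to the count expected if peak bases were spread at
their genome-wide density.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .annotation import (
    Bin,
    GeneModel,
    GenomeAnnotation,
    Interval,
    tss_relative_window,
)
from .coverage import Peak

# Rap1-binding consensus sequences enriched upstream of RP genes
RAP1_MOTIFS = ("ACACCCAYACAYYY", "ACACCCRYACAY")

IUPAC = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}
_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MotifHit:
    offset: int  # plus-strand offset within the scanned sequence
    strand: str
    matched: str
    gene_id: str = ""


def scan_iupac(sequence: str, motif: str, both_strands: bool = True) -> list[MotifHit]:
    """All matches of an IUPAC consensus in a sequence.

    ``N`` in the *sequence* never matches. Minus-strand hits are found on
    the reverse complement and reported with the plus-strand offset of
    the matched window.
    """
    motif = motif.upper()
    for ch in motif:
        if ch not in IUPAC:
            raise ValueError(f"invalid IUPAC character {ch!r} in motif")
    seq = sequence.upper()
    m = len(motif)
    hits: list[MotifHit] = []

    def scan_strand(s: str, strand: str):
        for i in range(len(s) - m + 1):
            window = s[i : i + m]
            if all(
                base != "N" and base in IUPAC[code]
                for base, code in zip(window, motif)
            ):
                offset = i if strand == "+" else len(s) - i - m
                hits.append(MotifHit(offset, strand, window))

    scan_strand(seq, "+")
    if both_strands:
        scan_strand(reverse_complement(seq), "-")
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


def scan_promoters(
    sequences: Mapping[str, str],
    genes: Sequence[GeneModel],
    annotation: GenomeAnnotation,
    motif: str,
    upstream: int = 1000,
) -> list[MotifHit]:
    """Scan each gene's 1 kb upstream sequence for a consensus motif.

    Offsets are TSS-relative (negative = upstream). Hits at the same
    locus on both strands (palindromes) are counted once.
    """
    out: list[MotifHit] = []
    for g in genes:
        seq = sequences[g.interval.chrom]
        win = tss_relative_window(g, annotation, -upstream, 0)
        if win.empty:
            continue
        sub = seq[win.start : win.end]
        if g.strand == "-":
            sub = reverse_complement(sub)
        width = win.length
        seen: set[int] = set()
        for m in (motif,) if isinstance(motif, str) else motif:
            for h in scan_iupac(sub, m):
                tss_offset = h.offset - width
                if tss_offset in seen:
                    continue  # palindrome / double-strand duplicate guard
                seen.add(tss_offset)
                out.append(MotifHit(tss_offset, h.strand, h.matched, g.gene_id))
    return out


@dataclass(frozen=True)
class EnrichmentResult:
    window: tuple[int, int]  # TSS-relative
    observed: int
    expected: float
    pvalue: float
    fdr: float = float("nan")
    stars: str = ""


def default_urs_windows(upstream: int = 1000, width: int = 100) -> list[tuple[int, int]]:
    return [(-upstream + k * width, -upstream + (k + 1) * width) for k in range(upstream // width)]


def urs_poisson_enrichment(
    independent_peaks: Sequence[Peak],
    rp_genes: Sequence[GeneModel],
    annotation: GenomeAnnotation,
    windows: Sequence[tuple[int, int]] | None = None,
    genome_size: int | None = None,
) -> list[EnrichmentResult]:
    """Poisson test of Pol II-independent peak enrichment in TSS windows.

    Per TSS-relative window: observed = number of genes whose window
    overlaps >= 1 peak; expected under a uniform-placement null = number
    of genes x sum over peaks of (window width + peak length) / genome
    size, i.e. each peak's probability of touching a given window if
    peaks were scattered at their genome-wide density. Upper-tail
    Poisson p, BH across windows; stars at FDR < 0.05 (*) and
    FDR < 0.001 (***).
    """
    if windows is None:
        windows = default_urs_windows()
    if genome_size is None:
        genome_size = sum(annotation.chrom_lengths.values())
    by_chrom: dict[str, list[Peak]] = {}
    for p in independent_peaks:
        by_chrom.setdefault(p.interval.chrom, []).append(p)

    results = []
    for lo, hi in windows:
        observed = 0
        n_valid = 0
        for g in rp_genes:
            win = tss_relative_window(g, annotation, lo, hi)
            if win.empty:
                continue
            n_valid += 1
            iv = win.to_interval()
            if any(iv.overlaps(p.interval) for p in by_chrom.get(iv.chrom, ())):
                observed += 1
        hit_prob = sum(
            ((hi - lo) + p.length) / genome_size for p in independent_peaks
        )
        expected = hit_prob * n_valid
        if expected <= 0:
            p = 1.0 if observed == 0 else float(np.finfo(float).tiny)
        else:
            p = float(stats.poisson.sf(observed - 1, expected))
        results.append(EnrichmentResult((lo, hi), observed, expected, p))
    _, fdrs, _, _ = multipletests([r.pvalue for r in results], method="fdr_bh")
    out = []
    for r, q in zip(results, fdrs):
        stars = "***" if q < 0.001 else ("*" if q < 0.05 else "")
        out.append(EnrichmentResult(r.window, r.observed, r.expected, r.pvalue, float(q), stars))
    return out


@dataclass(frozen=True)
class LocalEnrichment:
    window: tuple[int, int]
    hits_in_window: int
    total_hits: int
    pvalue: float  # Bonferroni-adjusted over window positions
    n_positions: int


def local_motif_enrichment(
    offsets: Sequence[int],
    region_span: tuple[int, int] = (-1000, 0),
    window_width: int = 100,
    step: int = 10,
) -> LocalEnrichment:
    """Best sliding-window positional enrichment of motif hits.

    Binomial test of the hit count in each window against the uniform
    null p0 = window_width / region_width, Bonferroni-corrected over
    window positions; the most enriched window is returned.
    """
    lo, hi = region_span
    region_width = hi - lo
    offsets = np.asarray([o for o in offsets if lo <= o < hi])
    n = len(offsets)
    starts = list(range(lo, hi - window_width + 1, step))
    if n == 0:
        return LocalEnrichment((lo, lo + window_width), 0, 0, 1.0, len(starts))
    p0 = window_width / region_width
    best = None
    for s in starts:
        k = int(((offsets >= s) & (offsets < s + window_width)).sum())
        p = stats.binom.sf(k - 1, n, p0)
        if best is None or p < best[1]:
            best = ((s, s + window_width), p, k)
    window, p, k = best
    return LocalEnrichment(window, k, n, float(min(1.0, p * len(starts))), len(starts))


# ---------------------------------------------------------------------------
# metagene matrices


def _per_bp(track: np.ndarray, bins: Sequence[Bin], chrom_lengths: Mapping[str, int]):
    arrays = {c: np.zeros(l) for c, l in chrom_lengths.items()}
    for b, v in zip(bins, track):
        arr = arrays.get(b.interval.chrom)
        if arr is not None:
            arr[b.interval.start : b.interval.end] = v
    return arrays


def _pool(values: np.ndarray, n_out: int) -> tuple[np.ndarray, bool]:
    """Mean-pool to n_out columns; short inputs are interpolated (flagged)."""
    if len(values) >= n_out:
        return np.array([c.mean() for c in np.array_split(values, n_out)]), False
    xp = np.linspace(0, 1, num=len(values)) if len(values) > 1 else np.array([0.0])
    xq = np.linspace(0, 1, num=n_out)
    return np.interp(xq, xp, values), True


@dataclass
class MetaMatrix:
    matrix: np.ndarray  # genes x (upstream bins + body bins)
    gene_ids: list[str]
    n_upstream_cols: int
    body_bins: int
    row_order_key: pd.Series  # sort values used for ordering
    interpolated: np.ndarray  # per-row flag: body shorter than one bin


def metagene_matrix(
    track: np.ndarray,
    bins: Sequence[Bin],
    genes: Sequence[GeneModel],
    annotation: GenomeAnnotation,
    upstream: int = 1000,
    body_bins: int = 100,
    sort_track: np.ndarray | None = None,
) -> MetaMatrix:
    """Per-gene signal matrix over 1 kb upstream + length-scaled body.

    The upstream stretch is sampled at the native bin resolution; the
    TSS..TES body is length-normalized into ``body_bins`` columns by mean
    pooling. Minus-strand genes are reversed so left = upstream. Rows are
    sorted in descending order of the mean body signal of ``sort_track``
    (the track itself by default; typically the +N Rpb3 track), ties
    broken by gene_id.
    """
    if not bins:
        raise ValueError("empty bin list")
    bin_size = bins[0].interval.length
    n_up = upstream // bin_size
    per_bp = _per_bp(np.asarray(track, float), bins, annotation.chrom_lengths)
    sort_bp = (
        per_bp
        if sort_track is None
        else _per_bp(np.asarray(sort_track, float), bins, annotation.chrom_lengths)
    )

    rows, keys, interp_flags = [], {}, []
    for g in genes:
        arr = per_bp[g.interval.chrom]
        s, e = g.interval.start, g.interval.end
        chrom_len = annotation.chrom_lengths[g.interval.chrom]
        if g.strand == "+":
            up_lo, up_hi = max(0, s - upstream), s
            up = arr[up_lo:up_hi]
            if len(up) < upstream:
                up = np.concatenate([np.zeros(upstream - len(up)), up])
            body = arr[s:e]
        else:
            up_lo, up_hi = e, min(chrom_len, e + upstream)
            up = arr[up_lo:up_hi][::-1]
            if len(up) < upstream:
                up = np.concatenate([np.zeros(upstream - len(up)), up])
            body = arr[s:e][::-1]
        up_cols = np.array([c.mean() for c in np.array_split(up, n_up)])
        body_cols, flagged = _pool(body, body_bins)
        rows.append(np.concatenate([up_cols, body_cols]))
        interp_flags.append(flagged)
        sarr = sort_bp[g.interval.chrom]
        keys[g.gene_id] = float(np.mean(sarr[s:e]))

    key_series = pd.Series(keys)
    order = sorted(range(len(genes)), key=lambda i: (-keys[genes[i].gene_id], genes[i].gene_id))
    matrix = np.array([rows[i] for i in order])
    return MetaMatrix(
        matrix=matrix,
        gene_ids=[genes[i].gene_id for i in order],
        n_upstream_cols=n_up,
        body_bins=body_bins,
        row_order_key=key_series.iloc[order] if len(order) else key_series,
        interpolated=np.array([interp_flags[i] for i in order], dtype=bool),
    )
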
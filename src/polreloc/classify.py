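"""Geometric classification of Hda1 peaks into genomic units.

Sequential rules, first match wins:

1. **tRNA** — the peak contains an entire tRNA gene.
2. **CDS** — the peak covers at least 30% of some gene's coding region.
3. **Intergenic** — the peak covers at least 90% of one of the five
   200-bp subregions of a Pol II gene's 1 kb upstream window, and that
   subregion overlaps no tRNA gene and no CDS of any other gene.
4. **Others** — none of the above.

Ties within a rule are resolved by highest coverage fraction, then by
smallest feature start, making the outcome independent of annotation
listing order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd
from intervaltree import IntervalTree

from .annotation import GeneModel, GenomeAnnotation, upstream_subregions
from .coverage import Peak

UNITS = ("tRNA", "CDS", "Intergenic", "Others")


@dataclass(frozen=True)
class PeakClass:
    peak: Peak
    unit: str
    evidence_id: str = ""
    evidence_fraction: float = 0.0
    evidence_subregion: int = -1  # 1..5 for Intergenic, else -1


class AnnotationIndex:
    """Interval trees over the features classification needs."""

    def __init__(
        self,
        annotation: GenomeAnnotation,
        upstream: int = 1000,
        n_subregions: int = 5,
    ):
        self.annotation = annotation
        self.trna: dict[str, IntervalTree] = {}
        self.cds: dict[str, IntervalTree] = {}
        self.subregions: dict[str, IntervalTree] = {}
        for g in annotation.genes:
            iv = g.interval
            if g.biotype == "tRNA":
                self.trna.setdefault(iv.chrom, IntervalTree()).addi(
                    iv.start, iv.end, g
                )
            if g.is_pol2:
                cds = g.cds_interval
                self.cds.setdefault(cds.chrom, IntervalTree()).addi(
                    cds.start, cds.end, g
                )
                subs = upstream_subregions(g, annotation, upstream, n_subregions)
                for k, sub in enumerate(subs, start=1):
                    if sub.empty:
                        continue
                    self.subregions.setdefault(sub.chrom, IntervalTree()).addi(
                        sub.start, sub.end, (g, k, sub)
                    )


def _best(candidates):
    """Pick by highest coverage fraction, then smallest feature start."""
    return min(candidates, key=lambda t: (-t[0], t[1]))


def classify_peak(
    peak: Peak,
    index: AnnotationIndex,
    cds_cover_frac: float = 0.30,
    subregion_cover_frac: float = 0.90,
) -> PeakClass:
    iv = peak.interval
    chrom = iv.chrom

    # rule 1: entire tRNA gene inside the peak
    hits = []
    for node in index.trna.get(chrom, IntervalTree()).overlap(iv.start, iv.end):
        g: GeneModel = node.data
        if iv.contains(g.interval):
            hits.append((1.0, g.interval.start, g.gene_id))
    if hits:
        _, _, gid = _best(hits)
        peak.unit = "tRNA"
        return PeakClass(peak, "tRNA", gid, 1.0)

    # rule 2: >= 30% of some coding region covered
    hits = []
    for node in index.cds.get(chrom, IntervalTree()).overlap(iv.start, iv.end):
        g = node.data
        cds = g.cds_interval
        frac = iv.overlap_len(cds) / cds.length
        if frac >= cds_cover_frac:
            hits.append((frac, cds.start, g.gene_id))
    if hits:
        frac, _, gid = _best(hits)
        peak.unit = "CDS"
        return PeakClass(peak, "CDS", gid, frac)

    # rule 3: >= 90% of an upstream subregion covered, subregion clean of
    # tRNA genes and other genes' CDS
    hits = []
    for node in index.subregions.get(chrom, IntervalTree()).overlap(iv.start, iv.end):
        g, k, sub = node.data
        if sub.length == 0:
            continue
        frac = max(0, min(iv.end, sub.end) - max(iv.start, sub.start)) / sub.length
        if frac < subregion_cover_frac:
            continue
        # exclusion clause, checked on the triggering subregion only
        dirty = False
        for tnode in index.trna.get(chrom, IntervalTree()).overlap(sub.start, sub.end):
            dirty = True
            break
        if not dirty:
            for cnode in index.cds.get(chrom, IntervalTree()).overlap(
                sub.start, sub.end
            ):
                if cnode.data.gene_id != g.gene_id:
                    dirty = True
                    break
        if not dirty:
            hits.append((frac, sub.start, (g.gene_id, k)))
    if hits:
        frac, _, (gid, k) = _best(hits)
        peak.unit = "Intergenic"
        return PeakClass(peak, "Intergenic", gid, frac, evidence_subregion=k)

    peak.unit = "Others"
    return PeakClass(peak, "Others")


def classify_peaks(
    peaks: Sequence[Peak],
    annotation: GenomeAnnotation,
    cds_cover_frac: float = 0.30,
    subregion_cover_frac: float = 0.90,
    upstream: int = 1000,
    n_subregions: int = 5,
) -> list[PeakClass]:
    index = AnnotationIndex(annotation, upstream, n_subregions)
    return [
        classify_peak(p, index, cds_cover_frac, subregion_cover_frac) for p in peaks
    ]


def summarize_units(classified: Sequence[PeakClass]) -> pd.DataFrame:
    """Counts and percentages per (condition, polii, unit).

    Percentages are rounded to the nearest integer for display; exact
    fractions are kept in the ``fraction`` column.
    """
    rows = []
    for pc in classified:
        rows.append(
            {
                "condition": pc.peak.condition or "all",
                "polii": pc.peak.polii or "all",
                "unit": pc.unit,
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=["condition", "polii", "unit", "count", "total", "fraction", "percent"]
        )
    df = pd.DataFrame(rows)
    counts = (
        df.groupby(["condition", "polii", "unit"]).size().rename("count").reset_index()
    )
    totals = df.groupby(["condition", "polii"]).size().rename("total").reset_index()
    out = counts.merge(totals, on=["condition", "polii"])
    out["fraction"] = out["count"] / out["total"]
    out["percent"] = (out["fraction"] * 100).round().astype(int)
    return out
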
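"""Spike-in normalization, binned signal construction, and a simple peak caller.

Samples carry co-precipitated chromatin from a second genome (here the
S. pombe spike-in added at ~10% of chromatin); reads exclusively assigned
to each genome anchor a multiplicative scale factor so that
immunoprecipitation efficiency differences cancel across samples.

The built-in caller is a deliberately simple Poisson/Benjamini-Hochberg
bin scan with a local-background lambda; externally called narrowPeak
files are the first-class input and bypass it entirely.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .annotation import Bin, Interval

logger = logging.getLogger(__name__)

#: Factors exempt from spike-in scaling (normalized instead to total H3
#: downstream; their scale factor is forced to 1).
SPIKE_EXEMPT_FACTORS = frozenset({"H3ac"})


@dataclass(frozen=True)
class SpikeInCounts:
    sample_id: str
    target_reads: int
    spike_reads: int
    ambiguous_reads: int = 0

    def __post_init__(self) -> None:
        if min(self.target_reads, self.spike_reads, self.ambiguous_reads) < 0:
            raise ValueError("read counts must be non-negative")


@dataclass
class CoverageTrack:
    factor: str
    condition: str
    genotype: str
    values: np.ndarray
    scale: float = 1.0
    spike_normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if (self.values < 0).any():
            raise ValueError("track values must be non-negative")


@dataclass
class Peak:
    """Scored genomic interval with provenance and downstream labels."""

    interval: Interval
    name: str = "."
    score: float = 0.0
    signal: float = 0.0
    pvalue: float = -1.0  # -log10, narrowPeak convention; -1 = unset
    qvalue: float = -1.0
    summit: int = -1
    factor: str = ""
    condition: str = ""
    polii: str = ""  # "associated" | "independent" | ""
    unit: str = ""  # "tRNA" | "CDS" | "Intergenic" | "Others" | ""

    @property
    def length(self) -> int:
        return self.interval.length


def exclusive_assignment(read_table: pd.DataFrame) -> SpikeInCounts:
    """Count reads exclusively assigned to the target or spike-in genome.

    ``read_table`` has columns ``read_id`` and ``genomes`` where genomes is
    a comma-separated subset of {target, spike}. Reads aligning to both
    genomes are ambiguous and excluded from both exclusive counts.
    """
    if len(read_table) == 0:
        raise ValueError("empty read-assignment table")
    sample_id = str(read_table["sample"].iloc[0]) if "sample" in read_table else ""
    target = spike = ambiguous = 0
    for g in read_table["genomes"]:
        genomes = {p.strip() for p in str(g).split(",") if p.strip()}
        if genomes == {"target"}:
            target += 1
        elif genomes == {"spike"}:
            spike += 1
        elif genomes == {"target", "spike"}:
            ambiguous += 1
        else:
            raise ValueError(f"unrecognized genome assignment {g!r}")
    return SpikeInCounts(sample_id, target, spike, ambiguous)


def spikein_scale(sample: SpikeInCounts, reference: SpikeInCounts) -> float:
    """Spike-in scale factor = reference spike reads / sample spike reads.

    Multiplying the sample's signal by this factor equalizes spike-derived
    signal across samples, so target-genome signal becomes comparable.
    """
    if sample.spike_reads <= 0 or reference.spike_reads <= 0:
        raise ValueError(
            "spike-in scaling requires positive spike read counts "
            f"(sample={sample.spike_reads}, reference={reference.spike_reads})"
        )
    return reference.spike_reads / sample.spike_reads


def scale_factor_for(factor: str, sample: SpikeInCounts, reference: SpikeInCounts) -> float:
    """Per-factor scale; H3ac is exempt from spike normalization (factor 1)."""
    if factor in SPIKE_EXEMPT_FACTORS:
        return 1.0
    return spikein_scale(sample, reference)


def bin_signal(
    fragment_intervals: Iterable[Interval],
    bins: Sequence[Bin],
    factor: float = 1.0,
) -> np.ndarray:
    """Mean per-bin depth (fragment-bases / bin width) times a scale factor.

    Fragments contribute to each bin in proportion to their overlap, so
    total mass is conserved within the binned territory.
    """
    values = np.zeros(len(bins))
    # per-chromosome sorted bin starts for O(log n) fragment placement
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, int]] = {}
    for b in bins:
        by_chrom.setdefault(b.interval.chrom, []).append(b)  # type: ignore[attr-defined]
    index = {}
    for chrom, blist in by_chrom.items():
        starts = np.array([b.interval.start for b in blist])
        idx = np.array([b.index for b in blist])
        width = blist[0].interval.length
        index[chrom] = (starts, idx, width)
    for frag in fragment_intervals:
        entry = index.get(frag.chrom)
        if entry is None:
            warnings.warn(f"fragment on unknown chromosome {frag.chrom!r}, skipped")
            continue
        starts, idx, width = entry
        lo = int(np.searchsorted(starts, frag.start - width + 1, side="left"))
        for j in range(lo, len(starts)):
            s = starts[j]
            if s >= frag.end:
                break
            ov = min(frag.end, s + width) - max(frag.start, s)
            if ov > 0:
                values[idx[j]] += ov / width
    return values * factor


def call_peaks(
    treatment: np.ndarray,
    control: np.ndarray,
    bins: Sequence[Bin],
    q_max: float = 0.01,
    min_merge_gap: int = 1,
    local_halfwidth: int = 5,
    factor: str = "",
    condition: str = "",
) -> list[Peak]:
    """Poisson bin-scan peak caller with BH correction and bin merging.

    For each bin, the treatment read count is tested against a Poisson
    null whose mean is max(global control mean, local control mean over
    +/- ``local_halfwidth`` bins) per bin. Adjacent significant bins
    (gap <= ``min_merge_gap``) merge into one peak scored by the best q.
    """
    treatment = np.asarray(treatment, dtype=float)
    control = np.asarray(control, dtype=float)
    if treatment.shape != control.shape or len(treatment) != len(bins):
        raise ValueError("treatment/control/bins must be congruent")
    if len(bins) == 0:
        return []
    width = bins[0].interval.length
    # counts per bin from mean depth
    t_counts = np.round(treatment * width).astype(int)
    c_depth = control.copy()
    if c_depth.sum() == 0:
        warnings.warn("all-zero control; applying 1 pseudo-read per bin floor")
        c_depth = np.full_like(c_depth, 1.0 / width)
    # local means must respect chromosome boundaries
    chroms = np.array([b.interval.chrom for b in bins])
    local = np.empty_like(c_depth)
    for chrom in pd.unique(chroms):
        mask = chroms == chrom
        x = c_depth[mask]
        k = local_halfwidth
        csum = np.concatenate([[0.0], np.cumsum(x)])
        n = len(x)
        loc = np.empty(n)
        for i in range(n):
            a, b = max(0, i - k), min(n, i + k + 1)
            loc[i] = (csum[b] - csum[a]) / (b - a)
        local[mask] = loc
    lam = np.maximum(c_depth.mean(), local) * width
    lam = np.maximum(lam, 1.0)  # one pseudo-read floor per bin
    pvals = stats.poisson.sf(t_counts - 1, lam)
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    sig_idx = np.flatnonzero(qvals <= q_max)

    # group significant bins: same chromosome and <= min_merge_gap
    # intervening non-significant bins
    groups: list[list[int]] = []
    for k in sig_idx:
        if (
            groups
            and chroms[k] == chroms[groups[-1][-1]]
            and k - groups[-1][-1] - 1 <= min_merge_gap
        ):
            groups[-1].append(int(k))
        else:
            groups.append([int(k)])

    peaks: list[Peak] = []
    for members in groups:
        qmin = max(qvals[members].min(), 1e-300)
        pmin = max(pvals[members].min(), 1e-300)
        summit_bin = members[int(np.argmax(t_counts[members]))]
        start = bins[members[0]].interval.start
        end = bins[members[-1]].interval.end
        peaks.append(
            Peak(
                interval=Interval(chroms[members[0]], start, end),
                name=f"peak_{len(peaks) + 1}",
                score=min(1000, round(10 * -np.log10(qmin))),
                signal=float(treatment[members].mean()),
                pvalue=float(-np.log10(pmin)),
                qvalue=float(-np.log10(qmin)),
                summit=bins[summit_bin].interval.start + width // 2 - start,
                factor=factor,
                condition=condition,
            )
        )
    return peaks


def peaks_to_narrowpeak(peaks: Sequence[Peak]) -> pd.DataFrame:
    from .io import NARROWPEAK_COLUMNS  # local import avoids cycle

    rows = []
    for p in peaks:
        rows.append(
            {
                "chrom": p.interval.chrom,
                "start": p.interval.start,
                "end": p.interval.end,
                "name": p.name,
                "score": int(min(1000, round(p.score))),
                "strand": ".",
                "signalValue": p.signal,
                "pValue": p.pvalue,
                "qValue": p.qvalue,
                "peak": p.summit,
            }
        )
    return pd.DataFrame(rows, columns=NARROWPEAK_COLUMNS)


def narrowpeak_to_peaks(df: pd.DataFrame, factor: str = "", condition: str = "") -> list[Peak]:
    return [
        Peak(
            interval=Interval(r.chrom, int(r.start), int(r.end)),
            name=str(r.name) if str(r.name) != "nan" else ".",
            score=float(r.score),
            signal=float(r.signalValue),
            pvalue=float(r.pValue),
            qvalue=float(r.qValue),
            summit=int(r.peak),
            factor=factor,
            condition=condition,
        )
        for r in df.itertuples(index=False)
    ]
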
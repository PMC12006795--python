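"""Histone acetylation-to-H3 ratio tracks and paired strain comparisons.

Acetylation ChIP signal is normalized to total H3 content per bin as
log2((ac + eps) / (h3 + eps)); the ratio cancels sequencing-depth
differences, which is why the H3ac track can enter unscaled by the
spike-in. WT vs hda1-delta comparisons over a region set (e.g. the
-600..-100 URS windows of the 137 RP genes) use the paired Wilcoxon
signed-rank test, with the unpaired rank-sum reported as a secondary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .annotation import Bin, Interval


@dataclass
class RatioTrack:
    numerator_factor: str
    genotype: str
    condition: str
    values: np.ndarray
    epsilon: float


def default_epsilon(h3_values: np.ndarray) -> float:
    """5th percentile of positive H3 signal (per-track pseudo-count)."""
    pos = h3_values[h3_values > 0]
    if len(pos) == 0:
        return 1.0
    return float(np.percentile(pos, 5))


def log2_ratio(
    ac_values: np.ndarray,
    h3_values: np.ndarray,
    epsilon: float | None = None,
    numerator_factor: str = "H4ac",
    genotype: str = "WT",
    condition: str = "",
) -> RatioTrack:
    """Per-bin log2((ac + eps)/(h3 + eps)) on a shared bin frame."""
    ac = np.asarray(ac_values, dtype=float)
    h3 = np.asarray(h3_values, dtype=float)
    if ac.shape != h3.shape:
        raise ValueError(
            f"mismatched bin frames: {ac.shape} vs {h3.shape}"
        )
    eps = default_epsilon(h3) if epsilon is None else float(epsilon)
    if eps <= 0:
        raise ValueError("epsilon must be positive")
    values = np.log2(ac + eps) - np.log2(h3 + eps)
    return RatioTrack(numerator_factor, genotype, condition, values, eps)


def region_aggregate(
    values: np.ndarray,
    bins: Sequence[Bin],
    regions: Sequence[Interval],
) -> np.ndarray:
    """Length-weighted mean of per-bin values over each region.

    Regions outside the binned territory come back NaN with a warning.
    """
    values = np.asarray(values, dtype=float)
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, int]] = {}
    tmp: dict[str, list[Bin]] = {}
    for b in bins:
        tmp.setdefault(b.interval.chrom, []).append(b)
    for chrom, blist in tmp.items():
        starts = np.array([b.interval.start for b in blist])
        idx = np.array([b.index for b in blist])
        by_chrom[chrom] = (starts, idx, blist[0].interval.length)

    out = np.full(len(regions), np.nan)
    for i, region in enumerate(regions):
        entry = by_chrom.get(region.chrom)
        if entry is None:
            warnings.warn(f"region on unbinned chromosome {region.chrom!r}")
            continue
        starts, idx, width = entry
        total = 0.0
        weight = 0
        lo = int(np.searchsorted(starts, region.start - width + 1))
        for j in range(lo, len(starts)):
            s = starts[j]
            if s >= region.end:
                break
            ov = min(region.end, s + width) - max(region.start, s)
            if ov > 0:
                total += values[idx[j]] * ov
                weight += ov
        if weight == 0:
            warnings.warn(
                f"region {region.chrom}:{region.start}-{region.end} outside "
                "binned territory"
            )
        else:
            out[i] = total / weight
    return out


def region_wilcoxon(
    wt_values: Sequence[float],
    mut_values: Sequence[float],
    exact_max_n: int = 25,
) -> tuple[float, float, int]:
    """Two-sided paired Wilcoxon signed-rank test of mutant vs wild type.

    Zero differences are dropped (Wilcoxon convention). The exact null
    distribution is used for n <= ``exact_max_n`` pairs after dropping;
    otherwise the normal approximation with continuity correction.
    Returns (statistic, pvalue, n_used).
    """
    wt = np.asarray(wt_values, dtype=float)
    mut = np.asarray(mut_values, dtype=float)
    if wt.shape != mut.shape:
        raise ValueError("paired vectors must have equal length")
    diffs = mut - wt
    nz = diffs[diffs != 0]
    if len(nz) == 0:
        warnings.warn("all paired differences are zero; p = 1")
        return 0.0, 1.0, 0
    if len(nz) < 5:
        raise ValueError(f"need >=5 nonzero differences, got {len(nz)}")
    method = "exact" if len(nz) <= exact_max_n else "approx"
    res = stats.wilcoxon(
        nz, method=method, correction=(method == "approx"), zero_method="wilcox"
    )
    return float(res.statistic), float(res.pvalue), len(nz)


def region_ranksum(
    wt_values: Sequence[float], mut_values: Sequence[float]
) -> tuple[float, float]:
    """Unpaired Mann-Whitney rank-sum secondary comparison."""
    res = stats.mannwhitneyu(mut_values, wt_values, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)
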
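"""Detection of Pol II-independent Hda1 binding.

Genome-wide, Hda1 occupancy tracks RNA Pol II (Rpb3) occupancy
approximately exponentially: hda1 ~= exp(alpha + beta * rpb3). We fit
log(hda1 + c) = alpha + beta * rpb3 by iteratively reweighted
M-estimation (Tukey bisquare, tuning 4.685) with the residual scale
re-estimated each iteration as the normalized MAD. Bins whose robustly
standardized residual exceeds 2.576 (the 99.5% normal quantile,
one-sided: Hda1 excess only) are flagged Pol II-independent.

Hda1 peaks are split the same way at peak level: peaks >= 100 bp that
overlap an Rpb3 peak by at least 1 bp are Pol II-associated, the rest
Pol II-independent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .annotation import Bin
from .coverage import Peak

TUKEY_TUNING = 4.685
MAD_NORMALIZER = 0.6744897501960817  # Phi^-1(0.75)
DEFAULT_RESIDUAL_THRESHOLD = 2.576  # 99.5% normal quantile


@dataclass
class RegressionFit:
    alpha: float
    beta: float
    scale: float
    n_used: int
    converged: bool
    n_iter: int
    pseudo: float


@dataclass
class BinTable:
    """Per-bin Rpb3/Hda1 signal with fit diagnostics and outlier flags."""

    bins: list[Bin]
    rpb3: np.ndarray
    hda1: np.ndarray
    fitted: np.ndarray | None = None
    std_residual: np.ndarray | None = None
    independent: np.ndarray | None = None
    fit: RegressionFit | None = None


def default_pseudocount(hda1: np.ndarray) -> float:
    """Pseudo-count for the log transform.

    One tenth of the 1st percentile of the positive signal: large enough
    to guard zero bins, small enough relative to even the weakest real
    signal that it barely distorts the log-scale residual distribution
    (a pseudo-count comparable to the background signal compresses
    background residuals and makes the flagging threshold behave
    differently in quiet and active territory). Scales with the data, so
    flagging is invariant to global rescaling of the Hda1 track.
    """
    pos = hda1[hda1 > 0]
    if len(pos) == 0:
        return 1.0
    return float(np.percentile(pos, 1)) / 10.0


def _mad_scale(resid: np.ndarray) -> float:
    """Normalized MAD with a percentile fallback for tied residuals.

    When half or more of the residuals are (near-)identical — e.g. a
    dominant flat-background predictor fitted exactly — the MAD reflects
    only the ties and collapses far below the real spread; in that
    degenerate regime fall back to the 90th percentile of absolute
    deviations, normalized to the standard normal (z_0.90 = 1.2816).
    For well-spread residuals the two estimates agree and the MAD wins.
    """
    dev = np.abs(resid - np.median(resid))
    s_mad = float(np.median(dev) / MAD_NORMALIZER)
    s_p90 = float(np.percentile(dev, 90) / 1.2815515655446004)
    if s_mad < 0.1 * s_p90:
        return s_p90
    return s_mad


def _is_perfect_fit(resid: np.ndarray, y: np.ndarray) -> bool:
    dev = np.abs(resid - np.median(resid))
    return bool(dev.max() <= 1e-10 * max(1.0, float(np.abs(y).max())))


def robust_exp_fit(
    bin_table: BinTable,
    pseudo: float | None = None,
    max_iter: int = 200,
    tol: float = 1e-8,
) -> BinTable:
    """Robust exponential regression of Hda1 on Rpb3 over genome bins.

    Fits log(hda1 + c) = alpha + beta * rpb3 by IRLS with Tukey bisquare
    weights, re-estimating the robust residual scale (normalized MAD)
    each iteration. Standardized residuals (residual / scale) are stored
    on the table; flagging is a separate step.
    """
    rpb3 = np.asarray(bin_table.rpb3, dtype=float)
    hda1 = np.asarray(bin_table.hda1, dtype=float)
    finite = np.isfinite(rpb3) & np.isfinite(hda1)
    if finite.sum() < 100:
        raise ValueError(f"need >=100 finite bins, got {int(finite.sum())}")
    if np.ptp(rpb3[finite]) == 0:
        raise ValueError("degenerate Rpb3 signal (zero variance)")
    c = default_pseudocount(hda1[finite]) if pseudo is None else float(pseudo)
    if c < 0:
        raise ValueError("pseudo-count must be non-negative")

    with np.errstate(divide="ignore"):
        y_all = np.log(hda1 + c)
    finite &= np.isfinite(y_all)
    if finite.sum() < 100:
        raise ValueError("need >=100 bins with positive (hda1 + pseudo)")
    x = rpb3[finite]
    y = y_all[finite]
    X = np.column_stack([np.ones_like(x), x])

    beta_vec, *_ = np.linalg.lstsq(X, y, rcond=None)  # OLS start
    converged = False
    it = 0
    scale = 1.0
    for it in range(1, max_iter + 1):
        resid = y - X @ beta_vec
        if _is_perfect_fit(resid, y):
            converged = True
            break
        scale = _mad_scale(resid)
        if scale <= 0:
            scale = max(np.abs(resid).max(), np.finfo(float).tiny)
            converged = True
            break
        u = resid / (TUKEY_TUNING * scale)
        w = np.where(np.abs(u) < 1, (1 - u**2) ** 2, 0.0)
        if w.sum() == 0:
            break
        WX = X * w[:, None]
        new_beta = np.linalg.solve(X.T @ WX, WX.T @ y)
        delta = np.max(np.abs(new_beta - beta_vec))
        beta_vec = new_beta
        if delta < tol:
            converged = True
            break
    resid = y - X @ beta_vec
    if _is_perfect_fit(resid, y):
        final_scale = max(np.abs(resid).max(), np.finfo(float).tiny)
    else:
        final_scale = _mad_scale(resid)
        if final_scale <= 0:
            final_scale = max(np.abs(resid).max(), np.finfo(float).tiny)

    fitted = np.full(len(rpb3), np.nan)
    std_resid = np.full(len(rpb3), np.nan)
    fitted[finite] = beta_vec[0] + beta_vec[1] * x
    std_resid[finite] = resid / final_scale

    bin_table.fitted = fitted
    bin_table.std_residual = std_resid
    bin_table.fit = RegressionFit(
        alpha=float(beta_vec[0]),
        beta=float(beta_vec[1]),
        scale=final_scale,
        n_used=int(finite.sum()),
        converged=converged,
        n_iter=it,
        pseudo=c,
    )
    return bin_table


def flag_outlier_bins(
    bin_table_or_residuals,
    threshold: float = DEFAULT_RESIDUAL_THRESHOLD,
) -> np.ndarray:
    """Flag bins whose standardized residual exceeds the threshold.

    One-sided: only Hda1 excess over the Pol II prediction is flagged
    (Pol II-independent binding). Accepts a :class:`BinTable` (flags are
    stored on it) or a bare residual array; returns the boolean mask.
    """
    if isinstance(bin_table_or_residuals, BinTable):
        resid = bin_table_or_residuals.std_residual
        if resid is None:
            raise ValueError("run robust_exp_fit before flagging")
        mask = np.nan_to_num(resid, nan=-np.inf) > threshold
        bin_table_or_residuals.independent = mask
        return mask
    resid = np.asarray(bin_table_or_residuals, dtype=float)
    return np.nan_to_num(resid, nan=-np.inf) > threshold


def independent_bin_intervals(bin_table: BinTable) -> list:
    """Genomic intervals of the flagged Pol II-independent bins."""
    if bin_table.independent is None:
        raise ValueError("run flag_outlier_bins first")
    return [
        b.interval for b, flag in zip(bin_table.bins, bin_table.independent) if flag
    ]


def split_peaks_by_polii(
    hda1_peaks: Sequence[Peak],
    rpb3_peaks: Sequence[Peak],
    min_len: int = 100,
) -> tuple[list[Peak], list[Peak]]:
    """Split Hda1 peaks into Pol II-associated and -independent sets.

    Peaks shorter than ``min_len`` bp are excluded first. A retained peak
    overlapping any Rpb3 peak by >= 1 bp is associated; otherwise
    independent. The two lists partition the retained peaks and carry the
    label in ``peak.polii``.
    """
    retained = [p for p in hda1_peaks if p.length >= min_len]
    by_chrom: dict[str, list[Peak]] = {}
    for rp in rpb3_peaks:
        by_chrom.setdefault(rp.interval.chrom, []).append(rp)
    associated, independent = [], []
    for p in retained:
        hit = any(
            p.interval.overlaps(rp.interval)
            for rp in by_chrom.get(p.interval.chrom, ())
        )
        p.polii = "associated" if hit else "independent"
        (associated if hit else independent).append(p)
    return associated, independent
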
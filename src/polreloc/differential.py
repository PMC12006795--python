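"""Per-gene differential occupancy between conditions.

A negative-binomial Wald test in the DESeq2 mold, at desk scale:
median-of-ratios size factors (or externally supplied spike-in factors),
per-gene method-of-moments dispersion shrunk toward a fitted
mean-dispersion trend, and a Wald test on the log2 fold change of
normalized means. Genes pass/fail a two-fold change + FDR 0.01 rule into
repressed / induced / unchanged classes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

LOG2FC_PSEUDOCOUNT = 0.5
MIN_DISPERSION = 1e-8


@dataclass(frozen=True)
class DifferentialResult:
    gene_id: str
    base_mean: float
    log2fc: float
    pvalue: float
    fdr: float
    klass: str  # repressed | induced | unchanged | NA


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors over genes with all-positive counts."""
    if counts.shape[1] < 2:
        raise ValueError("need at least two samples")
    positive = counts[(counts > 0).all(axis=1)]
    if len(positive) == 0:
        raise ValueError(
            "no gene with all-positive counts; supply external (e.g. "
            "spike-in) size factors or a pseudo-reference"
        )
    log_geo_mean = np.log(positive).mean(axis=1)
    ratios = np.log(positive).sub(log_geo_mean, axis=0)
    return np.exp(ratios.median(axis=0)).rename("size_factor")


def spike_size_factors(
    spike_counts: Mapping[str, "object"], samples: Sequence[str]
) -> pd.Series:
    """Size factors from spike-in reads, normalized to geometric mean 1.

    The spike chromatin is constant across samples, so spike read counts
    measure each sample's depth-times-efficiency nuisance directly; using
    them sidesteps the median-of-ratios assumption that most genes are
    unchanged between conditions.
    """
    raw = []
    for s in samples:
        sc = spike_counts[s]
        if sc.spike_reads <= 0:
            raise ValueError(f"sample {s!r} has no spike reads")
        raw.append(sc.spike_reads)
    raw = np.asarray(raw, dtype=float)
    return pd.Series(raw / np.exp(np.mean(np.log(raw))), index=list(samples))


def _trend_dispersion(base_means: np.ndarray, disps: np.ndarray) -> np.ndarray:
    """Fit dispersion ~ a0 + a1/mean on genes with positive raw dispersion."""
    ok = (disps > 0) & (base_means > 0)
    if ok.sum() < 10:
        fallback = float(np.median(disps[ok])) if ok.any() else 0.1
        return np.full_like(base_means, max(fallback, MIN_DISPERSION))
    X = np.column_stack([np.ones(ok.sum()), 1.0 / base_means[ok]])
    coef, *_ = np.linalg.lstsq(X, disps[ok], rcond=None)
    a0, a1 = coef
    trend = a0 + a1 / np.maximum(base_means, 1e-8)
    return np.maximum(trend, MIN_DISPERSION)


def nb_wald_test(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    size_factors: pd.Series,
    condition_order: tuple[str, str] | None = None,
    trend_shrinkage: float = 0.5,
) -> pd.DataFrame:
    """Per-gene NB Wald test of condition B vs condition A.

    ``design`` maps sample -> condition; ``condition_order`` names
    (reference, treatment) so log2fc = log2(treatment / reference)
    (defaults to the design's first two distinct conditions in order).
    Dispersions are gene-wise method-of-moments estimates shrunk toward a
    fitted 1/mean trend with weight ``trend_shrinkage``. Genes with zero
    counts everywhere are returned NA and excluded from FDR.
    """
    design = design.set_index("sample") if "sample" in design else design
    cond = design["condition"]
    levels = list(dict.fromkeys(cond))
    if condition_order is None:
        if len(levels) != 2:
            raise ValueError(f"expected exactly two conditions, got {levels}")
        condition_order = (levels[0], levels[1])
    ref, trt = condition_order
    cols_ref = [s for s in counts.columns if cond.get(s) == ref]
    cols_trt = [s for s in counts.columns if cond.get(s) == trt]
    if not cols_ref or not cols_trt:
        raise ValueError("each condition needs at least one sample column")

    sf = size_factors.reindex(counts.columns)
    norm = counts.div(sf, axis=1)
    raw = counts.values.astype(float)

    mu_ref = norm[cols_ref].mean(axis=1).values
    mu_trt = norm[cols_trt].mean(axis=1).values
    base_mean = norm.mean(axis=1).values

    # method-of-moments NB dispersion pooled across both conditions:
    # Var = mu + alpha * mu^2  =>  alpha = (Var - mu) / mu^2
    n_r, n_t = len(cols_ref), len(cols_trt)
    if n_r > 1 or n_t > 1:
        resid_var = np.zeros(len(counts))
        dof = 0
        for cols, mu in ((cols_ref, mu_ref), (cols_trt, mu_trt)):
            if len(cols) > 1:
                v = norm[cols].var(axis=1, ddof=1).values
                resid_var += v * (len(cols) - 1)
                dof += len(cols) - 1
        pooled_var = resid_var / max(dof, 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            disp_raw = (pooled_var - base_mean) / base_mean**2
        disp_raw = np.where(np.isfinite(disp_raw), disp_raw, 0.0)
    else:
        disp_raw = np.zeros(len(counts))
    disp_trend = _trend_dispersion(base_mean, np.maximum(disp_raw, 0.0))
    disp = np.maximum(
        (1 - trend_shrinkage) * np.maximum(disp_raw, 0.0)
        + trend_shrinkage * disp_trend,
        MIN_DISPERSION,
    )

    c = LOG2FC_PSEUDOCOUNT
    log2fc = np.log2(mu_trt + c) - np.log2(mu_ref + c)

    # Wald SE via the delta method on log2 of NB means:
    # Var(mean of k reps) = (mu + alpha mu^2) / k (normalized scale);
    # Var(log2(mu + c)) ~= Var(mu) / ((mu + c) ln 2)^2
    ln2 = np.log(2.0)
    var_ref = (mu_ref + disp * mu_ref**2) / n_r
    var_trt = (mu_trt + disp * mu_trt**2) / n_t
    se = np.sqrt(
        var_ref / ((mu_ref + c) * ln2) ** 2 + var_trt / ((mu_trt + c) * ln2) ** 2
    )
    testable = raw.sum(axis=1) > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        wald = np.where(se > 0, log2fc / se, 0.0)
    pvalue = np.where(testable, 2 * stats.norm.sf(np.abs(wald)), np.nan)

    out = pd.DataFrame(
        {
            "gene_id": counts.index,
            "baseMean": base_mean,
            "log2fc": np.where(testable, log2fc, np.nan),
            "pvalue": pvalue,
            "dispersion": disp,
        }
    ).set_index("gene_id")
    return out


def classify_genes(
    results: pd.DataFrame,
    fc_threshold: float = 2.0,
    fdr_threshold: float = 0.01,
) -> pd.DataFrame:
    """BH-adjust p-values and classify genes by fold change and FDR.

    repressed: log2fc <= -log2(fc_threshold) and fdr < fdr_threshold;
    induced: log2fc >= log2(fc_threshold) and fdr < fdr_threshold;
    unchanged otherwise. Untestable (all-zero) genes stay NA.
    """
    out = results.copy()
    testable = out["pvalue"].notna()
    fdr = np.full(len(out), np.nan)
    if testable.any():
        _, q, _, _ = multipletests(out.loc[testable, "pvalue"], method="fdr_bh")
        fdr[testable.values] = q
    out["fdr"] = fdr
    lfc_cut = np.log2(fc_threshold)
    klass = np.where(
        ~testable,
        "NA",
        np.where(
            (out["log2fc"] <= -lfc_cut) & (out["fdr"] < fdr_threshold),
            "repressed",
            np.where(
                (out["log2fc"] >= lfc_cut) & (out["fdr"] < fdr_threshold),
                "induced",
                "unchanged",
            ),
        ),
    )
    out["klass"] = klass
    return out


def occupancy_change_correlation(
    hda1_changes: pd.Series, rpb3_changes: pd.Series
) -> tuple[float, int]:
    """Pearson correlation of paired per-gene log2 occupancy changes."""
    df = pd.concat(
        {"hda1": hda1_changes, "rpb3": rpb3_changes}, axis=1, join="inner"
    ).dropna()
    if len(df) < 3:
        raise ValueError(f"need >=3 complete pairs, got {len(df)}")
    r, _ = stats.pearsonr(df["hda1"], df["rpb3"])
    return float(r), len(df)
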
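"""Disease differential-expression signature from a bulk count matrix.

A deliberately transparent two-group pipeline for negative-binomially
distributed RNA-seq counts:

* median-of-ratios size factors (each sample's median ratio to the
  per-gene geometric-mean reference);
* a gene-wise Wald test on the difference of log normalized group
  means (variance model Var(K) = mu + alpha * mu^2), with
  method-of-moments NB dispersion pooled across the two groups and
  shrunk toward a mean-binned trend (gene-wise estimates at 2-3
  replicates per group are far too noisy to use raw — the shrinkage
  weight is the moment estimator's degrees of freedom against a
  ``prior_df`` pseudo-count on the trend);
* Benjamini-Hochberg FDR;
* direction labels: up if FDR < fdr_cut and log2FC >= lfc_cut, down if
  FDR < fdr_cut and log2FC <= -lfc_cut, otherwise ns.

No dispersion shrinkage, no outlier replacement, no independent
filtering — the trade-offs are documented in the methods note.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["size_factors", "nb_wald_test", "bh_adjust", "label_degs", "deg_summary"]

DISPERSION_FLOOR = 1e-8


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios normalization factors, one per sample (column).

    The reference profile is the per-gene geometric mean over samples;
    only genes with strictly positive counts in every sample enter the
    median.  Scaling one sample's counts by λ scales its factor by λ.
    """
    mat = counts.to_numpy(dtype=float)
    if (mat < 0).any():
        raise ValueError("counts must be non-negative")
    all_pos = (mat > 0).all(axis=1)
    if not all_pos.any():
        raise ValueError(
            "no gene is expressed in every sample; median-of-ratios needs at "
            "least one all-positive gene (consider a pseudo-reference fallback)"
        )
    logs = np.log(mat[all_pos])
    log_ref = logs.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(logs - log_ref, axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def nb_wald_test(
    counts: pd.DataFrame,
    groups: Sequence[str],
    reference: str,
    factors: pd.Series | None = None,
    pseudocount: float = 0.5,
    prior_df: float = 20.0,
    n_trend_bins: int = 20,
) -> pd.DataFrame:
    """Two-group NB Wald test; returns gene, log2fc, p.

    ``groups`` gives one label per sample column; ``reference`` names the
    baseline group (log2fc is treatment over reference).  Each group
    needs >= 2 samples so the method-of-moments dispersion is estimable.
    Gene-wise dispersions are shrunk toward the median dispersion of
    genes with similar mean expression (``n_trend_bins`` quantile bins),
    with the trend carrying ``prior_df`` pseudo-degrees of freedom
    against the gene's own n1 + n2 - 2.  Genes with zero counts
    everywhere get p = 1 and log2fc = 0.
    """
    labels = np.asarray(list(groups))
    if len(labels) != counts.shape[1]:
        raise ValueError("one group label per sample column required")
    uniq = pd.unique(labels)
    if len(uniq) != 2:
        raise ValueError(f"exactly two groups required, got {list(uniq)}")
    if reference not in uniq:
        raise ValueError(f"reference {reference!r} not among groups {list(uniq)}")
    treatment = uniq[uniq != reference][0]
    idx1 = labels == reference
    idx2 = labels == treatment
    n1, n2 = int(idx1.sum()), int(idx2.sum())
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs >= 2 samples (dispersion not estimable)")

    if factors is None:
        factors = size_factors(counts)
    s = factors.to_numpy(dtype=float)
    y = counts.to_numpy(dtype=float) / s  # normalized counts

    y1, y2 = y[:, idx1], y[:, idx2]
    m1, m2 = y1.mean(axis=1), y2.mean(axis=1)
    v1 = y1.var(axis=1, ddof=1)
    v2 = y2.var(axis=1, ddof=1)

    # MoM dispersion: Var(y_ij) = mu/s_j + alpha*mu^2, pooled across groups
    c1 = (1.0 / s[idx1]).mean()
    c2 = (1.0 / s[idx2]).mean()
    with np.errstate(divide="ignore", invalid="ignore"):
        a1 = (v1 - m1 * c1) / m1**2
        a2 = (v2 - m2 * c2) / m2**2
    a1 = np.where(m1 > 0, a1, np.nan)
    a2 = np.where(m2 > 0, a2, np.nan)
    w1 = np.where(np.isnan(a1), 0.0, n1 - 1)
    w2 = np.where(np.isnan(a2), 0.0, n2 - 1)
    alpha_gene = (np.nan_to_num(a1) * w1 + np.nan_to_num(a2) * w2) / np.maximum(w1 + w2, 1)

    # shrink toward the median dispersion of similarly expressed genes
    base_mean = y.mean(axis=1)
    alpha_trend = _dispersion_trend(base_mean, alpha_gene, n_trend_bins)
    df_gene = n1 + n2 - 2
    alpha = (df_gene * np.maximum(alpha_gene, 0.0) + prior_df * alpha_trend) / (
        df_gene + prior_df
    )
    alpha = np.maximum(alpha, DISPERSION_FLOOR)

    mu1 = m1 + pseudocount
    mu2 = m2 + pseudocount
    var_m1 = (m1 * (1.0 / s[idx1]).sum() / n1**2) + alpha * m1**2 / n1
    var_m2 = (m2 * (1.0 / s[idx2]).sum() / n2**2) + alpha * m2**2 / n2
    se2 = var_m1 / mu1**2 + var_m2 / mu2**2
    se2 = np.maximum(se2, 1e-300)

    log2fc = np.log2(mu2 / mu1)
    wald = (np.log(mu2) - np.log(mu1)) / np.sqrt(se2)
    p = 2.0 * stats.t.sf(np.abs(wald), df=df_gene + prior_df)

    allzero = (m1 == 0) & (m2 == 0)
    p = np.where(allzero, 1.0, p)
    log2fc = np.where(allzero, 0.0, log2fc)

    return pd.DataFrame({"gene": counts.index, "log2fc": log2fc, "p": p}).reset_index(drop=True)


def _dispersion_trend(base_mean: np.ndarray, alpha_gene: np.ndarray, n_bins: int) -> np.ndarray:
    """Median raw dispersion within quantile bins of mean expression.

    The median over a bin is robust both to the moment estimator's noise
    and to the minority of genuinely high-dispersion genes.  Bins with
    no informative gene fall back to the global median.
    """
    ok = np.isfinite(alpha_gene) & (base_mean > 0)
    trend = np.full(base_mean.shape, np.nan)
    if ok.sum() == 0:
        return np.zeros_like(base_mean)
    global_med = max(float(np.median(alpha_gene[ok])), 0.0)
    n_bins = max(1, min(n_bins, int(ok.sum())))
    edges = np.quantile(base_mean[ok], np.linspace(0, 1, n_bins + 1))
    edges[0], edges[-1] = -np.inf, np.inf
    which = np.searchsorted(edges, base_mean, side="right") - 1
    which = np.clip(which, 0, n_bins - 1)
    for b in range(n_bins):
        in_bin = ok & (which == b)
        med = float(np.median(alpha_gene[in_bin])) if in_bin.any() else global_med
        trend[which == b] = max(med, 0.0)
    return np.where(np.isfinite(trend), trend, global_med)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values (FDR)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def label_degs(
    table: pd.DataFrame,
    fdr_cut: float = 0.05,
    lfc_cut: float = 1.0,
) -> pd.DataFrame:
    """Attach an fdr column (if absent) and up/down/ns direction labels.

    Significance is strict (fdr < fdr_cut); the fold-change bound is
    inclusive (|log2fc| >= lfc_cut).
    """
    out = table.copy()
    if "fdr" not in out.columns:
        out["fdr"] = bh_adjust(out["p"].to_numpy())
    sig = out["fdr"] < fdr_cut
    up = sig & (out["log2fc"] >= lfc_cut)
    down = sig & (out["log2fc"] <= -lfc_cut)
    out["direction"] = np.where(up, "up", np.where(down, "down", "ns"))
    return out


def deg_summary(labelled: pd.DataFrame, fdr_cut: float = 0.05, lfc_cut: float = 1.0) -> dict:
    """Counts of significant / up / down / significant-but-small-effect genes."""
    sig = labelled["fdr"] < fdr_cut
    up = int((labelled["direction"] == "up").sum())
    down = int((labelled["direction"] == "down").sum())
    small = int((sig & (labelled["log2fc"].abs() < lfc_cut)).sum())
    return {
        "total_significant": int(sig.sum()),
        "up": up,
        "down": down,
        "significant_below_fold_cut": small,
    }
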
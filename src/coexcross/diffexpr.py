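"""Two-group differential expression screen for RNA-seq counts.

A deliberately simple, documented negative-binomial Wald test:

1. library-size correction by median-of-ratios size factors;
2. per-gene NB model with a method-of-moments dispersion estimate
   (Var = mu + alpha * mu^2, single alpha per gene pooled across groups,
   floored at 1e-8);
3. Wald statistic on the log ratio of group means via the delta method,
   two-sided p from the normal reference;
4. Benjamini-Hochberg adjustment across tested genes.

Genes flagged as differentially expressed (DEG) satisfy
|fold change| > 1.2 and raw p < 0.05 by default; the raw p drives the flag,
the adjusted p is reported alongside. A pseudo-count of 0.5 stabilises the
log2 fold change when a group mean is zero.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

PSEUDO_COUNT = 0.5
DISPERSION_FLOOR = 1e-8

DE_COLUMNS = ["baseMean", "log2FC", "pvalue", "padj", "is_deg"]


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, one positive real per sample.

    Only genes with a positive geometric mean across all samples (i.e.
    nonzero in every sample) contribute to the medians.
    """
    if counts.shape[1] < 2:
        raise ValueError("size factors require at least 2 samples")
    x = counts.to_numpy(dtype=float)
    positive = (x > 0).all(axis=1)
    if not positive.any():
        raise ValueError("no gene has nonzero counts in all samples; cannot normalize")
    logx = np.log(x[positive])
    log_geomean = logx.mean(axis=1)
    factors = np.exp(np.median(logx - log_geomean[:, None], axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def _moment_dispersion(y: np.ndarray, groups: list[np.ndarray], inv_s: np.ndarray) -> np.ndarray:
    """Per-gene dispersion alpha pooled across groups, floored.

    For normalized counts y_ij = K_ij / s_j the within-group variance has
    expectation q * mean_j(1/s_j) + alpha * q^2; solving for alpha per group
    and weighting by group degrees of freedom pools the two estimates.
    """
    num = np.zeros(y.shape[0])
    den = 0.0
    for idx in groups:
        n = len(idx)
        m = y[:, idx].mean(axis=1)
        v = y[:, idx].var(axis=1, ddof=1)
        shot = m * inv_s[idx].mean()
        with np.errstate(divide="ignore", invalid="ignore"):
            a = np.where(m > 0, (v - shot) / np.maximum(m, 1e-300) ** 2, 0.0)
        num += (n - 1) * a
        den += n - 1
    return np.maximum(num / den, DISPERSION_FLOOR)


def de_test(counts: pd.DataFrame, groups: pd.Series, case: str = "case", control: str = "control") -> pd.DataFrame:
    """NB Wald differential expression, case vs control.

    ``groups`` maps sample id to group label; both groups need >= 2 samples.
    Genes with all-zero counts in both groups get NA statistics and are
    excluded from the BH family size.
    """
    groups = groups.reindex(counts.columns)
    if groups.isna().any():
        raise ValueError("every sample column needs a group label")
    case_idx = np.flatnonzero((groups == case).to_numpy())
    ctrl_idx = np.flatnonzero((groups == control).to_numpy())
    if len(case_idx) < 2 or len(ctrl_idx) < 2:
        raise ValueError("each group requires at least 2 samples")

    sf = size_factors(counts).to_numpy()
    x = counts.to_numpy(dtype=float)
    y = x / sf  # normalized counts
    inv_s = 1.0 / sf

    tested = x[:, np.concatenate([case_idx, ctrl_idx])].sum(axis=1) > 0
    alpha = _moment_dispersion(y, [case_idx, ctrl_idx], inv_s)

    res = pd.DataFrame(index=counts.index, columns=DE_COLUMNS, dtype=float)
    res["is_deg"] = False
    base_mean = y.mean(axis=1)

    m1 = y[:, case_idx].mean(axis=1)
    m0 = y[:, ctrl_idx].mean(axis=1)
    log2fc = np.log2((m1 + PSEUDO_COUNT) / (m0 + PSEUDO_COUNT))

    # delta-method variance of log(group mean + pseudo-count) under NB noise
    def _var_log_mean(m: np.ndarray, idx: np.ndarray) -> np.ndarray:
        n = len(idx)
        var_m = m * inv_s[idx].sum() / n**2 + alpha * m**2 / n
        return var_m / (m + PSEUDO_COUNT) ** 2

    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(_var_log_mean(m1, case_idx) + _var_log_mean(m0, ctrl_idx))
        z = np.where(se > 0, (np.log(m1 + PSEUDO_COUNT) - np.log(m0 + PSEUDO_COUNT)) / np.where(se > 0, se, 1.0), 0.0)
    pval = 2.0 * stats.norm.sf(np.abs(z))

    res.loc[tested, "baseMean"] = base_mean[tested]
    res.loc[tested, "log2FC"] = log2fc[tested]
    res.loc[tested, "pvalue"] = pval[tested]
    res["padj"] = bh_adjust(res["pvalue"].to_numpy())
    n_dropped = int((~tested).sum())
    if n_dropped:
        log.info("de_test: %d all-zero gene(s) reported as NA and excluded from BH", n_dropped)
    return res


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up in input order; NA propagated, excluded from m."""
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        out[ok] = stats.false_discovery_control(p[ok], method="bh")
    return out


def filter_degs(de: pd.DataFrame, fc_threshold: float = 1.2, p_threshold: float = 0.05) -> set[str]:
    """Genes with |log2FC| > log2(fc_threshold) and raw p < p_threshold (strict)."""
    if fc_threshold <= 1:
        raise ValueError(f"fc_threshold must exceed 1, got {fc_threshold}")
    if not (0 < p_threshold <= 1):
        raise ValueError(f"p_threshold must lie in (0, 1], got {p_threshold}")
    lfc = de["log2FC"]
    p = de["pvalue"]
    mask = (lfc.abs() > np.log2(fc_threshold)) & (p < p_threshold)
    mask &= lfc.notna() & p.notna()
    return set(de.index[mask])


def flag_degs(de: pd.DataFrame, fc_threshold: float = 1.2, p_threshold: float = 0.05) -> pd.DataFrame:
    """Return a copy of the DE table with the is_deg flag filled in."""
    degs = filter_degs(de, fc_threshold, p_threshold)
    out = de.copy()
    out["is_deg"] = out.index.isin(degs)
    return out
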
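"""Weighted co-expression module detection.

The chain follows the WGCNA recipe: Pearson correlation of log-normalized
expression, soft-threshold adjacency a_ij = |r_ij|^beta (unsigned network),
topological overlap TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij)
with l_ij = sum_u a_iu a_uj, average-linkage clustering of 1 - TOM, a static
tree cut into modules of at least ``min_module_size`` genes, eigengene-based
module merging below a dissimilarity threshold, and kME / hub-gene calls.

Two deliberate simplifications relative to the reference R tool, documented
in the methods note: a static cut (default height 0.99 on 1 - TOM) replaces
the dynamic hybrid cut, and module merging uses eigengene dissimilarity
1 - cor(ME_a, ME_b) < merge_height (default 0.15). Module labels are
positive integers in decreasing size order; 0 is the unassigned ("grey")
label. Hub genes are module members with kME strictly above 0.8.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .diffexpr import size_factors

log = logging.getLogger(__name__)

UNASSIGNED = 0
VARIANCE_FLOOR = 1e-12


def expression_transform(counts: pd.DataFrame) -> pd.DataFrame:
    """log2(normalized count + 1); constant genes dropped with a logged list."""
    sf = size_factors(counts)
    expr = np.log2(counts.div(sf, axis=1) + 1.0)
    variances = expr.var(axis=1, ddof=1)
    keep = variances > VARIANCE_FLOOR
    dropped = expr.index[~keep].tolist()
    if dropped:
        log.info("expression_transform: dropped %d zero-variance gene(s): %s%s",
                 len(dropped), ", ".join(dropped[:10]), "..." if len(dropped) > 10 else "")
    return expr.loc[keep]


def adjacency(expr: pd.DataFrame, power: float) -> pd.DataFrame:
    """Unsigned soft-threshold adjacency |pearson|^power, zero diagonal."""
    if expr.shape[1] < 3:
        raise ValueError("adjacency requires at least 3 samples")
    if power < 1:
        raise ValueError(f"soft-threshold power must be >= 1, got {power}")
    r = np.corrcoef(expr.to_numpy(dtype=float))
    r = np.clip(np.nan_to_num(r, nan=0.0), -1.0, 1.0)
    a = np.abs(r) ** power
    np.fill_diagonal(a, 0.0)
    return pd.DataFrame(a, index=expr.index, columns=expr.index)


def scale_free_fit(adj: pd.DataFrame, n_bins: int = 10) -> float:
    """R^2 of the log10 p(k) vs log10 k regression (scale-free topology fit).

    Connectivities are binned into ``n_bins`` equal-width bins; empty bins
    are skipped. Degenerate connectivity (all equal) returns 0 with a warning.
    """
    if adj.shape[0] < 20:
        raise ValueError("scale-free fit needs at least 20 genes")
    k = adj.to_numpy().sum(axis=1)
    if np.ptp(k) < 1e-12:
        log.warning("scale_free_fit: all connectivities equal; returning 0")
        return 0.0
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    logk, logp = [], []
    for b in range(n_bins):
        mask = which == b
        if mask.sum() == 0:
            continue
        km = k[mask].mean()
        if km <= 0:
            continue
        logk.append(np.log10(km))
        logp.append(np.log10(mask.mean()))
    if len(logk) < 3:
        log.warning("scale_free_fit: fewer than 3 usable bins; returning 0")
        return 0.0
    r = np.corrcoef(logk, logp)[0, 1]
    return float(r * r)


def tom_similarity(adj: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap matrix; symmetric, entries in [0, 1], unit diagonal."""
    a = adj.to_numpy(dtype=float)
    k = a.sum(axis=1)
    l = a @ a  # diagonal of adj is 0, so the u=i, u=j terms vanish
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = (l + a) / denom
    np.fill_diagonal(tom, 1.0)
    tom = np.clip((tom + tom.T) / 2.0, 0.0, 1.0)
    return pd.DataFrame(tom, index=adj.index, columns=adj.columns)


def cluster_dendrogram(diss: pd.DataFrame) -> np.ndarray:
    """Average-linkage tree on a dissimilarity matrix (scipy linkage format)."""
    if diss.shape[0] < 2:
        raise ValueError("clustering requires at least 2 genes")
    d = diss.to_numpy(dtype=float)
    condensed = squareform((d + d.T) / 2.0, checks=False)
    return hierarchy.linkage(condensed, method="average")


def cut_modules(dendrogram: np.ndarray, genes: pd.Index,
                min_module_size: int = 20, cut_height: float = 0.99) -> pd.Series:
    """Static cut at ``cut_height``; clusters under ``min_module_size`` -> grey.

    Surviving clusters are labeled 1..M in decreasing size order; size ties
    break by the smallest original gene index for determinism.
    """
    if not (0 < cut_height < 1):
        raise ValueError(f"cut_height must lie in (0, 1), got {cut_height}")
    flat = hierarchy.fcluster(dendrogram, t=cut_height, criterion="distance")
    return _relabel_by_size(pd.Series(flat, index=genes), min_module_size)


def _relabel_by_size(raw: pd.Series, min_module_size: int = 1) -> pd.Series:
    """Relabel clusters 1..M by decreasing size (ties: smallest first index)."""
    out = pd.Series(UNASSIGNED, index=raw.index, dtype=int)
    sizes: list[tuple[int, int, int]] = []  # (-size, first_index, label)
    for label in raw[raw != UNASSIGNED].unique():
        members = np.flatnonzero((raw == label).to_numpy())
        if len(members) >= min_module_size:
            sizes.append((-len(members), int(members[0]), int(label)))
    for new, (_, _, old) in enumerate(sorted(sizes), start=1):
        out[raw == old] = new
    return out


def module_eigengenes(expr: pd.DataFrame, assign: pd.Series) -> pd.DataFrame:
    """First principal component per module, unit norm, canonical sign.

    Genes are standardized across samples before the SVD; the eigengene sign
    is flipped when its mean correlation with member genes is negative (a
    mean of exactly zero resolves toward a positive first nonzero loading).
    Returns a modules x samples table.
    """
    assign = assign.reindex(expr.index).fillna(UNASSIGNED).astype(int)
    rows = {}
    for label in sorted(assign[assign != UNASSIGNED].unique()):
        sub = expr.loc[assign[assign == label].index].to_numpy(dtype=float)
        z = _standardize(sub)
        if z.shape[0] == 1:
            me = z[0] / np.linalg.norm(z[0])
        else:
            _, _, vt = np.linalg.svd(z, full_matrices=False)
            me = vt[0]
        corr = _row_correlations(z, me)
        mean_corr = np.nanmean(corr)
        if mean_corr < 0:
            me = -me
        elif mean_corr == 0:
            nz = me[np.abs(me) > 1e-12]
            if nz.size and nz[0] < 0:
                me = -me
        rows[label] = me
    return pd.DataFrame.from_dict(rows, orient="index", columns=expr.columns).rename_axis("module")


def merge_modules(expr: pd.DataFrame, assign: pd.Series,
                  merge_height: float = 0.15) -> pd.Series:
    """Iteratively merge the closest module pair while 1 - cor(ME) < height.

    Eigengenes are recomputed after every merge; final labels are reassigned
    in decreasing size order.
    """
    assign = assign.copy()
    while True:
        labels = sorted(assign[assign != UNASSIGNED].unique())
        if len(labels) < 2:
            break
        me = module_eigengenes(expr, assign)
        corr = np.corrcoef(me.to_numpy())
        diss = 1.0 - corr
        np.fill_diagonal(diss, np.inf)
        i, j = np.unravel_index(np.argmin(diss), diss.shape)
        if diss[i, j] >= merge_height:
            break
        a, b = me.index[i], me.index[j]
        assign[assign == max(a, b)] = min(a, b)
    return _relabel_by_size(assign)


def kme_and_hubs(expr: pd.DataFrame, assign: pd.Series, eigengenes: pd.DataFrame,
                 hub_threshold: float = 0.8) -> pd.DataFrame:
    """Per-gene kME (correlation with own-module eigengene) and hub flag.

    Hubs satisfy kME strictly greater than ``hub_threshold``; unassigned
    genes get NA kME and are never hubs.
    """
    assign = assign.reindex(expr.index).fillna(UNASSIGNED).astype(int)
    kme = pd.Series(np.nan, index=expr.index)
    for label in eigengenes.index:
        members = assign[assign == label].index
        if len(members) == 0:
            continue
        z = _standardize(expr.loc[members].to_numpy(dtype=float))
        kme[members] = _row_correlations(z, eigengenes.loc[label].to_numpy())
    return pd.DataFrame({
        "module": assign,
        "kme": kme,
        "is_hub": kme.notna() & (kme > hub_threshold),
    })


@dataclass
class ModuleDetectionResult:
    """Everything the module stage produces for one tissue."""
    assignment: pd.Series
    eigengenes: pd.DataFrame
    kme: pd.DataFrame
    tom: pd.DataFrame = field(repr=False)


def detect_modules(expr: pd.DataFrame, power: float,
                   min_module_size: int = 20, cut_height: float = 0.99,
                   merge_height: float = 0.15,
                   hub_threshold: float = 0.8) -> ModuleDetectionResult:
    """Full chain: adjacency -> TOM -> cluster -> cut -> merge -> kME/hubs."""
    adj = adjacency(expr, power)
    tom = tom_similarity(adj)
    tree = cluster_dendrogram(1.0 - tom)
    assign = cut_modules(tree, expr.index, min_module_size, cut_height)
    assign = merge_modules(expr, assign, merge_height)
    me = module_eigengenes(expr, assign)
    kme = kme_and_hubs(expr, assign, me, hub_threshold)
    log.info("detect_modules: %d modules, %d/%d genes assigned",
             int((assign.unique() != UNASSIGNED).sum()),
             int((assign != UNASSIGNED).sum()), len(assign))
    return ModuleDetectionResult(assignment=assign, eigengenes=me, kme=kme, tom=tom)


def _standardize(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=0, keepdims=True)
    sd[sd < 1e-12] = 1.0
    return (x - mu) / sd


def _row_correlations(rows: np.ndarray, v: np.ndarray) -> np.ndarray:
    vz = v - v.mean()
    nv = np.linalg.norm(vz)
    rz = rows - rows.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(rz, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (rz @ vz) / (norms * nv)
    return np.where((norms > 1e-12) & (nv > 1e-12), corr, np.nan)
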
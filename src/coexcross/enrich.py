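"""Hypergeometric enrichment machinery.

Covers four uses of the same upper-tail hypergeometric test:

* module x risk-list enrichment (SFARI-like and DVMT-like gene lists),
  with the "dysfunctional module" flag at raw p < 0.05;
* candidate-module selection (modules containing at least one DEG and
  smaller than 500 genes);
* generic over-representation analysis (ORA) of a gene list against a GMT
  collection;
* pivot regulator detection: a TF / miRNA / lncRNA is a pivot of a module
  when it has more than one target inside the module AND its target set is
  hypergeometrically enriched in the module (p < 0.05).

Raw p-values drive the flags, matching how the thresholds are usually
quoted; BH-adjusted values are always reported alongside.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .coexpr import UNASSIGNED
from .diffexpr import bh_adjust

log = logging.getLogger(__name__)

REGULATOR_TYPES = ("TF", "miRNA", "lncRNA")

ENRICHMENT_COLUMNS = ["unit", "k", "n", "K", "N", "pvalue", "padj", "overlap_genes"]


def hypergeom_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N population, K successes, n draws).

    Computed through scipy's log-gamma based survival function; returns 1.0
    for k = 0. Inconsistent arguments are a hard error.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"need 0 <= K,n <= N; got K={K}, n={n}, N={N}")
    if not (0 <= k <= min(n, K)):
        raise ValueError(f"need 0 <= k <= min(n, K); got k={k}, K={K}, n={n}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


@dataclass
class RegulatorTargetMap:
    """Regulator -> (type, target gene set); types TF / miRNA / lncRNA."""

    regulators: dict[str, tuple[str, frozenset[str]]] = field(default_factory=dict)

    def add(self, name: str, rtype: str, targets) -> None:
        if rtype not in REGULATOR_TYPES:
            raise ValueError(f"regulator type must be one of {REGULATOR_TYPES}, got '{rtype}'")
        targets = frozenset(targets)
        if not targets:
            raise ValueError(f"regulator '{name}' has an empty target set")
        if name in self.regulators:
            raise ValueError(f"duplicate regulator id '{name}'")
        self.regulators[name] = (rtype, targets)

    @classmethod
    def from_gmt(cls, sets: dict[str, tuple[str, set[str]]]) -> "RegulatorTargetMap":
        """Build from a GMT collection whose description field is the type."""
        out = cls()
        for name, (rtype, members) in sets.items():
            out.add(name, rtype, members)
        return out

    def to_gmt(self) -> dict[str, tuple[str, frozenset[str]]]:
        return {name: (rtype, targets) for name, (rtype, targets) in self.regulators.items()}

    def __len__(self) -> int:
        return len(self.regulators)


def module_sizes(assign: pd.Series) -> pd.Series:
    sizes = assign[assign != UNASSIGNED].value_counts().sort_index()
    sizes.index.name = "module"
    return sizes


def module_list_enrichment(assign: pd.Series, gene_list, universe=None) -> pd.DataFrame:
    """Hypergeometric enrichment of a gene list in every module (label > 0).

    The universe defaults to the genes carrying a module assignment table
    entry (the co-expression network); the list is intersected with it first.
    An empty list/universe intersection is a configuration error.
    """
    universe = set(assign.index) if universe is None else set(universe)
    in_universe = assign.index.intersection(universe)
    listed = set(gene_list) & set(in_universe)
    if not listed:
        raise ValueError("gene list has no overlap with the universe")
    N = len(in_universe)
    K = len(listed)
    rows = []
    sub = assign.loc[in_universe]
    for label in sorted(sub[sub != UNASSIGNED].unique()):
        members = set(sub[sub == label].index)
        overlap = members & listed
        k, n = len(overlap), len(members)
        p = hypergeom_tail(k, K, n, N)
        rows.append({"unit": label, "k": k, "n": n, "K": K, "N": N,
                     "pvalue": p, "overlap_genes": ",".join(sorted(overlap))})
    df = pd.DataFrame(rows, columns=[c for c in ENRICHMENT_COLUMNS if c != "padj"])
    df["padj"] = bh_adjust(df["pvalue"].to_numpy())
    return df[ENRICHMENT_COLUMNS]


def select_candidate_modules(assign: pd.Series, degs, max_size: int = 500) -> list[int]:
    """Modules containing at least one DEG and strictly smaller than max_size."""
    degs = set(degs)
    out = []
    for label, size in module_sizes(assign).items():
        if size >= max_size:
            continue
        members = set(assign[assign == label].index)
        if members & degs:
            out.append(int(label))
    return out


def flag_dysfunctional(enrich_sfari: pd.DataFrame, enrich_dvmt: pd.DataFrame,
                       alpha: float = 0.05) -> pd.DataFrame:
    """Per-module significance flags; dysfunctional = enriched in either list."""
    sfari = enrich_sfari.set_index("unit")["pvalue"]
    dvmt = enrich_dvmt.set_index("unit")["pvalue"]
    labels = sorted(set(sfari.index) | set(dvmt.index))
    rows = []
    for label in labels:
        ps = sfari.get(label, np.nan)
        pd_ = dvmt.get(label, np.nan)
        s_sig = bool(ps < alpha) if not np.isnan(ps) else False
        d_sig = bool(pd_ < alpha) if not np.isnan(pd_) else False
        rows.append({"module": label, "p_sfari": ps, "p_dvmt": pd_,
                     "sfari_significant": s_sig, "dvmt_significant": d_sig,
                     "dysfunctional": s_sig or d_sig})
    return pd.DataFrame(rows)


def ora_gmt(gene_list, collection: dict[str, tuple[str, set[str]]], universe,
            padj_alpha: float = 0.05) -> pd.DataFrame:
    """Over-representation of a gene list against a GMT collection.

    One hypergeometric test per set (sets without universe overlap are
    skipped with a log line); BH across the collection; sorted by padj.
    """
    if not collection:
        raise ValueError("empty gene-set collection")
    universe = set(universe)
    listed = set(gene_list) & universe
    n = len(listed)
    N = len(universe)
    rows = []
    for name, (_, members) in collection.items():
        inset = set(members) & universe
        if not inset:
            log.info("ora_gmt: set '%s' has no universe overlap; skipped", name)
            continue
        overlap = inset & listed
        p = hypergeom_tail(len(overlap), len(inset), n, N)
        rows.append({"unit": name, "k": len(overlap), "n": n, "K": len(inset), "N": N,
                     "pvalue": p, "overlap_genes": ",".join(sorted(overlap))})
    df = pd.DataFrame(rows, columns=[c for c in ENRICHMENT_COLUMNS if c != "padj"])
    df["padj"] = bh_adjust(df["pvalue"].to_numpy())
    df["significant"] = df["padj"] < padj_alpha
    return df.sort_values(["padj", "pvalue", "unit"], kind="stable").reset_index(drop=True)


PIVOT_COLUMNS = ["regulator", "type", "module", "k", "K", "n", "N", "pvalue", "padj", "is_pivot"]


def pivot_regulators(regmap: RegulatorTargetMap, assign: pd.Series,
                     candidate_modules, universe=None, alpha: float = 0.05,
                     min_targets: int = 2) -> pd.DataFrame:
    """Test every regulator against every candidate module.

    For a regulator with targets T and module M inside universe U:
    k = |T n M|, K = |T n U|, n = |M|, N = |U|; pivot iff k >= min_targets
    (the ">1 interactions" rule, read module-locally) and p < alpha. A
    regulator may be a pivot of several modules.
    """
    universe = set(assign.index) if universe is None else set(universe)
    sub = assign.loc[assign.index.intersection(universe)]
    N = len(sub)
    members = {int(label): set(sub[sub == label].index)
               for label in sorted(set(int(m) for m in candidate_modules))}
    rows = []
    for name, (rtype, targets) in sorted(regmap.regulators.items()):
        tu = set(targets) & set(sub.index)
        K = len(tu)
        for label, mem in members.items():
            k = len(tu & mem)
            p = hypergeom_tail(k, K, len(mem), N) if K else 1.0
            rows.append({"regulator": name, "type": rtype, "module": label,
                         "k": k, "K": K, "n": len(mem), "N": N, "pvalue": p})
    df = pd.DataFrame(rows, columns=[c for c in PIVOT_COLUMNS if c not in ("padj", "is_pivot")])
    df["padj"] = bh_adjust(df["pvalue"].to_numpy())
    df["is_pivot"] = (df["k"] >= min_targets) & (df["pvalue"] < alpha)
    return df[PIVOT_COLUMNS]
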
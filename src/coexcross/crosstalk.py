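"""Cross-tissue module crosstalk via a permutation null on the PPI network.

For a module pair (one module per tissue) the statistic is the number of
PPI edges running between the two gene sets. The null redraws both sets —
same sizes, uniformly without replacement from the full network node set —
and counts inter-set edges per draw; the empirical p is the fraction of
draws reaching at least the observed count, with no pseudo-count (a
zero-exceedance result is reported as p < 1/n_perm). The default is
100,000 draws per pair.

Tissue-specific modules are the candidate modules containing at least one
gene that is both differentially expressed and on the tissue-specific gene
list (the "strict" reading); a "loose" reading — the module touches the
tissue list and separately contains a DEG — is available via a flag.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .coexpr import UNASSIGNED
from .diffexpr import bh_adjust
from .netcore import inter_set_edge_count

log = logging.getLogger(__name__)

CROSSTALK_COLUMNS = ["module_a", "module_b", "size_a", "size_b", "e_obs",
                     "n_perm", "b", "p", "p_bh", "p_report", "significant"]


def tissue_specific_modules(assign: pd.Series, degs, tissue_genes,
                            candidate_modules, strict: bool = True) -> list[int]:
    """Candidate modules qualifying as tissue-specific.

    strict (default): the module contains a gene in degs AND tissue_genes.
    loose: the module intersects tissue_genes and (separately) contains a DEG.
    """
    tissue_genes = set(tissue_genes)
    if not tissue_genes:
        raise ValueError("tissue-specific gene list is empty")
    degs = set(degs)
    out = []
    for label in sorted(set(int(m) for m in candidate_modules)):
        members = set(assign[assign == label].index)
        if strict:
            ok = bool(members & degs & tissue_genes)
        else:
            ok = bool(members & tissue_genes) and bool(members & degs)
        if ok:
            out.append(label)
    if not out:
        log.info("tissue_specific_modules: no module qualifies; crosstalk will be skipped")
    return out


@dataclass
class CrosstalkResult:
    """Permutation-test outcome for one module pair."""
    e_obs: int
    n_perm: int
    b: int  # draws with E_perm >= E_obs

    @property
    def p(self) -> float:
        return self.b / self.n_perm

    @property
    def p_report(self) -> str:
        return f"<{1.0 / self.n_perm:g}" if self.b == 0 else f"{self.p:g}"


def _edge_arrays(net: nx.Graph) -> tuple[np.ndarray, np.ndarray, list]:
    nodes = sorted(net.nodes)
    pos = {g: i for i, g in enumerate(nodes)}
    eu = np.fromiter((pos[u] for u, _ in net.edges), dtype=np.int64, count=net.number_of_edges())
    ev = np.fromiter((pos[v] for _, v in net.edges), dtype=np.int64, count=net.number_of_edges())
    return eu, ev, nodes


def _null_inter_counts(eu: np.ndarray, ev: np.ndarray, n_nodes: int,
                       size_a: int, size_b: int, n_perm: int,
                       rng: np.random.Generator, chunk: int = 4000) -> np.ndarray:
    """Vectorised null: per draw, two uniform node sets and their inter-edge count."""
    counts = np.empty(n_perm, dtype=np.int64)
    done = 0
    while done < n_perm:
        c = min(chunk, n_perm - done)
        mask_a = _sample_masks(c, n_nodes, size_a, rng)
        mask_b = _sample_masks(c, n_nodes, size_b, rng)
        hits = (mask_a[:, eu] & mask_b[:, ev]) | (mask_a[:, ev] & mask_b[:, eu])
        counts[done:done + c] = hits.sum(axis=1)
        done += c
    return counts


def _sample_masks(n_draws: int, n_nodes: int, size: int, rng: np.random.Generator) -> np.ndarray:
    """Boolean membership masks for uniform without-replacement node sets."""
    keys = rng.random((n_draws, n_nodes))
    idx = np.argpartition(keys, size - 1, axis=1)[:, :size]
    masks = np.zeros((n_draws, n_nodes), dtype=bool)
    np.put_along_axis(masks, idx, True, axis=1)
    return masks


def crosstalk_permutation_test(net: nx.Graph, set_a, set_b,
                               n_perm: int = 100_000,
                               seed: int | np.random.SeedSequence = 0) -> CrosstalkResult:
    """Permutation test of inter-set edge excess between two gene sets.

    Both null sets are redrawn per draw from the full network node set,
    keeping the set sizes; overlap between draws is allowed (modules from
    different tissues may share genes).
    """
    set_a, set_b = set(set_a), set(set_b)
    n_nodes = net.number_of_nodes()
    if len(set_a) > n_nodes or len(set_b) > n_nodes:
        raise ValueError("a gene set is larger than the network node set")
    e_obs = inter_set_edge_count(net, set_a, set_b)
    eu, ev, _ = _edge_arrays(net)
    rng = np.random.default_rng(seed)
    null = _null_inter_counts(eu, ev, n_nodes, len(set_a), len(set_b), n_perm, rng)
    b = int((null >= e_obs).sum())
    return CrosstalkResult(e_obs=e_obs, n_perm=n_perm, b=b)


def _pair_seed(seed: int, label_a: int, label_b: int, genes_a, genes_b) -> np.random.SeedSequence:
    """Substream seed for one pair, symmetric in the roles of the two tissues."""
    content = "|".join(sorted([",".join(sorted(genes_a)), ",".join(sorted(genes_b))]))
    return np.random.SeedSequence(
        [int(seed) & 0x7FFFFFFF, min(label_a, label_b), max(label_a, label_b),
         zlib.crc32(content.encode())]
    )


def all_pairs_crosstalk(net: nx.Graph, modules_a: dict[int, set], modules_b: dict[int, set],
                        n_perm: int = 100_000, seed: int = 0,
                        alpha: float = 0.05) -> pd.DataFrame:
    """Test every tissue-A x tissue-B module pair; flag p < alpha.

    Each pair runs on its own substream seed derived from the root seed and
    a role-symmetric pair key, so exchanging the two tissues transposes the
    table with identical p-values. No multiplicity correction gates the
    flag; BH across the tested pairs is reported as an extra column.
    """
    if not modules_a or not modules_b:
        raise ValueError("both tissue module collections must be non-empty")
    rows = []
    for la in sorted(modules_a):
        for lb in sorted(modules_b):
            a, b_set = set(modules_a[la]), set(modules_b[lb])
            ss = _pair_seed(seed, la, lb, a, b_set)
            # canonical argument order keeps the draw sequence role-symmetric
            first, second = (a, b_set) if sorted(a) <= sorted(b_set) else (b_set, a)
            res = crosstalk_permutation_test(net, first, second, n_perm=n_perm, seed=ss)
            rows.append({"module_a": la, "module_b": lb,
                         "size_a": len(a), "size_b": len(b_set),
                         "e_obs": res.e_obs, "n_perm": res.n_perm, "b": res.b,
                         "p": res.p, "p_report": res.p_report})
    df = pd.DataFrame(rows)
    df["p_bh"] = bh_adjust(df["p"].to_numpy())
    df["significant"] = df["p"] < alpha
    return df[CROSSTALK_COLUMNS]


def module_gene_sets(assign: pd.Series, labels) -> dict[int, set]:
    """Gene sets of the given module labels from an assignment table."""
    return {int(l): set(assign[assign == int(l)].index)
            for l in labels if int(l) != UNASSIGNED}
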
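"""Protein-protein interaction network handling.

The PPI network is an undirected graph whose edges carry a STRING-style
integer combined confidence score on a 0-1000 scale. The operations here
are the network legs of the pipeline: parsing a detailed edge list,
restricting to high-confidence interactions (score >= 900 by default),
building the subnetwork induced by differentially expressed genes together
with their direct interactors, and counting edges between two gene sets
(the raw statistic behind the module-crosstalk permutation test).

Gene identifiers are opaque case-sensitive symbols; no identifier mapping
is attempted.
"""

from __future__ import annotations

import logging
from typing import Iterable

import networkx as nx
import pandas as pd

from .io import FileFormatError

log = logging.getLogger(__name__)

EDGE_COLUMNS = ("protein1", "protein2", "combined_score")


def read_edges(path) -> nx.Graph:
    """Parse a STRING-like TSV edge list into an undirected scored graph.

    Duplicate unordered pairs are collapsed keeping the maximum score;
    self-loops are dropped with a warning. Missing columns or non-integer
    scores are hard errors naming the offending column / line.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    for col in EDGE_COLUMNS:
        if col not in df.columns:
            raise FileFormatError(f"{path}: missing required column '{col}'")
    scores = pd.to_numeric(df["combined_score"], errors="coerce")
    bad = scores.isna() | (scores != scores.round())
    if bad.any():
        lineno = int(bad.idxmax()) + 2  # +1 header, +1 one-based
        raise FileFormatError(
            f"{path}:{lineno}: combined_score must be an integer, got "
            f"'{df['combined_score'].iloc[int(bad.idxmax())]}'"
        )
    net = nx.Graph()
    n_self = 0
    for u, v, s in zip(df["protein1"], df["protein2"], scores.astype(int)):
        if u == v:
            n_self += 1
            continue
        if net.has_edge(u, v):
            net[u][v]["combined_score"] = max(net[u][v]["combined_score"], int(s))
        else:
            net.add_edge(u, v, combined_score=int(s))
    if n_self:
        log.warning("%s: dropped %d self-loop(s)", path, n_self)
    return net


def write_edges(net: nx.Graph, path) -> None:
    rows = sorted((min(u, v), max(u, v), d["combined_score"]) for u, v, d in net.edges(data=True))
    df = pd.DataFrame(rows, columns=list(EDGE_COLUMNS))
    df.to_csv(path, sep="\t", index=False)


def filter_by_score(net: nx.Graph, min_score: int = 900) -> nx.Graph:
    """Keep edges with combined score >= ``min_score``; drop isolated nodes."""
    out = nx.Graph()
    for u, v, d in net.edges(data=True):
        if d["combined_score"] >= min_score:
            out.add_edge(u, v, **d)
    return out


def seed_subnetwork(net: nx.Graph, seeds: Iterable[str]) -> nx.Graph:
    """Subgraph induced by seed genes plus their direct interactors.

    The induced subgraph keeps interactor-interactor edges among retained
    nodes, not just seed-interactor edges. Seeds absent from the network are
    counted and logged; an empty seed/network intersection is an error.
    """
    seeds = set(seeds)
    present = seeds & set(net.nodes)
    if not present:
        raise ValueError("none of the seed genes are present in the network")
    missing = len(seeds) - len(present)
    if missing:
        log.info("seed_subnetwork: %d of %d seed genes absent from the network", missing, len(seeds))
    nodes = set(present)
    for s in present:
        nodes.update(net.neighbors(s))
    return net.subgraph(nodes).copy()


def inter_set_edge_count(net: nx.Graph, set_a: Iterable[str], set_b: Iterable[str]) -> int:
    """Number of distinct edges with one endpoint in A and the other in B.

    Each qualifying edge counts once even when both endpoints lie in the
    intersection of A and B.
    """
    a, b = set(set_a), set(set_b)
    n = 0
    for u, v in net.edges:
        if (u in a and v in b) or (u in b and v in a):
            n += 1
    return n
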
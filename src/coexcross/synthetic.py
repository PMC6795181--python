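"""Synthetic two-tissue study generator with planted ground truth.

Emulates the shapes of every pipeline input so that each downstream stage
can be tested for parameter recovery without any external download:

* a planted-partition PPI graph (within-module edge probability above
  between-module), STRING-style integer combined scores in [900, 1000] plus
  a configurable fraction of low-score decoy edges in [150, 899] so the
  score filter has something to remove;
* per tissue, a negative-binomial count matrix in which module members
  share a per-sample latent factor (strength ``module_loading``) and a
  chosen fraction of genes carry a planted case/control log2 fold change;
* regulator->target maps (TF / miRNA / lncRNA) in which planted pivot
  regulators draw targets from their module with elevated odds;
* risk-gene lists (SFARI-like, DVMT-like) enriched in designated modules,
  and a tissue-specific gene list that makes designated modules qualify as
  tissue-specific in each tissue;
* extra PPI edges between planted crosstalk module pairs (at least three
  times the expected background inter-edge count).

All randomness flows from one root seed through named substreams
(network / design / expression / regulators / lists), so regenerating one
stage never perturbs another.

The default configuration mirrors a small two-brain-region case/control
study: 12 cases vs 12 controls per tissue, six modules of 60 genes in a
600-gene universe, NB dispersion 0.2, within-module factor loading 0.8.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from ._seeds import substream
from .enrich import RegulatorTargetMap

GENE_FMT = "G{:04d}"
LN2 = math.log(2.0)

_REG_PREFIX = {"TF": "TF{:03d}", "miRNA": "miR{:03d}", "lncRNA": "lnc{:03d}"}


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic study; defaults are the standing study conditions."""

    n_genes: int = 600
    module_sizes: tuple[int, ...] = (60, 60, 60, 60, 60, 60)
    n_modules: int | None = None  # derived from module_sizes when None
    n_case: int = 12      # per tissue
    n_control: int = 12   # per tissue
    tissues: tuple[str, str] = ("CC", "PFC")
    module_loading: float = 0.8       # latent-factor strength lambda in [0, 1]
    de_log2fc: float = 1.0            # planted |log2 fold change|
    de_fraction: float = 0.1
    nb_dispersion: float = 0.2        # alpha in Var = mu + alpha * mu^2
    intra_edge_p: float = 0.3
    inter_edge_p: float = 0.01
    decoy_edge_fraction: float = 0.2  # extra low-score edges (scores 150-899)
    regulator_counts: tuple[int, int, int] = (12, 12, 6)  # (n_tf, n_mirna, n_lncrna)
    targeting_odds: float = 20.0      # planted pivot in-module target odds
    risk_odds: float = 10.0           # risk-list in-module sampling odds
    n_targets_range: tuple[int, int] = (20, 80)
    risk_list_size: int = 50
    tissue_list_size: int = 100
    sfari_modules: tuple[int, ...] = (1,)
    dvmt_modules: tuple[int, ...] = (2,)
    tissue_a_modules: tuple[int, ...] = (1, 3, 5)  # tissue-specific in tissues[0]
    tissue_b_modules: tuple[int, ...] = (2, 4, 6)  # tissue-specific in tissues[1]
    crosstalk_pairs: tuple[tuple[int, int], ...] = ((1, 2),)
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0 or any(s <= 0 for s in self.module_sizes):
            raise ValueError("n_genes and every module size must be positive")
        if sum(self.module_sizes) > self.n_genes:
            raise ValueError(
                f"module_sizes sum to {sum(self.module_sizes)} > n_genes={self.n_genes}")
        if self.n_modules is not None and self.n_modules != len(self.module_sizes):
            raise ValueError("n_modules disagrees with len(module_sizes)")
        if self.n_case < 1 or self.n_control < 1:
            raise ValueError("each tissue needs at least one case and one control sample")
        if not (0.0 <= self.module_loading <= 1.0):
            raise ValueError("module_loading must lie in [0, 1]")
        if self.de_log2fc < 0:
            raise ValueError("de_log2fc must be >= 0")
        if not (0.0 < self.de_fraction < 1.0):
            raise ValueError("de_fraction must lie in (0, 1)")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if not (0.0 < self.intra_edge_p <= 1.0):
            raise ValueError("intra_edge_p must lie in (0, 1]")
        if not (0.0 <= self.inter_edge_p < 1.0):
            raise ValueError("inter_edge_p must lie in [0, 1)")
        if self.intra_edge_p <= self.inter_edge_p:
            raise ValueError("planted partition must be assortative: intra_edge_p > inter_edge_p")
        if self.targeting_odds < 1 or self.risk_odds < 1:
            raise ValueError("targeting_odds and risk_odds must be >= 1")
        n_mod = len(self.module_sizes)
        for group in (self.sfari_modules, self.dvmt_modules,
                      self.tissue_a_modules, self.tissue_b_modules):
            if any(not (1 <= m <= n_mod) for m in group):
                raise ValueError(f"module label out of range 1..{n_mod}: {group}")
        for ma, mb in self.crosstalk_pairs:
            if ma not in self.tissue_a_modules or mb not in self.tissue_b_modules:
                raise ValueError(
                    f"crosstalk pair ({ma}, {mb}) must pair a tissue-A module "
                    "with a tissue-B module")

    @property
    def gene_ids(self) -> list[str]:
        return [GENE_FMT.format(i) for i in range(self.n_genes)]

    @property
    def tissue_modules(self) -> dict[str, tuple[int, ...]]:
        return {self.tissues[0]: self.tissue_a_modules,
                self.tissues[1]: self.tissue_b_modules}


@dataclass
class SyntheticTruth:
    """Planted ground truth for parameter-recovery tests."""

    module_membership: pd.Series          # gene -> planted label (0 = background)
    de_genes: dict[str, set[str]]         # tissue -> planted DE gene set
    de_signs: dict[str, dict[str, int]]   # tissue -> gene -> +1 / -1
    pivot_regulators: set[tuple[str, int]]
    crosstalk_pairs: set[tuple[int, int]]
    risk_genes: dict[str, set[str]] = field(default_factory=dict)  # SFARI / DVMT
    tissue_specific_genes: set[str] = field(default_factory=set)

    def module_genes(self, label: int) -> list[str]:
        return list(self.module_membership[self.module_membership == label].index)


# ---------------------------------------------------------------------------
# planted design (which genes are DE, which regulators are pivots, ...)
# ---------------------------------------------------------------------------

def _plant_design(config: SimulationConfig) -> SyntheticTruth:
    labels = np.zeros(config.n_genes, dtype=int)
    start = 0
    for m, size in enumerate(config.module_sizes, start=1):
        labels[start:start + size] = m
        start += size
    membership = pd.Series(labels, index=pd.Index(config.gene_ids, name="gene_id"))

    de_genes: dict[str, set[str]] = {}
    de_signs: dict[str, dict[str, int]] = {}
    n_de = int(round(config.de_fraction * config.n_genes))
    for tissue in config.tissues:
        rng = substream(config.seed, "design", "de", tissue)
        chosen = rng.choice(config.n_genes, size=n_de, replace=False)
        signs = rng.choice([-1, 1], size=n_de)
        ids = [config.gene_ids[i] for i in chosen]
        de_genes[tissue] = set(ids)
        de_signs[tissue] = dict(zip(ids, (int(s) for s in signs)))

    pivots: set[tuple[str, int]] = set()
    if config.targeting_odds > 1:
        n_mod = len(config.module_sizes)
        for rtype, count in zip(("TF", "miRNA", "lncRNA"), config.regulator_counts):
            for i in range(min(count, n_mod)):
                pivots.add((_REG_PREFIX[rtype].format(i + 1), i + 1))

    return SyntheticTruth(
        module_membership=membership,
        de_genes=de_genes,
        de_signs=de_signs,
        pivot_regulators=pivots,
        crosstalk_pairs=set(config.crosstalk_pairs),
    )


# ---------------------------------------------------------------------------
# PPI network
# ---------------------------------------------------------------------------

def generate_ppi_network(config: SimulationConfig) -> tuple[nx.Graph, SyntheticTruth]:
    """Planted-partition PPI graph plus the study's planted ground truth.

    High-confidence edges carry scores uniform in [900, 1000]; decoy edges
    (a configurable fraction, scores in [150, 899]) exercise the score
    filter; planted crosstalk pairs get extra inter-module edges up to at
    least three times the expected background count.
    """
    config.validate()
    truth = _plant_design(config)
    rng = substream(config.seed, "network")
    genes = config.gene_ids
    labels = truth.module_membership.to_numpy()

    iu, iv = np.triu_indices(config.n_genes, k=1)
    same = (labels[iu] == labels[iv]) & (labels[iu] > 0)
    p = np.where(same, config.intra_edge_p, config.inter_edge_p)
    drawn = rng.random(iu.size) < p
    eu, ev = iu[drawn], iv[drawn]

    net = nx.Graph()
    net.add_nodes_from(genes)
    scores = rng.integers(900, 1001, size=eu.size)
    for u, v, s in zip(eu, ev, scores):
        net.add_edge(genes[u], genes[v], combined_score=int(s))

    for ma, mb in sorted(truth.crosstalk_pairs):
        _plant_crosstalk_edges(net, truth, config, ma, mb, rng)

    n_decoys = int(round(config.decoy_edge_fraction * net.number_of_edges()))
    added = 0
    while added < n_decoys:
        u, v = (genes[i] for i in rng.integers(0, config.n_genes, size=2))
        if u == v or net.has_edge(u, v):
            continue
        net.add_edge(u, v, combined_score=int(rng.integers(150, 900)))
        added += 1
    return net, truth


def _plant_crosstalk_edges(net: nx.Graph, truth: SyntheticTruth,
                           config: SimulationConfig, ma: int, mb: int,
                           rng: np.random.Generator) -> None:
    """Add inter-module edges until the pair carries >= 3x background.

    Background is taken as the larger of (a) the partition's expected
    inter-module count and (b) the expected inter-set count of two random
    same-size node sets on the current graph — on an assortative graph (b)
    exceeds (a) because random sets also sample within-module edges, and it
    is (b) the downstream permutation null resamples.
    """
    genes_a, genes_b = truth.module_genes(ma), truth.module_genes(mb)
    sa, sb, n = len(genes_a), len(genes_b), config.n_genes
    partition_bg = config.inter_edge_p * sa * sb
    random_set_bg = net.number_of_edges() * 2.0 * (sa / n) * (sb / n)
    target = max(math.ceil(3.0 * max(partition_bg, random_set_bg)), 3)
    current = sum(1 for u in genes_a for v in genes_b if net.has_edge(u, v))
    absent = [(u, v) for u in genes_a for v in genes_b if u != v and not net.has_edge(u, v)]
    need = target - current
    if need > len(absent):
        raise ValueError(f"cannot plant {need} extra edges between modules {ma} and {mb}")
    if need > 0:
        picks = rng.choice(len(absent), size=need, replace=False)
        for idx in picks:
            u, v = absent[idx]
            net.add_edge(u, v, combined_score=int(rng.integers(900, 1001)))


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def generate_expression(network: nx.Graph, truth: SyntheticTruth,
                        config: SimulationConfig, tissue: str) -> tuple[pd.DataFrame, pd.DataFrame]:
    """NB count matrix and sample metadata for one tissue.

    counts_ij ~ NB(mean = s_j * exp(b_i + lambda * f_{m(i), j} + beta_i * case_j),
    dispersion alpha) with b_i ~ N(log 100, 1), s_j ~ LogNormal(0, 0.2),
    f a per-module per-sample standard normal shared by module members and
    beta_i = +/- de_log2fc * log 2 for planted DE genes.

    Co-expression structure is tissue-specific: the latent factor acts only
    on the modules designated to this tissue (``tissue_a_modules`` /
    ``tissue_b_modules``), mirroring a study in which each brain region has
    its own module set on a shared PPI network; the other tissue's module
    genes stay unstructured here.
    """
    config.validate()
    if tissue not in config.tissues:
        raise ValueError(f"unknown tissue '{tissue}'; configured: {config.tissues}")
    missing = set(network.nodes) - set(truth.module_membership.index)
    if missing:
        raise ValueError(f"module membership does not cover network nodes, e.g. {sorted(missing)[:5]}")
    if config.n_case < 1 or config.n_control < 1:
        raise ValueError("empty sample group")

    rng = substream(config.seed, "expression", tissue)
    n_samples = config.n_case + config.n_control
    genes = config.gene_ids
    labels = truth.module_membership.to_numpy()
    n_mod = len(config.module_sizes)

    case = np.zeros(n_samples)
    case[: config.n_case] = 1.0
    sample_ids = [f"{tissue}_case{i + 1:02d}" for i in range(config.n_case)] + \
                 [f"{tissue}_ctrl{i + 1:02d}" for i in range(config.n_control)]

    b = rng.normal(math.log(100.0), 1.0, size=config.n_genes)
    s = rng.lognormal(0.0, 0.2, size=n_samples)
    f = rng.normal(0.0, 1.0, size=(n_mod + 1, n_samples))  # row 0 unused (background)

    beta = np.zeros(config.n_genes)
    signs = truth.de_signs[tissue]
    for gid, sign in signs.items():
        beta[int(gid[1:])] = sign * config.de_log2fc * LN2

    log_mu = b[:, None] + beta[:, None] * case[None, :]
    active = np.isin(labels, list(config.tissue_modules[tissue]))
    log_mu[active] += config.module_loading * f[labels[active]]
    mu = s[None, :] * np.exp(log_mu)
    if not np.all(np.isfinite(mu)) or mu.max() > 1e12:
        raise ValueError("expression mean overflow; check b / loading / de_log2fc settings")

    alpha = config.nb_dispersion
    lam = rng.gamma(shape=1.0 / alpha, scale=mu * alpha)
    counts = rng.poisson(lam).astype(np.int64)

    counts_df = pd.DataFrame(counts, index=pd.Index(genes, name="gene_id"), columns=sample_ids)
    meta = pd.DataFrame({
        "condition": ["case"] * config.n_case + ["control"] * config.n_control,
        "tissue": tissue,
    }, index=pd.Index(sample_ids, name="sample_id"))
    return counts_df, meta


# ---------------------------------------------------------------------------
# regulators
# ---------------------------------------------------------------------------

def generate_regulators(truth: SyntheticTruth, config: SimulationConfig) -> RegulatorTargetMap:
    """Regulator target maps; planted pivots target their module with elevated odds.

    Target counts are uniform in ``n_targets_range``; planted pivots use
    weighted sampling without replacement (weight ``targeting_odds`` inside
    their module) and are guaranteed at least two in-module targets.
    """
    config.validate()
    rng = substream(config.seed, "regulators")
    genes = np.asarray(config.gene_ids)
    labels = truth.module_membership.to_numpy()
    pivot_of = dict(truth.pivot_regulators)
    lo, hi = config.n_targets_range

    regmap = RegulatorTargetMap()
    for rtype, count in zip(("TF", "miRNA", "lncRNA"), config.regulator_counts):
        for i in range(count):
            name = _REG_PREFIX[rtype].format(i + 1)
            n_targets = int(rng.integers(lo, hi + 1))
            module = pivot_of.get(name)
            if module is None:
                idx = rng.choice(config.n_genes, size=n_targets, replace=False)
            else:
                in_mod = labels == module
                if in_mod.sum() < 2:
                    raise ValueError(f"pivot module {module} has fewer than 2 genes")
                weights = np.where(in_mod, config.targeting_odds, 1.0)
                idx = _weighted_sample_without_replacement(rng, weights, n_targets)
                if in_mod[idx].sum() < 2:  # guarantee the planted invariant
                    forced = np.flatnonzero(in_mod)[:2]
                    keep = [j for j in idx if j not in forced][: n_targets - 2]
                    idx = np.concatenate([forced, keep])
            regmap.add(name, rtype, genes[idx])
    return regmap


def _weighted_sample_without_replacement(rng: np.random.Generator,
                                         weights: np.ndarray, size: int) -> np.ndarray:
    # Efraimidis-Spirakis exponential-key trick
    keys = rng.exponential(1.0, size=weights.size) / weights
    return np.argsort(keys)[:size]


# ---------------------------------------------------------------------------
# gene lists
# ---------------------------------------------------------------------------

def generate_gene_lists(truth: SyntheticTruth,
                        config: SimulationConfig) -> tuple[dict[str, set[str]], set[str]]:
    """Risk lists (SFARI-like, DVMT-like) and the tissue-specific gene list.

    Risk lists sample genes with odds ``risk_odds`` from their designated
    modules versus background. The tissue list contains, for each tissue,
    the planted DE genes of that tissue's designated modules (so those
    modules qualify as tissue-specific downstream), topped up with uniform
    background genes from outside all modules.
    """
    config.validate()
    rng = substream(config.seed, "lists")
    labels = truth.module_membership.to_numpy()
    genes = np.asarray(config.gene_ids)

    risk: dict[str, set[str]] = {}
    for list_name, modules in (("SFARI", config.sfari_modules), ("DVMT", config.dvmt_modules)):
        in_designated = np.isin(labels, list(modules)) if modules else np.zeros(len(labels), bool)
        weights = np.where(in_designated, config.risk_odds, 1.0)
        idx = _weighted_sample_without_replacement(rng, weights, config.risk_list_size)
        risk[list_name] = set(genes[idx])

    tissue_list: set[str] = set()
    tissue_names = list(config.tissue_modules)
    for tissue, modules in config.tissue_modules.items():
        other = [t for t in tissue_names if t != tissue][0]
        # exclusive DE genes so a module qualifies in its own tissue only
        exclusive = truth.de_genes[tissue] - truth.de_genes[other]
        for m in modules:
            tissue_list |= set(truth.module_genes(m)) & exclusive
    background = genes[labels == 0]
    n_fill = max(config.tissue_list_size - len(tissue_list), 0)
    n_fill = min(n_fill, background.size)
    if n_fill:
        tissue_list |= set(rng.choice(background, size=n_fill, replace=False))

    truth.risk_genes = risk
    truth.tissue_specific_genes = set(tissue_list)
    return risk, tissue_list


# ---------------------------------------------------------------------------
# whole-study convenience + file export
# ---------------------------------------------------------------------------

@dataclass
class SimulatedStudy:
    config: SimulationConfig
    network: nx.Graph
    truth: SyntheticTruth
    counts: dict[str, pd.DataFrame]
    metadata: pd.DataFrame
    regulators: RegulatorTargetMap
    risk_lists: dict[str, set[str]]
    tissue_list: set[str]


def simulate(config: SimulationConfig) -> SimulatedStudy:
    """Generate the full two-tissue study in memory."""
    net, truth = generate_ppi_network(config)
    counts, metas = {}, []
    for tissue in config.tissues:
        c, m = generate_expression(net, truth, config, tissue)
        counts[tissue] = c
        metas.append(m)
    regmap = generate_regulators(truth, config)
    risk, tissue_list = generate_gene_lists(truth, config)
    return SimulatedStudy(config=config, network=net, truth=truth, counts=counts,
                          metadata=pd.concat(metas), regulators=regmap,
                          risk_lists=risk, tissue_list=tissue_list)


def write_simulation(study: SimulatedStudy, outdir) -> dict[str, str]:
    """Write every pipeline input plus truth tables as plain text files."""
    from pathlib import Path

    from . import io as cio
    from .netcore import write_edges

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    for tissue, counts in study.counts.items():
        p = outdir / f"counts_{tissue}.tsv"
        cio.write_counts(counts, p)
        paths[f"counts_{tissue}"] = str(p)
    p = outdir / "metadata.tsv"
    cio.write_metadata(study.metadata, p)
    paths["metadata"] = str(p)

    p = outdir / "network.tsv"
    write_edges(study.network, p)
    paths["network"] = str(p)

    for name, genes in study.risk_lists.items():
        p = outdir / f"{name.lower()}.txt"
        cio.write_gene_list(genes, p)
        paths[name.lower()] = str(p)
    p = outdir / "tissue_specific.txt"
    cio.write_gene_list(study.tissue_list, p)
    paths["tissue_specific"] = str(p)

    p = outdir / "regulators.gmt"
    cio.write_gmt(study.regulators.to_gmt(), p)
    paths["regulators"] = str(p)

    truth_dir = outdir / "truth"
    truth_dir.mkdir(exist_ok=True)
    cio.write_table(study.truth.module_membership.rename("module").rename_axis("gene_id").reset_index(),
                    truth_dir / "modules.tsv")
    for tissue, genes in study.truth.de_genes.items():
        cio.write_gene_list(genes, truth_dir / f"de_{tissue}.txt")
    cio.write_table(pd.DataFrame(sorted(study.truth.pivot_regulators),
                                 columns=["regulator", "module"]),
                    truth_dir / "pivots.tsv")
    cio.write_table(pd.DataFrame(sorted(study.truth.crosstalk_pairs),
                                 columns=["module_a", "module_b"]),
                    truth_dir / "crosstalk_pairs.tsv")
    paths["truth_dir"] = str(truth_dir)
    return paths
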
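"""End-to-end two-tissue orchestration.

Stage order per tissue: differential expression -> DEG-seeded PPI
subnetwork -> co-expression modules -> risk-list enrichment and
dysfunctional-module flags -> pivot regulators; then cross-tissue module
crosstalk. Every stage reads and writes plain-text tables, so each is also
runnable standalone from the previous stage's files with identical results.

Outputs are bit-stable under a fixed configuration: all randomness comes
from named substreams of the root seed, and output headers record
parameters but never timestamps. The run manifest collects SHA-256
checksums of every output so reruns can be compared.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, coexpr, crosstalk, diffexpr, enrich, io, netcore

log = logging.getLogger(__name__)

EXIT_OK, EXIT_STAGE_FAILURE, EXIT_VALIDATION = 0, 1, 2


@dataclass
class TissueInputs:
    name: str
    counts: str
    power: float


@dataclass
class PipelineConfig:
    """Paths and parameters for a full two-tissue run."""

    tissues: list[TissueInputs]
    metadata: str
    network: str
    sfari: str
    dvmt: str
    tissue_list: str
    regulators: str
    outdir: str
    min_score: int = 900
    fc_threshold: float = 1.2
    p_threshold: float = 0.05
    min_module_size: int = 20
    cut_height: float = 0.99
    merge_height: float = 0.15
    hub_threshold: float = 0.8
    max_module_size: int = 500
    enrichment_alpha: float = 0.05
    n_perm: int = 100_000
    crosstalk_strict: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        tissues = [TissueInputs(**t) for t in raw.pop("tissues")]
        return cls(tissues=tissues, **raw)

    def input_paths(self) -> dict[str, str]:
        paths = {"metadata": self.metadata, "network": self.network,
                 "sfari": self.sfari, "dvmt": self.dvmt,
                 "tissue_list": self.tissue_list, "regulators": self.regulators}
        for t in self.tissues:
            paths[f"counts_{t.name}"] = t.counts
        return paths


def validate_inputs(config: PipelineConfig) -> list[str]:
    """Fail-fast validation of file existence, dialects and symbol overlap.

    Returns a list of warnings; structural problems raise before any stage
    runs. Expression/network symbol overlap below 50% warns, zero overlap
    is a hard error.
    """
    warnings: list[str] = []
    for label, path in config.input_paths().items():
        if not Path(path).exists():
            raise FileNotFoundError(f"input '{label}' not found: {path}")
    net = netcore.read_edges(config.network)
    io.read_metadata(config.metadata)
    for lst in (config.sfari, config.dvmt, config.tissue_list):
        io.read_gene_list(lst)
    enrich.RegulatorTargetMap.from_gmt(io.read_gmt(config.regulators))
    for t in config.tissues:
        counts = io.read_counts(t.counts)
        overlap = len(set(counts.index) & set(net.nodes))
        if overlap == 0:
            raise ValueError(f"expression genes of tissue '{t.name}' are disjoint "
                             "from the network nodes; pipeline cannot proceed")
        frac = overlap / len(counts.index)
        if frac < 0.5:
            msg = (f"tissue '{t.name}': only {frac:.0%} of expression genes are "
                   "on the network")
            warnings.append(msg)
            log.warning(msg)
    return warnings


def run_all(config: PipelineConfig) -> dict:
    """Execute every stage in dependency order; returns the run manifest."""
    t_start = time.time()
    warnings = validate_inputs(config)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}

    meta = io.read_metadata(config.metadata)
    full_net = netcore.read_edges(config.network)
    net = netcore.filter_by_score(full_net, config.min_score)
    log.info("network: %d nodes / %d edges after score >= %d filter",
             net.number_of_nodes(), net.number_of_edges(), config.min_score)
    outputs["network_filtered"] = outdir / "network_filtered.tsv"
    netcore.write_edges(net, outputs["network_filtered"])

    sfari = io.read_gene_list(config.sfari)
    dvmt = io.read_gene_list(config.dvmt)
    tissue_genes = io.read_gene_list(config.tissue_list)
    regmap = enrich.RegulatorTargetMap.from_gmt(io.read_gmt(config.regulators))

    per_tissue: dict[str, dict] = {}
    for t in config.tissues:
        stage = f"de[{t.name}]"
        try:
            per_tissue[t.name] = _run_tissue(config, t, meta, net, sfari, dvmt,
                                             regmap, outdir, outputs)
        except Exception as exc:  # noqa: BLE001 - named-stage abort contract
            raise PipelineStageError(stage, exc) from exc

    # cross-tissue crosstalk
    name_a, name_b = (t.name for t in config.tissues)
    sets_a = per_tissue[name_a]["tissue_specific_sets"]
    sets_b = per_tissue[name_b]["tissue_specific_sets"]
    if sets_a and sets_b:
        ct = crosstalk.all_pairs_crosstalk(net, sets_a, sets_b,
                                           n_perm=config.n_perm, seed=config.seed,
                                           alpha=config.enrichment_alpha)
        ct = ct.rename(columns={"module_a": f"module_{name_a}", "module_b": f"module_{name_b}"})
        outputs["crosstalk"] = outdir / "crosstalk.tsv"
        io.write_table(ct, outputs["crosstalk"],
                       f"crosstalk: n_perm={config.n_perm} seed={config.seed} "
                       f"alpha={config.enrichment_alpha} min_score={config.min_score}")
    else:
        log.info("crosstalk skipped: no tissue-specific modules in at least one tissue")

    manifest = {
        "package_version": __version__,
        "config": _config_dict(config),
        "warnings": warnings,
        "seed": config.seed,
        "outputs": {k: {"path": str(p), "sha256": _sha256(p)} for k, p in sorted(outputs.items())},
        "runtime_seconds": round(time.time() - t_start, 3),
        "finished_at": time.strftime("%Y-%m-%dT%H:%M:%S%z"),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


class PipelineStageError(RuntimeError):
    """A stage failed; carries the stage name for the abort message."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage


def _run_tissue(config: PipelineConfig, t: TissueInputs, meta: pd.DataFrame,
                net, sfari: set, dvmt: set, regmap, outdir: Path,
                outputs: dict[str, Path]) -> dict:
    counts = io.read_counts(t.counts)
    tmeta = meta[meta["tissue"] == t.name]
    if tmeta.empty:
        raise ValueError(f"no metadata rows for tissue '{t.name}'")
    counts = counts[tmeta.index.intersection(counts.columns)]

    # differential expression
    de = diffexpr.de_test(counts, tmeta["condition"])
    de = diffexpr.flag_degs(de, config.fc_threshold, config.p_threshold)
    degs = set(de.index[de["is_deg"]])
    outputs[f"de_{t.name}"] = outdir / f"de_{t.name}.tsv"
    io.write_table(de.rename_axis("gene_id").reset_index(), outputs[f"de_{t.name}"],
                   f"de: fc>{config.fc_threshold} p<{config.p_threshold} "
                   f"pseudo_count={diffexpr.PSEUDO_COUNT}")
    outputs[f"degs_{t.name}"] = outdir / f"degs_{t.name}.txt"
    io.write_gene_list(degs, outputs[f"degs_{t.name}"])
    log.info("%s: %d DEGs of %d genes", t.name, len(degs), len(de))

    # DEG-seeded subnetwork -> co-expression gene set
    sub = netcore.seed_subnetwork(net, degs)
    outputs[f"subnetwork_{t.name}"] = outdir / f"subnetwork_{t.name}.tsv"
    netcore.write_edges(sub, outputs[f"subnetwork_{t.name}"])
    coexpr_genes = counts.index.intersection(sorted(sub.nodes))

    # modules
    expr = coexpr.expression_transform(counts.loc[coexpr_genes])
    result = coexpr.detect_modules(expr, power=t.power,
                                   min_module_size=config.min_module_size,
                                   cut_height=config.cut_height,
                                   merge_height=config.merge_height,
                                   hub_threshold=config.hub_threshold)
    assign = result.assignment
    params = (f"power={t.power} min_module_size={config.min_module_size} "
              f"cut_height={config.cut_height} merge_height={config.merge_height} "
              f"hub_threshold={config.hub_threshold}")
    outputs[f"modules_{t.name}"] = outdir / f"modules_{t.name}.tsv"
    io.write_table(result.kme.rename_axis("gene_id").reset_index(),
                   outputs[f"modules_{t.name}"], f"modules: {params}")
    outputs[f"eigengenes_{t.name}"] = outdir / f"eigengenes_{t.name}.tsv"
    io.write_table(result.eigengenes.reset_index(), outputs[f"eigengenes_{t.name}"],
                   f"eigengenes: {params}")

    # candidate modules + risk-list enrichment
    candidates = enrich.select_candidate_modules(assign, degs, config.max_module_size)
    enrichments = {}
    for list_name, genes in (("sfari", sfari), ("dvmt", dvmt)):
        e = enrich.module_list_enrichment(assign, genes)
        e = e[e["unit"].isin(candidates)].reset_index(drop=True)
        e["padj"] = diffexpr.bh_adjust(e["pvalue"].to_numpy())
        enrichments[list_name] = e
        outputs[f"enrichment_{list_name}_{t.name}"] = outdir / f"enrichment_{list_name}_{t.name}.tsv"
        io.write_table(e, outputs[f"enrichment_{list_name}_{t.name}"],
                       f"enrichment list={list_name} alpha={config.enrichment_alpha} "
                       f"max_module_size={config.max_module_size}")
    flags = enrich.flag_dysfunctional(enrichments["sfari"], enrichments["dvmt"],
                                      config.enrichment_alpha)
    outputs[f"dysfunctional_{t.name}"] = outdir / f"dysfunctional_{t.name}.tsv"
    io.write_table(flags, outputs[f"dysfunctional_{t.name}"],
                   f"dysfunctional: alpha={config.enrichment_alpha}")

    # pivot regulators
    pivots = enrich.pivot_regulators(regmap, assign, candidates,
                                     alpha=config.enrichment_alpha)
    outputs[f"pivots_{t.name}"] = outdir / f"pivots_{t.name}.tsv"
    io.write_table(pivots, outputs[f"pivots_{t.name}"],
                   f"pivots: alpha={config.enrichment_alpha} min_targets=2")

    # tissue-specific modules for the crosstalk stage
    tissue_genes = io.read_gene_list(config.tissue_list)
    specific = crosstalk.tissue_specific_modules(assign, degs, tissue_genes,
                                                 candidates, strict=config.crosstalk_strict)
    sets = crosstalk.module_gene_sets(assign, specific)
    return {"de": de, "degs": degs, "assignment": assign,
            "candidates": candidates, "dysfunctional": flags,
            "pivots": pivots, "tissue_specific_sets": sets}


def _config_dict(config: PipelineConfig) -> dict:
    d = dataclasses.asdict(config)
    return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_pipeline_config(config: PipelineConfig, path) -> None:
    d = _config_dict(config)
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)
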
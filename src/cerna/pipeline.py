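"""End-to-end pipeline: screen -> expression filter -> coexpression ->
per-group networks -> degree/hub/compare/triads -> exports.

A single config (YAML-friendly dict) names either real input files or a
simulation block, plus every stage threshold.  All stage artifacts land
in the output directory in the same TSV/GraphML formats the per-stage
functions consume, so running stages by hand on each other's outputs is
byte-identical to one ``run``.  All randomness flows from the single
top-level seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Any

from . import __version__
from .expression import (
    coexpression_filter,
    filter_expressed,
    read_expression,
    read_group_labels,
    write_edges,
)
from .interactions import mirna_universe, read_interactions
from .network import (
    CeRNANetwork,
    build_network,
    compare_gene_sets,
    degree_distribution,
    export_network,
    extract_triads,
    fit_power_law,
    top_hubs,
    write_degree_table,
    write_hubs,
    write_overlap,
    write_triads,
)
from .screen import screen_pairs, write_candidates
from .simulate import SimConfig, evaluate_recovery, read_truth, write_simulation

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """The pipeline configuration is invalid or inconsistent."""


@dataclass(frozen=True)
class InputPaths:
    lnc_mirna: Path
    mrna_mirna: Path
    expression: Path
    labels: Path


@dataclass(frozen=True)
class PipelineConfig:
    """Everything one pipeline run needs, thresholds included.

    Exactly one of ``inputs`` (real files) or ``simulation`` (a
    :class:`~cerna.simulate.SimConfig`) must be set.
    """

    inputs: InputPaths | None = None
    simulation: SimConfig | None = None
    universe_mode: str = "union"
    explicit_n: int | None = None
    min_shared: int = 4
    alpha: float = 0.05
    correction: str = "none"
    min_fraction: float = 0.5
    rho_min: float = 0.5
    p_max: float = 0.01
    sign: str = "positive"
    scope: str = "per_group"
    p_method: str = "asymptotic_t"
    hub_k: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.inputs is None) == (self.simulation is None):
            raise ConfigError(
                "exactly one of real inputs and a simulation block must be set"
            )
        if not (0 < self.alpha <= 1) or not (0 < self.p_max <= 1):
            raise ConfigError("alpha and p_max must be in (0, 1]")
        if not (0 <= self.min_fraction < 1):
            raise ConfigError("min_fraction must be in [0, 1)")
        if not (0 <= self.rho_min < 1):
            raise ConfigError("rho_min must be in [0, 1)")
        if self.min_shared < 1 or self.hub_k < 1:
            raise ConfigError("min_shared and hub_k must be >= 1")


_SIM_FIELDS = {f.name for f in dataclasses.fields(SimConfig)}


def config_from_dict(raw: dict[str, Any]) -> PipelineConfig:
    """Build a PipelineConfig from a parsed YAML/JSON mapping."""
    raw = dict(raw)
    inputs = None
    simulation = None
    if "inputs" in raw and raw["inputs"] is not None:
        try:
            inputs = InputPaths(**{k: Path(v) for k, v in raw.pop("inputs").items()})
        except TypeError as exc:
            raise ConfigError(f"bad inputs block: {exc}") from None
    else:
        raw.pop("inputs", None)
    if "simulation" in raw and raw["simulation"] is not None:
        sim_raw = dict(raw.pop("simulation"))
        unknown = set(sim_raw) - _SIM_FIELDS
        if unknown:
            raise ConfigError(f"unknown simulation keys: {sorted(unknown)}")
        if "groups" in sim_raw:
            sim_raw["groups"] = tuple((str(g), int(n)) for g, n in sim_raw["groups"])
        if "seed" not in sim_raw and "seed" in raw:
            sim_raw["seed"] = raw["seed"]  # one top-level seed drives everything
        try:
            simulation = SimConfig(**sim_raw)
        except ValueError as exc:
            raise ConfigError(f"bad simulation block: {exc}") from None
    else:
        raw.pop("simulation", None)
    raw.pop("output_dir", None)  # handled by the caller
    known = {f.name for f in dataclasses.fields(PipelineConfig)} - {"inputs", "simulation"}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    try:
        return PipelineConfig(inputs=inputs, simulation=simulation, **raw)
    except TypeError as exc:
        raise ConfigError(str(exc)) from None


@dataclass
class RunSummary:
    """Machine-readable record of one pipeline run."""

    config: dict[str, Any]
    version: str
    interactions: dict[str, int]
    screen: dict[str, int]
    expression: dict[str, int]
    groups: list[str]
    edges_per_group: dict[str, int]
    nodes_per_group: dict[str, int]
    hubs_per_group: dict[str, list]
    degree_fit_per_group: dict[str, dict]
    overlap: dict[str, Any] | None
    recovery: dict[str, Any] | None
    timestamp: str = ""

    def validate(self) -> None:
        for g in self.groups:
            if self.edges_per_group[g] > self.screen["pairs_retained"]:
                raise ValueError("edge count exceeds retained candidates")
            if self.edges_per_group[g] < 0 or self.nodes_per_group[g] < 0:
                raise ValueError("negative count in summary")

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


def _config_echo(config: PipelineConfig) -> dict[str, Any]:
    d = dataclasses.asdict(config)
    if d.get("inputs"):
        d["inputs"] = {k: str(v) for k, v in d["inputs"].items()}
    if d.get("simulation"):
        d["simulation"]["groups"] = [list(g) for g in d["simulation"]["groups"]]
    return d


def run_pipeline(
    config: PipelineConfig, outdir: str | Path, timestamp: str = ""
) -> RunSummary:
    """Execute every stage and write all artifacts under ``outdir``.

    Artifacts: ``simulated/*`` (simulation mode), ``candidates.tsv``,
    ``edges.tsv``, per-group ``network_<g>.{graphml,sif,edges.tsv}``,
    ``degrees_<g>.tsv``, ``hubs_<g>.tsv``, ``triads_<g>.tsv``,
    ``compare.json`` (first two groups), ``recovery.json`` (simulation
    mode) and ``summary.json`` (written last).  Repeated runs with the
    same config are byte-identical except for the summary timestamp,
    which is injectable precisely so callers can pin it.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if config.simulation is not None:
        sim = dataclasses.replace(config.simulation, seed=config.simulation.seed)
        paths = write_simulation(sim, outdir / "simulated")
        lnc_path, mrna_path = paths["lnc_mirna"], paths["mrna_mirna"]
        expr_path, labels_path = paths["expression"], paths["labels"]
        truth = read_truth(paths["truth"])
    else:
        lnc_path = config.inputs.lnc_mirna
        mrna_path = config.inputs.mrna_mirna
        expr_path = config.inputs.expression
        labels_path = config.inputs.labels
        truth = None

    # stage 1: interactions + universe
    lnc_map = read_interactions(lnc_path, "lncRNA")
    mrna_map = read_interactions(mrna_path, "mRNA")
    universe = mirna_universe(
        lnc_map, mrna_map, mode=config.universe_mode, explicit_n=config.explicit_n
    )

    # stage 2: hypergeometric screen
    candidates, screen_stats = screen_pairs(
        lnc_map, mrna_map, universe,
        min_shared=config.min_shared, alpha=config.alpha,
        correction=config.correction,
    )
    write_candidates(candidates, outdir / "candidates.tsv")

    # stage 3: expression filter + coexpression screen
    gene_class = {g: "lncRNA" for g in lnc_map.entries}
    gene_class.update({g: "mRNA" for g in mrna_map.entries})
    matrix = read_expression(expr_path, gene_class=gene_class)
    labels = read_group_labels(labels_path)
    n_genes_before = len(matrix.gene_ids)
    matrix = filter_expressed(matrix, min_fraction=config.min_fraction)
    edges = coexpression_filter(
        candidates, matrix, labels,
        rho_min=config.rho_min, p_max=config.p_max,
        sign=config.sign, scope=config.scope, p_method=config.p_method,
    )
    write_edges(edges, outdir / "edges.tsv")

    # stage 4: per-group networks and analyses
    groups = sorted({e.group for e in edges})
    if config.scope == "per_group":
        # groups with zero retained edges still get (empty) artifacts
        groups = sorted({labels[s] for s in matrix.sample_ids})
    nets: dict[str, CeRNANetwork] = {}
    hubs_per_group: dict[str, list] = {}
    fit_per_group: dict[str, dict] = {}
    for g in groups:
        net = build_network([e for e in edges if e.group == g], group=g)
        nets[g] = net
        export_network(net, outdir / f"network_{g}.graphml", "graphml")
        export_network(net, outdir / f"network_{g}.sif", "sif")
        export_network(net, outdir / f"network_{g}.edges.tsv", "edge_tsv")
        dist = degree_distribution(net, "all")
        write_degree_table(dist, outdir / f"degrees_{g}.tsv")
        fit = fit_power_law(dist)
        fit_per_group[g] = dataclasses.asdict(fit)
        hubs = top_hubs(net, k=config.hub_k, node_class="lncRNA") if net.n_nodes else []
        hubs_per_group[g] = [list(h) for h in hubs]
        write_hubs(hubs, outdir / f"hubs_{g}.tsv")
        write_triads(extract_triads(net), outdir / f"triads_{g}.tsv")

    overlap_dict = None
    if len(groups) >= 2:
        overlap = compare_gene_sets(nets[groups[0]], nets[groups[1]])
        write_overlap(overlap, outdir / "compare.json")
        overlap_dict = overlap.to_dict()

    recovery_dict = None
    if truth is not None:
        rec = evaluate_recovery(edges, truth)
        recovery_dict = {
            "sensitivity": rec.sensitivity,
            "precision": rec.precision,
            "n_planted": rec.n_planted,
            "n_retained": rec.n_retained,
            "n_true_positive": rec.n_true_positive,
            "n_false_positive": rec.n_false_positive,
        }
        with open(outdir / "recovery.json", "w") as fh:
            json.dump(recovery_dict, fh, indent=2, sort_keys=True)
            fh.write("\n")

    summary = RunSummary(
        config=_config_echo(config),
        version=__version__,
        interactions={
            "n_lnc": len(lnc_map),
            "n_mrna": len(mrna_map),
            "n_mirna_universe": universe.size,
        },
        screen=dataclasses.asdict(screen_stats),
        expression={
            "genes_before_filter": n_genes_before,
            "genes_after_filter": len(matrix.gene_ids),
            "n_samples": len(matrix.sample_ids),
        },
        groups=groups,
        edges_per_group={g: nets[g].n_edges for g in groups},
        nodes_per_group={g: nets[g].n_nodes for g in groups},
        hubs_per_group=hubs_per_group,
        degree_fit_per_group=fit_per_group,
        overlap=overlap_dict,
        recovery=recovery_dict,
        timestamp=timestamp,
    )
    summary.validate()
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info("pipeline complete: %s", outdir)
    return summary
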
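"""End-to-end orchestration: simulate or load inputs, call DEGs per model,
map mouse genes to the human namespace, find per-stage common dysregulated
pathways, build and merge stage PPI networks, score 4-node motifs, track
centrality dynamics, prioritize targets and overlay drugs with the BBB
consensus.  Every intermediate is written to the output directory and the
run is fully reproducible from (config, seed).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .io_formats import (
    STAGES,
    read_bbb_calls,
    read_drug_targets,
    read_expression,
    read_gmt,
    read_ortholog_map,
    read_ppi,
    write_bbb_calls,
    write_drug_targets,
    write_expression,
    write_gmt,
    write_network,
    write_ortholog_map,
    write_ppi,
)
from .synthetic_data import (
    MODEL_A,
    MODEL_B,
    PlantedPathway,
    SimulationConfig,
    collection_from_memberships,
    simulate_drug_tables,
    simulate_interactome,
    simulate_study_pair,
)
from .differential_expression import deg_analysis
from .orthology_mapping import map_to_target_namespace
from .pathway_enrichment import (
    StageMatching,
    common_pathways,
    direction_concordance,
    enrich,
    enrichment_frame,
    significant_pathways,
)
from .network_construction import build_stage_network, merge_stage_networks
from .network_motifs import motif_zscores
from .centrality_dynamics import (
    METRICS,
    centralities,
    classify_trajectories,
    prioritize_targets,
    scale_for_heatmap,
    stack_stages,
    top_nodes,
)
from .drug_overlay import bbb_consensus, build_overlay

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class InputPaths:
    """File inputs for a run on real (non-simulated) data."""

    expression_a: str = ""
    design_a: str = ""
    expression_b: str = ""
    design_b: str = ""
    gene_sets: str = ""
    ppi_edges: str = ""
    tissue_scores: str = ""
    ortholog_map: str = ""
    drug_targets: str = ""
    bbb_calls: str = ""


@dataclass
class PipelineConfig:
    outdir: str = "sca1net_run"
    seed: int = 0
    simulate: SimulationConfig | None = None
    inputs: InputPaths | None = None
    # thresholds, each with the analysis default
    fc_threshold: float = 0.5
    p_threshold: float = 0.05
    pseudocount: float = 0.25
    test: str = "welch"
    min_rank: int = 8
    alpha: float = 0.05
    edge_threshold: float = 0.950
    tissue_threshold: float = 4.8
    ensemble_size: int = 1000
    swaps_per_edge: int = 10
    tolerance: float = 0.05
    cc_quantile: float = 0.8
    score_threshold: float = 0.5
    top_k: int = 5
    stage_matching: StageMatching = field(default_factory=StageMatching.default)

    def validate(self) -> None:
        if self.simulate is None and self.inputs is None:
            raise ValueError("config needs a simulation block or input paths")
        for name, lo, hi in [
            ("p_threshold", 0, 1), ("alpha", 0, 1), ("edge_threshold", 0, 1),
            ("score_threshold", 0, 1), ("cc_quantile", 0, 1),
        ]:
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")
        if self.fc_threshold < 0 or self.tolerance < 0 or self.tissue_threshold < 0:
            raise ValueError("thresholds must be non-negative")
        if self.ensemble_size < 2:
            raise ValueError("ensemble_size must be >= 2")
        if self.simulate is not None:
            self.simulate.validate()

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        sim = raw.pop("simulate", None)
        if sim is not None:
            planted = [
                PlantedPathway(**pp) for pp in sim.pop("planted_pathways", [])
            ]
            for key in ("genes_per_pathway", "within_confidence_range",
                        "background_confidence_range", "tissue_score_range",
                        "time_points"):
                if key in sim and isinstance(sim[key], list):
                    sim[key] = tuple(sim[key])
            sim = SimulationConfig(planted_pathways=planted, **sim)
        inputs = raw.pop("inputs", None)
        if inputs is not None:
            inputs = InputPaths(**inputs)
        matching = raw.pop("stage_matching", None)
        if matching is not None:
            matching = StageMatching(tuple(tuple(p) for p in matching))
        kwargs = dict(raw, simulate=sim, inputs=inputs)
        if matching is not None:
            kwargs["stage_matching"] = matching
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stage_matching"] = [list(p) for p in self.stage_matching.pairs]
        return d


def _write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)
        fh.write("\n")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full workflow; returns the run report (also written to
    ``<outdir>/report.json``)."""
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
    }
    _write_json(config.to_dict(), out / "config.resolved.json")

    # ---- stage: inputs (simulate or load) -------------------------------
    manifest = None
    try:
        if config.simulate is not None:
            sim = dataclasses.replace(config.simulate, seed=config.seed)
            study_a, study_b, manifest = simulate_study_pair(sim)
            collection = collection_from_memberships(manifest.pathway_memberships)
            ppi = simulate_interactome(sim, manifest.pathway_memberships)
            ortho = manifest.ortholog_map
            indir = out / "inputs"
            indir.mkdir(exist_ok=True)
            write_expression(study_a, indir / "cells.fpkm.tsv", indir / "cells.design.tsv")
            write_expression(study_b, indir / "mice.fpkm.tsv", indir / "mice.design.tsv")
            write_gmt(collection, indir / "pathways.gmt")
            write_ppi(ppi, indir / "ppi.edges.tsv", indir / "tissue.scores.tsv")
            write_ortholog_map(ortho, indir / "orthologs.tsv")
            manifest.to_json(out / "ground_truth.json")
        else:
            ip = config.inputs
            study_a = read_expression(ip.expression_a, ip.design_a, MODEL_A)
            study_b = read_expression(ip.expression_b, ip.design_b, MODEL_B)
            collection = read_gmt(ip.gene_sets)
            ppi = read_ppi(ip.ppi_edges, ip.tissue_scores)
            ortho = read_ortholog_map(ip.ortholog_map)
    except Exception as e:  # noqa: BLE001 - stage-named abort
        raise PipelineError("inputs", str(e)) from e
    logger.info(
        "inputs: %d genes (cells), %d genes (mice), %d gene sets, %d PPI edges",
        len(study_a.genes), len(study_b.genes), len(collection), len(ppi),
    )

    # ---- stage: differential expression ---------------------------------
    try:
        deg_a = deg_analysis(study_a, config.fc_threshold, config.p_threshold,
                             config.pseudocount, config.test)
        deg_b = deg_analysis(study_b, config.fc_threshold, config.p_threshold,
                             config.pseudocount, config.test)
    except Exception as e:
        raise PipelineError("differential-expression", str(e)) from e
    deg_a.write(out / "deg.cells.tsv")
    deg_b.write(out / "deg.mice.raw.tsv")
    report["deg_counts"] = {
        MODEL_A: {tp: len(deg_a.degs(tp)) for tp in deg_a.time_points()},
        MODEL_B: {tp: len(deg_b.degs(tp)) for tp in deg_b.time_points()},
    }
    logger.info("DEG counts: %s", report["deg_counts"])

    # ---- stage: ortholog mapping ----------------------------------------
    try:
        deg_b_mapped = map_to_target_namespace(deg_b, ortho, config.min_rank)
    except Exception as e:
        raise PipelineError("ortholog-mapping", str(e)) from e
    deg_b_mapped.write(out / "deg.mice.mapped.tsv")

    # ---- stage: enrichment and common pathways --------------------------
    try:
        universe = collection.universe()
        bg_a = sorted(set(study_a.genes) & universe)
        bg_b = sorted(
            {t for t in ortho["target_id"]} & universe & set(study_a.genes)
        ) if config.simulate is None else bg_a
        res_a = {}
        res_b = {}
        for tp in deg_a.time_points():
            res_a[tp] = enrich(deg_a.degs(tp), collection, bg_a)
            enrichment_frame(res_a[tp]).to_csv(
                out / f"enrichment.cells.{tp}.tsv", sep="\t", index=False
            )
        for tp in deg_b_mapped.time_points():
            res_b[tp] = enrich(deg_b_mapped.degs(tp), collection, bg_b)
            enrichment_frame(res_b[tp]).to_csv(
                out / f"enrichment.mice.{tp}.tsv", sep="\t", index=False
            )
        per_stage, persistent = common_pathways(
            res_a, res_b, config.stage_matching, config.alpha
        )
        concord = direction_concordance(deg_a, deg_b_mapped)
    except Exception as e:
        raise PipelineError("pathway-enrichment", str(e)) from e
    report["significant_pathways"] = {
        MODEL_A: {tp: significant_pathways(r, config.alpha) for tp, r in res_a.items()},
        MODEL_B: {tp: significant_pathways(r, config.alpha) for tp, r in res_b.items()},
    }
    report["common_pathways"] = per_stage
    report["persistent_pathways"] = persistent
    report["direction_concordance"] = {
        k: v for k, v in concord.items() if k != "shared_genes"
    }
    report["direction_concordance"]["p_value"] = (
        None if concord["p_value"] != concord["p_value"] else concord["p_value"]
    )
    _write_json(report["common_pathways"], out / "common_pathways.json")
    logger.info("common pathways per stage: %s", per_stage)

    # ---- stage: network construction ------------------------------------
    try:
        stage_networks = {}
        for stage in config.stage_matching.stages():
            members: set[str] = set()
            for pid in per_stage[stage]:
                members |= set(collection[pid].members)
            if members:
                sn = build_stage_network(
                    members, ppi, stage,
                    config.edge_threshold, config.tissue_threshold,
                    input_pathways=per_stage[stage],
                )
            else:
                sn = None
            stage_networks[stage] = sn
        built = {s: sn for s, sn in stage_networks.items() if sn is not None}
        union = merge_stage_networks(*built.values()) if built else None
    except Exception as e:
        raise PipelineError("network-construction", str(e)) from e
    report["network_sizes"] = {
        s: {"nodes": sn.n_nodes(), "edges": sn.n_edges()} if sn else
        {"nodes": 0, "edges": 0}
        for s, sn in stage_networks.items()
    }
    if union is not None:
        report["network_sizes"]["union"] = {
            "nodes": union.graph.number_of_nodes(),
            "edges": union.graph.number_of_edges(),
        }
        report["union_group_sizes"] = union.group_sizes()
        for s, sn in built.items():
            write_network(sn.graph, out / f"network.{s}.tsv", "edgelist")
        write_network(union.graph, out / "network.union.graphml", "graphml")
        union.membership_table().to_csv(
            out / "union.membership.tsv", sep="\t", index=False
        )
    else:
        report["union_group_sizes"] = {}
    logger.info("network sizes: %s", report["network_sizes"])

    # ---- stage: motifs ---------------------------------------------------
    try:
        motif_reports = {}
        for name, graph in [
            *[(s, sn.graph) for s, sn in built.items()],
            *([("union", union.graph)] if union is not None else []),
        ]:
            if graph.number_of_edges() < 2:
                motif_reports[name] = None
                continue
            mz = motif_zscores(
                graph, config.ensemble_size, seed=config.seed,
                swaps_per_edge=config.swaps_per_edge,
            )
            motif_reports[name] = mz.to_dict()
    except Exception as e:
        raise PipelineError("motifs", str(e)) from e
    report["motif_zscores"] = {
        name: (None if mz is None else
               {"aggregate_z": mz["aggregate_z"], "real_counts": mz["real_counts"]})
        for name, mz in motif_reports.items()
    }
    _write_json(motif_reports, out / "motifs.json")

    # ---- stage: centrality dynamics -------------------------------------
    prioritized: dict = {
        "inhibition_candidates": [], "stimulation_candidates": [],
        "persistent_high_cc": [],
    }
    try:
        if built:
            table = stack_stages(*(centralities(sn) for sn in built.values()))
            table = scale_for_heatmap(table)
            table.write(out / "centralities.tsv")
            report["top_nodes"] = {
                s: {m: top_nodes(table, m, s, config.top_k) for m in METRICS}
                for s in built
            }
            calls = classify_trajectories(table, config.tolerance)
            if len(built) == len(config.stage_matching.stages()):
                prioritized = prioritize_targets(calls, table, config.cc_quantile)
        else:
            report["top_nodes"] = {}
    except Exception as e:
        raise PipelineError("centrality-dynamics", str(e)) from e
    report["prioritized_targets"] = {
        k: prioritized[k]
        for k in ("inhibition_candidates", "stimulation_candidates",
                  "persistent_high_cc")
    }
    _write_json(prioritized, out / "prioritized_targets.json")
    logger.info("prioritized targets: %s", report["prioritized_targets"])

    # ---- stage: drug overlay --------------------------------------------
    try:
        targets = sorted(
            set(prioritized["inhibition_candidates"])
            | set(prioritized["stimulation_candidates"])
            | set(prioritized["persistent_high_cc"])
        )
        if config.simulate is not None:
            drug_table, bbb_table, planted = simulate_drug_tables(sim, targets)
            indir = out / "inputs"
            write_drug_targets(drug_table, indir / "drug_targets.tsv")
            write_bbb_calls(bbb_table, indir / "bbb_calls.tsv")
            if manifest is not None:
                manifest.drug_target_pairs = planted["pairs"]
                manifest.bbb_positive_drugs = planted["bbb_positive"]
                manifest.to_json(out / "ground_truth.json")
        else:
            drug_table = read_drug_targets(config.inputs.drug_targets)
            bbb_table = read_bbb_calls(config.inputs.bbb_calls)
        if targets:
            overlay = build_overlay(targets, drug_table, config.score_threshold)
            verdicts = bbb_consensus(overlay, bbb_table)
            overlay.verdict_table().to_csv(
                out / "drug_verdicts.tsv", sep="\t", index=False
            )
            write_network(overlay.graph, out / "drug_overlay.tsv", "edgelist")
            report["drug_overlay"] = {
                "n_drugs": len(overlay.drugs),
                "n_targets": len(overlay.targets),
                "target_degrees": overlay.target_degrees(),
                "permeable_drugs": sorted(
                    d for d, v in verdicts.items() if v == "permeable"
                ),
            }
        else:
            report["drug_overlay"] = {
                "n_drugs": 0, "n_targets": 0, "target_degrees": {},
                "permeable_drugs": [],
            }
    except Exception as e:
        raise PipelineError("drug-overlay", str(e)) from e

    _write_json(report, out / "report.json")
    return report
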
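"""End-to-end orchestration: simulate -> preprocess -> networks -> analyses.

A single :class:`RunConfig` drives every stage; defaults equal the
analysis thresholds used throughout (top 1% of pairs, soft power 12,
DE alpha 0.05, consensus cuts 0.01 / 1.75, ORA alpha 0.05, disease
inclusion at >=50 samples over >=2 datasets).  All randomness flows
from the single top-level seed through named per-stage substreams, and
every output is recorded in a manifest with content digests so a rerun
with the same config is byte-identical and fully attributable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .datatypes import CoexpressionNetwork, NORMAL_LABEL
from .simulate import (
    SimulationConfig, generate_cohort, generate_pathways,
    generate_knowledge_graph, write_edge_list,
)
from .preprocess import preprocess_cohort
from .coexpression import build_disease_networks
from .diffexp import run_differential_expression, consensus, extreme_degs
from .knowledge import relation_distribution
from .overlap import (
    protein_occurrence, edge_occurrence, unique_edge_count, overlap_sweep,
)
from .similarity import similarity_matrix, enrich
from .overlay import (
    PathwayGraph, classify_edges, color_nodes, write_overlay_graphml,
)
from . import figures

logger = logging.getLogger(__name__)

STAGES = ["simulate", "preprocess", "coexpress", "diffexp", "consensus",
          "similarity", "overlap", "overlay"]


@dataclasses.dataclass
class RunConfig:
    """All pipeline parameters in one place."""

    out_dir: str = "results"
    seed: int = 0
    fraction: float = 0.01
    beta: float = 12.0
    alpha_de: float = 0.05
    alpha_ora: float = 0.05
    p_consensus: float = 0.01
    lfc_consensus: float = 1.75
    min_samples: int = 50
    min_datasets: int = 2
    exclude_labels: list = dataclasses.field(default_factory=lambda: ["cancer"])
    simulation: dict = dataclasses.field(default_factory=dict)
    n_pathways: int = 12
    pathway_size_range: tuple = (8, 25)
    pathway_module_overlap: float = 0.5
    kg_edge_density: float = 0.08
    relation_mix: dict = dataclasses.field(default_factory=lambda: {
        "association": 0.73, "increase": 0.09, "decrease": 0.09,
        "regulates": 0.06, "has_component": 0.03,
    })

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["pathway_size_range"] = list(out["pathway_size_range"])
        return out


def _substream(seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31 derived from the run seed."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and return (and write) the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": config.to_dict(),
        "stages": {},
    }

    def record(stage: str, paths: dict[str, Path], **info) -> None:
        manifest["stages"][stage] = {
            "outputs": {k: str(p.relative_to(out)) for k, p in paths.items()},
            "digests": {k: _sha256(p) for k, p in paths.items()},
            **info,
        }

    def fail(stage: str, exc: Exception):
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    # ---- simulate -------------------------------------------------------
    stage = "simulate"
    try:
        sim_kwargs = dict(config.simulation)
        sim_kwargs.setdefault("seed", _substream(config.seed, "cohort"))
        sim = SimulationConfig(**sim_kwargs)
        study, truth = generate_cohort(sim)
        pathways = generate_pathways(
            study.gene_ids, config.n_pathways,
            tuple(config.pathway_size_range), config.pathway_module_overlap,
            seed=_substream(config.seed, "pathways"),
            modules=truth.module_genes,
        )
        kg = generate_knowledge_graph(
            pathways, config.kg_edge_density, config.relation_mix,
            seed=_substream(config.seed, "knowledge"),
        )
        paths = {
            "expression": out / "expression.tsv",
            "metadata": out / "samples.tsv",
            "pathways": out / "pathways.gmt",
            "edges": out / "knowledge_edges.tsv",
            "ground_truth": out / "ground_truth.json",
        }
        study.write_tsv(paths["expression"], paths["metadata"])
        pathways.write_gmt(paths["pathways"])
        write_edge_list(kg, paths["edges"])
        truth.write_json(paths["ground_truth"])
        record(stage, paths, n_genes=sim.n_genes, n_samples=study.n_samples)
    except Exception as exc:  # noqa: BLE001 - abort with stage name
        fail(stage, exc)

    # ---- preprocess -----------------------------------------------------
    stage = "preprocess"
    try:
        processed, retained = preprocess_cohort(
            study, config.min_samples, config.min_datasets,
            config.exclude_labels)
        paths = {
            "expression": out / "preprocessed.tsv",
            "metadata": out / "preprocessed_samples.tsv",
        }
        processed.write_tsv(paths["expression"], paths["metadata"])
        record(stage, paths, retained_diseases=retained)
    except Exception as exc:
        fail(stage, exc)

    # ---- coexpress ------------------------------------------------------
    stage = "coexpress"
    try:
        networks = build_disease_networks(processed, beta=config.beta,
                                          fraction=config.fraction)
        net_dir = out / "networks"
        net_dir.mkdir(exist_ok=True)
        paths = {}
        for label, net in networks.items():
            p = net_dir / f"{label}.tsv"
            net.write_tsv(p)
            paths[label] = p
        record(stage, paths,
               edge_count=len(next(iter(networks.values())).edges))
    except Exception as exc:
        fail(stage, exc)

    # ---- diffexp --------------------------------------------------------
    stage = "diffexp"
    try:
        full, filtered = run_differential_expression(
            processed, retained, alpha=config.alpha_de)
        de_dir = out / "diffexp"
        de_dir.mkdir(exist_ok=True)
        paths = {}
        for disease, table in full.items():
            p = de_dir / f"{disease}.tsv"
            table.to_csv(p, sep="\t", float_format="%.10g")
            paths[disease] = p
        record(stage, paths, n_diseases=len(full))
    except Exception as exc:
        fail(stage, exc)

    # ---- consensus ------------------------------------------------------
    stage = "consensus"
    try:
        cons = consensus(filtered)
        up, down = extreme_degs(cons, config.p_consensus,
                                config.lfc_consensus)
        paths = {"consensus": out / "consensus.tsv",
                 "volcano": out / "consensus_volcano.png"}
        cons.to_csv(paths["consensus"], sep="\t", index=False,
                    float_format="%.10g")
        figures.consensus_volcano(cons, paths["volcano"],
                                  config.p_consensus, config.lfc_consensus)
        record(stage, {"consensus": paths["consensus"]},
               extreme_up=up, extreme_down=down)
    except Exception as exc:
        fail(stage, exc)

    # ---- similarity -----------------------------------------------------
    stage = "similarity"
    try:
        disease_nets = {k: v for k, v in networks.items()
                        if k != NORMAL_LABEL}
        sim1 = similarity_matrix(pathways, disease_nets, "pathway")
        sim2 = similarity_matrix(pathways, disease_nets, "interactome", knowledge=kg)
        paths = {
            "pathway_raw": out / "pathway_similarity.tsv",
            "pathway_std": out / "pathway_similarity_standardized.tsv",
            "interactome_raw": out / "interactome_similarity.tsv",
            "heatmap": out / "similarity_heatmap.png",
        }
        sim1.write_tsv(paths["pathway_raw"])
        sim1.write_tsv(paths["pathway_std"], standardized=True)
        sim2.write_tsv(paths["interactome_raw"])
        figures.similarity_heatmap(sim1, paths["heatmap"])
        record(stage, {k: v for k, v in paths.items() if k != "heatmap"})
    except Exception as exc:
        fail(stage, exc)

    # ---- overlap --------------------------------------------------------
    stage = "overlap"
    try:
        prot_occ = protein_occurrence(networks)
        edge_occ = edge_occurrence(networks)
        per_label, n_unique, frac_unique = unique_edge_count(networks)
        normal_nodes = networks[NORMAL_LABEL].nodes \
            if NORMAL_LABEL in networks else set()
        ks = [k for k in (10, 20, 50, 100) if k <= len(prot_occ.counts)]
        sweep = overlap_sweep(prot_occ, normal_nodes, ks)
        paths = {
            "protein_occurrence": out / "protein_occurrence.tsv",
            "edge_occurrence": out / "edge_occurrence.tsv",
            "overlap_sweep": out / "overlap_sweep.tsv",
        }
        prot_occ.to_dataframe().to_csv(paths["protein_occurrence"], sep="\t",
                                       index=False)
        df = edge_occ.to_dataframe()
        df["item"] = df["item"].map(lambda p: f"{p[0]}|{p[1]}")
        df.to_csv(paths["edge_occurrence"], sep="\t", index=False)
        sweep.to_csv(paths["overlap_sweep"], sep="\t", index=False,
                     float_format="%.10g")
        record(stage, paths, unique_edges=n_unique,
               unique_fraction=frac_unique,
               relation_distribution={
                   k: v[1] for k, v in relation_distribution(kg).items()})
    except Exception as exc:
        fail(stage, exc)

    # ---- overlay --------------------------------------------------------
    stage = "overlay"
    try:
        # render the first pathway as a flat protein graph over its
        # knowledge-supported edges, against the first disease network
        pid = next(iter(pathways))
        members = sorted(pathways[pid])
        kinds = {g: "protein" for g in members}
        pg_edges = [(a, b, "interaction")
                    for a, b in sorted(kg.subgraph_edges(members))]
        pg = PathwayGraph(kinds, {}, pg_edges)
        disease_label = next(iter(disease_nets))
        overlay_graph = classify_edges(
            pg, disease_nets[disease_label],
            networks.get(NORMAL_LABEL))
        overlay_graph = color_nodes(overlay_graph, full[disease_label],
                                    alpha=config.alpha_de) \
            if disease_label in full else overlay_graph
        paths = {"overlay": out / "overlay.graphml"}
        write_overlay_graphml(overlay_graph, paths["overlay"])
        figures.overlay_figure(overlay_graph, out / "overlay.png")
        record(stage, paths, pathway=pid, disease=disease_label)
    except Exception as exc:
        fail(stage, exc)

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    logger.info("pipeline complete: %d stages, manifest at %s",
                len(manifest["stages"]), manifest_path)
    return manifest
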
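"""Synthetic cohorts, pathway collections and knowledge graphs.

The generator emulates the statistical structure the downstream analysis
assumes: several microarray-style datasets per disease on a shared gene
universe, additive dataset (batch) shifts, planted co-expressed gene
modules realised as block-correlated groups via a shared latent factor,
and planted case/control log2 fold changes.  Everything is driven by a
single :class:`numpy.random.Generator` so a fixed seed reproduces the
cohort bit for bit.

Module co-expression is disease-specific: each planted module is
assigned (round-robin) to one disease and its latent factor is active
only in the case samples of that disease.  This makes pathway-disease
similarity recovery identifiable - a globally co-expressed module would
light up every disease network equally.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    ExpressionStudy,
    PathwayCollection,
    KnowledgeGraph,
    RELATION_TYPES,
)

#: baseline log2 intensity distribution (typical microarray scale)
BASELINE_MEAN = 7.0
BASELINE_SD = 1.5


def _check(cond: bool, field: str, msg: str) -> None:
    if not cond:
        raise ValueError(f"invalid SimulationConfig.{field}: {msg}")


@dataclasses.dataclass
class SimulationConfig:
    """Parameters of one synthetic cohort.

    Counts are in genes / datasets / samples; shifts and noise are in
    log2 units.  ``module_correlation`` is the target pairwise Pearson r
    between genes of the same planted module (within the case samples of
    the module's disease).
    """

    n_genes: int = 300
    n_diseases: int = 3
    datasets_per_disease: tuple[int, int] = (2, 3)
    samples_per_dataset: tuple[int, int] = (30, 40)
    control_fraction: float = 0.4
    n_modules: int = 3
    module_size: tuple[int, int] = (15, 25)
    module_correlation: float = 0.8
    batch_shift_sd: float = 0.3
    de_fraction: float = 0.05
    de_lfc: float = 2.0
    noise_sd: float = 0.5
    seed: int = 0
    #: allow differentially expressed genes to fall inside planted modules
    de_overlaps_modules: bool = False

    def __post_init__(self) -> None:
        _check(self.n_genes >= 1, "n_genes", "must be >= 1")
        _check(self.n_diseases >= 1, "n_diseases", "must be >= 1")
        for field in ("datasets_per_disease", "samples_per_dataset", "module_size"):
            lo, hi = getattr(self, field)
            _check(1 <= lo <= hi, field, "must be a (low, high) range with 1 <= low <= high")
        _check(0 < self.control_fraction < 1, "control_fraction", "must be in (0,1)")
        _check(self.n_modules >= 0, "n_modules", "must be >= 0")
        _check(0 < self.module_correlation < 1, "module_correlation", "must be in (0,1)")
        _check(self.batch_shift_sd >= 0, "batch_shift_sd", "must be >= 0")
        _check(0 <= self.de_fraction < 1, "de_fraction", "must be in [0,1)")
        _check(self.de_lfc >= 0, "de_lfc", "must be >= 0")
        _check(self.noise_sd >= 0, "noise_sd", "must be >= 0")
        _check(self.n_modules * self.module_size[1] <= self.n_genes,
               "module_size", "modules cannot cover more than n_genes genes")


@dataclasses.dataclass
class GroundTruth:
    """What was planted: module membership, DE genes, batch offsets."""

    module_membership: dict[str, int]          # gene -> module id (0-based)
    module_genes: dict[int, list[str]]         # module id -> genes
    module_disease: dict[int, str]             # module id -> disease it is active in
    de_genes: dict[str, dict[str, float]]      # disease -> gene -> signed log2FC
    batch_offsets: dict[str, np.ndarray]       # dataset -> per-gene shift

    def to_json(self) -> str:
        payload = {
            "module_membership": self.module_membership,
            "module_genes": {str(k): v for k, v in self.module_genes.items()},
            "module_disease": {str(k): v for k, v in self.module_disease.items()},
            "de_genes": self.de_genes,
            "batch_offsets": {k: v.tolist() for k, v in self.batch_offsets.items()},
        }
        return json.dumps(payload, indent=1, sort_keys=True)

    def write_json(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())


def generate_cohort(config: SimulationConfig) -> tuple[ExpressionStudy, GroundTruth]:
    """Simulate a multi-disease, multi-dataset expression cohort.

    Returns the study (log2 values, sample metadata) and the ground
    truth of planted signals.  Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    genes = [f"G{i + 1:06d}" for i in range(config.n_genes)]
    gene_index = {g: i for i, g in enumerate(genes)}
    diseases = [f"disease_{i + 1:02d}" for i in range(config.n_diseases)]

    # --- plant disjoint modules over a shuffled gene pool ----------------
    pool = list(genes)
    rng.shuffle(pool)
    cursor = 0
    module_genes: dict[int, list[str]] = {}
    module_membership: dict[str, int] = {}
    module_disease: dict[int, str] = {}
    for m in range(config.n_modules):
        size = int(rng.integers(config.module_size[0], config.module_size[1] + 1))
        members = sorted(pool[cursor:cursor + size])
        cursor += size
        module_genes[m] = members
        module_disease[m] = diseases[m % len(diseases)]
        for g in members:
            module_membership[g] = m

    # --- plant DE genes per disease --------------------------------------
    non_module = [g for g in genes if g not in module_membership]
    de_pool = genes if config.de_overlaps_modules else non_module
    n_de = int(round(config.de_fraction * config.n_genes))
    if n_de > len(de_pool):
        raise ValueError(
            "invalid SimulationConfig.de_fraction: not enough non-module genes "
            "to plant DE effects (set de_overlaps_modules=True or lower it)")
    de_genes: dict[str, dict[str, float]] = {}
    for disease in diseases:
        chosen = rng.choice(len(de_pool), size=n_de, replace=False) if n_de else []
        signs = rng.choice([-1.0, 1.0], size=n_de)
        de_genes[disease] = {
            de_pool[int(i)]: float(s) * config.de_lfc
            for i, s in zip(chosen, signs)
        }

    baseline = rng.normal(BASELINE_MEAN, BASELINE_SD, size=config.n_genes)

    # --- lay out datasets and samples -------------------------------------
    columns: list[np.ndarray] = []
    meta_rows: list[tuple[str, str, str, bool]] = []
    batch_offsets: dict[str, np.ndarray] = {}
    r = config.module_correlation
    sqrt_r, sqrt_1mr = np.sqrt(r), np.sqrt(1.0 - r)
    ds_counter = 0

    for disease in diseases:
        n_datasets = int(rng.integers(config.datasets_per_disease[0],
                                      config.datasets_per_disease[1] + 1))
        active_modules = [m for m, d in module_disease.items() if d == disease]
        for _ in range(n_datasets):
            ds_counter += 1
            dataset = f"DS{ds_counter:03d}"
            offsets = rng.normal(0.0, config.batch_shift_sd, size=config.n_genes) \
                if config.batch_shift_sd > 0 else np.zeros(config.n_genes)
            batch_offsets[dataset] = offsets
            n_samples = int(rng.integers(config.samples_per_dataset[0],
                                         config.samples_per_dataset[1] + 1))
            n_controls = max(1, int(round(config.control_fraction * n_samples)))
            n_controls = min(n_controls, n_samples - 1)  # always >=1 case
            for s in range(n_samples):
                is_control = s < n_controls
                sample_id = f"{dataset}_s{s + 1:03d}"
                col = baseline + offsets
                noise = rng.standard_normal(config.n_genes)
                col = col + config.noise_sd * noise
                if not is_control:
                    # latent-factor module signal, active in cases only
                    for m in active_modules:
                        f = rng.standard_normal()
                        idx = [gene_index[g] for g in module_genes[m]]
                        col[idx] = (baseline[idx] + offsets[idx]
                                    + config.noise_sd
                                    * (sqrt_r * f + sqrt_1mr * noise[idx]))
                    for g, lfc in de_genes[disease].items():
                        col[gene_index[g]] += lfc
                meta_rows.append((sample_id, dataset, disease, is_control))
                columns.append(col)

    values = pd.DataFrame(
        np.column_stack(columns) if columns else np.empty((config.n_genes, 0)),
        index=pd.Index(genes, name="gene"),
        columns=[row[0] for row in meta_rows],
    )
    meta = pd.DataFrame(meta_rows, columns=["sample_id", "dataset_id",
                                            "disease_label", "is_control"])
    study = ExpressionStudy(values, meta)
    truth = GroundTruth(module_membership, module_genes, module_disease,
                        de_genes, batch_offsets)
    return study, truth


def generate_pathways(
    gene_universe: Sequence[str],
    n_pathways: int,
    size_range: tuple[int, int],
    overlap_with_modules: float,
    seed: int,
    modules: Mapping[int, Sequence[str]] | None = None,
) -> PathwayCollection:
    """Draw pathway gene sets from the universe.

    A fraction ``overlap_with_modules`` of the pathways is seeded from
    the planted modules (cycling through ``modules``): the module's
    genes are taken first and topped up with random genes if the drawn
    pathway size exceeds the module, or down-sampled if smaller.  The
    remainder are uniform random subsets.
    """
    universe = sorted(set(gene_universe))
    if not universe:
        raise ValueError("gene universe is empty")
    lo, hi = size_range
    if not (1 <= lo <= hi <= len(universe)):
        raise ValueError("size_range must satisfy 1 <= low <= high <= |universe|")
    if not (0.0 <= overlap_with_modules <= 1.0):
        raise ValueError("overlap_with_modules must be in [0,1]")

    rng = np.random.default_rng(seed)
    module_ids = sorted(modules) if modules else []
    n_module_pathways = int(round(overlap_with_modules * n_pathways)) \
        if module_ids else 0

    sets: dict[str, frozenset[str]] = {}
    for p in range(n_pathways):
        pid = f"PW{p + 1:04d}"
        size = int(rng.integers(lo, hi + 1))
        if p < n_module_pathways:
            members = list(modules[module_ids[p % len(module_ids)]])
            if size >= len(members):
                rest = [g for g in universe if g not in set(members)]
                extra = rng.choice(len(rest), size=size - len(members),
                                   replace=False)
                members = members + [rest[int(i)] for i in extra]
            else:
                keep = rng.choice(len(members), size=size, replace=False)
                members = [members[int(i)] for i in keep]
        else:
            pick = rng.choice(len(universe), size=size, replace=False)
            members = [universe[int(i)] for i in pick]
        sets[pid] = frozenset(members)
    return PathwayCollection(sets, names={pid: pid for pid in sets})


def generate_knowledge_graph(
    pathways: PathwayCollection,
    edge_density: float,
    relation_mix: Mapping[str, float],
    seed: int,
) -> KnowledgeGraph:
    """Random typed interaction graph over the pathway proteins.

    Every node belongs to >=1 pathway by construction (the node set is
    the union of the pathway gene sets, mirroring the restriction of the
    interactome to pathway-annotated proteins).  Edges are sampled
    uniformly without replacement at the requested density; each edge is
    typed by a draw from ``relation_mix``.
    """
    if not (0.0 < edge_density <= 1.0):
        raise ValueError("edge_density must be in (0, 1]")
    unknown = set(relation_mix) - RELATION_TYPES
    if unknown:
        raise ValueError(f"unknown relation types in mix: {sorted(unknown)}")
    total = float(sum(relation_mix.values()))
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"relation_mix must sum to 1 (got {total})")

    proteins = sorted(pathways.universe)
    n = len(proteins)
    n_pairs = n * (n - 1) // 2
    n_edges = int(round(edge_density * n_pairs))

    rng = np.random.default_rng(seed)
    chosen = rng.choice(n_pairs, size=n_edges, replace=False)
    rel_names = sorted(relation_mix)
    rel_p = np.array([relation_mix[t] for t in rel_names])
    rels = rng.choice(len(rel_names), size=n_edges, p=rel_p)

    kg = KnowledgeGraph()
    for node in proteins:
        kg.graph.add_node(node)
    # map a flat pair index k to (i, j), i < j, row-major over the triangle
    row_starts = np.cumsum([0] + [n - 1 - i for i in range(n)])
    for k, rel in zip(np.sort(chosen), rels[np.argsort(chosen, kind="stable")]):
        i = int(np.searchsorted(row_starts, k, side="right")) - 1
        j = i + 1 + int(k - row_starts[i])
        kg.add_edge(proteins[i], proteins[j], rel_names[int(rel)],
                    source="simulated")

    membership: dict[str, set[str]] = {}
    for pid, members in pathways.items():
        for g in members:
            membership.setdefault(g, set()).add(pid)
    kg.annotate(membership)
    return kg


def write_edge_list(kg: KnowledgeGraph, path) -> None:
    """Serialize a knowledge graph as a (source, relation, target,
    provenance) TSV, one line per (pair, relation type)."""
    lines = []
    for a, b, data in kg.graph.edges(data=True):
        x, y = (a, b) if a < b else (b, a)
        prov = ",".join(sorted(data["sources"])) or "na"
        for rel in sorted(data["relations"]):
            lines.append(f"{x}\t{rel}\t{y}\t{prov}")
    with open(path, "w") as fh:
        fh.write("\n".join(sorted(lines)) + ("\n" if lines else ""))
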
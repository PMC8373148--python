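"""Core in-memory containers shared across the pipeline stages.

The pipeline moves a handful of objects between stages: a labelled
expression study (genes x samples on log2 scale, with per-sample
metadata), disease-specific co-expression networks (top-TOM edge sets),
a pathway-annotated protein interaction graph, and pathway gene-set
collections.  Tabular results (differential-expression and consensus
tables) are plain :class:`pandas.DataFrame` objects with fixed column
names documented where they are produced.
"""

from __future__ import annotations

import dataclasses
import io
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

#: relation vocabulary of the protein interaction graph
RELATION_TYPES = frozenset(
    {"association", "increase", "decrease", "regulates", "has_component"}
)

#: label given to pooled control samples and the control network
NORMAL_LABEL = "normal"

#: fixed column order for sample metadata tables
META_COLUMNS = ["sample_id", "dataset_id", "disease_label", "is_control"]


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Order an unordered protein/gene pair lexicographically.

    Edge identity throughout the package is the sorted pair; weights are
    never part of identity.
    """
    if a == b:
        raise ValueError(f"self-pair not allowed: {a!r}")
    return (a, b) if a < b else (b, a)


@dataclasses.dataclass
class ExpressionStudy:
    """A merged expression study: log2 values plus sample metadata.

    Parameters
    ----------
    values
        genes x samples matrix of log2 intensities; index = gene (or
        probe) identifiers, columns = sample identifiers.
    sample_meta
        One row per sample with columns ``sample_id``, ``dataset_id``,
        ``disease_label``, ``is_control``; row order matches the column
        order of ``values``.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        meta = self.sample_meta
        missing = [c for c in META_COLUMNS if c not in meta.columns]
        if missing:
            raise ValueError(f"sample_meta missing columns: {missing}")
        if meta["sample_id"].duplicated().any():
            dupes = meta.loc[meta["sample_id"].duplicated(), "sample_id"].tolist()
            raise ValueError(f"duplicate sample ids: {dupes}")
        if list(self.values.columns) != list(meta["sample_id"]):
            raise ValueError("values columns and sample_meta sample_id disagree")
        if meta["dataset_id"].isna().any():
            raise ValueError("every sample needs a dataset id")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_samples(self, sample_ids: Iterable[str]) -> "ExpressionStudy":
        ids = list(sample_ids)
        meta = self.sample_meta.set_index("sample_id").loc[ids].reset_index()
        return ExpressionStudy(self.values[ids], meta)

    def case_samples(self, disease: str) -> list[str]:
        m = self.sample_meta
        sel = (m["disease_label"] == disease) & (~m["is_control"].astype(bool))
        return m.loc[sel, "sample_id"].tolist()

    # --- TSV round trip -------------------------------------------------

    def write_tsv(self, values_path, meta_path) -> None:
        self.values.to_csv(values_path, sep="\t", float_format="%.10g",
                           index_label="gene")
        self.sample_meta.to_csv(meta_path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, values_path, meta_path) -> "ExpressionStudy":
        values = pd.read_csv(values_path, sep="\t", index_col=0)
        values.index = values.index.astype(str)
        meta = pd.read_csv(meta_path, sep="\t")
        meta["sample_id"] = meta["sample_id"].astype(str)
        meta["is_control"] = meta["is_control"].astype(bool)
        return cls(values, meta)


@dataclasses.dataclass
class CoexpressionNetwork:
    """Co-expression network of one disease: the strongest-TOM edge set.

    ``edges`` maps lexicographically ordered gene pairs to their TOM
    weight in [0, 1].  ``universe_size`` is the number of genes that
    entered the TOM computation (after zero-variance drops), which can
    exceed the number of nodes because only edge endpoints are nodes.
    """

    label: str
    universe_size: int
    edges: dict[tuple[str, str], float]

    def __post_init__(self) -> None:
        for (a, b), w in self.edges.items():
            if a >= b:
                raise ValueError(f"edge pair not canonical: {(a, b)}")
            if not (0.0 <= w <= 1.0 + 1e-12):
                raise ValueError(f"edge weight outside [0,1]: {(a, b, w)}")

    @property
    def nodes(self) -> set[str]:
        out: set[str] = set()
        for a, b in self.edges:
            out.add(a)
            out.add(b)
        return out

    @property
    def edge_set(self) -> set[tuple[str, str]]:
        return set(self.edges)

    def has_edge(self, a: str, b: str) -> bool:
        return canonical_pair(a, b) in self.edges

    def neighbors(self, gene: str) -> set[str]:
        out = set()
        for a, b in self.edges:
            if a == gene:
                out.add(b)
            elif b == gene:
                out.add(a)
        return out

    def to_dataframe(self) -> pd.DataFrame:
        rows = sorted(self.edges.items())
        return pd.DataFrame(
            [(a, b, w) for (a, b), w in rows],
            columns=["gene_a", "gene_b", "weight"],
        )

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph(label=self.label, universe_size=self.universe_size)
        for (a, b), w in self.edges.items():
            g.add_edge(a, b, weight=float(w))
        return g

    def write_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False,
                                   float_format="%.10g")

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.to_networkx(), path)

    @classmethod
    def read_tsv(cls, path, label: str, universe_size: int | None = None
                 ) -> "CoexpressionNetwork":
        df = pd.read_csv(path, sep="\t", dtype={"gene_a": str, "gene_b": str})
        edges = {
            canonical_pair(a, b): float(w)
            for a, b, w in df[["gene_a", "gene_b", "weight"]].itertuples(index=False)
        }
        if universe_size is None:
            universe_size = len({g for e in edges for g in e})
        return cls(label=label, universe_size=universe_size, edges=edges)


@dataclasses.dataclass
class PathwayCollection:
    """Mapping pathway id -> protein/gene set, with optional display names."""

    sets: dict[str, frozenset[str]]
    names: dict[str, str] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        for pid, members in self.sets.items():
            if not members:
                raise ValueError(f"pathway {pid!r} has an empty gene set")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, pid: str) -> frozenset[str]:
        return self.sets[pid]

    def items(self):
        return self.sets.items()

    @property
    def universe(self) -> frozenset[str]:
        out: set[str] = set()
        for members in self.sets.values():
            out |= members
        return frozenset(out)

    def to_gmt(self) -> str:
        buf = io.StringIO()
        for pid in self.sets:
            desc = self.names.get(pid, "na")
            genes = "\t".join(sorted(self.sets[pid]))
            buf.write(f"{pid}\t{desc}\t{genes}\n")
        return buf.getvalue()

    def write_gmt(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_gmt())


class KnowledgeGraph:
    """Pathway-annotated, typed, undirected protein interaction graph.

    Thin wrapper around :class:`networkx.Graph`.  Each edge carries a
    ``relations`` set (subset of :data:`RELATION_TYPES`) and a
    ``sources`` set recording provenance; each node carries a
    ``pathways`` set once annotated.
    """

    def __init__(self, graph: nx.Graph | None = None) -> None:
        self.graph = graph if graph is not None else nx.Graph()

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_set(self) -> set[tuple[str, str]]:
        return {canonical_pair(a, b) for a, b in self.graph.edges}

    def add_edge(self, a: str, b: str, relation: str,
                 source: str | None = None) -> None:
        if relation not in RELATION_TYPES:
            raise ValueError(f"unknown relation type: {relation!r}")
        if a == b:
            return  # self-loops are dropped
        if self.graph.has_edge(a, b):
            data = self.graph[a][b]
            data["relations"].add(relation)
            if source is not None:
                data["sources"].add(source)
        else:
            self.graph.add_edge(
                a, b,
                relations={relation},
                sources=set() if source is None else {source},
            )

    def relations(self, a: str, b: str) -> set[str]:
        return set(self.graph[a][b]["relations"])

    def annotations(self, node: str) -> set[str]:
        return set(self.graph.nodes[node].get("pathways", set()))

    def annotate(self, membership: Mapping[str, set[str]]) -> None:
        for node in self.graph.nodes:
            self.graph.nodes[node]["pathways"] = set(membership.get(node, set()))

    def degree(self, node: str) -> int:
        return int(self.graph.degree[node])

    def subgraph_edges(self, proteins: Iterable[str]) -> set[tuple[str, str]]:
        """Edges of the graph with both endpoints in ``proteins``."""
        keep = set(proteins) & self.nodes
        return {
            canonical_pair(a, b)
            for a, b in self.graph.subgraph(keep).edges
        }

    def write_graphml(self, path) -> None:
        g = nx.Graph()
        for node, data in self.graph.nodes(data=True):
            g.add_node(node, pathways="|".join(sorted(data.get("pathways", set()))))
        for a, b, data in self.graph.edges(data=True):
            g.add_edge(
                a, b,
                relations="|".join(sorted(data["relations"])),
                sources="|".join(sorted(data["sources"])),
            )
        nx.write_graphml(g, path)


def degtable(log2fc: np.ndarray, p_value: np.ndarray, adj_p: np.ndarray,
             genes: Iterable[str]) -> pd.DataFrame:
    """Assemble a differential-expression table with fixed columns.

    Columns: ``gene`` (index), ``log2fc``, ``p_value``, ``adj_p``,
    ``direction`` in {up, down, zero}.
    """
    direction = np.where(log2fc > 0, "up", np.where(log2fc < 0, "down", "zero"))
    df = pd.DataFrame(
        {"log2fc": log2fc, "p_value": p_value, "adj_p": adj_p,
         "direction": direction},
        index=pd.Index(list(genes), name="gene"),
    )
    return df
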
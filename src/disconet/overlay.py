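"""Overlaying a pathway diagram with co-expression and DE evidence.

A pathway graph mixes protein nodes with protein-complex nodes (named
member sets), joined by typed edges: 'interaction' between functional
entities and 'membership' from a protein to its complex.  The overlay
classifies every pathway interaction edge by which co-expression
networks corroborate it (disease, normal, both, or neither), adds the
disease-network correlations between pathway proteins that match no
drawn interaction ('coexpression-only'), and colours nodes by the
direction and significance of differential expression.  Complex nodes
get a consensus direction only when all members agree.
"""

from __future__ import annotations

import dataclasses
import logging
from itertools import product
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

from .datatypes import CoexpressionNetwork, PathwayCollection, canonical_pair
from .similarity import enrich

logger = logging.getLogger(__name__)

EDGE_CLASSES = {
    "pathway∩both", "pathway∩disease", "pathway∩normal", "pathway-only",
    "coexpression-only", "membership",
}


@dataclasses.dataclass
class PathwayGraph:
    """A pathway diagram of proteins and complexes.

    ``kinds`` maps node id to 'protein' or 'complex'; ``members`` gives
    each complex its (non-empty) protein member set; ``edges`` are
    (a, b, type) with type 'interaction' or 'membership'; membership
    edges must join a protein to a complex.
    """

    kinds: dict[str, str]
    members: dict[str, frozenset[str]]
    edges: list[tuple[str, str, str]]
    display_names: dict[str, str] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        # endpoints not declared in the node table (typically complex
        # members drawn with membership edges) default to proteins
        for a, b, _ in self.edges:
            for node in (a, b):
                self.kinds.setdefault(node, "protein")
        for node, kind in self.kinds.items():
            if kind not in {"protein", "complex"}:
                raise ValueError(f"node {node!r} has unknown kind {kind!r}")
        for cid in (n for n, k in self.kinds.items() if k == "complex"):
            if not self.members.get(cid):
                raise ValueError(f"complex {cid!r} has no members")
        for a, b, etype in self.edges:
            if etype not in {"interaction", "membership"}:
                raise ValueError(f"edge ({a},{b}) has unknown type {etype!r}")
            if etype == "membership":
                kinds = {self.kinds[a], self.kinds[b]}
                if kinds != {"protein", "complex"}:
                    raise ValueError(
                        f"membership edge ({a},{b}) must join protein and complex")

    @classmethod
    def read_tsv(cls, nodes_path, edges_path) -> "PathwayGraph":
        """Nodes TSV: id, kind, members ('|'-joined, empty for proteins);
        edges TSV: a, b, type."""
        nodes = pd.read_csv(nodes_path, sep="\t", dtype=str).fillna("")
        edges = pd.read_csv(edges_path, sep="\t", dtype=str)
        kinds, members = {}, {}
        for _, row in nodes.iterrows():
            kinds[row["id"]] = row["kind"]
            if row["kind"] == "complex":
                members[row["id"]] = frozenset(
                    m for m in row["members"].split("|") if m)
        edge_list = [(r["a"], r["b"], r["type"])
                     for _, r in edges.iterrows()]
        return cls(kinds, members, edge_list)


def expand_complexes(pathway: PathwayGraph) -> dict[str, frozenset[str]]:
    """Map every pathway node to its protein expansion.

    Protein nodes expand to themselves; complexes to their member sets.
    """
    out = {}
    for node, kind in pathway.kinds.items():
        if kind == "protein":
            out[node] = frozenset({node})
        else:
            if not pathway.members.get(node):
                raise ValueError(f"complex {node!r} has no members")
            out[node] = pathway.members[node]
    return out


def covered_proteins(pathway: PathwayGraph) -> frozenset[str]:
    """All unique proteins the pathway covers (members included)."""
    out: set[str] = set()
    for expansion in expand_complexes(pathway).values():
        out |= expansion
    return frozenset(out)


def _matches(expansion_a: frozenset[str], expansion_b: frozenset[str],
             edge_set: set[tuple[str, str]]) -> bool:
    """Existential member-pair match of a pathway edge against a network."""
    for u, v in product(expansion_a, expansion_b):
        if u != v and canonical_pair(u, v) in edge_set:
            return True
    return False


def classify_edges(pathway: PathwayGraph,
                   disease_net: CoexpressionNetwork | None,
                   normal_net: CoexpressionNetwork | None) -> nx.Graph:
    """Build the overlay graph with one class per edge.

    A pathway interaction edge matches a network iff any protein pair
    across its two endpoint expansions is a network edge; classes are
    'pathway∩both', 'pathway∩disease', 'pathway∩normal' or
    'pathway-only'.  Disease-network edges between covered proteins
    that match no pathway interaction are added as 'coexpression-only';
    membership edges pass through unchanged.
    """
    expansions = expand_complexes(pathway)
    disease_edges = disease_net.edge_set if disease_net is not None else set()
    normal_edges = normal_net.edge_set if normal_net is not None else set()

    overlay = nx.Graph()
    for node, kind in pathway.kinds.items():
        overlay.add_node(node, kind=kind,
                         members="|".join(sorted(expansions[node]))
                         if kind == "complex" else "")

    for a, b, etype in pathway.edges:
        if etype == "membership":
            overlay.add_edge(a, b, edge_class="membership")
            continue
        in_disease = _matches(expansions[a], expansions[b], disease_edges)
        in_normal = _matches(expansions[a], expansions[b], normal_edges)
        if in_disease and in_normal:
            cls = "pathway∩both"
        elif in_disease:
            cls = "pathway∩disease"
        elif in_normal:
            cls = "pathway∩normal"
        else:
            cls = "pathway-only"
        overlay.add_edge(a, b, edge_class=cls)

    # disease correlations inside the pathway that match no drawn interaction
    proteins = covered_proteins(pathway)
    interaction_pairs = [
        (expansions[a], expansions[b])
        for a, b, etype in pathway.edges if etype == "interaction"
    ]
    for u, v in disease_edges:
        if u in proteins and v in proteins:
            drawn = any(
                (u in ea and v in eb) or (u in eb and v in ea)
                for ea, eb in interaction_pairs
            )
            if not drawn:
                if overlay.has_edge(u, v):
                    continue
                overlay.add_node(u, kind="protein", members="")
                overlay.add_node(v, kind="protein", members="")
                overlay.add_edge(u, v, edge_class="coexpression-only")
    return overlay


def color_nodes(overlay: nx.Graph, degs: pd.DataFrame,
                alpha: float = 0.05) -> nx.Graph:
    """Attach DE direction/significance attributes to the overlay nodes.

    Protein nodes get ``de_direction`` in {up, down, none} and a
    ``de_significant`` flag (adjusted p strictly below ``alpha``);
    proteins absent from the DEG table stay neutral.  Complex nodes get
    ``complex_consensus``: 'up'/'down' when all members agree on a
    non-zero direction, 'unknown' when any member is absent from the
    table, 'mixed' otherwise.
    """
    out = overlay.copy()

    def lookup(protein: str) -> tuple[str, bool] | None:
        if protein not in degs.index:
            return None
        rec = degs.loc[protein]
        direction = str(rec["direction"])
        direction = direction if direction in {"up", "down"} else "none"
        return direction, bool(rec["adj_p"] < alpha)

    for node, data in out.nodes(data=True):
        if data.get("kind") == "complex":
            members = [m for m in data.get("members", "").split("|") if m]
            infos = [lookup(m) for m in members]
            if any(info is None for info in infos):
                consensus = "unknown"
            else:
                directions = {info[0] for info in infos}
                if directions in ({"up"}, {"down"}):
                    consensus = directions.pop()
                else:
                    consensus = "mixed"
            data["complex_consensus"] = consensus
        else:
            info = lookup(node)
            if info is None:
                data["de_direction"], data["de_significant"] = "none", False
            else:
                data["de_direction"], data["de_significant"] = info
    return out


def coexpression_neighbors(network: CoexpressionNetwork,
                           gene: str) -> set[str]:
    """Direct co-expression partners of a gene (itself excluded)."""
    if gene not in network.nodes:
        logger.warning("gene %s absent from network %s", gene, network.label)
        return set()
    return network.neighbors(gene)


def neighborhood_enrichment(network: CoexpressionNetwork, gene: str,
                            pathways: PathwayCollection,
                            universe: Iterable[str],
                            alpha: float = 0.05) -> pd.DataFrame:
    """ORA of a gene's co-expression neighbourhood.

    A proxy for pathway crosstalk mediated by the gene: its direct
    co-expression partners (the gene itself excluded) are tested for
    over-representation in each pathway.  An empty neighbourhood yields
    an empty table.
    """
    neighbors = coexpression_neighbors(network, gene) - {gene}
    if not neighbors:
        return pd.DataFrame(columns=["pathway", "overlap", "p", "adj_p",
                                     "significant"])
    return enrich(neighbors, pathways, universe, alpha)


def write_overlay_graphml(overlay: nx.Graph, path) -> None:
    nx.write_graphml(overlay, path)
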
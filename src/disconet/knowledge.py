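"""Building and interrogating the pathway-annotated interaction graph.

Typed edge lists (SIF/TSV) from any number of interaction sources are
merged into a single undirected graph; direction is discarded and
conflicting relation types accumulate on the same edge.  The graph is
then restricted to proteins carrying at least one pathway annotation,
so every node of the final interactome belongs to a pathway.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from typing import Iterable

from .datatypes import KnowledgeGraph, PathwayCollection, RELATION_TYPES

logger = logging.getLogger(__name__)


def read_edge_lists(paths: Iterable) -> KnowledgeGraph:
    """Parse (source, relation, target [, provenance]) TSV/SIF files.

    Duplicate undirected pairs are merged: provenance sets are unioned
    and conflicting relation types are retained side by side on the
    edge.  An unknown relation token is an error naming the offending
    line.
    """
    kg = KnowledgeGraph()
    for path in paths:
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) < 3:
                    raise ValueError(
                        f"{path}:{lineno}: expected >=3 tab-separated fields")
                source, relation, target = fields[0], fields[1], fields[2]
                if relation not in RELATION_TYPES:
                    raise ValueError(
                        f"{path}:{lineno}: unknown relation token {relation!r}")
                provenance = fields[3] if len(fields) > 3 else str(path)
                for prov in provenance.split(","):
                    kg.add_edge(source, target, relation, source=prov)
    return kg


def restrict_to_annotated(graph: KnowledgeGraph,
                          pathways: PathwayCollection) -> KnowledgeGraph:
    """Keep only proteins with at least one pathway membership.

    Nodes outside every pathway are removed together with their incident
    edges, and the surviving nodes get their pathway annotation sets.
    Idempotent.
    """
    membership: dict[str, set[str]] = {}
    for pid, members in pathways.items():
        for protein in members:
            membership.setdefault(protein, set()).add(pid)
    keep = [n for n in graph.graph.nodes if n in membership]
    sub = graph.graph.subgraph(keep).copy()
    out = KnowledgeGraph(sub)
    out.annotate(membership)
    return out


def relation_distribution(graph: KnowledgeGraph
                          ) -> dict[str, tuple[int, float]]:
    """Relation-type counts and fractions over typed edge instances.

    A multi-type edge contributes one instance per relation type, so the
    fractions always sum to 1 over a non-empty graph.
    """
    counts: Counter[str] = Counter()
    for _, _, data in graph.graph.edges(data=True):
        for rel in data["relations"]:
            counts[rel] += 1
    total = sum(counts.values())
    if total == 0:
        return {}
    return {rel: (c, c / total) for rel, c in sorted(counts.items())}


def degree_ranking(graph: KnowledgeGraph, top_k: int) -> list[str]:
    """The ``top_k`` most connected proteins, ties by lexicographic id.

    Degree counts distinct neighbour proteins (multi-type edges count
    once).
    """
    if top_k > graph.graph.number_of_nodes():
        raise ValueError("top_k exceeds node count")
    ranked = sorted(graph.graph.nodes,
                    key=lambda n: (-graph.graph.degree[n], n))
    return ranked[:top_k]


def mean_degree(graph: KnowledgeGraph,
                subset: Iterable[str] | None = None) -> float:
    """Mean number of interaction partners over ``subset`` (default all).

    Proteins absent from the graph are ignored with a warning.
    """
    if subset is None:
        members = list(graph.graph.nodes)
    else:
        subset = set(subset)
        members = [n for n in subset if n in graph.graph]
        missing = subset - set(members)
        if missing:
            warnings.warn(
                f"{len(missing)} proteins absent from the graph ignored",
                UserWarning)
    if not members:
        raise ValueError("no proteins of the subset are in the graph")
    return sum(graph.graph.degree[n] for n in members) / len(members)


def read_gmt(path) -> PathwayCollection:
    """Read a GMT gene-set file (name, description, genes...).

    Duplicate genes within a line are collapsed.  Round-trips with
    :meth:`PathwayCollection.write_gmt`.
    """
    sets: dict[str, frozenset[str]] = {}
    names: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs >=3 tab-separated fields")
            pid, desc, genes = fields[0], fields[1], fields[2:]
            genes = [g for g in genes if g]
            if pid in sets:
                raise ValueError(f"{path}:{lineno}: duplicate pathway id {pid!r}")
            sets[pid] = frozenset(genes)
            names[pid] = desc
    return PathwayCollection(sets, names)


def annotation_count(pathways: PathwayCollection,
                     subset: Iterable[str]) -> tuple[float | None, float]:
    """Mean pathway memberships per protein of ``subset``, plus coverage.

    Returns ``(mean over proteins with >=1 membership, fraction of the
    subset with >=1 membership)``.  With zero coverage the mean is
    undefined and returned as ``None``.
    """
    subset = list(dict.fromkeys(subset))
    if not subset:
        raise ValueError("empty subset")
    counts = []
    for protein in subset:
        c = sum(1 for members in pathways.sets.values() if protein in members)
        counts.append(c)
    covered = [c for c in counts if c >= 1]
    coverage = len(covered) / len(subset)
    mean = sum(covered) / len(covered) if covered else None
    return mean, coverage
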
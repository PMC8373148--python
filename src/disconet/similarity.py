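"""Pathway-disease similarity statistics and over-representation analysis.

Two complementary statistics score how strongly a pathway's proteins
are co-expressed in a disease network D = (P', E_D):

* pathway-based similarity: the proportion of all unordered protein
  pairs of the pathway P that are edges of D, with the denominator
  |C_P| = |P|(|P|-1)/2 taken over the full pathway regardless of which
  proteins made it into the network;
* interactome-based similarity: restrict first to the pathway's edges
  that are supported by the interaction graph I = (U, E_I), i.e. the
  induced subgraph edges E_S = {e_uv : u,v in P & U, e_uv in E_I}, and
  report |E_S & E_D| / |E_S|.  With no supported edges the value is
  undefined and reported as missing (NaN) - "no knowledge" is not "no
  overlap".

For pathway x disease heat-map rendering, rows are min-max
standardised to [0, 1] per pathway.  Over-representation analysis uses
a one-sided Fisher exact test per pathway with Benjamini-Yekutieli
adjustment across pathways.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from itertools import combinations
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import (
    CoexpressionNetwork,
    KnowledgeGraph,
    PathwayCollection,
    canonical_pair,
)

logger = logging.getLogger(__name__)


def pathway_similarity(pathway_proteins: Iterable[str],
                       network: CoexpressionNetwork) -> float:
    """Pathway-based similarity: pathway pair coverage by network edges."""
    proteins = sorted(set(pathway_proteins))
    if len(proteins) < 2:
        raise ValueError("pathway needs >= 2 proteins")
    edge_set = network.edge_set
    hits = sum(1 for u, v in combinations(proteins, 2)
               if (u, v) in edge_set)
    n_pairs = len(proteins) * (len(proteins) - 1) // 2
    return hits / n_pairs


def interactome_similarity(pathway_proteins: Iterable[str],
                           network: CoexpressionNetwork,
                           knowledge: KnowledgeGraph) -> float | None:
    """Interactome-based similarity: supported-edge coverage by network.

    Returns ``None`` when the interaction graph supports no edge within
    the pathway (the statistic is undefined there).
    """
    proteins = set(pathway_proteins)
    if len(proteins) < 2:
        raise ValueError("pathway needs >= 2 proteins")
    supported = knowledge.subgraph_edges(proteins)
    if not supported:
        return None
    edge_set = network.edge_set
    hits = sum(1 for pair in supported if pair in edge_set)
    return hits / len(supported)


@dataclasses.dataclass
class SimilarityMatrix:
    """pathways x diseases similarity values, raw and row-standardised."""

    raw: pd.DataFrame
    standardized: pd.DataFrame
    method: str

    def write_tsv(self, path, standardized: bool = False) -> None:
        frame = self.standardized if standardized else self.raw
        frame.to_csv(path, sep="\t", float_format="%.10g",
                     index_label="pathway")


def similarity_matrix(pathways: PathwayCollection,
                      networks: Mapping[str, CoexpressionNetwork],
                      method: str = "pathway",
                      knowledge: KnowledgeGraph | None = None
                      ) -> SimilarityMatrix:
    """Score every (pathway, disease network) combination.

    Rows follow the pathway collection's order, columns the network
    mapping's order.  Undefined interactome-based values propagate as
    NaN.  The standardised view is filled by :func:`standardize_rows`.
    """
    if method not in {"pathway", "interactome"}:
        raise ValueError("method must be 'pathway' or 'interactome'")
    if method == "interactome" and knowledge is None:
        raise ValueError("interactome-based similarity needs a knowledge graph")
    labels = list(networks)
    data = np.full((len(pathways), len(labels)), np.nan)
    for i, pid in enumerate(pathways):
        proteins = pathways[pid]
        for j, label in enumerate(labels):
            if method == "pathway":
                data[i, j] = pathway_similarity(proteins, networks[label])
            else:
                value = interactome_similarity(proteins, networks[label], knowledge)
                data[i, j] = np.nan if value is None else value
    raw = pd.DataFrame(data, index=list(pathways), columns=labels)
    return standardize_rows(SimilarityMatrix(raw, raw.copy(), method))


def standardize_rows(matrix: SimilarityMatrix) -> SimilarityMatrix:
    """Min-max scale each pathway row to [0, 1].

    Constant rows map to all zeros; missing entries are ignored in the
    min/max and stay missing.
    """
    raw = matrix.raw
    std = raw.copy()
    for pid, row in raw.iterrows():
        vals = row.to_numpy(dtype=float)
        finite = np.isfinite(vals)
        if not finite.any():
            continue
        lo, hi = np.nanmin(vals), np.nanmax(vals)
        if hi > lo:
            std.loc[pid] = (vals - lo) / (hi - lo)
        else:
            scaled = np.where(finite, 0.0, np.nan)
            std.loc[pid] = scaled
    return SimilarityMatrix(raw, std, matrix.method)


def fisher_ora(query: Iterable[str], pathway: Iterable[str],
               universe: Iterable[str]) -> float:
    """One-sided (enrichment) Fisher exact p-value for a gene set pair.

    Genes outside the universe are dropped from query and pathway with
    a warning.  The p-value is the upper hypergeometric tail of the
    observed overlap.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    query = set(query)
    pathway = set(pathway)
    stray = (query - universe) | (pathway - universe)
    if stray:
        warnings.warn(f"{len(stray)} genes outside the universe ignored",
                      UserWarning)
        query &= universe
        pathway &= universe
    overlap = len(query & pathway)
    # P(X >= overlap), X ~ Hypergeom(|U|, |pathway|, |query|)
    p = float(stats.hypergeom.sf(overlap - 1, len(universe), len(pathway),
                                 len(query)))
    return min(max(p, np.finfo(float).tiny), 1.0)


def adjust_by(pvalues: Iterable[float]) -> np.ndarray:
    """Benjamini-Yekutieli step-up adjustment.

    Valid under arbitrary dependence via the harmonic-sum inflation
    c(m) = sum_{i<=m} 1/i; adjusted values are clipped to 1 and are
    always >= the corresponding BH values.
    """
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0,1]")
    return multipletests(p, method="fdr_by")[1]


def enrich(query: Iterable[str], pathways: PathwayCollection,
           universe: Iterable[str], alpha: float = 0.05) -> pd.DataFrame:
    """Over-representation analysis of a query set against a collection.

    One row per pathway (collection order) with columns pathway,
    overlap, p, adj_p and significant (strict ``adj_p < alpha``).
    """
    universe = set(universe)
    query = set(query) & universe
    rows = []
    for pid in pathways:
        members = set(pathways[pid]) & universe
        overlap = len(query & members)
        p = fisher_ora(query, members, universe) if members else 1.0
        rows.append((pid, overlap, p))
    table = pd.DataFrame(rows, columns=["pathway", "overlap", "p"])
    table["adj_p"] = adjust_by(table["p"]) if len(table) else []
    table["significant"] = table["adj_p"] < alpha
    return table
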
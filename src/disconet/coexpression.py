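"""Disease-specific co-expression networks from the topological overlap matrix.

The construction chain is: Pearson correlation over the disease's
samples, signed soft-threshold adjacency a_ij = ((1 + r_ij)/2)^beta,
topological overlap

    TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij),

with l_ij = sum_u a_iu a_uj and k_i = sum_u a_iu, and finally retention
of the top fraction (default 1%) of unordered gene pairs by TOM value.
Retaining a fixed fraction of all pairs keeps the edge count identical
across networks built on the same gene universe, while the node set
(edge endpoints) can vary - which is what makes the networks directly
comparable.

No module detection is performed: the network IS the thresholded TOM.
"""

from __future__ import annotations

import logging
import math
import warnings
from fractions import Fraction

import numpy as np
import pandas as pd

from .datatypes import CoexpressionNetwork, ExpressionStudy, NORMAL_LABEL

logger = logging.getLogger(__name__)

#: conventional soft power for signed networks
DEFAULT_BETA = 12.0
#: fraction of all gene pairs retained as network edges
DEFAULT_FRACTION = 0.01


def correlation_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Gene-gene Pearson correlation over samples.

    Zero-variance genes are dropped with a warning (their correlation is
    undefined).  Requires at least 3 samples.
    """
    if matrix.shape[1] < 3:
        raise ValueError("correlation needs >= 3 samples")
    variances = matrix.var(axis=1, ddof=1)
    keep = variances > 0
    if not keep.all():
        dropped = matrix.index[~keep].tolist()
        warnings.warn(f"dropping {len(dropped)} zero-variance genes",
                      UserWarning)
        matrix = matrix.loc[keep]
    if matrix.shape[0] == 0:
        raise ValueError("all genes have zero variance")
    corr = np.corrcoef(matrix.to_numpy(dtype=float))
    corr = np.clip(corr, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=matrix.index, columns=matrix.index)


def signed_adjacency(corr: pd.DataFrame | np.ndarray,
                     beta: float = DEFAULT_BETA) -> np.ndarray:
    """Signed soft-threshold adjacency ((1 + r)/2)^beta, zero diagonal.

    Negative correlations are pushed towards 0 rather than folded onto
    the positives; the transform is monotone increasing in r.
    """
    if beta <= 0:
        raise ValueError("beta must be positive")
    r = corr.to_numpy(dtype=float) if isinstance(corr, pd.DataFrame) else \
        np.asarray(corr, dtype=float)
    a = ((1.0 + r) / 2.0) ** beta
    a = np.clip(a, 0.0, 1.0)
    np.fill_diagonal(a, 0.0)
    return a


def pick_soft_power(corr: pd.DataFrame | np.ndarray,
                    candidate_betas: list[float],
                    r2_target: float = 0.8,
                    n_bins: int = 10) -> float:
    """Scale-free topology criterion for the soft power.

    For each candidate beta the connectivity distribution k_i of the
    resulting adjacency is binned, and the signed R^2 of the linear fit
    log10(freq) ~ log10(mean k) is computed (sign-flipped so a
    decreasing relation scores positively).  The smallest candidate
    reaching ``r2_target`` wins; if none does, the best-scoring one.
    """
    if len(candidate_betas) < 2:
        if len(candidate_betas) == 1:
            return candidate_betas[0]
        raise ValueError("need at least one candidate beta")
    betas = sorted(candidate_betas)
    best_beta, best_r2 = betas[0], -np.inf
    for beta in betas:
        k = signed_adjacency(corr, beta).sum(axis=1)
        if np.allclose(k, k[0]):
            warnings.warn("degenerate connectivity; returning smallest beta",
                          UserWarning)
            return betas[0]
        r2 = _scale_free_r2(k, n_bins)
        if r2 >= r2_target:
            return beta
        if r2 > best_r2:
            best_beta, best_r2 = beta, r2
    return best_beta


def _scale_free_r2(k: np.ndarray, n_bins: int) -> float:
    """Signed R^2 of log10(frequency) against log10(binned connectivity)."""
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        mask = which == b
        if mask.sum() == 0:
            continue
        mean_k = k[mask].mean()
        if mean_k <= 0:
            continue
        xs.append(np.log10(mean_k))
        ys.append(np.log10(mask.sum() / k.size))
    if len(xs) < 3:
        return -np.inf
    slope, intercept = np.polyfit(xs, ys, 1)
    pred = slope * np.asarray(xs) + intercept
    ss_res = float(((np.asarray(ys) - pred) ** 2).sum())
    ss_tot = float(((np.asarray(ys) - np.mean(ys)) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return -np.sign(slope) * r2


def topological_overlap(adjacency: np.ndarray) -> np.ndarray:
    """Topological overlap matrix of a soft-threshold adjacency.

    Requires a symmetric matrix with zero diagonal and entries in
    [0, 1].  TOM_ij blends the direct adjacency with the amount of
    shared neighbourhood; the diagonal is defined as 1.
    """
    a = np.asarray(adjacency, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(a, a.T, atol=1e-12):
        raise ValueError("adjacency must be symmetric")
    if np.abs(np.diagonal(a)).max(initial=0.0) > 1e-12:
        raise ValueError("adjacency must have zero diagonal")
    if a.min(initial=0.0) < -1e-12 or a.max(initial=0.0) > 1 + 1e-12:
        raise ValueError("adjacency entries must lie in [0,1]")
    k = a.sum(axis=1)
    l = a @ a
    denom = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = (l + a) / denom
    tom[denom == 0] = 0.0
    np.fill_diagonal(tom, 1.0)
    return np.clip(tom, 0.0, 1.0)


def retained_edge_count(universe_size: int, fraction: float = DEFAULT_FRACTION
                        ) -> int:
    """Number of edges kept at a given fraction of all gene pairs.

    The smallest integer >= fraction * C(universe_size, 2).  The
    fraction is interpreted exactly at its decimal representation, so
    e.g. 1% of 19,900 pairs is 199, not the float artefact 200.
    """
    if universe_size < 2:
        raise ValueError("universe_size must be >= 2")
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    frac = Fraction(str(fraction))
    n_pairs = universe_size * (universe_size - 1) // 2
    return int(math.ceil(frac * n_pairs))


def top_fraction_network(
    tom: np.ndarray,
    gene_ids: list[str],
    label: str,
    fraction: float = DEFAULT_FRACTION,
) -> CoexpressionNetwork:
    """Retain the highest-TOM gene pairs as the disease's network.

    Exactly ``retained_edge_count`` edges are kept; ties at the cut are
    broken by lexicographic (gene_a, gene_b) order.  Nodes are the edge
    endpoints only.
    """
    n = len(gene_ids)
    if tom.shape != (n, n):
        raise ValueError("tom shape does not match gene_ids")
    m = retained_edge_count(n, fraction)
    iu, ju = np.triu_indices(n, k=1)
    weights = tom[iu, ju]
    pairs = [
        (gene_ids[i], gene_ids[j]) if gene_ids[i] < gene_ids[j]
        else (gene_ids[j], gene_ids[i])
        for i, j in zip(iu, ju)
    ]
    # pre-sort lexicographically so the stable sort on descending weight
    # breaks ties at the cut by canonical pair order
    order_ids = np.array(sorted(range(len(pairs)), key=pairs.__getitem__))
    stable = order_ids[np.argsort(-weights[order_ids], kind="mergesort")]
    edges = {pairs[t]: float(weights[t]) for t in stable[:m]}
    return CoexpressionNetwork(label=label, universe_size=n, edges=edges)


def build_network(matrix: pd.DataFrame, label: str,
                  beta: float = DEFAULT_BETA,
                  fraction: float = DEFAULT_FRACTION,
                  pick_power: bool = False,
                  candidate_betas: list[float] | None = None
                  ) -> CoexpressionNetwork:
    """Correlation -> signed adjacency -> TOM -> top-fraction network."""
    corr = correlation_matrix(matrix)
    if pick_power:
        candidates = candidate_betas or [2, 4, 6, 8, 10, 12, 14, 16, 18, 20]
        beta = pick_soft_power(corr, list(candidates))
    adj = signed_adjacency(corr, beta)
    tom = topological_overlap(adj)
    return top_fraction_network(tom, list(corr.index), label, fraction)


def build_disease_networks(study: ExpressionStudy,
                           beta: float = DEFAULT_BETA,
                           fraction: float = DEFAULT_FRACTION,
                           pick_power: bool = False
                           ) -> dict[str, CoexpressionNetwork]:
    """One network per disease label plus the pooled-control 'normal' one.

    Disease networks use only the samples carrying the disease label
    (controls excluded); the 'normal' network uses the pooled controls.
    Labels with fewer than 3 samples are skipped with a warning.
    """
    meta = study.sample_meta
    networks: dict[str, CoexpressionNetwork] = {}
    for label in sorted(meta["disease_label"].unique()):
        if label == NORMAL_LABEL:
            ids = meta.loc[meta["disease_label"] == label, "sample_id"]
        else:
            ids = meta.loc[(meta["disease_label"] == label)
                           & (~meta["is_control"].astype(bool)), "sample_id"]
        ids = ids.tolist()
        if len(ids) < 3:
            warnings.warn(f"label {label!r} has <3 samples; skipped",
                          UserWarning)
            continue
        networks[label] = build_network(study.values[ids], label,
                                        beta=beta, fraction=fraction,
                                        pick_power=pick_power)
        logger.info("built network %s: %d nodes, %d edges", label,
                    len(networks[label].nodes), len(networks[label].edges))
    return networks
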
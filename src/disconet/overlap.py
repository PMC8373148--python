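"""Node- and edge-level commonality across disease co-expression networks.

Because every network retains the same number of top-TOM edges, asking
how often a protein (or an unordered protein pair) occurs across the
disease networks is a fair comparison.  The pooled-control 'normal'
network is excluded from the counting and serves as a reference set:
items common to many diseases that are also in the normal network are
widespread rather than disease-associated.
"""

from __future__ import annotations

import dataclasses
from collections import Counter
from typing import Hashable, Iterable, Mapping

import pandas as pd

from .datatypes import CoexpressionNetwork, NORMAL_LABEL


@dataclasses.dataclass
class OccurrenceCounts:
    """item -> number of disease networks containing it."""

    counts: dict[Hashable, int]
    total_networks: int

    def __post_init__(self) -> None:
        bad = {k: v for k, v in self.counts.items()
               if not (0 < v <= self.total_networks)}
        if bad:
            raise ValueError(f"counts outside (0, total]: {bad}")

    def to_dataframe(self) -> pd.DataFrame:
        rows = sorted(self.counts.items(), key=lambda kv: (-kv[1], str(kv[0])))
        return pd.DataFrame(rows, columns=["item", "count"])


def _counted_networks(networks: Mapping[str, CoexpressionNetwork],
                      exclude: Iterable[str]) -> list[CoexpressionNetwork]:
    excluded = set(exclude)
    kept = [net for label, net in networks.items() if label not in excluded]
    if not kept:
        raise ValueError("no networks left after exclusion")
    return kept


def protein_occurrence(networks: Mapping[str, CoexpressionNetwork],
                       exclude: Iterable[str] = (NORMAL_LABEL,)
                       ) -> OccurrenceCounts:
    """How many disease networks contain each protein."""
    kept = _counted_networks(networks, exclude)
    counter: Counter = Counter()
    for net in kept:
        counter.update(net.nodes)
    return OccurrenceCounts(dict(counter), total_networks=len(kept))


def edge_occurrence(networks: Mapping[str, CoexpressionNetwork],
                    exclude: Iterable[str] = (NORMAL_LABEL,)
                    ) -> OccurrenceCounts:
    """How many disease networks contain each unordered protein pair."""
    kept = _counted_networks(networks, exclude)
    counter: Counter = Counter()
    for net in kept:
        counter.update(net.edge_set)
    return OccurrenceCounts(dict(counter), total_networks=len(kept))


def common_items(counts: OccurrenceCounts,
                 min_count: int | None = None,
                 top_k: int | None = None,
                 max_count: int | None = None) -> list:
    """Most (or least) common items by occurrence.

    Exactly one of ``min_count`` / ``top_k`` selects the mode:
    threshold mode returns every item with count >= min_count (and
    <= max_count when given, which yields 'least common' item lists via
    min_count=1 with a low ceiling); top-k mode returns the k highest
    counts with ties broken by lexicographic item id.
    """
    if (min_count is None) == (top_k is None):
        raise ValueError("give exactly one of min_count or top_k")
    ranked = sorted(counts.counts.items(), key=lambda kv: (-kv[1], str(kv[0])))
    if top_k is not None:
        return [item for item, _ in ranked[:top_k]]
    out = [item for item, c in ranked
           if c >= min_count and (max_count is None or c <= max_count)]
    return out


def unique_edge_count(networks: Mapping[str, CoexpressionNetwork],
                      exclude: Iterable[str] = (NORMAL_LABEL,)
                      ) -> tuple[dict[str, int], int, float]:
    """Edges seen in exactly one disease network.

    Returns (per-label unique-edge counts, global unique total, and the
    unique total as a fraction of the summed per-network edge counts).
    """
    excluded = set(exclude)
    labels = [lab for lab in networks if lab not in excluded]
    occ = edge_occurrence(networks, exclude)
    unique_pairs = {pair for pair, c in occ.counts.items() if c == 1}
    per_label = {
        lab: sum(1 for pair in networks[lab].edge_set if pair in unique_pairs)
        for lab in labels
    }
    total_edges = sum(len(networks[lab].edges) for lab in labels)
    fraction = len(unique_pairs) / total_edges if total_edges else 0.0
    return per_label, len(unique_pairs), fraction


def top_edges_by_weight(network: CoexpressionNetwork, k: int
                        ) -> set[tuple[str, str]]:
    """The k strongest edges of one network by |weight|.

    Ties are broken by lexicographic pair order, so subsetting is
    deterministic.
    """
    if k > len(network.edges):
        raise ValueError("k exceeds the network's edge count")
    ranked = sorted(network.edges.items(),
                    key=lambda kv: (-abs(kv[1]), kv[0]))
    return {pair for pair, _ in ranked[:k]}


def set_overlap(a: set, b: set) -> tuple[int, float | None, float]:
    """(intersection size, |a&b|/|a|, Jaccard index).

    The directional fraction uses ``a`` as denominator (the convention
    for comparing common-disease items against a reference set); it is
    ``None`` when ``a`` is empty.  Jaccard of two empty sets is 0.
    """
    inter = len(a & b)
    union = len(a | b)
    frac = inter / len(a) if a else None
    jaccard = inter / union if union else 0.0
    return inter, frac, jaccard


def overlap_sweep(counts: OccurrenceCounts, reference: set,
                  k_values: list[int]) -> pd.DataFrame:
    """Fraction of the top-k most common items found in a reference set.

    One row per k with columns (k, fraction); top-k selection uses the
    :func:`common_items` tie rule.
    """
    if sorted(k_values) != list(k_values):
        raise ValueError("k_values must be sorted ascending")
    rows = []
    for k in k_values:
        top = common_items(counts, top_k=k)
        frac = sum(1 for item in top if item in reference) / len(top) \
            if top else 0.0
        rows.append((k, frac))
    return pd.DataFrame(rows, columns=["k", "fraction"])
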
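"""Per-disease differential expression and the cross-disease consensus.

Each disease is contrasted against the pooled control samples of its
own datasets with a per-gene Welch two-sample t-test (a deterministic
stand-in for a moderated-t engine, swappable behind this interface),
followed by Benjamini-Hochberg adjustment across genes.  The consensus
then splits each disease's significant genes by direction of change and
averages adjusted p-values and log2 fold changes per (gene, direction)
across diseases - a gene can therefore legitimately appear in both the
up and the down consensus.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import ExpressionStudy, degtable

logger = logging.getLogger(__name__)

CONSENSUS_COLUMNS = ["gene", "direction", "mean_adj_p", "mean_log2fc",
                     "n_diseases"]


def differential_expression(study: ExpressionStudy, disease: str
                            ) -> pd.DataFrame:
    """Welch-t differential expression of one disease vs its controls.

    Controls are the pooled 'normal' samples originating from the same
    datasets as the disease's case samples.  Returns a DEG table
    indexed by gene with columns log2fc (case mean minus control mean,
    log2 scale), p_value, adj_p (BH) and direction.
    """
    meta = study.sample_meta
    case_ids = study.case_samples(disease)
    case_datasets = set(meta.loc[meta["sample_id"].isin(case_ids),
                                 "dataset_id"])
    ctrl_sel = meta["is_control"].astype(bool) \
        & meta["dataset_id"].isin(case_datasets)
    ctrl_ids = meta.loc[ctrl_sel, "sample_id"].tolist()
    if len(case_ids) < 2:
        raise ValueError(f"disease {disease!r} has <2 case samples")
    if len(ctrl_ids) < 2:
        raise ValueError(
            f"no matching control data for {disease!r} (<2 control samples)")

    case = study.values[case_ids].to_numpy(dtype=float)
    ctrl = study.values[ctrl_ids].to_numpy(dtype=float)
    log2fc = case.mean(axis=1) - ctrl.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        _, p = stats.ttest_ind(case, ctrl, axis=1, equal_var=False)
    # degenerate rows (both groups constant): no evidence of change
    p = np.where(np.isnan(p), 1.0, p)
    adj = multipletests(p, method="fdr_bh")[1]
    return degtable(log2fc, p, adj, study.values.index)


def filter_significant(table: pd.DataFrame, alpha: float = 0.05
                       ) -> pd.DataFrame:
    """Keep genes with adjusted p strictly below ``alpha``."""
    return table[table["adj_p"] < alpha].copy()


def consensus(tables: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Direction-split consensus over per-disease filtered DEG tables.

    For every (gene, direction in {up, down}) pair, averages the
    adjusted p-values and log2 fold changes over the diseases where the
    gene passed the significance filter with that direction, recording
    the contributing disease count.  Genes with direction 'zero' are
    excluded from both sides.
    """
    if not tables:
        raise ValueError("need at least one DEG table")
    rows = []
    for disease, table in tables.items():
        sub = table[table["direction"].isin(["up", "down"])]
        for gene, rec in sub.iterrows():
            rows.append((gene, rec["direction"], rec["adj_p"],
                         rec["log2fc"], disease))
    if not rows:
        return pd.DataFrame(columns=CONSENSUS_COLUMNS)
    long = pd.DataFrame(rows, columns=["gene", "direction", "adj_p",
                                       "log2fc", "disease"])
    grouped = long.groupby(["gene", "direction"], sort=True).agg(
        mean_adj_p=("adj_p", "mean"),
        mean_log2fc=("log2fc", "mean"),
        n_diseases=("disease", "nunique"),
    ).reset_index()
    return grouped[CONSENSUS_COLUMNS]


def extreme_degs(consensus_table: pd.DataFrame,
                 p_cut: float = 0.01,
                 lfc_cut: float = 1.75) -> tuple[list[str], list[str]]:
    """The most extreme consensus genes: strict p and |log2FC| cuts.

    Returns (up-regulated genes, down-regulated genes) with mean
    adjusted p < ``p_cut`` and mean log2 fold change beyond
    +/-``lfc_cut`` (strict inequalities on both).
    """
    if consensus_table.empty:
        return [], []
    sig = consensus_table[consensus_table["mean_adj_p"] < p_cut]
    up = sig[(sig["direction"] == "up") & (sig["mean_log2fc"] > lfc_cut)]
    down = sig[(sig["direction"] == "down") & (sig["mean_log2fc"] < -lfc_cut)]
    return sorted(up["gene"]), sorted(down["gene"])


def direction_profile(tables: Mapping[str, pd.DataFrame],
                      gene: str) -> dict[str, str]:
    """Per-disease direction of one gene across the filtered tables.

    Only diseases where the gene passed the filter appear; an empty
    mapping means the gene was nowhere significant.  Supports auditing
    genes with mixed up/down patterns across diseases.
    """
    out = {}
    for disease, table in tables.items():
        if gene in table.index:
            out[disease] = str(table.loc[gene, "direction"])
    return out


def run_differential_expression(study: ExpressionStudy,
                                diseases: list[str],
                                alpha: float = 0.05
                                ) -> tuple[dict[str, pd.DataFrame],
                                           dict[str, pd.DataFrame]]:
    """DE for every disease with available controls.

    Returns (full tables, filtered tables); diseases without matching
    controls are skipped with a log message, mirroring cohorts where
    some disease datasets ship no control samples.
    """
    full: dict[str, pd.DataFrame] = {}
    filtered: dict[str, pd.DataFrame] = {}
    for disease in diseases:
        try:
            table = differential_expression(study, disease)
        except ValueError as exc:
            logger.warning("skipping %s: %s", disease, exc)
            continue
        full[disease] = table
        filtered[disease] = filter_significant(table, alpha)
    return full, filtered
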
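"""Normalisation, batch correction, probe collapsing and cohort filters.

Order of operations for a cohort: per-dataset quantile normalisation,
merge, per-gene location-scale batch adjustment, probe collapsing.
The batch adjustment is a direct, closed-form stand-in for empirical-
Bayes batch correction: per gene, every batch is rescaled to the gene's
pooled within-batch variance and recentred on the gene's grand mean.
"""

from __future__ import annotations

import logging
import warnings
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .datatypes import ExpressionStudy, NORMAL_LABEL

logger = logging.getLogger(__name__)


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalise columns (samples) of a genes x samples matrix.

    Every column is mapped onto the reference distribution, the row-wise
    mean of the per-column sorted values.  Ties within a column receive
    the mean of the reference values at their rank positions, so the
    transform is idempotent.
    """
    if matrix.shape[1] < 2:
        raise ValueError("quantile normalisation needs >= 2 samples")
    values = matrix.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ValueError("matrix contains NaN entries")
    reference = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        col = values[:, j]
        order = np.argsort(col, kind="mergesort")
        ranked = np.empty_like(reference)
        ranked[order] = reference
        # average the reference over tied positions
        tied = pd.Series(ranked).groupby(pd.Series(col)).transform("mean")
        out[:, j] = tied.to_numpy()
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def quantile_normalize_per_dataset(study: ExpressionStudy) -> ExpressionStudy:
    """Apply :func:`quantile_normalize` separately within each dataset."""
    values = study.values.copy()
    for dataset, group in study.sample_meta.groupby("dataset_id"):
        ids = group["sample_id"].tolist()
        if len(ids) < 2:
            logger.warning("dataset %s has <2 samples; left unnormalised", dataset)
            continue
        values[ids] = quantile_normalize(values[ids])
    return ExpressionStudy(values, study.sample_meta)


def correct_batch(study: ExpressionStudy) -> ExpressionStudy:
    """Per-gene location-scale batch adjustment.

    For each gene, each batch (dataset) is standardised with its own
    mean and sd, rescaled by the gene's pooled within-batch sd and
    recentred on the gene's grand mean.  Batches with a single sample,
    or zero within-batch variance for a gene, get a location-only
    adjustment.
    """
    meta = study.sample_meta
    batches = meta["dataset_id"].unique().tolist()
    if len(batches) < 2:
        return ExpressionStudy(study.values.copy(), meta)

    X = study.values.to_numpy(dtype=float)
    cols = {s: i for i, s in enumerate(study.values.columns)}
    batch_idx = {
        b: np.array([cols[s] for s in meta.loc[meta["dataset_id"] == b,
                                               "sample_id"]])
        for b in batches
    }
    for b, idx in batch_idx.items():
        if idx.size == 1:
            warnings.warn(
                f"batch {b!r} has a single sample; location-only adjustment",
                UserWarning,
            )

    grand_mean = X.mean(axis=1)
    # pooled within-batch variance, df-weighted over batches with >=2 samples
    num = np.zeros(X.shape[0])
    den = 0
    for b, idx in batch_idx.items():
        if idx.size >= 2:
            num += (idx.size - 1) * X[:, idx].var(axis=1, ddof=1)
            den += idx.size - 1
    pooled_sd = np.sqrt(num / den) if den > 0 else np.zeros(X.shape[0])

    out = np.empty_like(X)
    for b, idx in batch_idx.items():
        sub = X[:, idx]
        m_b = sub.mean(axis=1)
        if idx.size >= 2:
            s_b = sub.std(axis=1, ddof=1)
        else:
            s_b = np.zeros(X.shape[0])
        scale = np.ones(X.shape[0])
        ok = (s_b > 0) & (pooled_sd > 0)
        scale[ok] = pooled_sd[ok] / s_b[ok]
        out[:, idx] = (sub - m_b[:, None]) * scale[:, None] + grand_mean[:, None]

    values = pd.DataFrame(out, index=study.values.index,
                          columns=study.values.columns)
    return ExpressionStudy(values, meta)


def collapse_probes(matrix: pd.DataFrame,
                    probe_map: Mapping[str, str]) -> pd.DataFrame:
    """Collapse a probes x samples matrix to genes x samples.

    When several probes map to the same gene the most variable probe
    (unbiased sample variance) is kept; equal-variance ties go to the
    lexicographically smallest probe id.  Output rows are sorted by
    gene id.
    """
    unmapped = [p for p in matrix.index if p not in probe_map]
    if unmapped:
        raise ValueError(f"unmapped probes: {sorted(unmapped)}")
    var = matrix.var(axis=1, ddof=1)
    frame = pd.DataFrame({
        "probe": matrix.index,
        "gene": [probe_map[p] for p in matrix.index],
        "var": var.to_numpy(),
    })
    frame = frame.sort_values(["gene", "var", "probe"],
                              ascending=[True, False, True],
                              kind="mergesort")
    keep = frame.drop_duplicates("gene", keep="first")
    out = matrix.loc[keep["probe"]]
    out.index = pd.Index(keep["gene"].tolist(), name="gene")
    return out.sort_index()


def filter_disease_groups(
    meta: pd.DataFrame,
    min_samples: int = 50,
    min_datasets: int = 2,
    exclude_labels: Iterable[str] = ("cancer",),
) -> list[str]:
    """Disease inclusion filter.

    A disease label is retained iff it has at least ``min_samples``
    samples in total, spans at least ``min_datasets`` distinct datasets,
    and is not in ``exclude_labels`` (over-broad labels such as plain
    'cancer' are dropped regardless of size).
    """
    excluded = set(exclude_labels)
    retained = []
    disease_meta = meta[meta["disease_label"] != NORMAL_LABEL]
    for label, group in disease_meta.groupby("disease_label", sort=True):
        if label in excluded:
            continue
        n_samples = len(group)
        n_datasets = group["dataset_id"].nunique()
        if n_samples >= min_samples and n_datasets >= min_datasets:
            retained.append(label)
    logger.info("retained %d disease labels (min_samples=%d, min_datasets=%d)",
                len(retained), min_samples, min_datasets)
    return retained


def pool_controls(study: ExpressionStudy,
                  retained_diseases: Iterable[str]) -> ExpressionStudy:
    """Pool the control samples of the retained diseases' datasets.

    Only controls whose dataset contributed to a retained disease are
    kept; they are relabelled with the common 'normal' label.
    """
    retained = set(retained_diseases)
    meta = study.sample_meta
    contributing = set(
        meta.loc[(~meta["is_control"].astype(bool))
                 & meta["disease_label"].isin(retained), "dataset_id"]
    )
    sel = meta["is_control"].astype(bool) & meta["dataset_id"].isin(contributing)
    if not sel.any():
        raise ValueError("no control samples found in the retained datasets")
    ids = meta.loc[sel, "sample_id"].tolist()
    pooled = study.subset_samples(ids)
    new_meta = pooled.sample_meta.copy()
    new_meta["disease_label"] = NORMAL_LABEL
    return ExpressionStudy(pooled.values, new_meta)


def preprocess_cohort(
    study: ExpressionStudy,
    min_samples: int = 50,
    min_datasets: int = 2,
    exclude_labels: Iterable[str] = ("cancer",),
) -> tuple[ExpressionStudy, list[str]]:
    """Full preprocessing path for a raw cohort.

    Per-dataset quantile normalisation, disease-group filtering, batch
    correction over the retained samples, and pooling of controls under
    the 'normal' label.  Returns the analysis-ready study (disease cases
    plus pooled normal controls) and the retained disease labels.
    """
    normalized = quantile_normalize_per_dataset(study)
    retained = filter_disease_groups(normalized.sample_meta, min_samples,
                                     min_datasets, exclude_labels)
    if not retained:
        raise ValueError("no disease passes the inclusion filter")
    meta = normalized.sample_meta
    controls = pool_controls(normalized, retained)
    case_sel = (~meta["is_control"].astype(bool)) \
        & meta["disease_label"].isin(set(retained))
    case_ids = meta.loc[case_sel, "sample_id"].tolist()
    cases = normalized.subset_samples(case_ids)
    merged = ExpressionStudy(
        pd.concat([cases.values, controls.values], axis=1),
        pd.concat([cases.sample_meta, controls.sample_meta],
                  ignore_index=True),
    )
    corrected = correct_batch(merged)
    if not np.isfinite(corrected.values.to_numpy()).all():
        raise ValueError("non-finite values after preprocessing")
    return corrected, retained
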
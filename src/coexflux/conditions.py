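"""Activation/repression condition extraction for metabolic clusters.

For every cluster and every compendium dataset, the mean within-dataset
correlation over all within-cluster gene pairs is computed; those means are
z-scored across clusters within each dataset, and each cluster's datasets
are ranked by z-score.  The top datasets nominate conditions in which the
cluster is coherently switched on (or off) and are handed to manual
inspection.  A leave-one-condition-out flag marks datasets whose mean
coexpression collapses when a single condition is removed — rankings driven
by one outlier sample rather than genuine coregulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clustering import ClusterSet
from .preprocess import ExpressionDataset

MIN_CONDITIONS_FOR_PCC = 4
TOP_K = 30
LOO_DROP_THRESHOLD = 0.5


@dataclass
class ConditionRanking:
    mean_coexpr: pd.DataFrame  # clusters x datasets
    zscores: pd.DataFrame
    top_datasets: dict[int, list[str]] = field(default_factory=dict)
    outlier_flags: pd.DataFrame | None = None


def _mean_pair_pcc(values: pd.DataFrame) -> float:
    """Mean PCC over all unordered gene pairs of a genes x conditions block."""
    vals = values.dropna(axis=0, how="any")
    if vals.shape[0] < 2 or vals.shape[1] < MIN_CONDITIONS_FOR_PCC:
        return float("nan")
    corr = np.corrcoef(vals.to_numpy(dtype=float))
    iu = np.triu_indices(corr.shape[0], k=1)
    off = corr[iu]
    off = off[np.isfinite(off)]
    return float(off.mean()) if off.size else float("nan")


def cluster_dataset_coexpression(
    clusters: ClusterSet, datasets: list[ExpressionDataset]
) -> pd.DataFrame:
    """Clusters x datasets matrix of mean within-cluster, within-dataset PCC.

    Entries are missing when fewer than two cluster genes are present in the
    dataset or the dataset has fewer than 4 conditions.
    """
    ids = sorted(k for k in clusters.labels.unique() if k > 0)
    if not ids:
        raise ValueError("cluster set is empty")
    rows = {}
    for k in ids:
        members = clusters.members(k)
        rows[k] = {
            ds.dataset_id: _mean_pair_pcc(
                ds.values.loc[[g for g in members if g in ds.values.index]]
            )
            for ds in datasets
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def rank_conditions(
    mean_coexpr: pd.DataFrame,
    k: int = TOP_K,
    datasets: list[ExpressionDataset] | None = None,
    clusters: ClusterSet | None = None,
) -> ConditionRanking:
    """Z-score across clusters within each dataset and rank per cluster.

    When the underlying datasets and cluster set are supplied, top datasets
    additionally get a leave-one-condition-out outlier flag.
    """
    mc = mean_coexpr.to_numpy(dtype=float)
    mean = np.nanmean(mc, axis=0, keepdims=True)
    sd = np.nanstd(mc, axis=0, keepdims=True)  # population SD over clusters
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (mc - mean) / sd
    z[np.broadcast_to(sd == 0, z.shape)] = 0.0
    zscores = pd.DataFrame(z, index=mean_coexpr.index, columns=mean_coexpr.columns)

    top: dict[int, list[str]] = {}
    for cid in zscores.index:
        row = zscores.loc[cid].dropna()
        ordered = row.sort_values(ascending=False, kind="stable")
        top[int(cid)] = list(ordered.index[:k])

    flags = None
    if datasets is not None and clusters is not None:
        ds_map = {ds.dataset_id: ds for ds in datasets}
        rows = []
        for cid, ds_ids in top.items():
            members = clusters.members(cid)
            for ds_id in ds_ids:
                rows.append(
                    (cid, ds_id,
                     _loo_outlier(ds_map[ds_id], members))
                )
        flags = pd.DataFrame(rows, columns=["cluster", "dataset_id", "outlier_driven"])
    return ConditionRanking(
        mean_coexpr=mean_coexpr, zscores=zscores, top_datasets=top,
        outlier_flags=flags,
    )


def _loo_outlier(
    ds: ExpressionDataset, members: list[str], drop_threshold: float = LOO_DROP_THRESHOLD
) -> bool:
    """True when dropping one condition cuts the mean coexpression by more
    than ``drop_threshold`` of its value."""
    block = ds.values.loc[[g for g in members if g in ds.values.index]]
    full = _mean_pair_pcc(block)
    if not np.isfinite(full) or full <= 0:
        return False
    for col in block.columns:
        reduced = _mean_pair_pcc(block.drop(columns=col))
        if np.isfinite(reduced) and (full - reduced) > drop_threshold * full:
            return True
    return False
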
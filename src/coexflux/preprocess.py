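"""Expression preprocessing: gene filtering, low-expression filters, per-dataset
z-normalization, batch-skew detection/splitting, and compendium assembly.

The compendium workflow mirrors the standard expression-compendium recipe:
each member dataset (>= 10 conditions) is z-normalized gene-wise, datasets
whose condition-correlation structure betrays a two-batch composition are
split (or discarded when the skew cannot be resolved), and the survivors are
concatenated over the union gene set with explicit NaN for genes absent from
a member dataset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.mixture import GaussianMixture

MIN_COMPENDIUM_CONDITIONS = 10

EXPRESSION_LEVELS = ("rare", "low", "moderate", "high")


# --------------------------------------------------------------------- types


@dataclass
class ExpressionDataset:
    """One genes x conditions expression matrix (rows: genes)."""

    dataset_id: str
    values: pd.DataFrame
    normalized: bool = False
    log_scale: bool = True

    @property
    def condition_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_conditions(self) -> int:
        return self.values.shape[1]


@dataclass
class Compendium:
    """Concatenation of normalized datasets over the union gene set."""

    values: pd.DataFrame
    dataset_spans: dict[str, tuple[int, int]]  # dataset_id -> [start, end)

    @property
    def gene_index(self) -> pd.Index:
        return self.values.index

    def dataset_columns(self, dataset_id: str) -> pd.DataFrame:
        start, end = self.dataset_spans[dataset_id]
        return self.values.iloc[:, start:end]


@dataclass
class DevTimeCourse:
    """Developmental time course; values are RPKM-like nonnegative reals
    unless ``log_scale`` is set."""

    values: pd.DataFrame  # genes x timepoints
    timepoint_hours: np.ndarray
    flat_gene_ids: frozenset[str]
    log_scale: bool = False

    def __post_init__(self):
        extra = self.flat_gene_ids - set(self.values.index)
        if extra:
            raise ValueError(f"flat genes not in index: {sorted(extra)[:5]}")


@dataclass
class TissueMatrix:
    """TPM-like expression across tissues plus per-tissue level labels."""

    values: pd.DataFrame  # genes x tissues
    labels: pd.DataFrame | None = None  # same shape, values in EXPRESSION_LEVELS


@dataclass
class BimodalFit:
    """Two-Gaussian fit of a log2 expression histogram.

    The lower component is the low-expression subpopulation (LES); genes
    never exceeding ``les_threshold = mu_low + sd_low`` are filtered out.
    """

    mu_low: float
    sd_low: float
    mu_high: float
    sd_high: float
    weight_low: float = 0.5
    unimodal_warning: bool = False

    @property
    def les_threshold(self) -> float:
        return self.mu_low + self.sd_low


class MixtureFitError(RuntimeError):
    def __init__(self, message: str, best_fit: BimodalFit | None = None):
        super().__init__(message)
        self.best_fit = best_fit


# ---------------------------------------------------------------- operations


def filter_gene_catalog(catalog: pd.DataFrame) -> pd.DataFrame:
    """Keep only live, protein-coding genes.

    ``catalog`` needs boolean columns ``live`` and ``protein_coding``.
    """
    for col in ("live", "protein_coding"):
        if col not in catalog.columns:
            raise ValueError(f"catalog lacks required column {col!r}")
    mask = catalog["live"].astype(bool) & catalog["protein_coding"].astype(bool)
    return catalog.loc[mask]


def fit_bimodal_expression(
    log2_means, seed: int = 0, max_iter: int = 500, n_init: int = 10
) -> BimodalFit:
    """EM fit of a 2-component Gaussian mixture to per-gene log2 means."""
    x = np.asarray(log2_means, dtype=float).reshape(-1, 1)
    if not np.all(np.isfinite(x)):
        raise ValueError("log2 means must be finite")
    if len(x) < 4:
        raise ValueError("too few values for a mixture fit")
    gm = GaussianMixture(
        n_components=2,
        n_init=n_init,
        max_iter=max_iter,
        tol=1e-6,
        init_params="kmeans",
        random_state=seed,
        reg_covar=1e-10,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        gm.fit(x)
    means = gm.means_.ravel()
    sds = np.sqrt(gm.covariances_.ravel())
    weights = gm.weights_.ravel()
    order = np.argsort(means)
    mu_low, mu_high = means[order]
    sd_low, sd_high = sds[order]
    fit = BimodalFit(
        mu_low=float(mu_low),
        sd_low=float(sd_low),
        mu_high=float(mu_high),
        sd_high=float(sd_high),
        weight_low=float(weights[order][0]),
        unimodal_warning=bool(mu_high - mu_low < max(sd_low, sd_high)),
    )
    if not gm.converged_:
        raise MixtureFitError("EM did not converge", best_fit=fit)
    return fit


def filter_low_expression_dev(tc: DevTimeCourse, fit: BimodalFit) -> DevTimeCourse:
    """Drop genes below the LES threshold at every timepoint.

    The threshold is on the log2 scale; raw (RPKM-like) time courses are
    compared against ``2**threshold``.
    """
    thr = fit.les_threshold if tc.log_scale else 2.0**fit.les_threshold
    keep = (tc.values >= thr).any(axis=1)
    kept = tc.values.loc[keep]
    return DevTimeCourse(
        values=kept,
        timepoint_hours=tc.timepoint_hours,
        flat_gene_ids=frozenset(g for g in tc.flat_gene_ids if g in kept.index),
        log_scale=tc.log_scale,
    )


def filter_low_expression_tissue(tm: TissueMatrix) -> TissueMatrix:
    """Drop genes whose expression is rare or low in every tissue."""
    if tm.labels is None:
        raise ValueError("tissue matrix has no expression-level labels")
    keep = tm.labels.isin(["moderate", "high"]).any(axis=1)
    return TissueMatrix(values=tm.values.loc[keep], labels=tm.labels.loc[keep])


def label_tissue_levels(
    values: pd.DataFrame,
    quantiles: tuple[float, float, float] = (0.5, 0.7, 0.9),
) -> pd.DataFrame:
    """Assign rare/low/moderate/high labels by within-tissue quantile cuts."""
    q_rare, q_low, q_mod = quantiles
    labels = pd.DataFrame("rare", index=values.index, columns=values.columns)
    for t in values.columns:
        col = values[t]
        cuts = col.quantile([q_rare, q_low, q_mod])
        labels.loc[col > cuts.iloc[0], t] = "low"
        labels.loc[col > cuts.iloc[1], t] = "moderate"
        labels.loc[col > cuts.iloc[2], t] = "high"
    return labels


def znormalize_dataset(ds: ExpressionDataset) -> ExpressionDataset:
    """Per-gene z-scores across the dataset's conditions (population SD).

    Zero-variance genes become all-NaN: a constant gene carries no
    correlation information, and zeros would fabricate it.
    """
    vals = ds.values.to_numpy(dtype=float)
    mean = np.nanmean(vals, axis=1, keepdims=True)
    sd = np.nanstd(vals, axis=1, keepdims=True)  # population convention
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (vals - mean) / sd
    z[np.broadcast_to(sd == 0, z.shape)] = np.nan
    out = pd.DataFrame(z, index=ds.values.index, columns=ds.values.columns)
    return replace(ds, values=out, normalized=True)


# ------------------------------------------------------------ batch handling


@dataclass
class BatchSkewResult:
    status: str  # "clean" | "split" | "discard"
    parts: list[ExpressionDataset] = field(default_factory=list)
    skew_statistic: float = float("nan")


def _median_abs_condition_corr(values: pd.DataFrame) -> float:
    """Median |PCC| over condition pairs, after per-gene centering/scaling.

    Gene-wise z-scoring removes baseline-abundance structure so that a clean
    dataset shows near-zero condition-condition correlations while a
    two-batch dataset shows |PCC| near 1 both within and between batches.
    """
    vals = values.to_numpy(dtype=float)
    mean = np.nanmean(vals, axis=1, keepdims=True)
    sd = np.nanstd(vals, axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (vals - mean) / sd
    z[np.broadcast_to(sd == 0, z.shape)] = np.nan
    corr = pd.DataFrame(z).corr(min_periods=3).to_numpy()
    iu = np.triu_indices(corr.shape[0], k=1)
    off = corr[iu]
    off = off[np.isfinite(off)]
    return float(np.median(np.abs(off))) if off.size else float("nan")


def detect_batch_skew(
    ds: ExpressionDataset, skew_threshold: float = 0.5
) -> BatchSkewResult:
    """Flag datasets whose condition correlations are skewed toward +/-1.

    A flagged dataset is bipartitioned by a 2-way average-linkage cut of the
    condition-correlation dissimilarity; the split is accepted only when both
    halves have >= 2 conditions and drop below the threshold after re-scoring,
    otherwise the dataset is discarded (unexplained skew).
    """
    if ds.n_conditions < 4:
        raise ValueError("batch-skew detection needs >= 4 conditions")
    stat = _median_abs_condition_corr(ds.values)
    if not np.isfinite(stat) or stat <= skew_threshold:
        return BatchSkewResult("clean", [ds], skew_statistic=stat)

    vals = ds.values.to_numpy(dtype=float)
    mean = np.nanmean(vals, axis=1, keepdims=True)
    sd = np.nanstd(vals, axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (vals - mean) / sd
    z[np.broadcast_to(sd == 0, z.shape)] = np.nan
    corr = pd.DataFrame(z).corr(min_periods=3).to_numpy()
    corr = np.nan_to_num(np.clip(corr, -1, 1), nan=0.0)
    np.fill_diagonal(corr, 1.0)
    dissim = 1.0 - (corr + corr.T) / 2.0
    np.fill_diagonal(dissim, 0.0)
    Z = linkage(squareform(dissim, checks=False), method="average")
    halves = fcluster(Z, t=2, criterion="maxclust")

    parts = []
    for k in (1, 2):
        cols = [c for c, h in zip(ds.values.columns, halves) if h == k]
        if len(cols) < 2:
            return BatchSkewResult("discard", skew_statistic=stat)
        parts.append(
            ExpressionDataset(
                dataset_id=f"{ds.dataset_id}_{'ab'[k - 1]}",
                values=ds.values[cols],
                normalized=ds.normalized,
                log_scale=ds.log_scale,
            )
        )
    if all(
        _median_abs_condition_corr(p.values) <= skew_threshold for p in parts
    ):
        return BatchSkewResult("split", parts, skew_statistic=stat)
    return BatchSkewResult("discard", skew_statistic=stat)


def build_compendium(datasets: list[ExpressionDataset]) -> Compendium:
    """Concatenate normalized datasets over the union gene set.

    Genes absent from a member dataset are NaN (not zero) in its span.
    """
    ids = [ds.dataset_id for ds in datasets]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate dataset_id in compendium input")
    for ds in datasets:
        if not ds.normalized:
            raise ValueError(f"dataset {ds.dataset_id} is not normalized")
    genes = sorted(set().union(*(ds.values.index for ds in datasets)))
    blocks, spans, start = [], {}, 0
    for ds in datasets:
        block = ds.values.reindex(genes)
        block.columns = [f"{ds.dataset_id}::{c}" for c in ds.values.columns]
        blocks.append(block)
        spans[ds.dataset_id] = (start, start + block.shape[1])
        start += block.shape[1]
    return Compendium(values=pd.concat(blocks, axis=1), dataset_spans=spans)


def assemble_compendium(
    datasets: list[ExpressionDataset],
    min_conditions: int = MIN_COMPENDIUM_CONDITIONS,
    skew_threshold: float = 0.5,
) -> tuple[Compendium, pd.DataFrame]:
    """Full admission pipeline: size filter, skew handling, z-normalization,
    concatenation.  Returns the compendium and a manifest table."""
    admitted: list[ExpressionDataset] = []
    rows = []
    for ds in datasets:
        if ds.n_conditions < min_conditions:
            rows.append((ds.dataset_id, ds.n_conditions, "too_few_conditions"))
            continue
        res = detect_batch_skew(ds, skew_threshold=skew_threshold)
        if res.status == "discard":
            rows.append((ds.dataset_id, ds.n_conditions, "discarded"))
            continue
        for part in res.parts:
            admitted.append(znormalize_dataset(part))
            rows.append(
                (part.dataset_id, part.n_conditions,
                 "clean" if res.status == "clean" else "split")
            )
    comp = build_compendium(admitted)
    manifest = pd.DataFrame(rows, columns=["dataset_id", "n_conditions", "status"])
    manifest["span_start"] = [
        comp.dataset_spans.get(d, (-1, -1))[0] for d in manifest["dataset_id"]
    ]
    manifest["span_end"] = [
        comp.dataset_spans.get(d, (-1, -1))[1] for d in manifest["dataset_id"]
    ]
    return comp, manifest
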
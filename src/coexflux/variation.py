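"""Expression-variability statistics and categorization.

Three contexts, three rules:

* development — the variation score (VS): each gene's profile is normalized
  to sum 1 over timepoints, an envelope (mean +/- SD of normalized flat-gene
  profiles) defines invariant behavior, and VS is the mean per-timepoint
  distance to the nearest envelope border (0 inside).  Genes with VS = 0 are
  invariant, VS >= threshold (the 0.97 quantile of flat-gene VS) highly
  variant, in between moderately variant.
* tissues — coefficient of variation (CV = sigma/mu, population SD) with
  fixed bands: invariant < 0.3 <= moderately variant < 0.75 <= highly
  variant.
* compendium — per-dataset CVs: highly variant if CV >= 0.75 in >= 3
  datasets; invariant if CV < 0.3 in >= 95% of the datasets where the gene
  is present; absent everywhere = lowly expressed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .preprocess import DevTimeCourse

CV_HIGH = 0.75
CV_LOW = 0.3
MIN_HIGH_DATASETS = 3
INVARIANT_FRACTION = 0.95
VS_QUANTILE = 0.97

CATEGORIES = ("lowly_expressed", "invariant", "moderately_variant", "highly_variant")


@dataclass(frozen=True)
class FlatEnvelope:
    """Per-timepoint mean and SD of normalized flat-gene profiles."""

    mu: np.ndarray
    sigma: np.ndarray

    def __post_init__(self):
        if len(self.mu) != len(self.sigma):
            raise ValueError("mu and sigma lengths differ")
        if np.any(self.sigma < 0):
            raise ValueError("sigma must be nonnegative")


@dataclass(frozen=True)
class VSResult:
    gene_id: str
    vs: float
    d: np.ndarray  # per-timepoint deviations


def normalize_profile(x) -> np.ndarray:
    """Normalize a nonnegative profile by its total so it sums to 1."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("profile must be nonnegative")
    total = x.sum()
    if total <= 0:
        raise ValueError("all-zero profile cannot be normalized")
    return x / total


def flat_envelope(tc: DevTimeCourse) -> FlatEnvelope:
    """Envelope of the flat cluster: mean +/- SD of its normalized profiles."""
    if not tc.flat_gene_ids:
        raise ValueError("empty flat gene set")
    profiles = np.stack(
        [normalize_profile(tc.values.loc[g].to_numpy()) for g in sorted(tc.flat_gene_ids)]
    )
    return FlatEnvelope(
        mu=profiles.mean(axis=0), sigma=profiles.std(axis=0)  # population SD
    )


def variation_score(
    profile_norm, env: FlatEnvelope, gene_id: str = ""
) -> VSResult:
    """VS of a normalized profile: mean distance to the closest envelope
    border, 0 for points inside the (closed) envelope."""
    p = np.asarray(profile_norm, dtype=float)
    if len(p) != len(env.mu):
        raise ValueError("profile and envelope lengths differ")
    upper = env.mu + env.sigma
    lower = env.mu - env.sigma
    inside = (p >= lower) & (p <= upper)
    d = np.where(inside, 0.0, np.minimum(np.abs(p - upper), np.abs(p - lower)))
    return VSResult(gene_id=gene_id, vs=float(d.mean()), d=d)


def variation_scores(tc: DevTimeCourse, env: FlatEnvelope | None = None) -> pd.DataFrame:
    """VS for every gene of a time course; returns a gene-indexed table."""
    if env is None:
        env = flat_envelope(tc)
    rows = {}
    for g in tc.values.index:
        res = variation_score(normalize_profile(tc.values.loc[g].to_numpy()), env, g)
        rows[g] = res.vs
    return pd.DataFrame({"vs": pd.Series(rows)})


def vs_threshold(flat_vs, q: float = VS_QUANTILE) -> float:
    """The q-quantile (linear interpolation) of flat-gene VS values."""
    flat_vs = np.asarray(flat_vs, dtype=float)
    if flat_vs.size == 0:
        raise ValueError("empty flat VS list")
    return float(np.quantile(flat_vs, q))


def coefficient_of_variation(values) -> float:
    """CV = population SD / mean; requires a positive mean."""
    v = np.asarray(values, dtype=float)
    mu = v.mean()
    if mu <= 0:
        raise ValueError("CV requires a positive mean")
    return float(v.std() / mu)


def categorize_dev(
    vs: Mapping[str, float], threshold: float, lowly_expressed: set[str] = frozenset()
) -> pd.Series:
    """Development categories: lowly expressed (pre-filtered), invariant
    (VS = 0), highly variant (VS >= threshold, inclusive), else moderate."""
    out = {}
    for g, v in vs.items():
        if g in lowly_expressed:
            out[g] = "lowly_expressed"
        elif v == 0:
            out[g] = "invariant"
        elif v >= threshold:
            out[g] = "highly_variant"
        else:
            out[g] = "moderately_variant"
    for g in lowly_expressed:
        out.setdefault(g, "lowly_expressed")
    return pd.Series(out, name="category")


def categorize_tissue(cv: float, cv_low: float = CV_LOW, cv_high: float = CV_HIGH) -> str:
    if cv >= cv_high:
        return "highly_variant"
    if cv >= cv_low:
        return "moderately_variant"
    return "invariant"


def categorize_compendium(
    per_dataset_cvs: Mapping[str, float],
    cv_low: float = CV_LOW,
    cv_high: float = CV_HIGH,
    min_high_datasets: int = MIN_HIGH_DATASETS,
    invariant_fraction: float = INVARIANT_FRACTION,
) -> str:
    """Compendium category from per-dataset CVs (absent datasets omitted
    from the mapping; the invariant fraction is over datasets where the gene
    is present)."""
    cvs = np.asarray([c for c in per_dataset_cvs.values() if np.isfinite(c)])
    if cvs.size == 0:
        return "lowly_expressed"
    if int((cvs >= cv_high).sum()) >= min_high_datasets:
        return "highly_variant"
    if (cvs < cv_low).mean() >= invariant_fraction:
        return "invariant"
    return "moderately_variant"


def compendium_cv_table(datasets) -> pd.DataFrame:
    """Per-gene, per-dataset CV on raw (unnormalized) expression values.

    Genes absent from a dataset, or with nonpositive mean there, get NaN.
    """
    cols = {}
    for ds in datasets:
        vals = ds.values
        mu = vals.mean(axis=1)
        sd = vals.std(axis=1, ddof=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            cv = sd / mu
        cv[mu <= 0] = np.nan
        cols[ds.dataset_id] = cv
    return pd.DataFrame(cols)
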
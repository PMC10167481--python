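"""Preranked gene-set enrichment for pathway self-enrichment and gene-centric
queries.

The engine is the weighted running-sum statistic: walking down a ranked gene
list, the sum rises by ``|score|^w`` (normalized over the set's members) at
each gene-set hit and falls by ``1/(N - N_hit)`` at each miss.  Only the
positive side is scored — functionally related metabolic genes are expected
to be positively correlated — so the enrichment score (ES) is the maximum of
the running sum, in [0, 1].  NES divides ES by the mean ES of random
gene-label sets of equal size; FDR comes from the pooled positive-side
permutation distribution.

A pathway is *self-enriched* ("coexpressed") when, ranking all metabolic
genes by their mean correlation to the pathway's members, the pathway itself
is enriched at the top with FDR <= 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

FDR_CUTOFF = 0.05
NES_CUTOFF = 2.0
DEFAULT_NPERM = 1000


@dataclass(frozen=True)
class PathwayAnnotation:
    """A pathway or category gene set (>= 2 genes)."""

    pathway_id: str
    gene_ids: frozenset[str]
    name: str = ""
    kind: str = "pathway"

    def __post_init__(self):
        if len(self.gene_ids) < 2:
            raise ValueError(
                f"pathway {self.pathway_id} needs >= 2 genes, has {len(self.gene_ids)}"
            )


@dataclass
class RankedList:
    """Gene ids with descending ranking scores; ties broken by score then
    lexicographic gene id for determinism."""

    genes: list[str]
    scores: np.ndarray

    @classmethod
    def from_scores(cls, scores: pd.Series) -> "RankedList":
        s = scores.dropna()
        order = sorted(s.index, key=lambda g: (-s[g], g))
        return cls(genes=order, scores=s.loc[order].to_numpy(dtype=float))


@dataclass
class EnrichmentResult:
    pathway_id: str
    es: float
    nes: float
    fdr: float
    leading_edge: list[str] = field(default_factory=list)
    n_perm: int = 0

    @property
    def coexpressed_call(self) -> bool:
        return bool(np.isfinite(self.fdr) and self.fdr <= FDR_CUTOFF)


def rank_genes_for_pathway(
    coexpr: pd.DataFrame, pathway: PathwayAnnotation, universe
) -> RankedList:
    """Rank universe genes by mean correlation to the pathway's members,
    excluding self-correlations; missing entries drop out of the mean."""
    universe = [g for g in universe if g in coexpr.index]
    members = sorted(pathway.gene_ids & set(universe))
    if len(members) < 2:
        raise ValueError(f"pathway {pathway.pathway_id} has < 2 genes in the universe")
    sub = coexpr.loc[universe, members].copy()
    for g in members:  # exclude self-correlation
        if g in sub.index:
            sub.loc[g, g] = np.nan
    scores = sub.mean(axis=1, skipna=True)
    return RankedList.from_scores(scores)


def _hit_mask(ranked: RankedList, gene_set) -> np.ndarray:
    members = set(gene_set)
    return np.fromiter((g in members for g in ranked.genes), dtype=bool)


def _es_from_mask(weights: np.ndarray, hits: np.ndarray) -> tuple[float, int]:
    """Positive-side ES and the running-sum peak position for one hit mask."""
    n = len(weights)
    n_hit = int(hits.sum())
    if n_hit == 0 or n_hit == n:
        raise ValueError("gene set must hit a strict subset of the ranked list")
    w = np.where(hits, weights, 0.0)
    total = w.sum()
    if total <= 0:  # degenerate all-zero scores: fall back to equal weights
        w = hits.astype(float)
        total = w.sum()
    steps = w / total - (~hits) / (n - n_hit)
    running = np.cumsum(steps)
    peak = int(np.argmax(running))
    return float(max(running[peak], 0.0)), peak


def _perm_es(
    weights: np.ndarray, n_hit: int, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Vectorized ES of ``n_perm`` random gene-label sets of size ``n_hit``."""
    n = len(weights)
    miss_step = 1.0 / (n - n_hit)
    out = np.empty(n_perm)
    for b in range(n_perm):
        idx = np.sort(rng.choice(n, size=n_hit, replace=False))
        w = weights[idx]
        tot = w.sum()
        if tot <= 0:
            w = np.ones(n_hit)
            tot = float(n_hit)
        cum_hit = np.cumsum(w) / tot
        # running sum evaluated at hit positions (where it peaks):
        # misses before hit k: idx[k] - k
        running = cum_hit - (idx - np.arange(n_hit)) * miss_step
        out[b] = max(float(running.max()), 0.0)
    return out


def _enrich_with_null(
    ranked: RankedList,
    gene_set,
    weight_exponent: float,
    n_perm: int,
    seed: int,
    pathway_id: str,
) -> tuple[EnrichmentResult, np.ndarray]:
    """One gene set against one ranked list, plus its permutation NES null."""
    hits = _hit_mask(ranked, gene_set)
    if not hits.any():
        raise ValueError("gene set does not intersect the ranked list")
    weights = np.abs(ranked.scores) ** weight_exponent
    es, peak = _es_from_mask(weights, hits)
    rng = np.random.default_rng(seed)
    perm = _perm_es(weights, int(hits.sum()), n_perm, rng)
    mean_perm = perm.mean()
    nes = es / mean_perm if mean_perm > 0 else float("nan")
    perm_nes = perm / mean_perm if mean_perm > 0 else np.full_like(perm, np.nan)
    fdr = float((perm_nes >= nes).mean()) if np.isfinite(nes) else float("nan")
    leading = [g for g, h in zip(ranked.genes[: peak + 1], hits[: peak + 1]) if h]
    result = EnrichmentResult(
        pathway_id=pathway_id, es=es, nes=float(nes), fdr=fdr,
        leading_edge=leading, n_perm=n_perm,
    )
    return result, perm_nes


def pooled_fdr(results: list[EnrichmentResult], nulls: list[np.ndarray]) -> None:
    """Positive-side pooled-permutation FDR, in place.

    For each observed NES*, FDR = (fraction of pooled permutation NES >=
    NES*) / (fraction of observed NES >= NES*), clipped at 1.
    """
    finite = [r for r in results if np.isfinite(r.nes)]
    if not finite:
        return
    pool = np.concatenate([p[np.isfinite(p)] for p in nulls])
    obs = np.array([r.nes for r in finite])
    for r in finite:
        p_perm = float((pool >= r.nes).mean())
        p_obs = float((obs >= r.nes).mean())
        r.fdr = min(p_perm / p_obs, 1.0) if p_obs > 0 else 1.0
    # q-value monotonization: a set is rejectable at any threshold below its
    # NES, so its q is the min FDR among sets with NES <= its own
    order = sorted(range(len(finite)), key=lambda i: finite[i].nes)
    cummin = np.inf
    for i in order:
        cummin = min(cummin, finite[i].fdr)
        finite[i].fdr = cummin


def preranked_enrichment(
    ranked: RankedList,
    gene_set,
    weight_exponent: float = 1.0,
    n_perm: int = DEFAULT_NPERM,
    seed: int = 0,
    pathway_id: str = "",
) -> EnrichmentResult:
    """Weighted preranked enrichment of one gene set against one ranked list.

    FDR for a single set equals the fraction of permutation NES >= observed
    NES (the pooled procedure with one observed set).
    """
    result, _ = _enrich_with_null(
        ranked, gene_set, weight_exponent, n_perm, seed, pathway_id
    )
    return result


def _self_es_null(
    coexpr: pd.DataFrame,
    universe: list[str],
    set_size: int,
    n_perm: int,
    rng: np.random.Generator,
    weight_exponent: float,
) -> np.ndarray:
    """Null self-enrichment ES of random gene sets, structure preserved.

    Each null set of ``set_size`` genes is pushed through the same pipeline
    as a real pathway — rank all universe genes by mean correlation to the
    set (self-correlations excluded), then score the set against its own
    ranked list — so the null captures the coupling between a set's mutual
    correlation and its ranking, which a fixed-list gene-label permutation
    misses.
    """
    sub = coexpr.loc[universe, universe].to_numpy(dtype=float)
    finite = np.isfinite(sub)
    vals = np.where(finite, sub, 0.0)
    n = len(universe)
    if set_size >= n:
        raise ValueError("set size must be smaller than the universe")
    miss_step = 1.0 / (n - set_size)
    out = np.empty(n_perm)
    for b in range(n_perm):
        members = rng.choice(n, size=set_size, replace=False)
        s = vals[:, members].sum(axis=1)
        cnt = finite[:, members].sum(axis=1).astype(float)
        # members exclude their self-correlation term
        s[members] -= np.where(finite[members, members], vals[members, members], 0.0)
        cnt[members] -= finite[members, members]
        with np.errstate(invalid="ignore", divide="ignore"):
            scores = s / cnt
        scores[cnt == 0] = -np.inf  # no information: bottom of the list
        order = np.argsort(-scores, kind="stable")
        ranked_scores = scores[order]
        hit_pos = np.sort(np.argsort(order)[members])
        w = np.abs(ranked_scores[hit_pos]) ** weight_exponent
        w[~np.isfinite(w)] = 0.0
        tot = w.sum()
        if tot <= 0:
            w = np.ones(set_size)
            tot = float(set_size)
        running = np.cumsum(w) / tot - (hit_pos - np.arange(set_size)) * miss_step
        out[b] = max(float(running.max()), 0.0)
    return out


def self_enrichment_screen(
    coexpr: pd.DataFrame,
    pathways: list[PathwayAnnotation],
    universe=None,
    weight_exponent: float = 1.0,
    n_perm: int = DEFAULT_NPERM,
    seed: int = 0,
) -> list[EnrichmentResult]:
    """Run the self-enrichment pipeline for every pathway.

    NES and FDR are calibrated against the structure-preserving null of
    :func:`_self_es_null` (size-matched random gene sets, re-ranked through
    the same pipeline), pooled across the screen's pathways.
    """
    if universe is None:
        universe = list(coexpr.index)
    universe = [g for g in universe if g in coexpr.index]
    results, nulls = [], []
    null_cache: dict[int, np.ndarray] = {}
    for i, pw in enumerate(sorted(pathways, key=lambda p: p.pathway_id)):
        ranked = rank_genes_for_pathway(coexpr, pw, universe)
        k = len(pw.gene_ids & set(ranked.genes))
        if len(ranked.genes) <= k:
            raise ValueError(
                f"pathway {pw.pathway_id} covers the whole ranked universe"
            )
        hits = _hit_mask(ranked, pw.gene_ids)
        weights = np.abs(ranked.scores) ** weight_exponent
        es, peak = _es_from_mask(weights, hits)
        if k not in null_cache:
            rng = np.random.default_rng(seed * 100003 + k)
            null_cache[k] = _self_es_null(
                coexpr, universe, k, n_perm, rng, weight_exponent
            )
        null_es = null_cache[k]
        mean_null = null_es.mean()
        nes = es / mean_null if mean_null > 0 else float("nan")
        null_nes = null_es / mean_null if mean_null > 0 else np.full(n_perm, np.nan)
        leading = [
            g for g, h in zip(ranked.genes[: peak + 1], hits[: peak + 1]) if h
        ]
        results.append(
            EnrichmentResult(
                pathway_id=pw.pathway_id, es=es, nes=float(nes),
                fdr=float("nan"), leading_edge=leading, n_perm=n_perm,
            )
        )
        nulls.append(null_nes)
    pooled_fdr(results, nulls)
    return results


def n_coexpressed(results: list[EnrichmentResult]) -> int:
    return sum(r.coexpressed_call for r in results)


def randomization_validation(
    coexpr: pd.DataFrame,
    pathways: list[PathwayAnnotation],
    n_rand: int = 1000,
    n_perm: int = DEFAULT_NPERM,
    seed: int = 0,
    universe=None,
) -> np.ndarray:
    """Null distribution of the number of self-enriched pathways.

    Each randomization permutes the gene labels of the universe and applies
    the same permutation to every pathway, preserving the correlation
    matrix, pathway sizes, and each gene's multiplicity across pathways.
    """
    if universe is None:
        universe = sorted(coexpr.index)
    rng = np.random.default_rng(seed)
    counts = np.empty(n_rand, dtype=int)
    for b in range(n_rand):
        perm = rng.permutation(universe)
        relabel = dict(zip(universe, perm))
        rand_pathways = [
            PathwayAnnotation(
                pathway_id=pw.pathway_id,
                gene_ids=frozenset(relabel[g] for g in pw.gene_ids if g in relabel),
                kind=pw.kind,
            )
            for pw in pathways
        ]
        results = self_enrichment_screen(
            coexpr, rand_pathways, universe=universe, n_perm=n_perm,
            seed=seed + 1000 + b,
        )
        counts[b] = n_coexpressed(results)
    return counts


def gene_query(
    gene_id: str,
    coexpr: pd.DataFrame,
    pathways: list[PathwayAnnotation],
    metabolic_genes=None,
    fdr_cutoff: float = FDR_CUTOFF,
    nes_cutoff: float = NES_CUTOFF,
    n_perm: int = DEFAULT_NPERM,
    seed: int = 0,
    cluster_membership: dict[str, dict[str, int]] | None = None,
) -> tuple[list[EnrichmentResult], dict[str, int] | None]:
    """Gene-centric query: rank metabolic genes by correlation to the query
    gene and test every pathway; FDR is pooled across pathways (one shared
    ranked list).  Returns passing results and, for model genes, the gene's
    stringent/relaxed cluster ids."""
    if gene_id not in coexpr.index:
        raise KeyError(f"gene {gene_id} absent from the coexpression matrix")
    if metabolic_genes is None:
        metabolic_genes = [g for g in coexpr.index if g != gene_id]
    scores = coexpr.loc[gene_id, [g for g in metabolic_genes if g != gene_id]]
    ranked = RankedList.from_scores(scores)
    results, nulls = [], []
    for i, pw in enumerate(sorted(pathways, key=lambda p: p.pathway_id)):
        inter = pw.gene_ids & set(ranked.genes)
        if not inter or len(inter) >= len(ranked.genes):
            continue
        res, perm_nes = _enrich_with_null(
            ranked, pw.gene_ids, 1.0, n_perm, seed + i, pw.pathway_id
        )
        results.append(res)
        nulls.append(perm_nes)
    pooled_fdr(results, nulls)
    passing = [
        r for r in results
        if np.isfinite(r.nes) and r.nes >= nes_cutoff and r.fdr <= fdr_cutoff
    ]
    clusters = cluster_membership.get(gene_id) if cluster_membership else None
    return passing, clusters


def results_table(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "pathway_id": [r.pathway_id for r in results],
            "es": [r.es for r in results],
            "nes": [r.nes for r in results],
            "fdr": [r.fdr for r in results],
            "coexpressed": [r.coexpressed_call for r in results],
            "leading_edge": [";".join(r.leading_edge) for r in results],
        }
    )


def read_gmt(path) -> list[PathwayAnnotation]:
    """Read pathway gene sets from a GMT file (id, description, genes...)."""
    out = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            out.append(
                PathwayAnnotation(
                    pathway_id=parts[0], name=parts[1],
                    gene_ids=frozenset(g for g in parts[2:] if g),
                )
            )
    return out


def write_gmt(pathways: list[PathwayAnnotation], path) -> None:
    with open(path, "w") as fh:
        for pw in sorted(pathways, key=lambda p: p.pathway_id):
            genes = "\t".join(sorted(pw.gene_ids))
            fh.write(f"{pw.pathway_id}\t{pw.name or pw.pathway_id}\t{genes}\n")
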
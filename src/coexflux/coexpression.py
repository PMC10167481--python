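"""Pairwise coexpression over the compendium and gene-pair class analysis.

Coexpression is the Pearson correlation of two genes over the compendium
conditions where both are observed (pairwise-complete); entries backed by
fewer than ``min_overlap`` shared conditions are left missing.

Gene pairs are classed by how they relate in the metabolic network:

* AND — obligate complex partners (co-occur in a minimal satisfying
  assignment of some reaction's GPR);
* OR — isozyme alternatives within a reaction, never jointly required;
* other_paralog — same paralog family, never sharing a reaction;
* operon — same operon, both metabolic;
* PW — same pathway but annotated to distinct reactions, excluding AND/OR;
* PO — PW minus operon pairs;
* random — a seeded sample of metabolic pairs in none of the above.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .enrichment import PathwayAnnotation
from .gpr import and_or_pairs
from .model import MetabolicModel
from .preprocess import Compendium

MIN_OVERLAP = 10

PAIR_CLASSES = ("AND", "OR", "other_paralog", "operon", "PW", "PO", "random")


@dataclass
class CoexpressionMatrix:
    """Symmetric gene x gene PCC matrix with its overlap-count companion."""

    values: pd.DataFrame
    n_overlap: pd.DataFrame

    @property
    def genes(self) -> pd.Index:
        return self.values.index


def pairwise_pcc(comp: Compendium, min_overlap: int = MIN_OVERLAP) -> CoexpressionMatrix:
    """Pairwise-complete Pearson correlation across all compendium columns."""
    df = comp.values
    corr = df.T.corr(min_periods=min_overlap)
    present = df.notna().to_numpy(dtype=float)
    overlap = present @ present.T
    n_overlap = pd.DataFrame(
        overlap.astype(int), index=df.index, columns=df.index
    )
    corr = corr.where(n_overlap >= min_overlap)
    return CoexpressionMatrix(values=corr, n_overlap=n_overlap)


def classify_gene_pairs(
    model: MetabolicModel,
    catalog: pd.DataFrame | None = None,
    pathways: list[PathwayAnnotation] | None = None,
    seed: int = 0,
    metabolic_genes=None,
) -> pd.DataFrame:
    """Tabulate gene-pair classes; one row per (pair, class) membership.

    ``catalog`` (optional) is a gene-indexed table with ``operon_id`` and
    ``paralog_family`` columns; ``pathways`` supplies same-pathway
    annotations for PW/PO.  The random class is a seeded sample of metabolic
    pairs in no named class, matched in size to the largest named class.
    """
    gene_rxns = model.gene_to_reactions()
    model_genes = sorted(gene_rxns)
    if metabolic_genes is None:
        metabolic_genes = model_genes

    and_pairs: set[frozenset[str]] = set()
    or_pairs: set[frozenset[str]] = set()
    for expr in model.gprs.values():
        a, o = and_or_pairs(expr)
        and_pairs |= a
        or_pairs |= o
    or_pairs -= and_pairs  # AND anywhere trumps OR ("never conjointly")

    def share_reaction(a: str, b: str) -> bool:
        return bool(set(gene_rxns.get(a, ())) & set(gene_rxns.get(b, ())))

    operon_pairs: set[frozenset[str]] = set()
    paralog_pairs: set[frozenset[str]] = set()
    if catalog is not None:
        metab = set(metabolic_genes)
        if "operon_id" in catalog.columns:
            for _, grp in catalog.dropna(subset=["operon_id"]).groupby("operon_id"):
                members = [g for g in grp.index if g in metab]
                operon_pairs |= {
                    frozenset([a, b])
                    for i, a in enumerate(members)
                    for b in members[i + 1 :]
                }
        if "paralog_family" in catalog.columns:
            for _, grp in catalog.dropna(subset=["paralog_family"]).groupby(
                "paralog_family"
            ):
                members = list(grp.index)
                for i, a in enumerate(members):
                    for b in members[i + 1 :]:
                        if not share_reaction(a, b):
                            paralog_pairs.add(frozenset([a, b]))

    pw_pairs: set[frozenset[str]] = set()
    if pathways:
        for pw in pathways:
            members = sorted(pw.gene_ids & set(gene_rxns))
            for i, a in enumerate(members):
                for b in members[i + 1 :]:
                    pair = frozenset([a, b])
                    if share_reaction(a, b) or pair in and_pairs or pair in or_pairs:
                        continue
                    pw_pairs.add(pair)
    po_pairs = pw_pairs - operon_pairs

    named = {
        "AND": and_pairs,
        "OR": or_pairs,
        "other_paralog": paralog_pairs,
        "operon": operon_pairs,
        "PW": pw_pairs,
        "PO": po_pairs,
    }
    used = set().union(*named.values()) if any(named.values()) else set()
    candidates = sorted(
        frozenset([a, b])
        for i, a in enumerate(metabolic_genes)
        for b in metabolic_genes[i + 1 :]
        if frozenset([a, b]) not in used
    )
    n_random = max((len(s) for s in named.values()), default=0) or min(
        len(candidates), 100
    )
    rng = np.random.default_rng(seed)
    take = min(n_random, len(candidates))
    idx = rng.choice(len(candidates), size=take, replace=False) if take else []
    named["random"] = {candidates[i] for i in idx}

    rows = []
    for cls in PAIR_CLASSES:
        for pair in sorted(named[cls], key=sorted):
            a, b = sorted(pair)
            rows.append((a, b, cls))
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "class"])


def _pair_values(pairs: pd.DataFrame, coexpr: pd.DataFrame) -> np.ndarray:
    vals = []
    genes = set(coexpr.index)
    for a, b in zip(pairs["gene_a"], pairs["gene_b"]):
        if a in genes and b in genes:
            v = coexpr.loc[a, b]
            if np.isfinite(v):
                vals.append(float(v))
    return np.array(vals)


def compare_pair_distributions(
    pair_table: pd.DataFrame, coexpr: pd.DataFrame
) -> pd.DataFrame:
    """Two-sided Mann-Whitney U of each class's coexpression vs random."""
    ref = _pair_values(pair_table[pair_table["class"] == "random"], coexpr)
    rows = []
    for cls in PAIR_CLASSES:
        if cls == "random":
            continue
        vals = _pair_values(pair_table[pair_table["class"] == cls], coexpr)
        if len(vals) < 2 or len(ref) < 2:
            rows.append((cls, len(vals), np.nan, np.nan, np.nan, True))
            continue
        stat, p = mannwhitneyu(vals, ref, alternative="two-sided")
        rows.append(
            (cls, len(vals), float(stat), float(p),
             float(np.median(vals) - np.median(ref)), False)
        )
    return pd.DataFrame(
        rows,
        columns=["class", "n_pairs", "u_statistic", "p_value",
                 "median_shift", "flagged"],
    )


def fraction_coexpressed_at_cutoffs(
    pair_table: pd.DataFrame, coexpr: pd.DataFrame, cutoffs
) -> pd.DataFrame:
    """Per class and cutoff c: fraction of pairs with PCC >= c."""
    cutoffs = list(cutoffs)
    if cutoffs != sorted(cutoffs):
        raise ValueError("cutoffs must be sorted ascending")
    rows = []
    for cls in PAIR_CLASSES:
        vals = _pair_values(pair_table[pair_table["class"] == cls], coexpr)
        for c in cutoffs:
            frac = float((vals >= c).mean()) if len(vals) else np.nan
            rows.append((cls, c, frac, len(vals)))
    return pd.DataFrame(rows, columns=["class", "cutoff", "fraction", "n_pairs"])
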
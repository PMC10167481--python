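"""Coflux: pairwise flux dependency between reactions and genes.

For each reaction pair (i, j), coflux measures the relative drop in the
maximal attainable flux of i when j is constrained to zero::

    c_ij,forward = (v_max,i - v_max,ij) / v_max,i

For reversible i the same quantity is computed on the reverse direction from
flux minima, c_ij,reverse = (v_min,i - v_min,ij) / v_min,i (both terms
negative, so the ratio is positive when the knockout shrinks the reverse
capacity), and the two directions combine as c_ij =
max(c_forward, |c_reverse|).  Because c_ij and c_ji need not agree, the
final value is symmetrized: c_ij,final = max(c_ij, c_ji).  Fully coupled
reactions (strictly linear pathways) get coflux 1, stoichiometrically
independent reactions get 0, junction-coupled reactions land in between.

When a knocked-out reaction has a designated redundant partner (a
near-identical reaction differing only in a cofactor, e.g. NAD vs NADP), the
partner is constrained to zero too, so flux cannot trivially bypass the
knockout through the twin reaction.

Gene-level coflux maps the reaction matrix through GPR associations: a gene
pair linked through several reaction pairs takes the maximum reaction
coflux; genes sharing a reaction get 1 (diagonal convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import MetabolicModel

ACTIVITY_TOL = 1e-6


class BlockedReactionsError(RuntimeError):
    def __init__(self, blocked: list[str]):
        super().__init__(f"reactions cannot carry flux: {blocked}")
        self.blocked = blocked


@dataclass
class CofluxComputation:
    reaction_ids: list[str]
    v_max: pd.Series
    v_min: pd.Series
    c_directed: pd.DataFrame  # c_ij after Eq-6 direction combination
    c_final: pd.DataFrame  # symmetric, in [0, 1]


# ----------------------------------------------------------------- FBA bits


def _flux_range(cmodel, rxn_id: str) -> tuple[float, float]:
    rxn = cmodel.reactions.get_by_id(rxn_id)
    cmodel.objective = rxn
    cmodel.objective_direction = "max"
    vmax = cmodel.slim_optimize(error_value=np.nan)
    cmodel.objective_direction = "min"
    vmin = cmodel.slim_optimize(error_value=np.nan)
    if not (np.isfinite(vmax) and np.isfinite(vmin)):
        raise RuntimeError(f"LP infeasible when optimizing {rxn_id}")
    return float(vmin), float(vmax)


def max_flux(
    model: MetabolicModel,
    reaction: str,
    direction: str = "forward",
    knockouts: frozenset[str] | set[str] = frozenset(),
) -> float:
    """Optimum flux of one reaction under steady state, bounds, and
    knockouts (reactions constrained to zero flux)."""
    cmodel = model.cobra_model
    with cmodel:
        for k in knockouts:
            cmodel.reactions.get_by_id(k).bounds = (0.0, 0.0)
        rxn = cmodel.reactions.get_by_id(reaction)
        cmodel.objective = rxn
        cmodel.objective_direction = "max" if direction == "forward" else "min"
        value = cmodel.slim_optimize(error_value=np.nan)
    if not np.isfinite(value):
        raise RuntimeError(f"LP infeasible for {reaction} with knockouts {sorted(knockouts)}")
    return float(value)


# ------------------------------------------------------------ diet amendment


def blocked_reactions(
    model: MetabolicModel, tol: float = ACTIVITY_TOL, subset=None
) -> list[str]:
    """Reactions unable to attain |flux| > tol under current bounds."""
    cmodel = model.cobra_model
    blocked = []
    with cmodel:
        for rid in subset if subset is not None else model.reaction_ids:
            vmin, vmax = _flux_range(cmodel, rid)
            if max(abs(vmin), abs(vmax)) <= tol:
                blocked.append(rid)
    return blocked


def amend_diet(
    model: MetabolicModel,
    uptake_bound: float = 10.0,
    activity_tol: float = ACTIVITY_TOL,
) -> tuple[MetabolicModel, list[str]]:
    """Open a minimal greedy set of closed uptake exchanges until every
    reaction can carry flux.

    Candidate uptakes are closed exchange reactions (lower bound >= 0);
    each greedy step opens the candidate unblocking the most reactions
    (ties: lexicographic id).  Raises :class:`BlockedReactionsError` naming
    the still-blocked reactions if opening everything does not suffice.
    """
    amended = model.copy()
    amended.apply_diet()
    cmodel = amended.cobra_model
    opened: list[str] = []
    blocked = blocked_reactions(amended, activity_tol)
    candidates = sorted(
        rid for rid in amended.reaction_ids
        if amended.is_exchange(rid)
        and cmodel.reactions.get_by_id(rid).lower_bound >= 0
    )
    while blocked and candidates:
        best, best_gain, best_remaining = None, -1, blocked
        for cand in candidates:
            rxn = cmodel.reactions.get_by_id(cand)
            old = rxn.bounds
            rxn.lower_bound = -uptake_bound
            # opening an uptake only relaxes the LP, so re-check the
            # currently blocked subset only
            remaining = blocked_reactions(amended, activity_tol, subset=blocked)
            rxn.bounds = old
            gain = len(blocked) - len(remaining)
            if gain > best_gain:
                best, best_gain, best_remaining = cand, gain, remaining
        if best is None or best_gain <= 0:
            break
        cmodel.reactions.get_by_id(best).lower_bound = -uptake_bound
        opened.append(best)
        candidates.remove(best)
        blocked = best_remaining
    if blocked:
        raise BlockedReactionsError(sorted(blocked))
    amended.diet = dict(model.diet)
    amended.diet.update({rid: (-uptake_bound, 0.0) for rid in opened})
    return amended, opened


# ------------------------------------------------------------------- coflux


def reaction_coflux(
    model: MetabolicModel,
    activity_tol: float = ACTIVITY_TOL,
    redundant_on: str = "j",
) -> CofluxComputation:
    """Pairwise reaction coflux on an amended (fully active) model.

    ``redundant_on`` selects which reaction's redundant partner is
    co-constrained during a knockout: ``"j"`` (default) zeroes the partner
    of the knocked-out reaction j; ``"i"`` zeroes the partner of the
    measured reaction i instead.
    """
    if redundant_on not in ("i", "j"):
        raise ValueError("redundant_on must be 'i' or 'j'")
    rids = model.reaction_ids
    n = len(rids)
    cmodel = model.cobra_model

    v_max = pd.Series(index=rids, dtype=float)
    v_min = pd.Series(index=rids, dtype=float)
    with cmodel:
        for rid in rids:
            v_min[rid], v_max[rid] = _flux_range(cmodel, rid)

    def ko_set(i: str, j: str) -> set[str]:
        kos = {j}
        if redundant_on == "j":
            partner = model.redundant_partner(j)
        else:
            partner = model.redundant_partner(i)
        if partner is not None and partner != i:
            kos.add(partner)
        return kos

    c = np.zeros((n, n))
    for a, i in enumerate(rids):
        fwd_ok = v_max[i] > activity_tol
        rev_ok = v_min[i] < -activity_tol
        if not (fwd_ok or rev_ok):
            raise BlockedReactionsError([i])
        for b, j in enumerate(rids):
            if i == j:
                continue
            kos = ko_set(i, j)
            if i in kos:
                kos = kos - {i}
                if not kos:
                    continue
            parts = []
            if fwd_ok:
                v_ij = max_flux(model, i, "forward", kos)
                parts.append((v_max[i] - v_ij) / v_max[i])
            if rev_ok:
                v_ij = max_flux(model, i, "reverse", kos)
                parts.append(abs((v_min[i] - v_ij) / v_min[i]))
            c[a, b] = float(np.clip(max(parts), 0.0, 1.0))

    c_directed = pd.DataFrame(c, index=rids, columns=rids)
    c_final = pd.DataFrame(np.maximum(c, c.T), index=rids, columns=rids)
    np.fill_diagonal(c_final.values, 1.0)
    return CofluxComputation(
        reaction_ids=rids, v_max=v_max, v_min=v_min,
        c_directed=c_directed, c_final=c_final,
    )


@dataclass
class CofluxMatrix:
    values: pd.DataFrame  # genes x genes symmetric in [0, 1]
    excluded_genes: list[str] = field(default_factory=list)

    @property
    def genes(self) -> pd.Index:
        return self.values.index


def gene_coflux(comp: CofluxComputation, model: MetabolicModel) -> CofluxMatrix:
    """Map reaction coflux to gene pairs: max over associated reaction
    pairs; the c_final diagonal (1) makes same-reaction gene pairs 1."""
    gene_rxns = model.gene_to_reactions()
    genes = sorted(gene_rxns)
    cf = comp.c_final
    out = np.ones((len(genes), len(genes)))
    for a, ga in enumerate(genes):
        for b in range(a + 1, len(genes)):
            gb = genes[b]
            val = max(
                cf.loc[ra, rb]
                for ra in gene_rxns[ga]
                for rb in gene_rxns[gb]
            )
            out[a, b] = out[b, a] = val
    return CofluxMatrix(
        values=pd.DataFrame(out, index=genes, columns=genes)
    )


def coflux_pipeline(
    model: MetabolicModel,
    uptake_bound: float = 10.0,
    activity_tol: float = ACTIVITY_TOL,
    redundant_on: str = "j",
) -> tuple[CofluxMatrix, CofluxComputation, list[str]]:
    """amend_diet -> reaction_coflux -> gene_coflux in one call."""
    amended, opened = amend_diet(
        model, uptake_bound=uptake_bound, activity_tol=activity_tol
    )
    comp = reaction_coflux(
        amended, activity_tol=activity_tol, redundant_on=redundant_on
    )
    return gene_coflux(comp, amended), comp, opened
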
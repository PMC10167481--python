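"""Independent brute-force oracle for the coflux computation.

Reads only the stoichiometry, bounds and GPR gene lists out of a model and
re-derives gene coflux from first principles with scipy.optimize.linprog —
one LP per flux optimum, the directed ratios, the direction combination, the
symmetrization, and the gene mapping each spelled out separately.  Shares no
code with the package implementation.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linprog


def _extract(model):
    cmodel = model.cobra_model
    mets = [m.id for m in cmodel.metabolites]
    rxns = [r.id for r in cmodel.reactions]
    met_idx = {m: i for i, m in enumerate(mets)}
    S = np.zeros((len(mets), len(rxns)))
    bounds = []
    for j, r in enumerate(cmodel.reactions):
        for m, coef in r.metabolites.items():
            S[met_idx[m.id], j] = coef
        bounds.append((r.lower_bound, r.upper_bound))
    return S, rxns, bounds


def _optimum(S, bounds, j, maximize):
    c = np.zeros(S.shape[1])
    c[j] = -1.0 if maximize else 1.0
    res = linprog(
        c, A_eq=S, b_eq=np.zeros(S.shape[0]), bounds=bounds, method="highs"
    )
    if res.status != 0:
        raise RuntimeError(f"oracle LP failed with status {res.status}")
    return -res.fun if maximize else res.fun


def brute_force_gene_coflux(model, redundant_on="j", tol=1e-6):
    """Gene coflux matrix recomputed from scratch; returns (genes, matrix)."""
    S, rxns, bounds = _extract(model)
    idx = {r: i for i, r in enumerate(rxns)}
    n = len(rxns)

    partner = {}
    for pair in model.redundant_pairs:
        a, b = sorted(pair)
        partner[a], partner[b] = b, a

    vmax = np.array([_optimum(S, bounds, j, True) for j in range(n)])
    vmin = np.array([_optimum(S, bounds, j, False) for j in range(n)])

    def ko_bounds(kos):
        out = list(bounds)
        for k in kos:
            out[idx[k]] = (0.0, 0.0)
        return out

    directed = np.zeros((n, n))
    for i, ri in enumerate(rxns):
        for j, rj in enumerate(rxns):
            if i == j:
                continue
            kos = {rj}
            p = partner.get(rj) if redundant_on == "j" else partner.get(ri)
            if p is not None and p != ri:
                kos.add(p)
            kos.discard(ri)
            vals = []
            if vmax[i] > tol:  # forward direction ratio
                v_ij = _optimum(S, ko_bounds(kos), i, True)
                vals.append((vmax[i] - v_ij) / vmax[i])
            if vmin[i] < -tol:  # reverse direction ratio
                v_ij = _optimum(S, ko_bounds(kos), i, False)
                vals.append(abs((vmin[i] - v_ij) / vmin[i]))
            if vals:
                directed[i, j] = min(max(max(vals), 0.0), 1.0)

    final = np.maximum(directed, directed.T)
    np.fill_diagonal(final, 1.0)

    gene_rxns = {}
    for rid, expr in model.gprs.items():
        for g in expr.genes():
            gene_rxns.setdefault(g, set()).add(rid)
    genes = sorted(gene_rxns)
    gm = np.ones((len(genes), len(genes)))
    for a, ga in enumerate(genes):
        for b, gb in enumerate(genes):
            if a >= b:
                continue
            best = 0.0
            for ra in gene_rxns[ga]:
                for rb in gene_rxns[gb]:
                    best = max(best, final[idx[ra], idx[rb]])
            gm[a, b] = gm[b, a] = best
    return genes, gm
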
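"""Constraint-based metabolic model container and I/O.

Wraps a :class:`cobra.Model` together with the pieces the coflux algorithm
needs beyond plain stoichiometry: parsed GPR expressions, the list of
redundant reaction pairs (near-identical reactions differing only in a
cofactor, e.g. NAD vs NADP), and diet overrides on exchange bounds.

Two serializations are supported: SBML Level 3 (via cobrapy/libsbml) and a
small JSON dialect::

    {"metabolites": [{"id": ..., "compartment": ...}],
     "reactions":   [{"id": ..., "stoich": {met: coef}, "lb": ..., "ub": ...,
                      "gpr": "gA & (gB | gC)"}],
     "redundant_pairs": [["R1", "R2"]],
     "diet": {"EX_a": [-10, 0]}}
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import cobra

from .gpr import GPRExpression, parse_gpr


@dataclass
class MetabolicModel:
    cobra_model: cobra.Model
    gprs: dict[str, GPRExpression] = field(default_factory=dict)
    redundant_pairs: list[frozenset[str]] = field(default_factory=list)
    diet: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self):
        rxn_ids = {r.id for r in self.cobra_model.reactions}
        for pair in self.redundant_pairs:
            missing = set(pair) - rxn_ids
            if missing:
                raise ValueError(f"redundant pair member(s) not in model: {sorted(missing)}")

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.cobra_model.reactions]

    def is_exchange(self, rxn_id: str) -> bool:
        """A boundary reaction: exactly one metabolite."""
        return len(self.cobra_model.reactions.get_by_id(rxn_id).metabolites) == 1

    def is_reversible(self, rxn_id: str) -> bool:
        """Reversibility read from bounds: lb < 0 < ub."""
        r = self.cobra_model.reactions.get_by_id(rxn_id)
        return r.lower_bound < 0 < r.upper_bound

    def gene_to_reactions(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for rid, expr in self.gprs.items():
            for g in expr.genes():
                out.setdefault(g, []).append(rid)
        return {g: sorted(rs) for g, rs in sorted(out.items())}

    def redundant_partner(self, rxn_id: str) -> str | None:
        for pair in self.redundant_pairs:
            if rxn_id in pair:
                (other,) = set(pair) - {rxn_id}
                return other
        return None

    def apply_diet(self) -> None:
        """Apply exchange-bound overrides in-place."""
        for rid, (lb, ub) in self.diet.items():
            self.cobra_model.reactions.get_by_id(rid).bounds = (lb, ub)

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            cobra_model=self.cobra_model.copy(),
            gprs=dict(self.gprs),
            redundant_pairs=list(self.redundant_pairs),
            diet=dict(self.diet),
        )

    # ------------------------------------------------------------------ I/O

    def to_json(self, path: str | Path) -> None:
        doc = {
            "metabolites": [
                {"id": m.id, "compartment": m.compartment or "c"}
                for m in self.cobra_model.metabolites
            ],
            "reactions": [
                {
                    "id": r.id,
                    "stoich": {m.id: coef for m, coef in r.metabolites.items()},
                    "lb": r.lower_bound,
                    "ub": r.upper_bound,
                    "gpr": self.gprs[r.id].serialize() if r.id in self.gprs else "",
                }
                for r in self.cobra_model.reactions
            ],
            "redundant_pairs": [sorted(p) for p in self.redundant_pairs],
            "diet": {k: list(v) for k, v in self.diet.items()},
        }
        Path(path).write_text(json.dumps(doc, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "MetabolicModel":
        doc = json.loads(Path(path).read_text())
        m = cobra.Model(Path(path).stem)
        mets = {
            d["id"]: cobra.Metabolite(d["id"], compartment=d.get("compartment", "c"))
            for d in doc["metabolites"]
        }
        m.add_metabolites(list(mets.values()))
        gprs: dict[str, GPRExpression] = {}
        rxns = []
        for d in doc["reactions"]:
            r = cobra.Reaction(d["id"], lower_bound=d["lb"], upper_bound=d["ub"])
            rxns.append(r)
        m.add_reactions(rxns)
        for d in doc["reactions"]:
            m.reactions.get_by_id(d["id"]).add_metabolites(
                {mets[k]: v for k, v in d["stoich"].items()}
            )
            if d.get("gpr"):
                gprs[d["id"]] = parse_gpr(d["gpr"])
        return cls(
            cobra_model=m,
            gprs=gprs,
            redundant_pairs=[frozenset(p) for p in doc.get("redundant_pairs", [])],
            diet={k: tuple(v) for k, v in doc.get("diet", {}).items()},
        )

    def to_sbml(self, path: str | Path) -> None:
        m = self.cobra_model.copy()
        for rid, expr in self.gprs.items():
            m.reactions.get_by_id(rid).gene_reaction_rule = (
                expr.serialize().replace("&", "and").replace("|", "or")
            )
        cobra.io.write_sbml_model(m, str(path))

    @classmethod
    def from_sbml(cls, path: str | Path) -> "MetabolicModel":
        m = cobra.io.read_sbml_model(str(path))
        gprs = {
            r.id: parse_gpr(r.gene_reaction_rule)
            for r in m.reactions
            if r.gene_reaction_rule.strip()
        }
        return cls(cobra_model=m, gprs=gprs)
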
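"""Coflux: diet amendment, flux optima, the pairwise dependency metric, and
the GPR mapping — checked against an independent brute-force LP oracle."""

import cobra
import numpy as np
import pytest

import coexflux as cx
from coexflux.coflux import (
    BlockedReactionsError,
    amend_diet,
    blocked_reactions,
    gene_coflux,
    max_flux,
    reaction_coflux,
)
from coexflux.gpr import parse_gpr
from coexflux.model import MetabolicModel
from oracle_coflux import brute_force_gene_coflux

ALL_TOPOLOGIES = [
    ("linear_chain", {}),
    ("branch", {"n_internal_reactions": 3}),
    ("parallel_independent", {}),
    ("complex_gpr", {}),
    ("redundant_pair", {}),
]


def toy(topology, **kw):
    return cx.make_toy_model(cx.ToyModelSpec(topology=topology, **kw))


class TestAmendDiet:
    def test_closed_uptake_opened(self):
        model = toy("linear_chain", open_exchanges=False)
        assert blocked_reactions(model) != []
        amended, opened = amend_diet(model)
        assert opened == ["EX_up"]
        assert blocked_reactions(amended) == []

    def test_orphan_reaction_reported(self):
        model = toy("linear_chain")
        m = model.cobra_model
        orphan_met = cobra.Metabolite("X_never", compartment="c")
        orphan = cobra.Reaction("R_orphan", lower_bound=0, upper_bound=1000)
        m.add_reactions([orphan])
        orphan.add_metabolites({m.metabolites.M0: 0.0, orphan_met: -1.0})
        with pytest.raises(BlockedReactionsError) as exc:
            amend_diet(model)
        assert "R_orphan" in exc.value.blocked

    def test_parallel_chains_need_every_uptake(self):
        """With all uptakes closed, amendment opens exactly one uptake per
        disconnected chain (verified necessary by brute force on the toy)."""
        model = toy("parallel_independent", n_chains=3, open_exchanges=False)
        amended, opened = amend_diet(model)
        assert sorted(opened) == ["c1EX_up", "c2EX_up", "c3EX_up"]
        # brute force: any proper subset leaves that chain blocked
        for leave_out in opened:
            trial = toy("parallel_independent", n_chains=3, open_exchanges=False)
            for rid in opened:
                if rid != leave_out:
                    trial.cobra_model.reactions.get_by_id(rid).lower_bound = -10
            assert blocked_reactions(trial) != []


class TestMaxFlux:
    def test_linear_chain_bounded_by_uptake(self):
        model = toy("linear_chain", uptake_bound=10)
        for rid in ("R1", "R2", "EX_sec"):
            assert max_flux(model, rid) == pytest.approx(10.0)

    def test_upstream_knockout_zeroes_downstream(self):
        model = toy("linear_chain")
        assert max_flux(model, "R2", knockouts={"R1"}) == pytest.approx(0.0)

    def test_self_knockout_is_zero(self):
        model = toy("linear_chain")
        assert max_flux(model, "R1", knockouts={"R1"}) == pytest.approx(0.0)


class TestReactionCoflux:
    def test_linear_pathway_fully_coupled(self):
        comp = reaction_coflux(toy("linear_chain"))
        assert comp.c_final.loc["R1", "R2"] == pytest.approx(1.0, abs=1e-9)

    def test_disconnected_chains_uncoupled(self):
        comp = reaction_coflux(toy("parallel_independent"))
        assert comp.c_final.loc["c1R1", "c2R1"] == pytest.approx(0.0, abs=1e-9)

    def test_branch_values_against_oracle(self):
        """Trunk-vs-branch coupling is asymmetric before symmetrization:
        killing the trunk zeroes a branch (c=1); killing one branch leaves
        the other branch's maximum unchanged (c=0)."""
        model = toy("branch", n_internal_reactions=3)
        comp = reaction_coflux(model)
        # two branches from the junction are mutually independent at max flux
        assert comp.c_directed.loc["RB1", "RB2"] == pytest.approx(0.0, abs=1e-9)
        # each branch fully depends on the trunk
        assert comp.c_final.loc["R1", "RB1"] == pytest.approx(1.0, abs=1e-9)

    def test_redundant_partner_constrained_with_knockout(self):
        """Knocking out one reaction of a redundant pair also zeroes its
        twin, so the downstream flux collapses; without the rule the twin
        would silently carry the flux."""
        model = toy("redundant_pair")
        comp = reaction_coflux(model)
        assert comp.c_directed.loc["EX_sec", "R_nad"] == pytest.approx(1.0, abs=1e-9)
        no_rule = MetabolicModel(
            cobra_model=model.cobra_model, gprs=model.gprs, redundant_pairs=[]
        )
        comp2 = reaction_coflux(no_rule)
        assert comp2.c_directed.loc["EX_sec", "R_nad"] == pytest.approx(0.0, abs=1e-9)

    def test_redundant_on_i_variant(self):
        """Under the alternative reading, the partner of the MEASURED
        reaction is co-constrained, so secretion sees the bypass survive."""
        model = toy("redundant_pair")
        comp = reaction_coflux(model, redundant_on="i")
        # i = EX_sec has no partner: knocking out R_nad alone lets flux
        # reroute through R_nadp
        assert comp.c_directed.loc["EX_sec", "R_nad"] == pytest.approx(0.0, abs=1e-9)
        # the twins remain independent: zeroing one leaves the other's
        # maximum intact
        assert comp.c_directed.loc["R_nad", "R_nadp"] == pytest.approx(0.0, abs=1e-9)

    def test_symmetry_range_and_determinism(self):
        model = toy("branch", n_internal_reactions=3)
        a = reaction_coflux(model).c_final
        b = reaction_coflux(model).c_final
        vals = a.to_numpy()
        np.testing.assert_allclose(vals, vals.T, atol=0)
        assert vals.min() >= 0.0 and vals.max() <= 1.0
        np.testing.assert_allclose(vals, b.to_numpy(), atol=1e-9)

    def test_bypass_never_increases_coupling(self):
        """Adding a bypass route between two coupled reactions can only
        lower their coflux."""
        base = toy("linear_chain", n_internal_reactions=2)
        coupled = reaction_coflux(base).c_final.loc["R1", "R2"]
        bypass = toy("linear_chain", n_internal_reactions=2)
        m = bypass.cobra_model
        alt = cobra.Reaction("R_alt", lower_bound=0, upper_bound=1000)
        m.add_reactions([alt])
        alt.add_metabolites({m.metabolites.M0: -1, m.metabolites.M1: 1})
        with_bypass = reaction_coflux(bypass).c_final.loc["R1", "R2"]
        assert with_bypass <= coupled + 1e-9


class TestGeneCoflux:
    def test_consecutive_genes_fully_coupled(self):
        model = toy("linear_chain")
        comp = reaction_coflux(model)
        gm = gene_coflux(comp, model)
        assert gm.values.loc["g1", "g2"] == pytest.approx(1.0, abs=1e-9)

    def test_disconnected_genes_uncoupled(self):
        model = toy("parallel_independent")
        comp = reaction_coflux(model)
        gm = gene_coflux(comp, model)
        assert gm.values.loc["gc11", "gc21"] == pytest.approx(0.0, abs=1e-9)

    def test_max_rule_over_multiple_reactions(self):
        """A gene catalyzing two reactions takes the best coupling of
        either toward its partner."""
        model = toy("branch", n_internal_reactions=3)
        # give branch gene gb1 a second (trunk) reaction
        model.gprs["R1"] = parse_gpr("g1 | gb1")
        comp = reaction_coflux(model)
        gm = gene_coflux(comp, model)
        # gb2's branch is independent of RB1 but fully coupled to R1
        assert gm.values.loc["gb1", "gb2"] == pytest.approx(1.0, abs=1e-9)

    def test_same_reaction_genes_get_one(self):
        model = toy("linear_chain", genes_per_reaction="and-complex")
        comp = reaction_coflux(model)
        gm = gene_coflux(comp, model)
        assert gm.values.loc["g1a", "g1b"] == 1.0


class TestOracleEquivalence:
    @pytest.mark.parametrize("topology, kw", ALL_TOPOLOGIES)
    def test_matches_brute_force_lp(self, topology, kw):
        """Gene coflux equals an independently coded LP-by-LP oracle to
        1e-6 on every toy topology (all <= 8 reactions)."""
        model = toy(topology, **kw)
        amended, _ = amend_diet(model)
        comp = reaction_coflux(amended)
        mine = gene_coflux(comp, amended)
        genes, oracle = brute_force_gene_coflux(amended)
        assert list(mine.values.index) == genes
        np.testing.assert_allclose(
            mine.values.to_numpy(), oracle, atol=1e-6
        )


class TestModelIO:
    def test_json_roundtrip_preserves_coflux(self, tmp_path):
        model = toy("redundant_pair")
        path = tmp_path / "m.json"
        model.to_json(path)
        back = MetabolicModel.from_json(path)
        assert back.redundant_pairs == model.redundant_pairs
        a = gene_coflux(reaction_coflux(model), model).values
        b = gene_coflux(reaction_coflux(back), back).values
        np.testing.assert_allclose(a.to_numpy(), b.to_numpy(), atol=1e-9)

    def test_sbml_roundtrip(self, tmp_path):
        model = toy("complex_gpr")
        path = tmp_path / "m.xml"
        model.to_sbml(path)
        back = MetabolicModel.from_sbml(path)
        assert back.gprs["R1"].genes() == model.gprs["R1"].genes()
        assert len(back.reaction_ids) == len(model.reaction_ids)

    def test_reversibility_read_from_bounds(self):
        model = toy("linear_chain")
        assert model.is_reversible("EX_up") is False  # (-10, 0): one-way uptake
        model.cobra_model.reactions.R1.bounds = (-5, 5)
        assert model.is_reversible("R1")
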
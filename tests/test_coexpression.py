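"""Pairwise coexpression over the compendium and gene-pair class analysis."""

import numpy as np
import pandas as pd
import pytest

import coexflux as cx
from coexflux.coexpression import (
    classify_gene_pairs,
    compare_pair_distributions,
    fraction_coexpressed_at_cutoffs,
)
from coexflux.preprocess import Compendium
from coexflux.synthetic import expected_module_pcc


def toy_compendium(values, genes=None):
    df = pd.DataFrame(
        np.asarray(values, dtype=float),
        index=genes or [f"g{i}" for i in range(len(values))],
    )
    df.columns = [f"c{j}" for j in range(df.shape[1])]
    return Compendium(values=df, dataset_spans={"d": (0, df.shape[1])})


class TestPairwisePCC:
    def test_self_and_anticorrelation(self):
        x = np.arange(12, dtype=float)
        comp = toy_compendium([x, -x, x * 2])
        m = cx.pairwise_pcc(comp, min_overlap=10)
        assert m.values.loc["g0", "g0"] == pytest.approx(1.0)
        assert m.values.loc["g0", "g1"] == pytest.approx(-1.0)
        assert m.values.loc["g0", "g2"] == pytest.approx(1.0)

    def test_min_overlap_masks_sparse_pairs(self):
        x = np.arange(12, dtype=float)
        a = x.copy()
        b = x.copy()
        b[:5] = np.nan  # overlap of 7 < 10
        comp = toy_compendium([a, b])
        m = cx.pairwise_pcc(comp, min_overlap=10)
        assert np.isnan(m.values.loc["g0", "g1"])
        assert m.n_overlap.loc["g0", "g1"] == 7

    def test_planted_module_matches_closed_form(self, planted_run):
        """Across the active datasets, module-gene PCC approaches
        loading^2/(loading^2+noise^2)."""
        gt = planted_run["ground_truth"]
        datasets = {d.dataset_id: d for d in planted_run["datasets"]}
        members = sorted(gt.module_members["module0"])[:2]
        active = sorted(gt.active_datasets["module0"])
        a = np.concatenate(
            [datasets[d].values.loc[members[0]].to_numpy() for d in active]
        )
        b = np.concatenate(
            [datasets[d].values.loc[members[1]].to_numpy() for d in active]
        )
        pcc = np.corrcoef(a, b)[0, 1]
        assert abs(pcc - expected_module_pcc(0.9, 0.1)) < 0.05

    def test_symmetry_and_range(self, planted_run):
        vals = planted_run["coexpression"].values.to_numpy()
        np.testing.assert_allclose(vals, vals.T, atol=1e-12)
        finite = vals[np.isfinite(vals)]
        assert finite.min() >= -1 - 1e-12 and finite.max() <= 1 + 1e-12


@pytest.fixture()
def pair_model():
    """Two reactions: R1 with the isozyme/complex GPR, R2 single-gene."""
    import cobra

    from coexflux.gpr import parse_gpr
    from coexflux.model import MetabolicModel

    m = cobra.Model("pairs")
    mets = {k: cobra.Metabolite(k, compartment="c") for k in ("A", "B", "C")}
    m.add_metabolites(list(mets.values()))
    rxns = []
    for rid in ("EX_A", "R1", "R2", "EX_C"):
        rxns.append(cobra.Reaction(rid, lower_bound=0, upper_bound=1000))
    m.add_reactions(rxns)
    m.reactions.EX_A.add_metabolites({mets["A"]: -1})
    m.reactions.EX_A.bounds = (-10, 0)
    m.reactions.R1.add_metabolites({mets["A"]: -1, mets["B"]: 1})
    m.reactions.R2.add_metabolites({mets["B"]: -1, mets["C"]: 1})
    m.reactions.EX_C.add_metabolites({mets["C"]: -1})
    return MetabolicModel(
        cobra_model=m,
        gprs={"R1": parse_gpr("(gA | gB) & gC"), "R2": parse_gpr("gY")},
    )


class TestClassifyGenePairs:
    def test_gpr_and_or_extraction(self, pair_model):
        table = classify_gene_pairs(pair_model, seed=0)
        and_pairs = {
            frozenset([a, b])
            for a, b in table[table["class"] == "AND"][["gene_a", "gene_b"]].values
        }
        or_pairs = {
            frozenset([a, b])
            for a, b in table[table["class"] == "OR"][["gene_a", "gene_b"]].values
        }
        assert and_pairs == {frozenset({"gA", "gC"}), frozenset({"gB", "gC"})}
        assert or_pairs == {frozenset({"gA", "gB"})}

    def test_other_paralogs_require_separate_reactions(self, pair_model):
        catalog = pd.DataFrame(
            {"paralog_family": ["f1", "f1", "f1", None]},
            index=["gA", "gY", "gB", "gC"],
        )
        table = classify_gene_pairs(pair_model, catalog=catalog, seed=0)
        para = {
            frozenset([a, b])
            for a, b in table[table["class"] == "other_paralog"][
                ["gene_a", "gene_b"]
            ].values
        }
        # gA/gB share R1, so only the cross-reaction pairs qualify
        assert para == {frozenset({"gA", "gY"}), frozenset({"gB", "gY"})}

    def test_pw_and_po_composition(self, pair_model):
        pathways = [
            cx.PathwayAnnotation(
                pathway_id="pw1", gene_ids=frozenset({"gA", "gB", "gC", "gY"})
            )
        ]
        catalog = pd.DataFrame(
            {"operon_id": ["op1", None, None, "op1"]},
            index=["gA", "gB", "gC", "gY"],
        )
        table = classify_gene_pairs(
            pair_model, catalog=catalog, pathways=pathways, seed=0
        )
        pw = {
            frozenset([a, b])
            for a, b in table[table["class"] == "PW"][["gene_a", "gene_b"]].values
        }
        po = {
            frozenset([a, b])
            for a, b in table[table["class"] == "PO"][["gene_a", "gene_b"]].values
        }
        # same pathway, distinct reactions, AND/OR excluded
        assert pw == {
            frozenset({"gA", "gY"}),
            frozenset({"gB", "gY"}),
            frozenset({"gC", "gY"}),
        }
        # gA-gY are in one operon, so PO drops that pair
        assert po == pw - {frozenset({"gA", "gY"})}

    def test_named_classes_seed_independent(self, pair_model):
        t1 = classify_gene_pairs(pair_model, seed=1)
        t2 = classify_gene_pairs(pair_model, seed=2)
        for cls in ("AND", "OR"):
            a = t1[t1["class"] == cls].reset_index(drop=True)
            b = t2[t2["class"] == cls].reset_index(drop=True)
            pd.testing.assert_frame_equal(a, b)


class TestCompareDistributions:
    def _null_table(self, rng, n=40):
        genes = [f"g{i}" for i in range(30)]
        vals = rng.normal(size=(30, 60))
        coexpr = pd.DataFrame(np.corrcoef(vals), index=genes, columns=genes)
        pairs = [(genes[i], genes[j]) for i in range(30) for j in range(i + 1, 30)]
        idx = rng.choice(len(pairs), size=2 * n, replace=False)
        rows = [(pairs[i][0], pairs[i][1], "AND") for i in idx[:n]]
        rows += [(pairs[i][0], pairs[i][1], "random") for i in idx[n:]]
        return pd.DataFrame(rows, columns=["gene_a", "gene_b", "class"]), coexpr

    def test_null_pvalues_center_at_half(self):
        """Relabeled random pairs vs random: median MWU p over 100 seeded
        replicates is near 0.5."""
        pvals = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            table, coexpr = self._null_table(rng)
            out = compare_pair_distributions(table, coexpr)
            pvals.append(float(out.set_index("class").loc["AND", "p_value"]))
        assert 0.3 < np.median(pvals) < 0.7

    def test_planted_class_detected(self, planted_run):
        gt = planted_run["ground_truth"]
        coexpr = planted_run["coexpression"].values
        members = sorted(gt.module_members["module0"])
        rows = [
            (members[i], members[j], "AND")
            for i in range(len(members))
            for j in range(i + 1, len(members))
        ]
        background = [g for g in coexpr.index if g >= "g0040"][:30]
        rng = np.random.default_rng(0)
        for _ in range(30):
            a, b = rng.choice(background, 2, replace=False)
            rows.append((a, b, "random"))
        table = pd.DataFrame(rows, columns=["gene_a", "gene_b", "class"])
        out = compare_pair_distributions(table, coexpr).set_index("class")
        assert out.loc["AND", "p_value"] < 0.01
        assert out.loc["AND", "median_shift"] > 0

    def test_single_pair_class_flagged(self):
        genes = ["a", "b", "c", "d"]
        coexpr = pd.DataFrame(np.eye(4), index=genes, columns=genes)
        table = pd.DataFrame(
            [("a", "b", "AND"), ("a", "c", "random"), ("b", "d", "random")],
            columns=["gene_a", "gene_b", "class"],
        )
        out = compare_pair_distributions(table, coexpr).set_index("class")
        assert bool(out.loc["AND", "flagged"])


class TestFractionCurves:
    def test_bounds_and_monotonicity(self, planted_run):
        gt = planted_run["ground_truth"]
        coexpr = planted_run["coexpression"].values
        members = sorted(gt.module_members["module1"])
        rows = [
            (members[i], members[j], "AND")
            for i in range(len(members))
            for j in range(i + 1, len(members))
        ]
        table = pd.DataFrame(rows, columns=["gene_a", "gene_b", "class"])
        cutoffs = [-1.0, -0.5, 0.0, 0.5, 1.01]
        curves = fraction_coexpressed_at_cutoffs(table, coexpr, cutoffs)
        sub = curves[curves["class"] == "AND"].sort_values("cutoff")
        fracs = sub["fraction"].to_numpy()
        assert fracs[0] == 1.0  # cutoff -1 catches every finite pair
        assert fracs[-1] == 0.0  # cutoff > 1 catches none
        assert np.all(np.diff(fracs) <= 1e-12)

    def test_unsorted_cutoffs_rejected(self):
        with pytest.raises(ValueError, match="sorted"):
            fraction_coexpressed_at_cutoffs(
                pd.DataFrame(columns=["gene_a", "gene_b", "class"]),
                pd.DataFrame(),
                [0.5, 0.0],
            )
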
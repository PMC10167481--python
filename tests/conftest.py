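import numpy as np
import pytest

import coexflux as cx
from coexflux.preprocess import assemble_compendium
from coexflux.synthetic import planted_compendium_params


@pytest.fixture(scope="session")
def planted_run():
    """One planted compendium (seed 0) with its coexpression matrix."""
    params = planted_compendium_params(seed=0)
    datasets, gt = cx.simulate_compendium(params)
    comp, manifest = assemble_compendium(datasets)
    coexpr = cx.pairwise_pcc(comp)
    return {
        "params": params,
        "datasets": datasets,
        "ground_truth": gt,
        "compendium": comp,
        "manifest": manifest,
        "coexpression": coexpr,
    }


@pytest.fixture(scope="session")
def linear_chain_model():
    return cx.make_toy_model(
        cx.ToyModelSpec(topology="linear_chain", n_internal_reactions=2)
    )


def background_pathways(coexpr, ground_truth, n_sets, size, seed):
    """Random gene sets drawn from genes outside every planted module."""
    module_genes = set().union(*ground_truth.module_members.values())
    pool = [g for g in coexpr.values.index if g not in module_genes]
    rng = np.random.default_rng(seed)
    return [
        cx.PathwayAnnotation(
            pathway_id=f"random{i}",
            gene_ids=frozenset(rng.choice(pool, size=size, replace=False)),
        )
        for i in range(n_sets)
    ]
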
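"""Synthetic benchmark data with known ground truth.

Generates (i) toy constraint-based metabolic models covering the topologies
the coflux metric distinguishes (linear chains, branches, disconnected
pathways, complex GPRs, cofactor-redundant reaction pairs) and (ii) simulated
expression data emulating the statistical structure of the real inputs: a
developmental time course with a flat-profile reference cluster and a bimodal
log2 expression distribution, a tissue matrix with one-hot tissue-specific
genes, and a multi-dataset compendium with planted latent-factor coexpression
modules, per-dataset activation, missing genes, and batch-contaminated
datasets.

All randomness flows through one ``numpy.random.default_rng(seed)`` per call;
identical seeds give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import cobra
import numpy as np
import pandas as pd

from .gpr import parse_gpr
from .model import MetabolicModel
from .preprocess import DevTimeCourse, ExpressionDataset, TissueMatrix, label_tissue_levels

TOPOLOGIES = (
    "linear_chain",
    "branch",
    "parallel_independent",
    "complex_gpr",
    "redundant_pair",
)

GPR_PATTERNS = ("single", "and-complex", "or-isozymes", "nested")


class UnsupportedTopologyError(ValueError):
    pass


@dataclass(frozen=True)
class ToyModelSpec:
    topology: str = "linear_chain"
    n_internal_reactions: int = 2
    genes_per_reaction: str = "single"
    n_chains: int = 2  # parallel_independent only
    uptake_bound: float = 10.0
    open_exchanges: bool = True

    def __post_init__(self):
        if self.topology not in TOPOLOGIES:
            raise UnsupportedTopologyError(
                f"unsupported topology {self.topology!r}; expected one of {TOPOLOGIES}"
            )
        if self.genes_per_reaction not in GPR_PATTERNS:
            raise ValueError(f"unknown GPR pattern {self.genes_per_reaction!r}")


def _gpr_for(pattern: str, tag: str) -> str:
    if pattern == "single":
        return f"g{tag}"
    if pattern == "and-complex":
        return f"g{tag}a & g{tag}b"
    if pattern == "or-isozymes":
        return f"g{tag}a | g{tag}b"
    return f"(g{tag}a | g{tag}b) & g{tag}c"


def _build(metabolites, reactions, gprs, redundant=(), name="toy"):
    m = cobra.Model(name)
    mets = {mid: cobra.Metabolite(mid, compartment="c") for mid in metabolites}
    m.add_metabolites(list(mets.values()))
    objs = []
    for rid, stoich, lb, ub in reactions:
        r = cobra.Reaction(rid, lower_bound=lb, upper_bound=ub)
        objs.append((r, stoich))
    m.add_reactions([r for r, _ in objs])
    for r, stoich in objs:
        r.add_metabolites({mets[k]: v for k, v in stoich.items()})
    return MetabolicModel(
        cobra_model=m,
        gprs={rid: parse_gpr(text) for rid, text in gprs.items()},
        redundant_pairs=[frozenset(p) for p in redundant],
    )


def _chain(prefix: str, n: int, pattern: str, uptake: float, open_ex: bool):
    """A linear pathway: uptake -> n conversions -> secretion."""
    mets = [f"{prefix}M{i}" for i in range(n + 1)]
    lb_up = -uptake if open_ex else 0.0
    reactions = [(f"{prefix}EX_up", {mets[0]: -1.0}, lb_up, 0.0)]
    gprs = {}
    for i in range(1, n + 1):
        rid = f"{prefix}R{i}"
        reactions.append((rid, {mets[i - 1]: -1.0, mets[i]: 1.0}, 0.0, 1000.0))
        gprs[rid] = _gpr_for(pattern, f"{prefix}{i}")
    reactions.append((f"{prefix}EX_sec", {mets[-1]: -1.0}, 0.0, 1000.0))
    return mets, reactions, gprs


def make_toy_model(spec: ToyModelSpec) -> MetabolicModel:
    """Construct a mass-balanced toy model for the requested topology."""
    p, up, open_ex = spec.genes_per_reaction, spec.uptake_bound, spec.open_exchanges
    if spec.topology == "linear_chain":
        mets, rxns, gprs = _chain("", spec.n_internal_reactions, p, up, open_ex)
        return _build(mets, rxns, gprs, name="linear_chain")

    if spec.topology == "branch":
        n = max(spec.n_internal_reactions, 3)
        trunk = n - 2
        mets = [f"M{i}" for i in range(trunk + 1)] + ["MB1", "MB2"]
        lb_up = -up if open_ex else 0.0
        rxns = [("EX_up", {"M0": -1.0}, lb_up, 0.0)]
        gprs = {}
        for i in range(1, trunk + 1):
            rid = f"R{i}"
            rxns.append((rid, {f"M{i - 1}": -1.0, f"M{i}": 1.0}, 0.0, 1000.0))
            gprs[rid] = _gpr_for(p, str(i))
        top = f"M{trunk}"
        for k, bm in enumerate(("MB1", "MB2"), start=1):
            rid = f"RB{k}"
            rxns.append((rid, {top: -1.0, bm: 1.0}, 0.0, 1000.0))
            gprs[rid] = _gpr_for(p, f"b{k}")
            rxns.append((f"EX_{bm}", {bm: -1.0}, 0.0, 1000.0))
        return _build(mets, rxns, gprs, name="branch")

    if spec.topology == "parallel_independent":
        mets, rxns, gprs = [], [], {}
        for k in range(1, spec.n_chains + 1):
            m_k, r_k, g_k = _chain(f"c{k}", spec.n_internal_reactions, p, up, open_ex)
            mets += m_k
            rxns += r_k
            gprs.update(g_k)
        return _build(mets, rxns, gprs, name="parallel_independent")

    if spec.topology == "complex_gpr":
        mets, rxns, gprs = _chain("", max(spec.n_internal_reactions, 2), p, up, open_ex)
        # succinate-dehydrogenase-style complex with isozyme subunits
        gprs["R1"] = "[(gA | gB) & gC] & gD"
        return _build(mets, rxns, gprs, name="complex_gpr")

    # redundant_pair: two conversions identical modulo NAD/NADP cofactor
    lb_up = -up if open_ex else 0.0
    mets = ["A", "B", "NAD", "NADH", "NADP", "NADPH"]
    rxns = [
        ("EX_up", {"A": -1.0}, lb_up, 0.0),
        ("R_nad", {"A": -1.0, "NAD": -1.0, "B": 1.0, "NADH": 1.0}, 0.0, 1000.0),
        ("R_nadp", {"A": -1.0, "NADP": -1.0, "B": 1.0, "NADPH": 1.0}, 0.0, 1000.0),
        ("R_regen_nad", {"NADH": -1.0, "NAD": 1.0}, 0.0, 1000.0),
        ("R_regen_nadp", {"NADPH": -1.0, "NADP": 1.0}, 0.0, 1000.0),
        ("EX_sec", {"B": -1.0}, 0.0, 1000.0),
    ]
    gprs = {"R_nad": "gR1", "R_nadp": "gR2"}
    return _build(
        mets, rxns, gprs, redundant=[("R_nad", "R_nadp")], name="redundant_pair"
    )


# ---------------------------------------------------------------- compendium


@dataclass(frozen=True)
class PlantedModule:
    name: str
    genes: tuple[str, ...]
    loading: float  # latent-factor loading in [0, 1]
    active_datasets: tuple[int, ...]  # dataset indices where the module is on


@dataclass
class CompendiumSimParams:
    n_datasets: int = 20
    conditions_range: tuple[int, int] = (10, 20)
    n_genes: int = 120
    planted_modules: list[PlantedModule] = field(default_factory=list)
    noise_sd: float = 0.1
    missing_gene_fraction: float = 0.0
    batch_contaminated_datasets: tuple[int, ...] = ()
    baseline_mu: float = 7.0
    baseline_sd: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if self.conditions_range[0] < 10:
            raise ValueError("every dataset needs >= 10 conditions")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        seen: set[str] = set()
        for mod in self.planted_modules:
            overlap = seen & set(mod.genes)
            if overlap:
                raise ValueError(f"planted modules overlap on {sorted(overlap)}")
            seen |= set(mod.genes)


@dataclass
class GroundTruth:
    """Per-axis ground truth for the simulated datasets."""

    module_members: dict[str, frozenset[str]] = field(default_factory=dict)
    active_datasets: dict[str, frozenset[str]] = field(default_factory=dict)
    batch_datasets: frozenset[str] = frozenset()
    missing_genes: dict[str, frozenset[str]] = field(default_factory=dict)
    flat_genes: frozenset[str] = frozenset()
    les_genes: frozenset[str] = frozenset()
    tissue_specific: dict[str, str] = field(default_factory=dict)
    ubiquitous_genes: frozenset[str] = frozenset()
    low_expressed_genes: frozenset[str] = frozenset()

    def module_labels(self, genes) -> np.ndarray:
        """Integer module label per gene (0 = background)."""
        lookup = {
            g: k
            for k, (_, members) in enumerate(sorted(self.module_members.items()), 1)
            for g in members
        }
        return np.array([lookup.get(g, 0) for g in genes])


def default_gene_ids(n_genes: int) -> list[str]:
    return [f"g{i:04d}" for i in range(n_genes)]


def expected_module_pcc(loading: float, noise_sd: float) -> float:
    """Closed-form within-module Pearson correlation of the factor model."""
    return loading**2 / (loading**2 + noise_sd**2)


def simulate_compendium(
    params: CompendiumSimParams,
) -> tuple[list[ExpressionDataset], GroundTruth]:
    """Simulate a multi-dataset expression compendium.

    Gene values are log-scale: ``baseline_g + loading * f_c + noise`` where
    the latent factor ``f_c ~ N(0,1)`` is shared by module genes only in the
    module's active datasets.  Batch-contaminated datasets receive a
    gene-specific additive offset (magnitude ``5 * noise_sd``, random sign)
    on the second half of their conditions.  Missing genes are dropped per
    dataset, sparing genes of modules active there so planted structure is
    observable.
    """
    rng = np.random.default_rng(params.seed)
    genes = default_gene_ids(params.n_genes)
    gene_pos = {g: i for i, g in enumerate(genes)}
    for mod in params.planted_modules:
        unknown = set(mod.genes) - set(genes)
        if unknown:
            raise ValueError(f"module {mod.name} references unknown genes {sorted(unknown)}")
    baseline = rng.normal(params.baseline_mu, params.baseline_sd, params.n_genes)

    datasets: list[ExpressionDataset] = []
    gt = GroundTruth(
        module_members={m.name: frozenset(m.genes) for m in params.planted_modules},
    )
    active: dict[str, set[str]] = {m.name: set() for m in params.planted_modules}
    batch_ids: set[str] = set()
    missing: dict[str, frozenset[str]] = {}

    lo, hi = params.conditions_range
    for d in range(params.n_datasets):
        ds_id = f"ds{d:03d}"
        n_cond = int(rng.integers(lo, hi + 1))
        vals = baseline[:, None] + rng.normal(
            0.0, params.noise_sd, (params.n_genes, n_cond)
        )
        protected: set[str] = set()
        for mod in params.planted_modules:
            if d in mod.active_datasets:
                f = rng.normal(0.0, 1.0, n_cond)
                rows = [gene_pos[g] for g in mod.genes]
                vals[rows, :] += mod.loading * f[None, :]
                active[mod.name].add(ds_id)
                protected |= set(mod.genes)
        if d in params.batch_contaminated_datasets:
            delta = rng.choice([-1.0, 1.0], params.n_genes) * 5.0 * params.noise_sd
            vals[:, n_cond // 2 :] += delta[:, None]
            batch_ids.add(ds_id)
        df = pd.DataFrame(
            vals, index=genes, columns=[f"c{j:03d}" for j in range(n_cond)]
        )
        if params.missing_gene_fraction > 0:
            candidates = [g for g in genes if g not in protected]
            n_miss = int(round(params.missing_gene_fraction * params.n_genes))
            n_miss = min(n_miss, len(candidates))
            drop = rng.choice(candidates, size=n_miss, replace=False)
            missing[ds_id] = frozenset(drop)
            df = df.drop(index=list(drop))
        datasets.append(ExpressionDataset(dataset_id=ds_id, values=df))

    gt.active_datasets = {k: frozenset(v) for k, v in active.items()}
    gt.batch_datasets = frozenset(batch_ids)
    gt.missing_genes = missing
    return datasets, gt


def planted_compendium_params(
    n_modules: int = 4,
    module_size: int = 8,
    n_datasets: int = 20,
    n_active: int = 4,
    n_genes: int = 120,
    loading: float = 0.9,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> CompendiumSimParams:
    """Convenience builder: disjoint planted modules with seeded activation."""
    if n_modules * n_active > n_datasets:
        raise ValueError("not enough datasets for disjoint activations")
    rng = np.random.default_rng(seed)
    genes = default_gene_ids(n_genes)
    # disjoint activation sets: each dataset activates at most one module,
    # so per-module activation conditions are identifiable
    perm = rng.permutation(n_datasets)
    modules = []
    for k in range(n_modules):
        member = genes[k * module_size : (k + 1) * module_size]
        act = tuple(sorted(int(d) for d in perm[k * n_active : (k + 1) * n_active]))
        modules.append(
            PlantedModule(
                name=f"module{k}", genes=tuple(member), loading=loading,
                active_datasets=act,
            )
        )
    return CompendiumSimParams(
        n_datasets=n_datasets,
        n_genes=n_genes,
        planted_modules=modules,
        noise_sd=noise_sd,
        seed=seed,
    )


# ------------------------------------------------------------- developmental


def simulate_dev_timecourse(
    n_genes: int = 2000,
    n_flat: int = 400,
    n_timepoints: int = 25,
    seed: int = 0,
    les_fraction: float = 0.3,
    mu_low: float = 1.0,
    sd_low: float = 0.5,
    mu_high: float = 8.0,
    sd_high: float = 1.0,
    flat_jitter: float = 0.03,
) -> tuple[DevTimeCourse, GroundTruth]:
    """Simulate an RPKM-like developmental time course.

    Flat genes keep a near-constant profile (their total-normalized profiles
    stay close to the common 1/n line); variant genes get ramp or pulse
    shapes.  Per-gene mean log2 levels are drawn from a two-component
    Gaussian mixture; the lower component is the low-expression
    subpopulation (LES), which is flat-shaped so that filtering on the
    fitted threshold removes exactly those genes.
    """
    if n_flat > n_genes:
        raise ValueError("n_flat must not exceed n_genes")
    if n_timepoints < 3:
        raise ValueError("need at least 3 timepoints")
    rng = np.random.default_rng(seed)
    genes = default_gene_ids(n_genes)
    flat = set(genes[:n_flat])

    n_var = n_genes - n_flat
    n_les = int(round(les_fraction * n_var))
    les = set(genes[n_flat : n_flat + n_les])

    levels = np.empty(n_genes)
    levels[:n_flat] = rng.normal(mu_high, sd_high, n_flat)
    levels[n_flat : n_flat + n_les] = rng.normal(mu_low, sd_low, n_les)
    levels[n_flat + n_les :] = rng.normal(mu_high, sd_high, n_var - n_les)

    shapes = np.ones((n_genes, n_timepoints))
    # flat and LES genes: constant profile with small jitter
    n_const = n_flat + n_les
    shapes[:n_const] += rng.normal(0.0, flat_jitter, (n_const, n_timepoints))
    shapes[:n_const] = np.clip(shapes[:n_const], 0.01, None)
    t = np.linspace(0.0, 1.0, n_timepoints)
    for i in range(n_const, n_genes):
        kind = rng.integers(3)
        if kind == 0:  # rising ramp
            shapes[i] = 0.2 + 1.8 * t
        elif kind == 1:  # falling ramp
            shapes[i] = 2.0 - 1.8 * t
        else:  # pulse: 10x excursion at one timepoint
            shapes[i, rng.integers(n_timepoints)] = 10.0
        shapes[i] *= 1.0 + rng.normal(0.0, flat_jitter, n_timepoints)
        shapes[i] = np.clip(shapes[i], 0.01, None)

    values = (2.0 ** levels)[:, None] * shapes
    tc = DevTimeCourse(
        values=pd.DataFrame(
            values, index=genes,
            columns=[f"t{2 * i:02d}h" for i in range(n_timepoints)],
        ),
        timepoint_hours=np.arange(n_timepoints) * 2.0,
        flat_gene_ids=frozenset(flat),
    )
    gt = GroundTruth(flat_genes=frozenset(flat), les_genes=frozenset(les))
    return tc, gt


# ------------------------------------------------------------------- tissues


def simulate_tissue_matrix(
    n_genes: int = 1000,
    n_tissues: int = 7,
    seed: int = 0,
    frac_specific: float = 0.35,
) -> tuple[TissueMatrix, GroundTruth]:
    """Simulate a TPM-like tissue expression matrix.

    Tissue-specific genes are one-hot (expressed in exactly one tissue,
    assigned round-robin), ubiquitous genes near-uniform, and a
    low-expression block gives the rare/low filter true positives.  Block
    sizes are chosen so that, in every tissue, the moderate quantile cut
    falls inside the wide value gap between the low and ubiquitous blocks:
    the planted retained/filtered split is unambiguous by construction.
    Levels are labeled by within-tissue quantile cuts.
    """
    if n_tissues < 2:
        raise ValueError("need at least 2 tissues")
    rng = np.random.default_rng(seed)
    genes = default_gene_ids(n_genes)
    tissues = [f"tissue{k}" for k in range(n_tissues)]
    n_spec = (int(round(frac_specific * n_genes)) // n_tissues) * n_tissues
    # per tissue: zeros from other tissues' specific genes, plus the low
    # block, must end exactly at the moderate cut index
    n_zero_per_tissue = n_spec - n_spec // n_tissues
    n_below_cut = int(np.floor((n_genes - 1) * 0.7)) + 1
    n_low = n_below_cut - n_zero_per_tissue
    if n_low < 1 or n_spec + n_low >= n_genes:
        raise ValueError("n_genes too small for the planted block layout")

    values = np.zeros((n_genes, n_tissues))
    specific: dict[str, str] = {}
    for i in range(n_spec):
        t = i % n_tissues
        values[i, t] = rng.uniform(200.0, 1000.0)
        specific[genes[i]] = tissues[t]
    values[n_spec : n_spec + n_low] = rng.uniform(
        0.01, 0.5, (n_low, n_tissues)
    )
    n_ubiq = n_genes - n_spec - n_low
    base = rng.uniform(5.0, 50.0, n_ubiq)
    values[n_spec + n_low :] = base[:, None] * np.clip(
        1.0 + rng.normal(0.0, 0.05, (n_ubiq, n_tissues)), 0.8, 1.2
    )

    df = pd.DataFrame(values, index=genes, columns=tissues)
    tm = TissueMatrix(values=df, labels=label_tissue_levels(df))
    gt = GroundTruth(
        tissue_specific=specific,
        low_expressed_genes=frozenset(genes[n_spec : n_spec + n_low]),
        ubiquitous_genes=frozenset(genes[n_spec + n_low :]),
    )
    return tm, gt
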
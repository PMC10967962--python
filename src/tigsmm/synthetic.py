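"""Generators for desk-scale pipeline inputs.

Three kinds of synthetic input stand in for a deposited genome-scale
model and its companion RNA-seq tables:

* toy metabolic models that are feasible by construction — a linear
  backbone from a carbon exchange through a transport step and an
  internal chain into a biomass drain, decorated with parallel duplicate
  reactions carrying their own GPRs;
* FPKM tables drawn from a log-normal (the shape of real RNA-seq
  expression), with designated "planted low" reactions whose genes are
  forced into the bottom tail so they fall below any median threshold;
* gene-level differential statistics with uniform null p-values and
  planted "hot" metabolite neighborhoods whose genes share direction and
  very small p-values.

Synthetic gene ids use the ``CCMX_%04d`` format so they can never collide
with real CCM_ locus tags.  All outputs are fully determined by seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np

from tigsmm.expression import ExpressionProfile
from tigsmm.model_io import (
    GprExpr,
    MetabolicModel,
    Metabolite,
    Reaction,
    ReactionKind,
    parse_gpr,
)
from tigsmm.reporter import GeneStat, build_neighborhoods

__all__ = [
    "SyntheticSpec",
    "make_textbook_model",
    "generate_model",
    "generate_fpkm",
    "generate_gene_stats",
]

_SUBSYSTEMS = (
    "glycolysis",
    "tca_cycle",
    "pentose_phosphate",
    "lipid_metabolism",
    "amino_acid_metabolism",
    "nucleotide_metabolism",
)


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic dataset.

    ``fpkm_lognormal_params`` are (μ, σ) on the log scale; the defaults
    give a long-tailed distribution with most mass between 1 and 100
    FPKM, matching the shape of typical fungal RNA-seq libraries.
    """

    n_metabolites: int = 8
    n_reactions: int = 12
    n_parallel_pairs: int = 2
    seed: int = 0
    fpkm_lognormal_params: Tuple[float, float] = (2.0, 1.2)
    planted_low_reactions: Set[str] = field(default_factory=set)
    hot_metabolites: Set[str] = field(default_factory=set)
    hot_effect: float = 0.11  # Beta(a, 1) shape; a = 0.11 gives median p ≈ 0.002


def make_textbook_model() -> MetabolicModel:
    """Hand-written 10-reaction fixture.

    Carbon A enters through an exchange and a transport step, reaches B
    by two parallel unit-yield paths (R_HI, R_LO, distinct genes) or a
    half-yield bypass (R_BYP), nutrient N enters separately as C, and the
    biomass drain consumes B + C.  A spontaneous reaction leaks B to a
    secreted by-product D.  Census: 4 genes, 6 metabolites, 10 reactions
    of which 3 exchanges and 1 biomass.
    """
    metabolites = [
        Metabolite("A_e", "carbon substrate (external)", "e"),
        Metabolite("N_e", "nutrient (external)", "e"),
        Metabolite("A_c", "carbon substrate", "c"),
        Metabolite("B_c", "carbon intermediate", "c"),
        Metabolite("C_c", "nutrient intermediate", "c"),
        Metabolite("D_c", "by-product", "c"),
    ]
    rxns = [
        Reaction("EX_A", {"A_e": -1.0}, name="carbon exchange", lb=-10.0,
                 kind=ReactionKind.EXCHANGE),
        Reaction("EX_N", {"N_e": -1.0}, name="nutrient exchange", lb=-1000.0,
                 kind=ReactionKind.EXCHANGE),
        Reaction("EX_D", {"D_c": -1.0}, name="by-product secretion", lb=0.0,
                 kind=ReactionKind.EXCHANGE),
        Reaction("T_A", {"A_e": -1.0, "A_c": 1.0}, name="carbon transport", lb=0.0,
                 gpr=parse_gpr("g4"), kind=ReactionKind.TRANSPORT),
        Reaction("R_HI", {"A_c": -1.0, "B_c": 1.0}, name="high-yield path", lb=0.0,
                 gpr=parse_gpr("g1"), subsystem="glycolysis"),
        Reaction("R_LO", {"A_c": -1.0, "B_c": 1.0}, name="parallel path", lb=0.0,
                 gpr=parse_gpr("g2"), subsystem="glycolysis"),
        Reaction("R_BYP", {"A_c": -1.0, "B_c": 0.5}, name="half-yield bypass", lb=0.0,
                 gpr=parse_gpr("g3"), subsystem="bypass"),
        Reaction("T_N", {"N_e": -1.0, "C_c": 1.0}, name="nutrient assimilation", lb=0.0,
                 gpr=parse_gpr("g4"), kind=ReactionKind.TRANSPORT),
        Reaction("R_SPONT", {"B_c": -1.0, "D_c": 1.0}, name="spontaneous leak", lb=0.0,
                 kind=ReactionKind.SPONTANEOUS),
        Reaction("BIOMASS", {"B_c": -1.0, "C_c": -1.0}, name="biomass drain", lb=0.0,
                 kind=ReactionKind.BIOMASS),
    ]
    model = MetabolicModel(
        id="textbook",
        metabolites=metabolites,
        reactions=rxns,
        compartments={"c": "cytosol", "e": "extracellular"},
        biomass_id="BIOMASS",
    )
    model.validate()
    return model


def _gene_name(i: int) -> str:
    return f"CCMX_{i:04d}"


def generate_model(spec: SyntheticSpec) -> MetabolicModel:
    """Random feasible toy model, deterministic per seed.

    Backbone: EX_S (carbon exchange, uptake capacity 10) → T_S transport →
    chain M1 → … → M_L → biomass, guaranteeing growth > 0.  Additional
    reactions beyond the backbone duplicate random chain steps with fresh
    GPRs (isozyme-style parallel paths); some chain steps are made
    reversible for variety.
    """
    rng = np.random.default_rng(spec.seed)
    n_chain_mets = spec.n_metabolites - 1  # M1..ML; plus external S_e
    if n_chain_mets < 2:
        raise ValueError("need at least 3 metabolites (external substrate + 2 internal)")
    backbone = n_chain_mets + 2  # exchange + transport + (L-1) chain steps + biomass
    if spec.n_reactions < backbone:
        raise ValueError(
            f"n_reactions={spec.n_reactions} below backbone size {backbone} "
            f"for {spec.n_metabolites} metabolites"
        )

    metabolites = [Metabolite("S_e", "substrate (external)", "e")] + [
        Metabolite(f"M{i}_c", f"intermediate {i}", "c")
        for i in range(1, n_chain_mets + 1)
    ]

    gene_counter = [0]

    def fresh_gpr() -> GprExpr:
        style = rng.integers(0, 3)
        gene_counter[0] += 1
        g1 = _gene_name(gene_counter[0])
        if style == 0:
            return GprExpr.gene_(g1)
        gene_counter[0] += 1
        g2 = _gene_name(gene_counter[0])
        pair = (GprExpr.gene_(g1), GprExpr.gene_(g2))
        return GprExpr("and" if style == 1 else "or", children=pair)

    def subsystem() -> str:
        return _SUBSYSTEMS[int(rng.integers(0, len(_SUBSYSTEMS)))]

    reactions: List[Reaction] = [
        Reaction("EX_S", {"S_e": -1.0}, name="substrate exchange", lb=-10.0,
                 kind=ReactionKind.EXCHANGE),
        Reaction("T_S", {"S_e": -1.0, "M1_c": 1.0}, name="substrate transport",
                 lb=0.0, gpr=fresh_gpr(), kind=ReactionKind.TRANSPORT),
    ]
    chain_rxns: List[Reaction] = []
    for i in range(1, n_chain_mets):
        reversible = bool(rng.random() < 0.3)
        rxn = Reaction(
            f"R{i:03d}",
            {f"M{i}_c": -1.0, f"M{i + 1}_c": 1.0},
            name=f"chain step {i}",
            lb=-1000.0 if reversible else 0.0,
            gpr=fresh_gpr(),
            subsystem=subsystem(),
        )
        reactions.append(rxn)
        chain_rxns.append(rxn)
    reactions.append(
        Reaction("BIOMASS", {f"M{n_chain_mets}_c": -1.0}, name="biomass drain",
                 lb=0.0, kind=ReactionKind.BIOMASS)
    )

    n_extra = spec.n_reactions - len(reactions)
    n_pairs = min(spec.n_parallel_pairs, n_extra) if chain_rxns else 0
    for j in range(n_extra):
        template = chain_rxns[int(rng.integers(0, len(chain_rxns)))]
        reactions.append(
            Reaction(
                f"P{j:03d}",
                dict(template.stoich),
                name=f"parallel to {template.id}",
                lb=0.0,
                gpr=fresh_gpr(),
                subsystem=subsystem(),
            )
        )
    _ = n_pairs  # parallel pairs are a subset of the extras

    model = MetabolicModel(
        id=f"synthetic_seed{spec.seed}",
        metabolites=metabolites,
        reactions=reactions,
        compartments={"c": "cytosol", "e": "extracellular"},
        biomass_id="BIOMASS",
    )
    model.validate()
    return model


def generate_fpkm(
    model: MetabolicModel,
    spec: SyntheticSpec,
    conditions: Sequence[str] = ("LG", "LS"),
) -> List[ExpressionProfile]:
    """Log-normal FPKM per condition with independent noise.

    Genes of ``spec.planted_low_reactions`` are drawn uniformly from
    [0, 0.5), far below the log-normal's lower quartile (≈ 3.3 at the
    default μ=2, σ=1.2), so a planted reaction reliably falls under any
    percentile-50 threshold.
    """
    rng = np.random.default_rng(spec.seed + 1)
    genes = sorted(model.genes)
    low_genes: Set[str] = set()
    for rxn_id in spec.planted_low_reactions:
        low_genes |= model.get_reaction(rxn_id).genes()
    mu, sigma = spec.fpkm_lognormal_params
    profiles = []
    for cond in conditions:
        values = {}
        for g in genes:
            if g in low_genes:
                values[g] = float(rng.uniform(0.0, 0.5))
            else:
                values[g] = float(rng.lognormal(mean=mu, sigma=sigma))
        profiles.append(ExpressionProfile(condition=cond, values=values))
    return profiles


def generate_gene_stats(
    model: MetabolicModel,
    hot_metabolites: Iterable[str] = (),
    effect: float = 0.11,
    seed: int = 0,
    extra_null_genes: int = 0,
) -> List[GeneStat]:
    """Gene-level differential statistics with planted hot neighborhoods.

    Null genes get p ~ Uniform(0, 1] and a random direction.  Genes in
    the neighborhoods of ``hot_metabolites`` get p ~ Beta(effect, 1) —
    at the default shape 0.11 the median planted p is ≈ 0.002 — and a
    shared "up" direction.  ``extra_null_genes`` pads the universe with
    genes outside the model, enlarging the background.
    """
    rng = np.random.default_rng(seed)
    hot_set = set(hot_metabolites)
    hot_genes: Set[str] = set()
    if hot_set:
        missing = hot_set - set(model.metabolite_ids())
        if missing:
            raise KeyError(f"hot metabolites not in model: {sorted(missing)[:5]}")
        for nb in build_neighborhoods(model):
            if nb.metabolite_id in hot_set:
                hot_genes |= nb.genes
    genes = sorted(model.genes) + [
        f"CCMX_N{i:04d}" for i in range(extra_null_genes)
    ]
    out: List[GeneStat] = []
    for g in genes:
        if g in hot_genes:
            p = float(rng.random() ** (1.0 / effect))
            direction = "up"
        else:
            p = float(rng.random())
            direction = "up" if rng.random() < 0.5 else "down"
        p = min(max(p, 1e-12), 1.0)
        out.append(GeneStat(gene_id=g, p_value=p, direction=direction))
    return out
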
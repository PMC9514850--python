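"""Synthetic inputs: toy metabolic networks, expression tables with planted
pathway effects, and promoter signal matrices with planted enriched genes.

The toy network is a bundle of parallel linear chains — one chain per
pathway — running from a shared source metabolite to a shared sink. Each
pathway has its own uptake and secretion exchange (subsystem ``exchange``)
with loose bounds, so the flux ceiling of a chain is set by its own
internal reaction bounds; scaling those bounds with expression fold changes
therefore moves the chain's FVA maxima monotonically, which is what makes
planted pathway effects recoverable end to end. Every intermediate
metabolite additionally has a supplementary uptake and an overflow leak
(bound ``SIDE_BOUND``): a strict chain at steady state forces one shared
bottleneck — hence identical FVA maxima — onto all of its reactions,
collapsing the per-reaction flux distribution into exact ties, and a single
silenced step (all its genes NaN) would abolish the response of the whole
chain. The side exchanges emulate the bypass routes of real networks: each
reaction's maximum remains capped by its own expression-scaled bound, while
an unresponsive neighbour only attenuates (by ``SIDE_BOUND`` per step)
rather than blocks propagation. Every internal reaction carries a GPR over
1–3 fresh genes.

Expression fold changes are lognormal around the planted per-pathway log2
effect (multiplicative noise); a configurable fraction of genes is set to
missing (NaN) to emulate genes without a usable differential-expression
estimate. Promoter matrices are i.i.d. lognormal signal with the enriched
genes' rows multiplied up in one track, next to an undisturbed null track.

All generators are deterministic functions of the spec seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .expression import ExpressionTable
from .gpr import gpr_genes, parse_gpr
from .model import Enzyme, MetabolicModel, Reaction
from .tfbs import TFBSSignalMatrix

__all__ = ["SyntheticSpec", "make_toy_model", "make_expression", "make_tfbs_signal"]

#: Bound of internal chain reactions; pathway uptake/secretion exchanges get
#: the loose EXCHANGE_BOUND; intermediate side exchanges get SIDE_BOUND.
CHAIN_BOUND = 10.0
EXCHANGE_BOUND = 1000.0
SIDE_BOUND = 10.0


@dataclass
class SyntheticSpec:
    n_pathways: int = 8
    reactions_per_pathway: int = 4
    genes_per_reaction: tuple[int, int] = (1, 3)
    planted_effects: dict[str, float] = field(default_factory=dict)  # subsystem -> log2 effect
    noise_sd: float = 0.2      # log2 scale
    nan_fraction: float = 0.1
    enzyme_layer: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.n_pathways < 1 or self.reactions_per_pathway < 1:
            raise ValueError("need at least one pathway with at least one reaction")
        lo, hi = self.genes_per_reaction
        if not (1 <= lo <= hi <= 3):
            raise ValueError("genes_per_reaction range must lie within [1, 3]")
        if not 0 <= self.nan_fraction < 1:
            raise ValueError("nan_fraction must lie in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def pathway_names(self) -> list[str]:
        return [f"pathway_{i:02d}" for i in range(self.n_pathways)]


def _check_planted(spec: SyntheticSpec) -> None:
    unknown = set(spec.planted_effects) - set(spec.pathway_names())
    if unknown:
        raise ValueError(f"planted effects name unknown pathways: {sorted(unknown)}")


def make_toy_model(spec: SyntheticSpec) -> MetabolicModel:
    """Generate the toy model described in the module docstring."""
    _check_planted(spec)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0]))
    lo, hi = spec.genes_per_reaction

    metabolites = ["src", "snk"]
    reactions: list[Reaction] = []
    genes: list[str] = []
    for pw in spec.pathway_names():
        chain = ["src"] + [f"{pw}_m{i}" for i in range(1, spec.reactions_per_pathway)] + ["snk"]
        metabolites.extend(chain[1:-1])
        for i in range(spec.reactions_per_pathway):
            rid = f"{pw}_r{i}"
            n_genes = int(rng.integers(lo, hi + 1))
            rxn_genes = [f"{rid}_g{j}" for j in range(n_genes)]
            genes.extend(rxn_genes)
            if n_genes == 1:
                rule = rxn_genes[0]
            else:
                op = " and " if rng.random() < 0.5 else " or "
                rule = op.join(rxn_genes)
            enzyme = None
            if spec.enzyme_layer:
                kcat = float(np.exp(rng.uniform(math.log(1.0), math.log(100.0))))
                mw = float(rng.uniform(10.0, 100.0))
                enzyme = Enzyme(kcat=kcat, mw=mw)
            reactions.append(Reaction(
                id=rid, stoichiometry={chain[i]: -1.0, chain[i + 1]: 1.0},
                lower_bound=0.0, upper_bound=CHAIN_BOUND,
                gpr=parse_gpr(rule), subsystem=pw, enzyme=enzyme))
        reactions.append(Reaction(f"EX_{pw}_uptake", {"src": 1.0},
                                  0.0, EXCHANGE_BOUND, None, "exchange"))
        reactions.append(Reaction(f"EX_{pw}_secretion", {"snk": -1.0},
                                  0.0, EXCHANGE_BOUND, None, "exchange"))
        for met in chain[1:-1]:
            reactions.append(Reaction(f"EX_{met}_feed", {met: 1.0},
                                      0.0, SIDE_BOUND, None, "exchange"))
            reactions.append(Reaction(f"EX_{met}_leak", {met: -1.0},
                                      0.0, SIDE_BOUND, None, "exchange"))

    enzyme_pool = None
    if spec.enzyme_layer:
        # pool sized to support roughly half of every chain's nominal
        # capacity at once: maxima stay positive but the pool can bind
        internal = [r for r in reactions if r.enzyme is not None]
        enzyme_pool = 0.5 * sum(CHAIN_BOUND * r.enzyme.mw / r.enzyme.kcat for r in internal)

    return MetabolicModel(model_id=f"toy_{spec.seed}", metabolites=metabolites,
                          reactions=reactions, genes=genes, enzyme_pool=enzyme_pool)


def make_expression(model: MetabolicModel, spec: SyntheticSpec) -> ExpressionTable:
    """Fold changes 2^(pathway effect + N(0, noise_sd)) per gene, with a
    ``nan_fraction`` of genes dropped to missing.

    The missing genes are chosen uniformly, except that a planted pathway is
    never silenced entirely (at least one of its genes keeps a value).
    """
    _check_planted(spec)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    gene_pathway: dict[str, str] = {}
    for rxn in model.reactions:
        if rxn.gpr is None:
            continue
        for g in gpr_genes(rxn.gpr):
            gene_pathway[g] = rxn.subsystem
    genes = [g for g in model.genes if g in gene_pathway]

    n_nan = int(math.floor(spec.nan_fraction * len(genes)))
    missing: set[str] = set(rng.choice(genes, size=n_nan, replace=False)) if n_nan else set()
    for pw in spec.planted_effects:
        pw_genes = [g for g in genes if gene_pathway[g] == pw]
        if pw_genes and all(g in missing for g in pw_genes):
            keep = pw_genes[int(rng.integers(len(pw_genes)))]
            missing.discard(keep)
            spare = [g for g in genes if g not in missing and gene_pathway[g] != pw]
            if spare:
                missing.add(spare[int(rng.integers(len(spare)))])

    entries = {}
    for g in genes:
        if g in missing:
            continue
        effect = spec.planted_effects.get(gene_pathway[g], 0.0)
        entries[g] = float(2.0 ** (effect + rng.normal(0.0, spec.noise_sd)))
    return ExpressionTable(entries)


def make_tfbs_signal(n_genes: int, n_bins: int, enriched_gene_count: int,
                     effect_multiplier: float, seed: int = 0,
                     ) -> tuple[TFBSSignalMatrix, list[str]]:
    """Promoter signal over a ±1 kb TSS window with one planted track.

    Returns the matrix (tracks ``TF_planted`` and ``TF_null``) and the list
    of enriched genes, whose rows in the planted track are multiplied by
    ``effect_multiplier``.
    """
    if n_genes < 2 or n_bins < 1:
        raise ValueError("need n_genes >= 2 and n_bins >= 1")
    if not 0 <= enriched_gene_count < n_genes:
        raise ValueError("enriched_gene_count must be < n_genes")
    if effect_multiplier < 1:
        raise ValueError("effect_multiplier must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    universe = [f"g{i:05d}" for i in range(n_genes)]
    positions = np.linspace(-1000.0, 1000.0, n_bins, endpoint=False)
    planted = rng.lognormal(0.0, 1.0, size=(n_genes, n_bins))
    null = rng.lognormal(0.0, 1.0, size=(n_genes, n_bins))
    enriched_idx = rng.choice(n_genes, size=enriched_gene_count, replace=False)
    planted[enriched_idx] *= effect_multiplier
    matrix = TFBSSignalMatrix(universe=universe, positions=positions,
                              tracks={"TF_planted": planted, "TF_null": null})
    return matrix, [universe[i] for i in sorted(enriched_idx)]
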
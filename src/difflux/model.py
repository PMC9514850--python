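"""Constraint-based metabolic model containers, validation and I/O.

A :class:`MetabolicModel` is a stoichiometric network with per-reaction flux
bounds (mmol·gDW⁻¹·h⁻¹), optional GPR rules, a subsystem (pathway) label per
reaction, and an optional enzyme layer: per-reaction turnover number ``kcat``
(h⁻¹), enzyme molar mass ``mw`` (mg·mmol⁻¹) and a shared protein pool
(mg·gDW⁻¹). Models round-trip through a compact JSON dialect and through
SBML Level 3 + FBC (via COBRApy, used for serialisation only).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from .gpr import GPRNode, gpr_genes, parse_gpr, serialize_gpr

logger = logging.getLogger(__name__)

#: Default magnitude cap for flux bounds; keeps every LP bounded.
BOUND_CAP = 1000.0

__all__ = ["Enzyme", "Reaction", "MetabolicModel", "EnzymeAugmentation",
           "ModelValidationError", "read_model", "write_model",
           "apply_enzyme_constraints", "BOUND_CAP"]


class ModelValidationError(ValueError):
    """Raised when a model violates its structural invariants.

    ``violations`` lists every problem found, not just the first.
    """

    def __init__(self, violations: list[str]):
        super().__init__("invalid model: " + "; ".join(violations))
        self.violations = violations


@dataclass(frozen=True)
class Enzyme:
    """Kinetic annotation of a catalysed reaction."""

    kcat: float  # turnover number, h^-1
    mw: float    # enzyme molar mass, mg·mmol^-1


@dataclass
class Reaction:
    id: str
    stoichiometry: dict[str, float]
    lower_bound: float
    upper_bound: float
    gpr: Optional[GPRNode] = None
    subsystem: str = "exchange"
    enzyme: Optional[Enzyme] = None

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0

    def copy(self) -> "Reaction":
        return Reaction(self.id, dict(self.stoichiometry), self.lower_bound,
                        self.upper_bound, self.gpr, self.subsystem, self.enzyme)


@dataclass
class EnzymeAugmentation:
    """Bookkeeping attached to a model produced by :func:`apply_enzyme_constraints`.

    ``original_reactions`` are the metabolic reaction ids of the parent
    model; ``split_pairs`` maps a reversible enzymatic reaction to its
    forward/backward irreversible halves (net flux = forward − backward);
    ``usage_reactions`` maps each enzymatic reaction to its enzyme-draw
    pseudo-reaction, whose flux is the enzyme usage u_j in mmol·gDW⁻¹·h⁻¹.
    """

    original_reactions: list[str]
    split_pairs: dict[str, tuple[str, str]] = field(default_factory=dict)
    usage_reactions: dict[str, str] = field(default_factory=dict)
    pool_exchange: str = "prot_pool_exchange"


@dataclass
class MetabolicModel:
    model_id: str
    metabolites: list[str]
    reactions: list[Reaction]
    genes: list[str]
    enzyme_pool: Optional[float] = None  # mg·gDW^-1
    augmentation: Optional[EnzymeAugmentation] = None

    def __post_init__(self):
        self.validate()

    # -- lookups -----------------------------------------------------------
    def reaction(self, rid: str) -> Reaction:
        try:
            return self._rxn_index[rid]
        except KeyError:
            raise KeyError(f"unknown reaction id {rid!r}") from None

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def subsystem_map(self) -> dict[str, str]:
        return {r.id: r.subsystem for r in self.reactions}

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(self.model_id, list(self.metabolites),
                              [r.copy() for r in self.reactions],
                              list(self.genes), self.enzyme_pool, self.augmentation)

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        problems: list[str] = []
        if len(set(self.metabolites)) != len(self.metabolites):
            problems.append("duplicate metabolite ids")
        rids = [r.id for r in self.reactions]
        if len(set(rids)) != len(rids):
            dupes = sorted({r for r in rids if rids.count(r) > 1})
            problems.append(f"duplicate reaction ids: {dupes}")
        mets = set(self.metabolites)
        genes = set(self.genes)
        for rxn in self.reactions:
            for met, coef in rxn.stoichiometry.items():
                if met not in mets:
                    problems.append(f"reaction {rxn.id!r} references undeclared metabolite {met!r}")
                if not math.isfinite(coef) or coef == 0:
                    problems.append(f"reaction {rxn.id!r}: coefficient for {met!r} must be finite and nonzero")
            if not (math.isfinite(rxn.lower_bound) and math.isfinite(rxn.upper_bound)):
                problems.append(f"reaction {rxn.id!r}: bounds must be finite")
            elif rxn.lower_bound > rxn.upper_bound:
                problems.append(f"reaction {rxn.id!r}: lower bound exceeds upper bound")
            if not rxn.subsystem:
                problems.append(f"reaction {rxn.id!r}: empty subsystem label")
            if rxn.gpr is not None:
                missing = gpr_genes(rxn.gpr) - genes
                if missing:
                    problems.append(f"reaction {rxn.id!r} GPR references undeclared genes {sorted(missing)}")
            if rxn.enzyme is not None and (rxn.enzyme.kcat <= 0 or rxn.enzyme.mw <= 0):
                problems.append(f"reaction {rxn.id!r}: kcat and mw must be positive")
        if problems:
            raise ModelValidationError(problems)
        self._rxn_index = {r.id: r for r in self.reactions}

    def has_enzyme_data(self) -> bool:
        return any(r.enzyme is not None for r in self.reactions)


def _clamp_bound(value: float, rxn_id: str, which: str) -> float:
    if value is None or not math.isfinite(value):
        value = BOUND_CAP if which == "ub" else -BOUND_CAP
        logger.warning("reaction %s: missing/non-finite %s set to %g", rxn_id, which, value)
    elif abs(value) > BOUND_CAP:
        clamped = math.copysign(BOUND_CAP, value)
        logger.warning("reaction %s: %s %g clamped to %g", rxn_id, which, value, clamped)
        value = clamped
    return float(value)


# ---------------------------------------------------------------------------
# JSON dialect
# ---------------------------------------------------------------------------

def _model_to_dict(model: MetabolicModel) -> dict:
    return {
        "model_id": model.model_id,
        "enzyme_pool": model.enzyme_pool,
        "metabolites": list(model.metabolites),
        "reactions": [
            {
                "id": r.id,
                "stoichiometry": r.stoichiometry,
                "lb": r.lower_bound,
                "ub": r.upper_bound,
                "gpr": serialize_gpr(r.gpr) if r.gpr is not None else None,
                "subsystem": r.subsystem,
                "enzyme": {"kcat": r.enzyme.kcat, "mw": r.enzyme.mw} if r.enzyme else None,
            }
            for r in model.reactions
        ],
    }


def _model_from_dict(data: dict) -> MetabolicModel:
    reactions = []
    genes: set[str] = set()
    for rd in data.get("reactions", []):
        gpr = parse_gpr(rd["gpr"]) if rd.get("gpr") else None
        if gpr is not None:
            genes |= gpr_genes(gpr)
        enz = rd.get("enzyme")
        reactions.append(Reaction(
            id=rd["id"],
            stoichiometry={m: float(c) for m, c in rd["stoichiometry"].items()},
            lower_bound=_clamp_bound(rd.get("lb"), rd["id"], "lb"),
            upper_bound=_clamp_bound(rd.get("ub"), rd["id"], "ub"),
            gpr=gpr,
            subsystem=rd.get("subsystem") or "exchange",
            enzyme=Enzyme(float(enz["kcat"]), float(enz["mw"])) if enz else None,
        ))
    return MetabolicModel(
        model_id=data.get("model_id", "model"),
        metabolites=list(data.get("metabolites", [])),
        reactions=reactions,
        genes=sorted(genes),
        enzyme_pool=data.get("enzyme_pool"),
    )


# ---------------------------------------------------------------------------
# SBML (via COBRApy; FBC bounds + GPR, subsystem as reaction group)
# ---------------------------------------------------------------------------

def _to_cobra(model: MetabolicModel):
    import cobra

    cm = cobra.Model(model.model_id)
    mets = {m: cobra.Metabolite(m, compartment="c") for m in model.metabolites}
    cm.add_metabolites(list(mets.values()))
    for r in model.reactions:
        cr = cobra.Reaction(r.id, lower_bound=r.lower_bound, upper_bound=r.upper_bound)
        cr.subsystem = r.subsystem
        cm.add_reactions([cr])
        cr.add_metabolites({mets[m]: c for m, c in r.stoichiometry.items()})
        if r.gpr is not None:
            cr.gene_reaction_rule = serialize_gpr(r.gpr)
        if r.enzyme is not None:
            cr.notes["difflux_kcat"] = repr(r.enzyme.kcat)
            cr.notes["difflux_mw"] = repr(r.enzyme.mw)
    if model.enzyme_pool is not None:
        cm.notes["difflux_enzyme_pool"] = repr(model.enzyme_pool)
    subsystems: dict[str, list] = {}
    for r in model.reactions:
        subsystems.setdefault(r.subsystem, []).append(cm.reactions.get_by_id(r.id))
    cm.add_groups([cobra.core.Group(name, name=name, members=members, kind="partonomy")
                   for name, members in subsystems.items()])
    return cm


def _from_cobra(cm) -> MetabolicModel:
    group_subsystem: dict[str, str] = {}
    for group in getattr(cm, "groups", []):
        for member in group.members:
            group_subsystem[member.id] = group.name or group.id
    reactions = []
    for cr in cm.reactions:
        enz = None
        if "difflux_kcat" in cr.notes:
            enz = Enzyme(float(cr.notes["difflux_kcat"]), float(cr.notes["difflux_mw"]))
        rule = cr.gene_reaction_rule
        reactions.append(Reaction(
            id=cr.id,
            stoichiometry={m.id: float(c) for m, c in cr.metabolites.items()},
            lower_bound=_clamp_bound(cr.lower_bound, cr.id, "lb"),
            upper_bound=_clamp_bound(cr.upper_bound, cr.id, "ub"),
            gpr=parse_gpr(rule) if rule else None,
            subsystem=group_subsystem.get(cr.id) or cr.subsystem or "exchange",
            enzyme=enz,
        ))
    pool = cm.notes.get("difflux_enzyme_pool")
    return MetabolicModel(
        model_id=cm.id or "model",
        metabolites=[m.id for m in cm.metabolites],
        reactions=reactions,
        genes=sorted(g.id for g in cm.genes),
        enzyme_pool=float(pool) if pool is not None else None,
    )


# ---------------------------------------------------------------------------
# public I/O
# ---------------------------------------------------------------------------

def read_model(path: str | Path, format: str = None) -> MetabolicModel:
    """Read a model from JSON (native dialect) or SBML L3+FBC.

    The format is inferred from the suffix when not given (.json / .xml|.sbml).
    """
    path = Path(path)
    fmt = format or ("sbml" if path.suffix.lower() in (".xml", ".sbml") else "json")
    if fmt == "json":
        with open(path) as fh:
            return _model_from_dict(json.load(fh))
    if fmt == "sbml":
        import cobra.io

        return _from_cobra(cobra.io.read_sbml_model(str(path)))
    raise ValueError(f"unsupported model format {fmt!r} (expected 'json' or 'sbml')")


def write_model(model: MetabolicModel, path: str | Path, format: str = None) -> Path:
    """Write a model; inverse of :func:`read_model` for both formats."""
    path = Path(path)
    fmt = format or ("sbml" if path.suffix.lower() in (".xml", ".sbml") else "json")
    if fmt == "json":
        with open(path, "w") as fh:
            json.dump(_model_to_dict(model), fh, indent=1, sort_keys=True)
            fh.write("\n")
    elif fmt == "sbml":
        import cobra.io

        cobra.io.write_sbml_model(_to_cobra(model), str(path))
    else:
        raise ValueError(f"unsupported model format {fmt!r} (expected 'json' or 'sbml')")
    return path


# ---------------------------------------------------------------------------
# GECKO-style enzyme augmentation
# ---------------------------------------------------------------------------

def apply_enzyme_constraints(model: MetabolicModel) -> MetabolicModel:
    """Augment a model with enzyme-usage variables and a shared protein pool.

    For each enzymatic reaction j (reversible reactions are first split into
    irreversible forward/backward halves sharing one enzyme) the reaction
    consumes an enzyme pseudo-metabolite at rate 1/kcat_j, a draw reaction
    converts pool mass into that enzyme at cost mw_j, and a single pool
    exchange bounded by ``enzyme_pool`` supplies all draws. At steady state
    this enforces v_j ≤ kcat_j·u_j and Σ_j mw_j·u_j ≤ pool — the canonical
    GECKO coupling — purely through stoichiometry and bounds, so downstream
    FBA/FVA needs no special casing. Models without enzyme annotations are
    returned unchanged (a copy).
    """
    if not model.has_enzyme_data():
        return model.copy()
    if model.enzyme_pool is None:
        raise ValueError("model has enzyme-annotated reactions but no enzyme_pool")

    metabolites = list(model.metabolites) + ["prot_pool"]
    reactions: list[Reaction] = []
    aug = EnzymeAugmentation(original_reactions=model.reaction_ids)

    for r in model.reactions:
        if r.enzyme is None:
            reactions.append(r.copy())
            continue
        prot = f"prot_{r.id}"
        metabolites.append(prot)
        inv_kcat = 1.0 / r.enzyme.kcat
        if r.reversible:
            fwd_id, rev_id = f"{r.id}__fwd", f"{r.id}__rev"
            fwd = Reaction(fwd_id, {**r.stoichiometry, prot: -inv_kcat},
                           max(r.lower_bound, 0.0), max(r.upper_bound, 0.0),
                           r.gpr, r.subsystem, r.enzyme)
            rev = Reaction(rev_id,
                           {**{m: -c for m, c in r.stoichiometry.items()}, prot: -inv_kcat},
                           0.0, -r.lower_bound, r.gpr, r.subsystem, r.enzyme)
            reactions.extend([fwd, rev])
            aug.split_pairs[r.id] = (fwd_id, rev_id)
        else:
            reactions.append(Reaction(r.id, {**r.stoichiometry, prot: -inv_kcat},
                                      r.lower_bound, r.upper_bound,
                                      r.gpr, r.subsystem, r.enzyme))
        draw_id = f"draw_prot_{r.id}"
        reactions.append(Reaction(draw_id, {"prot_pool": -r.enzyme.mw, prot: 1.0},
                                  0.0, BOUND_CAP, None, "enzyme_usage", None))
        aug.usage_reactions[r.id] = draw_id

    reactions.append(Reaction(aug.pool_exchange, {"prot_pool": 1.0},
                              0.0, float(model.enzyme_pool), None, "enzyme_usage", None))
    return MetabolicModel(f"{model.model_id}_ec", metabolites, reactions,
                          list(model.genes), model.enzyme_pool, aug)
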
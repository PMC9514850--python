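"""Flux balance analysis (FBA) and flux variability analysis (FVA).

Both operate on the steady-state flux polytope {v : S·v = 0, lb ≤ v ≤ ub}
of a :class:`~difflux.model.MetabolicModel`. FVA solves two LPs per
reaction (minimise and maximise its flux), optionally after pinning an
objective reaction to a fraction of its FBA optimum. LPs are solved with
the HiGHS solvers behind :func:`scipy.optimize.linprog`; any solver meeting
the default 1e-6 feasibility tolerance is interchangeable here.

For an enzyme-augmented model (see
:func:`~difflux.model.apply_enzyme_constraints`) results are reported for
the parent model's reaction ids, with split reversible pairs re-merged as
net flux (forward − backward).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np
from scipy.optimize import linprog

from .model import MetabolicModel

__all__ = ["FVAResult", "InfeasibleModelError", "SolverError", "fba", "fva"]

#: LP feasibility/optimality tolerance; fluxes below SNAP_TOL are reported as 0.
LP_TOL = 1e-6
SNAP_TOL = 1e-9


class InfeasibleModelError(RuntimeError):
    """The model's constraints admit no steady-state flux distribution."""


class SolverError(RuntimeError):
    """The LP solver failed for a reason other than infeasibility."""


@dataclass
class FVAResult:
    """Per-reaction flux ranges: ``bounds[rid] = (min_flux, max_flux)``."""

    bounds: dict[str, tuple[float, float]]
    status: dict[str, str] = field(default_factory=dict)
    tolerance: float = LP_TOL

    def min(self, rid: str) -> float:
        return self.bounds[rid][0]

    def max(self, rid: str) -> float:
        return self.bounds[rid][1]

    def max_fluxes(self) -> dict[str, float]:
        return {rid: mx for rid, (_, mx) in self.bounds.items()}


class _LP:
    """Cached LP data for one model: stoichiometric matrix and bounds."""

    def __init__(self, model: MetabolicModel):
        self.model = model
        self.rxn_ids = model.reaction_ids
        self.idx = {rid: j for j, rid in enumerate(self.rxn_ids)}
        met_idx = {m: i for i, m in enumerate(model.metabolites)}
        S = np.zeros((len(model.metabolites), len(model.reactions)))
        for j, rxn in enumerate(model.reactions):
            for met, coef in rxn.stoichiometry.items():
                S[met_idx[met], j] = coef
        self.S = S
        self.lb = np.array([r.lower_bound for r in model.reactions])
        self.ub = np.array([r.upper_bound for r in model.reactions])
        self.extra_A: list[np.ndarray] = []  # rows of A_ub
        self.extra_b: list[float] = []

    def objective_vector(self, objective: str | Mapping[str, float]) -> np.ndarray:
        """Build c from a reaction id (net flux for split pairs) or a coef map."""
        c = np.zeros(len(self.rxn_ids))
        aug = self.model.augmentation
        if isinstance(objective, str):
            objective = {objective: 1.0}
        for rid, coef in objective.items():
            if aug is not None and rid in aug.split_pairs:
                fwd, rev = aug.split_pairs[rid]
                c[self.idx[fwd]] += coef
                c[self.idx[rev]] -= coef
            elif rid in self.idx:
                c[self.idx[rid]] += coef
            else:
                raise KeyError(f"unknown reaction id {rid!r}")
        return c

    def add_constraint(self, row: np.ndarray, rhs: float) -> None:
        self.extra_A.append(row)
        self.extra_b.append(rhs)

    def solve(self, c: np.ndarray, maximize: bool) -> tuple[float, np.ndarray]:
        sign = -1.0 if maximize else 1.0
        A_ub = np.vstack(self.extra_A) if self.extra_A else None
        b_ub = np.array(self.extra_b) if self.extra_A else None
        res = linprog(sign * c, A_ub=A_ub, b_ub=b_ub, A_eq=self.S,
                      b_eq=np.zeros(self.S.shape[0]),
                      bounds=list(zip(self.lb, self.ub)), method="highs")
        if res.status == 2:
            raise InfeasibleModelError("model is infeasible under the given constraints")
        if not res.success:
            raise SolverError(f"LP solver failed (status {res.status}): {res.message}")
        return sign * res.fun, res.x


def _net_fluxes(model: MetabolicModel, x: np.ndarray, idx: dict[str, int]) -> dict[str, float]:
    aug = model.augmentation
    originals = aug.original_reactions if aug is not None else model.reaction_ids
    out = {}
    for rid in originals:
        if aug is not None and rid in aug.split_pairs:
            fwd, rev = aug.split_pairs[rid]
            v = x[idx[fwd]] - x[idx[rev]]
        else:
            v = x[idx[rid]]
        out[rid] = 0.0 if abs(v) < SNAP_TOL else float(v)
    return out


def fba(model: MetabolicModel, objective: str | Mapping[str, float],
        direction: str = "max") -> tuple[float, dict[str, float]]:
    """Optimise one flux (or a linear combination) over the feasible polytope.

    Returns the optimum and a flux vector attaining it, keyed by the parent
    model's reaction ids (net fluxes for split reversible pairs).
    """
    if direction not in ("max", "min"):
        raise ValueError("direction must be 'max' or 'min'")
    lp = _LP(model)
    value, x = lp.solve(lp.objective_vector(objective), maximize=direction == "max")
    if abs(value) < SNAP_TOL:
        value = 0.0
    return float(value), _net_fluxes(model, x, lp.idx)


def fva(model: MetabolicModel, reactions: Optional[Iterable[str]] = None,
        fraction_of_optimum: float = 0.0,
        objective_reaction: Optional[str] = None) -> FVAResult:
    """Min and max flux of each reaction over the steady-state polytope.

    With ``fraction_of_optimum`` f > 0 the polytope is first intersected with
    {objective ≥ f × FBA optimum}; by default no objective cut is applied
    (pure feasibility FVA). Exactly two LPs are solved per requested
    reaction. For enzyme-augmented models the requested ids are the parent
    model's and ranges are net-flux ranges.
    """
    if not 0.0 <= fraction_of_optimum <= 1.0:
        raise ValueError("fraction_of_optimum must lie in [0, 1]")
    if fraction_of_optimum > 0 and objective_reaction is None:
        raise ValueError("fraction_of_optimum > 0 requires an objective_reaction")

    aug = model.augmentation
    if reactions is None:
        reactions = aug.original_reactions if aug is not None else model.reaction_ids
    reactions = list(reactions)

    lp = _LP(model)
    if fraction_of_optimum > 0:
        c_obj = lp.objective_vector(objective_reaction)
        try:
            opt, _ = lp.solve(c_obj, maximize=True)
        except InfeasibleModelError:
            raise InfeasibleModelError("base model infeasible (before optimality cut)")
        lp.add_constraint(-c_obj, -fraction_of_optimum * opt)

    bounds: dict[str, tuple[float, float]] = {}
    status: dict[str, str] = {}
    for rid in reactions:
        c = lp.objective_vector(rid)
        try:
            vmin, _ = lp.solve(c, maximize=False)
            vmax, _ = lp.solve(c, maximize=True)
        except InfeasibleModelError:
            raise InfeasibleModelError(
                f"model infeasible while scanning reaction {rid!r}"
                + (" (after optimality cut)" if fraction_of_optimum > 0 else ""))
        vmin = 0.0 if abs(vmin) < SNAP_TOL else float(vmin)
        vmax = 0.0 if abs(vmax) < SNAP_TOL else float(vmax)
        bounds[rid] = (vmin, vmax)
        status[rid] = "optimal"
    return FVAResult(bounds=bounds, status=status, tolerance=LP_TOL)
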
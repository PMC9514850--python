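"""Integration of gene expression fold changes into reaction bounds.

Gene-level fold changes (linear scale, condition vs baseline) are collapsed
to reaction level through each reaction's GPR rule — by default AND → min
(a complex is limited by its scarcest subunit) and OR → max (isozymes
provide alternative capacity) — and the resulting per-reaction scale factor
multiplies the reaction's flux bounds, producing the condition-specific
model. Genes with missing (NaN) fold change are treated as unperturbed:
they are dropped from their operator's operand list, and a reaction whose
GPR genes are all missing keeps its baseline bounds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional

import numpy as np
import pandas as pd

from .gpr import GPRNode, evaluate_gpr, gpr_genes
from .model import BOUND_CAP, MetabolicModel

__all__ = ["ExpressionTable", "ReactionFoldChanges", "GPR_OPERATORS",
           "read_expression_table", "write_expression_table",
           "reaction_fold_change", "reaction_fold_changes", "constrain_bounds"]

#: Named collapse operators accepted for and_op / or_op.
GPR_OPERATORS: dict[str, Callable[[list[float]], float]] = {
    "min": min, "max": max, "mean": lambda xs: sum(xs) / len(xs), "sum": sum,
}


@dataclass
class ExpressionTable:
    """Gene id → linear-scale fold change (> 0); absent genes are unperturbed."""

    entries: dict[str, float]

    def __post_init__(self):
        bad = {g: f for g, f in self.entries.items()
               if not math.isfinite(f) or f <= 0}
        if bad:
            raise ValueError(f"fold changes must be finite and > 0: {bad}")

    def get(self, gene: str) -> Optional[float]:
        return self.entries.get(gene)

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class ReactionFoldChanges:
    """Reaction id → collapsed fold change, with contributing genes."""

    values: dict[str, float]
    provenance: dict[str, list[str]] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "reaction_id": list(self.values),
            "fold_change": list(self.values.values()),
            "contributing_genes": [",".join(self.provenance.get(r, [])) for r in self.values],
        })


def read_expression_table(path: str | Path) -> ExpressionTable:
    """Read a TSV with columns ``gene_id`` and ``fold_change``.

    ``fold_change`` is numeric or the literal NaN; NaN rows are stored as
    missing (unperturbed genes). Duplicate gene ids and non-positive fold
    changes are rejected.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"gene_id": str})
    required = {"gene_id", "fold_change"}
    if not required.issubset(df.columns):
        raise ValueError(f"expression table must have columns {sorted(required)}, "
                         f"got {list(df.columns)}")
    if df["gene_id"].duplicated().any():
        dupes = sorted(df.loc[df["gene_id"].duplicated(), "gene_id"].unique())
        raise ValueError(f"duplicate gene ids in expression table: {dupes}")
    fc = pd.to_numeric(df["fold_change"], errors="coerce")
    bad_text = df.loc[fc.isna() & df["fold_change"].notna()
                      & (df["fold_change"].astype(str).str.lower() != "nan"), "gene_id"]
    if len(bad_text):
        raise ValueError(f"non-numeric fold changes for genes: {sorted(bad_text)}")
    present = fc.notna()
    if (fc[present] <= 0).any():
        bad = sorted(df.loc[present & (fc <= 0), "gene_id"])
        raise ValueError(f"fold changes must be strictly positive (linear scale): {bad}")
    return ExpressionTable({g: float(f) for g, f in zip(df["gene_id"][present], fc[present])})


def write_expression_table(table: ExpressionTable, path: str | Path,
                           all_genes: Optional[list[str]] = None) -> Path:
    """Write the TSV read by :func:`read_expression_table`; genes in
    ``all_genes`` but absent from the table are emitted with NaN."""
    genes = list(all_genes) if all_genes is not None else list(table.entries)
    rows = [(g, table.entries.get(g, float("nan"))) for g in genes]
    pd.DataFrame(rows, columns=["gene_id", "fold_change"]).to_csv(
        path, sep="\t", index=False, na_rep="NaN")
    return Path(path)


def _resolve_op(op) -> Callable[[list[float]], float]:
    if callable(op):
        return op
    try:
        return GPR_OPERATORS[op]
    except KeyError:
        raise ValueError(f"unknown GPR operator {op!r}; expected one of {sorted(GPR_OPERATORS)}")


def reaction_fold_change(gpr: GPRNode, expr: ExpressionTable,
                         and_op="min", or_op="max") -> Optional[float]:
    """Collapse one GPR over the expression table; None if all genes missing."""
    return evaluate_gpr(gpr, expr.entries, _resolve_op(and_op), _resolve_op(or_op))


def reaction_fold_changes(model: MetabolicModel, expr: ExpressionTable,
                          and_op="min", or_op="max") -> ReactionFoldChanges:
    """Collapse every reaction's GPR; reactions without a GPR, or whose
    genes are all missing, are absent from the result (unperturbed)."""
    values, provenance = {}, {}
    for rxn in model.reactions:
        if rxn.gpr is None:
            continue
        f = reaction_fold_change(rxn.gpr, expr, and_op, or_op)
        if f is None:
            continue
        values[rxn.id] = f
        provenance[rxn.id] = sorted(g for g in gpr_genes(rxn.gpr) if expr.get(g) is not None)
    return ReactionFoldChanges(values, provenance)


def constrain_bounds(model: MetabolicModel, rfc: ReactionFoldChanges,
                     scale_cap: float = 64.0) -> MetabolicModel:
    """Scale reaction bounds by their expression fold change.

    For a reaction with fold change f, the scale is s = clip(f, 1/scale_cap,
    scale_cap); the upper bound is multiplied by s when positive and the
    lower bound when negative (so a reversible span shrinks or grows
    symmetrically); zero bounds and fold-change-free reactions are left
    untouched. Scaled bounds are clamped to the global magnitude cap.
    The enzyme layer (kcat, mw, pool) is never rescaled.
    """
    if scale_cap < 1:
        raise ValueError("scale_cap must be >= 1")
    known = set(model.reaction_ids)
    unknown = set(rfc.values) - known
    if unknown:
        raise ValueError(f"fold changes reference unknown reactions: {sorted(unknown)}")
    out = model.copy()
    out.model_id = f"{model.model_id}_condition"
    for rxn in out.reactions:
        f = rfc.values.get(rxn.id)
        if f is None:
            continue
        s = float(np.clip(f, 1.0 / scale_cap, scale_cap))
        if rxn.upper_bound > 0:
            rxn.upper_bound = min(rxn.upper_bound * s, BOUND_CAP)
        if rxn.lower_bound < 0:
            rxn.lower_bound = max(rxn.lower_bound * s, -BOUND_CAP)
    out.validate()
    return out
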
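"""Hypergeometric over-representation of dysregulated reactions in pathways.

Given the classification produced by :mod:`difflux.differential`, each
pathway (subsystem) is tested for an excess of up- (or down-) regulated
reactions among its members with a one-sided hypergeometric test: the
universe is the set of reactions with a valid flux fold change, draws are
the pathway members, successes are the labelled reactions, and the p-value
is the upper tail P(X ≥ k). p-values are Benjamini–Hochberg adjusted within
each direction's family of pathways (a pooled two-direction family is
available as an option).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .differential import ReactionDelta

__all__ = ["PathwayEnrichmentRecord", "hypergeom_upper_tail", "bh_adjust",
           "pathway_enrichment", "pathway_enrichment_all", "enrichment_to_frame"]


@dataclass
class PathwayEnrichmentRecord:
    subsystem: str
    direction: str          # "up" or "down"
    universe_size: int      # N: valid reactions
    pathway_size: int       # K: valid reactions in the pathway
    hits_total: int         # n: labelled reactions overall
    hits_in_pathway: int    # k
    p_value: float
    q_value: float = np.nan


def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """P(X ≥ k) for X ~ Hypergeometric(N, K, n).

    N population size, K marked items, n draws without replacement, k
    observed marked draws.
    """
    for name, v in (("N", N), ("K", K), ("n", n), ("k", k)):
        if int(v) != v or v < 0:
            raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
    if not (K <= N and n <= N and k <= min(K, n)):
        raise ValueError(f"inconsistent counts: need k <= min(K, n) and K, n <= N, "
                         f"got N={N}, K={K}, n={n}, k={k}")
    return float(hypergeom.sf(k - 1, N, K, n))


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def pathway_enrichment(deltas: Sequence[ReactionDelta],
                       subsystem_map: Mapping[str, str],
                       direction: str,
                       adjust: bool = True) -> list[PathwayEnrichmentRecord]:
    """One-sided over-representation test of ``direction``-labelled reactions
    per subsystem, BH-adjusted across the subsystems of that direction.

    Records are sorted by (q, p). Requires classification to have been run.
    With ``adjust=False`` the q-values are left unset (used by
    :func:`pathway_enrichment_all` when pooling both directions into one
    BH family).
    """
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    valid = [d for d in deltas if d.valid]
    if not valid:
        raise ValueError("no valid reactions to test")
    N = len(valid)
    hits = {d.reaction_id for d in valid if d.label == direction}
    n = len(hits)
    pathways: dict[str, list[str]] = {}
    for d in valid:
        subsystem = subsystem_map.get(d.reaction_id)
        if subsystem is None:
            raise ValueError(f"reaction {d.reaction_id!r} missing from subsystem map")
        pathways.setdefault(subsystem, []).append(d.reaction_id)
    records = []
    for subsystem in sorted(pathways):
        member_ids = pathways[subsystem]
        K = len(member_ids)
        k = sum(1 for rid in member_ids if rid in hits)
        p = hypergeom_upper_tail(N, K, n, k)
        records.append(PathwayEnrichmentRecord(subsystem, direction, N, K, n, k, p))
    if adjust:
        q = bh_adjust([r.p_value for r in records])
        for rec, qv in zip(records, q):
            rec.q_value = float(qv)
        records.sort(key=lambda r: (r.q_value, r.p_value, r.subsystem))
    return records


def pathway_enrichment_all(deltas: Sequence[ReactionDelta],
                           subsystem_map: Mapping[str, str],
                           directions: Sequence[str] = ("up", "down"),
                           family: str = "separate") -> list[PathwayEnrichmentRecord]:
    """Enrichment for several directions with a configurable BH family.

    ``family='separate'`` (default) adjusts within each direction;
    ``family='pooled'`` adjusts once across all direction × pathway tests.
    """
    if family not in ("separate", "pooled"):
        raise ValueError("family must be 'separate' or 'pooled'")
    if family == "separate":
        out: list[PathwayEnrichmentRecord] = []
        for direction in directions:
            out.extend(pathway_enrichment(deltas, subsystem_map, direction))
        return out
    records: list[PathwayEnrichmentRecord] = []
    for direction in directions:
        records.extend(pathway_enrichment(deltas, subsystem_map, direction, adjust=False))
    q = bh_adjust([r.p_value for r in records])
    for rec, qv in zip(records, q):
        rec.q_value = float(qv)
    records.sort(key=lambda r: (r.q_value, r.p_value, r.direction, r.subsystem))
    return records


def enrichment_to_frame(records: Sequence[PathwayEnrichmentRecord]) -> pd.DataFrame:
    return pd.DataFrame([{
        "subsystem": r.subsystem,
        "direction": r.direction,
        "N": r.universe_size,
        "K": r.pathway_size,
        "n": r.hits_total,
        "k": r.hits_in_pathway,
        "p_value": r.p_value,
        "q_value": r.q_value,
    } for r in records])
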
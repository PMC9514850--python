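"""Per-reaction flux fold change and up/down classification.

The differential statistic compares, reaction by reaction, the maximum
feasible flux of a condition-specific model against the baseline model:

    ffc = (MaxFlux_condition + 1) / (MaxFlux_baseline + 1)

The +1 pseudo-flux guards the 0/0 case so that two silent reactions give
ffc = 1 (log2 = 0). A corrected term ≤ 0 (MaxFlux ≤ −1, a strongly
reverse-operating reaction) leaves the ratio outside the log2 domain; such
reactions are flagged ``invalid`` and excluded from classification rather
than silently transformed.

A reaction is called *up* when its log2 ffc both exceeds an absolute
threshold (default 1.0) and lies above a high percentile of the observed
log2 ffc distribution (default the 95th); *down* symmetrically with
defaults −0.1 and the 5th percentile. The dual criterion means at most ~5%
of reactions can be called in each direction regardless of the effect
sizes. Percentiles use linear interpolation between closest ranks and the
threshold comparisons are strict.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["ReactionDelta", "ClassificationConfig", "PathwayDelta",
           "flux_fold_change", "build_deltas", "classify_reactions",
           "pathway_flux_change", "deltas_to_frame", "pathways_to_frame"]

UP, DOWN, UNCHANGED, INVALID = "up", "down", "unchanged", "invalid"

_AGGREGATORS = {"mean": np.mean, "median": np.median, "sum": np.sum}


@dataclass
class ReactionDelta:
    reaction_id: str
    max_flux_condition: float
    max_flux_baseline: float
    ffc: float = math.nan
    log2_ffc: float = math.nan
    label: str = UNCHANGED

    @property
    def valid(self) -> bool:
        return self.label != INVALID


@dataclass(frozen=True)
class ClassificationConfig:
    up_log2_threshold: float = 1.0
    up_percentile: float = 95.0
    down_log2_threshold: float = -0.1
    down_percentile: float = 5.0

    def __post_init__(self):
        if not 0 <= self.down_percentile < self.up_percentile <= 100:
            raise ValueError("require 0 <= down_percentile < up_percentile <= 100")


@dataclass
class PathwayDelta:
    subsystem: str
    aggregate_log2_ffc: float
    aggregator: str
    member_reactions: list[str] = field(default_factory=list)


def flux_fold_change(max_flux_condition: float,
                     max_flux_baseline: float) -> tuple[float, float, bool]:
    """Return (ffc, log2_ffc, valid) for one reaction's pair of max fluxes."""
    if not (math.isfinite(max_flux_condition) and math.isfinite(max_flux_baseline)):
        raise ValueError("max fluxes must be finite")
    num = max_flux_condition + 1.0
    den = max_flux_baseline + 1.0
    if num <= 0 or den <= 0:
        return math.nan, math.nan, False
    ffc = num / den
    return ffc, math.log2(ffc), True


def build_deltas(condition_max: Mapping[str, float],
                 baseline_max: Mapping[str, float]) -> list[ReactionDelta]:
    """Pair condition/baseline FVA maxima into :class:`ReactionDelta` records.

    The two maps must cover the same reactions.
    """
    if set(condition_max) != set(baseline_max):
        diff = set(condition_max) ^ set(baseline_max)
        raise ValueError(f"condition and baseline cover different reactions: {sorted(diff)[:5]}")
    deltas = []
    for rid in condition_max:
        c, b = condition_max[rid], baseline_max[rid]
        ffc, log2_ffc, valid = flux_fold_change(c, b)
        deltas.append(ReactionDelta(rid, c, b, ffc, log2_ffc,
                                    UNCHANGED if valid else INVALID))
    return deltas


def classify_reactions(deltas: Sequence[ReactionDelta],
                       cfg: ClassificationConfig = ClassificationConfig()) -> list[ReactionDelta]:
    """Label each valid delta up/down/unchanged by the dual threshold +
    percentile criterion; invalid deltas are excluded from the percentile
    computation and never labelled. Labels are set in place and the list
    returned for convenience."""
    valid = [d for d in deltas if d.valid]
    if len(valid) < 2:
        raise ValueError(f"need >= 2 valid deltas to form a percentile distribution, got {len(valid)}")
    values = np.array([d.log2_ffc for d in valid])
    hi = np.percentile(values, cfg.up_percentile)
    lo = np.percentile(values, cfg.down_percentile)
    for d in valid:
        if d.log2_ffc > cfg.up_log2_threshold and d.log2_ffc > hi:
            d.label = UP
        elif d.log2_ffc < cfg.down_log2_threshold and d.log2_ffc < lo:
            d.label = DOWN
        else:
            d.label = UNCHANGED
    return list(deltas)


def pathway_flux_change(deltas: Sequence[ReactionDelta],
                        subsystem_map: Mapping[str, str],
                        aggregator: str = "mean") -> list[PathwayDelta]:
    """Aggregate valid member log2 ffc per subsystem (mean by default).

    Pathways whose members are all invalid are omitted with a logged note.
    """
    if not subsystem_map:
        raise ValueError("empty subsystem map")
    if aggregator not in _AGGREGATORS:
        raise ValueError(f"unknown aggregator {aggregator!r}; expected one of {sorted(_AGGREGATORS)}")
    agg = _AGGREGATORS[aggregator]
    members: dict[str, list[ReactionDelta]] = {}
    for d in deltas:
        try:
            subsystem = subsystem_map[d.reaction_id]
        except KeyError:
            raise ValueError(f"reaction {d.reaction_id!r} missing from subsystem map") from None
        members.setdefault(subsystem, []).append(d)
    out = []
    for subsystem in sorted(members):
        valid = [d for d in members[subsystem] if d.valid]
        if not valid:
            logger.info("pathway %s omitted: no valid flux fold changes", subsystem)
            continue
        out.append(PathwayDelta(subsystem, float(agg([d.log2_ffc for d in valid])),
                                aggregator, [d.reaction_id for d in valid]))
    return out


def deltas_to_frame(deltas: Sequence[ReactionDelta],
                    subsystem_map: Optional[Mapping[str, str]] = None) -> pd.DataFrame:
    rows = []
    for d in deltas:
        rows.append({
            "reaction_id": d.reaction_id,
            "subsystem": subsystem_map.get(d.reaction_id, "") if subsystem_map else "",
            "max_flux_baseline": d.max_flux_baseline,
            "max_flux_condition": d.max_flux_condition,
            "ffc": d.ffc,
            "log2_ffc": d.log2_ffc,
            "label": d.label,
        })
    return pd.DataFrame(rows)


def pathways_to_frame(pathways: Sequence[PathwayDelta]) -> pd.DataFrame:
    return pd.DataFrame([{
        "subsystem": p.subsystem,
        "n_reactions": len(p.member_reactions),
        "aggregate_log2_ffc": p.aggregate_log2_ffc,
        "aggregator": p.aggregator,
    } for p in pathways])
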
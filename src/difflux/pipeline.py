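"""End-to-end orchestration: model → condition constraints → FVA ×2 →
flux fold change → classification → pathway enrichment (→ optional promoter
signal test), with every table written to an output directory.

The baseline is by default the unconstrained base model; a baseline
expression table may be supplied to constrain it the same way as the
condition. Outputs are deterministic functions of the configuration and
seed (no timestamps), so re-running a configuration reproduces the tables
byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import __version__
from .differential import (ClassificationConfig, build_deltas, classify_reactions,
                           deltas_to_frame, pathway_flux_change, pathways_to_frame)
from .enrichment import enrichment_to_frame, pathway_enrichment_all
from .expression import (ExpressionTable, constrain_bounds, read_expression_table,
                         reaction_fold_changes)
from .fva import fva
from .model import MetabolicModel, apply_enzyme_constraints, read_model
from .tfbs import (TFBSSignalMatrix, binding_heatmap_table, read_signal_track,
                   tfbs_overrepresentation)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunReport", "run_pipeline", "load_config"]


@dataclass
class RunConfig:
    model_path: str
    condition_expression: str
    output_dir: str
    model_format: Optional[str] = None          # inferred from suffix when None
    baseline_expression: Optional[str] = None   # None -> unconstrained baseline
    and_op: str = "min"
    or_op: str = "max"
    scale_cap: float = 64.0
    use_enzyme_constraints: bool = True         # applied when the model has a layer
    fraction_of_optimum: float = 0.0
    objective_reaction: Optional[str] = None
    classification: ClassificationConfig = field(default_factory=ClassificationConfig)
    pathway_aggregator: str = "mean"
    enrichment_directions: tuple[str, ...] = ("up", "down")
    fdr_family: str = "separate"                # or "pooled"
    tfbs_tracks: Optional[str] = None           # directory of track TSVs, optional stage
    tfbs_gene_list: Optional[str] = None        # text file, one gene per line
    tfbs_B: int = 1000
    tfbs_alpha: float = 5.0e-2
    seed: int = 0
    log_level: str = "INFO"

    def validate_paths(self) -> None:
        missing = [p for p in (self.model_path, self.condition_expression,
                               self.baseline_expression, self.tfbs_tracks,
                               self.tfbs_gene_list)
                   if p is not None and not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"configured paths do not exist: {missing}")

    def config_hash(self) -> str:
        """Hash of the analysis parameters (not output location or logging)."""
        payload = dataclasses.asdict(self)
        payload.pop("output_dir")
        payload.pop("log_level")
        return hashlib.sha256(json.dumps(payload, sort_keys=True,
                                         default=str).encode()).hexdigest()[:12]


@dataclass
class RunReport:
    tables: dict[str, Path]
    n_reactions: int
    n_valid: int
    n_up: int
    n_down: int
    n_invalid: int
    significant_pathways: dict[str, int]  # direction -> count at q < 0.05


def load_config(path: str | Path) -> RunConfig:
    """Load a RunConfig from a YAML mapping (keys = field names)."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if "classification" in data and isinstance(data["classification"], dict):
        data["classification"] = ClassificationConfig(**data["classification"])
    if "enrichment_directions" in data:
        data["enrichment_directions"] = tuple(data["enrichment_directions"])
    return RunConfig(**data)


def _write_table(df: pd.DataFrame, path: Path, cfg: RunConfig) -> Path:
    with open(path, "w") as fh:
        fh.write(f"# difflux {__version__} config_hash={cfg.config_hash()} seed={cfg.seed}\n")
        df.to_csv(fh, sep="\t", index=False, na_rep="NaN")
    return path


def run_pipeline(cfg: RunConfig) -> RunReport:
    """Run the full differential-flux analysis described in the module
    docstring and return a report of written tables and summary counts."""
    logging.basicConfig(level=cfg.log_level)
    cfg.validate_paths()
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    def stage(name):
        logger.info("stage: %s", name)

    stage("load model")
    model = read_model(cfg.model_path, cfg.model_format)

    stage("constrain condition model")
    condition_expr = read_expression_table(cfg.condition_expression)
    rfc = reaction_fold_changes(model, condition_expr, cfg.and_op, cfg.or_op)
    condition = constrain_bounds(model, rfc, cfg.scale_cap)

    baseline = model
    if cfg.baseline_expression is not None:
        stage("constrain baseline model")
        rfc_base = reaction_fold_changes(model, read_expression_table(cfg.baseline_expression),
                                         cfg.and_op, cfg.or_op)
        baseline = constrain_bounds(model, rfc_base, cfg.scale_cap)

    if cfg.use_enzyme_constraints and model.has_enzyme_data():
        stage("apply enzyme constraints")
        condition = apply_enzyme_constraints(condition)
        baseline = apply_enzyme_constraints(baseline)

    stage("flux variability analysis")
    fva_kwargs = dict(fraction_of_optimum=cfg.fraction_of_optimum,
                      objective_reaction=cfg.objective_reaction)
    fva_condition = fva(condition, **fva_kwargs)
    fva_baseline = fva(baseline, **fva_kwargs)

    stage("flux fold changes and classification")
    deltas = build_deltas(fva_condition.max_fluxes(), fva_baseline.max_fluxes())
    classify_reactions(deltas, cfg.classification)
    subsystems = model.subsystem_map()

    stage("pathway aggregation and enrichment")
    pathways = pathway_flux_change(deltas, subsystems, cfg.pathway_aggregator)
    records = pathway_enrichment_all(deltas, subsystems, cfg.enrichment_directions,
                                     cfg.fdr_family)

    tables = {
        "reaction_deltas": _write_table(deltas_to_frame(deltas, subsystems),
                                        outdir / "reaction_deltas.tsv", cfg),
        "pathway_deltas": _write_table(pathways_to_frame(pathways),
                                       outdir / "pathway_deltas.tsv", cfg),
        "enrichment": _write_table(enrichment_to_frame(records),
                                   outdir / "pathway_enrichment.tsv", cfg),
        "reaction_fold_changes": _write_table(rfc.to_frame(),
                                              outdir / "reaction_fold_changes.tsv", cfg),
    }

    if cfg.tfbs_tracks is not None:
        stage("promoter signal overrepresentation")
        if cfg.tfbs_gene_list is None:
            raise ValueError("tfbs_tracks given without tfbs_gene_list")
        matrix = _load_tracks(Path(cfg.tfbs_tracks))
        gene_list = [line.strip() for line in open(cfg.tfbs_gene_list)
                     if line.strip() and not line.startswith("#")]
        results = tfbs_overrepresentation(matrix, gene_list, B=cfg.tfbs_B, seed=cfg.seed)
        res_df = pd.DataFrame([{
            "tf": r.tf, "list_size": r.list_size, "statistic": r.statistic,
            "background_mean": r.background_mean, "p_empirical": r.p_empirical,
            "p_bonferroni": r.p_bonferroni, "n_resamples": r.n_resamples,
        } for r in results])
        tables["tfbs_results"] = _write_table(res_df, outdir / "tfbs_results.tsv", cfg)
        tables["tfbs_heatmap"] = _write_table(binding_heatmap_table(results, cfg.tfbs_alpha),
                                              outdir / "tfbs_heatmap.tsv", cfg)

    sig = {}
    for direction in cfg.enrichment_directions:
        sig[direction] = sum(1 for r in records
                             if r.direction == direction and r.q_value < 0.05)
    report = RunReport(
        tables=tables,
        n_reactions=len(deltas),
        n_valid=sum(d.valid for d in deltas),
        n_up=sum(d.label == "up" for d in deltas),
        n_down=sum(d.label == "down" for d in deltas),
        n_invalid=sum(not d.valid for d in deltas),
        significant_pathways=sig,
    )
    summary = {"n_reactions": report.n_reactions, "n_valid": report.n_valid,
               "n_up": report.n_up, "n_down": report.n_down,
               "n_invalid": report.n_invalid,
               "significant_pathways": report.significant_pathways,
               "seed": cfg.seed, "config_hash": cfg.config_hash(),
               "version": __version__}
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
        fh.write("\n")
    tables["summary"] = outdir / "summary.json"
    return report


def _load_tracks(directory: Path) -> TFBSSignalMatrix:
    """Assemble a signal matrix from all ``*.tsv`` track files in a directory
    (track name = file stem); all tracks must share gene order and bins."""
    tracks = {}
    universe = positions = None
    paths = sorted(directory.glob("*.tsv"))
    if not paths:
        raise FileNotFoundError(f"no .tsv tracks found in {directory}")
    for path in paths:
        genes, pos, mat = read_signal_track(path)
        if universe is None:
            universe, positions = genes, pos
        elif genes != universe or len(pos) != len(positions):
            raise ValueError(f"track {path.name} disagrees with the first track's "
                             "gene order or bin count")
        tracks[path.stem] = mat
    return TFBSSignalMatrix(universe=universe, positions=positions, tracks=tracks)
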
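"""End-to-end orchestration: load -> filter -> score -> rank -> export.

``run_pipeline`` executes the whole analysis on an in-memory bundle and is
deterministic given the configured seed; ``run_from_config`` adds file I/O
around it for the CLI.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import data_io, expression_scores, filtering, interaction_scores, sponge
from .data_io import InputBundle
from .errors import ConfigError, EmptyResultError

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All tunable constants of a run; defaults follow the published method."""

    paths: dict[str, str] = field(default_factory=dict)
    enrichmre_alpha: float = 0.05
    affinity_percentile: float = 95.0
    min_clip: int = 2
    min_degradome: int = 2
    mirna_fraction_threshold: float = 0.90
    target_fraction: float = 0.10
    nperm: int = sponge.DEFAULT_NPERM
    seed: int = 0
    weights_sg: list[float] | None = None
    weights_ss: list[float] | None = None
    abs_fc: bool = True
    mrna_cutoff: bool = False
    q1_excludes_zeros: bool = False
    neglog_costs: bool = False

    def __post_init__(self):
        if not 0 < self.enrichmre_alpha < 1:
            raise ConfigError("enrichmre_alpha must lie in (0, 1)")
        if not 0 < self.affinity_percentile <= 100:
            raise ConfigError("affinity_percentile must lie in (0, 100]")
        if not 0 <= self.mirna_fraction_threshold < 1:
            raise ConfigError("mirna_fraction_threshold must lie in [0, 1)")
        if not 0 < self.target_fraction <= 1:
            raise ConfigError("target_fraction must lie in (0, 1]")
        if self.nperm < 1:
            raise ConfigError("nperm must be >= 1")
        if self.seed is None:
            raise ConfigError("a seed is required for reproducibility")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def run_pipeline(
    bundle: InputBundle, cfg: RunConfig | None = None
) -> tuple[pd.DataFrame, dict[str, Any]]:
    """Run the full analysis; returns (score matrix, summary report).

    The summary records every stage's surviving candidate count plus the
    parameters and seed, so a run can be audited and reproduced.
    """
    cfg = cfg or RunConfig()
    t0 = time.perf_counter()
    summary: dict[str, Any] = {"parameters": {k: v for k, v in asdict(cfg).items() if k != "paths"}}
    stages: dict[str, int] = {}
    summary["stages"] = stages

    # -- miRNA sufficiency ------------------------------------------------
    if bundle.mirna_expr is not None:
        result = filtering.filter_mirnas(
            bundle.mirna_expr,
            fraction_threshold=cfg.mirna_fraction_threshold,
            exclude_zero_rows_from_pool=cfg.q1_excludes_zeros,
        )
        kept = result.kept_mirnas
        summary["mirna_cutoff"] = result.cutoff
        mirexpr = expression_scores.compute_mirna_expression_score(bundle.mirna_expr)
        mirexpr = mirexpr[mirexpr.index.isin(kept)]
    else:
        # signatures are pre-filtered by the same sufficiency rule upstream
        kept = set(bundle.mirna_signature.values)
        summary["mirna_cutoff"] = None
        mirexpr = expression_scores.compute_mirna_expression_score(bundle.mirna_signature)
    stages["mirnas_kept"] = len(kept)
    if not kept:
        raise EmptyResultError("mirna_filter")

    # -- interaction scores ----------------------------------------------
    circ_pairs = interaction_scores.collapse_sites(bundle.circ_sites)
    mrna_pairs = interaction_scores.collapse_sites(bundle.mrna_sites)
    stages["circ_pairs_collapsed"] = len(circ_pairs)
    stages["mrna_pairs_collapsed"] = len(mrna_pairs)
    if circ_pairs.empty or mrna_pairs.empty:
        raise EmptyResultError("collapse_sites")

    if bundle.validated is not None:
        cutoff = interaction_scores.calibrate_affinity_cutoff(
            circ_pairs,
            bundle.validated,
            percentile=cfg.affinity_percentile,
            min_clip=cfg.min_clip,
            min_degradome=cfg.min_degradome,
        )
        summary["affinity_cutoff"] = cutoff.cutoff
        summary["n_validated_used"] = cutoff.n_validated_used
        circ_pairs = interaction_scores.apply_affinity_cutoff(circ_pairs, cutoff)
        if cfg.mrna_cutoff:
            mrna_pairs = interaction_scores.apply_affinity_cutoff(mrna_pairs, cutoff)
    else:
        summary["affinity_cutoff"] = None
    stages["circ_pairs_after_cutoff"] = len(circ_pairs)
    stages["mrna_pairs_after_cutoff"] = len(mrna_pairs)
    if circ_pairs.empty or mrna_pairs.empty:
        raise EmptyResultError("affinity_cutoff")

    circ_pairs = interaction_scores.rescale_affinity(circ_pairs)
    mrna_pairs = interaction_scores.rescale_affinity(mrna_pairs)
    circ_pairs = interaction_scores.normalize_mre_counts(circ_pairs, bundle.circ_lengths)
    mrna_pairs = interaction_scores.normalize_mre_counts(mrna_pairs)

    _, circ_pairs = interaction_scores.test_mre_enrichment(
        circ_pairs, alpha=cfg.enrichmre_alpha
    )
    stages["circ_pairs_enriched"] = len(circ_pairs)
    if circ_pairs.empty:
        raise EmptyResultError("mre_enrichment")

    # -- expression scores ------------------------------------------------
    fc_circ = expression_scores.compute_fold_change(bundle.circ_expr, bundle.annotation)
    fc_mrna = expression_scores.compute_fold_change(bundle.mrna_expr, bundle.annotation)
    targetexpr_circ = expression_scores.compute_target_expression_score(
        bundle.circ_expr, bundle.annotation
    )
    targetexpr_mrna = expression_scores.compute_target_expression_score(
        bundle.mrna_expr, bundle.annotation
    )
    directions = filtering.split_by_direction(pd.concat([fc_circ, fc_mrna]))

    # -- prerequisites -----------------------------------------------------
    eligible = filtering.apply_sponge_prerequisites(
        circ_pairs, mrna_pairs, kept, directions
    )
    stages["eligible_pairs"] = len(eligible)
    if eligible.empty:
        raise EmptyResultError("prerequisites")

    # -- SG, EnrichSG, SS --------------------------------------------------
    weights_sg = np.asarray(cfg.weights_sg, dtype=float) if cfg.weights_sg else None
    weights_ss = np.asarray(cfg.weights_ss, dtype=float) if cfg.weights_ss else None
    sg_table = sponge.compute_sg(
        mrna_pairs, fc_mrna, mirexpr, targetexpr_mrna, eligible,
        weights=weights_sg, abs_fc=cfg.abs_fc,
    )
    stages["sg_pairs"] = len(sg_table)
    enrich_sg = sponge.compute_enrich_sg(sg_table, nperm=cfg.nperm, seed=cfg.seed)
    rows = sponge.compute_sponge_scores(
        circ_pairs, fc_circ, mirexpr, targetexpr_circ, enrich_sg, sg_table, eligible,
        weights=weights_ss, abs_fc=cfg.abs_fc, neglog_costs=cfg.neglog_costs,
    )
    matrix = sponge.assemble_score_matrix(rows)
    stages["score_matrix_rows"] = len(matrix)
    summary["condition_counts"] = matrix["condition"].value_counts().to_dict()
    summary["runtime_seconds"] = round(time.perf_counter() - t0, 3)
    summary["sg_table"] = sg_table
    logger.info(
        "pipeline complete: %d ranked pairs in %.2fs",
        len(matrix),
        summary["runtime_seconds"],
    )
    return matrix, summary


def load_bundle_from_config(cfg: RunConfig) -> InputBundle:
    paths = dict(cfg.paths)
    required = ["circ_expr", "mrna_expr", "annotation", "circ_sites", "mrna_sites", "circ_lengths"]
    missing = [k for k in required if k not in paths]
    if missing:
        raise ConfigError(f"config paths missing entries: {missing}")
    return data_io.load_input_bundle(
        circ_expr=paths["circ_expr"],
        mrna_expr=paths["mrna_expr"],
        annotation=paths["annotation"],
        circ_sites=paths["circ_sites"],
        mrna_sites=paths["mrna_sites"],
        circ_lengths=paths["circ_lengths"],
        mirna_expr=paths.get("mirna_expr"),
        mirna_annotation=paths.get("mirna_annotation"),
        mirna_signature=paths.get("mirna_signature"),
        validated=paths.get("validated"),
    )


def run_from_config(cfg: RunConfig, out_matrix: str | Path) -> dict[str, Any]:
    bundle = load_bundle_from_config(cfg)
    matrix, summary = run_pipeline(bundle, cfg)
    data_io.write_score_matrix(matrix, out_matrix)
    summary.pop("sg_table")
    return summary
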
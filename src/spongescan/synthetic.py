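"""Seeded synthetic input bundles with planted sponge mechanisms.

Every generated quantity of a planted mechanism is a linear blend between a
background draw (strength 0) and a dominating value (strength 1), so at full
strength the planted (miRNA, circRNA) pair outscores the background on every
criterion, while at strength 0 it is statistically indistinguishable from the
background.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import data_io
from .data_io import (
    CONDITION_1,
    CONDITION_2,
    ExpressionMatrix,
    InputBundle,
    SampleAnnotation,
    validate_site_table,
)
from .errors import ConfigError

logger = logging.getLogger(__name__)


@dataclass
class FixtureConfig:
    n_circ: int = 200
    n_mrna: int = 500
    n_mirna: int = 50
    n_samples_per_condition: int = 6
    n_planted: int = 1
    planted_strength: float = 1.0
    background_site_rate: float = 0.04
    noise_sd: float = 0.3
    n_planted_mrna_targets: int = 4
    seed: int = 0

    def __post_init__(self):
        counts = {
            "n_circ": self.n_circ,
            "n_mrna": self.n_mrna,
            "n_mirna": self.n_mirna,
            "n_planted": self.n_planted,
        }
        for name, value in counts.items():
            if value < 1:
                raise ConfigError(f"{name} must be >= 1, got {value}")
        if self.n_samples_per_condition < 3:
            raise ConfigError(
                "n_samples_per_condition must be >= 3, got "
                f"{self.n_samples_per_condition}"
            )
        if not 0.0 <= self.planted_strength <= 1.0:
            raise ConfigError("planted_strength must lie in [0, 1]")
        if self.n_planted > min(self.n_circ, self.n_mirna):
            raise ConfigError("more planted mechanisms than circRNAs or miRNAs")
        if self.n_planted * self.n_planted_mrna_targets > self.n_mrna:
            raise ConfigError("not enough mRNAs for the planted target sets")


@dataclass
class FixtureTruth:
    planted: list[tuple[str, str, tuple[str, ...]]]  # (mirna, circ, mrna targets)
    directions: list[int] = field(default_factory=list)  # +1 = up in condition_2


def _circ_id(i: int) -> str:
    return f"hsa_circ_{i + 1:07d}"


def _mrna_id(i: int) -> str:
    return f"GENE{i + 1:04d}"


def _mirna_id(i: int) -> str:
    return f"hsa-miR-{100 + i}-5p"


def generate_fixture(cfg: FixtureConfig) -> tuple[InputBundle, FixtureTruth]:
    """Generate a complete, validated input bundle plus its ground truth."""
    rng = np.random.default_rng(cfg.seed)
    s = cfg.planted_strength
    n_samples = 2 * cfg.n_samples_per_condition

    circ_ids = [_circ_id(i) for i in range(cfg.n_circ)]
    mrna_ids = [_mrna_id(i) for i in range(cfg.n_mrna)]
    mirna_ids = [_mirna_id(i) for i in range(cfg.n_mirna)]
    sample_ids = [f"S{i + 1:02d}" for i in range(n_samples)]
    annotation = SampleAnnotation(
        {
            sid: (CONDITION_1 if i < cfg.n_samples_per_condition else CONDITION_2)
            for i, sid in enumerate(sample_ids)
        }
    )
    in_cond2 = np.array([annotation.sample_to_condition[x] == CONDITION_2 for x in sample_ids])

    # planted assignments: first n_planted of each id space, disjoint mRNA blocks
    planted_circ = circ_ids[: cfg.n_planted]
    planted_mirna = mirna_ids[: cfg.n_planted]
    planted_mrnas = [
        tuple(
            mrna_ids[i * cfg.n_planted_mrna_targets : (i + 1) * cfg.n_planted_mrna_targets]
        )
        for i in range(cfg.n_planted)
    ]
    truth = FixtureTruth(
        planted=[
            (m, c, t) for m, c, t in zip(planted_mirna, planted_circ, planted_mrnas)
        ],
        directions=[1] * cfg.n_planted,
    )

    def blend(background: np.ndarray | float, planted: float) -> np.ndarray | float:
        return (1.0 - s) * background + s * planted

    # ---- expression matrices -------------------------------------------
    def expr_matrix(
        ids: list[str],
        baseline: np.ndarray,
        effect: np.ndarray,
        rna_type: str,
    ) -> ExpressionMatrix:
        noise = rng.normal(0.0, cfg.noise_sd, size=(len(ids), n_samples))
        values = baseline[:, None] + effect[:, None] * in_cond2[None, :] + noise
        df = pd.DataFrame(values, index=ids, columns=sample_ids)
        return ExpressionMatrix(rna_type, df).canonical()

    circ_base = rng.uniform(4.0, 10.0, cfg.n_circ)
    circ_eff = rng.uniform(0.5, 2.0, cfg.n_circ) * rng.choice([-1.0, 1.0], cfg.n_circ)
    for i in range(cfg.n_planted):
        circ_base[i] = blend(circ_base[i], 9.5)
        circ_eff[i] = blend(circ_eff[i], 4.5)
    circ_expr = expr_matrix(circ_ids, circ_base, circ_eff, "circRNA")

    mrna_base = rng.uniform(4.0, 10.0, cfg.n_mrna)
    mrna_eff = rng.uniform(0.5, 2.0, cfg.n_mrna) * rng.choice([-1.0, 1.0], cfg.n_mrna)
    for i, targets in enumerate(planted_mrnas):
        for t in targets:
            j = mrna_ids.index(t)
            mrna_base[j] = blend(mrna_base[j], 9.0)
            mrna_eff[j] = blend(mrna_eff[j], 3.5)
    mrna_expr = expr_matrix(mrna_ids, mrna_base, mrna_eff, "mRNA")

    mirna_base = rng.uniform(1.0, 8.0, cfg.n_mirna)
    for i in range(cfg.n_planted):
        mirna_base[i] = blend(mirna_base[i], 12.0)
    mirna_eff = np.zeros(cfg.n_mirna)  # sponge prerequisite: miRNA not DE
    mirna_expr = expr_matrix(mirna_ids, mirna_base, mirna_eff, "miRNA")
    # a couple of silent miRNAs exercise the nonzero-sum rule
    n_silent = max(1, cfg.n_mirna // 20)
    silent = rng.choice(np.arange(cfg.n_planted, cfg.n_mirna), n_silent, replace=False)
    silent_ids = [mirna_ids[i] for i in silent]
    mirna_expr.data.loc[silent_ids] = 0.0

    # ---- circRNA site table --------------------------------------------
    site_rows: list[tuple[str, str, str, float, int]] = []
    site_counter: dict[tuple[str, str], int] = {}

    def add_sites(mirna: str, target: str, ttype: str, scores: np.ndarray) -> None:
        start = site_counter.get((mirna, target), 0)
        for j, score in enumerate(scores):
            site_rows.append((mirna, target, ttype, float(score), start + j + 1))
        site_counter[(mirna, target)] = start + len(scores)

    site_count_choices = np.array([1, 1, 1, 1, 2, 2, 3, 5])
    for circ in circ_ids:
        degree = min(int(rng.integers(3, 8)), cfg.n_mirna)
        partners = rng.choice(mirna_ids, size=degree, replace=False)
        for mirna in partners:
            k = int(rng.choice(site_count_choices))
            add_sites(mirna, circ, "circRNA", rng.uniform(-0.45, -0.05, k))

    for mirna, circ, _ in truth.planted:
        k = max(1, round(blend(1.0, 15.0)))
        best = blend(-0.25, -0.92)
        add_sites(mirna, circ, "circRNA", rng.uniform(best, best + 0.04, k))

    circ_sites = validate_site_table(
        pd.DataFrame(site_rows, columns=data_io.SITE_TABLE_COLUMNS), "<synthetic circ sites>"
    )

    # ---- mRNA site table ------------------------------------------------
    site_rows = []
    site_counter = {}
    hit = rng.random((cfg.n_mirna, cfg.n_mrna)) < cfg.background_site_rate
    for i, mirna in enumerate(mirna_ids):
        for j in np.flatnonzero(hit[i]):
            k = int(rng.integers(1, 4))
            add_sites(mirna, mrna_ids[j], "mRNA", rng.uniform(-0.45, -0.05, k))
    for mirna, _, targets in truth.planted:
        for t in targets:
            k = max(1, round(blend(1.0, 5.0)))
            best = blend(-0.25, -0.88)
            add_sites(mirna, t, "mRNA", rng.uniform(best, best + 0.04, k))
    mrna_sites = validate_site_table(
        pd.DataFrame(site_rows, columns=data_io.SITE_TABLE_COLUMNS), "<synthetic mRNA sites>"
    )

    # ---- lengths, validated interactions --------------------------------
    lengths = {
        circ: int(length)
        for circ, length in zip(circ_ids, rng.integers(300, 2001, cfg.n_circ))
    }
    for i, circ in enumerate(planted_circ):
        lengths[circ] = int(round(blend(float(lengths[circ]), 450.0)))

    val_rows = [
        {"mirna_id": m, "circ_id": c, "n_clipseq": 3, "n_degradome": 3}
        for m, c, _ in truth.planted
    ]
    background_pairs = list(
        dict.fromkeys(zip(circ_sites["mirna_id"], circ_sites["target_id"]))
    )
    planted_set = {(m, c) for m, c, _ in truth.planted}
    candidates = [p for p in background_pairs if p not in planted_set]
    n_val = min(40, len(candidates))
    chosen = rng.choice(len(candidates), size=n_val, replace=False)
    for idx in chosen:
        mirna, circ = candidates[idx]
        val_rows.append(
            {
                "mirna_id": mirna,
                "circ_id": circ,
                "n_clipseq": int(rng.integers(0, 5)),
                "n_degradome": int(rng.integers(0, 5)),
            }
        )
    validated = (
        pd.DataFrame(val_rows)
        .sort_values(["mirna_id", "circ_id"])
        .reset_index(drop=True)
    )

    bundle = InputBundle(
        circ_expr=circ_expr,
        mrna_expr=mrna_expr,
        annotation=annotation,
        circ_sites=circ_sites,
        mrna_sites=mrna_sites,
        circ_lengths=lengths,
        mirna_expr=mirna_expr,
        validated=validated,
    )
    return bundle, truth


def write_fixture(bundle: InputBundle, truth: FixtureTruth, outdir: str | Path) -> dict[str, Path]:
    """Write the full CSV bundle plus ``truth.csv`` to a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "circ_expr": outdir / "circ_expression.csv",
        "mrna_expr": outdir / "mrna_expression.csv",
        "mirna_expr": outdir / "mirna_expression.csv",
        "annotation": outdir / "annotation.csv",
        "circ_sites": outdir / "circ_sites.csv",
        "mrna_sites": outdir / "mrna_sites.csv",
        "circ_lengths": outdir / "circ_lengths.csv",
        "validated": outdir / "validated.csv",
        "truth": outdir / "truth.csv",
    }
    data_io.write_expression_csv(bundle.circ_expr, paths["circ_expr"])
    data_io.write_expression_csv(bundle.mrna_expr, paths["mrna_expr"])
    data_io.write_expression_csv(bundle.mirna_expr, paths["mirna_expr"])
    data_io.write_annotation_csv(bundle.annotation, paths["annotation"])
    data_io.write_site_csv(bundle.circ_sites, paths["circ_sites"])
    data_io.write_site_csv(bundle.mrna_sites, paths["mrna_sites"])
    data_io.write_lengths_csv(bundle.circ_lengths, paths["circ_lengths"])
    data_io.write_validated_csv(bundle.validated, paths["validated"])
    pd.DataFrame(
        {
            "mirna_id": [m for m, _, _ in truth.planted],
            "circ_id": [c for _, c, _ in truth.planted],
            "mrna_targets": [";".join(t) for _, _, t in truth.planted],
            "direction": truth.directions,
        }
    ).to_csv(paths["truth"], index=False)
    logger.info("fixture written to %s", outdir)
    return paths
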
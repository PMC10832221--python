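"""Sponge-mechanism prerequisites.

Three rules gate the candidate space before any scoring:

1. miRNA sufficiency — a miRNA must have a nonzero total expression and sit
   above the pooled first-quartile cutoff in strictly more than 90% of its
   samples (both comparisons strict).
2. Connectivity — a miRNA must target at least one circRNA and one mRNA after
   the affinity filters.
3. Co-direction — a candidate (miRNA, circRNA) pair is retained only with at
   least one mRNA target whose fold-change sign matches the circRNA's, and
   that sign must be nonzero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import ExpressionMatrix
from .errors import EmptyInputError

logger = logging.getLogger(__name__)

DEFAULT_FRACTION_THRESHOLD = 0.90


@dataclass
class MirnaFilterResult:
    kept_mirnas: set[str]
    cutoff: float
    per_mirna_fraction: dict[str, float]


def filter_mirnas(
    mirna_expr: ExpressionMatrix,
    fraction_threshold: float = DEFAULT_FRACTION_THRESHOLD,
    exclude_zero_rows_from_pool: bool = False,
) -> MirnaFilterResult:
    """Apply the miRNA sufficiency rule.

    The cutoff is the first quartile of the pooled value distribution (all
    miRNAs x all samples, linear-interpolation quantile). By default all-zero
    rows contribute to the pool; ``exclude_zero_rows_from_pool`` drops them
    before pooling.
    """
    df = mirna_expr.data
    if df.empty:
        raise EmptyInputError("miRNA expression matrix is empty")
    pool = df.to_numpy(dtype=float)
    if exclude_zero_rows_from_pool:
        nonzero = pool.sum(axis=1) != 0
        pool = pool[nonzero]
        if pool.size == 0:
            raise EmptyInputError("all miRNA rows are zero")
    cutoff = float(np.quantile(pool.ravel(), 0.25))  # linear interpolation

    fractions = (df.to_numpy(dtype=float) > cutoff).mean(axis=1)
    row_sums = df.to_numpy(dtype=float).sum(axis=1)
    kept = {
        mirna
        for mirna, frac, total in zip(df.index, fractions, row_sums)
        if total != 0 and frac > fraction_threshold
    }
    logger.info(
        "miRNA sufficiency filter: cutoff=%.4g, kept %d/%d", cutoff, len(kept), len(df)
    )
    return MirnaFilterResult(
        kept_mirnas=kept,
        cutoff=cutoff,
        per_mirna_fraction=dict(zip(df.index, fractions)),
    )


def split_by_direction(fc: pd.Series) -> pd.Series:
    """Sign of log2 fold change: +1 up in condition_2, -1 up in condition_1."""
    sign = np.sign(fc).astype(int)
    sign.name = "direction"
    return sign


def apply_sponge_prerequisites(
    circ_pairs: pd.DataFrame,
    mrna_pairs: pd.DataFrame,
    kept: MirnaFilterResult | set[str] | None,
    directions: pd.Series,
) -> pd.DataFrame:
    """Build the eligible (miRNA, circRNA, co-directional mRNA set) table.

    ``kept=None`` skips the sufficiency rule (signature mode pre-filters the
    miRNAs upstream). Returns columns ``mirna_id, circ_id, mrna_ids`` where
    ``mrna_ids`` is a tuple of co-directional mRNA targets, never empty.
    """
    if isinstance(kept, MirnaFilterResult):
        kept_set = kept.kept_mirnas
    else:
        kept_set = kept

    dirs = directions.to_dict()
    mrna_by_mirna: dict[str, list[str]] = {}
    for mirna, target in zip(mrna_pairs["mirna_id"], mrna_pairs["target_id"]):
        mrna_by_mirna.setdefault(mirna, []).append(target)

    rows = []
    for mirna, circ in zip(circ_pairs["mirna_id"], circ_pairs["target_id"]):
        if kept_set is not None and mirna not in kept_set:
            continue
        circ_dir = dirs.get(circ, 0)
        if circ_dir == 0:
            continue
        codirectional = tuple(
            sorted(
                m for m in mrna_by_mirna.get(mirna, []) if dirs.get(m, 0) == circ_dir
            )
        )
        if not codirectional:
            continue
        rows.append((mirna, circ, codirectional))

    out = pd.DataFrame(rows, columns=["mirna_id", "circ_id", "mrna_ids"])
    if out.empty:
        logger.info("sponge prerequisites: no eligible (miRNA, circRNA) pair")
    else:
        out = out.sort_values(["mirna_id", "circ_id"]).reset_index(drop=True)
        logger.info(
            "sponge prerequisites: %d eligible pairs over %d miRNAs",
            len(out),
            out["mirna_id"].nunique(),
        )
    return out
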
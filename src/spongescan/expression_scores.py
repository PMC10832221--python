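"""Expression-level criteria: fold change, miRNA expression, target expression.

Inputs are assumed log2-transformed, so the fold change between conditions is
the plain difference of per-condition means. The miRNA expression score is the
median over all samples pooled across conditions; the target expression score
is the larger of the two per-condition means.
"""

from __future__ import annotations

import logging

import pandas as pd

from .data_io import CONDITION_1, CONDITION_2, ExpressionMatrix, MirnaSignature, SampleAnnotation

logger = logging.getLogger(__name__)


def compute_fold_change(
    expr: ExpressionMatrix, annotation: SampleAnnotation
) -> pd.Series:
    """Per-feature log2 fold change: mean(condition_2) - mean(condition_1)."""
    s1 = annotation.samples_for(CONDITION_1)
    s2 = annotation.samples_for(CONDITION_2)
    fc = expr.data[s2].mean(axis=1) - expr.data[s1].mean(axis=1)
    fc.name = "s_fc"
    return fc


def compute_mirna_expression_score(
    mirna_expr: ExpressionMatrix | MirnaSignature,
) -> pd.Series:
    """Per-miRNA median log2 expression over all samples (both conditions).

    A signature is passed through verbatim; cross-dataset comparability of
    signature units is the user's responsibility.
    """
    if isinstance(mirna_expr, MirnaSignature):
        logger.warning(
            "using signature '%s' for miRNA expression scores; values are "
            "taken as-is without rescaling",
            mirna_expr.label,
        )
        s = pd.Series(mirna_expr.values, dtype=float)
    else:
        s = mirna_expr.data.median(axis=1)
    s.name = "s_mirexpr"
    return s


def compute_target_expression_score(
    expr: ExpressionMatrix, annotation: SampleAnnotation
) -> pd.Series:
    """Per-target max of the two per-condition mean log2 expressions."""
    m1 = expr.data[annotation.samples_for(CONDITION_1)].mean(axis=1)
    m2 = expr.data[annotation.samples_for(CONDITION_2)].mean(axis=1)
    s = pd.concat([m1, m2], axis=1).max(axis=1)
    s.name = "s_targetexpr"
    return s
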
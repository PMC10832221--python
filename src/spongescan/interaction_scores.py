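"""Per-pair interaction reliability scores.

Per-site predicted interactions are collapsed to one row per (miRNA, target)
keeping the strongest site. Raw context scores follow the TargetScan
convention: lower (more negative) = stronger predicted binding. Three scores
are derived per pair:

* ``s_affinity`` — the best raw score min-max rescaled to [0, 1] within the
  table being scored (1 = strongest in table);
* ``s_nbmre`` — the site count, divided by spliced length for circRNA targets;
* ``s_enrichmre`` — BH-adjusted upper-tail binomial p-value testing whether a
  circRNA is enriched in sites of a specific miRNA against the background of
  all sites on all circRNAs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_adjust
from .errors import (
    CalibrationError,
    DegenerateBackgroundError,
    EmptyInputError,
    MissingLengthError,
)

logger = logging.getLogger(__name__)

PAIR_COLUMNS = ["mirna_id", "target_id", "target_type", "raw_score_best", "n_sites"]

DEFAULT_ENRICH_ALPHA = 0.05


@dataclass
class AffinityCutoff:
    cutoff: float
    percentile: float
    n_validated_used: int


def collapse_sites(sites: pd.DataFrame) -> pd.DataFrame:
    """One row per (miRNA, target): site count and most favorable raw score."""
    if sites.empty:
        return pd.DataFrame(columns=PAIR_COLUMNS)
    grouped = sites.groupby(["mirna_id", "target_id", "target_type"], sort=True)
    out = grouped["raw_score"].agg(raw_score_best="min", n_sites="size").reset_index()
    return out[PAIR_COLUMNS]


def calibrate_affinity_cutoff(
    predicted: pd.DataFrame,
    validated: pd.DataFrame,
    percentile: float = 95.0,
    min_clip: int = 2,
    min_degradome: int = 2,
) -> AffinityCutoff:
    """Affinity cutoff = given percentile of predicted scores restricted to
    well-supported validated pairs (>= min_clip CLIP-seq and >= min_degradome
    degradome-seq experiments). Pairs are kept downstream iff their best raw
    score is <= the cutoff (at least as strong as the cutoff).
    """
    qualified = validated[
        (validated["n_clipseq"] >= min_clip)
        & (validated["n_degradome"] >= min_degradome)
    ]
    merged = predicted.merge(
        qualified[["mirna_id", "circ_id"]],
        left_on=["mirna_id", "target_id"],
        right_on=["mirna_id", "circ_id"],
    )
    if merged.empty:
        raise CalibrationError(
            "no validated interaction passes the evidence thresholds and "
            "matches a predicted pair"
        )
    scores = merged["raw_score_best"].to_numpy(dtype=float)
    cutoff = float(np.percentile(scores, percentile))  # linear interpolation
    logger.info(
        "affinity cutoff calibration: %d validated pairs, P%.0f = %.4g",
        len(scores),
        percentile,
        cutoff,
    )
    return AffinityCutoff(cutoff=cutoff, percentile=percentile, n_validated_used=len(scores))


def apply_affinity_cutoff(pairs: pd.DataFrame, cutoff: AffinityCutoff) -> pd.DataFrame:
    """Keep pairs at least as strong as the cutoff (raw_score_best <= cutoff)."""
    kept = pairs[pairs["raw_score_best"] <= cutoff.cutoff].reset_index(drop=True)
    logger.info("affinity cutoff %.4g: kept %d/%d pairs", cutoff.cutoff, len(kept), len(pairs))
    return kept


def rescale_affinity(pairs: pd.DataFrame) -> pd.DataFrame:
    """Fill ``s_affinity`` = (max - raw) / (max - min) over this table.

    Strongest (most negative) raw score maps to 1, weakest to 0. A constant
    column degenerates to 0.5 for every pair.
    """
    if pairs.empty:
        raise EmptyInputError("cannot rescale an empty pair table")
    out = pairs.copy()
    raw = out["raw_score_best"].to_numpy(dtype=float)
    lo, hi = raw.min(), raw.max()
    if hi == lo:
        out["s_affinity"] = 0.5
    else:
        out["s_affinity"] = (hi - raw) / (hi - lo)
    return out


def normalize_mre_counts(
    pairs: pd.DataFrame, lengths: Mapping[str, int] | None = None
) -> pd.DataFrame:
    """Fill ``s_nbmre``: sites per nucleotide for circRNA targets (spliced
    length), raw site count for mRNA targets."""
    out = pairs.copy()
    values = np.empty(len(out), dtype=float)
    for i, (target, ttype, n) in enumerate(
        zip(out["target_id"], out["target_type"], out["n_sites"])
    ):
        if ttype == "circRNA":
            if lengths is None or target not in lengths:
                raise MissingLengthError(f"no spliced length for circRNA {target!r}")
            values[i] = n / lengths[target]
        else:
            values[i] = float(n)
    out["s_nbmre"] = values
    return out


def binomial_enrichment_pvalue(k: int, n_trials: int, p0: float) -> float:
    """Upper-tail P(X >= k) for X ~ Binomial(n_trials, p0)."""
    if k <= 0:
        return 1.0
    return float(stats.binom.sf(k - 1, n_trials, p0))


def test_mre_enrichment(
    circ_pairs: pd.DataFrame,
    alpha: float = DEFAULT_ENRICH_ALPHA,
    exclude_focal_from_background: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Binomial MRE-enrichment test for every (miRNA, circRNA) pair.

    For pair (m, c): k = sites of m on c; trials N = all sites on c; success
    probability p0 = global frequency of m's sites among all circRNA sites
    (optionally excluding m's own sites from both numerator's pair and the
    background). BH adjustment spans all pairs tested in the run.

    Returns ``(scored, filtered)`` where ``filtered`` keeps pairs with
    ``s_enrichmre < alpha``.
    """
    if circ_pairs.empty:
        raise EmptyInputError("no circRNA pairs to test for MRE enrichment")
    out = circ_pairs.copy()
    grand_total = int(out["n_sites"].sum())
    if grand_total == 0:
        raise DegenerateBackgroundError("grand total of circRNA MRE sites is zero")
    per_circ = out.groupby("target_id")["n_sites"].sum()
    per_mirna = out.groupby("mirna_id")["n_sites"].sum()

    pvals = np.empty(len(out), dtype=float)
    for i, (mirna, circ, k) in enumerate(
        zip(out["mirna_id"], out["target_id"], out["n_sites"])
    ):
        n_trials = int(per_circ[circ])
        if exclude_focal_from_background:
            denom = grand_total - int(per_mirna[mirna])
            numer = int(per_mirna[mirna]) - int(k)
            p0 = numer / denom if denom > 0 else 0.0
        else:
            p0 = per_mirna[mirna] / grand_total
        pvals[i] = binomial_enrichment_pvalue(int(k), n_trials, p0)
    out["s_enrichmre"] = bh_adjust(pvals)
    filtered = out[out["s_enrichmre"] < alpha].reset_index(drop=True)
    logger.info(
        "MRE enrichment: %d/%d pairs with adjusted p < %g", len(filtered), len(out), alpha
    )
    return out, filtered
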
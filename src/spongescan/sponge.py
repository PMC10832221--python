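"""Global interaction scores (SG), GSEA-based SG enrichment, sponge scores
(SS), ranks and the 16-column score matrix.

SG integrates five benefit criteria per miRNA-mRNA pair in one joint TOPSIS
run; the SG enrichment test asks, per miRNA, whether that miRNA's pairs
concentrate at the top of the SG ranking (weighted Kolmogorov-Smirnov running
sum, permutation p-value with exact enumeration at small sizes); SS integrates
seven criteria per miRNA-circRNA pair (five benefit, the two adjusted
enrichment p-values as cost).
"""

from __future__ import annotations

import logging
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd

from ._stats import bh_adjust
from .data_io import CONDITION_1, CONDITION_2, SCORE_MATRIX_COLUMNS
from .errors import EmptyInputError
from .mcda import BENEFIT, COST, DecisionMatrix, topsis

logger = logging.getLogger(__name__)

SG_CRITERIA = ["s_affinity", "s_nbmre", "s_fc_abs", "s_mirexpr", "s_targetexpr"]

DEFAULT_NPERM = 10_000
EXHAUSTIVE_LIMIT = 100_000


# ---------------------------------------------------------------------------
# SG
# ---------------------------------------------------------------------------


def compute_sg(
    mrna_pairs: pd.DataFrame,
    fc: pd.Series,
    mirexpr: pd.Series,
    targetexpr: pd.Series,
    eligible: pd.DataFrame,
    weights: np.ndarray | None = None,
    abs_fc: bool = True,
) -> pd.DataFrame:
    """One joint TOPSIS run over all eligible miRNA-mRNA pairs.

    The pair pool is the union of the eligible rows' co-directional mRNA
    sets. Criteria (all benefit): affinity, MRE count, |fold change| of the
    mRNA, miRNA expression, target expression of the mRNA.
    """
    wanted = {
        (mirna, mrna)
        for mirna, mrnas in zip(eligible["mirna_id"], eligible["mrna_ids"])
        for mrna in mrnas
    }
    if not wanted:
        raise EmptyInputError("no eligible miRNA-mRNA pair for SG scoring")
    mask = [
        (m, t) in wanted for m, t in zip(mrna_pairs["mirna_id"], mrna_pairs["target_id"])
    ]
    pool = mrna_pairs[mask].sort_values(["mirna_id", "target_id"]).reset_index(drop=True)
    missing = wanted - set(zip(pool["mirna_id"], pool["target_id"]))
    if missing:
        raise EmptyInputError(f"eligible pairs missing from scored pair table: {sorted(missing)[:3]}")

    fc_vals = fc.reindex(pool["target_id"]).to_numpy()
    matrix = np.column_stack(
        [
            pool["s_affinity"].to_numpy(dtype=float),
            pool["s_nbmre"].to_numpy(dtype=float),
            np.abs(fc_vals) if abs_fc else fc_vals,
            mirexpr.reindex(pool["mirna_id"]).to_numpy(),
            targetexpr.reindex(pool["target_id"]).to_numpy(),
        ]
    )
    dm = DecisionMatrix(
        alternative_ids=list(zip(pool["mirna_id"], pool["target_id"])),
        criterion_names=SG_CRITERIA,
        values=matrix,
        directions=[BENEFIT] * 5,
        weights=weights,
    )
    sg = topsis(dm).to_numpy()
    out = pool[["mirna_id", "target_id"]].rename(columns={"target_id": "mrna_id"}).copy()
    out["sg"] = sg
    return out


# ---------------------------------------------------------------------------
# Preranked GSEA
# ---------------------------------------------------------------------------


def _es_batch(positions: np.ndarray, weights: np.ndarray, n: int) -> np.ndarray:
    """Signed enrichment score for each row of sorted 0-based hit positions.

    Weighted KS running sum with weight exponent 1: hits advance by
    |score| / sum(|scores in set|), misses recede by 1 / (n - k). ES is the
    extremum of the running sum with the largest absolute value.
    """
    positions = np.atleast_2d(positions)
    n_sets, k = positions.shape
    if k == n:
        return np.ones(n_sets)
    hit_w = weights[positions]
    cum_w = np.cumsum(hit_w, axis=1)
    nr = cum_w[:, -1:].copy()
    degenerate = nr[:, 0] == 0  # all-zero scores in set: fall back to uniform steps
    if degenerate.any():
        cum_w[degenerate] = np.arange(1, k + 1)
        nr[degenerate] = k
    p_hit_after = cum_w / nr
    p_hit_before = np.concatenate([np.zeros((n_sets, 1)), p_hit_after[:, :-1]], axis=1)
    miss_before = (positions - np.arange(k)) / (n - k)
    dev_max = (p_hit_after - miss_before).max(axis=1)
    dev_min = (p_hit_before - miss_before).min(axis=1)
    # tolerance makes the sign choice stable when |max| == |min| analytically
    return np.where(dev_max >= -dev_min - 1e-12, dev_max, dev_min)


def compute_enrich_sg(
    sg: pd.DataFrame,
    nperm: int = DEFAULT_NPERM,
    seed: int = 0,
    exhaustive_limit: int = EXHAUSTIVE_LIMIT,
) -> pd.DataFrame:
    """Per-miRNA preranked enrichment of SG scores.

    Pairs are ranked by SG descending (stable (mirna_id, mrna_id) tiebreak);
    each miRNA's gene set is its pairs' positions in that list. P-values come
    from random same-size position sets: exhaustive enumeration when
    C(n, k) <= ``exhaustive_limit``, otherwise ``nperm`` seeded draws with the
    +1/(nperm+1) correction. One-sided in the direction of the observed ES.
    BH adjustment spans all miRNAs in the run.
    """
    if sg["mirna_id"].nunique() < 2:
        logger.warning("fewer than 2 distinct miRNAs in SG table; p-values degenerate")
    ranked = sg.sort_values(
        by=["sg", "mirna_id", "mrna_id"], ascending=[False, True, True], kind="stable"
    ).reset_index(drop=True)
    n = len(ranked)
    weights = np.abs(ranked["sg"].to_numpy(dtype=float))
    rng = np.random.default_rng(seed)

    positions_by_mirna = {
        mirna: np.asarray(sorted(idx)) for mirna, idx in ranked.groupby("mirna_id").groups.items()
    }
    mirnas = sorted(positions_by_mirna)
    # shared null distribution per set size (depends only on k and the list)
    null_cache: dict[int, tuple[np.ndarray, bool]] = {}

    def null_for(k: int) -> tuple[np.ndarray, bool]:
        if k not in null_cache:
            if k == n:
                null_cache[k] = (np.ones(1), True)
            elif comb(n, k) <= exhaustive_limit:
                sets = np.array(list(combinations(range(n), k)), dtype=int)
                null_cache[k] = (_es_batch(sets, weights, n), True)
            else:
                samples = np.empty((nperm, k), dtype=int)
                for i in range(nperm):
                    samples[i] = rng.choice(n, size=k, replace=False)
                samples.sort(axis=1)
                null_cache[k] = (_es_batch(samples, weights, n), False)
        return null_cache[k]

    rows = []
    for mirna in mirnas:
        pos = positions_by_mirna[mirna]
        k = len(pos)
        es = float(_es_batch(pos[None, :], weights, n)[0])
        if k == n:
            p = 1.0  # the set covers the whole list: every permutation identical
        else:
            null, exact = null_for(k)
            # tie-tolerant tail counting: analytically equal ES values are
            # hits regardless of last-ulp float noise
            if es >= 0:
                hits = int((null >= es - 1e-9).sum())
            else:
                hits = int((null <= es + 1e-9).sum())
            if exact:
                p = hits / len(null)
            else:
                p = (hits + 1) / (len(null) + 1)
        rows.append((mirna, es, p))

    out = pd.DataFrame(rows, columns=["mirna_id", "es", "pvalue"])
    out["s_enrichsg"] = bh_adjust(out["pvalue"].to_numpy())
    return out


# ---------------------------------------------------------------------------
# SS and the score matrix
# ---------------------------------------------------------------------------


def compute_sponge_scores(
    circ_pairs: pd.DataFrame,
    fc_circ: pd.Series,
    mirexpr: pd.Series,
    targetexpr_circ: pd.Series,
    enrich_sg: pd.DataFrame,
    sg: pd.DataFrame,
    eligible: pd.DataFrame,
    weights: np.ndarray | None = None,
    abs_fc: bool = True,
    neglog_costs: bool = False,
) -> pd.DataFrame:
    """One joint TOPSIS run over all eligible miRNA-circRNA pairs.

    Benefit criteria: affinity, length-normalized MRE count, miRNA
    expression, circRNA expression, |fold change| of the circRNA. Cost
    criteria: the two adjusted enrichment p-values (raw by default; with
    ``neglog_costs`` they enter as -log10(p) benefit criteria).
    """
    if eligible.empty:
        raise EmptyInputError("no eligible miRNA-circRNA pair for sponge scoring")
    pairs = circ_pairs.set_index(["mirna_id", "target_id"])
    enrich_by_mirna = enrich_sg.set_index("mirna_id")["s_enrichsg"]
    sg_by_pair = sg.set_index(["mirna_id", "mrna_id"])["sg"]

    rows = []
    for mirna, circ, mrnas in zip(
        eligible["mirna_id"], eligible["circ_id"], eligible["mrna_ids"]
    ):
        pair = pairs.loc[(mirna, circ)]
        target_sgs = sg_by_pair.loc[[(mirna, m) for m in mrnas]]
        rows.append(
            {
                "mirna_id": mirna,
                "circ_id": circ,
                "s_affinity": float(pair["s_affinity"]),
                "s_nbmre": float(pair["s_nbmre"]),
                "s_enrichmre": float(pair["s_enrichmre"]),
                "s_fc_circ": float(fc_circ[circ]),
                "s_mirexpr": float(mirexpr[mirna]),
                "s_targetexpr_circ": float(targetexpr_circ[circ]),
                "s_enrichsg": float(enrich_by_mirna[mirna]),
                "n_mrna_targets": len(mrnas),
                "mean_sg_of_targets": float(target_sgs.mean()),
                "mrna_target_list": ";".join(mrnas),
            }
        )
    out = pd.DataFrame(rows)

    fc_col = np.abs(out["s_fc_circ"]) if abs_fc else out["s_fc_circ"].to_numpy()
    benefit = [
        out["s_affinity"].to_numpy(dtype=float),
        out["s_nbmre"].to_numpy(dtype=float),
        fc_col,
        out["s_mirexpr"].to_numpy(dtype=float),
        out["s_targetexpr_circ"].to_numpy(dtype=float),
    ]
    cost_raw = [
        out["s_enrichsg"].to_numpy(dtype=float),
        out["s_enrichmre"].to_numpy(dtype=float),
    ]
    if neglog_costs:
        cols = benefit + [-np.log10(np.maximum(c, 1e-300)) for c in cost_raw]
        directions = [BENEFIT] * 7
    else:
        cols = benefit + cost_raw
        directions = [BENEFIT] * 5 + [COST] * 2
    dm = DecisionMatrix(
        alternative_ids=list(zip(out["mirna_id"], out["circ_id"])),
        criterion_names=[
            "s_affinity", "s_nbmre", "s_fc_abs", "s_mirexpr",
            "s_targetexpr_circ", "s_enrichsg", "s_enrichmre",
        ],
        values=np.column_stack(cols),
        directions=directions,
        weights=weights,
    )
    out["ss"] = topsis(dm).to_numpy()
    out["condition"] = np.where(out["s_fc_circ"] > 0, CONDITION_2, CONDITION_1)
    return out


def assemble_score_matrix(rows: pd.DataFrame) -> pd.DataFrame:
    """Attach global and per-condition ranks; order columns for export.

    Ranks are by SS descending with a deterministic (mirna_id, circ_id)
    lexicographic tiebreak; per-condition ranks use the same order within
    each condition stratum.
    """
    out = rows.sort_values(
        by=["ss", "mirna_id", "circ_id"], ascending=[False, True, True], kind="stable"
    ).reset_index(drop=True)
    out["rank_global"] = np.arange(1, len(out) + 1)
    out["rank_in_condition"] = out.groupby("condition").cumcount() + 1
    ties = out["ss"].duplicated(keep=False)
    if ties.any():
        logger.info(
            "score-matrix ranking: %d tied SS values broken lexicographically "
            "by (mirna_id, circ_id)",
            int(ties.sum()),
        )
    return out[SCORE_MATRIX_COLUMNS]
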
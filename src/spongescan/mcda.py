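"""TOPSIS multi-criteria scorer.

Canonical Hwang-Yoon variant: vector normalization of each criterion column,
multiplication by normalized weights, ideal/anti-ideal points per criterion
direction, Euclidean distances, closeness C = d- / (d+ + d-).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import EmptyInputError, WeightError

BENEFIT = "benefit"
COST = "cost"


@dataclass
class DecisionMatrix:
    """Alternatives x criteria with per-criterion direction and weight."""

    alternative_ids: list
    criterion_names: list[str]
    values: np.ndarray
    directions: list[str]
    weights: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n_alt, n_crit = self.values.shape
        if n_alt != len(self.alternative_ids) or n_crit != len(self.criterion_names):
            raise ValueError("decision matrix shape mismatch")
        if len(self.directions) != n_crit:
            raise ValueError("one direction per criterion required")
        if any(d not in (BENEFIT, COST) for d in self.directions):
            raise ValueError(f"directions must be '{BENEFIT}' or '{COST}'")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("decision matrix contains non-finite values")
        if self.weights is None:
            self.weights = np.full(n_crit, 1.0 / n_crit)
        else:
            w = np.asarray(self.weights, dtype=float)
            if w.shape != (n_crit,) or np.any(w <= 0) or not np.isfinite(w).all():
                raise WeightError(f"weights must be {n_crit} positive finite numbers")
            self.weights = w / w.sum()


def topsis(dm: DecisionMatrix) -> pd.Series:
    """Closeness coefficient in [0, 1] per alternative.

    All-zero columns normalize to zeros; a degenerate geometry where every
    alternative coincides with the ideal point (d+ + d- = 0) yields 0.5.
    """
    x = dm.values
    if x.shape[0] == 0:
        raise EmptyInputError("decision matrix has no alternatives")

    norms = np.sqrt((x**2).sum(axis=0))
    safe = np.where(norms == 0, 1.0, norms)
    r = x / safe  # all-zero column stays zero
    v = r * dm.weights

    is_benefit = np.array([d == BENEFIT for d in dm.directions])
    ideal = np.where(is_benefit, v.max(axis=0), v.min(axis=0))
    anti = np.where(is_benefit, v.min(axis=0), v.max(axis=0))

    d_pos = np.sqrt(((v - ideal) ** 2).sum(axis=1))
    d_neg = np.sqrt(((v - anti) ** 2).sum(axis=1))
    denom = d_pos + d_neg
    closeness = np.where(denom == 0, 0.5, d_neg / np.where(denom == 0, 1.0, denom))
    return pd.Series(closeness, index=pd.Index(dm.alternative_ids), name="closeness")
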
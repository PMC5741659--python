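"""P-values, multiple-testing correction, filtering and summaries.

Analytic p-values use the classical t transform of a Pearson correlation,
t = r * sqrt((n - 2) / (1 - r^2)) referred to Student's t with n - 2 degrees
of freedom (two-sided).  Because the stoichiometric correlation is a maximum
over a grid of weight assignments, the analytic p ignores selection; a
permutation alternative re-maximizes under each permutation of one side's
sample order and is therefore calibrated for the maximized statistic.
Multiple testing is corrected by Benjamini-Hochberg, applied jointly across
all splits (pairs, triplets and quadruples) of one analysis run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "SignificanceConfig",
    "correlation_pvalue",
    "permutation_pvalue",
    "adjust_bh",
    "filter_significant",
    "count_by_category",
    "summarize_distribution",
]

DEFAULT_THRESHOLDS = (0.8, 0.85, 0.9, 0.95)


@dataclass
class SignificanceConfig:
    alpha: float = 0.05
    thresholds: tuple = DEFAULT_THRESHOLDS
    method: str = "analytic"
    n_permutations: int = 1000
    seed: int | None = None

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if any(not 0 < t <= 1 for t in self.thresholds):
            raise ValueError("thresholds must lie in (0, 1]")
        if self.method not in ("analytic", "permutation"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.method == "permutation" and self.n_permutations < 100:
            raise ValueError("n_permutations must be >= 100")


def correlation_pvalue(r: float, n: int) -> float:
    """Two-sided p-value of a Pearson correlation ``r`` over ``n`` samples."""
    if n < 5:
        raise ValueError("need at least 5 samples")
    r = float(r)
    if abs(r) > 1 + 1e-12:
        raise ValueError("|r| must be <= 1")
    r = min(1.0, max(-1.0, r))
    denom = 1.0 - r * r
    if denom <= 0:
        return 0.0
    t = r * np.sqrt((n - 2) / denom)
    return float(2.0 * stats.t.sf(abs(t), n - 2))


def permutation_pvalue(
    log_values: np.ndarray,
    split,
    i_max: int = 4,
    n_permutations: int = 1000,
    seed: int | None = None,
) -> float:
    """Permutation p-value for the maximized stoichiometric correlation.

    The sample order of side B alone is permuted and the full maximization
    over weight grids is repeated per permutation, so the null distribution
    carries the same selection effect as the observed statistic.
    p = (1 + #{r_b >= r_obs}) / (B + 1).
    """
    from .sca import (
        DegenerateSplitError,
        _standardize,
        combine,
        reduced_coefficient_ratios,
    )

    if n_permutations < 100:
        raise ValueError("n_permutations must be >= 100")
    log_values = np.asarray(log_values, dtype=float)
    n = log_values.shape[0]
    ratios_a = reduced_coefficient_ratios(len(split.side_a), i_max)
    ratios_b = reduced_coefficient_ratios(len(split.side_b), i_max)
    za = [_standardize(combine(log_values, split.side_a, w)) for w in ratios_a]
    za = [z for z in za if z is not None]
    if not za:
        raise DegenerateSplitError("side A is degenerate")
    ZA = np.column_stack(za)
    B_cols = log_values[:, list(split.side_b)]

    def max_r(cols: np.ndarray) -> float:
        zb = [
            _standardize(cols @ np.asarray(w, dtype=float)) for w in ratios_b
        ]
        zb = [z for z in zb if z is not None]
        if not zb:
            return -np.inf
        return float((ZA.T @ np.column_stack(zb)).max())

    r_obs = max_r(B_cols)
    if not np.isfinite(r_obs):
        raise DegenerateSplitError("side B is degenerate")
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        r_b = max_r(B_cols[rng.permutation(n)])
        if r_b >= r_obs:
            exceed += 1
    return (1 + exceed) / (n_permutations + 1)


def adjust_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def filter_significant(records: pd.DataFrame, alpha: float, tau: float) -> pd.DataFrame:
    """Records with ``p_adj <= alpha`` and ``r >= tau`` (both inclusive)."""
    mask = (records["p_adj"] <= alpha) & (records["r"] >= tau)
    return records.loc[mask].reset_index(drop=True)


def count_by_category(
    records: pd.DataFrame,
    thresholds=DEFAULT_THRESHOLDS,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Significant-split counts per category at each threshold.

    Returns a DataFrame indexed by threshold with columns
    ``pairs, triplets, quadruples, total``.
    """
    rows = {}
    for tau in thresholds:
        sig = filter_significant(records, alpha, tau)
        by_cat = sig["category"].value_counts()
        pair = int(by_cat.get("pair", 0))
        trip = int(by_cat.get("triplet", 0))
        quad = int(by_cat.get("quadruple", 0))
        rows[tau] = {
            "pairs": pair,
            "triplets": trip,
            "quadruples": quad,
            "total": pair + trip + quad,
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "threshold"
    return out


def summarize_distribution(records: pd.DataFrame) -> dict:
    """Quintiles (0/20/40/60/80/100 percentiles) and ECDF of the r values."""
    if len(records) == 0:
        raise ValueError("no records to summarize")
    r = np.asarray(records["r"], dtype=float)
    quintiles = {
        q: float(np.percentile(r, q)) for q in (0, 20, 40, 60, 80, 100)
    }
    from statsmodels.distributions.empirical_distribution import ECDF

    ecdf = ECDF(r)
    support = np.sort(np.unique(r))
    return {
        "quintiles": quintiles,
        "ecdf_x": support,
        "ecdf_y": ecdf(support),
    }
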
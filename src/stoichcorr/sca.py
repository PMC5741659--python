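"""Constrained maximal correlation of integer-weighted sums of log-profiles.

The stoichiometric correlation of two disjoint metabolite subsets U_p, U_q
(each of cardinality at most two) is the maximum Pearson correlation between
f = sum_i beta_i * log(x_i), i in U_p, and g = sum_i eta_i * log(x_i),
i in U_q, with the weights restricted to positive integers {1, ..., I_max}
(default I_max = 4, the range of stoichiometric coefficients found in
genome-scale metabolic reconstructions).  Because Pearson correlation is
invariant to positive rescaling of either side, only the weight *ratio*
matters within a side, so the search runs over coprime weight tuples; the
result is identical to the exhaustive grid search.

If several weight assignments attain the maximal correlation (within a
relative tolerance of 1e-12), the assignment with the smallest Euclidean
norm of the concatenated weight vector (beta, eta) is reported, with
lexicographic order as the final deterministic tie-break.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from joblib import Parallel, delayed
from sklearn.base import BaseEstimator

from .profile_io import ProfileMatrix, ProfileValidationError, ResultTable

__all__ = [
    "Split",
    "DegenerateSplitError",
    "log_transform",
    "reduced_coefficient_ratios",
    "combine",
    "enumerate_splits",
    "count_splits",
    "max_stoich_correlation",
    "StoichiometricCorrelationAnalysis",
    "run_sca",
]

logger = logging.getLogger(__name__)

#: relative tolerance under which two correlations count as tied
TIE_TOL = 1e-12

CATEGORIES = ("pair", "triplet", "quadruple")


class DegenerateSplitError(ValueError):
    """Every coefficient choice produced a constant combination."""


@dataclass(frozen=True)
class Split:
    """Canonical split hypothesis: two disjoint index sets, each of size 1-2.

    Canonical form: members within a side strictly ascending and
    ``min(side_a) < min(side_b)``.
    """

    side_a: tuple[int, ...]
    side_b: tuple[int, ...]

    def __post_init__(self):
        a, b = self.side_a, self.side_b
        if not (1 <= len(a) <= 2 and 1 <= len(b) <= 2):
            raise ValueError("sides must have cardinality 1 or 2")
        if set(a) & set(b):
            raise ValueError("sides must be disjoint")
        if list(a) != sorted(a) or list(b) != sorted(b):
            raise ValueError("side members must be strictly ascending")
        if min(a) > min(b):
            raise ValueError("canonical form requires min(side_a) < min(side_b)")

    @property
    def category(self) -> str:
        size = len(self.side_a) + len(self.side_b)
        return CATEGORIES[size - 2]


def log_transform(m: ProfileMatrix) -> ProfileMatrix:
    """Element-wise natural logarithm of the abundance block.

    Missing values (NaN) pass through; any nonpositive value is a hard
    error naming the offending sample and metabolite.
    """
    arr = m.values.to_numpy(dtype=float)
    bad = np.isfinite(arr) & (arr <= 0)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ProfileValidationError(
            f"cannot log-transform nonpositive value {arr[i, j]!r} at sample "
            f"{m.values.index[i]!r}, metabolite {m.values.columns[j]!r}"
        )
    with np.errstate(invalid="ignore"):
        logged = np.log(arr)
    return ProfileMatrix(
        pd.DataFrame(logged, index=m.values.index, columns=m.values.columns),
        m.metadata,
    )


def reduced_coefficient_ratios(side_size: int, i_max: int = 4) -> list[tuple[int, ...]]:
    """All coprime weight tuples representing distinct ratios on one side.

    For a singleton side the single tuple ``(1,)`` suffices (correlation is
    invariant to positive scaling); for a two-member side every coprime
    ``(a, b)`` with ``1 <= a, b <= i_max``, sorted lexicographically.
    """
    if i_max < 1:
        raise ValueError("i_max must be >= 1")
    if side_size == 1:
        return [(1,)]
    if side_size == 2:
        return [
            (a, b)
            for a in range(1, i_max + 1)
            for b in range(1, i_max + 1)
            if math.gcd(a, b) == 1
        ]
    raise ValueError("side_size must be 1 or 2")


def combine(
    log_values: np.ndarray, members: Sequence[int], weights: Sequence[int]
) -> np.ndarray:
    """Weighted sum of the selected log-profile columns, per sample."""
    if len(members) != len(weights):
        raise ValueError("weights and members must have equal length")
    log_values = np.asarray(log_values, dtype=float)
    n_cols = log_values.shape[1]
    for m in members:
        if not (0 <= m < n_cols):
            raise IndexError(f"metabolite index {m} out of range")
    out = np.zeros(log_values.shape[0])
    for m, w in zip(members, weights):
        out = out + w * log_values[:, m]
    return out


def enumerate_splits(n_metabolites: int, max_cardinality: int = 2) -> Iterator[Split]:
    """Yield every canonical split over ``n_metabolites`` indices.

    Pairs (singleton vs singleton), then triplet splits (each unordered
    triple contributes its 3 pair-vs-singleton partitions), then quadruple
    splits (each unordered quadruple contributes its 3 pair-vs-pair
    partitions).  Deterministic lexicographic order throughout.
    """
    if n_metabolites < 2:
        raise ValueError("need at least 2 metabolites")
    if max_cardinality != 2:
        raise ValueError("only cardinality-2 sides are supported")
    idx = range(n_metabolites)
    for i, j in combinations(idx, 2):
        yield Split((i,), (j,))
    for i, j, k in combinations(idx, 3):
        yield Split((i,), (j, k))
        yield Split((i, j), (k,))
        yield Split((i, k), (j,))
    for i, j, k, l in combinations(idx, 4):
        yield Split((i, j), (k, l))
        yield Split((i, k), (j, l))
        yield Split((i, l), (j, k))


def count_splits(n_metabolites: int) -> dict[str, int]:
    """Closed-form split counts: C(n,2) pairs, 3*C(n,3) triplets, 3*C(n,4) quadruples."""
    n = n_metabolites
    counts = {
        "pair": math.comb(n, 2),
        "triplet": 3 * math.comb(n, 3),
        "quadruple": 3 * math.comb(n, 4),
    }
    counts["total"] = sum(counts.values())
    return counts


# ---------------------------------------------------------------------------
# maximization engine


def _standardize(v: np.ndarray) -> np.ndarray | None:
    """Center and scale to unit norm; None when (numerically) constant."""
    c = v - v.mean()
    norm = np.linalg.norm(c)
    if norm == 0 or not np.isfinite(norm):
        return None
    if norm <= 1e-13 * max(1.0, float(np.abs(v).max())):
        return None
    return c / norm


def _select_best(
    r_matrix: np.ndarray,
    ratios_a: Sequence[tuple[int, ...]],
    ratios_b: Sequence[tuple[int, ...]],
    tie_tol: float = TIE_TOL,
) -> tuple[float, tuple[int, ...], tuple[int, ...]]:
    """Pick the maximal entry; ties broken by weight norm, then lexicographically."""
    finite = np.isfinite(r_matrix)
    if not finite.any():
        raise DegenerateSplitError("all coefficient choices are degenerate")
    rmax = r_matrix[finite].max()
    tol = tie_tol * max(1.0, abs(rmax))
    best_key = None
    best = None
    for i, j in zip(*np.nonzero(finite & (r_matrix >= rmax - tol))):
        ba, eb = ratios_a[i], ratios_b[j]
        key = (sum(x * x for x in ba) + sum(x * x for x in eb), ba, eb)
        if best_key is None or key < best_key:
            best_key = key
            best = (float(r_matrix[i, j]), ba, eb)
    return best


def max_stoich_correlation(
    log_values: np.ndarray,
    split: Split,
    i_max: int = 4,
    tie_tol: float = TIE_TOL,
) -> tuple[float, tuple[int, ...], tuple[int, ...]]:
    """Maximize Pearson correlation over integer weight assignments for one split.

    Parameters
    ----------
    log_values : (n_samples, n_metabolites) array of log abundances, no NaN.

    Returns
    -------
    (r, beta, eta) with reduced (coprime) weight tuples.

    Raises
    ------
    DegenerateSplitError
        when every weight choice yields a constant combination on a side.
    """
    log_values = np.asarray(log_values, dtype=float)
    if log_values.shape[0] < 5:
        raise ValueError("need at least 5 samples")
    ratios_a = reduced_coefficient_ratios(len(split.side_a), i_max)
    ratios_b = reduced_coefficient_ratios(len(split.side_b), i_max)
    za = [
        _standardize(combine(log_values, split.side_a, w)) for w in ratios_a
    ]
    zb = [
        _standardize(combine(log_values, split.side_b, w)) for w in ratios_b
    ]
    return _select_best(_corr_matrix(za, zb), ratios_a, ratios_b, tie_tol)


def _pair_blocks(
    logX: np.ndarray, pairs: list[tuple[int, int]], ratios: list[tuple[int, ...]]
) -> dict[tuple[int, int], list[np.ndarray | None]]:
    """Standardized weighted-sum columns for every unordered pair, per ratio."""
    blocks = {}
    for i, j in pairs:
        blocks[(i, j)] = [
            _standardize(a * logX[:, i] + b * logX[:, j]) for a, b in ratios
        ]
    return blocks


def _corr_matrix(za, zb) -> np.ndarray:
    out = np.full((len(za), len(zb)), np.nan)
    valid_b = [(j, v) for j, v in enumerate(zb) if v is not None]
    if not valid_b:
        return out
    vb = np.column_stack([v for _, v in valid_b])
    cols = [j for j, _ in valid_b]
    for i, u in enumerate(za):
        if u is None:
            continue
        out[i, cols] = np.clip(u @ vb, -1.0, 1.0)
    return out


def _compute_records(
    logX: np.ndarray,
    splits: list[Split],
    i_max: int,
    tie_tol: float,
) -> tuple[list[tuple], list[dict]]:
    """Fast path: complete data, shared standardized blocks."""
    one = [(1,)]
    ratios2 = reduced_coefficient_ratios(2, i_max)
    singles = [_standardize(logX[:, i]) for i in range(logX.shape[1])]
    needed_pairs = sorted(
        {s.side_a for s in splits if len(s.side_a) == 2}
        | {s.side_b for s in splits if len(s.side_b) == 2}
    )
    blocks = _pair_blocks(logX, needed_pairs, ratios2)
    n = logX.shape[0]
    rows, skipped = [], []
    for s in splits:
        za = [singles[s.side_a[0]]] if len(s.side_a) == 1 else blocks[s.side_a]
        zb = [singles[s.side_b[0]]] if len(s.side_b) == 1 else blocks[s.side_b]
        ra = one if len(s.side_a) == 1 else ratios2
        rb = one if len(s.side_b) == 1 else ratios2
        try:
            r, beta, eta = _select_best(_corr_matrix(za, zb), ra, rb, tie_tol)
        except DegenerateSplitError:
            skipped.append(
                {"side_a": s.side_a, "side_b": s.side_b, "reason": "degenerate"}
            )
            continue
        rows.append((s, beta, eta, r, n))
    return rows, skipped


def _compute_records_complete_case(
    logX: np.ndarray,
    splits: list[Split],
    i_max: int,
    tie_tol: float,
    min_samples: int,
) -> tuple[list[tuple], list[dict]]:
    """Slow path: per-split complete-case sample selection (missing data)."""
    rows, skipped = [], []
    finite = np.isfinite(logX)
    for s in splits:
        cols = list(s.side_a) + list(s.side_b)
        mask = finite[:, cols].all(axis=1)
        n_used = int(mask.sum())
        if n_used < min_samples:
            skipped.append(
                {
                    "side_a": s.side_a,
                    "side_b": s.side_b,
                    "reason": f"only {n_used} usable samples (< {min_samples})",
                }
            )
            continue
        try:
            r, beta, eta = max_stoich_correlation(
                logX[mask], s, i_max=i_max, tie_tol=tie_tol
            )
        except DegenerateSplitError:
            skipped.append(
                {"side_a": s.side_a, "side_b": s.side_b, "reason": "degenerate"}
            )
            continue
        rows.append((s, beta, eta, r, n_used))
    return rows, skipped


class StoichiometricCorrelationAnalysis(BaseEstimator):
    """Detect couplings of reaction rates from metabolite profiles.

    For every canonical split of the metabolites into two disjoint subsets
    of cardinality at most two, the estimator maximizes the Pearson
    correlation between positive integer-weighted sums of the
    log-transformed profiles (weights in ``{1, ..., i_max}``), attaches
    p-values, and applies Benjamini-Hochberg correction jointly across all
    tested splits.

    Parameters
    ----------
    i_max : int, default=4
        Upper bound of the integer weight set.
    alpha : float, default=0.05
        FDR level used by :meth:`significant` when none is given.
    thresholds : tuple of float, default=(0.8, 0.85, 0.9, 0.95)
        Correlation cutoffs for :meth:`counts_by_category`.
    pvalue_method : {"analytic", "permutation"}, default="analytic"
        Analytic t-based correlation p-values, or a permutation null that
        re-maximizes per permutation (accounting for selection over the
        weight grid).
    n_permutations : int, default=1000
        Permutations per split when ``pvalue_method="permutation"``.
    min_samples : int, default=5
        Minimum usable samples per split; splits below are skipped and logged.
    nonpositive : {"error", "drop-sample", "offset"}, default="error"
        Policy for nonpositive/missing abundances.
    offset : float, optional
        Constant added under the ``"offset"`` policy.
    n_jobs : int, optional
        Parallel workers over split chunks; any value yields identical output.
    random_state : int, optional
        Seed for the permutation null.

    Attributes
    ----------
    records_ : pandas.DataFrame
        One row per computable split: category, side_A_members,
        side_B_members, beta, eta, r, n_used, p, p_adj.
    skipped_ : list of dict
        Skipped splits with reasons.
    n_splits_ : int
        Number of enumerated split hypotheses.
    feature_names_in_ : ndarray of str
        Metabolite names seen during :meth:`fit`.
    """

    def __init__(
        self,
        i_max: int = 4,
        alpha: float = 0.05,
        thresholds: tuple = (0.8, 0.85, 0.9, 0.95),
        pvalue_method: str = "analytic",
        n_permutations: int = 1000,
        min_samples: int = 5,
        nonpositive: str = "error",
        offset: float | None = None,
        n_jobs: int | None = None,
        random_state: int | None = None,
    ):
        self.i_max = i_max
        self.alpha = alpha
        self.thresholds = thresholds
        self.pvalue_method = pvalue_method
        self.n_permutations = n_permutations
        self.min_samples = min_samples
        self.nonpositive = nonpositive
        self.offset = offset
        self.n_jobs = n_jobs
        self.random_state = random_state

    # -- fitting ------------------------------------------------------------

    def _validate_params_(self):
        if self.i_max < 1:
            raise ValueError("i_max must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if any(not 0 < t <= 1 for t in self.thresholds):
            raise ValueError("thresholds must lie in (0, 1]")
        if self.pvalue_method not in ("analytic", "permutation"):
            raise ValueError(f"unknown pvalue_method {self.pvalue_method!r}")
        if self.pvalue_method == "permutation" and self.n_permutations < 100:
            raise ValueError("n_permutations must be >= 100")
        if self.min_samples < 5:
            raise ValueError("min_samples must be >= 5")

    def _coerce(self, X) -> pd.DataFrame:
        if isinstance(X, ProfileMatrix):
            X = X.values
        if isinstance(X, pd.DataFrame):
            df = X.astype(float)
        else:
            arr = np.asarray(X, dtype=float)
            if arr.ndim != 2:
                raise ValueError("X must be 2-dimensional")
            df = pd.DataFrame(arr, columns=[f"x{i}" for i in range(arr.shape[1])])
        if df.shape[1] < 2:
            raise ValueError("need at least 2 metabolites")
        return df

    def fit(self, X, y=None):
        """Run the analysis on a samples x metabolites table of abundances."""
        from . import significance

        self._validate_params_()
        df = self._coerce(X)
        arr = df.to_numpy()
        nonpos = np.isfinite(arr) & (arr <= 0)
        has_missing = np.isnan(arr).any()
        if nonpos.any() or has_missing:
            if self.nonpositive == "error":
                ProfileMatrix(df).validate(require_positive=True)
                raise ProfileValidationError("missing value in input")
            elif self.nonpositive == "offset":
                if self.offset is None or self.offset <= 0:
                    raise ValueError("'offset' policy requires a positive offset")
                arr = arr + self.offset
                if (arr[np.isfinite(arr)] <= 0).any():
                    raise ProfileValidationError("offset too small")
            elif self.nonpositive == "drop-sample":
                arr = np.where(nonpos, np.nan, arr)
            else:
                raise ValueError(f"unknown nonpositive policy {self.nonpositive!r}")
        with np.errstate(invalid="ignore"):
            logX = np.log(arr)

        names = list(df.columns)
        splits = list(enumerate_splits(len(names)))
        self.n_splits_ = len(splits)
        complete = np.isfinite(logX).all()

        n_jobs = self.n_jobs or 1
        chunks = self._chunk(splits, n_jobs)
        worker = (
            _compute_records if complete else _compute_records_complete_case
        )
        results = Parallel(n_jobs=n_jobs)(
            delayed(worker)(
                logX,
                chunk,
                self.i_max,
                TIE_TOL,
                *(() if complete else (self.min_samples,)),
            )
            for chunk in chunks
        )
        rows: list[tuple] = []
        skipped: list[dict] = []
        for rws, skp in results:
            rows.extend(rws)
            skipped.extend(skp)

        if self.pvalue_method == "analytic":
            p = np.array(
                [significance.correlation_pvalue(r, n) for (_, _, _, r, n) in rows]
            )
        else:
            rng = np.random.default_rng(self.random_state)
            p = np.array(
                [
                    significance.permutation_pvalue(
                        logX[np.isfinite(logX[:, list(s.side_a) + list(s.side_b)]).all(axis=1)],
                        s,
                        i_max=self.i_max,
                        n_permutations=self.n_permutations,
                        seed=int(rng.integers(2**31 - 1)),
                    )
                    for (s, _, _, _, _) in rows
                ]
            )
        p_adj = significance.adjust_bh(p) if len(p) else p

        self.records_ = pd.DataFrame(
            {
                "category": [s.category for (s, *_ ) in rows],
                "side_A_members": [
                    tuple(names[i] for i in s.side_a) for (s, *_ ) in rows
                ],
                "side_B_members": [
                    tuple(names[i] for i in s.side_b) for (s, *_ ) in rows
                ],
                "beta": [beta for (_, beta, _, _, _) in rows],
                "eta": [eta for (_, _, eta, _, _) in rows],
                "r": [r for (_, _, _, r, _) in rows],
                "n_used": [n for (_, _, _, _, n) in rows],
                "p": p,
                "p_adj": p_adj,
            }
        )
        self.skipped_ = skipped
        self.n_features_in_ = len(names)
        self.feature_names_in_ = np.asarray(names, dtype=object)
        logger.info(
            "SCA: tested %d splits (%d computable, %d skipped)",
            self.n_splits_,
            len(rows),
            len(skipped),
        )
        return self

    @staticmethod
    def _chunk(splits: list, n_jobs: int) -> list[list]:
        if n_jobs <= 1 or len(splits) < 64:
            return [splits]
        k = max(1, len(splits) // (4 * n_jobs))
        return [splits[i : i + k] for i in range(0, len(splits), k)]

    # -- views --------------------------------------------------------------

    def _check_fitted(self):
        if not hasattr(self, "records_"):
            raise AttributeError("estimator is not fitted yet; call fit first")

    def significant(self, tau: float = 0.8, alpha: float | None = None) -> pd.DataFrame:
        """Records with ``p_adj <= alpha`` and ``r >= tau``."""
        from . import significance

        self._check_fitted()
        return significance.filter_significant(
            self.records_, alpha if alpha is not None else self.alpha, tau
        )

    def counts_by_category(
        self, thresholds: Sequence[float] | None = None, alpha: float | None = None
    ) -> pd.DataFrame:
        from . import significance

        self._check_fitted()
        return significance.count_by_category(
            self.records_,
            thresholds if thresholds is not None else self.thresholds,
            alpha if alpha is not None else self.alpha,
        )

    def coupling_degrees(self, tau: float = 0.8, alpha: float | None = None) -> pd.Series:
        from . import compare

        self._check_fitted()
        return compare.coupling_degree(
            self.records_,
            tau,
            alpha if alpha is not None else self.alpha,
            metabolites=list(self.feature_names_in_),
        )

    def result_table(self, provenance: dict | None = None) -> ResultTable:
        self._check_fitted()
        prov = {"params": {k: _jsonable(v) for k, v in self.get_params().items()}}
        if provenance:
            prov.update(provenance)
        return ResultTable(self.records_.copy(), prov)


def _jsonable(v):
    if isinstance(v, tuple):
        return list(v)
    if isinstance(v, (np.integer, np.floating)):
        return v.item()
    return v


def run_sca(
    m: ProfileMatrix | pd.DataFrame,
    provenance: dict | None = None,
    **params,
) -> ResultTable:
    """One-call analysis: fit the estimator and return a :class:`ResultTable`."""
    est = StoichiometricCorrelationAnalysis(**params)
    est.fit(m)
    return est.result_table(provenance)
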
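"""Independent reference implementations used to check the package.

Everything here is deliberately naive (exhaustive grids, hand-rolled
step-up, textbook formulas) and shares no code with the implementation
under test.
"""

from __future__ import annotations

from itertools import combinations, product
from math import gcd

import numpy as np
from scipy import stats

TIE_TOL = 1e-12


def brute_force_max(
    logX: np.ndarray,
    side_a: tuple[int, ...],
    side_b: tuple[int, ...],
    i_max: int = 4,
):
    """Exhaustive grid search over {1..i_max}^|A| x {1..i_max}^|B|.

    Ties within 1e-12 relative are resolved by the smallest Euclidean norm
    of the reduced concatenated weight vector, then lexicographically.
    Returns (r, reduced beta, reduced eta).
    """
    cands = []
    for beta in product(range(1, i_max + 1), repeat=len(side_a)):
        va = np.zeros(logX.shape[0])
        for w, m in zip(beta, side_a):
            va = va + w * logX[:, m]
        if np.std(va) < 1e-12:
            continue
        for eta in product(range(1, i_max + 1), repeat=len(side_b)):
            vb = np.zeros(logX.shape[0])
            for w, m in zip(eta, side_b):
                vb = vb + w * logX[:, m]
            if np.std(vb) < 1e-12:
                continue
            r = float(np.corrcoef(va, vb)[0, 1])
            cands.append((r, _reduce(beta), _reduce(eta)))
    if not cands:
        return None
    rmax = max(r for r, _, _ in cands)
    tol = TIE_TOL * max(1.0, abs(rmax))
    ties = [(r, b, e) for r, b, e in cands if r >= rmax - tol]
    r, b, e = min(
        ties,
        key=lambda t: (
            sum(x * x for x in t[1]) + sum(x * x for x in t[2]),
            t[1],
            t[2],
        ),
    )
    return r, b, e


def _reduce(t: tuple[int, ...]) -> tuple[int, ...]:
    g = t[0] if len(t) == 1 else gcd(*t)
    return tuple(x // g for x in t)


def enumerate_splits_brute(n: int) -> set[tuple]:
    """All canonical splits by filtering every (A, B) subset pair."""
    idx = range(n)
    out = set()
    subsets = [c for k in (1, 2) for c in combinations(idx, k)]
    for a in subsets:
        for b in subsets:
            if set(a) & set(b):
                continue
            if min(a) > min(b):
                continue
            out.add((a, b))
    return out


def bh_stepup(p: np.ndarray) -> np.ndarray:
    """Hand-rolled Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        adj[i] = running
    return adj


def pearson_pvalue_beta(r: float, n: int) -> float:
    """Two-sided Pearson p via the beta form of the null distribution of r."""
    ab = n / 2.0 - 1.0
    return float(2.0 * stats.beta.cdf(0.5 * (1.0 - abs(r)), ab, ab))


def quantile_sort_index(values: np.ndarray, q_percent: float) -> float:
    """Sort-and-interpolate percentile (linear between closest ranks)."""
    v = np.sort(np.asarray(values, dtype=float))
    pos = (len(v) - 1) * q_percent / 100.0
    lo = int(np.floor(pos))
    hi = int(np.ceil(pos))
    frac = pos - lo
    return float(v[lo] * (1 - frac) + v[hi] * frac)


def membership_counts(records, names) -> dict[str, int]:
    """Count record participation per metabolite by plain iteration."""
    counts = {m: 0 for m in names}
    for _, row in records.iterrows():
        for m in tuple(row["side_A_members"]) + tuple(row["side_B_members"]):
            counts[m] += 1
    return counts
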
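"""Per-metabolite coupling degrees and cross-dataset overlap of result sets.

The coupling degree of a metabolite S at threshold tau is the number of
significant stoichiometric correlations (p_adj <= alpha, r >= tau) in which
S participates on either side.  Overlap between two result sets matches
records by canonical split identity (metabolite membership of the two
sides), optionally also requiring identical reduced coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .profile_io import ResultTable
from .significance import filter_significant

__all__ = ["OverlapReport", "coupling_degree", "rank_coupled", "overlap"]

CATEGORIES = ("pair", "triplet", "quadruple")


def _norm_name(name: str) -> str:
    return " ".join(str(name).casefold().split())


def _records(results) -> pd.DataFrame:
    return results.records if isinstance(results, ResultTable) else results


def coupling_degree(
    results,
    tau: float = 0.8,
    alpha: float = 0.05,
    metabolites: list[str] | None = None,
) -> pd.Series:
    """Count significant records each metabolite participates in.

    ``metabolites`` fixes the output namespace (absent metabolites get 0);
    by default the union of names appearing in the records is used.
    """
    records = _records(results)
    sig = filter_significant(records, alpha, tau)
    if metabolites is None:
        metabolites = sorted(
            {m for t in records["side_A_members"] for m in t}
            | {m for t in records["side_B_members"] for m in t}
        )
    counts = {m: 0 for m in metabolites}
    for a, b in zip(sig["side_A_members"], sig["side_B_members"]):
        for m in tuple(a) + tuple(b):
            if m in counts:
                counts[m] += 1
    out = pd.Series(counts, name="degree").sort_index()
    out.index.name = "metabolite"
    return out


def rank_coupled(table: pd.Series, k: int = 10) -> list[str]:
    """Top-k metabolites by descending degree; ties broken alphabetically."""
    if k < 1:
        raise ValueError("k must be >= 1")
    ordered = sorted(table.items(), key=lambda kv: (-kv[1], str(kv[0])))
    return [name for name, _ in ordered[:k]]


@dataclass
class OverlapReport:
    """Shared and unique significant records per category, between two runs."""

    mode: str
    tau: float
    alpha: float
    shared: dict[str, set] = field(default_factory=dict)
    unique_a: dict[str, set] = field(default_factory=dict)
    unique_b: dict[str, set] = field(default_factory=dict)

    def counts(self) -> pd.DataFrame:
        rows = {}
        for cat in CATEGORIES:
            rows[cat] = {
                "shared": len(self.shared.get(cat, ())),
                "unique_A": len(self.unique_a.get(cat, ())),
                "unique_B": len(self.unique_b.get(cat, ())),
            }
        df = pd.DataFrame.from_dict(rows, orient="index")
        df.index.name = "category"
        df.loc["total"] = df.sum()
        return df


def _keys(records: pd.DataFrame, mode: str) -> dict[str, set]:
    out: dict[str, set] = {c: set() for c in CATEGORIES}
    for _, row in records.iterrows():
        a = tuple(_norm_name(m) for m in row["side_A_members"])
        b = tuple(_norm_name(m) for m in row["side_B_members"])
        key = (a, b)
        if mode == "split+coefficients":
            key = (a, b, tuple(row["beta"]), tuple(row["eta"]))
        out[row["category"]].add(key)
    return out


def overlap(
    results_a,
    results_b,
    mode: str = "split",
    tau: float = 0.8,
    alpha: float = 0.05,
) -> OverlapReport:
    """Shared/unique significant records of two result sets, per category.

    Metabolite names are matched after case-folding and whitespace
    normalization; fully disjoint namespaces raise, partially unmatched
    names are reported on the returned object as ``unmatched_names``.
    """
    if mode not in ("split", "split+coefficients"):
        raise ValueError(f"unknown overlap mode {mode!r}")
    ra, rb = _records(results_a), _records(results_b)
    names_a = {
        _norm_name(m)
        for t in list(ra["side_A_members"]) + list(ra["side_B_members"])
        for m in t
    }
    names_b = {
        _norm_name(m)
        for t in list(rb["side_A_members"]) + list(rb["side_B_members"])
        for m in t
    }
    if names_a and names_b and not (names_a & names_b):
        raise ValueError("result sets share no metabolite names")
    keys_a = _keys(filter_significant(ra, alpha, tau), mode)
    keys_b = _keys(filter_significant(rb, alpha, tau), mode)
    report = OverlapReport(mode=mode, tau=tau, alpha=alpha)
    for cat in CATEGORIES:
        report.shared[cat] = keys_a[cat] & keys_b[cat]
        report.unique_a[cat] = keys_a[cat] - keys_b[cat]
        report.unique_b[cat] = keys_b[cat] - keys_a[cat]
    report.unmatched_names = sorted((names_a | names_b) - (names_a & names_b))
    return report
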
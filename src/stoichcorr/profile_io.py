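"""Reading, writing and validation of metabolite profile tables and result tables.

A profile matrix is a samples x metabolites table of strictly positive
abundances (arbitrary concentration units).  The first column of an input
file holds the sample identifier; metadata columns (condition, time,
replicate, ...) are declared by name and split off from the numeric block.
Result tables are TSV files with ``#``-prefixed provenance header lines.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ProfileMatrix",
    "ResultTable",
    "ProfileValidationError",
    "read_profile_matrix",
    "write_profile_matrix",
    "aggregate_replicates",
    "read_result_table",
    "write_result_table",
    "RESULT_COLUMNS",
]

#: canonical column order of a serialized result table
RESULT_COLUMNS = [
    "category",
    "side_A_members",
    "side_B_members",
    "beta",
    "eta",
    "r",
    "n_used",
    "p",
    "p_adj",
]


class ProfileValidationError(ValueError):
    """Raised when a profile table violates the analysis preconditions."""


@dataclass
class ProfileMatrix:
    """Samples x metabolites abundance matrix with optional sample metadata.

    Attributes
    ----------
    values : pandas.DataFrame
        Numeric block, index = sample ids, columns = metabolite names.
    metadata : pandas.DataFrame or None
        Per-sample fields (condition, time, replicate, ...), same index.
    """

    values: pd.DataFrame
    metadata: pd.DataFrame | None = None

    @property
    def sample_ids(self) -> list:
        return list(self.values.index)

    @property
    def metabolite_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_metabolites(self) -> int:
        return self.values.shape[1]

    def validate(self, require_positive: bool = True) -> "ProfileMatrix":
        """Check structural invariants; return self for chaining."""
        cols = list(self.values.columns)
        if len(cols) == 0 or self.values.shape[0] == 0:
            raise ProfileValidationError("empty profile table")
        dupes = [c for c in set(cols) if cols.count(c) > 1]
        if dupes:
            raise ProfileValidationError(
                f"duplicate metabolite names: {sorted(dupes)}"
            )
        if any(not str(c).strip() for c in cols):
            raise ProfileValidationError("empty metabolite name")
        arr = self.values.to_numpy(dtype=float)
        finite = np.isfinite(arr)
        if not finite.all():
            # NaN is allowed only as an explicit missing-value marker; +-inf never
            if np.isinf(arr).any():
                raise ProfileValidationError("non-finite (inf) value in table")
        if require_positive:
            bad = finite & (arr <= 0)
            if bad.any():
                i, j = np.argwhere(bad)[0]
                raise ProfileValidationError(
                    "nonpositive value "
                    f"{arr[i, j]!r} at sample {self.values.index[i]!r}, "
                    f"metabolite {self.values.columns[j]!r}"
                )
        if self.metadata is not None and not self.metadata.index.equals(
            self.values.index
        ):
            raise ProfileValidationError("metadata index mismatch")
        return self

    def __eq__(self, other) -> bool:  # structural equality, used in tests
        if not isinstance(other, ProfileMatrix):
            return NotImplemented
        same_meta = (self.metadata is None) == (other.metadata is None)
        if same_meta and self.metadata is not None:
            same_meta = self.metadata.equals(other.metadata)
        return same_meta and self.values.equals(other.values)


def read_profile_matrix(
    path,
    sep: str = "\t",
    metadata_columns: Sequence[str] = (),
    nonpositive: str = "error",
    offset: float | None = None,
) -> ProfileMatrix:
    """Read a wide profile table (first column = sample id).

    Parameters
    ----------
    sep : field separator; ``"\\t"`` (default) or ``","``.
    metadata_columns : names of columns to treat as sample metadata.
    nonpositive : policy for nonpositive abundances.
        ``"error"`` (default) — hard error; ``"drop-sample"`` — mark as
        missing (complete-case handling downstream); ``"offset"`` — add
        the constant ``offset`` to every value.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    # pandas silently mangles duplicate header names; check the raw header
    with open(path) as fh:
        for line in fh:
            if line.strip() and not line.startswith("#"):
                header = [c.strip() for c in line.rstrip("\n").split(sep)][1:]
                break
        else:
            raise ProfileValidationError(f"empty profile table: {path}")
    dupes = sorted({c for c in header if header.count(c) > 1})
    if dupes:
        raise ProfileValidationError(f"duplicate metabolite names: {dupes}")
    df = pd.read_csv(path, sep=sep, index_col=0, comment="#")
    if df.shape[1] == 0 or df.shape[0] == 0:
        raise ProfileValidationError(f"empty profile table: {path}")
    missing_meta = [c for c in metadata_columns if c not in df.columns]
    if missing_meta:
        raise ProfileValidationError(
            f"metadata columns not found: {missing_meta}"
        )
    meta = df[list(metadata_columns)] if metadata_columns else None
    num = df.drop(columns=list(metadata_columns))

    parsed = num.apply(pd.to_numeric, errors="coerce")
    unparseable = parsed.isna() & num.notna()
    bad_rows = unparseable.any(axis=1)
    if bad_rows.any():
        idx = list(num.index[bad_rows])
        warnings.warn(
            f"rejected {bad_rows.sum()} row(s) with unparseable numeric "
            f"cells: {idx}",
            stacklevel=2,
        )
        parsed = parsed.loc[~bad_rows]
        if meta is not None:
            meta = meta.loc[~bad_rows]
    parsed = parsed.astype(float)

    arr = parsed.to_numpy()
    nonpos = np.isfinite(arr) & (arr <= 0)
    if nonpos.any() or np.isnan(arr).any():
        if nonpositive == "error":
            m = ProfileMatrix(parsed, meta)
            m.validate(require_positive=True)  # raises with location
            raise ProfileValidationError("missing value in table")
        elif nonpositive == "drop-sample":
            parsed = parsed.mask(nonpos)
        elif nonpositive == "offset":
            if offset is None or offset <= 0:
                raise ProfileValidationError(
                    "policy 'offset' requires a positive offset constant"
                )
            parsed = parsed + offset
            if (parsed.to_numpy() <= 0).any():
                raise ProfileValidationError(
                    "offset too small: nonpositive values remain"
                )
        else:
            raise ValueError(f"unknown nonpositive policy {nonpositive!r}")
    return ProfileMatrix(parsed, meta).validate(require_positive=False)


def write_profile_matrix(m: ProfileMatrix, path, sep: str = "\t") -> None:
    df = m.values
    if m.metadata is not None:
        df = pd.concat([m.metadata, m.values], axis=1)
    df.to_csv(path, sep=sep, index_label="sample_id", float_format="%.17g")


def aggregate_replicates(
    m: ProfileMatrix,
    policy: str = "none",
    group_keys: Sequence[str] = (),
) -> ProfileMatrix:
    """Collapse replicate rows by metadata group.

    ``policy="none"`` returns the input unchanged (every row treated as an
    independent sample, the default analysis mode).  ``"mean"``/``"median"``
    aggregate the numeric block over the groups defined by ``group_keys``.
    """
    if policy == "none":
        return m
    if policy not in ("mean", "median"):
        raise ValueError(f"unknown replicate policy {policy!r}")
    if m.metadata is None:
        raise ProfileValidationError("aggregation requires sample metadata")
    missing = [k for k in group_keys if k not in m.metadata.columns]
    if missing or not group_keys:
        raise ProfileValidationError(
            f"group keys not found in metadata: {missing or 'none given'}"
        )
    keys = list(group_keys)
    grouped = m.values.groupby([m.metadata[k] for k in keys], sort=True)
    agg = grouped.mean() if policy == "mean" else grouped.median()
    if len(keys) == 1:
        agg.index = [str(v) for v in agg.index]
    else:
        agg.index = ["/".join(str(v) for v in tup) for tup in agg.index]
    meta_first = m.metadata.groupby(
        [m.metadata[k] for k in keys], sort=True
    ).first()
    meta_first.index = agg.index
    return ProfileMatrix(agg, meta_first)


# ---------------------------------------------------------------------------
# result tables


@dataclass
class ResultTable:
    """Ordered collection of stoichiometric-correlation records + provenance.

    ``records`` is a DataFrame with columns ``category`` (pair / triplet /
    quadruple), ``side_A_members`` / ``side_B_members`` (tuples of metabolite
    names), ``beta`` / ``eta`` (tuples of reduced integer weights), ``r``,
    ``n_used``, ``p`` and ``p_adj``.
    """

    records: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        missing = [c for c in RESULT_COLUMNS if c not in self.records.columns]
        if missing:
            raise ValueError(f"result table missing columns: {missing}")
        self.records = self.records[RESULT_COLUMNS].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)

    def split_keys(self) -> set[tuple]:
        return {
            (tuple(a), tuple(b))
            for a, b in zip(
                self.records["side_A_members"], self.records["side_B_members"]
            )
        }

    def equals(self, other: "ResultTable", rtol: float = 1e-12) -> bool:
        a, b = self.records, other.records
        if len(a) != len(b):
            return False
        for col in ("category", "side_A_members", "side_B_members", "beta", "eta"):
            if list(a[col]) != list(b[col]):
                return False
        for col in ("r", "p", "p_adj"):
            if not np.allclose(a[col], b[col], rtol=rtol, atol=0, equal_nan=True):
                return False
        return list(a["n_used"]) == list(b["n_used"])


def _fmt_members(t: Iterable) -> str:
    return ",".join(str(x) for x in t)


def _parse_members(s: str) -> tuple[str, ...]:
    return tuple(x for x in str(s).split(",") if x != "")


def _parse_ints(s: str) -> tuple[int, ...]:
    return tuple(int(x) for x in str(s).split(",") if x != "")


def write_result_table(t: ResultTable, path) -> None:
    """Serialize to TSV; provenance as ``# key<TAB>json(value)`` header lines."""
    with open(path, "w") as fh:
        for key in sorted(t.provenance):
            fh.write(f"# {key}\t{json.dumps(t.provenance[key], sort_keys=True)}\n")
        out = t.records.copy()
        for col in ("side_A_members", "side_B_members", "beta", "eta"):
            out[col] = out[col].map(_fmt_members)
        out.to_csv(fh, sep="\t", index=False, float_format="%.17g")


def read_result_table(path) -> ResultTable:
    provenance: dict = {}
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for lineno, line in enumerate(lines):
        if line.startswith("#"):
            body_start = lineno + 1
            try:
                key, raw = line[1:].strip().split("\t", 1)
                provenance[key] = json.loads(raw)
            except ValueError as exc:
                raise ValueError(
                    f"{path}: malformed provenance header at line {lineno + 1}"
                ) from exc
        else:
            break
    from io import StringIO

    body = "".join(lines[body_start:])
    if not body.strip():
        raise ValueError(f"{path}: missing header row (line {body_start + 1})")
    try:
        df = pd.read_csv(StringIO(body), sep="\t", dtype={"category": str})
    except Exception as exc:
        raise ValueError(f"{path}: malformed result table") from exc
    missing = [c for c in RESULT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing} (line {body_start + 1})")
    if len(df):
        df["side_A_members"] = df["side_A_members"].map(_parse_members)
        df["side_B_members"] = df["side_B_members"].map(_parse_members)
        df["beta"] = df["beta"].map(_parse_ints)
        df["eta"] = df["eta"].map(_parse_ints)
    else:
        for col in ("side_A_members", "side_B_members", "beta", "eta"):
            df[col] = df[col].astype(object)
    df["n_used"] = df["n_used"].astype(int)
    return ResultTable(df, provenance)
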
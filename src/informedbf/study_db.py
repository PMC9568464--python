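"""Reading, validating, filtering and sampling study databases.

Two CSV schemas are supported. The correlation schema mirrors meta-analytic
correlation databases with two per-variable sample sizes
(``study_id, r, n1, n2``); the t-test schema mirrors collections of reported
t statistics (``study_id, design, t, n1, n2``). The filtering rules implement
the usual hygiene steps for reanalyzing such a correlation database: drop
perfect correlations, drop rows with unequal or non-integer sample sizes, and
restrict the sample-size range, then draw at most one record per study for
independence.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .bayes_factors import StudyRecord

__all__ = [
    "SchemaError",
    "CORRELATION_COLUMNS",
    "TTEST_COLUMNS",
    "read_tables",
    "validate_correlation_table",
    "validate_ttest_table",
    "filter_bosco",
    "sample_one_per_study",
    "correlation_records",
    "ttest_records",
    "write_table",
]

CORRELATION_COLUMNS = ("study_id", "r", "n1", "n2")
TTEST_COLUMNS = ("study_id", "design", "t", "n1", "n2")
_DESIGNS = ("one_sample", "paired", "independent")


class SchemaError(ValueError):
    """A table does not conform to the expected schema."""


def _check_columns(df: pd.DataFrame, required, schema: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{schema} table missing column(s): {missing}")


def validate_correlation_table(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and coerce a correlation table; raises SchemaError with row index."""
    _check_columns(df, CORRELATION_COLUMNS, "correlation")
    out = df.loc[:, list(CORRELATION_COLUMNS)].copy()
    for col in ("r", "n1", "n2"):
        parsed = pd.to_numeric(out[col], errors="coerce")
        bad = parsed.isna() & out[col].notna()
        if bad.any():
            raise SchemaError(
                f"unparseable {col!r} at row(s) {list(out.index[bad][:5])}"
            )
        if parsed.isna().any():
            raise SchemaError(f"missing {col!r} at row(s) {list(out.index[parsed.isna()][:5])}")
        out[col] = parsed
    bad = ~out["r"].between(-1.0, 1.0)
    if bad.any():
        raise SchemaError(f"r outside [-1, 1] at row(s) {list(out.index[bad][:5])}")
    bad = (out["n1"] <= 0) | (out["n2"] <= 0)
    if bad.any():
        raise SchemaError(f"non-positive sample size at row(s) {list(out.index[bad][:5])}")
    out["study_id"] = out["study_id"].astype(str)
    return out


def validate_ttest_table(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a t-test table; flags paired rows with n1 != n2 in ``attrs``."""
    _check_columns(df, TTEST_COLUMNS, "ttest")
    out = df.loc[:, list(TTEST_COLUMNS)].copy()
    bad = ~out["design"].isin(_DESIGNS)
    if bad.any():
        raise SchemaError(f"unknown design at row(s) {list(out.index[bad][:5])}")
    for col in ("t", "n1"):
        parsed = pd.to_numeric(out[col], errors="coerce")
        if parsed.isna().any():
            raise SchemaError(
                f"missing/unparseable {col!r} at row(s) {list(out.index[parsed.isna()][:5])}"
            )
        out[col] = parsed
    out["n2"] = pd.to_numeric(out["n2"], errors="coerce")
    indep = out["design"] == "independent"
    if out.loc[indep, "n2"].isna().any():
        raise SchemaError("independent rows need n2")
    small = (out["n1"] < 2) | (indep & (out["n2"] < 2))
    if small.any():
        raise SchemaError(f"sample sizes must be >= 2 at row(s) {list(out.index[small][:5])}")
    out["study_id"] = out["study_id"].astype(str)
    # paired designs use n = n1; rows reporting a different n2 are flagged, not dropped
    flagged = out.index[(out["design"] == "paired") & out["n2"].notna() & (out["n1"] != out["n2"])]
    out.attrs["paired_n_mismatch_rows"] = list(flagged)
    return out


def read_tables(
    path,
    schema: str,
    column_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Read and validate a study database CSV.

    Parameters
    ----------
    schema
        ``"correlation"`` or ``"ttest"``.
    column_map
        Optional mapping from the file's native headers to the canonical
        column names, for databases published with their own layouts.
    """
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=dict(column_map))
    if schema == "correlation":
        return validate_correlation_table(df)
    if schema == "ttest":
        return validate_ttest_table(df)
    raise ValueError(f"unknown schema {schema!r}")


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format="%.12g")


def filter_bosco(table: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the correlation-database hygiene rules, in order.

    1. remove perfect correlations (|r| = 1);
    2. remove rows with unequal or non-integer per-variable sample sizes;
    3. remove rows with n < 10 or n > 500.

    Returns the surviving rows and the per-rule removal counts (each rule is
    counted on the rows surviving the previous one).
    """
    table = validate_correlation_table(table)
    counts: dict[str, int] = {}

    keep = table["r"].abs() < 1.0
    counts["perfect_correlation"] = int((~keep).sum())
    table = table[keep]

    integer_n = (table["n1"] == np.floor(table["n1"])) & (
        table["n2"] == np.floor(table["n2"])
    )
    keep = (table["n1"] == table["n2"]) & integer_n
    counts["unequal_or_noninteger_n"] = int((~keep).sum())
    table = table[keep]

    keep = table["n1"].between(10, 500)
    counts["n_out_of_range"] = int((~keep).sum())
    table = table[keep]

    return table.reset_index(drop=True), counts


def sample_one_per_study(table: pd.DataFrame, k: int, seed: int) -> pd.DataFrame:
    """Draw ``k`` rows, at most one per study, uniformly without replacement.

    Within each selected study one of its rows is chosen uniformly;
    reproducible per seed.
    """
    rng = np.random.default_rng(seed)
    ids = table["study_id"].unique()
    if k > ids.size:
        raise ValueError(f"k={k} exceeds the {ids.size} distinct studies")
    chosen = rng.choice(ids, size=k, replace=False)
    groups = table.groupby("study_id", sort=False).indices
    rows = [groups[s][rng.integers(len(groups[s]))] for s in chosen]
    return table.iloc[rows].reset_index(drop=True)


def correlation_records(table: pd.DataFrame) -> list[StudyRecord]:
    """Convert a (filtered) correlation table to study records (n taken as n1)."""
    return [
        StudyRecord(study_id=row.study_id, kind="correlation", r=float(row.r), n=int(row.n1))
        for row in table.itertuples(index=False)
    ]


def ttest_records(table: pd.DataFrame) -> list[StudyRecord]:
    """Convert a t-test table to study records (paired/one-sample use n1)."""
    out = []
    for row in table.itertuples(index=False):
        n2 = int(row.n2) if row.design == "independent" else None
        out.append(
            StudyRecord(
                study_id=row.study_id,
                kind="ttest",
                design=row.design,
                t=float(row.t),
                n1=int(row.n1),
                n2=n2,
            )
        )
    return out
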
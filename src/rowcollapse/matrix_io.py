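"""Reading, writing and aligning expression-like matrices and row-group maps.

The on-disk convention matches the delimited files common in the R
expression-analysis ecosystem: a header row of sample identifiers, a first
column of unique row identifiers, and ``NA`` (or an empty cell) for missing
values.  In memory a matrix is a plain :class:`pandas.DataFrame` with row
identifiers on the index and sample identifiers on the columns; a group map
(row identifier -> group label) is a :class:`pandas.Series`.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Tokens treated as missing on read; missing cells are written back as "NA".
MISSING_TOKENS = ("NA", "NaN", "")


class MatrixFormatError(ValueError):
    """Raised when an input file violates the expression-matrix contract."""


def validate_expression(matrix: pd.DataFrame, *, drop_all_missing: bool = True) -> pd.DataFrame:
    """Validate (and lightly clean) an expression matrix.

    Enforces unique, non-empty row identifiers, unique column identifiers,
    float-valued entries, and — when ``drop_all_missing`` — drops rows whose
    values are entirely missing (with a logged count).
    """
    index = matrix.index.astype(str)
    if index.has_duplicates:
        dupes = sorted(index[index.duplicated()].unique())
        raise MatrixFormatError(f"duplicate row identifiers: {dupes}")
    if (index == "").any():
        raise MatrixFormatError("empty row identifier")
    columns = matrix.columns.astype(str)
    if columns.has_duplicates:
        dupes = sorted(columns[columns.duplicated()].unique())
        raise MatrixFormatError(f"duplicate sample identifiers: {dupes}")
    out = matrix.copy()
    out.index = index
    out.columns = columns
    try:
        out = out.astype(float)
    except (TypeError, ValueError) as exc:
        raise MatrixFormatError(f"non-numeric entries in matrix: {exc}") from exc
    if drop_all_missing:
        all_missing = out.isna().all(axis=1)
        if all_missing.any():
            logger.warning(
                "dropping %d row(s) with no non-missing values: %s",
                int(all_missing.sum()),
                list(out.index[all_missing][:10]),
            )
            out = out.loc[~all_missing]
    if out.shape[0] == 0:
        raise MatrixFormatError("matrix has no retained rows")
    return out


def read_expression(path: str | Path, delimiter: str = "\t") -> pd.DataFrame:
    """Read a delimited expression matrix (first column row IDs, header samples).

    Non-numeric cells other than the missing tokens raise
    :class:`MatrixFormatError` with the offending coordinates; duplicate row
    identifiers raise naming the duplicates.
    """
    raw = pd.read_csv(
        path,
        sep=delimiter,
        index_col=0,
        dtype=str,
        keep_default_na=False,
    )
    values = raw.replace(list(MISSING_TOKENS), np.nan)
    numeric = values.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & values.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise MatrixFormatError(
            f"non-numeric cell {values.iat[r, c]!r} at row {raw.index[r]!r}, "
            f"column {raw.columns[c]!r} in {path}"
        )
    return validate_expression(numeric)


def write_expression(matrix: pd.DataFrame, path: str | Path, delimiter: str = "\t") -> None:
    """Write a matrix in the same layout ``read_expression`` reads."""
    matrix.to_csv(path, sep=delimiter, na_rep="NA", index_label="")


def read_group_map(path: str | Path, delimiter: str = "\t") -> pd.Series:
    """Read a two-column (row_id, group) file into a row->group Series.

    Rows with a blank group are excluded with a logged warning.  The same
    row identifier mapped to two different groups is an error.
    """
    table = pd.read_csv(
        path, sep=delimiter, header=None, names=["row_id", "group"],
        dtype=str, keep_default_na=False, skip_blank_lines=True,
    )
    # tolerate a header line ("row_id<TAB>group" or similar non-data first row)
    blank = table["group"].str.strip() == ""
    if blank.any():
        logger.warning("excluding %d row(s) with blank group label", int(blank.sum()))
        table = table.loc[~blank]
    dup = table.drop_duplicates().groupby("row_id")["group"].nunique()
    conflicts = dup[dup > 1]
    if len(conflicts):
        raise MatrixFormatError(
            f"conflicting group assignments for row id(s): {sorted(conflicts.index)}"
        )
    table = table.drop_duplicates("row_id")
    return pd.Series(table["group"].to_numpy(), index=table["row_id"].to_numpy(), name="group")


def write_group_map(groups: pd.Series, path: str | Path, delimiter: str = "\t") -> None:
    groups.rename("group").to_csv(path, sep=delimiter, header=False)


def read_gene_list(path: str | Path) -> list[str]:
    """One identifier per line; blank lines ignored."""
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def align_to_groups(matrix: pd.DataFrame, groups: pd.Series) -> tuple[pd.DataFrame, pd.Series]:
    """Restrict a matrix to rows carrying a usable group label.

    Rows absent from the map or mapped to a blank label are unusable for
    collapsing and are dropped with a logged count.
    """
    groups = groups.astype(str)
    usable = groups[groups.str.strip() != ""]
    keep = matrix.index.intersection(usable.index)
    dropped = matrix.shape[0] - len(keep)
    if dropped:
        logger.warning("dropping %d row(s) without a usable group label", dropped)
    if len(keep) == 0:
        raise MatrixFormatError("no matrix rows carry a group label")
    sub = matrix.loc[keep]
    return sub, usable.loc[keep]


def intersect_on_groups(a: pd.DataFrame, b: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Restrict two collapsed matrices to their shared row labels.

    Both outputs carry the sorted intersection of labels in identical order,
    so row-wise statistics line up position by position.
    """
    shared = sorted(set(a.index) & set(b.index))
    if not shared:
        raise MatrixFormatError("no shared group labels between matrices")
    return a.loc[shared], b.loc[shared]
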
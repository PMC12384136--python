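"""Reading and writing two-column ratings files.

Accepted input: delimited text with exactly two numeric columns (one row
per subject), optionally with a header line.  The delimiter is sniffed
with :class:`csv.Sniffer` over comma/tab/semicolon (falling back to
comma), so plain CSV and TSV both work.  Rows with missing or non-numeric
cells are rejected with their 1-based file line numbers reported.
"""

from __future__ import annotations

import csv
import io

import numpy as np

from .errors import InvalidRatingsError
from .icc import RatingsMatrix, as_ratings

__all__ = ["read_ratings", "write_ratings"]

_DELIMITERS = ",\t;"


def _sniff_dialect(sample: str):
    try:
        return csv.Sniffer().sniff(sample, delimiters=_DELIMITERS)
    except csv.Error:
        return csv.get_dialect("excel")  # plain comma-separated


def _is_float(tok: str) -> bool:
    try:
        float(tok)
    except ValueError:
        return False
    return True


def read_ratings(path, has_header: bool | None = None) -> RatingsMatrix:
    """Parse a two-column delimited text file into a ratings matrix.

    Parameters
    ----------
    path
        File of >= 3 data rows with exactly two numeric columns.
    has_header
        True/False to force; None (default) auto-detects — the first row
        is treated as a header iff any of its cells is non-numeric.

    Raises
    ------
    FileNotFoundError
        Missing file.
    InvalidRatingsError
        Wrong column count, non-numeric cells (1-based line numbers are
        listed), or fewer than 3 data rows.
    """
    with open(path, "r", newline="") as fh:
        text = fh.read()
    lines = [(i + 1, ln) for i, ln in enumerate(text.splitlines()) if ln.strip()]
    if not lines:
        raise InvalidRatingsError(f"{path}: file contains no data")

    dialect = _sniff_dialect("\n".join(ln for _, ln in lines[:10]))
    parsed = []
    for lineno, ln in lines:
        row = next(csv.reader(io.StringIO(ln), dialect))
        parsed.append((lineno, [c.strip() for c in row]))

    first_cells = parsed[0][1]
    if has_header is None:
        has_header = not all(_is_float(c) for c in first_cells if c != "")
    if has_header:
        parsed = parsed[1:]
    if not parsed:
        raise InvalidRatingsError(f"{path}: no data rows after the header")

    bad_width = [lineno for lineno, row in parsed if len(row) != 2]
    if bad_width:
        raise InvalidRatingsError(
            f"{path}: expected exactly 2 columns, violated on line(s) "
            f"{bad_width[:20]}"
        )
    bad_rows = [
        lineno for lineno, row in parsed
        if not all(c != "" and _is_float(c) for c in row)
    ]
    if bad_rows:
        raise InvalidRatingsError(
            f"{path}: non-numeric or missing cells on line(s) {bad_rows[:20]}"
        )
    values = np.array([[float(a), float(b)] for _, (a, b) in parsed])
    if values.shape[0] < 3:
        raise InvalidRatingsError(
            f"{path}: need at least 3 subjects, got {values.shape[0]}"
        )
    return RatingsMatrix(values)


def write_ratings(path, ratings, header: bool = True) -> None:
    """Write a ratings matrix as CSV with full float precision.

    Uses ``repr``-exact formatting so a write/read round trip reproduces
    the matrix bit-for-bit.
    """
    r = as_ratings(ratings)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        if header:
            w.writerow(["rater1", "rater2"])
        for a, b in r.values:
            w.writerow([repr(float(a)), repr(float(b))])
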
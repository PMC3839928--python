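"""Readers and writers for the tab-delimited transcript/expression dialects.

Transcript tables carry one row per transcript: an identifier column, a
block of annotation columns (a delimiter-separated GO-term list, optional
0/1 flag columns, an optional ``length_nt`` column), and a block of numeric
profile columns labeled by migration distance in mm.  The profile block is
auto-detected as the maximal contiguous run of numeric-labeled columns;
everything to its left is identifier/annotation.

Expression tables carry two header lines: sample ids, then per-sample
condition labels.

All writers are deterministic and locale-independent (UTF-8, tab separators,
fixed decimal point and column order).
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path
from typing import Dict, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .enrichment import ExpressionMatrix
from .lengthstats import LengthTable
from .model import GelGrid
from .svd import ProfileMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "read_transcript_table",
    "write_transcript_table",
    "read_expression_matrix",
    "write_expression_matrix",
]

GO_COLUMN = "go_terms"
LENGTH_COLUMN = "length_nt"


def _numeric_labels(columns: Sequence[str]) -> list:
    out = []
    for c in columns:
        try:
            out.append(float(c))
        except ValueError:
            out.append(None)
    return out


def _detect_profile_block(columns: Sequence[str]) -> Tuple[int, int]:
    """Index range [start, stop) of the maximal contiguous run of
    numeric-labeled columns."""
    labels = _numeric_labels(columns)
    best = (0, 0)
    i = 0
    n = len(labels)
    while i < n:
        if labels[i] is None:
            i += 1
            continue
        j = i
        while j < n and labels[j] is not None:
            j += 1
        if j - i > best[1] - best[0]:
            best = (i, j)
        i = j
    if best[1] - best[0] < 2:
        raise ValueError("no numeric profile block found in the header")
    return best


def read_transcript_table(path, go_delimiter: str = ";"
                          ) -> Tuple[ProfileMatrix, LengthTable]:
    """Parse a tab-delimited transcript table into matched profile and
    length tables (shared ids and ordering)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False,
                     encoding="utf-8")
    if df.shape[0] == 0:
        raise ValueError(f"{path}: empty table")
    cols = list(df.columns)
    start, stop = _detect_profile_block(cols)
    profile_cols = cols[start:stop]
    positions = np.array([float(c) for c in profile_cols])
    if np.any(np.diff(positions) <= 0):
        raise ValueError(f"{path}: migration labels must be strictly increasing")
    ids = df.iloc[:, 0].tolist()

    values = np.empty((df.shape[0], len(profile_cols)))
    for j, c in enumerate(profile_cols):
        col = df[c]
        bad = col.index[col.str.strip() == ""]
        if len(bad):
            raise ValueError(
                f"{path}: missing profile value at row {bad[0] + 2}, column {c!r}")
        try:
            values[:, j] = col.astype(float)
        except ValueError as exc:
            raise ValueError(f"{path}: unparseable numeric in column {c!r}: {exc}")

    grid = GelGrid(positions)
    matrix = ProfileMatrix(values=values, row_ids=ids, grid=grid)

    annotation_sets: Dict[str, Set[str]] = {}
    lengths = None
    for c in cols[1:start]:
        col = df[c]
        if c == GO_COLUMN:
            for gid, cell in zip(ids, col):
                for term in str(cell).split(go_delimiter):
                    term = term.strip()
                    if term:
                        annotation_sets.setdefault(term, set()).add(gid)
        elif c == LENGTH_COLUMN:
            lengths = col.replace("", "nan").astype(float).to_numpy()
        elif set(col.unique()) <= {"0", "1"}:
            annotation_sets[c] = {g for g, v in zip(ids, col) if v == "1"}
        else:
            logger.warning("%s: unknown annotation column %r preserved as a "
                           "flat term list", path, c)
            for gid, cell in zip(ids, col):
                cell = str(cell).strip()
                if cell:
                    annotation_sets.setdefault(f"{c}={cell}", set()).add(gid)

    if lengths is None or np.any(~np.isfinite(lengths)):
        # impute missing lengths from profile-peak migration via the
        # calibration of the grid endpoints, flagged in the log
        from .model import fit_calibration
        logger.warning("%s: no complete length column; lengths imputed from "
                       "profile peaks via an endpoint calibration", path)
        peak_x = positions[np.argmax(values, axis=1)]
        lo, hi = positions[0], positions[-1]
        cal = fit_calibration([(lo, 6400.0), (hi, 500.0)])
        imputed = cal.migration_to_length(peak_x)
        lengths = imputed if lengths is None else np.where(
            np.isfinite(lengths), lengths, imputed)

    table = LengthTable(entity_ids=ids, lengths=lengths,
                        annotation_sets=annotation_sets)
    logger.info("%s: %d entities, %d slices, %d annotation terms (sha256 %s)",
                path, len(ids), grid.n_slices, len(annotation_sets),
                hashlib.sha256(path.read_bytes()).hexdigest()[:12])
    return matrix, table


def write_transcript_table(path, matrix: ProfileMatrix,
                           table: Optional[LengthTable] = None,
                           go_delimiter: str = ";") -> None:
    """Write a transcript table in the tab-delimited dialect read back by
    :func:`read_transcript_table`."""
    path = Path(path)
    cols: Dict[str, Sequence] = {"id": list(matrix.row_ids)}
    if table is not None:
        if list(table.entity_ids) != list(matrix.row_ids):
            raise ValueError("length table ids must match the profile matrix")
        terms = sorted(t for t in table.annotation_sets
                       if not t.startswith("flag:"))
        go_lists = []
        for gid in table.entity_ids:
            mine = sorted(t for t in terms if gid in table.annotation_sets[t])
            go_lists.append(go_delimiter.join(mine))
        cols[GO_COLUMN] = go_lists
        cols[LENGTH_COLUMN] = [f"{v:.6g}" for v in table.lengths]
    for j, x in enumerate(matrix.grid.positions):
        label = f"{x:g}"
        cols[label] = [f"{v:.10g}" for v in matrix.values[:, j]]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False, encoding="utf-8")


def read_expression_matrix(path) -> ExpressionMatrix:
    """Parse a two-header-line expression table (sample ids, conditions)."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\r\n").split("\t")
        cond_line = fh.readline().rstrip("\r\n").split("\t")
    if len(header) < 2:
        raise ValueError(f"{path}: malformed header, need id + sample columns")
    if len(cond_line) != len(header):
        raise ValueError(
            f"{path}: condition line has {len(cond_line)} fields, header has "
            f"{len(header)} (offending column {min(len(cond_line), len(header))})")
    if cond_line[0] != "condition":
        raise ValueError(f"{path}: second line must start with 'condition'")
    df = pd.read_csv(path, sep="\t", skiprows=[1], encoding="utf-8")
    ids = df.iloc[:, 0].astype(str).tolist()
    try:
        values = df.iloc[:, 1:].astype(float).to_numpy()
    except ValueError as exc:
        raise ValueError(f"{path}: unparseable expression value: {exc}")
    return ExpressionMatrix(values=values, entity_ids=tuple(ids),
                            sample_ids=tuple(header[1:]),
                            conditions=tuple(cond_line[1:]))


def write_expression_matrix(path, E: ExpressionMatrix) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("id\t" + "\t".join(E.sample_ids) + "\n")
        fh.write("condition\t" + "\t".join(E.conditions) + "\n")
        for i, gid in enumerate(E.entity_ids):
            row = "\t".join(f"{v:.10g}" for v in E.values[i])
            fh.write(f"{gid}\t{row}\n")
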
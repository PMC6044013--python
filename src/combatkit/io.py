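"""Reading and writing expression matrices and sample metadata.

Expression tables are TSV/CSV with gene ids in the first column and one
column per sample.  Metadata tables have one row per sample; samples are
matched to the expression matrix *by id*, never by order — silent
misalignment between an expression file and its sample sheet is the classic
failure mode of batch tools.

Values are written in full-precision scientific notation by default so that
a write/read round trip is exact and the reference-batch byte-identity
guarantee survives file I/O.
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DuplicateIdError,
    MissingColumnError,
    MissingSampleError,
    ParseError,
)
from .model import ExpressionMatrix, StudyDesign, expand_categorical

logger = logging.getLogger(__name__)

#: %.17g round-trips every IEEE double exactly
FULL_PRECISION = "%.17g"


def _sniff_sep(path: Path) -> str:
    with open(path, newline="") as fh:
        sample = fh.read(8192)
    try:
        return csv.Sniffer().sniff(sample, delimiters="\t,;").delimiter
    except csv.Error:
        return "\t"


def read_expression(path, sep: Optional[str] = None) -> ExpressionMatrix:
    """Read a gene x sample table; delimiter sniffed unless ``sep`` given.

    Raises :class:`DuplicateIdError` on repeated gene or sample ids and
    :class:`ParseError` naming the (gene, sample) coordinate of any cell
    that is missing or not numeric.
    """
    path = Path(path)
    sep = sep or _sniff_sep(path)
    try:
        df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    except Exception as exc:  # malformed table structure
        raise ParseError(f"{path}: {exc}") from exc
    if df.shape[1] == 0:
        raise ParseError(f"{path}: no sample columns found (delimiter {sep!r})")
    gene_ids = [str(g) for g in df.index]
    sample_ids = [str(s) for s in df.columns]
    dup_g = _duplicates(gene_ids)
    if dup_g:
        raise DuplicateIdError(f"{path}: duplicate gene id(s): {dup_g}")
    dup_s = _duplicates(sample_ids)
    if dup_s:
        raise DuplicateIdError(f"{path}: duplicate sample id(s): {dup_s}")
    raw = df.to_numpy()
    values = np.empty(raw.shape, dtype=float)
    for i in range(raw.shape[0]):
        for j in range(raw.shape[1]):
            cell = raw[i, j]
            try:
                if cell is None or (isinstance(cell, float) and np.isnan(cell)):
                    raise ValueError("missing")
                values[i, j] = float(cell)
            except (TypeError, ValueError) as exc:
                raise ParseError(
                    f"{path}: cell ({gene_ids[i]!r}, {sample_ids[j]!r}) "
                    f"is not numeric: {cell!r}"
                ) from exc
    return ExpressionMatrix(values, gene_ids, sample_ids)


def _duplicates(ids: Sequence[str]) -> list[str]:
    seen: set[str] = set()
    dups = []
    for x in ids:
        if x in seen and x not in dups:
            dups.append(x)
        seen.add(x)
    return dups


def write_expression(
    path,
    M: ExpressionMatrix,
    sep: str = "\t",
    float_format: str = FULL_PRECISION,
    index_label: str = "gene_id",
) -> None:
    """Write a matrix; default format round-trips doubles exactly."""
    M.to_dataframe().to_csv(
        path, sep=sep, float_format=float_format, index_label=index_label
    )


def read_metadata(
    path,
    batch_col: str,
    covariate_cols: Sequence[str] = (),
    sample_ids: Optional[Sequence[str]] = None,
    sample_col: Optional[str] = None,
    reference_batch: Optional[str] = None,
    sep: Optional[str] = None,
) -> StudyDesign:
    """Read a sample sheet into a :class:`StudyDesign`.

    ``sample_col`` names the sample-id column (default: the first column).
    When ``sample_ids`` (typically the expression column ids) is given, rows
    are re-ordered to match and ids present in only one of the two inputs
    raise :class:`MissingSampleError`.  Numeric covariate columns are used
    as-is; non-numeric ones are treatment-coded with the first level
    dropped.
    """
    path = Path(path)
    sep = sep or _sniff_sep(path)
    try:
        df = pd.read_csv(path, sep=sep, dtype=str)
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if sample_col is None:
        sample_col = df.columns[0]
    for col in [sample_col, batch_col, *covariate_cols]:
        if col not in df.columns:
            raise MissingColumnError(
                f"{path}: column {col!r} not found (have: {list(df.columns)})"
            )
    ids = [str(x) for x in df[sample_col]]
    dups = _duplicates(ids)
    if dups:
        raise DuplicateIdError(f"{path}: duplicate sample id(s): {dups}")
    if sample_ids is not None:
        sample_ids = [str(s) for s in sample_ids]
        missing_meta = sorted(set(sample_ids) - set(ids))
        extra_meta = sorted(set(ids) - set(sample_ids))
        if missing_meta or extra_meta:
            parts = []
            if missing_meta:
                parts.append(f"absent from metadata: {missing_meta}")
            if extra_meta:
                parts.append(f"only in metadata: {extra_meta}")
            raise MissingSampleError(f"{path}: sample id mismatch — " + "; ".join(parts))
        df = df.set_index(sample_col).loc[sample_ids].reset_index()

    batch = df[batch_col].to_numpy()
    cov_blocks, cov_names = [], []
    for col in covariate_cols:
        raw = df[col]
        try:
            cov_blocks.append(raw.astype(float).to_numpy()[:, None])
            cov_names.append(col)
        except ValueError:
            mat, names = expand_categorical(raw, name=col)
            if mat.shape[1]:
                cov_blocks.append(mat)
                cov_names.extend(names)
    covariates = np.hstack(cov_blocks) if cov_blocks else None
    return StudyDesign(
        batch,
        covariates=covariates,
        covariate_names=cov_names or None,
        reference_batch=reference_batch,
    )
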
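"""Tabular I/O for the expression screen.

The central object is :class:`ExpressionTable`, a gene × age matrix of
expression densities.  An expression density is the fraction of expressing
pixels among the pixels intersecting a brain region, so all present values are
nonnegative (and for real atlas data lie in [0, 1]).  Missing measurements are
explicit: they are carried as NaN in the underlying DataFrame and exposed as a
boolean mask.

Readers accept TSV/CSV with a header row whose first column is ``gene_id`` and
whose remaining columns are developmental-stage labels in chronological order
(the default stages are E11.5, E13.5, E15.5, E18.5, P4, P14, P28).  Blank
cells and the strings ``NaN``/``nan`` both denote missing data.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Developmental stages of the atlas, embryonic before postnatal.
DEFAULT_AGES = ("E11.5", "E13.5", "E15.5", "E18.5", "P4", "P14", "P28")

_MISSING_TOKENS = ["", "NaN", "nan", "NA", "N/A"]


@dataclass
class ExpressionTable:
    """Gene × age expression-density matrix with explicit missingness.

    ``data`` is indexed by unique gene identifiers with one column per age
    label, in chronological order taken from the source column order.  Missing
    cells are NaN.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        idx = self.data.index
        if idx.has_duplicates:
            dups = sorted(idx[idx.duplicated()].unique())
            raise ValueError(f"duplicate gene ids: {dups}")
        if self.data.columns.has_duplicates:
            raise ValueError("duplicate age labels")
        neg = self.data.lt(0)
        if neg.any().any():
            g = neg.any(axis=1)
            gene = g[g].index[0]
            age = neg.loc[gene][neg.loc[gene]].index[0]
            raise ValueError(f"negative expression density for gene {gene!r} at age {age!r}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def age_labels(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean gene × age array, True where the measurement is absent."""
        return self.data.isna().to_numpy()

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionTable):
            return NotImplemented
        if list(self.data.index) != list(other.data.index):
            return False
        if list(self.data.columns) != list(other.data.columns):
            return False
        a, b = self.data.to_numpy(), other.data.to_numpy()
        both = np.isnan(a) & np.isnan(b)
        return bool(np.all(both | np.isclose(a, b, rtol=0, atol=1e-12, equal_nan=False)))


def _sep_for(path: Path, dialect: str | None) -> str:
    if dialect in ("tsv", "\t"):
        return "\t"
    if dialect in ("csv", ","):
        return ","
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_expression_table(path: str | Path, dialect: str | None = None) -> ExpressionTable:
    """Read a gene × age density table from TSV or CSV.

    The first column holds gene identifiers; every remaining column is an age.
    Non-numeric cells spelled ``NaN``/``nan`` and blank cells become missing.
    Duplicate gene identifiers and negative densities are hard errors.
    """
    path = Path(path)
    df = pd.read_csv(
        path,
        sep=_sep_for(path, dialect),
        index_col=0,
        na_values=_MISSING_TOKENS,
        keep_default_na=False,
        dtype=str,
        comment="#",
    )
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected one id column plus >=2 age columns")
    df.index = df.index.astype(str)
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric density cell ({exc})") from exc
    table = ExpressionTable(df)
    logger.info("read %d genes x %d ages from %s", table.n_genes, len(table.age_labels), path)
    return table


def filter_all_missing(table: ExpressionTable) -> tuple[ExpressionTable, list[str]]:
    """Drop genes with no measurement at any age.

    Returns the retained table (input gene order preserved) and the list of
    removed gene ids.  Idempotent: re-applying removes nothing.
    """
    all_missing = table.data.isna().all(axis=1)
    removed = list(table.data.index[all_missing])
    kept = ExpressionTable(table.data.loc[~all_missing].copy())
    if removed:
        logger.info("removed %d all-missing genes: %s", len(removed), ", ".join(removed))
    return kept, removed


def write_table(obj, path: str | Path, format: str | None = None) -> None:
    """Write a tabular result (ExpressionTable, DataFrame, or JSON-able dict).

    ``format`` is ``tsv``, ``csv`` or ``json``; when omitted it is inferred
    from the file suffix.  Output is UTF-8 and newline-terminated, and
    round-trips through the matching reader.
    """
    path = Path(path)
    fmt = format or path.suffix.lstrip(".").lower() or "tsv"
    if fmt == "json":
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(obj, fh, indent=2, default=_jsonify)
            fh.write("\n")
        return
    if fmt not in ("tsv", "csv"):
        raise ValueError(f"unknown format {fmt!r}")
    sep = "\t" if fmt == "tsv" else ","
    if isinstance(obj, ExpressionTable):
        df = obj.data
        df.to_csv(path, sep=sep, index_label="gene_id", encoding="utf-8")
    elif isinstance(obj, pd.DataFrame):
        obj.to_csv(path, sep=sep, encoding="utf-8")
    else:
        raise TypeError(f"cannot serialize {type(obj).__name__} to {fmt}")


def _jsonify(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, pd.DataFrame):
        return {"index": list(o.index), "columns": list(o.columns), "values": o.to_numpy().tolist()}
    if isinstance(o, pd.Series):
        return o.to_dict()
    if isinstance(o, set):
        return sorted(o)
    raise TypeError(f"not JSON serializable: {type(o).__name__}")
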
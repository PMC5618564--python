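"""Reading and writing cycle-threshold (Ct) matrices and tabular results.

The on-disk format is a plain CSV matrix: one row per cell, a header of
gene symbols preceded by three metadata columns (cell id, biological
group, chip/run label). A qPCR reaction that fails to amplify within the
detection limit ("non-expresser") is written as an empty field; on input,
an empty field, the literal ``NA``, or a numeric value at or above
``max_cycles`` are all normalized to the single internal FAILED marker,
because instrument exports spell censoring in all three ways. A Ct of
exactly ``max_cycles`` counts as failed: amplification must occur strictly
before the detection limit to be called.

Internally FAILED is ``numpy.nan``; every valid Ct is finite, positive and
below ``max_cycles``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CtTable",
    "CtFormatError",
    "CtParseError",
    "read_ct_table",
    "write_ct_table",
    "write_table",
]

#: Internal marker for a reaction that failed to amplify.
FAILED = np.nan

_META_COLUMNS = ("cell_id", "group", "chip")


class CtFormatError(ValueError):
    """Structural problem in a Ct matrix file (ragged rows, duplicate ids)."""


class CtParseError(CtFormatError):
    """A field that should be a Ct value could not be parsed."""


@dataclass
class CtTable:
    """A cells x genes matrix of qPCR cycle-threshold values.

    Failed amplifications are stored as ``nan``. Rows are cells, columns
    are genes; ``group`` and ``chip`` are per-cell annotations.
    """

    cell_ids: list[str]
    gene_ids: list[str]
    ct: np.ndarray
    group: np.ndarray
    chip: np.ndarray
    max_cycles: float = 40.0

    def __post_init__(self) -> None:
        self.ct = np.asarray(self.ct, dtype=float)
        self.group = np.asarray(self.group, dtype=object)
        self.chip = np.asarray(self.chip, dtype=object)
        n, g = len(self.cell_ids), len(self.gene_ids)
        if self.ct.shape != (n, g):
            raise CtFormatError(
                f"ct matrix shape {self.ct.shape} does not match "
                f"({n} cells, {g} genes)"
            )
        if len(set(self.cell_ids)) != n:
            raise CtFormatError("duplicate cell ids")
        if len(set(self.gene_ids)) != g:
            raise CtFormatError("duplicate gene ids")
        if self.group.shape != (n,) or self.chip.shape != (n,):
            raise CtFormatError("group/chip annotations must have one entry per cell")
        finite = self.ct[~np.isnan(self.ct)]
        if finite.size and (np.any(finite <= 0) or np.any(finite > self.max_cycles)):
            raise CtFormatError(
                f"Ct values must lie in (0, {self.max_cycles}]; "
                "use nan for failed reactions"
            )

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def failed(self) -> np.ndarray:
        """Boolean cells x genes mask of failed amplifications."""
        return np.isnan(self.ct)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CtTable):
            return NotImplemented
        return (
            self.cell_ids == other.cell_ids
            and self.gene_ids == other.gene_ids
            and self.max_cycles == other.max_cycles
            and np.array_equal(self.ct, other.ct, equal_nan=True)
            and np.array_equal(self.group, other.group)
            and np.array_equal(self.chip, other.chip)
        )


def _parse_ct_field(raw: str, max_cycles: float, row: int, col: str) -> float:
    raw = raw.strip()
    if raw == "" or raw == "NA":
        return FAILED
    try:
        value = float(raw)
    except ValueError as exc:
        raise CtParseError(
            f"non-numeric Ct field {raw!r} at row {row}, gene {col!r}"
        ) from exc
    if value >= max_cycles:
        return FAILED
    if value <= 0:
        raise CtParseError(
            f"non-positive Ct value {value} at row {row}, gene {col!r}"
        )
    return value


def read_ct_table(
    path, max_cycles: float = 40.0, dialect: str = "matrix_csv"
) -> CtTable:
    """Read a Ct matrix CSV.

    Expected layout: header ``cell_id,group,chip,<gene>,...``; one row per
    cell. Empty fields, ``NA``, and values >= ``max_cycles`` become FAILED.
    """
    if dialect != "matrix_csv":
        raise ValueError(f"unknown dialect {dialect!r}")
    with open(path, newline="") as handle:
        reader = csv.reader(handle)
        try:
            header = next(reader)
        except StopIteration:
            raise CtFormatError(f"{path}: empty file") from None
        if len(header) < 4 or tuple(header[:3]) != _META_COLUMNS:
            raise CtFormatError(
                f"{path}: header must start with {','.join(_META_COLUMNS)} "
                "followed by at least one gene column"
            )
        gene_ids = header[3:]
        cell_ids: list[str] = []
        groups: list[str] = []
        chips: list[str] = []
        rows: list[list[float]] = []
        for i, record in enumerate(reader, start=1):
            if len(record) != len(header):
                raise CtFormatError(
                    f"{path}: row {i} has {len(record)} fields, "
                    f"expected {len(header)}"
                )
            cell_ids.append(record[0])
            groups.append(record[1])
            chips.append(record[2])
            rows.append(
                [
                    _parse_ct_field(raw, max_cycles, i, gene)
                    for raw, gene in zip(record[3:], gene_ids)
                ]
            )
    ct = np.array(rows, dtype=float).reshape(len(cell_ids), len(gene_ids))
    return CtTable(
        cell_ids=cell_ids,
        gene_ids=gene_ids,
        ct=ct,
        group=np.array(groups, dtype=object),
        chip=np.array(chips, dtype=object),
        max_cycles=max_cycles,
    )


def write_ct_table(table: CtTable, path) -> str:
    """Write a Ct matrix CSV; FAILED entries become empty fields.

    Values are written with full round-trip precision so that
    ``read_ct_table(write_ct_table(t))`` reproduces ``t`` bit-exactly.
    """
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle)
        writer.writerow(list(_META_COLUMNS) + list(table.gene_ids))
        for i, cell in enumerate(table.cell_ids):
            fields = [cell, str(table.group[i]), str(table.chip[i])]
            for v in table.ct[i]:
                fields.append("" if np.isnan(v) else repr(float(v)))
            writer.writerow(fields)
    return str(path)


def write_table(rows, path, float_format: str = "%.6g") -> str:
    """Write a generic tabular result as CSV with a deterministic column order.

    ``rows`` is a pandas DataFrame or a sequence of uniformly-keyed dicts.
    Floats are rendered with 6 significant digits by default, which makes
    re-serialization of a parsed output byte-identical.
    """
    if isinstance(rows, pd.DataFrame):
        frame = rows
    else:
        rows = list(rows)
        if rows:
            keys = list(rows[0].keys())
            for r in rows:
                if list(r.keys()) != keys:
                    raise CtFormatError("rows have inconsistent columns")
        frame = pd.DataFrame(rows)
    frame.to_csv(path, index=False, float_format=float_format)
    return str(path)
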
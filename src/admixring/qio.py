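"""Input/output for ancestry-proportion data.

Reads ADMIXTURE-style ``.Q`` matrices (whitespace-separated proportions, one
row per individual, no header) and ``.ind``-style label files (first column =
individual ID, last column = population label; middle columns such as the
EIGENSTRAT sex column are ignored).  Writes the text outputs that accompany a
figure: the sorted proportion table and the color-scheme file.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .errors import FormatError, UnknownLabelError, ValidationError

__all__ = [
    "AncestryMatrix",
    "IndividualRecord",
    "Dataset",
    "read_q_matrix",
    "write_q_matrix",
    "read_individual_file",
    "bind",
    "write_sorted_table",
    "write_color_scheme",
    "read_color_scheme_lines",
]

#: Default tolerance on |row sum - 1| when renormalization is off.  Real
#: ADMIXTURE output carries per-entry rounding error of ~1e-6, so sums can
#: deviate by a few 1e-6; 1e-4 accepts that while rejecting genuinely broken
#: rows.
ROW_SUM_TOLERANCE = 1e-4


@dataclass(frozen=True)
class AncestryMatrix:
    """N x K matrix of per-individual ancestry proportions.

    Rows sum to one (within tolerance, or exactly after renormalization).
    ``raw_tokens`` preserves the verbatim input tokens when the matrix was
    parsed from a file without renormalization, so downstream writers can echo
    the input at full precision.
    """

    values: np.ndarray
    raw_tokens: Optional[tuple[tuple[str, ...], ...]] = field(
        default=None, compare=False
    )

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 2:
            raise ValidationError("ancestry matrix must be two-dimensional")
        if arr.shape[0] < 1 or arr.shape[1] < 2:
            raise ValidationError(
                f"ancestry matrix must be N>=1 by K>=2, got {arr.shape}"
            )
        if np.any(arr < 0) or np.any(arr > 1):
            raise ValidationError("ancestry proportions must lie in [0, 1]")
        object.__setattr__(self, "values", arr)

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    @property
    def n_ancestries(self) -> int:
        return self.values.shape[1]

    def row_tokens(self, row: int) -> tuple[str, ...]:
        """Tokens for one row: verbatim input if available, else repr floats."""
        if self.raw_tokens is not None:
            return self.raw_tokens[row]
        return tuple(repr(float(v)) for v in self.values[row])


@dataclass(frozen=True)
class IndividualRecord:
    """One sampled individual: its ID, its population label, its matrix row."""

    individual_id: str
    group_label: str
    row_index: int

    def __post_init__(self) -> None:
        if not self.individual_id:
            raise ValidationError("individual_id must be non-empty")
        if not self.group_label:
            raise ValidationError("group_label must be non-empty")
        if self.row_index < 0:
            raise ValidationError("row_index must be non-negative")


@dataclass(frozen=True)
class Dataset:
    """An ancestry matrix bound to its row-aligned individual records."""

    matrix: AncestryMatrix
    individuals: tuple[IndividualRecord, ...]

    def __post_init__(self) -> None:
        if len(self.individuals) != self.matrix.n_individuals:
            raise ValidationError(
                f"{len(self.individuals)} individual records for "
                f"{self.matrix.n_individuals} matrix rows"
            )

    @property
    def n_individuals(self) -> int:
        return self.matrix.n_individuals

    @property
    def n_ancestries(self) -> int:
        return self.matrix.n_ancestries

    def population_labels(self) -> list[str]:
        """Distinct group labels in order of first appearance."""
        seen: dict[str, None] = {}
        for rec in self.individuals:
            seen.setdefault(rec.group_label, None)
        return list(seen)

    def members_of(self, label: str) -> list[int]:
        rows = [r.row_index for r in self.individuals if r.group_label == label]
        if not rows:
            raise UnknownLabelError(f"unknown population label: {label!r}")
        return rows


def _nonblank_lines(path: Path) -> list[tuple[int, str]]:
    out = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip():
                out.append((lineno, line))
    return out


def read_q_matrix(
    path: str | Path,
    renormalize: bool = False,
    tolerance: float = ROW_SUM_TOLERANCE,
) -> AncestryMatrix:
    """Parse a ``.Q`` file into an :class:`AncestryMatrix`.

    Each non-blank line must carry the same number of whitespace-separated
    numeric tokens.  With ``renormalize`` on, each row is divided by its sum;
    otherwise a row whose sum deviates from 1 by more than ``tolerance``
    raises :class:`ValidationError`.
    """
    path = Path(path)
    lines = _nonblank_lines(path)
    if not lines:
        raise FormatError(f"{path}: no data rows")

    rows: list[list[float]] = []
    tokens: list[tuple[str, ...]] = []
    width = None
    for lineno, line in lines:
        toks = line.split()
        if width is None:
            width = len(toks)
            if width < 2:
                raise FormatError(
                    f"{path}:{lineno}: need at least 2 ancestry columns, got {width}"
                )
        elif len(toks) != width:
            raise FormatError(
                f"{path}:{lineno}: expected {width} columns, got {len(toks)}"
            )
        try:
            vals = [float(t) for t in toks]
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: non-numeric token ({exc})") from None
        if any(v < 0 or not math.isfinite(v) for v in vals):
            raise ValidationError(
                f"{path}:{lineno}: proportions must be finite and non-negative"
            )
        rows.append(vals)
        tokens.append(tuple(toks))

    arr = np.array(rows, dtype=float)
    if renormalize:
        sums = arr.sum(axis=1)
        bad = np.flatnonzero(sums <= 0)
        if bad.size:
            raise ValidationError(
                f"{path}: row {bad[0] + 1} sums to zero; cannot renormalize"
            )
        arr = arr / sums[:, None]
        return AncestryMatrix(arr)

    sums = arr.sum(axis=1)
    bad = np.flatnonzero(np.abs(sums - 1.0) > tolerance)
    if bad.size:
        i = int(bad[0])
        raise ValidationError(
            f"{path}: row {i + 1} sums to {sums[i]:.6g}, not 1 "
            f"(tolerance {tolerance:g}); pass renormalize to rescale"
        )
    return AncestryMatrix(arr, raw_tokens=tuple(tokens))


def write_q_matrix(matrix: AncestryMatrix, path: str | Path) -> None:
    """Serialize a matrix back to the ``.Q`` dialect.

    Verbatim input tokens are echoed when available, so parse followed by
    serialize is the identity on valid files.
    """
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for i in range(matrix.n_individuals):
            fh.write(" ".join(matrix.row_tokens(i)) + "\n")


def read_individual_file(path: str | Path) -> list[IndividualRecord]:
    """Parse an ``.ind``-style label file.

    Column 1 is the individual ID and the last column the population label;
    any middle columns (e.g. the EIGENSTRAT sex column) are ignored.
    """
    path = Path(path)
    records: list[IndividualRecord] = []
    seen_ids: set[str] = set()
    for row_index, (lineno, line) in enumerate(_nonblank_lines(path)):
        toks = line.split()
        if len(toks) < 2:
            raise FormatError(
                f"{path}:{lineno}: need at least 2 columns (id, group), got {len(toks)}"
            )
        ind_id, group = toks[0], toks[-1]
        if ind_id in seen_ids:
            raise ValidationError(f"{path}:{lineno}: duplicate individual id {ind_id!r}")
        seen_ids.add(ind_id)
        records.append(IndividualRecord(ind_id, group, row_index))
    if not records:
        raise FormatError(f"{path}: no data rows")
    return records


def bind(matrix: AncestryMatrix, individuals: Sequence[IndividualRecord]) -> Dataset:
    """Bind a Q matrix to its row-aligned individual records."""
    if len(individuals) != matrix.n_individuals:
        raise ValidationError(
            f"row count mismatch: Q matrix has {matrix.n_individuals} rows but "
            f"individual file has {len(individuals)} records"
        )
    return Dataset(matrix, tuple(individuals))


def load_dataset(
    q_path: str | Path,
    ind_path: str | Path,
    renormalize: bool = False,
    tolerance: float = ROW_SUM_TOLERANCE,
) -> Dataset:
    """Convenience: read both input files and bind them."""
    return bind(
        read_q_matrix(q_path, renormalize=renormalize, tolerance=tolerance),
        read_individual_file(ind_path),
    )


def write_sorted_table(dataset: Dataset, order, path: str | Path) -> None:
    """Write the final plotting order as a TSV table.

    One row per individual in plotting order: ID, population label, then the
    K proportions at input precision.  ``order`` is a
    :class:`~admixring.ordering.PlotOrder` (anything exposing
    ``individual_sequence``).
    """
    seq = list(order.individual_sequence)
    by_row = {r.row_index: r for r in dataset.individuals}
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for row in seq:
            rec = by_row[row]
            fields = [rec.individual_id, rec.group_label]
            fields.extend(dataset.matrix.row_tokens(row))
            fh.write("\t".join(fields) + "\n")


def write_color_scheme(scheme, path: str | Path) -> None:
    """Write a color scheme as ``<1-based ancestry index>\\t#RRGGBB`` lines.

    The file is accepted by :func:`admixring.render.read_color_scheme` in a
    later run.
    """
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for i, color in enumerate(scheme.colors, start=1):
            fh.write(f"{i}\t{color}\n")


def read_color_scheme_lines(path: str | Path) -> list[str]:
    """Parse the color-scheme file format back into an ordered color list."""
    path = Path(path)
    entries: list[tuple[int, str]] = []
    for lineno, line in _nonblank_lines(path):
        toks = line.split()
        if len(toks) != 2:
            raise FormatError(
                f"{path}:{lineno}: expected '<index> <color>', got {len(toks)} fields"
            )
        try:
            idx = int(toks[0])
        except ValueError:
            raise FormatError(f"{path}:{lineno}: bad ancestry index {toks[0]!r}") from None
        entries.append((idx, toks[1]))
    entries.sort(key=lambda e: e[0])
    if [i for i, _ in entries] != list(range(1, len(entries) + 1)):
        raise FormatError(f"{path}: ancestry indices must be 1..K without gaps")
    return [c for _, c in entries]
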
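"""Reading amino-acid property scales in AAindex1 flat-file format.

AAindex1 records start with an ``H`` (accession) line and carry their 20
per-residue values on the two lines following the ``I`` header, ten values
per line, in the database's fixed A/R/N/D/C/Q/E/G/H/I // L/K/M/F/P/S/T/W/Y/V
layout.  ``NA`` marks a missing value.  Records are delimited by ``//``.

Values are re-ordered here into the package-wide canonical alphabet
``ACDEFGHIKLMNPQRSTVWY`` so that every downstream matrix indexes residues
the same way.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, TextIO

import numpy as np

#: Canonical residue order used by every matrix in this package.
CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"

#: Residue order of the two AAindex1 value lines.
_AAINDEX_ORDER = "ARNDCQEGHI" + "LKMFPSTWYV"


class AAindexParseError(ValueError):
    """Raised when an AAindex1 record is malformed; names the record."""


@dataclass(frozen=True)
class PropertyMatrix:
    """A 20 x P table of per-residue physicochemical property values.

    Rows follow :data:`CANONICAL_AA`; missing entries are NaN and flagged
    per property in ``complete_mask``.
    """

    properties: tuple[str, ...]
    values: np.ndarray            # (20, P), NaN where missing
    complete_mask: np.ndarray     # (P,) bool, True = no missing values

    amino_acids: str = CANONICAL_AA

    def __post_init__(self) -> None:
        if self.values.shape != (20, len(self.properties)):
            raise ValueError(
                f"values must be 20 x {len(self.properties)}, got {self.values.shape}"
            )
        if len(set(self.properties)) != len(self.properties):
            raise ValueError("property identifiers must be unique")
        expected = ~np.isnan(self.values).any(axis=0)
        if not np.array_equal(expected, self.complete_mask):
            raise ValueError("complete_mask inconsistent with NaN pattern in values")

    @property
    def n_properties(self) -> int:
        return len(self.properties)

    def filter_complete(self) -> "PropertyMatrix":
        """Drop every property that has at least one missing value."""
        keep = self.complete_mask
        return PropertyMatrix(
            properties=tuple(p for p, k in zip(self.properties, keep) if k),
            values=self.values[:, keep],
            complete_mask=np.ones(int(keep.sum()), dtype=bool),
        )


def _iter_records(lines: Iterable[str]):
    record: list[str] = []
    for line in lines:
        if line.strip() == "//":
            if record:
                yield record
            record = []
        else:
            record.append(line.rstrip("\n"))
    if any(l.strip() for l in record):
        yield record


def _parse_record(record: list[str]) -> tuple[str, np.ndarray]:
    accession = None
    values: list[float] | None = None
    for i, line in enumerate(record):
        if line.startswith("H "):
            accession = line[2:].strip()
        elif line.startswith("I "):
            tokens: list[str] = []
            for value_line in record[i + 1 : i + 3]:
                tokens.extend(value_line.split())
            label = accession or "<record without H line>"
            if len(tokens) != 20:
                raise AAindexParseError(
                    f"record {label}: expected 20 values after the I line, "
                    f"got {len(tokens)}"
                )
            try:
                values = [np.nan if t.upper() == "NA" else float(t) for t in tokens]
            except ValueError as exc:
                raise AAindexParseError(f"record {label}: {exc}") from exc
    if accession is None:
        raise AAindexParseError("record without an H (accession) line")
    if values is None:
        raise AAindexParseError(f"record {accession}: no I value block")
    # reorder from the AAindex line layout into the canonical alphabet
    by_residue = dict(zip(_AAINDEX_ORDER, values))
    return accession, np.array([by_residue[aa] for aa in CANONICAL_AA])


def parse_property_table(source: TextIO | str) -> PropertyMatrix:
    """Parse an AAindex1 flat file into a :class:`PropertyMatrix`.

    Parameters
    ----------
    source
        An open text stream, or the file content itself as a string.

    Raises
    ------
    AAindexParseError
        On a record missing its ``H`` line, missing the ``I`` value block,
        or carrying the wrong number of values.
    """
    if isinstance(source, str):
        lines: Iterable[str] = source.splitlines()
    else:
        lines = source
    names: list[str] = []
    columns: list[np.ndarray] = []
    for record in _iter_records(lines):
        name, column = _parse_record(record)
        names.append(name)
        columns.append(column)
    if not names:
        raise AAindexParseError("no records found")
    values = np.column_stack(columns)
    return PropertyMatrix(
        properties=tuple(names),
        values=values,
        complete_mask=~np.isnan(values).any(axis=0),
    )
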
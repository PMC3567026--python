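"""Reading, writing, and subsetting gene-expression matrices.

The on-disk dialect is a tab-delimited UTF-8 table: one header row of sample
identifiers (optionally preceded by a label for the probe column), then one
row per probe set whose first field is the probe identifier. ``NA``, ``na``
and the empty string denote missing values. Row and column order is
significant and preserved everywhere — no silent sorting — so seeded
perturbations are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import DuplicateIdentifier, MalformedInput, UnknownIdentifier

_MISSING_TOKENS = {"NA", "na", ""}


@dataclass
class ExpressionMatrix:
    """A probes x samples real matrix with missing values stored as NaN.

    Invariants (checked on construction): identifier lists match the matrix
    shape, contain no duplicates, and every non-missing value is finite.
    """

    probe_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise MalformedInput("expression values must form a 2-D matrix")
        n, m = self.values.shape
        if len(self.probe_ids) != n or len(self.sample_ids) != m:
            raise MalformedInput(
                f"identifier counts ({len(self.probe_ids)} probes, "
                f"{len(self.sample_ids)} samples) do not match matrix shape {self.values.shape}"
            )
        for kind, ids in (("probe", self.probe_ids), ("sample", self.sample_ids)):
            if len(set(ids)) != len(ids):
                seen: set[str] = set()
                dup = next(i for i in ids if i in seen or seen.add(i))  # type: ignore[func-returns-value]
                raise DuplicateIdentifier(f"duplicate {kind} identifier: {dup!r}")
        finite = np.isfinite(self.values) | np.isnan(self.values)
        if not finite.all():
            raise MalformedInput("expression matrix contains non-finite values")

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        if self.probe_ids != other.probe_ids or self.sample_ids != other.sample_ids:
            return False
        a, b = self.values, other.values
        return bool(((a == b) | (np.isnan(a) & np.isnan(b))).all())


def _parse_cell(token: str, row: int, col: int) -> float:
    if token in _MISSING_TOKENS:
        return np.nan
    try:
        return float(token)
    except ValueError:
        raise MalformedInput(
            f"non-numeric cell {token!r} at data row {row}, column {col}"
        ) from None


def read_expression_matrix(path) -> ExpressionMatrix:
    """Parse a tab-delimited expression matrix file.

    The header row carries the sample identifiers; it may optionally begin
    with a label for the probe-identifier column. Every data row must have
    exactly ``1 + n_samples`` fields.
    """
    with open(path, encoding="utf-8") as fh:
        lines = [ln.rstrip("\n").rstrip("\r") for ln in fh]
    lines = [ln for ln in lines if ln != ""]
    if len(lines) < 2:
        raise MalformedInput("expression file needs a header row and at least one data row")
    rows = [ln.split("\t") for ln in lines]
    width = len(rows[1])
    header = rows[0]
    if len(header) == width:
        sample_ids = header[1:]  # first header field labels the probe column
    elif len(header) == width - 1:
        sample_ids = header
    else:
        raise MalformedInput(
            f"header has {len(header)} fields but data rows have {width}"
        )
    probe_ids: list[str] = []
    values = np.empty((len(rows) - 1, width - 1), dtype=float)
    for r, fields in enumerate(rows[1:]):
        if len(fields) != width:
            raise MalformedInput(f"ragged row {r}: {len(fields)} fields, expected {width}")
        probe_ids.append(fields[0])
        for c, tok in enumerate(fields[1:]):
            values[r, c] = _parse_cell(tok, r, c)
    return ExpressionMatrix(probe_ids, sample_ids, values)


def write_expression_matrix(em: ExpressionMatrix, path) -> None:
    """Write the tab-delimited dialect read by :func:`read_expression_matrix`."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("probe_id\t" + "\t".join(em.sample_ids) + "\n")
        for pid, row in zip(em.probe_ids, em.values):
            cells = ("NA" if np.isnan(v) else repr(float(v)) for v in row)
            fh.write(pid + "\t" + "\t".join(cells) + "\n")


def subset(
    em: ExpressionMatrix,
    keep_probes: Iterable[str] | None = None,
    keep_samples: Iterable[str] | None = None,
) -> ExpressionMatrix:
    """Restrict to the requested probes/samples, preserving original order.

    ``None`` keeps everything along that axis. The order of the keep lists is
    irrelevant: rows and columns always come out in the order of the source
    matrix, so nested subsets compose like ordered set intersection.
    """

    def _index(ids: Sequence[str], keep: Iterable[str] | None, kind: str) -> list[int]:
        if keep is None:
            return list(range(len(ids)))
        keep_set = set(keep)
        unknown = keep_set - set(ids)
        if unknown:
            raise UnknownIdentifier(f"unknown {kind} identifier(s): {sorted(unknown)}")
        return [i for i, x in enumerate(ids) if x in keep_set]

    rows = _index(em.probe_ids, keep_probes, "probe")
    cols = _index(em.sample_ids, keep_samples, "sample")
    return ExpressionMatrix(
        [em.probe_ids[i] for i in rows],
        [em.sample_ids[j] for j in cols],
        em.values[np.ix_(rows, cols)] if rows and cols else em.values[rows][:, cols],
    )


def read_id_list(path) -> list[str]:
    """Read a one-identifier-per-line keep/drop list (blank lines skipped)."""
    with open(path, encoding="utf-8") as fh:
        return [ln.strip() for ln in fh if ln.strip()]
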
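"""Readers and writers for every external format the tool touches.

Formats
-------
* **Omics matrix** — tab-delimited text; header row; column 1 holds the gene
  identifier, every other column is numeric.  ``NA``/``nan``/empty cells are
  missing.  Lines starting with ``#`` before the header are skipped.
* **GMT** — one geneset per line: name, description, then member identifiers,
  tab-separated (the MSigDB distribution format).
* **Polygon** — one vertex per line, two tab-separated numeric columns, in
  data coordinates.
* **Enrichment report** — 10-column TSV, one row per tested geneset.

Gene identifiers are normalized (whitespace-stripped, uppercased) on the way
in so that table rows and geneset members match robustly.
"""

from __future__ import annotations

import io as _io
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Literal, Sequence

import numpy as np
import pandas as pd

from .errors import DuplicateIdentifierError, FormatError, GeometryError

__all__ = [
    "OmicsTable",
    "GeneSet",
    "GeneSetCollection",
    "normalize_gene_id",
    "read_table",
    "write_table",
    "read_gmt",
    "read_polygon",
    "write_enrichment_report",
    "read_enrichment_report",
]

_MISSING_TOKENS = {"", "na", "nan"}

REPORT_COLUMNS = (
    "geneset",
    "description",
    "universe_size",
    "selection_size",
    "geneset_size_in_universe",
    "expected_overlap",
    "observed_overlap",
    "p_value",
    "neg_log10_p",
    "q_value",
)


def normalize_gene_id(raw: str) -> str:
    """Canonical form of a gene identifier: stripped and uppercased."""
    return raw.strip().upper()


class OmicsTable:
    """A gene-by-measurement matrix, the object the whole tool operates on.

    Thin wrapper around a float ``pandas.DataFrame`` whose index holds the
    normalized gene identifiers and whose columns are measurement names.
    Missing measurements are NaN.
    """

    def __init__(self, frame: pd.DataFrame):
        if frame.shape[1] < 1:
            raise FormatError("table needs at least one measurement column")
        if frame.shape[0] < 1:
            raise FormatError("table needs at least one data row")
        index = pd.Index([normalize_gene_id(str(g)) for g in frame.index], name=frame.index.name or "gene")
        if not index.is_unique:
            dup = index[index.duplicated()][0]
            raise DuplicateIdentifierError(f"duplicate gene identifier {dup!r}")
        cols = pd.Index([str(c) for c in frame.columns])
        if not cols.is_unique or any(c == "" for c in cols):
            raise FormatError("measurement names must be unique and non-empty")
        self.frame = pd.DataFrame(
            np.asarray(frame, dtype=float), index=index, columns=cols
        )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def measurement_names(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy()

    @property
    def n_genes(self) -> int:
        return self.frame.shape[0]

    def column(self, name: str) -> np.ndarray:
        return self.frame[name].to_numpy()

    def universe(self) -> set[str]:
        """All normalized gene ids in the table — the default enrichment universe."""
        return set(self.frame.index)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, OmicsTable):
            return NotImplemented
        if self.gene_ids != other.gene_ids or self.measurement_names != other.measurement_names:
            return False
        a, b = self.values, other.values
        return bool(np.all((a == b) | (np.isnan(a) & np.isnan(b))))

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"OmicsTable({self.n_genes} genes x {len(self.measurement_names)} measurements)"


@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    members: frozenset[str]


class GeneSetCollection:
    """Named genesets with normalized members, insertion-ordered."""

    def __init__(self, sets: Iterable[GeneSet] = ()):
        self._sets: dict[str, GeneSet] = {}
        for s in sets:
            self.add(s)

    def add(self, geneset: GeneSet) -> None:
        if geneset.name in self._sets:
            raise FormatError(f"duplicate geneset name {geneset.name!r}")
        if not geneset.members:
            raise FormatError(f"geneset {geneset.name!r} has no members")
        self._sets[geneset.name] = geneset

    def __len__(self) -> int:
        return len(self._sets)

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self._sets.values())

    def __contains__(self, name: str) -> bool:
        return name in self._sets

    def __getitem__(self, name: str) -> GeneSet:
        return self._sets[name]

    @property
    def names(self) -> list[str]:
        return list(self._sets)


def _open_text(source, mode: str = "r"):
    """Return (stream, owns) for a path or an already-open text stream."""
    if isinstance(source, (str, Path)):
        return open(source, mode, encoding="utf-8", newline=""), True
    return source, False


def _iter_lines(stream: IO[str]) -> Iterator[tuple[int, str]]:
    for lineno, line in enumerate(stream, start=1):
        yield lineno, line.rstrip("\r\n")


def read_table(
    source,
    delimiter: str = "\t",
    duplicate_policy: Literal["error", "keep-first"] = "error",
) -> OmicsTable:
    """Parse a tab-delimited gene-by-measurement matrix.

    The first non-comment line is the header; its first field names the
    identifier column.  Non-numeric measurement cells become NaN.  Duplicate
    gene ids raise under the default ``"error"`` policy and keep the first
    occurrence under ``"keep-first"``.
    """
    stream, owns = _open_text(source)
    try:
        header: list[str] | None = None
        header_width = 0
        gene_ids: list[str] = []
        seen: dict[str, int] = {}
        rows: list[list[float]] = []
        for lineno, line in _iter_lines(stream):
            if header is None and line.startswith("#"):
                continue
            if line == "" and header is None:
                continue
            fields = line.split(delimiter)
            if header is None:
                if len(fields) < 2:
                    raise FormatError(
                        "header must have an identifier column and at least one measurement column",
                        line=lineno,
                    )
                header = fields
                header_width = len(fields)
                continue
            if line == "":
                continue
            if len(fields) != header_width:
                raise FormatError(
                    f"expected {header_width} fields, found {len(fields)}", line=lineno
                )
            gid = normalize_gene_id(fields[0])
            if gid in seen:
                if duplicate_policy == "error":
                    raise DuplicateIdentifierError(
                        f"duplicate gene identifier {gid!r}", line=lineno
                    )
                continue  # keep-first
            seen[gid] = lineno
            gene_ids.append(gid)
            rows.append([_parse_cell(c) for c in fields[1:]])
        if header is None:
            raise FormatError("empty file: no header line found")
        if not rows:
            raise FormatError("table has a header but no data rows")
        frame = pd.DataFrame(rows, index=gene_ids, columns=header[1:])
        frame.index.name = header[0]
        return OmicsTable(frame)
    finally:
        if owns:
            stream.close()


def _parse_cell(cell: str) -> float:
    if cell.strip().lower() in _MISSING_TOKENS:
        return math.nan
    try:
        return float(cell)
    except ValueError:
        return math.nan  # non-numeric treated as missing, not a hard error


def write_table(table: OmicsTable, sink, delimiter: str = "\t") -> None:
    """Emit the same dialect ``read_table`` accepts; missing cells become ``NA``.

    ``read_table(write_table(t))`` reproduces ``t`` exactly (floats are
    serialized with ``repr`` so the round trip is bit-faithful).
    """
    stream, owns = _open_text(sink, "w")
    try:
        id_name = table.frame.index.name or "gene"
        stream.write(delimiter.join([id_name, *table.measurement_names]) + "\n")
        for gid, row in zip(table.gene_ids, table.values):
            cells = ["NA" if math.isnan(v) else repr(float(v)) for v in row]
            stream.write(delimiter.join([gid, *cells]) + "\n")
    finally:
        if owns:
            stream.close()


def read_gmt(source) -> GeneSetCollection:
    """Parse a GMT geneset file: name, description, members..., tab-separated.

    Duplicate members within a line are deduplicated; empty member fields are
    dropped; duplicate geneset names are a format error.
    """
    stream, owns = _open_text(source)
    try:
        collection = GeneSetCollection()
        for lineno, line in _iter_lines(stream):
            if line == "":
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"GMT line needs >= 3 tab-separated fields, found {len(fields)}",
                    line=lineno,
                )
            name, description = fields[0], fields[1]
            members = frozenset(
                normalize_gene_id(m) for m in fields[2:] if m.strip() != ""
            )
            if not members:
                raise FormatError(f"geneset {name!r} has no members", line=lineno)
            if name in collection:
                raise FormatError(f"duplicate geneset name {name!r}", line=lineno)
            collection.add(GeneSet(name, description, members))
        return collection
    finally:
        if owns:
            stream.close()


def read_polygon(source):
    """Read a polygon vertex file: one ``x<TAB>y`` pair per line, >= 3 vertices.

    The polygon is implicitly closed; a repeated final vertex equal to the
    first is dropped.  Returns a :class:`scattergate.gating.Polygon`.
    """
    from .gating import Polygon  # local import to avoid a cycle

    stream, owns = _open_text(source)
    try:
        vertices: list[tuple[float, float]] = []
        for lineno, line in _iter_lines(stream):
            if line == "":
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise FormatError(
                    f"polygon vertex needs 2 tab-separated fields, found {len(fields)}",
                    line=lineno,
                )
            try:
                x, y = float(fields[0]), float(fields[1])
            except ValueError:
                raise FormatError(
                    f"non-numeric polygon coordinate {fields!r}", line=lineno
                ) from None
            vertices.append((x, y))
        if len(vertices) >= 4 and vertices[-1] == vertices[0]:
            vertices = vertices[:-1]
        if len(vertices) < 3:
            raise GeometryError(
                f"polygon needs at least 3 vertices, found {len(vertices)}"
            )
        return Polygon(vertices)
    finally:
        if owns:
            stream.close()


def write_polygon(polygon, sink) -> None:
    """Write a polygon in the two-column vertex format ``read_polygon`` accepts."""
    stream, owns = _open_text(sink, "w")
    try:
        for x, y in polygon.vertices:
            stream.write(f"{x!r}\t{y!r}\n")
    finally:
        if owns:
            stream.close()


def _fmt6(value: float) -> str:
    """Format a float with 6 significant digits."""
    return f"{value:.6g}"


def write_enrichment_report(results: Sequence, sink) -> None:
    """Write the 10-column TSV enrichment report, one row per result.

    Row order equals input order (``overlap_analysis`` already sorts by
    ascending p-value).  Floats are printed with 6 significant digits.
    """
    stream, owns = _open_text(sink, "w")
    try:
        stream.write("\t".join(REPORT_COLUMNS) + "\n")
        for r in results:
            stream.write(
                "\t".join(
                    [
                        r.geneset_name,
                        r.description,
                        str(r.universe_size),
                        str(r.selection_size),
                        str(r.geneset_size_in_universe),
                        _fmt6(r.expected_overlap),
                        str(r.observed_overlap),
                        _fmt6(r.p_value),
                        _fmt6(r.neg_log10_p),
                        _fmt6(r.q_value),
                    ]
                )
                + "\n"
            )
    finally:
        if owns:
            stream.close()


def read_enrichment_report(source) -> pd.DataFrame:
    """Parse an enrichment report back into a DataFrame (round-trip harness)."""
    stream, owns = _open_text(source)
    try:
        frame = pd.read_csv(stream, sep="\t", dtype={"geneset": str, "description": str})
    finally:
        if owns:
            stream.close()
    missing = set(REPORT_COLUMNS) - set(frame.columns)
    if missing:
        raise FormatError(f"report is missing columns {sorted(missing)}")
    return frame
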
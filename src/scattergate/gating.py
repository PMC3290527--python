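"""Polygon gating: which plotted genes fall inside a selection polygon.

The hit test is even-odd ray casting in **data** coordinates (not canvas
pixels), so a saved polygon selects the same genes whatever the canvas size.
Points exactly on a polygon edge or vertex count as inside.  Self-intersecting
polygons are accepted and interpreted under the even-odd rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import GeometryError
from .io import OmicsTable

__all__ = ["Polygon", "Selection", "point_in_polygon", "points_in_polygon", "select_genes"]


class Polygon:
    """A closed polygon given by its vertices in data coordinates.

    The closing edge from the last vertex back to the first is implicit.
    Consecutive duplicate vertices are collapsed at construction; at least
    three distinct consecutive vertices must remain.
    """

    __slots__ = ("vertices",)

    def __init__(self, vertices: Sequence[tuple[float, float]]):
        cleaned: list[tuple[float, float]] = []
        for x, y in vertices:
            x, y = float(x), float(y)
            if not (np.isfinite(x) and np.isfinite(y)):
                raise GeometryError(f"non-finite polygon vertex ({x}, {y})")
            if cleaned and cleaned[-1] == (x, y):
                continue
            cleaned.append((x, y))
        if len(cleaned) >= 2 and cleaned[-1] == cleaned[0]:
            cleaned.pop()
        if len(cleaned) < 3:
            raise GeometryError(
                f"polygon needs at least 3 distinct vertices, got {len(cleaned)}"
            )
        self.vertices: tuple[tuple[float, float], ...] = tuple(cleaned)

    def __len__(self) -> int:
        return len(self.vertices)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Polygon):
            return NotImplemented
        return self.vertices == other.vertices

    def __repr__(self) -> str:  # pragma: no cover
        return f"Polygon({len(self.vertices)} vertices)"

    def translated(self, dx: float, dy: float) -> "Polygon":
        return Polygon([(x + dx, y + dy) for x, y in self.vertices])

    def bounding_box(self) -> tuple[float, float, float, float]:
        xs = [v[0] for v in self.vertices]
        ys = [v[1] for v in self.vertices]
        return min(xs), min(ys), max(xs), max(ys)


@dataclass(frozen=True)
class Selection:
    """The genes captured by a polygon gate, in table row order."""

    gene_ids: tuple[str, ...]
    polygon: Polygon
    source_mapping: "object" = None  # ChannelMapping; untyped to avoid a cycle

    def __len__(self) -> int:
        return len(self.gene_ids)


def points_in_polygon(xs: np.ndarray, ys: np.ndarray, polygon: Polygon) -> np.ndarray:
    """Vectorized even-odd test; boundary points count as inside.

    Casts a horizontal ray to +x from each point and counts edge crossings
    with the half-open vertex rule (an edge covers ``min(y1,y2) <= y <
    max(y1,y2)``) so shared vertices are never double-counted.  Points lying
    exactly on an edge are detected separately and forced inside.
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    inside = np.zeros(xs.shape, dtype=bool)
    boundary = np.zeros(xs.shape, dtype=bool)
    verts = polygon.vertices
    n = len(verts)
    for i in range(n):
        x1, y1 = verts[i]
        x2, y2 = verts[(i + 1) % n]
        # exact on-segment check: zero cross product and inside the bbox
        cross = (x2 - x1) * (ys - y1) - (y2 - y1) * (xs - x1)
        on_seg = (
            (cross == 0.0)
            & (xs >= min(x1, x2))
            & (xs <= max(x1, x2))
            & (ys >= min(y1, y2))
            & (ys <= max(y1, y2))
        )
        boundary |= on_seg
        if y1 == y2:
            continue  # horizontal edge: never crossed by the half-open rule
        straddles = (y1 > ys) != (y2 > ys)
        with np.errstate(invalid="ignore"):
            x_at_y = x1 + (ys - y1) * (x2 - x1) / (y2 - y1)
        inside ^= straddles & (xs < x_at_y)
    result = inside | boundary
    result[~(np.isfinite(xs) & np.isfinite(ys))] = False
    return result


def point_in_polygon(point: tuple[float, float], polygon: Polygon) -> bool:
    """True iff ``point`` is inside ``polygon`` under the even-odd rule.

    Boundary points (on an edge or a vertex) are inside.
    """
    x, y = point
    return bool(points_in_polygon(np.array([x]), np.array([y]), polygon)[0])


def select_genes(table: OmicsTable, mapping, polygon: Polygon) -> Selection:
    """Gate the plotted genes of ``table`` with ``polygon``.

    The polygon lives in the data coordinates of the mapping's x/y columns
    (log10-transformed coordinates when the mapping is log-scaled).  Genes
    excluded from the plot because of missing mapped values can never be
    selected.  The returned gene ids follow table row order; an empty
    selection is valid.
    """
    from .channels import resolve_channels  # deferred: channels imports gating types

    resolved = resolve_channels(table, mapping)
    xs, ys = resolved.x, resolved.y
    hit = points_in_polygon(xs, ys, polygon) & resolved.retained
    gene_ids = tuple(np.asarray(table.gene_ids, dtype=object)[hit])
    return Selection(gene_ids=gene_ids, polygon=polygon, source_mapping=mapping)
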
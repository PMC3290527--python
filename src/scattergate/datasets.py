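"""Seeded synthetic data emulating an H3K27me3 / H3K79me2 / expression table.

The generator reproduces the qualitative structure seen when plotting a
repressive mark against expression: an L-shaped joint distribution in which
genes are either (a) highly expressed with low H3K27me3, (b) repressed with
high H3K27me3, or (c) lowly expressed with low H3K27me3 — there is no
high-expression/high-H3K27me3 stratum.  H3K79me2 tracks active transcription:
elevated in the high-expression stratum, at background elsewhere, so it is
anticorrelated with H3K27me3 and positively correlated with expression.

Stratum assignment is exact (noise only perturbs the measurement values), and
every draw flows through a single seeded generator, so a fixture is fully
reproducible from its spec.

Genesets are planted inside a named stratum, then the collection is padded
with random background sets drawn from all genes — the raw material for
end-to-end enrichment-recovery checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Literal, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError
from .gating import Polygon
from .io import GeneSet, GeneSetCollection, OmicsTable

__all__ = [
    "FixtureSpec",
    "PlantedSet",
    "LShapeDataset",
    "generate_l_shape_dataset",
    "STRATA",
]

Region = Literal["high_expression", "repressed", "background"]
STRATA: tuple[Region, ...] = ("high_expression", "repressed", "background")

# Declared stratum constants on a log2-like scale: expression high ~= 10,
# low ~= 4; mark levels high ~= 8, background ~= 1.
EXPR_HIGH = 10.0
EXPR_LOW = 4.0
MARK_HIGH = 8.0
MARK_BACKGROUND = 1.0

MEASUREMENTS = ("expression", "H3K27me3", "H3K79me2")

#                       expression  H3K27me3         H3K79me2
_STRATUM_MEANS: dict[Region, tuple[float, float, float]] = {
    "high_expression": (EXPR_HIGH, MARK_BACKGROUND, MARK_HIGH),
    "repressed": (EXPR_LOW, MARK_HIGH, MARK_BACKGROUND),
    "background": (EXPR_LOW, MARK_BACKGROUND, MARK_BACKGROUND),
}


@dataclass(frozen=True)
class PlantedSet:
    """A geneset to plant wholly inside one stratum."""

    name: str
    region: Region
    size: int


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic dataset.

    ``frac_repressed`` genes carry the repressive mark; of the remainder,
    ``frac_high_expression`` (of all genes) are highly expressed and the rest
    form the low/low background stratum.  ``n_random_sets`` decoy genesets of
    ``random_set_size`` genes each are drawn uniformly from all genes.
    """

    n_genes: int = 5000
    frac_repressed: float = 0.4
    seed: int = 0
    noise_sd: float = 0.7
    planted_sets: tuple[PlantedSet, ...] = ()
    frac_high_expression: float = 0.3
    n_random_sets: int = 50
    random_set_size: int = 50

    def __post_init__(self):
        if not (0 < self.frac_repressed < 1):
            raise DomainError("frac_repressed must lie in (0, 1)")
        if not (0 < self.frac_high_expression < 1 - self.frac_repressed):
            raise DomainError(
                "frac_high_expression must lie in (0, 1 - frac_repressed)"
            )
        if self.noise_sd <= 0:
            raise DomainError("noise_sd must be positive")
        if any(p.size < 1 for p in self.planted_sets):
            raise DomainError("planted set sizes must be >= 1")
        if sum(p.size for p in self.planted_sets) > self.n_genes:
            raise DomainError("planted set sizes exceed n_genes")


@dataclass(frozen=True)
class LShapeDataset:
    """Generated table + genesets, plus the ground truth tests need.

    Iterable as ``(table, collection)`` so the two main artifacts unpack
    directly; ``strata`` maps each region to its gene ids (table order) and
    ``stratum_polygon`` returns a generous gate around a stratum in
    (H3K27me3, expression) coordinates.
    """

    table: OmicsTable
    collection: GeneSetCollection
    strata: dict[Region, tuple[str, ...]]
    spec: FixtureSpec

    def __iter__(self) -> Iterator:
        return iter((self.table, self.collection))

    def stratum_polygon(self, region: Region) -> Polygon:
        """Axis-aligned box around ``region`` in (H3K27me3, expression) space.

        Thresholds sit halfway between the stratum means; with the default
        noise_sd = 0.7 that is >4 standard deviations from either mean, so
        the box captures a stratum essentially exactly.
        """
        mark_cut = 0.5 * (MARK_BACKGROUND + MARK_HIGH)  # 4.5
        expr_cut = 0.5 * (EXPR_LOW + EXPR_HIGH)  # 7.0
        lo, hi = -10.0, 25.0  # generous outer bounds, beyond any noisy value
        boxes: dict[Region, tuple[float, float, float, float]] = {
            "high_expression": (lo, mark_cut, expr_cut, hi),
            "repressed": (mark_cut, hi, lo, expr_cut),
            "background": (lo, mark_cut, lo, expr_cut),
        }
        x0, x1, y0, y1 = boxes[region]
        return Polygon([(x0, y0), (x1, y0), (x1, y1), (x0, y1)])


def generate_l_shape_dataset(spec: FixtureSpec) -> LShapeDataset:
    """Generate the synthetic table and geneset collection for ``spec``.

    Fully deterministic given ``spec.seed``; calling twice with the same spec
    yields identical output.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_genes
    n_rep = int(round(spec.frac_repressed * n))
    n_high = int(round(spec.frac_high_expression * n))
    n_bg = n - n_rep - n_high
    if min(n_rep, n_high, n_bg) < 1:
        raise DomainError("every stratum must receive at least one gene")

    width = len(str(n))
    gene_ids = np.array([f"GENE{i + 1:0{width}d}" for i in range(n)], dtype=object)
    region_of = np.empty(n, dtype=object)
    shuffled = rng.permutation(n)
    region_of[shuffled[:n_high]] = "high_expression"
    region_of[shuffled[n_high : n_high + n_rep]] = "repressed"
    region_of[shuffled[n_high + n_rep :]] = "background"

    values = np.empty((n, 3), dtype=float)
    for region, means in _STRATUM_MEANS.items():
        mask = region_of == region
        values[mask] = means
    values += rng.normal(0.0, spec.noise_sd, size=values.shape)

    frame = pd.DataFrame(values, index=gene_ids, columns=list(MEASUREMENTS))
    frame.index.name = "gene"
    table = OmicsTable(frame)

    strata: dict[Region, tuple[str, ...]] = {
        region: tuple(gene_ids[region_of == region]) for region in STRATA
    }

    collection = GeneSetCollection()
    for planted in spec.planted_sets:
        pool = np.asarray(strata[planted.region], dtype=object)
        if planted.size > pool.size:
            raise DomainError(
                f"planted set {planted.name!r} wants {planted.size} genes but "
                f"stratum {planted.region!r} has only {pool.size}"
            )
        members = rng.choice(pool, size=planted.size, replace=False)
        collection.add(
            GeneSet(planted.name, f"planted in {planted.region}", frozenset(members))
        )
    for i in range(spec.n_random_sets):
        members = rng.choice(gene_ids, size=spec.random_set_size, replace=False)
        collection.add(GeneSet(f"RANDOM_{i + 1:03d}", "random background set", frozenset(members)))

    return LShapeDataset(table=table, collection=collection, strata=strata, spec=spec)
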
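# Methods

## Overview

`scattergate` decomposes the interactive explore-gate-test workflow into
four deterministic stages: channel resolution (table columns → per-point
positions, colors, radii), rasterization/HTML export, polygon gating in
data coordinates, and geneset over-representation testing.  Every stage is
a pure function of its inputs, so identical inputs produce byte-identical
outputs — the property all round-trip and determinism tests rely on.

## Enrichment model

The sampling frame ("universe") is the set of gene identifiers in the
loaded table, after normalization (strip whitespace, uppercase — MSigDB
symbols are uppercase, which makes table–GMT matching robust).  The gated
genes are modelled as a simple random sample of size `n` from the universe
of size `N`; for a geneset with `K` members in the universe the observed
overlap `k` is referred to the hypergeometric upper tail `P(X ≥ k)`, the
standard one-sided over-representation test (equivalent to one-sided
Fisher).  The reported expected overlap is the hypergeometric mean `nK/N`.

Design choices where the workflow is genuinely open:

* **Universe = table genes**, not the union of geneset members: the
  selection is drawn from plotted genes, so the table is the frame.  An
  override is accepted for callers with a different frame.
* **Geneset size bounds** `[5, 2000]` after restriction to the universe,
  the usual MSigDB-style convention; sets outside the bounds are skipped so
  degenerate tests never enter the multiple-testing correction.
* **Multiple testing**: Benjamini–Hochberg q-values over exactly the tested
  sets (delegated to `statsmodels.stats.multitest`); the CLI report filter
  defaults to q ≤ 0.25 and is configurable.  Raw p and −log10 p are always
  reported alongside.
* **Ordering**: ascending p, ties broken by descending observed overlap
  then geneset name, so output order is total and reproducible.

### Numerical notes

Tail sums use log-space binomials (`gammaln`) combined with `logsumexp`.
This matters in exactly the regime the tool exists for: a tight selection
capturing a whole geneset easily drives `p` below `1e-300`, where a naive
sum underflows to 0 and −log10 p becomes infinite.  `-log10(p)` is derived
from the log-space value directly.  `P(X ≥ k)` is exactly 1 whenever `k` is
at or below the lower support bound `max(0, n+K−N)`.

## Geometry

Point-in-polygon uses even-odd ray casting with the half-open vertex rule
(an edge covers `min(y1,y2) ≤ y < max(y1,y2)`), so rays through shared
vertices are never double-counted and horizontal edges contribute no
crossings.  Points exactly on an edge or vertex are detected by an exact
cross-product/bounding-box test and count as **inside** — the convention a
user expects when a gate border touches a point.  Self-intersecting
polygons (a user can draw one) are accepted under the even-odd rule with no
special-casing.  Gating operates in *data* coordinates, making saved
polygons portable across canvas sizes; on log-scaled axes the polygon is
interpreted in log coordinates.  The test suite checks the implementation
against an independently written winding-number oracle (the two rules agree
on simple polygons, off-boundary).

## Channels and color

Axis ranges are the min/max of the mapped values over retained points,
expanded by 5% padding; a degenerate range (all values equal) expands to
`[v−0.5, v+0.5]`.  Screen convention: y is inverted (high values at the
top), canvas `(0,0)` top-left.  The color ramp is piecewise-linear in RGB
through blue `(0,0,255)` → green `(0,255,0)` → red `(255,0,0)`, anchored at
the observed min, midpoint and max of the color column (value-based, not
rank-based — the simplest defensible scheme for a continuous measurement);
components round half-up.  Size is a linear radius ramp clamped to
`[r_min, r_max]` = `[3, 12]` px by default on an 800×600 canvas with a
40 px margin — all configurable.  A point missing any mapped value is
excluded and counted; retained + excluded always equals the table row
count.  Overplotting follows painter's order (table row order), no alpha.
Non-positive values become missing under a log10 axis.

## Synthetic data generator

The generator emulates the joint structure of a repressive histone mark
(H3K27me3), an activity-linked mark (H3K79me2) and expression: three exact
strata — high-expression (expression ≈ 10, H3K27me3 background, H3K79me2
≈ 8), repressed (expression ≈ 4, H3K27me3 ≈ 8, H3K79me2 background ≈ 1)
and low/low background — with i.i.d. Gaussian noise (sd 0.7) on every
value.  There is deliberately no high/high stratum, producing the L-shaped
scatter, a negative H3K27me3–expression correlation and a positive
H3K79me2–expression correlation.  Defaults: 5,000 genes, 40% repressed,
30% high-expression (the spec of strata fractions needs one more number
than the repressed fraction; 30% is a typical "actively expressed" share),
padded with 50 random 50-gene decoy sets so planted-recovery checks run
against a realistic multiple-testing background.

Stratum means sit 3 units (≈4.3 sd) from the midpoint gates used by
`stratum_polygon`, so a gate recovers its stratum exactly up to rare >4σ
noise excursions (expected ≈0.1 genes per 5,000); tests allow for that
Poisson tail rather than asserting impossibility.

What the generator does **not** emulate: read-count noise, normalization
artifacts, correlated genesets, gene-length effects, or any upstream
processing (RMA summarization, promoter read counting).  Passing tests
therefore demonstrate correctness of the geometry/statistics pipeline, not
robustness to real-data pathologies.

## Problem sizes in tests

The geometry oracle comparison uses 100 random star-shaped polygons ×
10,000 points; hypergeometric enumeration covers every valid tuple with
N ≤ 25 (~24k tuples); null calibration uses 2,000 independent
selection/geneset pairs on a 20,000-gene universe (selection 10,000, set
sizes 500–2,000 — large enough that the discreteness of the test keeps its
achievable size close to the nominal 0.05); rendering checks run at 25,000
points.  These sizes make every statistical check well-powered while the
whole suite stays fast.

## Known limitations

* Value-based color scaling is sensitive to outliers in the color column;
  pass an explicit `color_range` to clamp.
* The enrichment model assumes the gate is independent of geneset
  membership; gating on a measurement that itself defined a geneset
  invalidates the null, as with any post-selection over-representation
  test.
* Duplicate gene identifiers abort loading by default (`keep-first` is
  opt-in); probe-level tables should be collapsed upstream.
* No GSEA-style ranked/weighted enrichment and no identifier mapping
  between species or platforms.
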
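import io as _io

import numpy as np
import pandas as pd
import pytest

from scattergate import FixtureSpec, OmicsTable, PlantedSet, generate_l_shape_dataset


@pytest.fixture
def small_table() -> OmicsTable:
    frame = pd.DataFrame(
        {
            "expr": [1.0, 3.5, np.nan, 0.5, 2.0],
            "k27": [2.0, 0.1, 4.0, 1.5, 3.0],
        },
        index=["A", "B", "C", "D", "E"],
    )
    frame.index.name = "gene"
    return OmicsTable(frame)


def make_random_table(n_rows: int, n_cols: int, seed: int, missing_frac: float = 0.1) -> OmicsTable:
    """Seeded random table with optional missing cells, for round-trip tests."""
    rng = np.random.default_rng(seed)
    values = rng.normal(size=(n_rows, n_cols)) * rng.lognormal(size=(n_rows, n_cols))
    mask = rng.random(size=values.shape) < missing_frac
    values[mask] = np.nan
    frame = pd.DataFrame(
        values,
        index=[f"G{i}" for i in range(n_rows)],
        columns=[f"m{j}" for j in range(n_cols)],
    )
    frame.index.name = "gene"
    return OmicsTable(frame)


@pytest.fixture
def random_table_factory():
    return make_random_table


@pytest.fixture(scope="session")
def l_shape():
    """A moderate L-shaped dataset with one planted set per stratum."""
    spec = FixtureSpec(
        n_genes=5000,
        frac_repressed=0.4,
        seed=42,
        planted_sets=(
            PlantedSet("ACTIVE_PATHWAY", "high_expression", 40),
            PlantedSet("SILENCED_PATHWAY", "repressed", 40),
        ),
    )
    return generate_l_shape_dataset(spec)


def winding_number_inside(px, py, vertices) -> np.ndarray:
    """Independent winding-number oracle (nonzero rule), vectorized over points.

    Written directly from the signed-crossing definition; shares no code with
    the even-odd implementation under test.
    """
    px = np.asarray(px, dtype=float)
    py = np.asarray(py, dtype=float)
    wn = np.zeros(px.shape, dtype=int)
    n = len(vertices)
    for i in range(n):
        x1, y1 = vertices[i]
        x2, y2 = vertices[(i + 1) % n]
        is_left = (x2 - x1) * (py - y1) - (px - x1) * (y2 - y1)
        upward = (y1 <= py) & (y2 > py) & (is_left > 0)
        downward = (y1 > py) & (y2 <= py) & (is_left < 0)
        wn += upward.astype(int) - downward.astype(int)
    return wn != 0


def random_simple_polygon(rng: np.random.Generator, n_vertices: int = 8):
    """A random star-shaped (hence simple) polygon around a random center."""
    from scattergate import Polygon

    center = rng.uniform(-5, 5, size=2)
    angles = np.sort(rng.uniform(0, 2 * np.pi, size=n_vertices))
    radii = rng.uniform(0.5, 5.0, size=n_vertices)
    xs = center[0] + radii * np.cos(angles)
    ys = center[1] + radii * np.sin(angles)
    return Polygon(list(zip(xs, ys)))
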
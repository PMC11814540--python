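"""Shared fixtures: small deterministic rasters, points and feature tables."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import scalescape as sc
from scalescape.features import AREA_COLUMNS, BufferSpec
from scalescape.landscape import MaskSet


EIGHT_MIX = (0.20, 0.25, 0.05, 0.15, 0.10, 0.05, 0.08, 0.12)


@pytest.fixture(scope="session")
def small_raster() -> sc.LanduseRaster:
    """64 x 64 landscape at 100 m cells, all eight classes present."""
    return sc.generate_landscape(64, 64, 100.0, EIGHT_MIX, 300.0, seed=42)


@pytest.fixture(scope="session")
def water_raster() -> sc.LanduseRaster:
    """Uniform all-water raster at 30 m cells (analytic-area checks)."""
    grid = np.full((128, 128), 5, dtype=np.int16)
    return sc.LanduseRaster(grid=grid, cell_size=30.0)


@pytest.fixture()
def no_masks(small_raster) -> MaskSet:
    shape = small_raster.extent
    return MaskSet(np.zeros(shape, dtype=bool), np.zeros(shape, dtype=bool))


def brute_force_buffer_areas(raster, point, spec):
    """All-cells double-loop oracle for buffer class areas."""
    x, y = point
    areas = np.zeros(8)
    for i in range(raster.n_rows):
        for j in range(raster.n_cols):
            cx, cy = raster.cell_center(i, j)
            d = np.hypot(cx - x, cy - y)
            code = int(raster.grid[i, j])
            if code != 0 and spec.inner <= d < spec.outer:
                areas[code - 1] += raster.cell_size**2
    return areas


def synthetic_feature_table(
    n_per_class: int = 100,
    water_gap: float = 0.2,
    label_noise: float = 0.0,
    seed: int = 0,
    outer_m: float = 1000.0,
) -> pd.DataFrame:
    """Feature table at one disc scale where water area separates the labels.

    Presences draw water uniformly from [0.5 + gap/2, 1], absences from
    [0, 0.5 - gap/2] (times 1e6 m^2); other classes are uniform noise.
    A negative ``water_gap`` makes the ranges overlap, giving imperfectly
    separable classes (non-degenerate accuracy variance).  ``label_noise``
    flips that fraction of labels (the planted outliers).
    """
    rng = np.random.default_rng(seed)
    n = 2 * n_per_class
    water = np.concatenate(
        [
            rng.uniform(0.5 + water_gap / 2, 1.0, n_per_class),
            rng.uniform(0.0, 0.5 - water_gap / 2, n_per_class),
        ]
    ) * 1e6
    table = pd.DataFrame(
        rng.uniform(0, 2e5, (n, 7)),
        columns=[c for c in AREA_COLUMNS if c != "water"],
    )
    table.insert(AREA_COLUMNS.index("water"), "water", water)
    labels = np.array([1] * n_per_class + [0] * n_per_class)
    if label_noise > 0:
        n_flip = int(round(label_noise * n))
        flip = rng.choice(n, size=n_flip, replace=False)
        labels[flip] = 1 - labels[flip]
    table["point_id"] = [f"pt{i:04d}" for i in range(n)]
    table["label"] = labels
    table["inner_m"] = 0.0
    table["outer_m"] = outer_m
    table["shannon"] = np.nan
    return table


@pytest.fixture()
def separable_features() -> pd.DataFrame:
    return synthetic_feature_table(n_per_class=100, water_gap=0.2, seed=1)


@pytest.fixture()
def disc_1km() -> BufferSpec:
    return BufferSpec(outer=1000.0)
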
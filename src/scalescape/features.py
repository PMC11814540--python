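"""Land-use class areas inside circular and annular buffers, plus Shannon diversity.

Zonal statistics on the categorical raster: for each point and each buffer
(disc ``[0, outer)`` or ring ``[inner, outer)``) the area of each of the eight
land-use classes is the count of cells whose *center* falls in the buffer
times the cell area.  Rings are half-open so adjacent rings partition the
enclosing disc exactly, and a ring table is an exact set difference of two
disc tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .landscape import CLASS_NAMES, N_CLASSES, LanduseRaster

__all__ = [
    "BufferSpec",
    "default_radii_km",
    "disc_specs",
    "extract_buffer_areas",
    "build_feature_table",
    "shannon_index",
    "AREA_COLUMNS",
]

log = logging.getLogger(__name__)

#: Feature column names, one per land-use class in code order.
AREA_COLUMNS = list(CLASS_NAMES)

#: The 13 study radii in kilometres.
DEFAULT_RADII_KM = (0.5, 1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 15, 20)


@dataclass(frozen=True, order=True)
class BufferSpec:
    """Half-open annulus ``[inner, outer)`` in meters; ``inner=0`` is a disc."""

    outer: float
    inner: float = 0.0

    def __post_init__(self) -> None:
        if not 0 <= self.inner < self.outer:
            raise ValueError("BufferSpec requires 0 <= inner < outer")

    @property
    def label(self) -> str:
        if self.inner == 0:
            return f"{self.outer / 1000:g}km"
        return f"{self.inner / 1000:g}-{self.outer / 1000:g}km"


def default_radii_km() -> tuple[float, ...]:
    return DEFAULT_RADII_KM


def disc_specs(radii_km=DEFAULT_RADII_KM) -> list[BufferSpec]:
    """Disc buffers at the given radii (km), sorted by outer radius."""
    return [BufferSpec(outer=r * 1000.0) for r in sorted(radii_km)]


def _point_window(raster: LanduseRaster, x: float, y: float, outer: float):
    """Distance-to-cell-center array and grid slice within the outer radius."""
    row, col = raster.point_to_cell(x, y)
    r_cells = int(np.ceil(outer / raster.cell_size)) + 1
    r0, r1 = max(0, row - r_cells), min(raster.n_rows, row + r_cells + 1)
    c0, c1 = max(0, col - r_cells), min(raster.n_cols, col + r_cells + 1)
    rows = np.arange(r0, r1)
    cols = np.arange(c0, c1)
    cx, _ = raster.cell_center(np.zeros_like(cols), cols)
    _, cy = raster.cell_center(rows, np.zeros_like(rows))
    d = np.hypot(cx[None, :] - x, cy[:, None] - y)
    return d, raster.grid[r0:r1, c0:c1]


def _areas_from_window(d, window, spec: BufferSpec, cell_area: float) -> np.ndarray:
    mask = (d >= spec.inner) & (d < spec.outer)
    codes = window[mask]
    counts = np.bincount(codes, minlength=N_CLASSES + 1)[1:]
    return counts.astype(float) * cell_area


def extract_buffer_areas(
    raster: LanduseRaster, point: tuple[float, float], spec: BufferSpec
) -> np.ndarray:
    """Area (m^2) of each of the 8 classes inside the buffer around ``point``.

    A cell contributes if its center ``c`` satisfies
    ``inner <= dist(c, point) < outer``.  Buffers may overhang the raster
    edge; the overhang contributes nothing.
    """
    x, y = point
    if not raster.contains(x, y):
        raise ValueError(f"point {point} lies outside the raster extent")
    d, window = _point_window(raster, x, y, spec.outer)
    return _areas_from_window(d, window, spec, raster.cell_size**2)


def build_feature_table(
    raster: LanduseRaster,
    points: pd.DataFrame,
    specs: list[BufferSpec],
    warn_overhang: float = 0.5,
) -> pd.DataFrame:
    """Per (point, buffer) class areas: the model input table.

    Rows are ordered by point (input order) then by buffer outer radius.
    Columns: ``point_id, label, inner_m, outer_m``, the 8 class areas (m^2)
    and ``shannon`` (nats; NaN for an empty buffer).  Points whose largest
    buffer is mostly off-raster (> ``warn_overhang`` missing) are logged.
    """
    if len(points) == 0 or len(specs) == 0:
        raise ValueError("points and specs must be non-empty")
    specs = sorted(specs, key=lambda s: (s.outer, s.inner))
    cell_area = raster.cell_size**2
    max_outer = max(s.outer for s in specs)
    records = []
    for _, pt in points.iterrows():
        x, y = float(pt["x"]), float(pt["y"])
        if not raster.contains(x, y):
            raise ValueError(f"point {pt['id']} lies outside the raster extent")
        d, window = _point_window(raster, x, y, max_outer)
        largest = float("nan")
        for spec in specs:
            areas = _areas_from_window(d, window, spec, cell_area)
            total = areas.sum()
            h = shannon_index(areas) if total > 0 else float("nan")
            if total == 0:
                log.warning("empty buffer %s for point %s", spec.label, pt["id"])
            if spec.outer == max_outer:
                largest = total
            rec = {
                "point_id": pt["id"],
                "label": pt["label"],
                "inner_m": spec.inner,
                "outer_m": spec.outer,
            }
            rec.update(dict(zip(AREA_COLUMNS, areas)))
            rec["shannon"] = h
            records.append(rec)
        nominal = np.pi * max_outer**2
        if largest < (1 - warn_overhang) * nominal:
            log.warning(
                "point %s: largest buffer is %.0f%% off-raster",
                pt["id"],
                100 * (1 - largest / nominal),
            )
    return pd.DataFrame.from_records(records)


def shannon_index(areas, base: float | None = None) -> float:
    """Shannon diversity H = -sum p_k log p_k of a class-area composition.

    Natural log by default (nats); pass ``base`` to change it.  Zero-area
    classes contribute nothing; an all-zero composition is undefined and
    raises ``ValueError``.  For 8 classes, 0 <= H <= ln 8.
    """
    a = np.asarray(areas, dtype=float)
    if np.any(a < 0):
        raise ValueError("areas must be non-negative")
    if a.sum() <= 0:
        raise ValueError("Shannon index undefined for an all-zero composition")
    return float(sps.entropy(a, base=base))
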
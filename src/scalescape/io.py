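"""Plain-text I/O: ESRI ASCII rasters, point CSV/GeoJSON, feature tables.

The raster interchange format is the ESRI ASCII grid (``.asc``): a
six-line header (ncols, nrows, xllcorner, yllcorner, cellsize,
NODATA_value) followed by the grid rows top-down, readable by standard GIS
stacks.  Points travel as CSV (``id,x,y,label,source``) or GeoJSON point
collections; feature tables as CSV with areas rounded to 2 decimals.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .features import AREA_COLUMNS
from .landscape import NODATA, LanduseRaster, MaskSet

__all__ = [
    "write_ascii_grid",
    "read_ascii_grid",
    "write_points_csv",
    "read_points_csv",
    "write_points_geojson",
    "write_feature_table",
    "read_feature_table",
    "write_mask_set",
]

POINT_COLUMNS = ["id", "x", "y", "label", "source"]


def write_ascii_grid(raster: LanduseRaster, path) -> None:
    path = Path(path)
    x0, y0 = raster.origin
    yll = y0 - raster.n_rows * raster.cell_size
    header = (
        f"ncols {raster.n_cols}\n"
        f"nrows {raster.n_rows}\n"
        f"xllcorner {x0:.6f}\n"
        f"yllcorner {yll:.6f}\n"
        f"cellsize {raster.cell_size:.6f}\n"
        f"NODATA_value {NODATA}\n"
    )
    with path.open("w") as fh:
        fh.write(header)
        np.savetxt(fh, raster.grid, fmt="%d")


def read_ascii_grid(path) -> LanduseRaster:
    path = Path(path)
    header: dict[str, float] = {}
    with path.open() as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        grid = np.loadtxt(fh, dtype=np.int16)
    grid = np.atleast_2d(grid)
    n_rows = int(header["nrows"])
    cs = header["cellsize"]
    x0 = header["xllcorner"]
    y0 = header["yllcorner"] + n_rows * cs
    return LanduseRaster(grid=grid, cell_size=cs, origin=(x0, y0))


def write_points_csv(points: pd.DataFrame, path) -> None:
    points[POINT_COLUMNS].to_csv(path, index=False, float_format="%.3f")


def read_points_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"id": str, "label": object, "source": str})


def write_points_geojson(points: pd.DataFrame, path) -> None:
    features = [
        {
            "type": "Feature",
            "geometry": {"type": "Point", "coordinates": [round(r.x, 3), round(r.y, 3)]},
            "properties": {"id": r.id, "label": r.label, "source": r.source},
        }
        for r in points.itertuples()
    ]
    payload = {"type": "FeatureCollection", "features": features}
    Path(path).write_text(json.dumps(payload, indent=None, sort_keys=True))


def write_feature_table(features: pd.DataFrame, path) -> None:
    cols = ["point_id", "label", "inner_m", "outer_m", *AREA_COLUMNS, "shannon"]
    out = features[cols].copy()
    for c in AREA_COLUMNS:
        out[c] = out[c].round(2)
    out["shannon"] = out["shannon"].round(6)
    out.to_csv(path, index=False)


def read_feature_table(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"point_id": str})


def write_mask_set(masks: MaskSet, raster: LanduseRaster, border_path, town_path) -> None:
    for mask, path in ((masks.border_mask, border_path), (masks.town_mask, town_path)):
        as_raster = LanduseRaster(
            grid=mask.astype(np.int16),
            cell_size=raster.cell_size,
            origin=raster.origin,
        )
        write_ascii_grid(as_raster, path)
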
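"""Plain-text readers and writers for the pipeline's tabular formats.

Depth records and GPS fixes travel as CSV; bathymetry as an ESRI ASCII grid
or an xarray/NetCDF-style container (see BathymetryGrid.to_xarray).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .extraction import DepthSeries
from .geolocation import BathymetryGrid

__all__ = [
    "write_depth_csv", "read_depth_csv", "write_fixes_csv", "read_fixes_csv",
    "write_esri_ascii", "read_esri_ascii",
]


def write_depth_csv(series: DepthSeries, path) -> None:
    """Columns: tag_id, timestamp (ISO-8601 UTC), depth_m."""
    times = series.start_time + pd.to_timedelta(np.arange(len(series)), unit="s")
    pd.DataFrame({
        "tag_id": series.tag_id,
        "timestamp": times.strftime("%Y-%m-%dT%H:%M:%SZ"),
        "depth_m": series.depth,
    }).to_csv(path, index=False)


def read_depth_csv(path, local_utc_offset: float = 0.0) -> list[DepthSeries]:
    """Read a depth CSV, splitting on sampling gaps (one series per gap-free run).

    Non-uniform spacing other than whole missing seconds is rejected.
    """
    df = pd.read_csv(path)
    out = []
    for tag, g in df.groupby("tag_id", sort=False):
        t = pd.to_datetime(g["timestamp"], utc=True)
        dt = t.diff().dt.total_seconds().to_numpy()[1:]
        if np.any(dt < 1) or np.any(dt != np.round(dt)):
            raise ValueError(f"non-uniform sampling for tag {tag!r}")
        breaks = np.flatnonzero(dt > 1) + 1
        for chunk_idx in np.split(np.arange(len(g)), breaks):
            if len(chunk_idx) == 0:
                continue
            out.append(DepthSeries(
                tag_id=str(tag),
                start_time=t.iloc[chunk_idx[0]],
                depth=g["depth_m"].to_numpy()[chunk_idx],
                local_utc_offset=local_utc_offset,
            ))
    return out


def write_fixes_csv(fixes: pd.DataFrame, path) -> None:
    out = fixes.copy()
    out["time"] = pd.to_datetime(out["time"], utc=True).dt.strftime("%Y-%m-%dT%H:%M:%SZ")
    out.to_csv(path, index=False)


def read_fixes_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["time"] = pd.to_datetime(df["time"], utc=True)
    if np.any(df["lat"].abs() > 90) or np.any(df["lon"].abs() > 180):
        raise ValueError("fix coordinates out of range")
    return df.sort_values(["tag_id", "time"]).reset_index(drop=True)


def write_esri_ascii(grid: BathymetryGrid, path) -> None:
    """ESRI ASCII raster (requires equal lon/lat cell size)."""
    dlon = grid.lon[1] - grid.lon[0]
    dlat = grid.lat[1] - grid.lat[0]
    if abs(dlon - dlat) > 1e-9:
        raise ValueError("ESRI ASCII requires square cells")
    with open(path, "w") as fh:
        fh.write(f"ncols {len(grid.lon)}\n")
        fh.write(f"nrows {len(grid.lat)}\n")
        fh.write(f"xllcenter {grid.lon[0]:.10f}\n")
        fh.write(f"yllcenter {grid.lat[0]:.10f}\n")
        fh.write(f"cellsize {dlon:.10f}\n")
        fh.write("NODATA_value -9999\n")
        # rows from north to south per the format
        for row in grid.depth[::-1]:
            fh.write(" ".join(f"{v:.3f}" for v in row) + "\n")


def read_esri_ascii(path) -> BathymetryGrid:
    header = {}
    with open(path) as fh:
        lines = fh.readlines()
    for line in lines[:6]:
        key, val = line.split()
        header[key.lower()] = float(val)
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    cell = header["cellsize"]
    lon = header["xllcenter"] + np.arange(ncols) * cell
    lat = header["yllcenter"] + np.arange(nrows) * cell
    depth = np.loadtxt(lines[6:])
    depth = np.atleast_2d(depth)[::-1]  # back to south-to-north
    nodata = header.get("nodata_value", -9999)
    depth = np.where(depth == nodata, np.nan, depth)
    return BathymetryGrid(lon=lon, lat=lat, depth=depth)
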
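"""Activity budgets, surface periods, spatial dive densities, diel contrasts.

The activity budget partitions each tag's tracked time into the six dive
types plus surface time.  The time denominator is the sum of all dive
durations and post-dive intervals; each type's time share uses dive
durations only, and all post-dive intervals are pooled as surface time, so
both the dive-count percentages and the time-plus-surface percentages sum
to 100.

Dive locations are binned on a flat-top hexagonal grid (default 5-km cells,
measured across flats) in a local azimuthal equal-area plane centered on the
deployment's centroid, so cell areas are equal and counts are comparable
across the map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geolocation import EARTH_RADIUS_KM

__all__ = [
    "DielConfig", "activity_budget", "find_surface_periods", "hex_density",
    "diel_label", "diel_contrast", "laea_project",
]


@dataclass(frozen=True)
class DielConfig:
    """Local-time night window; wraps midnight (20:00 inclusive to 07:00 exclusive)."""

    night_start_hour: float = 20.0
    night_end_hour: float = 7.0


def activity_budget(labeled: pd.DataFrame,
                    type_names=None) -> pd.DataFrame:
    """Per-tag percent of dives and of time per type, plus surface time.

    ``labeled`` needs columns tag_id, type_name, duration_min, and PDI
    (minutes; a missing final PDI counts as 0).  Returns one row per tag
    with n_dives, total_time_days, pct_dives_<type>, pct_time_<type>, and
    pct_surface.
    """
    if len(labeled) == 0:
        return pd.DataFrame()
    if type_names is None:
        type_names = sorted(labeled["type_name"].unique())
    rows = []
    for tag, g in labeled.groupby("tag_id", sort=True):
        pdi = g["PDI"].fillna(0.0)
        denom = g["duration_min"].sum() + pdi.sum()
        row = {"tag_id": tag, "n_dives": len(g),
               "total_time_days": denom / (60 * 24)}
        for name in type_names:
            sel = g["type_name"] == name
            row[f"pct_dives_{name}"] = 100.0 * sel.sum() / len(g)
            row[f"pct_time_{name}"] = 100.0 * g.loc[sel, "duration_min"].sum() / denom
        row["pct_surface"] = 100.0 * pdi.sum() / denom
        rows.append(row)
    return pd.DataFrame(rows)


def find_surface_periods(dives: pd.DataFrame) -> pd.DataFrame:
    """Gaps between consecutive detected dives, flagged when extended.

    Returns start/end times, duration in minutes, and flags for gaps longer
    than 30 and 60 minutes.
    """
    out_rows = []
    for tag, g in dives.groupby("tag_id", sort=False):
        g = g.sort_values("start_time")
        ends = pd.to_datetime(g["end_time"]).to_numpy()[:-1]
        starts = pd.to_datetime(g["start_time"]).to_numpy()[1:]
        durations = (starts - ends) / np.timedelta64(1, "m")
        for e, s, d in zip(ends, starts, durations):
            out_rows.append({"tag_id": tag, "start": e, "end": s,
                             "duration_min": float(d),
                             "over_30min": bool(d > 30), "over_60min": bool(d > 60)})
    return pd.DataFrame(out_rows,
                        columns=["tag_id", "start", "end", "duration_min",
                                 "over_30min", "over_60min"])


def laea_project(lon, lat, lon0: float, lat0: float):
    """Spherical Lambert azimuthal equal-area forward projection (km)."""
    lon, lat = np.radians(np.asarray(lon, float)), np.radians(np.asarray(lat, float))
    lam0, phi0 = np.radians(lon0), np.radians(lat0)
    dlam = lon - lam0
    denom = 1.0 + np.sin(phi0) * np.sin(lat) + np.cos(phi0) * np.cos(lat) * np.cos(dlam)
    k = np.sqrt(2.0 / denom)
    x = EARTH_RADIUS_KM * k * np.cos(lat) * np.sin(dlam)
    y = EARTH_RADIUS_KM * k * (np.cos(phi0) * np.sin(lat)
                               - np.sin(phi0) * np.cos(lat) * np.cos(dlam))
    return x, y


def _hex_axial(x, y, size_r: float):
    """Flat-top hexagon axial coordinates via cube rounding.

    ``size_r`` is the hexagon circumradius.  Every point maps to exactly one
    cell (ties resolved by the largest rounding error), so binning is a
    partition of the plane.
    """
    q = (2.0 / 3.0) * x / size_r
    r = (-1.0 / 3.0 * x + np.sqrt(3.0) / 3.0 * y) / size_r
    s = -q - r
    rq, rr, rs = np.round(q), np.round(r), np.round(s)
    dq, dr, ds = np.abs(rq - q), np.abs(rr - r), np.abs(rs - s)
    fix_q = (dq > dr) & (dq > ds)
    fix_r = ~fix_q & (dr > ds)
    rq = np.where(fix_q, -rr - rs, rq)
    rr = np.where(fix_r, -rq - rs, rr)
    return rq.astype(int), rr.astype(int)


def _hex_center(q, r, size_r: float):
    x = size_r * 1.5 * q
    y = size_r * np.sqrt(3.0) * (r + q / 2.0)
    return x, y


def hex_density(located: pd.DataFrame, cell_km: float = 5.0) -> pd.DataFrame:
    """Per-cell, per-type dive counts on a hexagonal grid.

    ``cell_km`` is the cell size measured across flats.  Only spatially
    valid dives are binned; the per-type cell counts sum exactly to the
    number of valid dives of that type.  Returns cell axial coordinates,
    center lon/lat, type, and count.
    """
    valid = located[located["spatial_valid"]].copy()
    if len(valid) == 0:
        return pd.DataFrame(columns=["q", "r", "center_lon", "center_lat",
                                     "type_name", "count"])
    lon0 = float(valid["lon"].mean())
    lat0 = float(valid["lat"].mean())
    x, y = laea_project(valid["lon"].to_numpy(), valid["lat"].to_numpy(), lon0, lat0)
    size_r = cell_km / np.sqrt(3.0)  # across-flats width -> circumradius
    q, r = _hex_axial(x, y, size_r)
    valid["q"], valid["r"] = q, r
    counts = (valid.groupby(["q", "r", "type_name"], sort=True)
              .size().rename("count").reset_index())
    cx, cy = _hex_center(counts["q"].to_numpy(float), counts["r"].to_numpy(float), size_r)
    # inverse of the local projection, adequate at study scale for cell centers
    counts["center_lat"] = lat0 + np.degrees(cy / EARTH_RADIUS_KM)
    counts["center_lon"] = lon0 + np.degrees(
        cx / (EARTH_RADIUS_KM * np.cos(np.radians(lat0))))
    return counts[["q", "r", "center_lon", "center_lat", "type_name", "count"]]


def diel_label(times, local_utc_offset: float,
               cfg: DielConfig = DielConfig()) -> np.ndarray:
    """Label UTC timestamps day/night by local clock time.

    Night spans [night_start, 24) and [0, night_end) local hours; the window
    wraps midnight.  Local time is UTC plus a fixed offset (single study
    area, no DST).
    """
    t = pd.DatetimeIndex(pd.to_datetime(times)) + pd.Timedelta(hours=local_utc_offset)
    hours = t.hour + t.minute / 60.0 + t.second / 3600.0
    night = (hours >= cfg.night_start_hour) | (hours < cfg.night_end_hour)
    return np.where(night, "night", "day")


def diel_contrast(labeled: pd.DataFrame, B: int = 10000, seed: int = 0,
                  value: str = "MaxDepth") -> pd.DataFrame:
    """Descriptive day/night contrast per dive type with a paired sign test.

    For each type, per-tag mean night-minus-day differences of ``value`` are
    combined into a mean paired difference; significance is assessed with a
    sign-permutation test (random sign flips of the per-tag differences).
    The model-based analysis (mixed-effects regression) is standard-package
    territory and intentionally not reimplemented here.  Requires columns
    tag_id, type_name, diel, and ``value``.  With a single informative tag
    the pooled p-value is undefined (NaN).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for type_name, g in labeled.groupby("type_name", sort=True):
        by = g.groupby(["tag_id", "diel"])[value].agg(["mean", "size"]).unstack("diel")
        means = by["mean"] if "mean" in by.columns.get_level_values(0) else pd.DataFrame()
        diffs = []
        if {"day", "night"}.issubset(set(means.columns)):
            paired = means.dropna(subset=["day", "night"])
            diffs = (paired["night"] - paired["day"]).to_numpy()
        n_day = int(g[g["diel"] == "day"].shape[0])
        n_night = int(g[g["diel"] == "night"].shape[0])
        row = {"type_name": type_name, "n_day": n_day, "n_night": n_night,
               "mean_day": g.loc[g["diel"] == "day", value].mean(),
               "mean_night": g.loc[g["diel"] == "night", value].mean(),
               "n_tags_paired": len(diffs),
               "mean_paired_diff": float(np.mean(diffs)) if len(diffs) else np.nan,
               "p_value": np.nan}
        if len(diffs) >= 2:
            stat = abs(np.mean(diffs))
            signs = rng.choice([-1.0, 1.0], size=(B, len(diffs)))
            perm = np.abs((signs * diffs).mean(axis=1))
            row["p_value"] = float((np.sum(perm >= stat - 1e-12) + 1) / (B + 1))
        rows.append(row)
    return pd.DataFrame(rows)
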
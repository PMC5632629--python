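"""Per-dive summary variables, their transformations, and outlier flags.

Twelve variables describe each dive: maximum depth (MaxDepth, m), duration
(DiveDur, min), ascent and descent rates (AscRt/DescRt, m/s, computed from
phase-boundary depths over phase durations), bottom-phase duration (BottDur,
min), mean and SD of bottom-phase depth (MeanBottDepth/SDBottDepth, m),
post-dive interval (PDI, min, time from the end of a dive to the start of
the next), the bottom-to-total duration ratio (BottFrac), distance from the
dive's maximum depth to the charted seafloor (DistToSeaFlr, m), travel speed
between consecutive dive locations (Speed, km/hr), and the absolute heading
change across three sequential dives (TA, degrees).

Most variables are right-skewed and are square-root transformed before
multivariate analysis; PDI is log10-transformed; DiveDur and BottFrac are
left untransformed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .extraction import DepthSeries

METRIC_COLUMNS = [
    "MaxDepth", "DiveDur", "AscRt", "DescRt", "BottDur", "MeanBottDepth",
    "SDBottDepth", "PDI", "BottFrac", "DistToSeaFlr", "Speed", "TA",
]

#: minimum PDI (min) substituted before the log transform; back-to-back
#: dives would otherwise produce -inf.
PDI_FLOOR_MIN = 0.03

DEFAULT_TRANSFORMS = {
    "MaxDepth": "square_root",
    "DiveDur": "identity",
    "AscRt": "square_root",
    "DescRt": "square_root",
    "BottDur": "square_root",
    "MeanBottDepth": "square_root",
    "SDBottDepth": "square_root",
    "PDI": "log10",
    "BottFrac": "identity",
    "DistToSeaFlr": "square_root",
    "Speed": "square_root",
    "TA": "square_root",
}

__all__ = [
    "METRIC_COLUMNS", "DEFAULT_TRANSFORMS", "PDI_FLOOR_MIN", "TransformSpec",
    "compute_dive_metrics", "apply_transforms", "invert_transforms",
    "flag_outliers",
]


@dataclass(frozen=True)
class TransformSpec:
    """Per-variable transform, one of identity / square_root / log10."""

    transforms: dict = field(default_factory=lambda: dict(DEFAULT_TRANSFORMS))

    def __post_init__(self) -> None:
        bad = {v for v in self.transforms.values()} - {"identity", "square_root", "log10"}
        if bad:
            raise ValueError(f"unknown transforms: {sorted(bad)}")


def compute_dive_metrics(series: DepthSeries, dives: pd.DataFrame) -> pd.DataFrame:
    """Compute the 12 variables for every dive in an extracted, located table.

    ``dives`` must carry phase boundaries (descent_end, ascent_start) and,
    for the movement metrics, Speed/TA/DistToSeaFlr columns from
    :func:`divetype.geolocation.add_movement_metrics` (absent columns yield
    NaN).  The last dive's PDI is missing, as is Speed for the first dive
    and TA for both ends.
    """
    out = dives.reset_index(drop=True).copy()
    n = len(out)
    maxdepth = np.empty(n)
    ascrt = np.empty(n)
    descrt = np.empty(n)
    bottdur = np.empty(n)
    meanbott = np.empty(n)
    sdbott = np.empty(n)
    for i, row in out.iterrows():
        seg = series.depth[int(row["start_index"]):int(row["end_index"])]
        de, a0 = int(row["descent_end"]), int(row["ascent_start"])
        m = len(seg)
        maxdepth[i] = seg.max()
        descrt[i] = (seg[de] - seg[0]) / de
        asc_len = (m - 1) - (a0 - 1)
        ascrt[i] = (seg[a0 - 1] - seg[m - 1]) / asc_len if asc_len > 0 else np.nan
        bottom = seg[de:a0]
        bottdur[i] = len(bottom) / 60.0
        if len(bottom) == 0:
            meanbott[i] = np.nan
            sdbott[i] = np.nan
        else:
            meanbott[i] = bottom.mean()
            sdbott[i] = bottom.std(ddof=1) if len(bottom) > 1 else 0.0

    start = pd.to_datetime(out["start_time"])
    end = pd.to_datetime(out["end_time"])
    pdi = np.full(n, np.nan)
    if n > 1:
        pdi[:-1] = (start.iloc[1:].to_numpy() - end.iloc[:-1].to_numpy()) / np.timedelta64(1, "m")

    metrics = pd.DataFrame(
        {
            "MaxDepth": maxdepth,
            "DiveDur": out["duration_min"].to_numpy(),
            "AscRt": ascrt,
            "DescRt": descrt,
            "BottDur": bottdur,
            "MeanBottDepth": meanbott,
            "SDBottDepth": sdbott,
            "PDI": pdi,
            "BottFrac": bottdur / out["duration_min"].to_numpy(),
            "DistToSeaFlr": out.get("DistToSeaFlr", pd.Series(np.nan, index=out.index)).to_numpy(),
            "Speed": out.get("Speed", pd.Series(np.nan, index=out.index)).to_numpy(),
            "TA": out.get("TA", pd.Series(np.nan, index=out.index)).to_numpy(),
        }
    )
    return metrics


def apply_transforms(table: pd.DataFrame, spec: TransformSpec = TransformSpec()) -> pd.DataFrame:
    """Column-wise monotone transforms; NaNs pass through.

    PDI values below the observed support floor are raised to
    ``PDI_FLOOR_MIN`` before the log.  Negative input to a square root is a
    violation of upstream invariants and is rejected.
    """
    out = table.copy()
    for col, tf in spec.transforms.items():
        if col not in out.columns:
            continue
        x = out[col].to_numpy(dtype=float)
        if tf == "identity":
            continue
        if tf == "square_root":
            if np.nanmin(x, initial=0.0) < 0:
                raise ValueError(f"negative value in column {col!r} under square_root")
            out[col] = np.sqrt(x)
        elif tf == "log10":
            x = np.where(np.isnan(x), np.nan, np.maximum(x, PDI_FLOOR_MIN))
            out[col] = np.log10(x)
    return out


def invert_transforms(table: pd.DataFrame, spec: TransformSpec = TransformSpec()) -> pd.DataFrame:
    """Inverse of :func:`apply_transforms` (round-trips within 1e-9)."""
    out = table.copy()
    for col, tf in spec.transforms.items():
        if col not in out.columns:
            continue
        if tf == "square_root":
            out[col] = out[col] ** 2
        elif tf == "log10":
            out[col] = 10.0 ** out[col]
    return out


def flag_outliers(table: pd.DataFrame, n_mad: float = 5.0,
                  override_add=None, override_remove=None):
    """Flag univariate outliers per column at median +/- ``n_mad`` * MAD.

    MAD is the raw median absolute deviation (unscaled).  ``override_add``
    and ``override_remove`` are iterables of row labels that force or clear
    a flag, preserving an analyst's manual decisions.  Returns
    ``(kept, flags)`` where ``flags`` is a boolean frame aligned to the
    input and ``kept`` drops rows flagged in any column.
    """
    flags = pd.DataFrame(False, index=table.index, columns=table.columns)
    for col in table.columns:
        x = table[col].astype(float)
        med = x.median(skipna=True)
        mad = (x - med).abs().median(skipna=True)
        if not np.isfinite(mad) or mad == 0:
            continue
        flags[col] = (x - med).abs() > n_mad * mad
    any_flag = flags.any(axis=1)
    if override_add is not None:
        any_flag.loc[list(override_add)] = True
    if override_remove is not None:
        any_flag.loc[list(override_remove)] = False
    kept = table.loc[~any_flag]
    return kept, flags
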
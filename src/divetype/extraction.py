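"""Dive detection and phase segmentation for 1-Hz time-depth-recorder records.

A *dive* is any maximal contiguous submergence (depth above a surface
threshold) lasting longer than a minimum duration and reaching deeper than a
minimum depth.  Each dive is partitioned into descent, bottom, and ascent
phases from the per-second depth rate: the bottom phase begins at the first
instance where the rate changes sign (descending to not-descending) or is
zero for a sustained run, and ends at the mirrored instance found from the
end of the dive.  Brief stalls during descent or ascent ("shoulders") that
are much shallower than a subsequent phase boundary are relabeled so the
bottom phase reflects the true foraging depth.

Sign convention: depth is positive down, so a positive depth rate means the
animal is descending.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DepthSeries",
    "DetectionConfig",
    "DiveRecord",
    "DivePhases",
    "detect_dives",
    "segment_phases",
    "refine_shoulders",
    "extract_dive_table",
]


@dataclass
class DepthSeries:
    """A uniform 1-Hz depth record for one tag deployment.

    Depths are metres, positive down.  Negative sensor readings are clamped
    to zero on construction; non-finite values are rejected.  Records with
    gaps must be split into separate series before construction.
    """

    tag_id: str
    start_time: pd.Timestamp
    depth: np.ndarray
    local_utc_offset: float = 0.0

    def __post_init__(self) -> None:
        depth = np.asarray(self.depth, dtype=float)
        if depth.ndim != 1:
            raise ValueError("depth must be a 1-D array")
        if not np.all(np.isfinite(depth)):
            raise ValueError("depth contains non-finite values")
        self.depth = np.clip(depth, 0.0, None)
        self.start_time = pd.Timestamp(self.start_time)
        if self.start_time.tzinfo is None:
            self.start_time = self.start_time.tz_localize("UTC")

    def __len__(self) -> int:
        return len(self.depth)

    def time_at(self, index: int | np.ndarray) -> pd.Timestamp | pd.DatetimeIndex:
        """UTC time of a sample index (vectorized)."""
        offsets = pd.to_timedelta(np.asarray(index), unit="s")
        if np.ndim(index) == 0:
            return self.start_time + pd.Timedelta(seconds=int(index))
        return pd.DatetimeIndex(self.start_time + offsets)


@dataclass(frozen=True)
class DetectionConfig:
    """Thresholds for dive detection and phase segmentation.

    surface_threshold : depth (m) above which a sample counts as submerged.
    min_depth         : a dive's maximum depth must exceed this (m).
    min_duration      : a dive must last longer than this (s).
    zero_rate_run     : length (s) of a sustained zero-rate run that marks a
                        phase boundary.
    zero_rate_tol     : |rate| below this (m/s) counts as zero; guards
                        against sensor quantization.
    shoulder_ratio    : normalized-depth ratio below which an early phase
                        boundary is relabeled a shoulder.
    """

    surface_threshold: float = 1.0
    min_depth: float = 10.0
    min_duration: float = 60.0
    zero_rate_run: int = 10
    zero_rate_tol: float = 0.01
    shoulder_ratio: float = 0.68

    def __post_init__(self) -> None:
        for name in ("surface_threshold", "min_depth", "min_duration",
                     "zero_rate_run", "zero_rate_tol"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.shoulder_ratio < 1.0:
            raise ValueError("shoulder_ratio must be in (0, 1)")


@dataclass(frozen=True)
class DiveRecord:
    """One detected dive; indices are 0-based and half-open into the series."""

    tag_id: str
    start_index: int
    end_index: int
    start_time: pd.Timestamp
    end_time: pd.Timestamp
    max_depth: float
    duration_min: float


@dataclass(frozen=True)
class DivePhases:
    """Phase partition of one dive, indices relative to the dive start.

    descent = samples [0, descent_end); bottom = [descent_end, ascent_start);
    ascent = [ascent_start, n).  Shoulders record a relabeled early phase
    boundary as (index, depth).
    """

    descent_end: int
    ascent_start: int
    descent_shoulder: Optional[tuple[int, float]] = None
    ascent_shoulder: Optional[tuple[int, float]] = None


def detect_dives(series: DepthSeries, cfg: DetectionConfig = DetectionConfig()) -> list[DiveRecord]:
    """Find all dives: maximal submergence runs that pass both thresholds.

    Returns time-ordered, non-overlapping records.  A series shorter than
    two samples yields no dives.
    """
    depth = series.depth
    n = len(depth)
    if n < 2:
        return []
    wet = depth > cfg.surface_threshold
    padded = np.concatenate(([False], wet, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, ends = edges[0::2], edges[1::2]
    records = []
    for s, e in zip(starts, ends):
        dur_s = e - s  # 1-Hz samples: one second each
        maxd = float(depth[s:e].max())
        if dur_s > cfg.min_duration and maxd > cfg.min_depth:
            records.append(
                DiveRecord(
                    tag_id=series.tag_id,
                    start_index=int(s),
                    end_index=int(e),
                    start_time=series.time_at(int(s)),
                    end_time=series.time_at(int(e)),
                    max_depth=maxd,
                    duration_min=dur_s / 60.0,
                )
            )
    return records


def _bottom_start_candidates(depth: np.ndarray, cfg: DetectionConfig) -> np.ndarray:
    """Sample indices where the bottom phase could begin.

    A candidate is (a) a strict sign change of the depth rate from
    descending to ascending (the most recent non-zero rate was positive and
    the current rate is negative), or (b) the start of a run of at least
    ``zero_rate_run`` consecutive zero rates.  Indices are >= 1 so the
    descent phase is never empty.
    """
    r = np.diff(depth)
    m = len(r)
    if m == 0:
        return np.empty(0, dtype=int)
    sign = np.zeros(m, dtype=np.int8)
    sign[r >= cfg.zero_rate_tol] = 1
    sign[r <= -cfg.zero_rate_tol] = -1

    # forward-fill of the last non-zero sign strictly before each rate index
    nz = sign != 0
    idx = np.where(nz, np.arange(m), -1)
    filled = np.maximum.accumulate(idx)
    prev_nz = np.zeros(m, dtype=np.int8)
    prev_idx = np.concatenate(([-1], filled[:-1]))
    has_prev = prev_idx >= 0
    prev_nz[has_prev] = sign[prev_idx[has_prev]]

    sign_change = np.flatnonzero((sign == -1) & (prev_nz == 1))

    zero = sign == 0
    run_start = zero & np.concatenate(([True], ~zero[:-1]))
    starts = np.flatnonzero(run_start)
    zero_cands = []
    for s in starts:
        rest = zero[s:]
        length = m - s if rest.all() else int(np.argmax(~rest))
        if length >= cfg.zero_rate_run:
            zero_cands.append(s)
    cands = np.union1d(sign_change, np.asarray(zero_cands, dtype=int))
    return cands[cands >= 1]


def segment_phases(dive_depth: np.ndarray, cfg: DetectionConfig = DetectionConfig()) -> DivePhases:
    """Partition one dive's samples into descent / bottom / ascent.

    The bottom phase starts at the first rate sign change or sustained
    zero-rate run, and ends at the mirrored instance located from the dive's
    end.  A strict V-shaped dive has a single-sample bottom at the apex.
    """
    depth = np.asarray(dive_depth, dtype=float)
    n = len(depth)
    if n < 3:
        raise ValueError("dive must have at least 3 samples")
    fwd = _bottom_start_candidates(depth, cfg)
    rev = _bottom_start_candidates(depth[::-1], cfg)
    apex = int(np.argmax(depth))
    descent_end = int(fwd[0]) if len(fwd) else max(1, min(apex, n - 2))
    ascent_start = int(n - rev[0]) if len(rev) else descent_end + 1
    if descent_end > ascent_start:
        descent_end = max(1, min(apex, n - 2))
        ascent_start = descent_end + 1
    return DivePhases(descent_end=descent_end, ascent_start=ascent_start)


def _refine_side(depth: np.ndarray, cands: np.ndarray, current: int, limit: int,
                 ratio: float) -> tuple[int, Optional[tuple[int, float]]]:
    """Iterate the shoulder rule on one side until a fixed point.

    The normalized-depth ratio p1/p2 reduces to depth[current]/depth[second]
    because the dive's maximum depth cancels.
    """
    shoulder = None
    while True:
        later = cands[(cands > current) & (cands < limit)]
        deeper = later[depth[later] > depth[current]]
        if len(deeper) == 0:
            break
        second = int(deeper[0])
        if depth[current] / depth[second] < ratio:
            if shoulder is None:
                shoulder = (current, float(depth[current]))
            current = second
        else:
            break
    return current, shoulder


def refine_shoulders(dive_depth: np.ndarray, phases: DivePhases,
                     cfg: DetectionConfig = DetectionConfig()) -> DivePhases:
    """Relabel descent/ascent shoulders and move the phase boundaries.

    If the next deeper phase-boundary candidate after the current descent
    end is such that the ratio of their depths (each normalized by the
    dive's maximum depth) is below ``shoulder_ratio``, the current boundary
    is a shoulder and the deeper candidate becomes the descent end; the
    mirrored rule applies to the ascent side.  Idempotent at the fixed
    point; never moves the descent end earlier nor the ascent start later.
    """
    depth = np.asarray(dive_depth, dtype=float)
    n = len(depth)
    fwd = _bottom_start_candidates(depth, cfg)
    de, d_sh = _refine_side(depth, fwd, phases.descent_end, phases.ascent_start,
                            cfg.shoulder_ratio)

    rev_depth = depth[::-1]
    rev = _bottom_start_candidates(rev_depth, cfg)
    cur_rev = n - phases.ascent_start
    limit_rev = n - de
    as_rev, a_sh_rev = _refine_side(rev_depth, rev, cur_rev, limit_rev,
                                    cfg.shoulder_ratio)
    ascent_start = n - as_rev
    a_sh = None
    if a_sh_rev is not None:
        a_sh = (n - 1 - a_sh_rev[0], a_sh_rev[1])
    return DivePhases(descent_end=de, ascent_start=ascent_start,
                      descent_shoulder=d_sh, ascent_shoulder=a_sh)


def extract_dive_table(series: DepthSeries,
                       cfg: DetectionConfig = DetectionConfig()) -> pd.DataFrame:
    """Detect dives, segment and shoulder-correct each, return one table.

    One row per dive with indices, times, max depth, duration, phase
    boundaries (absolute sample indices relative to the dive start) and
    shoulder flags.
    """
    rows = []
    for rec in detect_dives(series, cfg):
        seg = series.depth[rec.start_index:rec.end_index]
        phases = refine_shoulders(seg, segment_phases(seg, cfg), cfg)
        rows.append(
            {
                "tag_id": rec.tag_id,
                "start_index": rec.start_index,
                "end_index": rec.end_index,
                "start_time": rec.start_time,
                "end_time": rec.end_time,
                "max_depth_m": rec.max_depth,
                "duration_min": rec.duration_min,
                "descent_end": phases.descent_end,
                "ascent_start": phases.ascent_start,
                "descent_shoulder_idx": (phases.descent_shoulder[0]
                                         if phases.descent_shoulder else np.nan),
                "descent_shoulder_depth": (phases.descent_shoulder[1]
                                           if phases.descent_shoulder else np.nan),
                "ascent_shoulder_idx": (phases.ascent_shoulder[0]
                                        if phases.ascent_shoulder else np.nan),
                "ascent_shoulder_depth": (phases.ascent_shoulder[1]
                                          if phases.ascent_shoulder else np.nan),
            }
        )
    cols = ["tag_id", "start_index", "end_index", "start_time", "end_time",
            "max_depth_m", "duration_min", "descent_end", "ascent_start",
            "descent_shoulder_idx", "descent_shoulder_depth",
            "ascent_shoulder_idx", "ascent_shoulder_depth"]
    return pd.DataFrame(rows, columns=cols)
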
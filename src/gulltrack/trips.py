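"""Foraging-trip segmentation and quality control for central-place foragers.

A foraging trip starts when a bird moves more than ``nest_radius`` (default
100 m) from its nest and ends when it returns within that radius.  Each fix
carries a *centered duration* — the mean of its backward and forward
inter-fix intervals — so that per-fix time weights sum exactly to the trip's
elapsed time.  Trips are dropped when an away-from-colony gap exceeds 20 min
or when fewer than 80% of fixes carry an acceleration burst.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class SegmentationConfig:
    nest_radius: float = 100.0          # m; excursion requires dist > radius
    max_gap: float = 1200.0             # s; away-from-colony gap tolerance
    min_acc_coverage: float = 0.8       # fraction of fixes with a burst
    standard_interval_colony: float = 600.0   # s
    standard_interval_away: float = 300.0     # s

    def __post_init__(self) -> None:
        if min(self.nest_radius, self.max_gap,
               self.standard_interval_colony, self.standard_interval_away) <= 0:
            raise ValueError("all intervals/radii must be positive")
        if not 0 < self.min_acc_coverage <= 1:
            raise ValueError("min_acc_coverage must be in (0, 1]")


@dataclass
class Trip:
    """One foraging trip: an ordered fix table plus QC bookkeeping."""

    bird_id: str
    fixes: pd.DataFrame                  # columns t, x, y, dist_to_nest, has_acc, centered_duration
    start_t: float
    end_t: float
    kept: bool = True
    qc_flags: dict = field(default_factory=dict)
    trip_id: str | None = None

    @property
    def duration_h(self) -> float:
        return float(self.fixes["centered_duration"].sum()) / 3600.0

    @property
    def acc_coverage(self) -> float:
        return float(self.fixes["has_acc"].mean())


def resample_track(fixes: pd.DataFrame, target_interval: float) -> pd.DataFrame:
    """Thin a fix table to at least ``target_interval`` seconds between fixes.

    Keeps the first fix, then each subsequent fix whose time since the last
    kept fix is >= target_interval (minus a 1 s tolerance for timestamp
    jitter).  No interpolation.
    """
    if len(fixes) == 0:
        return fixes.copy()
    t = fixes["t"].to_numpy(dtype=float)
    keep = np.zeros(len(t), dtype=bool)
    keep[0] = True
    last = t[0]
    tol = 1.0
    for i in range(1, len(t)):
        if t[i] - last >= target_interval - tol:
            keep[i] = True
            last = t[i]
    return fixes.loc[keep].reset_index(drop=True)


def compute_centered_durations(t: np.ndarray | pd.Series) -> np.ndarray:
    """Per-fix time weight: mean of backward and forward inter-fix intervals.

    Boundary fixes get half their single adjacent interval, so the weights
    telescope to exactly ``t[-1] - t[0]``.
    """
    t = np.asarray(t, dtype=float)
    if t.ndim != 1 or len(t) < 2:
        raise ValueError("need at least two time-sorted fixes")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValueError("timestamps must be strictly increasing")
    out = np.empty(len(t))
    out[0] = dt[0] / 2.0
    out[-1] = dt[-1] / 2.0
    if len(t) > 2:
        out[1:-1] = (dt[:-1] + dt[1:]) / 2.0
    return out


def _dist_to_nest(fixes: pd.DataFrame, nest_xy: tuple[float, float]) -> np.ndarray:
    return np.hypot(fixes["x"].to_numpy(float) - nest_xy[0],
                    fixes["y"].to_numpy(float) - nest_xy[1])


def segment_trips(
    fixes: pd.DataFrame,
    nest_xy: tuple[float, float],
    config: SegmentationConfig = SegmentationConfig(),
) -> list[Trip]:
    """Split one bird's time-sorted fixes into foraging trips.

    A trip runs from the last fix within ``nest_radius`` before an excursion
    (strictly beyond the radius) to the first fix back within it.  An
    excursion still open at the end of the data is emitted with
    ``kept=False`` and flag ``truncated`` rather than silently discarded.
    """
    if nest_xy is None:
        raise ValueError("nest coordinates required")
    if len(fixes) == 0:
        return []
    fixes = fixes.sort_values("t").reset_index(drop=True)
    if "bird_id" in fixes.columns and fixes["bird_id"].nunique() > 1:
        raise ValueError("segment_trips expects fixes from a single bird")
    bird_id = str(fixes["bird_id"].iloc[0]) if "bird_id" in fixes.columns else "bird"
    dist = _dist_to_nest(fixes, nest_xy)
    away = dist > config.nest_radius

    trips: list[Trip] = []
    i = 0
    n = len(fixes)
    counter = 0
    while i < n:
        if not away[i]:
            i += 1
            continue
        # fix i is the first away fix of an excursion
        start_idx = i - 1 if i > 0 and not away[i - 1] else i
        j = i
        while j < n and away[j]:
            j += 1
        truncated = j >= n
        end_idx = j if not truncated else n - 1
        sub = fixes.iloc[start_idx:end_idx + 1].copy().reset_index(drop=True)
        sub["dist_to_nest"] = dist[start_idx:end_idx + 1]
        if "has_acc" not in sub.columns:
            sub["has_acc"] = True
        if len(sub) >= 2:
            sub["centered_duration"] = compute_centered_durations(sub["t"])
            counter += 1
            trip = Trip(
                bird_id=bird_id,
                fixes=sub,
                start_t=float(sub["t"].iloc[0]),
                end_t=float(sub["t"].iloc[-1]),
                kept=not truncated,
                qc_flags={"truncated": truncated},
                trip_id=f"{bird_id}_trip{counter:03d}",
            )
            trips.append(trip)
        i = end_idx + 1
    return trips


def filter_trips(
    trips: list[Trip],
    config: SegmentationConfig = SegmentationConfig(),
) -> tuple[list[Trip], list[tuple[Trip, str]]]:
    """Apply the gap and acceleration-coverage filters.

    A trip is dropped iff an away-from-colony inter-fix gap is strictly
    greater than ``max_gap``, or the fraction of fixes carrying acceleration
    is strictly below ``min_acc_coverage``.  Boundaries (gap exactly 20 min,
    coverage exactly 80%) keep the trip.
    """
    kept: list[Trip] = []
    dropped: list[tuple[Trip, str]] = []
    for trip in trips:
        reasons = []
        if trip.qc_flags.get("truncated"):
            reasons.append("truncated")
        # gaps between consecutive fixes while outside the colony: both
        # endpoints of the interval away from the nest
        t = trip.fixes["t"].to_numpy(float)
        away = trip.fixes["dist_to_nest"].to_numpy(float) > config.nest_radius
        gaps = np.diff(t)
        away_gap = gaps[(away[:-1] | away[1:])]
        if len(away_gap) and away_gap.max() > config.max_gap:
            reasons.append("gap_exceeded")
            trip.qc_flags["gap_exceeded"] = True
        if trip.acc_coverage < config.min_acc_coverage:
            reasons.append("low_acc_coverage")
            trip.qc_flags["low_acc_coverage"] = True
        if reasons:
            trip.kept = False
            dropped.append((trip, ",".join(reasons)))
        else:
            trip.kept = True
            kept.append(trip)
    return kept, dropped


def trips_table(trips: list[Trip], reasons: dict[str, str] | None = None) -> pd.DataFrame:
    """Summarise trips as one row each (for CSV export)."""
    rows = []
    for tr in trips:
        rows.append({
            "trip_id": tr.trip_id,
            "bird_id": tr.bird_id,
            "start_t": tr.start_t,
            "end_t": tr.end_t,
            "duration_h": tr.duration_h,
            "n_fixes": len(tr.fixes),
            "acc_coverage": tr.acc_coverage,
            "kept": tr.kept,
            "reason": (reasons or {}).get(tr.trip_id, ""),
        })
    return pd.DataFrame(rows)
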
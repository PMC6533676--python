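"""Plain-text interchange: fixes/bursts/truth CSV and habitat GeoJSON."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

#: epoch used to render simulated seconds as ISO-8601 UTC timestamps
EPOCH = pd.Timestamp("2020-05-01T00:00:00Z")

AXES = ("surge", "sway", "heave")


def write_fixes_csv(fixes: pd.DataFrame, path: str | Path) -> None:
    out = fixes.copy()
    out["timestamp"] = (EPOCH + pd.to_timedelta(out["t"], unit="s")).dt.strftime(
        "%Y-%m-%dT%H:%M:%SZ")
    cols = ["bird_id", "fix_id", "timestamp", "t", "x", "y", "has_acc"]
    out[cols].to_csv(path, index=False)


def read_fixes_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "t" not in df.columns and "timestamp" in df.columns:
        ts = pd.to_datetime(df["timestamp"], utc=True)
        df["t"] = (ts - EPOCH).dt.total_seconds()
    return df


def write_bursts_csv(bursts: dict[str, np.ndarray], path: str | Path) -> None:
    """Long format: one row per (burst, axis, sample)."""
    rows = []
    for fid, arr in bursts.items():
        for ax_i, ax in enumerate(AXES):
            for s, v in enumerate(arr[ax_i]):
                rows.append((fid, ax, s, v))
    pd.DataFrame(rows, columns=["burst_id", "axis", "sample", "value"]).to_csv(
        path, index=False)


def read_bursts_csv(path: str | Path) -> dict[str, np.ndarray]:
    df = pd.read_csv(path)
    out = {}
    for fid, grp in df.groupby("burst_id", sort=False):
        n = int(grp["sample"].max()) + 1
        arr = np.zeros((3, n))
        for ax_i, ax in enumerate(AXES):
            sub = grp[grp["axis"] == ax].sort_values("sample")
            arr[ax_i, sub["sample"].to_numpy()] = sub["value"].to_numpy()
        out[fid] = arr
    return out
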
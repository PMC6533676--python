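"""Acceleration-burst behavior classification and class aggregation.

Tri-axial bursts (surge, sway, heave; 20 Hz for 1 s after a GPS fix) are
summarised into simple waveform features and classified into one of 11 fine
behaviors by a supervised classifier (random forest by default).  Fine
behaviors aggregate onto the four energetic classes:

    sit, stand, float                      -> inactive
    terrestrial-locomotion,
    look-for-food-moving,
    look-for-food-standing,
    handle-prey, other                     -> terrestrial_movement
    soar, manoeuvre                        -> soaring_flight
    flap, extreme-flap                     -> flapping_flight
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import periodogram
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split

from .energetics import AGGREGATE_CLASSES, UNANNOTATED

DEFAULT_AGGREGATE_MAP: dict[str, str] = {
    "sit": "inactive",
    "stand": "inactive",
    "float": "inactive",
    "terrestrial-locomotion": "terrestrial_movement",
    "look-for-food-moving": "terrestrial_movement",
    "look-for-food-standing": "terrestrial_movement",
    "handle-prey": "terrestrial_movement",
    "other": "terrestrial_movement",
    "soar": "soaring_flight",
    "manoeuvre": "soaring_flight",
    "flap": "flapping_flight",
    "extreme-flap": "flapping_flight",
}

FINE_LABELS = tuple(DEFAULT_AGGREGATE_MAP)


@dataclass(frozen=True)
class BehaviorScheme:
    """The fine-label set and its (total) aggregation onto the 4 classes."""

    aggregate_map: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_AGGREGATE_MAP)
    )

    def __post_init__(self) -> None:
        bad = set(self.aggregate_map.values()) - set(AGGREGATE_CLASSES)
        if bad:
            raise ValueError(f"unknown aggregate classes: {bad}")

    @property
    def fine_labels(self) -> tuple[str, ...]:
        return tuple(self.aggregate_map)

    def aggregate(self, fine_label: str) -> str:
        if fine_label not in self.aggregate_map:
            raise KeyError(f"fine label {fine_label!r} not in scheme")
        return self.aggregate_map[fine_label]


FEATURE_NAMES = (
    "surge_mean", "surge_sd", "surge_min", "surge_max",
    "sway_mean", "sway_sd", "sway_min", "sway_max",
    "heave_mean", "heave_sd", "heave_min", "heave_max",
    "odba", "dom_freq", "dom_power_frac",
)


def extract_features(burst: np.ndarray, sample_rate: float = 20.0) -> np.ndarray:
    """Feature vector for one 3 x n burst (axes surge, sway, heave, in g).

    ODBA (overall dynamic body acceleration) is the summed per-axis mean
    absolute deviation from the axis mean.  The dominant heave frequency
    comes from a periodogram; a constant heave signal reports 0 Hz.
    """
    burst = np.asarray(burst, dtype=float)
    if burst.ndim != 2 or burst.shape[0] != 3 or burst.shape[1] < 2:
        raise ValueError("burst must be 3 axes x >=2 samples")
    feats: list[float] = []
    for ax in range(3):
        x = burst[ax]
        feats += [x.mean(), x.std(), x.min(), x.max()]
    odba = sum(np.abs(burst[ax] - burst[ax].mean()).mean() for ax in range(3))
    heave = burst[2]
    freqs, power = periodogram(heave - heave.mean(), fs=sample_rate)
    if power.sum() <= 0:
        dom_freq, dom_frac = 0.0, 0.0
    else:
        k = int(np.argmax(power))
        dom_freq = float(freqs[k])
        dom_frac = float(power[k] / power.sum())
    feats += [odba, dom_freq, dom_frac]
    return np.asarray(feats)


def features_table(bursts: dict | pd.DataFrame, sample_rate: float = 20.0) -> pd.DataFrame:
    """Extract features for many bursts.

    Accepts either a mapping key -> 3 x n array, or a long-format DataFrame
    with columns (burst_id, axis, sample, value) as written by the
    simulator's burst CSV.
    """
    if isinstance(bursts, pd.DataFrame):
        bursts = bursts_from_long(bursts)
    rows = {k: extract_features(b, sample_rate) for k, b in bursts.items()}
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(FEATURE_NAMES))


def bursts_from_long(df: pd.DataFrame) -> dict:
    """Rebuild 3 x n burst arrays from a long table (burst_id, axis, sample, value)."""
    axis_order = {"surge": 0, "sway": 1, "heave": 2}
    out = {}
    for bid, grp in df.groupby("burst_id", sort=False):
        n = grp["sample"].max() + 1
        arr = np.zeros((3, n))
        for ax_name, ax_i in axis_order.items():
            sub = grp[grp["axis"] == ax_name].sort_values("sample")
            arr[ax_i, sub["sample"].to_numpy()] = sub["value"].to_numpy()
        out[bid] = arr
    return out


@dataclass
class TrainedClassifier:
    """A fitted fine-behavior classifier with its hold-out report."""

    model: RandomForestClassifier
    classes: tuple[str, ...]
    holdout_accuracy: float

    def predict(self, features: pd.DataFrame | np.ndarray) -> np.ndarray:
        return self.model.predict(np.asarray(features, dtype=float))

    def predict_proba(self, features: pd.DataFrame | np.ndarray) -> np.ndarray:
        return self.model.predict_proba(np.asarray(features, dtype=float))


def train_classifier(
    features: pd.DataFrame | np.ndarray,
    labels: np.ndarray | pd.Series,
    seed: int = 0,
    holdout_fraction: float = 0.25,
    n_estimators: int = 200,
) -> TrainedClassifier:
    """Train the fine-behavior classifier and report hold-out accuracy.

    Deterministic under a fixed seed.  Requires at least two classes with
    at least five examples each.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=object)
    uniq, counts = np.unique(y, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("need at least two behavior classes to train")
    if counts.min() < 5:
        raise ValueError("need at least five examples per class")
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=holdout_fraction, random_state=seed, stratify=y
    )
    rf = RandomForestClassifier(n_estimators=n_estimators, random_state=seed)
    rf.fit(X_tr, y_tr)
    acc = float((rf.predict(X_te) == y_te).mean())
    return TrainedClassifier(model=rf, classes=tuple(rf.classes_), holdout_accuracy=acc)


def classify_and_aggregate(
    features: pd.DataFrame | None,
    classifier: TrainedClassifier | None,
    scheme: BehaviorScheme = BehaviorScheme(),
    fine_labels: np.ndarray | pd.Series | None = None,
) -> pd.DataFrame:
    """Map bursts to fine labels and aggregate classes.

    Either classify `features` with a trained model, or pass pre-labeled
    `fine_labels` directly (index-aligned) to bypass the classifier.
    Returns a DataFrame with columns fine, aggregate (indexed like the
    input).  Fixes without a burst are handled upstream as 'unannotated'.
    """
    if fine_labels is not None:
        idx = getattr(fine_labels, "index", pd.RangeIndex(len(fine_labels)))
        fine = np.asarray(fine_labels, dtype=object)
    else:
        if features is None or classifier is None:
            raise ValueError("need features+classifier or pre-labeled behaviors")
        idx = getattr(features, "index", pd.RangeIndex(len(features)))
        fine = classifier.predict(features)
    agg = np.array([scheme.aggregate(f) for f in fine], dtype=object)
    return pd.DataFrame({"fine": fine, "aggregate": agg}, index=idx)


def attach_behaviors(
    trip_fixes: pd.DataFrame,
    per_burst: pd.DataFrame,
    key: str = "fix_id",
) -> pd.Series:
    """Aggregate class per fix; fixes without a burst get 'unannotated'."""
    merged = trip_fixes[[key]].merge(
        per_burst["aggregate"].rename("aggregate"),
        how="left", left_on=key, right_index=True,
    )
    return merged["aggregate"].fillna(UNANNOTATED)
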
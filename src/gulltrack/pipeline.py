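"""End-to-end analysis: raw fixes and bursts to a per-trip energetics table.

Chains the pipeline stages — trip segmentation and QC, burst classification,
movement-mode clustering (commuting detection), habitat assignment and trip
categorisation, and per-trip energy expenditure — into one call returning
the trip table the inferential stage consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import behavior as beh
from . import energetics as en
from .habitat import HabitatRules, assign_habitats, summarize_trip_habitat
from .modes import EmbcModel, derive_kinematics
from .trips import SegmentationConfig, Trip, filter_trips, segment_trips


@dataclass
class PipelineConfig:
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    scheme: beh.BehaviorScheme = field(default_factory=beh.BehaviorScheme)
    smooth_window: int = 3
    unannotated_policy: str = "redistribute"
    seed: int = 0


def annotate_trip(
    trip: Trip,
    per_fix_behavior: pd.DataFrame,
    config: PipelineConfig,
) -> pd.DataFrame:
    """Attach behavior, kinematics and commuting flags to one trip's fixes."""
    fx = trip.fixes.copy()
    merged = fx.merge(per_fix_behavior, on="fix_id", how="left")
    merged["aggregate"] = merged["aggregate"].fillna(en.UNANNOTATED)
    merged.loc[~merged["has_acc"], "aggregate"] = en.UNANNOTATED
    if len(merged) >= 8:
        kin = derive_kinematics(merged)
        res = EmbcModel().fit(kin, seed=config.seed).smooth(config.smooth_window)
        merged["speed"] = kin["speed"]
        merged["turn"] = kin["turn"]
        merged["mode"] = res.modes
    else:
        merged["speed"] = np.nan
        merged["turn"] = np.nan
        merged["mode"] = "LL"
    merged["commuting"] = merged["mode"] == "HL"
    return merged


def run_pipeline(
    fixes: pd.DataFrame,
    bursts: dict[str, np.ndarray],
    rules: HabitatRules,
    nest_xy: tuple[float, float],
    masses: pd.DataFrame | float,
    classifier: beh.TrainedClassifier | None = None,
    true_fine_labels: pd.Series | None = None,
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Run the full analysis and return one row per kept trip.

    Behaviors come from `classifier` applied to burst features, or from
    `true_fine_labels` (a Series indexed by fix_id) to bypass the
    classifier.  `masses` is a per-bird table (bird_id, mass_g) or a single
    mass in grams.  Returns columns bird_id, trip_id, category, duration_h,
    flapping_h, total_kJ, rate_kJ_h plus habitat fractions.
    """
    config = config or PipelineConfig()

    if true_fine_labels is not None:
        per_fix = beh.classify_and_aggregate(
            None, None, config.scheme, fine_labels=true_fine_labels)
    else:
        if classifier is None:
            raise ValueError("need a classifier or true labels")
        feats = beh.features_table(bursts)
        per_fix = beh.classify_and_aggregate(feats, classifier, config.scheme)
    per_fix = per_fix.rename_axis("fix_id").reset_index()

    if isinstance(masses, pd.DataFrame):
        mass_of = dict(zip(masses["bird_id"], masses["mass_g"]))
    else:
        mass_of = None

    rows = []
    for bird_id, bird_fixes in fixes.groupby("bird_id", sort=False):
        mass = mass_of[bird_id] if mass_of else float(masses)
        profile = en.EnergeticProfile(mass_g=mass)
        trips = segment_trips(bird_fixes, nest_xy, config.segmentation)
        kept, _dropped = filter_trips(trips, config.segmentation)
        for trip in kept:
            ann = annotate_trip(trip, per_fix, config)
            ann["habitat"] = assign_habitats(ann, rules)
            # fixes inside the nest radius belong to the colony, not a habitat
            ann.loc[ann["dist_to_nest"] <= config.segmentation.nest_radius,
                    "habitat"] = "unassigned"
            summary = summarize_trip_habitat(ann["habitat"], ann["commuting"], rules)
            te = en.trip_energy(
                ann["aggregate"], ann["centered_duration"], profile,
                unannotated_policy=config.unannotated_policy)
            row = {
                "bird_id": bird_id,
                "trip_id": trip.trip_id,
                "start_t": trip.start_t,
                "end_t": trip.end_t,
                "category": summary.category,
                "n_noncommuting": summary.n_noncommuting,
                "n_unassigned": summary.n_unassigned,
                "duration_h": te.duration_h,
                "flapping_h": te.flapping_h,
                "total_kJ": te.total_kJ,
                "rate_kJ_h": te.rate_kJ_h,
            }
            for hab, frac in summary.fractions.items():
                row[f"frac_{hab}"] = frac
            rows.append(row)
    return pd.DataFrame(rows)
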
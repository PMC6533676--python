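"""Habitat annotation of non-commuting GPS fixes and trip categorisation.

Fixes are matched against polygon layers (urban areas, North Sea, Wadden
Sea, breakwaters, beach, intertidal mudflats, agricultural & natural land)
with a fixed precedence.  Mudflats are conditional on behavior: a flying or
floating bird over a mudflat is using the water column (marine), a resting
or walking bird is foraging on the exposed flat (intertidal).  Sea fixes
within 50 m of a breakwater, beach or mudflat also count as intertidal,
since those edges are available at low tide.

A trip is categorised by the habitat holding >= 50% of its assigned
non-commuting fixes, else 'mixed'.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry

#: polygon layer names understood by the rules
LAYERS = (
    "north_sea", "wadden_sea", "urban", "breakwater", "beach", "mudflat",
    "agri_natural",
)

HABITATS = ("urban", "marine", "intertidal", "terrestrial")

#: fine behaviors / aggregate classes that count as "flying or floating"
#: for the mudflat rule
FLIGHT_CLASSES = ("flapping_flight", "soaring_flight")


@dataclass
class HabitatRules:
    """Polygon layers plus the buffer and threshold parameters."""

    layers: dict[str, BaseGeometry]
    intertidal_buffer: float = 50.0     # m around breakwater/beach/mudflat
    category_threshold: float = 0.5     # fraction of fixes for a category
    tie_precedence: tuple[str, ...] = ("urban", "marine", "intertidal", "terrestrial")

    def __post_init__(self) -> None:
        if self.intertidal_buffer < 0:
            raise ValueError("buffer must be >= 0")
        if not 0 < self.category_threshold <= 1:
            raise ValueError("threshold must be in (0, 1]")
        for name, geom in self.layers.items():
            if not geom.is_valid:
                raise ValueError(f"invalid geometry in layer {name!r}")

    def _geom(self, name: str) -> BaseGeometry:
        return self.layers.get(name, shapely.GeometryCollection())

    @classmethod
    def from_geojson(cls, path: str | Path, **kwargs) -> "HabitatRules":
        """Load layers from a GeoJSON FeatureCollection.

        Features are grouped by their ``habitat_layer`` property and
        unioned per layer.
        """
        with open(path) as fh:
            fc = json.load(fh)
        grouped: dict[str, list[BaseGeometry]] = {}
        for feat in fc["features"]:
            layer = feat["properties"].get("habitat_layer")
            if layer is None:
                continue
            grouped.setdefault(layer, []).append(shape(feat["geometry"]))
        layers = {k: shapely.union_all(v) for k, v in grouped.items()
                  if k in LAYERS}
        return cls(layers=layers, **kwargs)

    def to_geojson(self, path: str | Path, extra_features: list | None = None) -> None:
        feats = []
        for name, geom in self.layers.items():
            feats.append({
                "type": "Feature",
                "properties": {"habitat_layer": name},
                "geometry": mapping(geom),
            })
        feats.extend(extra_features or [])
        with open(path, "w") as fh:
            json.dump({"type": "FeatureCollection", "features": feats}, fh)


def assign_habitat(
    x: float,
    y: float,
    aggregate_behavior: str,
    rules: HabitatRules,
    fine_behavior: str | None = None,
) -> str:
    """Habitat of one non-commuting fix, or 'unassigned'.

    Rule order (first match wins):

    1. urban polygon                                     -> urban
    2. breakwater or beach polygon                       -> intertidal
    3. sea polygon within `intertidal_buffer` of
       breakwater/beach/mudflat                          -> intertidal
    4. mudflat polygon: flying (flapping/soaring) or
       fine behavior 'float'                             -> marine,
       otherwise (resting / terrestrial movement)        -> intertidal
    5. sea polygon (North Sea or Wadden Sea)             -> marine
    6. agricultural / natural land                       -> terrestrial
    7. no polygon                                        -> unassigned

    Boundary points count as inside (`covers` semantics).
    """
    pt = shapely.Point(x, y)
    if rules._geom("urban").covers(pt):
        return "urban"
    on_hard_intertidal = (rules._geom("breakwater").covers(pt)
                          or rules._geom("beach").covers(pt))
    if on_hard_intertidal:
        return "intertidal"
    in_sea = (rules._geom("north_sea").covers(pt)
              or rules._geom("wadden_sea").covers(pt))
    if in_sea:
        near = any(
            shapely.dwithin(rules._geom(layer), pt, rules.intertidal_buffer)
            for layer in ("breakwater", "beach", "mudflat")
            if not rules._geom(layer).is_empty
        )
        if near:
            return "intertidal"
    if rules._geom("mudflat").covers(pt):
        floating = (fine_behavior == "float") if fine_behavior is not None else False
        if aggregate_behavior in FLIGHT_CLASSES or floating:
            return "marine"
        return "intertidal"
    if in_sea:
        return "marine"
    if rules._geom("agri_natural").covers(pt):
        return "terrestrial"
    return "unassigned"


def assign_habitats(
    fixes: pd.DataFrame,
    rules: HabitatRules,
    behavior_col: str = "aggregate",
    fine_col: str | None = "fine",
) -> pd.Series:
    """Vectorised habitat assignment over a fix table (rule order as above)."""
    pts = shapely.points(fixes["x"].to_numpy(float), fixes["y"].to_numpy(float))
    n = len(fixes)

    def covers(layer: str) -> np.ndarray:
        g = rules._geom(layer)
        if g.is_empty:
            return np.zeros(n, dtype=bool)
        return shapely.covers(g, pts)

    urban = covers("urban")
    hard = covers("breakwater") | covers("beach")
    sea = covers("north_sea") | covers("wadden_sea")
    mud = covers("mudflat")
    terr = covers("agri_natural")
    near = np.zeros(n, dtype=bool)
    for layer in ("breakwater", "beach", "mudflat"):
        g = rules._geom(layer)
        if not g.is_empty:
            near |= shapely.dwithin(g, pts, rules.intertidal_buffer)

    beh = fixes[behavior_col].astype(object).to_numpy()
    flying = np.isin(beh, FLIGHT_CLASSES)
    if fine_col and fine_col in fixes.columns:
        flying |= fixes[fine_col].astype(object).to_numpy() == "float"

    out = np.full(n, "unassigned", dtype=object)
    out[terr] = "terrestrial"
    out[sea] = "marine"
    out[mud & ~flying] = "intertidal"
    out[mud & flying] = "marine"
    out[sea & near & ~hard & ~urban] = "intertidal"
    out[hard] = "intertidal"
    out[urban] = "urban"
    return pd.Series(out, index=fixes.index, name="habitat")


@dataclass
class TripHabitatSummary:
    """Habitat-use fractions and the resulting trip category."""

    fractions: dict[str, float] = field(default_factory=dict)
    category: str = "undefined"
    n_noncommuting: int = 0
    n_unassigned: int = 0
    tie: bool = False


def summarize_trip_habitat(
    habitats: pd.Series | np.ndarray,
    commuting: pd.Series | np.ndarray,
    rules: HabitatRules,
) -> TripHabitatSummary:
    """Categorise a trip from its per-fix habitats.

    Fractions are taken over assigned non-commuting fixes; the category is
    the habitat with the largest fraction if it reaches the threshold
    (inclusive), otherwise 'mixed'.  Exact ties at the threshold break by
    the precedence urban > marine > intertidal > terrestrial and are
    flagged.  A trip with no non-commuting assigned fixes is 'undefined'.
    """
    hab = np.asarray(habitats, dtype=object)
    com = np.asarray(commuting, dtype=bool)
    non_com = hab[~com]
    assigned = non_com[non_com != "unassigned"]
    n_un = int((non_com == "unassigned").sum())
    if len(assigned) == 0:
        return TripHabitatSummary(
            category="undefined", n_noncommuting=len(non_com), n_unassigned=n_un
        )
    fracs = {h: float((assigned == h).mean()) for h in HABITATS}
    best = max(rules.tie_precedence, key=lambda h: fracs[h])
    tie = sum(1 for h in HABITATS if fracs[h] == fracs[best]) > 1
    category = best if fracs[best] >= rules.category_threshold else "mixed"
    return TripHabitatSummary(
        fractions=fracs,
        category=category,
        n_noncommuting=len(non_com),
        n_unassigned=n_un,
        tie=tie and category != "mixed",
    )
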
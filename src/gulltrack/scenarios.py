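"""Daily energy budgets and prey-equivalent scenarios.

Worked-example calculator: a gull spending ``hours_colony`` at a colony
rate and ``hours_away`` at an away rate has a daily cost of the weighted
sum; dividing by the assimilation efficiency (default 0.75) gives the gross
intake needed, and dividing by the energy content of one prey item (default
84 kJ, a discarded flatfish of 12-13 cm) gives the number of prey to catch.
"""

from __future__ import annotations

from dataclasses import dataclass

from .energetics import AGGREGATE_CLASSES, EnergeticProfile


@dataclass(frozen=True)
class ScenarioSpec:
    hours_colony: float = 14.0
    rate_colony: float = 33.0       # kJ/h, ~RMR at the colony
    hours_away: float = 10.0
    rate_away: float = 100.0        # kJ/h while foraging
    assimilation: float = 0.75
    prey_energy: float = 84.0       # kJ per item

    def __post_init__(self) -> None:
        if self.hours_colony < 0 or self.hours_away < 0:
            raise ValueError("hours must be non-negative")
        if self.hours_colony + self.hours_away > 24 + 1e-9:
            raise ValueError("hours exceed one day")
        if not 0 < self.assimilation <= 1:
            raise ValueError("assimilation must be in (0, 1]")
        if self.prey_energy <= 0:
            raise ValueError("prey energy must be positive")


def daily_cost(spec: ScenarioSpec) -> float:
    """Daily energy expenditure in kJ."""
    return spec.hours_colony * spec.rate_colony + spec.hours_away * spec.rate_away


def prey_equivalents(daily_kJ: float, spec: ScenarioSpec = ScenarioSpec()) -> tuple[int, int]:
    """Gross intake (kJ, nearest integer) and prey items (nearest integer)
    needed to cover a daily cost at the given assimilation efficiency."""
    if daily_kJ < 0:
        raise ValueError("daily cost must be non-negative")
    gross_exact = daily_kJ / spec.assimilation
    return round(gross_exact), round(gross_exact / spec.prey_energy)


def extra_prey(
    cost_high_kJ: float,
    cost_low_kJ: float,
    spec: ScenarioSpec = ScenarioSpec(),
) -> tuple[float, int]:
    """Extra gross intake (kJ) and extra prey items per day needed to
    sustain the more expensive of two daily budgets."""
    if cost_high_kJ < cost_low_kJ:
        raise ValueError("cost_high must be >= cost_low")
    extra_gross = (cost_high_kJ - cost_low_kJ) / spec.assimilation
    return extra_gross, round(extra_gross / spec.prey_energy)


@dataclass(frozen=True)
class HypotheticalTrip:
    """An imaginary trip as a list of (aggregate behavior, duration h) legs."""

    legs: tuple[tuple[str, float], ...]
    mass_g: float = 1000.0

    def __post_init__(self) -> None:
        for beh, dur in self.legs:
            if beh not in AGGREGATE_CLASSES:
                raise ValueError(f"unknown behavior class {beh!r}")
            if dur <= 0:
                raise ValueError("leg durations must be positive")


def hypothetical_trip_cost(trip: HypotheticalTrip) -> float:
    """Energy cost (kJ) of an imaginary trip, e.g. a visit to a refuse dump
    at a chosen distance with a chosen flight/ground time composition."""
    rates = EnergeticProfile(trip.mass_g).rates()
    return sum(dur * rates[beh] for beh, dur in trip.legs)


def habitat_rate_contrast(rates: dict[str, float]) -> float:
    """Percent difference of mean hourly cost, high-caloric (urban, marine)
    over low-caloric (intertidal, terrestrial) habitats."""
    missing = {"urban", "marine", "intertidal", "terrestrial"} - set(rates)
    if missing:
        raise ValueError(f"missing categories: {missing}")
    high = (rates["urban"] + rates["marine"]) / 2.0
    low = (rates["intertidal"] + rates["terrestrial"]) / 2.0
    return 100.0 * (high / low - 1.0)


def budget_report(spec: ScenarioSpec = ScenarioSpec()) -> str:
    cost = daily_cost(spec)
    gross, n = prey_equivalents(cost, spec)
    return "\n".join([
        f"daily cost: {spec.hours_colony:g} h x {spec.rate_colony:g} kJ/h "
        f"+ {spec.hours_away:g} h x {spec.rate_away:g} kJ/h = {cost:.0f} kJ",
        f"gross intake at {spec.assimilation:.0%} assimilation: {gross} kJ",
        f"prey items at {spec.prey_energy:g} kJ each: {n}",
    ])
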
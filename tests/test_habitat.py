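"""Habitat assignment rules and trip categorisation."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

from gulltrack.habitat import (
    HABITATS,
    HabitatRules,
    assign_habitat,
    assign_habitats,
    summarize_trip_habitat,
)


@pytest.fixture(scope="module")
def toy_rules():
    """Small orthogonal landscape exercising every rule branch.

    Sea above y=100 (wadden 100-200, north sea 200-400), beach strip at
    95-100, a breakwater poking into the sea, a mudflat patch inside the
    wadden band, urban and farmland blocks on land.
    """
    layers = {
        "north_sea": box(0, 200, 400, 400),
        "wadden_sea": box(0, 100, 400, 200).difference(box(100, 100, 200, 150)),
        "beach": box(0, 95, 400, 100),
        "breakwater": box(300, 100, 310, 130),
        "mudflat": box(100, 100, 200, 150),
        "urban": box(0, 0, 50, 50),
        "agri_natural": box(50, 0, 400, 95),
    }
    return HabitatRules(layers=layers)


class TestRuleOrder:
    def test_urban_point(self, toy_rules):
        assert assign_habitat(25, 25, "terrestrial_movement", toy_rules) == "urban"

    def test_breakwater_and_beach_are_intertidal(self, toy_rules):
        assert assign_habitat(305, 120, "inactive", toy_rules) == "intertidal"
        assert assign_habitat(200, 97, "flapping_flight", toy_rules) == "intertidal"

    def test_sea_point_near_breakwater_is_intertidal(self, toy_rules):
        # 30 m from the breakwater, inside the wadden sea
        assert assign_habitat(340, 120, "inactive", toy_rules) == "intertidal"

    def test_sea_point_far_from_edges_is_marine(self, toy_rules):
        assert assign_habitat(350, 350, "inactive", toy_rules) == "marine"

    def test_mudflat_flying_is_marine(self, toy_rules):
        assert assign_habitat(150, 125, "flapping_flight", toy_rules) == "marine"
        assert assign_habitat(150, 125, "soaring_flight", toy_rules) == "marine"

    def test_mudflat_floating_is_marine(self, toy_rules):
        assert assign_habitat(150, 125, "inactive", toy_rules,
                              fine_behavior="float") == "marine"

    def test_mudflat_foraging_is_intertidal(self, toy_rules):
        assert assign_habitat(150, 125, "terrestrial_movement", toy_rules) == "intertidal"
        assert assign_habitat(150, 125, "inactive", toy_rules,
                              fine_behavior="stand") == "intertidal"

    def test_farmland_is_terrestrial(self, toy_rules):
        assert assign_habitat(200, 50, "terrestrial_movement", toy_rules) == "terrestrial"

    def test_outside_everything_unassigned(self, toy_rules):
        assert assign_habitat(-50, -50, "inactive", toy_rules) == "unassigned"

    def test_vectorised_matches_scalar_on_grid(self, toy_rules):
        """Exhaustive grid x behavior sweep: the vectorised assignment and
        the single-point rule chain agree everywhere."""
        xs, ys = np.meshgrid(np.arange(-20, 420, 10.0), np.arange(-20, 420, 10.0))
        for agg in ("inactive", "terrestrial_movement", "soaring_flight",
                    "flapping_flight"):
            fx = pd.DataFrame({
                "x": xs.ravel(), "y": ys.ravel(), "aggregate": agg})
            vec = assign_habitats(fx, toy_rules)
            scal = [assign_habitat(x, y, agg, toy_rules)
                    for x, y in zip(fx["x"], fx["y"])]
            assert (vec.to_numpy() == np.array(scal, dtype=object)).all()

    def test_buffer_monotonicity(self, toy_rules):
        """Shrinking the intertidal buffer never increases intertidal use."""
        xs, ys = np.meshgrid(np.arange(0, 400, 7.0), np.arange(100, 400, 7.0))
        fx = pd.DataFrame({"x": xs.ravel(), "y": ys.ravel(),
                           "aggregate": "inactive"})
        n50 = (assign_habitats(fx, toy_rules) == "intertidal").sum()
        zero = HabitatRules(layers=toy_rules.layers, intertidal_buffer=0.0)
        n0 = (assign_habitats(fx, zero) == "intertidal").sum()
        assert n0 <= n50


class TestTripCategory:
    def _summary(self, habs, commuting=None):
        habs = np.asarray(habs, dtype=object)
        com = np.zeros(len(habs), bool) if commuting is None else np.asarray(commuting)
        return summarize_trip_habitat(habs, com, HabitatRules(layers={}))

    def test_majority_habitat_wins(self):
        s = self._summary(["intertidal"] * 6 + ["marine"] * 4)
        assert s.category == "intertidal"
        assert s.fractions["intertidal"] == pytest.approx(0.6)

    def test_no_majority_is_mixed(self):
        habs = (["urban"] * 4 + ["marine"] * 3 + ["intertidal"] * 2
                + ["terrestrial"])
        assert self._summary(habs).category == "mixed"

    def test_exact_tie_broken_by_precedence_and_recorded(self):
        s = self._summary(["marine"] * 5 + ["intertidal"] * 5)
        assert s.category == "marine"
        assert s.tie

    def test_threshold_inclusive_at_half(self):
        s = self._summary(["urban"] * 5 + ["marine"] * 3 + ["terrestrial"] * 2)
        assert s.category == "urban"

    def test_commuting_and_unassigned_excluded(self):
        habs = ["marine"] * 4 + ["unassigned"] * 3 + ["intertidal"] * 2
        com = [False] * 4 + [False] * 3 + [True] * 2
        s = self._summary(habs, com)
        assert s.category == "marine"
        assert s.n_unassigned == 3
        assert s.fractions["marine"] == pytest.approx(1.0)

    def test_no_noncommuting_fixes_undefined(self):
        s = self._summary(["marine"] * 3, [True] * 3)
        assert s.category == "undefined"

    def test_category_recovery_on_synthetic_days(self, gull_days, landscape,
                                                 sim_config, trained_classifier):
        from gulltrack.pipeline import run_pipeline

        table = run_pipeline(
            gull_days["fixes"], gull_days["bursts"], landscape,
            sim_config.nest_xy, gull_days["birds"],
            classifier=trained_classifier)
        m = table.merge(gull_days["truth"].trips, on=["bird_id", "start_t"],
                        suffixes=("", "_true"))
        assert len(m) == len(table)
        assert (m["category"] == m["intended_category"]).mean() >= 0.95
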
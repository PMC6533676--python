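"""The synthetic-data generator: determinism, landscape, trips, bursts."""

import numpy as np
import pandas as pd
import pytest
from scipy.signal import periodogram
from shapely.geometry import box

from gulltrack.behavior import FINE_LABELS
from gulltrack.synthetic import (
    ScheduleLeg,
    SimConfig,
    generate_landscape,
    simulate_acc_burst,
    simulate_bird_days,
    simulate_trip,
)
from gulltrack.trips import filter_trips, segment_trips


class TestLandscape:
    def test_deterministic_under_seed(self):
        a = generate_landscape(3)
        b = generate_landscape(3)
        for name in a.layers:
            assert a.layers[name].equals(b.layers[name])

    def test_layers_inside_extent(self):
        extent = (0, 0, 30000, 25000)
        rules = generate_landscape(1, extent)
        bounds = box(*extent)
        for geom in rules.layers.values():
            assert bounds.covers(geom)

    def test_mudflat_layer_present(self, landscape):
        assert not landscape.layers["mudflat"].is_empty
        assert landscape.layers["mudflat"].area > 0

    def test_degenerate_extent_rejected(self):
        with pytest.raises(ValueError):
            generate_landscape(0, (0, 0, 100, 100))


class TestBursts:
    def test_sit_burst_is_quiet(self):
        burst = simulate_acc_burst("sit", SimConfig(seed=0), seed=1)
        assert burst.shape == (3, 20)
        assert burst.std(axis=1).max() < 0.05
        assert burst[2].mean() == pytest.approx(1.0, abs=0.05)

    def test_flap_burst_dominant_frequency(self):
        cfg = SimConfig(seed=0)
        burst = simulate_acc_burst("flap", cfg, seed=2)
        freqs, power = periodogram(burst[2] - burst[2].mean(), fs=20.0)
        dom = freqs[np.argmax(power)]
        assert dom == pytest.approx(cfg.behavior_acc_params["flap"].freq, abs=0.5)

    def test_deterministic_under_seed(self):
        cfg = SimConfig(seed=0)
        assert np.array_equal(simulate_acc_burst("soar", cfg, 9),
                              simulate_acc_burst("soar", cfg, 9))

    def test_unknown_behavior_rejected(self):
        with pytest.raises(KeyError):
            simulate_acc_burst("swim", SimConfig(seed=0), 0)

    def test_params_cover_all_eleven_behaviors(self):
        cfg = SimConfig(seed=0)
        for lab in FINE_LABELS:
            assert lab in cfg.behavior_acc_params


def commute_schedule(habitat="intertidal", forage_s=3600.0, commute_s=3600.0):
    return [
        ScheduleLeg("stand", 600, None),
        ScheduleLeg("flap", commute_s, habitat, commute=True),
        ScheduleLeg("terrestrial-locomotion", forage_s, habitat),
        ScheduleLeg("flap", commute_s, None, commute=True),
        ScheduleLeg("stand", 600, None),
    ]


class TestSimulateTrip:
    def test_one_segmentable_trip(self, sim_config, landscape):
        fixes, bursts, truth = simulate_trip(
            sim_config, commute_schedule(), rules=landscape)
        trips = segment_trips(fixes, sim_config.nest_xy)
        kept, _ = filter_trips(trips)
        assert len(kept) == 1

    def test_full_acc_coverage_without_gaps(self, sim_config, landscape):
        fixes, bursts, _ = simulate_trip(
            sim_config, commute_schedule(), rules=landscape)
        assert fixes["has_acc"].all()
        assert set(fixes["fix_id"]) == set(bursts)

    def test_commute_speed_matches_flap_mean(self, sim_config, landscape):
        fixes, _, truth = simulate_trip(
            sim_config, commute_schedule(), rules=landscape)
        d = fixes.merge(truth.fixes[["fix_id", "commuting"]], on="fix_id")
        spd = np.hypot(d["x"].diff(), d["y"].diff()) / d["t"].diff()
        fwd = np.roll(spd.to_numpy(), -1)
        com = d["commuting"].to_numpy()
        com[-1] = False
        sample = fwd[com]
        # exclude turnaround/hover fixes at leg edges
        sample = sample[sample > 1.0]
        mean = sim_config.behavior_speed_means["flap"]
        assert abs(sample.mean() - mean) <= 2 * max(sample.std(), 0.5)

    def test_gap_injection_drops_fixes(self, landscape):
        cfg = SimConfig(seed=5, gap_prob=0.3)
        full_cfg = SimConfig(seed=5, gap_prob=0.0)
        gappy, _, _ = simulate_trip(cfg, commute_schedule(), rules=landscape)
        full, _, _ = simulate_trip(full_cfg, commute_schedule(), rules=landscape)
        assert len(gappy) < len(full)

    def test_no_away_time_rejected(self, sim_config):
        with pytest.raises(ValueError):
            simulate_trip(sim_config, [ScheduleLeg("stand", 1200, None)])

    def test_nonpositive_duration_rejected(self, sim_config):
        sched = commute_schedule()
        sched[1].duration_s = 0.0
        with pytest.raises(ValueError):
            simulate_trip(sim_config, sched)


class TestBirdDays:
    def test_deterministic_under_seed(self, landscape):
        cfg = SimConfig(seed=13)
        a = simulate_bird_days(cfg, 2, 1, rules=landscape)
        b = simulate_bird_days(cfg, 2, 1, rules=landscape)
        pd.testing.assert_frame_equal(a[0], b[0])
        pd.testing.assert_frame_equal(a[2].trips, b[2].trips)

    def test_single_habitat_mix_recovered_in_truth(self, landscape):
        cfg = SimConfig(seed=4)
        _, _, truth, _ = simulate_bird_days(
            cfg, 2, 2, strategy_mix={"intertidal": 1.0}, rules=landscape)
        assert (truth.trips["category"] == "intertidal").all()

    def test_masses_near_colony_mean(self, gull_days):
        masses = gull_days["birds"]["mass_g"]
        assert 700 < masses.min() and masses.max() < 1300
        assert abs(masses.mean() - 969) < 120

    def test_invalid_args_rejected(self, sim_config):
        with pytest.raises(ValueError):
            simulate_bird_days(sim_config, 0, 1)
        with pytest.raises(ValueError):
            simulate_bird_days(sim_config, 1, 1, strategy_mix={"urban": 0.0})

    def test_truth_energy_matches_trip_energy_oracle(self, gull_days, sim_config,
                                                     landscape):
        """The generator's independently computed trip energy agrees with
        the pipeline's trip_energy evaluated on the true labels."""
        from gulltrack.pipeline import run_pipeline

        labels = gull_days["truth"].fixes.set_index("fix_id")["fine"]
        table = run_pipeline(
            gull_days["fixes"], gull_days["bursts"], landscape,
            sim_config.nest_xy, gull_days["birds"], true_fine_labels=labels)
        m = table.merge(gull_days["truth"].trips, on=["bird_id", "start_t"])
        assert len(m) == len(gull_days["truth"].trips)
        rel = np.abs(m["total_kJ"] - m["energy_kJ"]) / m["energy_kJ"]
        assert rel.max() < 1e-6

    def test_flap_fraction_contrast_by_construction(self, gull_days):
        tr = gull_days["truth"].trips.copy()
        tr["ff"] = tr["flapping_h"] / tr["duration_h"]
        high = tr[tr["intended_category"].isin(["urban", "marine"])]["ff"].mean()
        low = tr[tr["intended_category"].isin(["intertidal", "terrestrial"])]["ff"].mean()
        assert high == pytest.approx(0.30, abs=0.03)
        assert low == pytest.approx(0.17, abs=0.03)
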
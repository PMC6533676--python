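# gulltrack

Time–energy budgets of central-place foraging gulls from GPS tracking and
tri-axial accelerometry.

Herring gulls (*Larus argentatus*) breeding at coastal colonies forage in
very different habitats — urban areas and the open sea (high-caloric refuse
and fishery discards) versus intertidal flats and farmland (low-caloric
bivalves, crabs and earthworms). `gulltrack` implements the full analysis
chain needed to ask whether foraging for high-caloric anthropogenic food is
also energetically more expensive:

1. **Trip segmentation** — GPS fixes become foraging trips (departure beyond
   100 m from the nest until return within 100 m), with per-fix *centered
   durations* (mean of backward and forward inter-fix intervals) so time
   budgets conserve elapsed time exactly; trips with >20 min away-from-colony
   gaps or <80% acceleration coverage are excluded.
2. **Behavior classification** — 20 Hz × 1 s tri-axial bursts are
   summarised (per-axis moments, ODBA, dominant heave frequency) and
   classified into 11 fine behaviors by a random forest, then aggregated to
   four energetic classes: inactive, terrestrial movement, soaring flight,
   flapping flight.
3. **Movement modes** — expectation–maximization binary clustering of speed
   and turning angle labels each fix LL/LH/HL/HH; HL (high velocity, low
   turn) is commuting and is excluded from habitat use.
4. **Habitat assignment** — polygon rules with a 50 m intertidal buffer and
   a behavior-conditional mudflat rule map non-commuting fixes to urban,
   marine, intertidal or terrestrial; a trip's category is the habitat
   holding ≥50% of its assigned fixes, else *mixed*.
5. **Energetics** — allometric behavior-specific rates price each trip:

   BMR = 2.3·*m*(g)^0.774 kJ day⁻¹, RMR = 1.7·BMR,
   inactive = RMR, terrestrial = 2·BMR, soaring = 2·RMR, flapping = 7·RMR,

   with trip energy = Σ (centered duration × class rate) and hourly rate =
   trip energy / trip duration.
6. **Inference** — linear mixed models (habitat category fixed, bird random
   intercept) on log duration, √flapping time and log hourly rate, with
   likelihood-ratio null comparison, ΔAICc, Tukey letter groups and
   Nakagawa's marginal/conditional R².
7. **Scenarios** — daily budget and prey-equivalent arithmetic
   (assimilation efficiency 0.75, 84 kJ per discarded flatfish) and a
   hypothetical-trip cost calculator.

A synthetic-data module generates gull-days over an abstract coastal
landscape with known per-fix behavior, commuting, habitat and per-trip
energy, so every stage is testable without any field data.

## Worked example

```python
>>> from gulltrack import EnergeticProfile, ScenarioSpec, daily_cost, prey_equivalents, extra_prey
>>> p = EnergeticProfile(mass_g=1000)
>>> {k: round(v, 1) for k, v in p.rates().items()}
{'inactive': 34.2, 'terrestrial_movement': 40.2, 'soaring_flight': 68.4, 'flapping_flight': 239.4}
>>> discards = ScenarioSpec(hours_colony=14, rate_colony=33, hours_away=10, rate_away=100)
>>> daily_cost(discards)
1462.0
>>> prey_equivalents(1462.0)          # gross kJ at 75% assimilation, fish at 84 kJ
(1949, 23)
>>> extra_prey(1462.0, 1162.0)        # vs an intertidal/terrestrial forager
(400.0, 5)
```

A discard-foraging gull spends 1462 kJ/day and must catch 23 flatfish
(1949 kJ gross) to cover it — about 5 fish and ~400 kJ more per day than a
bird foraging in cheap habitats (1162 kJ/day). Or from a shell:

```bash
gulltrack simulate --seed 5 --birds 6 --days 2 --out-dir sim
gulltrack run sim --seed 5 --out trips.csv
gulltrack stats trips.csv --response rate_kJ_h
```

which fits the mixed model to the simulated trips and prints, e.g.:

```
Mixed model: log(rate_kJ_h) ~ category + (1 | bird_id)
n = 24 trips, 6 birds

term                        estimate      SE  letters
Intercept                      4.548   0.038  a
category[T.marine]             0.022   0.014  a
category[T.intertidal]        -0.281   0.013  b
category[T.terrestrial]       -0.281   0.017  b

LRT vs null: chi2(3) = 79.78, p = 3.41e-17, dAICc = 70.04
```

Urban and marine trips share a letter (equally expensive per hour);
intertidal and terrestrial trips are significantly cheaper.

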
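# Methods

## Trip definition and time accounting

A foraging trip starts when a bird is recorded strictly more than 100 m
from its nest and ends at the first fix back within 100 m; the trip
includes the last at-nest fix before departure and the first after return.
Each fix carries a *centered duration*, the mean of its backward and
forward inter-fix intervals; boundary fixes take half their single adjacent
interval. This edge convention makes per-fix weights telescope to exactly
the trip's elapsed time, which every downstream time budget relies on.
Excursions left open at the end of a record are emitted but flagged
(`kept=False`) rather than guessed at.

Quality control drops a trip when any away-from-colony inter-fix gap
exceeds 20 min (strictly), or when fewer than 80% (inclusive keep) of its
fixes carry an acceleration burst. High-rate segments are thinned to the
standard regime (10 min at the colony, 5 min away) by keeping the first fix
of each target interval; no interpolation is performed. Distances are
planar Euclidean on projected coordinates.

## Behavior from acceleration

Bursts are 3 axes (surge, sway, heave) × 20 samples at 20 Hz in g-units.
Features per burst: per-axis mean/sd/min/max, overall dynamic body
acceleration (summed per-axis mean absolute deviation), dominant heave
frequency from a periodogram, and the dominant frequency's power fraction.
A random forest (200 trees, stratified 25% hold-out) predicts one of 11
fine behaviors; the forest is pluggable behind a `predict` contract, and
every stage also accepts pre-labeled behaviors so it can be tested in
isolation. The 11→4 aggregation is fixed: {sit, stand, float}→inactive;
{terrestrial locomotion, both looking-for-food variants, handling prey,
other}→terrestrial movement; {soar, manoeuvre}→soaring flight; {flap,
extreme flap}→flapping flight. Fixes without a burst are `unannotated`.

## Movement modes and commuting

Speeds come from consecutive displacements over elapsed time; turning
angles are unsigned heading changes at interior fixes (endpoints copy their
nearest interior value — the quadrant semantics need magnitude only). The
binary clustering is a four-component Gaussian mixture on (speed, turn)
constrained to the quadrants of a per-variable binary split: each variable
has a low and a high level (mean and variance), components are the four
level combinations, and EM updates are standard weighted averages with the
low ≤ high order re-imposed each iteration. Delimiters are placed midway
between the fitted low and high means; labels are
maximum-responsibility components mapped to LL/LH/HL/HH, so relabeling is
governed by the split geometry, not component indices. Initialisation
splits each variable at its median; the log-likelihood is checked
non-decreasing; degenerate inputs (all points identical) return a single
mode with a flag. A modal-window smoother (default window 3, ties keep the
original label) accounts for temporal association. Clustering is fitted
per bird (per bird-year where a year column exists), and HL = commuting.

## Habitat rules

Layers: north sea, wadden sea, urban, breakwater, beach, mudflat,
agricultural/natural land. Rule order for a non-commuting fix, first match
wins: (1) urban; (2) breakwater/beach → intertidal; (3) sea within 50 m of
breakwater/beach/mudflat → intertidal (those edges are exposed at low
tide); (4) mudflat: flying (flapping or soaring aggregate) or floating
(fine label) → marine, otherwise → intertidal (resting or walking on a
flat indicates foraging); (5) sea → marine; (6) agricultural/natural →
terrestrial; (7) unassigned. Boundary points count as inside; precedence
between overlapping layers is the stated order and is configurable, since
no external convention exists for overlaps. Trip categories use fractions
over *assigned, non-commuting* fixes (unassigned fixes are excluded from
the denominator but counted for audit): the top habitat wins at ≥50%
(inclusive), exact ties break urban > marine > intertidal > terrestrial and
are flagged, otherwise the trip is mixed. Commuting fixes stay in the
duration/flapping/energy responses; they are excluded only from habitat
fractions.

## Energetics

BMR = 2.3·m(g)^0.774 kJ/day (≈19.6 kJ/h at the 969 g colony mean), carried
per hour as BMR/24. RMR = 1.7·BMR covers thermoregulation, digestion and
minor movement and prices the inactive class. Terrestrial movement is
2·BMR — the package retains the Bautista et al. treadmill formula
(5.6·W^0.246 + 11.4·W^−0.285·v)·86.4 kJ/day, v = 0.4 m/s walking speed,
purely as a cross-check oracle (they agree within ~9% at 1 kg). Soaring is
2·RMR and flapping 7·RMR, so flapping/inactive = 7 and
soaring/terrestrial = 1.7 at any mass, and the rate order flapping >
soaring > terrestrial > inactive holds for all positive masses.

Up to 20% of a kept trip's fixes may lack a behavior (the coverage floor),
so the pricing of unannotated time is an explicit policy: `redistribute`
(default) prices it at the trip's annotated mean rate, `rmr` prices it at
rest; both report the unannotated hours. Neither choice is claimed to be
the field convention — the original handling is unstated.

## Inference

Responses per kept trip: duration (h), flapping time (h), hourly rate
(kJ/h), transformed log/√/log respectively. The model is a linear mixed
model with habitat category fixed (urban reference) and bird random
intercept, estimated by REML (statsmodels `MixedLM`); the null comparison
(random intercept only) uses ML refits for the likelihood ratio and AICc
(small-sample corrected, k counting fixed effects + intercept variance +
residual). Pairwise contrasts use a studentized-range (Tukey) adjustment
with large-sample residual df and are summarised as compact letters.
Variance explained follows Nakagawa: R²m = σ²f/(σ²f+σ²a+σ²e) and
R²c = (σ²f+σ²a)/(σ²f+σ²a+σ²e), σ²f being the variance of the fixed-effect
predictions. REML for estimates with ML for the LRT and α = 0.05 letters
are package defaults; the source convention is unstated. Sex, year and
mass can enter as covariates but are excluded from the default model.

## Synthetic data

The generator emulates the measurement process the pipeline assumes: fixes
every 600 s at the colony and 300 s away, a 20 Hz × 1 s tri-axial burst per
fix, central-place trips (commute out — foraging bout — commute back) over
an abstract rectangular coastal landscape (sea bands, beach, breakwaters,
mudflats, an urban block, farmland, a colony clearing). It is deliberately
not a replica of any real colony: the assignment rules, not geography, are
under test.

Behavior-specific speeds default to flap 11, soar 8, walk 0.4 (the tracked
average), float 0.2 m/s; only the walking speed has an external anchor, the
rest are editorial. Burst statistics per fine behavior are configurable
(per-axis mean/sd, heave oscillation frequency/amplitude); defaults are
well separated — flapping has a strong 4–5 Hz heave oscillation, inactive
behaviors sit near a 1 g resultant with low variance — so a classifier
reaching ≥90% hold-out accuracy demonstrates the pipeline contract, *not*
the accuracy attainable on real, overlapping behaviors.

Commutes fly straight toward a habitat anchor at per-fix speeds drawn
around the flap mean (CV 0.08); a commute scheduled longer than the direct
flight overflies the target and doubles back so commuting stays fast and
straight. Foraging flight orbits the anchor (high turn, bounded
displacement); ground behaviors wander near it with a boundary pull. Legs
are whole numbers of fix intervals and commute anchors sit at
whole-interval flight distances, so realized class durations track the
plan; the planner also budgets for the inactive colony time that trip
boundaries add and for the half-weight of the first flap fix. Gaps are
injected by deleting fixes (never endpoints), matching how tracker gaps
appear; a separate probability drops bursts to exercise the coverage
filter.

Trip composition is planned by habitat strategy: flapping takes 0.30 of
total trip time for urban/marine trips and 0.17 for intertidal/terrestrial
ones; remaining time splits 0.182/0.718/0.100 over
inactive/terrestrial-movement/soaring. Those shares were chosen once so
that, with the rate multipliers above, high-caloric trips cost ≈34% more
per hour than low-caloric ones by construction — the generator plants the
contrast the pipeline is expected to recover, at any body mass (the ratio
is mass-free). Masses are drawn N(969, 60) g.

Ground truth (per-fix fine behavior, class, commuting flag, habitat;
per-trip category and energy) is computed inside the generator with its own
explicitly written-out centered-duration and rate arithmetic — a deliberate
code-path duplication so it can serve as an independent oracle for the
pipeline. Fix labels are the majority behavior over the coming inter-fix
interval, which is also what the fix-to-fix kinematics and the burst
reflect.

What the synthetic data does **not** emulate: tides and dynamic mudflat
exposure, weather and wind-dependent flight costs, classifier-relevant
behavior overlap, GPS positional error, multi-nest birds, chick
provisioning. Passing tests therefore validate the pipeline's logic and
numerics, not field-data performance.

## Numerical choices and scales

Resampling tolerance 1 s; EM tolerance 1e-6 with ≤200 iterations and a
1e-3 variance floor; boundary comparisons: excursion > 100 m, gap > 20 min,
coverage ≥ 80%, category ≥ 50%. Prey arithmetic rounds gross intake and
item counts to the nearest integer, the only convention consistent with the
printed triple (1949 kJ, 23 fish, 5 extra). Simulation sizes in the test
and acceptance runs (e.g. 14 birds × 4 days ≈ 112 trips for the end-to-end
contrast; 605 planted trips × 17 birds, 200–500 replicates for the
inferential checks) were chosen to keep Monte-Carlo error well inside the
assertion bands while the whole suite stays fast.

## Known limitations

The binary clustering is a re-implementation of the published contract
(quadrant labels, smoothing, HL = commuting), not a numerical clone of the
original R package. Energetic rates are multiplier-based approximations —
no dynamic-body-acceleration calibration, no thermoregulatory model beyond
the fixed 1.7 factor. The hypothetical-trip calculator exposes leg
composition as free parameters rather than asserting any specific imaginary
trip. Letter groupings use large-sample df rather than Kenward–Roger-style
corrections.
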
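# MarCPFS methods note

MarCPFS simulates a lactating female Antarctic fur seal (*Arctocephalus
gazella*) and her pup over one rearing season on an artificial prey
landscape. The female is a central place forager: she alternates foraging
trips at sea with shore visits at the breeding island to suckle the pup. The
simulation asks how prey abundance, prey aggregation, the distance between
the colony and the feeding grounds, body length and spatial memory combine to
determine the pair's breeding success — and which body length minimises the
energetic cost per unit of success at each distance.

## The landscape

A 100 x 100 grid of 10 x 10 km cells holds prey abundance in grams of
catchable prey per fishing hour; the island sits at the central cell, and
coordinates are continuous kilometres. Construction:

1. **Correlated random field.** White Gaussian noise smoothed with an
   isotropic Gaussian kernel of `SIGMA_PER_LEVEL x aggreg` cells (wrap
   boundary), then standardised. The aggregation level `aggreg` in
   {0,1,2,3,4,6,8,10} is therefore a correlation-length dial: level 0 is
   spatially uncorrelated speckle, level 10 a handful of large blobs.
2. **Truncation.** Negative field values become zero abundance, so roughly
   half of the accessible area carries prey.
3. **Masks.** Cells on the island plateau (<= 50 km) and beyond the 500 km
   foraging range are zero. Between the plateau edge and the
   distance-to-resource `dist`, an accessibility gradient rises linearly from
   0 to 1 and multiplies cell abundance (exponent `GRADIENT_EXPONENT`,
   default 0.15); the near field is present but poor. A Bernoulli-retention
   variant of the gradient is available (`apply_masks(mode="retention")`).
4. **Normalisation.** The grid-wide mean equals the abundance level `abund`
   in {90, 180, 270, 360} g/h: the level fixes the map's total prey budget.
   The mean over the non-zero cells alone (AvgEnv, roughly 2 x `abund`) is a
   recorded per-map property and parameterises the fishing threshold below.

Patch statistics count 4-connected components above the fishing-profitability
abundance (55 g/h). At level 0 a map holds several hundred small patches; at
level 10 roughly eight large ones. The smoothing scale (0.45 cells per
aggregation level) was calibrated once against these patch counts; with this
construction the large-aggregation patches are larger (hundreds of cells)
than the field observation the model family reports (~67 cells), a known
limitation: a construction sparse enough to reproduce both printed patch
counts and sizes (~10% occupancy) is not energetically survivable under the
published metabolic rates, so the dense construction that supports realistic
demography was preferred.

## The female's hour

Time advances hourly with a 16 h day / 8 h night cycle (night 22:00-06:00);
prey is reachable only at night. One simulation covers a 15-day prenatal
prospection (no pup; the first half is a pure survey during which
memory-directed travel is suppressed), a 5-7 day perinatal shore fast
(drawn uniformly; the pup gains a fixed 1.5 kg from the mother), and the
2880-hour rearing period.

**Energetics.** The female's mass and energy are interconvertible at
10.59 MJ/kg. At sea she pays her field metabolic rate (6.09 W/kg) every hour
plus a displacement cost per km when moving; ashore she pays a fraction
(0.25) of the at-sea rate. The displacement cost is quadratic in body length
(cross-section of a streamlined body), anchored at the published endpoints
0.041 MJ/km (85 cm) and 0.12 MJ/km (145 cm). A fishing hour on a cell of
abundance `a` g/h yields `a x 4 kcal/g` of energy, truncated by satiation: no
single feeding exceeds 7% of her energy at the previous dawn, and her energy
never exceeds the fixed ceiling E_max = 1.07 x her initial mass in energy
terms. The ceiling, not the per-feeding cap, is what limits growth: final
masses of successful females sit just below it.

**Decisions.** At night, on a cell above the 1.5-map-unit (55 g/h)
profitability floor and below satiety, she fishes with probability
`expit(2 (a - th))` where the threshold `th` interpolates between the
profitability floor (when her energy is at the lethal limit) and AvgEnv (when
her reserves are full): hungry females work poor cells, sated females hold
out for rich ones. While fishing she does not move. Otherwise she moves at
2.11 m/s (7.6 km/h): directly toward the island when returning; directly
toward a memorised cell in transit; else by a correlated random walk whose
wrapped-normal turning angle (sd 1.5475 rad, lag-1 heading autocorrelation
0.30) applies on profitable water, with near-straight travel (sd 0.3 rad)
across unprofitable water and a 180-degree bias after crossing into a poorer
cell (gradient sensing). Returns are decided per night hour by a logistic in
the margin between her energy fraction and the cost fraction of returning
(travel home plus two days ashore), plus a steep trip-clock ramp; a female
still near satiety at dawn after a minimum trip heads home with her load
complete. Both trip clocks (minimum trip, ceiling T_max = 216 h) scale with
body mass relative to the 115 cm reference, so large females make fewer,
longer trips.

**Memory.** A Mem1 female remembers the best cell she has encountered,
scoring cells by abundance discounted by `exp(-d/250 km)` so equally rich
cells nearer the colony are preferred. Leaving the island she heads for it
with a fidelity `g/(g + 0.05)` set by the previous trip's gain rate `g`
(MJ/h), and aims with a navigation error of sd 10% of the transit distance —
small dispersed patches are found but hard to relocate, large aggregates easy
to relocate but hard to find, which is what makes intermediate aggregation
favourable. Mid-trip she re-engages transit whenever local abundance falls
below 0.6 x her memorised value. Mem0 females search by CRW and gradient
alone. Shore departures are timed (around the colony's typical 17:00
departure) so that straight travel to the memorised cell lands at nightfall.

**Milk.** Each shore hour the pup receives `r x` the mother's donation
surplus — her energy above 0.85 x her initial stores; a depleted mother
protects her own reserve first, which is what starves the pups of small or
overstretched mothers. `r = 0.0035`/h was calibrated once against the
published weaning mass (~11 kg) at the reference condition and then frozen.
The pup's tissue energy density is 8.24 MJ/kg and its mass is capped at
18 kg. A fasting pup loses 0.12% of its energy per hour, with the loss floored
at the structural (post-perinatal, 7 kg) level so chronic underfeeding is
genuinely lethal rather than self-stabilising.

**Mortality.** Death is an hourly Bernoulli draw with probability given by a
Normal CDF of current energy as a percentage of a reference: centred at 70%
for females and 56% for pups, with a width of 2 percentage points. The pup's
reference is its best-fed post-suckling energy (ratcheting up as it grows);
the female's reference is taken at birth and at each departure as the minimum
of her current and initial energy (ratcheting down: a starving animal defends
a lowered set point). Mortality is evaluated from birth onward; the
prospection phase precedes the simulated season.

## The experiment layer

A condition (aggregation x abundance x distance x length x memory) is
simulated over `n_maps` landscape replicates x `n_seals` females; statistics
aggregate per map first, then mean +/- SD across maps. Behavioural summaries
(trip distance and duration, trip and fishing-event counts) use females alive
at day 120; pup masses use surviving pups. Breeding success is
SP = (1 - D_f)(1 - D_p). The cost/benefit ratio R = E/SP uses the female's
total energy expenditure over the rearing period; the body length minimising
R is found by fitting quadratic and cubic curves over the five lengths and
taking the argmin of the better curve on [85, 145], bootstrapped (resampling
runs within lengths) for a 95% interval. The optimal length regressed on
distance gives the slope that converts a drift rate of the foraging grounds
into a matching drift of body length.

## Problem sizes and numerics

The hourly core is a numba-compiled kernel (~1 ms per simulated season), so
the acceptance script recomputes every headline quantity from scratch —
roughly 6,000 full simulations — in well under a minute after JIT
compilation. The test suite uses 10 maps x 15-25 females per condition and
the acceptance script 10 x 50 for the reference condition (the published
experiment used 10 x 50 per cell of a 28,800-cell factorial). Each run uses
one seeded RNG stream; identical (configuration, seed) pairs reproduce
bit-identical results. Positions are continuous; the occupied cell is
floor(position/10 km); map borders reflect. Energy is clamped at zero, at
which point the mortality draw is certain.

## What the generator does and does not emulate

The landscapes are static, isotropic and two-dimensional: no seasonal or
advective prey dynamics, no bathymetry, no vertical (dive-depth) structure,
no competition or predation, and no depletion by foraging. Passing tests
therefore demonstrate the internal consistency of the behavioural-energetic
model under controlled prey fields, not predictions for any specific ocean
state. Within those limits the model reproduces the published reference
demography (pup survival ~86-93% depending on the landscape draw, weaning
mass ~11 kg, female final mass ~30 kg), trip durations (~83 h at 100 km),
fishing events per trip (~21), the rise of mortality with prey aggregation,
and the preferential fishing of rich cells near the colony.

## Known limitations

- Trip distance and trip count cannot both match their published values: with
  stationary fishing, distance per trip is bounded by speed x (duration -
  fishing hours), which is below the published distance at 100 km; and the
  published maximum trip count (14.5) reflects a statistic pooled over all
  distances and abundances, while a single-condition estimate at 150 km runs
  near 20.
- The optimal-length-versus-distance slope is positive but weak at feasible
  replication: the mechanisms that should penalise small females at large
  distances (storage-scaled trips, the donation floor) move SP in the right
  direction, but the cost numerator E grows so steeply with mass that the
  R-minimum stays near the short end at most distances.
- Aggregation level 10 yields ~8 patches of several hundred cells rather
  than ~10 of ~67 (see the landscape section).
- The distance-to-resource axis compresses: females exploit the inner edge of
  the accessible field, so realised foraging distance grows much more slowly
  than the nominal `dist`. Steeper accessibility gradients restore the
  distance effect but depress reference-condition survival below its
  published value; the default favours the latter.
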
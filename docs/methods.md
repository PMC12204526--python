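# Methods

This note documents the model implemented by `triadscape`: its state
variables, process rules, default parameters, the synthetic data the
pipeline runs on, and the numerical and design choices that were genuinely
open. Nothing here reports an empirical result; all quantitative claims
are the ones the test suite and `scripts/acceptance.py` recompute.

## State and time

The landscape is a raster of 1-ha cells (100 m grid). Each active cell
carries a community of **age cohorts**: one biomass pool (g/m²) per
(species, 10-year age class). A cohort's nominal age is the midpoint of
its class (class *k* covers [10k, 10k+10), nominal age 10k+5). The
midpoint convention is what makes the age-filtered prescriptions behave
as written: a 5-year-old cohort escapes the ">10 y" clearcut filter, a
95-year-old cohort falls in the 91–100 thinning bin, and a cohort dies in
the step after its nominal age first exceeds the species' longevity.

Simulation year 0 represents 2020. Runs last 200 years in 10-year steps
with the catastrophic pulse at year 100. Climate-sensitive parameters are
piecewise constant over three periods (years [0,20), [20,50), [50,∞)),
frozen after the last boundary — mirroring forcing projections that end
mid-century while the simulation continues beyond it.

Within each step the operations execute in a fixed order: growth →
mortality/aging → background fire → budworm outbreak → harvest →
catastrophe (event year only) → establishment → summaries. Process order
within a step is a genuine free choice in cohort models of this type; it
is fixed (and tested) for reproducibility, with establishment last so
that freshly disturbed ground can recruit in the same step.

## Succession

Three parameters per (species, ecoregion, climate, period) govern
dynamics: establishment probability, maximum ANPP (g·m⁻²·y⁻¹) and
maximum cohort biomass (g/m²). The growth rule is deliberately simple
while preserving the two climate levers of biomass-succession models —
ANPP as "escalator", maximum biomass as "hard ceiling":

```
gain(cohort s in cell c) = Δt · maxANPP[s, eco(c)] · (1 − crowding(c))
crowding(c) = total biomass(c) / capacity(c)
capacity(c) = max over species of maxBiomass[·, eco(c)]
```

If the summed cohort gains of a cell would push its total past capacity,
all gains in that cell are scaled down proportionally; each cohort is
additionally clipped at its species ceiling. Without the cell-level cap a
many-cohort cell would overshoot its site capacity arbitrarily, because
the crowding term is evaluated at the start of the step.

Mortality: a configured background fraction of biomass is removed each
step (default 5% per decade ≈ 0.5%/y), ages advance one class, and
cohorts past their species longevity die. Establishment: a species can
recruit into a cell if a live cohort exists within the dispersal
neighbourhood (uniform square kernel, default radius 2 cells — a
stand-in for species-specific kernels, which the planting/harvest
dynamics dominate anyway), the site shade class (1–5, a monotone map of
crowding with thresholds 0.15/0.35/0.55/0.75) does not exceed the
species' shade tolerance, and a Bernoulli draw at the establishment
probability succeeds. New cohorts start in age class 0 at 50 g/m². The
shade curve is a declared stand-in: no calibrated shade-productivity
parameters exist for the synthetic pool.

Serotinous species may re-establish on cells burned by a *background*
fire in the same step (seed released from the canopy) even though their
parent cohorts burned; this pathway is disabled for the step following
the catastrophic fire, whose severity model already spares tolerant
cohorts.

## Synthetic inputs

The generators replace proprietary maps and calibrated growth tables with
seeded synthetic structures that preserve what the analysis actually
uses:

* **Species pool** — 17 species in 5 archetype groups (3 gymnosperm:
  shade-tolerant fir/spruces, fire-adapted pines, dry-site conifers; 2
  angiosperm: pioneer and late-succession hardwoods). Nine response
  traits are drawn around group archetypes (lognormal noise, σ≈10%, for
  physical traits; additive σ=0.3, clipped to [1,5], for the tolerance
  scores), so Ward clustering recovers the generating groups essentially
  perfectly at default separation; an `archetype_separation` parameter
  scales group distinctness down to chance. Three pines are beetle
  hosts (one serotinous); four fir/spruce species carry the budworm
  vulnerability ranking. Roles are fixed; trait values vary with seed.
* **Landscape** — Voronoi stands around uniform seed points (default mean
  25 ha), four latitudinal ecoregion bands, a north/south fire-region
  split, and a protected network grown patch-by-patch from a heavy-tailed
  (Lomax) size distribution to exactly the target fraction (default 9%):
  many small patches, few large, median ≪ mean.
* **Growth tables** — per-species base values (ANPP 350–750, maximum
  biomass 9,000–22,000 g/m², establishment 0.15–0.55) shaped by a
  latitudinal clade suitability (gymnosperms favoured north, hardwoods
  south — this alone produces the boreal-north/mixedwood-south gradient
  of the initial communities) and per-period climate multipliers:
  hardwoods gain under warming (up to +28% ANPP in the last RCP 8.5
  period), boreal conifers lose (down to −32%); establishment and
  maximum biomass drift with half the ANPP amplitude.
* **Initial communities** — 2–5 cohorts per cell, species drawn by
  establishment-probability weights, ages uniform within longevity,
  biomass 15–55% of the species ceiling.

What the generators do **not** emulate: real spatial autocorrelation of
soils and stand composition, species-specific dispersal kernels,
calibrated fire-size distributions, or any absolute biomass calibration.
Passing tests therefore demonstrate the internal consistency and
qualitative behaviour of the pipeline (directions of climate, planting
and disturbance effects; conservation of the zoning and harvest
arithmetic), not quantitative predictions for any real landscape.

## Background disturbances

Background wildfires are stand-replacing: per region and step, ignition
counts are Poisson with mean = expected burned area / mean fire size,
sizes uniform on the regime's bounds (north: 5–200 ha, south: 2–50 ha),
patches grown by randomised accretion. Defaults burn 0.25%/y (north) and
0.10%/y (south), multiplied under forcing up to ×3 (RCP 8.5, last
period), so burn rates are ordered RCP 8.5 ≥ RCP 4.5 ≥ baseline in every
period. Budworm outbreaks recur every 40 years for one 10-year step
(first onset at year 30, giving five windows in a 200-year run); host
cohorts lose rank-dependent fractions (0.6/0.4/0.3/0.2) scaled by the
cell's host biomass share; climate does not modify the outbreak regime.
The severity fractions are configuration, not calibration: only the host
ranking is anchored.

## Management

Zoning: conservation = the initial protected network plus a
distance-ordered buffer (cap 5,000 m) around the largest 10% of
protected patches, grown to 24% of the active area; intensive = whole
stands of highest potential productivity (best ecoregion ANPP × stand
site quality) outside conservation, to 16%; extensive = the rest. BAU
landscapes use the same allocator with a zero intensive share and
conservation equal to the protected network.

The six prescriptions and their age rules, the four scenarios' shares
and zone codes, and the selection-cut / thinning revisit schedules are
tabulated in `management.py`. Scheduling details that were open:

* Prescriptions execute in a fixed (table-column) order each step.
* Stands are consumed in descending order of harvestable biomass, except
  the functional-planting clearcut, which targets ascending stand FD.
* Revisit entries (selection cutting at +30/+60 y, intensive-zone
  thinning at +20/+50 y) are served before new selections and are
  truncated at the prescription's share of the target, so removal per
  prescription never exceeds its share by more than one partial stand and
  all four strategies extract the same total (shortfalls are recorded in
  the ledger as data, not errors).
* Only the last stand needed for a share is harvested partially, by a
  random subset of its cells.
* The biomass target defaults to 3% of the initial unprotected landscape
  biomass per step — a sustained-yield-scale figure computed from the
  same initial state for every scenario, which is what makes the
  equal-harvest comparison meaningful.
* Functional planting adds one age-0 cohort of one species per
  functional group missing from the treated stand (ties on establishment
  probability broken uniformly at random), or one species from the
  rarest group if none is missing. Intensive plantations pair the
  region-appropriate hybrid (angiosperm "poplar" south, gymnosperm
  "larch" north) with the marketable spruce analogue. Hybrids double
  ANPP, gain 15% maximum biomass, halve longevity, and keep all other
  traits; their establishment probability is copied from the parent, so
  they can regenerate naturally once present.

## Catastrophes

Each event multiplies a species-level loss by one minus a stand-level
protection, both from binned lookup tables (`catastrophe.py`). Bin
intervals are right-closed, (a, b], with the bottom bin closed on the
left: this puts FD = 1 (a monoculture) in the zero-protection bin, which
any defensible convention must. Host-abundance bins for the beetle event
descend from 100% in steps of 10. Stand modifiers (CWM fire tolerance,
FD, host share) are evaluated on the year-90 state — protection reflects
the pre-disturbance community. The drought covers the whole landscape;
the fire spares refugia. Refugium sizes follow a truncated discrete power
law on [1, 100] ha (exponent 2.0, a config default — steep enough that
large refugia are rare); patches grow stand-by-stand from a uniformly
random seed stand, the last stand truncated so the sampled size is met
exactly (keeping every patch within the 1–100 ha bounds), and
accumulation stops with the first patch reaching 30% coverage, so
realised coverage overshoots by less than one patch.

## Resilience metrics

Resistance uses the displacement form R = 1 − 2|D|/(C + |D|) (C =
pre-event value at t=90, D = displacement at t=100). The compact form
R = 1 − 2B/(A+B) that this lineage of indicators is often written in
cannot satisfy its own stated range (it returns 0 for an unchanged
trajectory under either reading of A/B); the displacement form is the
unique reading that is 1 at no change and 0 at total loss. Gains use |D|
and R is floored at 0. Net change NC = (E − B)/B with E the value at
t=200. Recovery rate RR = 1/(first time after the event at which the
value regains its pre-event level − event time); on the 10-year grid RR
is quantised to {1/10, …, 1/100} with 0.01 as the unrecovered floor. A
trajectory that never drops "recovers" at the first post-event sample
(RR = 0.1) — the metric measures time-to-threshold, not impact.

## Experiment design

The grid is 4 management × 3 climate × 4 catastrophe = 48 scenarios,
default 5 replicates (240 runs). All scenarios of one master seed share
identical inputs; scenarios sharing a replicate index share their random
stream (common random numbers), so catastrophe and management contrasts
are paired — the no-catastrophe and fire arms of a replicate are
bit-identical through year 90. Aggregation reports per-scenario means,
standard deviations and replicate counts; no statistical tests are
attached, since the factors differ by construction.

## Problem sizes

The default landscape is 50,000 cells — all area-based shares (9%, 16%,
24%, 30%) are scale-free, so structural results transfer. The package's
own test suite exercises the full pipeline on 1,200–2,000-cell
landscapes, where a complete 200-year scenario takes on the order of a
second; the structural generators (zoning, refugia) are tested at the
full 50,000-cell default. A full 240-run grid at default scale is a
multi-hour batch job and is left to the user.

## Known limitations

* No water/nutrient competition, no spatially explicit self-thinning, no
  complementarity between species at the cell scale: diversity effects
  enter only through the catastrophe protection terms.
* Disturbance severity is age-independent; bark thickness, rooting depth
  and other age-linked protections are not modelled.
* Background fire sizes are uniform within bounds and ignitions spatially
  uniform; no fire-weather, topography or fuel feedbacks.
* The budworm model is aspatial within a step (no epicentre propagation).
* Stand-level severity bins are step functions; a cohort's fate changes
  discontinuously at bin edges.
* Harvest allocation is instantaneous and costless: no roads, adjacency
  constraints or operational feasibility.
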
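# Methods

This note records the model's assumptions, the parameter defaults and why
they were chosen, the numerical choices, and what the synthetic study
system can and cannot say about real woodlands.

## The simulated system

The package simulates a community of wood-hauling households drawing
firewood from a surrounding pinyon–juniper woodland over 2020–2100, under
three crossed factors: adherence to the Indigenous dead-wood-only harvest
rule, household demand, and a climate-driven supply scenario. The model is
individual-based on both sides: every stem and every household is an
explicit agent. All inputs are synthetic and seeded; no external data are
read.

## Landscape generation

Suitability is white Gaussian noise convolved with an isotropic Gaussian
kernel and min–max rescaled to [0, 1]. The kernel scale is set so the
smoothed field's autocorrelation decays by *e* at the requested
correlation length (kernel σ = L / 2 in cell units); a zero length gives
independent cells. Min–max rescaling makes the field's mean ≈ 0.5
regardless of seed, which the stocking arithmetic below relies on.
This is the simplest reproducible generator of a patchy resource surface;
it makes no claim to reproduce real vegetation maps.

Default arena: **21 × 21 cells of 8 km** (168 × 168 km) with one
community of 25 households at the centre cell. The coarse cell was chosen
over a finer grid of equal extent as a resolution/cost trade-off: a patch
is the area a single truck trip exploits, and per-cell annual deadwood
production at the default demography (≈ 0.8 t per mean cell, see below)
is then commensurate with one truckload, so trips are meaningful units of
depletion. The 120 km trip radius spans essentially the whole arena from
the centre; the arena, not the radius, is the binding constraint on
travel.

Initial stocking is Poisson per cell and species with mean
`density × suitability`. The default density is the demographic
stationary density (recruitment × expected lifetime ≈ 314 stems/cell per
species at suitability 1), ages are drawn from the stationary age
distribution (truncated geometric under background mortality), and 10% of
stems start dead. Starting at the stationary structure means short
spin-ups suffice; the exponential age option (mean 80 yr) remains
available for non-equilibrium starts. Because a tenth of the stationary
stocking starts dead, the live population sits slightly below its
equilibrium and drifts upward a few percent per century under neutral
climate; calibration and all reported reductions are ratios against the
realized 2020 baseline, so this drift cancels.

## Demography

Annual sub-steps in fixed order: recruit → grow → kill → decay (order
matters for reproducibility and for the mean-field mirror). Growth is
deterministic along the logistic curve given the climate multiplier;
stochasticity enters through recruitment (Poisson), mortality (Bernoulli)
and decay (Bernoulli). Defaults, all overridable:

| parameter | pinyon | juniper | rationale |
|---|---|---|---|
| max biomass (kg) | 500 | 400 | slow-growing semi-arid conifer magnitudes |
| growth rate (1/yr) | 0.06 | 0.06 | multi-decade maturation |
| inflection age (yr) | 60 | 60 | half-size at ~60 yr |
| max age (yr) | 400 | 400 | multi-century stands |
| background mortality (1/yr) | 0.01 | 0.01 | ~100 yr expected lifetime |
| deadwood decay (1/yr) | 0.04 | 0.04 | ~25 yr standing-dead residence |
| recruitment (stems/cell/yr at suitability 1) | 3.2 | 3.2 | 0.05 stems/km²/yr on 64 km² cells |

These are configuration defaults chosen for plausible magnitudes and for
a sustainable baseline (see "supply vs demand" below), not estimates for
any real stand.

At these defaults the mean cell (suitability ≈ 0.5) carries ≈ 315 live
stems and ≈ 80 t live biomass, and produces ≈ 0.8 t of new standing dead
wood per year (mortality flux plus max-age senescence); arena-wide
deadwood production is ≈ 370 t/yr against a current-demand community
draw of 175 t/yr (25 households × 7 loads × 1 t) — comfortable at
current demand, tight at 1.5× demand under forced decline. This 2:1
supply:demand ratio at baseline encodes the premise that present-day
practice is sustainable; the interesting dynamics come from pushing
demand up and supply down.

## Climate forcing and calibration

A scenario is defined by its *endpoint*: the fractional loss of live
biomass by 2100 in an unharvested woodland (0.13 low emissions, 0.21
high). Mechanistically the loss is applied symmetrically — growth and
recruitment scaled by max(0, 1 − λr), mortality by 1 + λr, with r ramping
linearly 0→1 over 2020–2100 — because the endpoint constrains only the
total decline, not its mechanism; the symmetric single-λ form keeps
calibration one-dimensional and the decline smooth. Which demographic
channel carries the decline is a genuine unknown; it is exposed only
through λ, not as separate dials.

λ is calibrated by bisection on a **mean-field recursion**: expected live
cohort counts n(a) and cohort biomass b(a) stepped with the same sub-step
order as the simulator. Because growth is deterministic within a cohort
and mortality is biomass-independent, the recursion is the exact
expectation of the stochastic model, which makes it double-duty: a noise
free calibration target (bisection against a stochastic target would be
ill-conditioned) and an independent validation oracle (the test suite
requires the across-seed stochastic mean to track it within 2% at every
decade). Bisection runs to a relative tolerance of 1e-3 on the reduction;
the bracket doubles up to λ = 64 and fails loudly if the target is
unreachable.

## Harvest

Adherence is a per-trip probability of restricting to dead wood: full =
1.0, partial = 0.5, none = 0.0. A trip goes to the nearest patch (ties
uniform at random) with harvestable stock of the allowed status and takes
up to 1000 kg; within a patch dead stems go first, oldest first, then
(unrestricted trips only) live stems smallest first — even non-adherent
harvesters take the easiest wood. Distance is straight-line between cell
centres and accrues as round trips; the reported `mean_distance` is each
household's annual round-trip sum, averaged over households.

Two numerical thresholds keep trips physically sensible:

- **minimum harvestable stem, 50 kg** (≈ a 23-year-old pinyon on the
  default curve): smaller stems are saplings, not firewood. Without this
  floor, freshly regrowing or just-stripped patches re-enter the trip
  rotation with a few kg of seedlings, and nearest-first foragers burn
  their trip budgets on worthless visits.
- **whole-stem threshold, 50 kg**: when a partial harvest would leave
  less than this on a stem, the stem is taken whole (a load may exceed
  1000 kg by at most the threshold). This keeps conservation exact: the
  biomass leaving the landscape equals the summed loads, to the last kg.

A household stops for the year when demand is met, a trip returns empty,
or it reaches its trip cap (four times the demand, rounded up; a season is
finite). The cap is sized from the trip economics of the depleted steady
state: once nearby patches are harvested down to their annual deadwood
input, a typical trip yields roughly one mean cell's annual deadfall
(≈ 0.6 load at the defaults), so a household needs ≈ 1.7 trips per load
and a tighter cap would ration households that ample standing stock could
serve — an artifact of the one-patch-per-trip convention, not a supply
limit. Failed trips accrue no distance.
Households take turns trip-by-trip in an order shuffled once per year.

Demand levels are {0.5, 1.0, 1.5} × the 7-load baseline: "low"
operationalizes added alternative energy, "high" the loss of coal as a
supplementary fuel.

## Experiment and analysis

Each run: landscape generation → 30-year spin-up (neutral climate, no
harvest; a settling period from the stationary start, checked against a
|trend| < 0.2%/yr criterion over its final quarter) → 81 annual cycles of
demography-then-harvest, recording the six responses. Replicate seeds
derive from (base seed, cell index, replicate) via `SeedSequence`, with
independent spawned streams for suitability, stocking, demography and
harvest — so a zero-forager run is tree-for-tree identical to a pure
demography run, and output files are byte-identical across repeated
invocations. The packaged experiment is 27 cells × 10 replicates;
replicates are a flag (100 is the scaled-up design) and the desk scale was
chosen so the whole grid runs in minutes-to-tens-of-minutes on one core.

Cell summaries are grand means over (year, replicate) rows (panels are
balanced, so this equals the mean of per-replicate means); across
replicate standard deviations of per-replicate means accompany them. The
qualitative checks: (a) meeting need non-increasing in demand within each
(IEK, supply) pair; (b) live biomass under full adherence ≥ none in every
(demand, supply) cell; (c) meeting need under full adherence ≥ none; (d)
positive Spearman trend (α = 0.05) of mean distance over years when
adherence is absent. Comparisons on the 0–1 meeting-need scale use a
tolerance of 1e-3 because cells where essentially everyone meets demand
are ties up to replicate jitter; check (c) in particular is
near-degenerate whenever the arena still holds live wood within range, a
one-sided comparison between two quantities pinned at 1.0. Response-grid
figures normalise the colour scale per response over all 27 cells and
report the scale and per-cell normalised values in their metadata.

## What passing tests do and do not show

The generator emulates the *structure* of the study system — patchy
biomass, two taxa, central-place travel up to ~120 km, seven-truckload
demand — not its quantities. Biomass totals, distances and ages scale with
the stocking and load conventions; only orderings, trends and calibrated
ratios are interpretable. Passing tests show the mechanisms are coded
consistently (conservation, taboo, nearest-first selection, calibrated
decline) and that the qualitative patterns emerge under the stated
conditions; they say nothing about any real woodland's carrying capacity
or any real community's behaviour. Real-world features deliberately absent:
terrain and road networks (straight-line travel), fire and insect
outbreaks, seed dispersal, wood sharing between households, seasonality
within a year, permits and land tenure, and fuel costs.

One behaviour worth flagging: because climate forcing raises mortality,
the *deadwood* supply transiently rises as live biomass falls, so strict
adherents can be temporarily better supplied under decline while the
woodland itself deteriorates — dead wood is a lagging, not leading,
indicator of woodland health in this model.

## Known limitations

- Patch-level depletion is all-or-nothing per trip within one cell; a
  real trip may span several stands.
- Partial live harvest leaves a standing live stem with reduced biomass
  that resumes growing along age-indexed increments.
- The mean-field oracle covers demography only; harvest has no closed
  form expectation and is validated by hand-traced fixtures and
  conservation identities instead.
- With a single central place, "distance" conflates depletion with arena
  geometry at radii near the grid edge.
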
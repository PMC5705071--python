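# Methods

`reefsources` implements a desk-scale version of a robust-source analysis
for reef metapopulations: simulate larval dispersal over a seascape, build
directed connectivity networks under many life-history scenarios, and
intersect three per-reef criteria — key larval source, thermal-stress
refuge, low crown-of-thorns (COTS) outbreak risk — into a set of *robust
sources*, whose system-wide replenishment reach is then quantified.

## The synthetic seascape

All stages run on synthetic inputs with known structure. The domain is a
planar Cartesian box (default 320 × 120 km, km units throughout), which
removes geodesy while keeping every physical constant (4-km forcing grid,
1-km arrest radius, 12-h check interval) at its natural value.

**Reefs.** Convex polygons (mean area 3 km²) arranged in three
shelf-parallel bands (inner/mid/outer) and partitioned alongshore into
management regions. Convexity is guaranteed by taking the convex hull of
radius-jittered ellipse samples; placement enforces pairwise disjointness.
A configurable fraction of reefs (default 27%, matching typical marine-park
zoning coverage) carries a no-take flag.

**Currents.** The velocity field is the *discrete curl* of a scalar
streamfunction evaluated on the grid, so its centred-difference divergence
vanishes identically (to rounding) in the grid interior — the kinematic
analogue of an incompressible surface layer. Components: an alongshore jet
(default 0.25 m/s, sech² profile, core in the outer band), a uniform
shoreward inflow (0.04 m/s) representing oceanic water flushing the shelf,
a weak inshore counter-current (0.05 m/s) so inner-band reefs exchange
larvae rather than sitting in dead water, and drifting mid-shelf Gaussian
eddies (0.08 m/s, 18 km) supplying inter-event variability. Each stored
time slice is divergence-free on its own; temporal variability enters only
through slow eddy drift.

**Climate.** Weekly SST over a multi-decadal record (default 36 years): a
seasonal cycle, a cross-shelf gradient, and bounded uniform weather noise
(±0.6 °C) that by construction never crosses the 1 °C hotspot threshold —
so non-event years accumulate exactly zero thermal stress. Planted warming
events raise the *hotspot* (SST − MMM) to a fixed intensity (default
+3 °C for 4 weeks) over the whole domain, optionally excluding circular
refuge holes; a noise-free event of intensity *I* over *n* weeks therefore
accumulates exactly *n·I* °C-weeks, giving closed-form oracles.

**Surveys.** Adult COTS densities are drawn from an exact compound
Poisson–gamma (Tweedie) sampler: for 1 < p < 2, a Poisson number of gamma
jumps with λ = μ^(2−p)/(φ(2−p)), α = (2−p)/(p−1), scale φ(p−1)μ^(p−1).
This reproduces the Tweedie moment identities (mean μ, variance φμ^p) and
the exact-zero mass e^(−λ). Defaults p = 1.6 and φ = 3.58 (the dispersion
scale reported for manta-tow COTS densities). The survey mean links to the
reef's modelled external larval supply either log-linearly in the
standardised supply or, in planted mode, as a step between μ = 40 and
μ = 3 200 km⁻² across the planted supply-percentile class — inverting the
classifier the sweep is meant to recover.

**Planted ground truth.** In planted mode a designed set of reefs (default
8) is made robust by construction: they sit at the upstream edge of the
outer band inside the jet, staggered *against* the cross-shelf plume drift
(both x and y increase along the line while plumes descend in y), so each
planted reef supplies a long downstream chain while receiving almost
nothing — including from other planted reefs. Warming events exclude
refuge holes (8 km) around them, and ordinary reefs are kept ≥ 11 km away
so no other reef hides in a hole. Eddies are confined to the mid-shelf so
a randomly placed eddy cannot park on the planted line and feed it. The
recovery experiments measure how faithfully the full pipeline rediscovers
this set.

## Dispersal and arrest

Particles are released uniformly inside each source polygon (default
demo: 2 runs × 120 particles per reef; the full-scale convention is
10 × 1 000) and advected hourly by classical RK4 on the bilinearly
interpolated field, plus an isotropic Gaussian random walk with variance
2K·dt per axis (K = 10 m²/s by default; the bundled demo uses 20 m²/s so
that plumes are adequately sampled at its reduced particle counts). Every
12 hours, any particle within 1 km of a reef polygon is arrested there
permanently; the nearest reef wins, ties break to the smaller id. A
particle may be arrested by its own source only after it has first been
observed outside the source's 1-km zone — otherwise every particle would
self-arrest at its first check and local retention would be 1 everywhere.
Particles leaving the grid are lost immediately; tracking stops at 30
days. Arrested + lost = released holds exactly per source reef.

The engine tracks all (reef, run) releases of an event in one vectorised
batch, but initial positions and diffusion noise are drawn from
per-(reef, run) generators in a fixed order, so any single release can be
reproduced in isolation bit-for-bit.

## Connectivity networks

Each arrested particle contributes to the source→sink edge the value of a
survival-competency curve at its arrest age: a gamma density (shape k,
scale fixed at 1 day) times exponential survival e^(−m·age). The default
grid is 13 shapes (1.5–25, competency peaks from ~0.5 days to over three
weeks) at mortality 0.1/day (0.05 and 0.2 available), and one network per
(event × curve) scenario: 16 × 13 = 208 at the reference schedule. Edge
weights are normalised by particles released from the source; self-loops
are local retention. Using the gamma *density* (a rise-then-decline
competency window) rather than a CDF-based competent fraction is a
modelling choice; the formulation is isolated in one function if the
alternative is wanted.

## The three criteria

**Criterion 1 — key sources.** Five per-network metrics (self-loops
excluded): out-degree; out-strength; strong-link degree (out-edges
carrying > 10% of the sink's inflow); major-source degree (out-edges to
reefs at/above their regional median on the first three metrics in that
same network); out-component size. Reefs are mid-rank percentile-ranked
within management regions; a reef qualifies in a scenario when all five
percentiles are ≥ 50, and is a key source when its qualifying-scenario
count reaches half the maximum observed count (ceil). Both "≥ 50" choices
are the inclusive reading of "top 50th percentile".

**Criterion 2 — thermal refugia.** DHW at week w is the 12-week trailing
sum of hotspots strictly exceeding 1 °C over the pixel's MMM. Years in
which a strict majority of reef pixels accumulate any DHW are significant
warming events. A reef is a refuge when, in *every* event year, at least
75% of its pixels stayed at or below 6 °C-weeks (both boundaries
inclusive: clean fraction exactly 0.75 qualifies, DHW exactly 6 is clean).
A 1–100 stress rank index (mean annual-max DHW over event years,
mid-ranked, affinely mapped) is also reported; it averages over event
years only.

**Criterion 3 — low COTS risk.** Per network, reefs are mid-rank
percentile-ranked by external supply; a reef exceeds threshold p when its
percentile is strictly above p, and is 'high' supply when it exceeds p in
at least half of the maximum observed network count (ceil). The threshold
is chosen by sweeping p ∈ {5, …, 95} against surveys: selected p minimises
the outbreak rate among low-class reefs (outbreak = density ≥ 1 500 km⁻²,
inclusive), ties to the larger p (the larger protected class). Validation
statistics: 2×2 odds ratio (Haldane +0.5 only when a cell is empty),
per-class outbreak rates, prevalence, and the fold contrast of mean
maximum densities.

## Integration and reach

Robust sources are the intersection of the three flags. Replenishment
reach uses duration-truncated connectivity: for maximum larval duration d,
edge i→j exists when any particle from i was arrested at j at age ≤ d in
any spawning event (links of all strengths; self-loops excluded, since
self-supply is not replenishment of a disturbed sink). Direct reach is the
fraction of all reefs with ≥ 1 incoming edge from a robust source (each
sink counted once; a robust source counts only if itself supplied).
Colonisation steps are multi-source BFS distances from the robust set;
reach-within-k curves use the shortest incoming *walk of length ≥ 1* so
that k = 1 coincides exactly with direct reach. Union across events is
used because recolonisation can use any link in any year. The no-take
overlap is the fraction of robust sources flagged no-take.

## Problem sizes and what the tests show

The bundled demo runs 50 ordinary + 8 planted reefs, 4 spawning events,
3 competency curves (shapes 2, 5, 12) and 240 particles per reef — sizes
chosen so a laptop-class single core completes a full run in well under a
minute per event and the whole recovery experiment in minutes. Passing
recovery tests show that the pipeline's rules rediscover a planted
configuration whose structure matches the analysis' assumptions; they do
not show that any real reef system satisfies those assumptions. The
synthetic generator omits, among other things: realistic ocean physics
(tides, 3-D shear, upwelling), spatially correlated weather noise and SST
trends, larval behaviour, density dependence and fecundity scaling,
observation error structure in surveys beyond Tweedie noise, and spatial
autocorrelation of survey effort.

## Numerical choices

- RK4 on a bilinearly interpolated field is exact for constant fields and
  drifts < 0.1% in radius per period on solid-body rotation at hourly
  steps; halving dt moves unarrested endpoints by < 1 km over toy runs.
- Velocity components are built as discrete centred differences of the
  streamfunction, so the centred divergence cancels exactly (not just to
  truncation order) in the grid interior.
- Arrest distance ties break by (distance, reef index) with a 1e-12
  distance epsilon; sweep-rate ties break to the larger percentile with
  the same epsilon.
- Inflow shares into a sink with zero inflow are defined as 0; a
  single-reef region gets percentile 50 (mid-rank convention); a
  single-reef system gets stress rank 100 with a warning.
- All stage seeds derive from the run seed via SHA-256, keeping every
  derived seed below 2³¹; identical (config, seed) gives identical
  outputs, byte for byte.

## Known limitations

- The survey-validation statistics on real survey tables require the
  original survey data, which is not redistributable with the package;
  `cots_risk.load_survey_validation` ingests such a table (CSV/XLSX with
  reef id, max density, predicted supply class) when provided.
- The competency-weight formulation (gamma density vs CDF-based competent
  fraction) is an open modelling question; only the density form ships.
- Percentile-based rules are scale-free but not robust to heavy tie
  blocks: systems where most reefs receive exactly zero supply make the
  bottom-percentile classes degenerate (the synthetic inshore
  counter-current exists partly to keep the demo away from that regime).
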
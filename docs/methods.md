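# Methods

`scomber` is a spatially-explicit, super-individual (SI) simulator of
Northeast Atlantic mackerel (*Scomber scombrus*) population dynamics.  A
super-individual is an agent standing for many identical fish through an
abundance counter: mortality scales the abundance, and population metrics
(spawning stock biomass, weight-at-age, distribution maps) are obtained by
summarising SI state.  The model couples four sub-systems on a grid of
square sea-surface cells (default 60 km edge): bioenergetics, movement,
mortality, and recruitment, driven by gridded phytoplankton density, sea
surface temperature (SST), photoperiod and surface currents.

## The seascape

The grid spans a configurable extent (production default 47–77°N,
−45–20°E) with row 0 at the southern edge.  Each cell carries depth,
latitude/longitude, phytoplankton biomass X (g m⁻²), SST (°C), photoperiod
(fraction of 24 h), current velocities U, V (km h⁻¹), and the local
mackerel density D (g patch⁻¹, recomputed every step).  Masks define the
stock's geography:

- **shelf edge**: −550 m < depth < −50 m, the corridor along which the
  spawning and feeding migrations are constrained;
- **nursery area**: depth ≥ −200 m in the configured sector, where
  juveniles live;
- **overwintering area**: a configurable cell set (the synthetic default is
  the shelf-depth band at the corridor's northern end);
- **spawning area**: shelf-edge cells in the spawning sector with
  10 °C < SST < 14 °C (strict inequalities), recomputed whenever SST
  updates.

Migration routing uses a breadth-first-search hop count R from every ocean
cell to a destination cell, with land impassable and 4-neighbour
adjacency (the same adjacency the foraging model senses).  Unreachable
cells are flagged rather than erroring.

Forcing updates follow the data cadences: X and SST refresh as ten-day
composites (days 1, 11, 21, …), photoperiod and currents at each month's
start (photoperiod valued at the month's 15th day), fishing mortality-at-age
annually with monthly catch fractions.  The calendar ignores leap days:
365-day years in 73 five-day steps, with dated events bound to the step
containing them.

### Synthetic forcing

No gridded satellite/ESM inputs ship with the package, so a deterministic
generator supplies the study conditions.  Its defaults were chosen once to
reproduce the qualitative features the model's behaviour depends on, and are
not tuning knobs:

- SST: meridional gradient (0.5 °C per degree latitude from 15 °C at the
  southern edge) plus a seasonal cosine (amplitude 4 °C, peak August 1),
  with 0.05 °C observation noise.  This opens a 10–14 °C band in the south
  in early March that progresses northward through spring (so the
  northward spawning drift is exercised), and drops the far north below
  the 7 °C avoidance limit outside high summer.
- Phytoplankton: a Gaussian bloom in time (width 45 days) peaking in
  early summer, later and stronger at high latitude (amplitude 2.5 g m⁻²
  scaled by latitude above a 0.3 g m⁻² background), so the feeding
  migration into the north is rewarded.
- Currents: weak steady drift (U = 0.05, V = 0.03 km h⁻¹) with 20%
  spatial noise.
- Photoperiod: the closed-form CBM daylength model evaluated per latitude.

The synthetic bathymetry is a deep basin with an eastern landmass fringed
by a shallow shelf (−120 m) and a two-cell shelf-edge corridor (−300 m)
running the grid's full meridional extent; destination cells sit at the
corridor's southern end (spawning) and northern exit (feeding and
overwintering).

What the generator does *not* emulate: cloud gaps and regridding artefacts
of real composites, inter-annual circulation anomalies, realistic
coastline complexity, and any correlation between bloom timing and SST
anomalies.  Tests passing on this world demonstrate the mechanics and the
internal consistency of the model, not predictive skill on the real stock.

### Synthetic stock scale

Default initial numbers-at-age are N(a) = 10⁸ · e^(−0.35a) fish for ages
0–14.  The scale was chosen once so that, on the reduced grid, the
interference term c·D of the functional response operates in the same
regime as a realistically-sized stock on a realistically-sized grid
(c was calibrated at the real stock's per-patch densities; packing a
full-size stock onto a small corridor would put every cell deep into
interference and starve the population).  At this scale the stock
self-regulates: SSB grows until density-dependent food competition induces
starvation mortality, then oscillates.

## Bioenergetics

Mass is wet weight throughout; energies are kJ; rates are stored per day
and integrated over the step.  Two Arrhenius forms are used exactly as the
model defines them: ingestion and growth scale with the *relative* form
A(T) = exp(−(E_a/K)(1/T − 1/T_ref)), while the metabolic rates use the
*absolute* form exp(−E_a/(K·T)) folded into their normalizing constants.
T_ref is not prescribed anywhere; the default is 283.15 K (10 °C, the
middle of the spawning window) and it is configurable.

Per step and per SI, in order:

1. **Ingestion** (feeding stages only): a Beddington–DeAngelis response,
   IR = A(SST)·C_max·X/(X + h + cD)·M^(2/3) g day⁻¹, with D including the
   focal SI.  If a cannibalism victim is available (same cell, ≥3.5×
   smaller, and shorter than the 0.33 cm absolute cutoff — which as printed
   restricts prey to eggs and yolk-sac larvae; the cutoff is configurable),
   a fraction IR_cannibalism of the intake is fish prey valued at the
   victim's own lipid/flesh energy mix; the rest is phytoplankton at
   E_phyto.  Assimilation applies A_e.
2. **Maintenance**: standard metabolic rate a_SMR·M^0.75·e^(−E_a/KT)
   kJ day⁻¹, replaced (not augmented) by the active rate
   a_AMR·M^0.75·V·e^(−E_a/KT) on steps spent migrating (V = V_min) or
   foraging (V = realized swimming distance / time).  Maintenance is paid
   from assimilate first, then from the lipid store.
3. **Reproduction** (spawning adults): potential fecundity f_p = a_f·L^b_f
   is fixed on March 1; each of n_b = 5 batches costs
   b_max = f_p·M₀·(E_flesh + E_sf)/n_b and is provisioned at b_max/b_int
   per day over the 12-day inter-batch interval (5 × 12 = the 60-day
   season).  Provisioning draws on post-maintenance assimilate and then on
   the lipid store — the store exists to fund spawning through the winter
   fast — but never below a floor equal to the projected fasting
   maintenance until feeding resumes on May 1.  Short energy therefore
   shrinks batches (f_r < 1) rather than killing the spawner; a fish that
   still cannot pay maintenance starves as usual.  Males mirror the
   allocation computed from their own length so reproductive investment is
   equal between sexes; only females produce eggs.  Gonad mass equals the
   mass of the current batch and resets to zero at each release.
4. **Growth**: maximum length increments follow the first-season Gompertz
   law dL/dt = k₁·A·L·ln(L₁/L) until age 240 days and von Bertalanffy
   dL/dt = k·A·(L∞ − L) after, with k doubled for adults (they grow only
   while feeding, half the year).  Increments are integrated with the
   exact per-step solution of each law rather than an Euler step — the
   5-day Euler rate overshoots early Gompertz growth by several percent,
   while the exact map reproduces the analytic curves to machine
   precision.  Length maps to structural mass through M_struct = a_w·L^b_w
   (defaults a_w = 0.0049, b_w = 3.17, a typical scombrid length–weight
   relation; configurable) and growth costs ΔM(E_flesh + E_sf).  Growth is
   paid only from post-maintenance surplus; short energy scales ΔM down
   proportionally.
5. **Storage**: remaining surplus becomes lipid, paying E_sl per gram of
   lipid synthesised, capped at E_max·M_struct in lipid-mass terms (the
   "proportion of structural mass" reading of E_max, applied literally).
   Larvae prioritise growth and store nothing.  Deficits draw lipid at
   E_lipid per gram.

Eggs and yolk-sac larvae are treated as energy-sufficient: eggs only
accumulate development days (five days to hatch at L_hatch = 0.3 cm,
temperature-independent by design), and yolk-sac larvae grow at the
maximum rate at no cost until 0.61 cm.

Every step writes an energy ledger per SI: assimilated − maintenance −
growth − reproduction − storage-cost − discarded − Δreserve ≡ 0, with
unmet maintenance tracked separately.  The identity is exact by
construction and the test suite verifies closure below 10⁻⁹ kJ over
multi-year runs.  "Discarded" collects surplus rejected at the reserve cap
(and larval surplus); it is the only sink that is not a modelled tissue.

## Movement

Adults cycle annually: spawning migration from February 1, spawning with
northward drift March 1 – April 29, feeding migration from May 1, GAS
foraging through summer, overwintering migration from October 1, random
walk in the overwintering area through winter.  The fast runs from
November 1 until the end of spawning; feeding resumes with the May 1
departure.

- **Migrations** move an SI each step to the lowest-R cell within its
  search radius (V_min = a_v·L^b_v·A_r^c_v km h⁻¹ times the step length),
  ties broken uniformly at random; larger fish therefore arrive first.
  Spawning and feeding migrations are constrained to shelf-edge cells.
  The feeding migration ends at a stop distance drawn uniformly on
  0–10 cells from the feeding-area entrance (the distribution is not
  prescribed; uniform is the declared choice).
- **GAS foraging** runs daily (five sub-steps per step) in continuous
  space.  Each day: a directed half-day — keep yesterday's heading if the
  profitability cue c_dd = A(SST)·p_photo·X/(X + h + cD) improved,
  otherwise step along the cue gradient sensed from the four neighbouring
  cells at speed V_r = V_min(1 + ε), ε ~ U(0,1); a random half-day in a
  non-southward direction (uniform heading over the semicircle from due
  east through north to due west — the exact angular convention is ours,
  documented, not the source's); and passive current displacement
  (U, V × 24 h).  Cold cells (< 7 °C) have zero cue, reverse a random
  heading, and current displacement into cold or land is abandoned for
  the centroid of the nearest suitable cell.  Heading memory is one day,
  initialized from the gradient on the first feeding day.
- **Spawning drift**: after each batch an SI moves to the nearest cell
  strictly north of it with 10–14 °C water, falling back to a random
  in-window neighbour, else staying put.
- **Juveniles** random-walk within the nursery area; overwintering adults
  within the overwintering area (uniform choice among same-area cells in
  the search radius).

## Mortality and recruitment

Four channels: background (M_e = 0.287 day⁻¹ for eggs through larvae;
M_a·(L_mat/L) for juveniles; M_a = 4.1·10⁻⁴ day⁻¹ for adults), fishing
(annual F-at-age apportioned by mean monthly catch fractions and spread
evenly over each month's steps, applied uniformly in space), predation
(a cannibalising SI removes predator-abundance · IR·IR_cannibalism / prey
mass individuals per day from its victim), and starvation.  Background and
fishing convert to a surviving fraction e^(−(M+F)·Δt); SIs below one
individual are removed.

Starvation removal is interpreted as a *reduction* event: an SI is removed
when a deficit has run its lipid store and gonads to zero ("total mass
reduces to structural mass"), not merely for possessing zero reserves —
otherwise every larva reaching juvenile size with an empty store would be
removed on arrival.  Larvae are exempt until their first successful meal.

Recruitment is emergent by default: each female's realized eggs enter the
model as egg SIs at the spawners' batch locations, with each of the five
batch events funding an equal share of the year's n_cohort new SIs sized
to that event's egg production (the annual count is fixed; the within-
season split is the package's choice).  Recruitment is censused as
young-of-the-year abundance on December 31.  A Ricker alternative
R = α·SSB·e^(−β·SSB + γ·SST̄) with user-supplied coefficients (no
defaults) replaces the egg/larval stages and inserts recruits on
December 31; SST̄ averages over the spawning-area mask.

During the ten-year spin-up, recruitment is forced: n_cohort juveniles of
length L₁ − 3ε (ε ~ U(0,1), hence 17–20 cm) enter each December 31 with
abundance from the configured series, and emergent egg entries are
suppressed (spawning energetics still run, so egg production is still
reported).

## Scheduling and reproducibility

Each step runs the twelve phases in fixed order (forcing; monthly/annual
updates; mortality; movement; energy budgets; stage progression with the
February 1 maturation census; March 1 fecundity; the spawning module;
new-SI entry; ageing; recording), with SI processing order reshuffled
every step.  One master seed derives independent streams for the shuffle,
initialization, and forcing, plus a private stream per SI keyed by (seed,
SI id) — so the death of one SI never shifts another's draws, and runs
replay bit-for-bit from a seed and configuration.

## Calibration and validation

- **Rejection ABC** for (h, c, M_e), the three constants with no
  literature value: uniform priors, n simulations with parameters drawn
  independently (optionally Latin hypercube for small n), cost = sum of
  squared deviations from the target SSB and weight-at-age series with
  each dataset normalized by its own variance (the normalization scheme
  is declared, not prescribed, and swappable), best fraction accepted as
  the posterior sample.  The same child seed drives every draw so cost
  differences reflect parameters alone.  Prior bounds used in the
  recovery experiment — h ∈ (0.5, 2.5) g m⁻², c ∈ (10⁻¹¹, 3·10⁻¹⁰),
  M_e ∈ (0.15, 0.45) day⁻¹ — are declared defaults bracketing the
  published point values, not the original study's bounds.
- **Distribution skill**: predicted July/August density maps are pooled
  across years with presence/absence observations; an exhaustive scan
  over every observed density value (the candidate set that exhausts all
  distinct confusion tables) picks the threshold maximizing Youden's
  J = sensitivity + specificity − 1 (accuracy is selectable), then
  sensitivity and specificity are reported.

## Problem sizes used by the test suite

The reduced test world is a 40×40 grid with 105 SIs (7 per age class —
the production validator's 1050-multiple rule is relaxed only behind an
explicit test-scale flag), two spin-up years plus three main years.  The
ABC recovery experiment uses 200 draws at 5% acceptance against
pseudo-data generated at the known truth with 5% observation noise.  The
acceptance script's spin-up check uses 2100 SIs for ten spin-up years
(1400 forced recruits).  These sizes are the package's declared
experimental design for desk-scale verification.

## Known limitations

- Eggs and larvae do not drift with currents; they sit at the spawning
  location until juveniles relocate to the nursery.
- Movement outside the summer GAS phase is cell-discrete.
- The cannibalism prey-length cutoff is applied as printed (0.33 cm),
  which restricts predation to eggs and yolk-sac larvae.
- Fishing is spatially uniform within an age class.
- The synthetic world is a scaled stand-in; none of its outputs are
  comparable to assessment or survey values for the real stock.
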
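# Methods

`expochain` implements a desk-scale, fully synthetic version of an integrated
source-to-internal-dose exposure assessment for agricultural pyrethroids
(cypermethrin and deltamethrin, sharing the urinary metabolite 3-phenoxybenzoic
acid, 3-PBA). The chain runs on a common reference grid (default 2 km cells,
i.e. 4 km² support, weekly time step) and couples six stages: synthetic region
generation → emissions and atmospheric dispersion → geostatistical mapping of
monitored media → multimedia transfer to soil and local foods → multi-pathway
dose aggregation → PBPK conversion to urinary 3-PBA, followed by
exposure-inequality indicators (annual maps, hotspots, parent contributions,
grid-resolution diagnostics, point estimation).

## Synthetic study region

The generator emulates the statistical structure of an arable NW-European
region, not any real dataset:

* **Grid.** Row-major regular grid, half-open cells, cell-centre support for
  all fields. Default 50×50 cells of 2000 m.
* **Parcels.** Rectangular parcels (side 200–800 m) with crops drawn from a
  configurable mix over {apple, lettuce, potato, tomato, cereal}; per-parcel
  annual applied mass per substance is lognormal (σ = 0.5 on the log scale)
  around a configurable mean (default 3 kg/yr cypermethrin, 0.8 kg/yr
  deltamethrin — the cypermethrin excess drives its dominant share of 3-PBA).
* **Application schedule.** Each parcel's annual mass is split equally over
  `events_per_parcel` tri-hourly slots drawn uniformly from the crop's
  spreading window; the schedule re-aggregates to the annual totals exactly
  (this uniform rule is a modelling choice; no empirical disaggregation rule
  is available at desk scale).
* **Meteorology.** 3-hourly series: Weibull wind speeds (shape 2, scale
  4.5 m/s) floored at 0.5 m/s (a Gaussian plume is undefined at u = 0;
  flooring calms is standard regulatory practice), von Mises directions around
  a prevailing 225°, sinusoidal annual temperature, Bernoulli–exponential
  precipitation, and cloudiness in octas. Pasquill stability classes A–F come
  from a documented lookup on (wind speed, daytime flag, cloudiness).
* **Monitoring.** Stations sample gridded "true" fields with multiplicative
  lognormal error (σ = 0.3); each draw is compared to the station's LOD/LOQ
  to assign `quantified`, `detected_below_LOQ` or `non_detect` status. Only
  quantified samples carry values.
* **Population.** Voronoi municipalities around random seats with lognormal
  totals; each cell carries its municipality's total as its urban-unit size.

## Emissions and dispersion

Each application is partitioned among **soil, plant canopy and airborne
drift**. The default rule scales the per-crop base drift fraction linearly
with wind speed (capped at 0.5) and renormalizes soil/plant proportionally; a
constant-table mode bypasses the wind dependence. Plant and soil stores then
volatilize with first-order kinetics (defaults 0.04/h and 0.01/h) over a
short post-application horizon (default 4 three-hour steps); the residual
soil store feeds the topsoil compartment directly.

Airborne emissions disperse with a steady-state **Gaussian plume**
(Pasquill–Gifford class curves in the Briggs open-country form, full ground
reflection, receptor at ground level, source height 1 m ≈ spray boom):

    C(x, y)/Q = 1 / (2π u σy σz) · exp(−y²/2σy²) · 2 exp(−H²/2σz²)

Particles deposit with a constant dry-deposition velocity (default
0.005 m/s); wet deposition and any chemical transformation are out of scope
(passive-tracer assumption). The gas/particle split of drift is a
substance-specific constant (default 0.5).

### Dispersion metamodel

The plume solution above is the in-repo *teacher*; a fast statistical
emulator (extremely randomized trees) reproduces it so that thousands of
parcel-events can be superposed cheaply, preserving the learn-then-superpose
architecture. Three design choices matter:

1. **Wind speed is factored out, not learned.** The teacher scales exactly as
   1/u, so the learner's target is log₁₀(u · dilution) and predictions divide
   by u. This removes all interpolation error in wind speed.
2. **Crosswind is normalized by the plume width**: the feature is
   |y|/σy(class, x), making the log-dilution surface smooth in feature space;
   half the training receptors sit on the centerline (the kernel peak).
3. **Trained support is enforced at prediction**: kernels are zero upwind,
   beyond the configured range (default 20–30 km) and beyond 4 plume widths
   crosswind (where the Gaussian factor is < 4·10⁻⁴ of centerline).

With the default training database (40 met conditions × 600 receptors) the
held-out R² on log-dilution exceeds 0.99 and whole-field errors against the
teacher are a few percent. Superposed fields are exactly linear in emitted
mass because mass multiplies a per-kg unit field outside the learner.

## Geostatistical mapping

Sparse censored monitoring data are carried to the grid with:

* **Empirical 2D variograms** (Matheron estimator) with optional directional
  binning; **anisotropy** is declared when the max/min fitted directional
  range ratio exceeds 1.5 and is handled by rotation + scaling before
  isotropic kriging.
* **Variogram fitting** by weighted least squares (Cressie weights
  N(h)/γ²), family chosen among spherical/exponential by the achieved
  objective. Pure-nugget data pin the structure to ~0 or the range to its
  bound (documented convention).
* **Ordinary kriging** (global neighbourhood up to 500 samples, 32 nearest
  beyond), exact at data points with zero nugget; duplicate locations are
  averaged with a warning.
* **External-drift kriging** with the mean affine in an auxiliary covariate
  (a standardized combination of log annual emissions, log population and
  synthetic altitude, weights configurable); a constant auxiliary degrades
  exactly to ordinary kriging.
* **Regression-kriging**: random-forest trend + ordinary kriging of the
  residuals, for nonlinear covariate relations.
* **Censoring scenarios**: lower bound (non-detect → 0, detected-below-LOQ →
  LOD) and upper bound (non-detect → LOD, detected-below-LOQ → LOQ); the UB
  series dominates LB elementwise by construction.
* **Bootstrap EM** for left-censored multivariate normal (log-scale) samples:
  the E-step uses exact univariate truncated-normal conditional moments when
  a row has one censored coordinate (the dominant case at realistic detection
  frequencies); rows with several censored coordinates condition each
  censored coordinate on the observed ones sequentially — an approximation
  that ignores cross-truncation terms. The observed-data log-likelihood is
  asserted nondecreasing (numerical tolerance 10⁻⁶ relative); convergence at
  10⁻⁶ relative change or 500 iterations. Station bootstrap refits the EM and
  draws imputations from the conditional truncated normal, giving multiple
  imputed datasets.

In the orchestrated chain, LB/UB substitution is applied **before**
interpolation and kriging runs on the linear scale (LB substitution produces
zeros, which a log transform cannot carry; the log option remains available
on the standalone functions). Soil baselines are mapped with external-drift
kriging, tap water with ordinary kriging; market-food residues are aspatial
(LB, UB) means of a simulated censored residue survey. The EM estimator is
exercised and validated at method level; plugging it into the chain in place
of LB/UB substitution is a configuration-level extension, not wired by
default.

## Multimedia transfer

Mass balance with first-order kinetics throughout:

* **Soil**: dC/dt = (D + A)/(ρ d) − k_s C solved in closed form per weekly
  step (defaults: mixing depth 0.2 m, bulk density 1300 kg/m³, dissipation
  0.023/d ≈ 30-d half-life).
* **Crops**: per crop a linear compartment system (≤ 5 of root, stem, leaf,
  fruit, tuber) with week-dependent biomasses, inter-compartment transfer
  coefficients, first-order losses, Beer–Lambert canopy interception of
  deposits 1 − e^(−k_int·LAI(t)), and root uptake proportional to soil
  concentration and root biomass. Integration is exact per weekly step via
  the matrix exponential of the augmented system; because the system matrix
  depends on the week but not the cell, weekly propagators are computed once
  per crop and applied to all grid cells as a matrix recursion.
* **Harvest**: edible-compartment mass over edible biomass at harvest
  (apple/tomato → fruit, potato → tuber); lettuce is harvested year-round,
  so weekly concentrations are averaged with LAI-proportional weights
  w_k = LAI_k/ΣLAI (the harvest-probability weighting; an LAI-derivative
  variant was considered and not adopted).
* **BCF mode**: C_plant = BCF_air·C̄_gas + BCF_soil·C̄_soil on
  cultivation-period means, as the fast alternative to the dynamic model.

All default crop parameters (transfer coefficients, biomass and LAI curves,
BCFs) are *illustrative magnitudes*, clearly not measured values; the
configuration table is the interface for realism.

## Exposure aggregation

Weekly external doses per cell combine ingestion and inhalation (the dermal
slot exists in the PBPK input and is held at zero):

    dose = [ Σ_f IR_f (sc_f·C_local,f + (1−sc_f)·C_market,f)
             + IR_w·C_water + IR_s·10⁻⁶·C_soil ] / BW        (mg/kg bw/d)

The self-consumption fraction sc_f depends on the cell's urban-unit class
(1: < 2000 inhabitants, 2: [2000, 10 000), 3: [10 000, 100 000), 4: ≥ 100 000
— left-closed boundaries) with defaults 0.35/0.25/0.12/0.03. The inhalation
concentration is the sum of gaseous and particulate forms. The default
profile is an adult pregnant woman (67 kg, 1.5 L/d water, 50 mg/d soil,
13.3 m³/d air, ~0.25 kg/d of the four local food groups).

## PBPK

A flow-limited compartment model (default 23 tissues + one urinary metabolite
compartment): dA_i/dt = Q_i(C_art − A_i/(V_i·P_i)), venous mixing
ΣQ_iC_v,i/Q_c, oral input (×f_abs) to the liver, inhaled input mixed into
arterial blood, hepatic metabolism CL_int on the free liver concentration. A
fraction f_m of metabolized parent becomes 3-PBA (molar-mass corrected),
drains to urine at k_u and is reported as the 24-h-average-equivalent
concentration over the averaging window via the daily urine flow F_u
(1.5 L/d). Mixture additivity of 3-PBA across parents gives contribution
shares U_p/ΣU_q.

Kinetics are linear at environmental doses, so weekly piecewise-constant
forcing is integrated exactly with matrix exponentials; the weekly propagator
is computed once and applied to all grid cells simultaneously (a 26-state
recursion vectorized over 2500 cells). Cumulative absorbed, metabolized and
excreted masses are tracked as extra states, giving a closed mass-balance
audit (≤ 0.1% relative by contract; ~10⁻¹⁵ in practice). The default
physiology (60 L, 330 L/h cardiac output over 23 illustrative tissues,
uniform partition coefficients of 3) has literature-style structure but is
*not* a calibrated parameterization; substance parameters (f_abs, f_m,
CL_int, molar masses) are configurable per substance.

## Indicators

* **Annual maps**: unweighted means of the 52 weekly urinary layers, per
  censoring scenario; UB ≥ LB propagates from the market/monitoring inputs
  through every linear stage.
* **Hotspots**: cells at or above a percentile of the map's nonzero values,
  ties included.
* **Resolution diagnostic**: variogram fit to (a ≤ 400-cell subsample of) an
  air input field; recommends the largest cell size ≤ range/4; flat fields
  support any resolution; fields whose fitted structure is > 80% nugget (or
  range < 2 cells) support none.
* **Point estimation**: ordinary kriging from nearby cell centres with the
  fitted variogram made nugget-free (maps are noise-free model output, so the
  estimator should interpolate exactly at cell centres); bilinear fallback.

## Determinism, persistence, problem sizes

Every stage draws from a generator seeded by a (seed, stage-index) spawn of
the master seed, so a fixed (config, seed) reproduces every array bit for
bit. With `outdir` set, the expensive stages (dispersion fields, urinary
cubes) persist as `.npz` plus JSON manifests keyed by a configuration/seed
hash, and a re-run resumes from them.

Default problem sizes were chosen so that a full study — 50×50 cells, 52
weeks, 2 substances, ~200 parcels, ~800 application events — runs in well
under a minute on one CPU: the metamodel evaluates one kernel per unique
(parcel, time-step) pair shared across phases and substances, and the crop
and PBPK recursions are vectorized across cells.

## What the synthetic conditions do and do not show

Passing tests demonstrate the internal correctness of each stage (closed
forms, independent ODE and linear-algebra oracles, parameter-recovery and
censoring simulations with known truth) and the integration contracts
(linearity, non-negativity, scenario ordering, determinism). They do **not**
validate the parameter values against field data: real regions have
irregular parcels, spatially correlated application practices, non-Gaussian
plume behaviour (calms, inversions, terrain), measured crop transfer
parameters and calibrated PBPK physiology. The synthetic region reproduces
the *statistical shapes* of those inputs, not any territory.

## Known limitations

* Wet deposition, photolysis/reaction, and building/terrain effects are out
  of scope (passive tracer, flat rural dispersion).
* The EM E-step is approximate for rows with ≥ 2 censored coordinates.
* The chain's in-grid soil/water mapping uses LB/UB substitution + kriging;
  the bootstrap-EM path is validated standalone but not wired into the
  default chain.
* Crop and PBPK parameter defaults are illustrative; absolute output
  magnitudes should not be interpreted as predictions for any real region.
* Dermal exposure is carried as a zero-filled input slot only.
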
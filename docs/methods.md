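# Methods

This note documents the models, numerical choices and limitations behind
`metalburden`. The pipeline has four stages — receptor modelling, toxicity
and exposure, burden accounting, aggregation — driven either by measured
concentration panels or by the package's synthetic generator.

## Receptor model (uncertainty-weighted PMF)

**Model.** A panel `X` (n time points × m species, ng/m³) is factorised as
`X ≈ G F` with `G ≥ 0` (n × p source contributions) and `F ≥ 0` (p × m
source profiles), minimising

    Q = Σᵢ Σⱼ ((xᵢⱼ − Σₖ gᵢₖ fₖⱼ) / uᵢⱼ)².

Scale is fixed by the convention that each row of `F` sums to 1, with the
scale pushed into `G`; this reparameterisation leaves `G F` (and hence `Q`)
unchanged and makes `G` interpretable as each source's mass concentration.

**Uncertainties.** Following standard receptor-model practice:
below-detection cells get `u = (5/6)·MDL`; quantified cells
`u = √((ε·c)² + (0.5·MDL)²)` with error fraction ε = 0.05 by default;
missing cells are median-substituted and weighted down with
`u = 4 × species median`, so they contribute almost nothing to `Q`.
Below-MDL concentrations are substituted by MDL/2. Substitution happens in
exactly one place (the model's working matrix); panels store raw values and
flags only.

**Solver.** Alternating nonnegative least squares: each iteration solves
every row of `G` and every column of `F` exactly (NNLS on 1/u-scaled
systems). Because each half-step is an exact minimisation of `Q` over a
block, descent is monotone, and on exact low-rank data the iteration
reaches essentially machine-precision residuals within a few hundred
sweeps. Defaults: p = 5 factors, 20 restarts from seeded random starts
(best-`Q` restart wins, ties to the lowest restart index), 300 iterations
per restart, relative-`Q` tolerance 1e-8. For very ill-conditioned weighted
systems the NNLS call falls back to bounded least squares (BVLS). A
`Q/Q_expected` scan over candidate p is available as a diagnostic, with
`Q_expected = n·m − p·(n+m)`.

**Factor labelling.** Each factor is scored against the five source
categories by the mean profile share over that source's tracer elements
(vehicle: Cu/Zn/Pb/Mn; fuel oil: Ni/Cr; industrial: Cd/Ag/Pb/As/Sn/Sb/Cr;
dust: Ca/Ba/Si; coal & biomass: K/As/Pb/Hg), and labels are assigned
one-to-one by maximising the total score. Exact ties resolve
deterministically in the order dust, coal/biomass, vehicle, industrial,
fuel oil. Labels are advisory; no computation depends on them.

**Known limitation.** Rotational-ambiguity exploration (FPEAK-style) and
bootstrap/displacement error estimates are not implemented. The factor
solution is as rotationally determined as the data make it (see below).

## Synthetic-data generator

The generator emulates a multi-city metal-speciation monitoring campaign:

- **Profiles**: five row-stochastic source profiles built from the tracer
  structure above, with a small cross-contamination floor (0.002 per
  off-tracer species), seeded multiplicative jitter (σ = 0.05), and a
  redraw guard keeping all pairwise cosine similarities below 0.9.
- **Contributions**: independent lognormal daily source activities with
  mean levels (vehicle 400, fuel oil 120, industrial 150, dust 900,
  coal/biomass 800 ng/m³ of summed metal mass) chosen so species means land
  in realistic ranges — K and Ca in the hundreds of ng/m³, Cd and Cr in the
  units to tens. The activity coefficient of variation is 1.5 (geometric SD
  near 3): daily source impacts are episodic, with near-quiescent days.
  This intermittency matters beyond realism — it is what anchors the
  rotation of the factorization. Strictly positive, low-variability
  contribution columns admit nonnegative rotations `G T⁻¹, T F` that fit as
  well as the truth, and a generator without episodic behaviour produces
  panels whose factorisation is *not* identifiable, however good the solver.
- **Regimes**: inland sites are dustier (dust × 1.3, coal × 1.2) and their
  coal/biomass activity is multiplied by (1 + amplitude), default 1.8×,
  during the heating season (15 Nov – 15 Mar inclusive, configurable);
  coastal sites carry elevated fuel-oil activity (× 2.5) and less dust.
- **Observation**: multiplicative lognormal noise with mean 1 and
  coefficient of variation `noise_cv` (default 0.05, which makes the 5%
  error-fraction uncertainty model approximately well calibrated); MDL
  censoring flags (true values retained internally for oracle use); random
  missingness (default 2%).
- **MDLs**: per-species fractions of the expected mean — 0.30 for Cd and
  Ag, 0.16 for Hg (near-single-source, hence more episodic), 0.02
  elsewhere — sized so roughly 5–10% of Cd/Ag/Hg observations censor while
  the fit is not dominated by censored cells.
- **Seeding**: one master seed; deterministic substreams per site and per
  generator stage.

For attribution experiments, `make_attribution_truth` builds a sharper
world: profiles without the contamination floor (structural zeros), one
metal (Cd by default) emitted by a single source, sources genuinely off on
15% of days, and uniformly small MDLs (2% of mean). Under these conditions
the exact factorization is essentially unique, so the pipeline's
attribution of that metal can be compared against a near-certain truth.
Large MDLs would defeat this: censoring substitution (MDL/2) places
artificial mass on days the emitting source is off, which the model must
assign to *other* sources — a real bias of substitution-based PMF, visible
here because the truth is known.

**What passing synthetic tests does not show.** The generator draws source
activities independently across sources and days (no meteorology, no
autocorrelation, no covarying sources), uses a single noise CV for all
species, and draws its toxicity/DALY/population tables from deterministic
synthetic fixtures. Recovery results on these panels demonstrate the
correctness of the estimator and pipeline plumbing, not performance on real
atmospheres, where correlated sources and structured noise make
factorisations harder and rotationally more ambiguous.

## Toxicity and exposure

Endpoints with a published inhalation unit risk (IUR, per μg/m³) use it
directly. Otherwise the chain `NOAEL = LOAEL/3.81`, `BMC10 = 1.96·NOAEL`,
`IUR = 0.10/BMC10` converts a LOAEL (μg/m³) into a unit risk at the 10%
benchmark response.

Exposure concentrations are fractions of the ambient mean `C` (ng/m³):

- non-carcinogenic: `EC_nc = C·EF·ED/AT` with EF = 350 d/yr, ED = 30 yr,
  AT = 30×365 d (so `EC_nc ≈ 0.959·C`);
- carcinogenic: `EC_c = C·EF·(ED_<2·ADAF_<2 + ED_2–16·ADAF_2–16 +
  ED_>16·ADAF_>16)/LT` with durations 2/14/14 yr, ADAFs 10/3/1 and
  LT = 79.18×365 d. The ADAF-weighted bracket is 2·10 + 14·3 + 14·1 = 76 yr
  (so `EC_c ≈ 0.920·C`). The 14-yr adult duration is kept as the default
  deliberately (it is the convention this pipeline reproduces) and is
  configurable.

`C` is the calendar-year arithmetic mean of non-missing observations with
below-MDL values at MDL/2. EC stays in ng/m³; the single ng→μg conversion
(×10⁻³) is applied inside the excess-case product and nowhere else, so no
double conversion is possible.

## Burden accounting

Per disease, `DALY_ind = YLL/N + YLD/P` (years lost per death plus years
lived with disability per prevalent case, from GBD-style totals — N and P
are interpreted as deaths and prevalent cases, configurable per record).
Excess cases are `NP = EC·IUR·TP`; annualised burden is
`BOD = Σ NP·DALY_ind/A`, dividing the lifetime-scale case count by life
expectancy A (79.18 yr default). Carcinogenic endpoints use `EC_c`,
non-carcinogenic `EC_nc`; a metal–disease pair is one or the other, never
both.

**Source attribution** splits each per-metal burden row proportionally to
that metal's per-species source shares from the receptor model,
`share(k, j) = ḡₖ·fₖⱼ / Σₖ' ḡₖ'·fₖ'ⱼ`. This is exact, not approximate,
because every burden quantity is linear in `C`, hence in each source's
contribution to it — a methodological interpretation this package makes
explicit rather than inheriting from any particular software.

**Stratification** splits burden by population fraction × relative DALY
weight per sex/age stratum, renormalised so the stratum set sums exactly to
its total. Only weight-based splitting is implemented (no stratum-specific
unit risks).

**Aggregation** produces the city × year DALYs-per-1000 matrix; the yearly
mean is unweighted over cities reporting that year, and multi-year city
means ignore missing years.

No uncertainty intervals are propagated onto DALYs; outputs are point
values.

## Numerical and testing choices

- Tolerances: `F` row sums to 1 within 1e-9; solver-reported `Q` must match
  a brute-force double loop within 1e-8 relative; split/total conservation
  within 1e-9 relative; doubling all concentrations doubles every burden
  entry exactly in floating point (all operations commute with
  multiplication by 2).
- Degenerate factors (all-zero profile rows) are reset to uniform with zero
  contribution before renormalisation.
- Test problem sizes: recovery and noise-free exactness run at 500 time
  points × 17 species with 10 restarts; attribution experiments at 400 time
  points; unit tests use 120-day panels and toy matrices small enough for
  brute-force oracles.
- Property tests (hypothesis, derandomised) cover exposure linearity, the
  IUR–LOAEL monotonicity, and `Q` against the brute-force oracle on random
  instances.
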
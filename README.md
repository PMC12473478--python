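# metalburden

Source apportionment and disease-burden assessment for PM2.5-bound metals.

Ambient fine particulate matter carries trace metals (Pb, Cd, Cr, Ni, As, …)
whose toxicity is large relative to their mass. Air-quality and public-health
analysts need to answer two linked questions: *which emission sources put
each metal into the air*, and *how much population health is lost to each
metal, disease and source*. `metalburden` implements that chain as a tested,
reusable pipeline:

1. **Receptor modelling** — uncertainty-weighted positive matrix
   factorization (PMF). A concentration panel `X` (time × species, ng/m³) is
   decomposed as `X ≈ G F` with nonnegative source contributions `G` and
   row-stochastic source profiles `F`, minimising the weighted residual sum
   of squares `Q = Σᵢⱼ ((xᵢⱼ − Σₖ gᵢₖ fₖⱼ)/uᵢⱼ)²`. Cell uncertainties follow
   the EPA conventions: `u = (5/6)·MDL` below the detection limit, otherwise
   `u = √((0.05·c)² + (0.5·MDL)²)`. Factors are labelled (vehicle, fuel oil,
   industrial, dust, coal/biomass) by their tracer elements.
2. **Toxicity and exposure** — endpoints lacking a published inhalation unit
   risk derive one via `NOAEL = LOAEL/3.81`, `BMC10 = 1.96·NOAEL`,
   `IUR = 0.10/BMC10`; lifetime-averaged exposure concentrations are
   `EC_nc = C·EF·ED/AT` and the ADAF-weighted `EC_c = C·EF·(ΣᵦEDᵦ·ADAFᵦ)/LT`.
3. **Burden** — excess cases `NP = EC·IUR·TP`, per-case severity
   `DALY_ind = YLL/N + YLD/P`, annualised burden `BOD = Σ NP·DALY_ind/A`,
   with exact proportional attribution of burden to emission sources (valid
   because every step is linear in concentration) and sex/age stratification.
4. **Aggregation** — city × year DALYs-per-1000 summaries with
   missing-year-aware means.

A seeded synthetic-data generator produces multi-city panels with known
ground-truth sources (inland/coastal regimes, heating-season coal elevation,
lognormal noise, MDL censoring, missingness), so every stage is testable
without any external download.

## Worked example

```python
import metalburden as mb

panel = mb.generate_panel(site_id="demo", region_class="inland",
                          n_times=500, noise_cv=0.05, seed=1)
u = mb.build_uncertainty(panel)                    # EPA uncertainty rules
model = mb.fit_pmf(panel, u=u, p=5, restarts=10, seed=1)
print(f"Q = {model.Q:.0f}  (Q/Qexp = {model.Q / model.Q_expected:.2f})")
print(mb.label_factors(model.F))
pairs, cos = mb.match_factors_to_truth(model.F, panel.truth.profiles)
print(cos.round(3))
```

prints

```
Q = 3984  (Q/Qexp = 0.67)
['vehicle', 'dust', 'fuel oil', 'coal/biomass', 'industrial']
[1.    1.    0.988 1.    1.   ]
```

The fitted `Q` sits below the degrees-of-freedom proxy `Q_expected`
(n·m − p·(n+m)), as expected when per-cell uncertainties are realistic; the
five factors are recognised from their tracer elements; and each recovered
profile matches its ground-truth source with cosine similarity ≥ 0.98.

From there, annual means feed the burden chain:

```python
tox = mb.make_toxicity_fixture()
weights = mb.make_daly_fixture()
pop = mb.make_population_fixture()[0]
conc = {sp: mb.annual_mean_concentration(panel, sp, 2022) for sp in panel.species}
table = mb.burden_for_city_year("demo", 2022, conc, tox, weights, pop)
shares, _ = mb.source_contribution_shares(model)
shares.columns = mb.label_factors(model.F)
table = mb.attribute_burden_to_sources(table, shares)
print(table.data[table.data.source == "total"]["dalys"].sum())
```

which prints `159786.21133654626` — the annualised burden in DALYs summed
over all metal–disease endpoints for this synthetic city of 9.2 million
(≈ 17 DALYs per 1000; the magnitude reflects the synthetic fixture toxicity
table, not any real population).

The full pipeline (panels → PMF → exposure → burden → summary, with a
checksum manifest) runs from a YAML config via the CLI:

```bash
metalburden simulate --sites 2 --days 365 --seed 1
metalburden run config.yml
```

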
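# cryosip

Single-cell and bulk stable-isotope-probing (SIP) analysis for glacier ice
algae — from ion-count images or isotope-ratio tables to assimilation rates,
growth rates, doubling times, C:N:P stoichiometry, and error-propagated
estimates of the algal contribution to community nutrient uptake.

## The problem

Dark-pigmented glacier ice algae (*Ancylonema* spp.) bloom on bare glacial
ice, lower its albedo and accelerate melt. Whether nutrient availability
limits these blooms is addressed experimentally with dual-label tracer
incubations: meltwater communities receive ¹³C-bicarbonate and ¹⁵N-labelled
NH₄⁺ or NO₃⁻, and the label appearing in bulk particulate organic matter
(EA-IRMS) and in individual cells (HR-SIMS ion imaging) is converted into
rates. This package implements that full calculation chain as a tested
library with a thin CLI, plus a synthetic-experiment generator that produces
ground-truthed cell tables, bulk tables, pool tables, SEM-EDS tables and
Poisson ion-count images, so every stage of the pipeline is verifiable
without access to field data.

## The model

All quantities are atom% (100 · heavy/(heavy+light)); the tracer signal is
the **atom% excess** *E* = atom% − natural abundance. For a source pool with
excess *E*<sub>pool</sub>, biomass (bulk POM or one cell) with excess
*E*<sub>bio</sub>, biomass pool *B* (µmol L⁻¹, or the cellular quota in
pmol cell⁻¹) and incubation length Δ*t* (days):

- assimilation rate = (*E*<sub>bio</sub>/*E*<sub>pool</sub>) · *B*/Δ*t*
- growth rate μ = log₂[*E*<sub>pool</sub>/(*E*<sub>pool</sub> −
  *E*<sub>bio</sub>)]/Δ*t*  (exponential growth; μ = 1 day⁻¹ is one
  doubling per day), doubling time = 1/μ
- relative contribution (%) = 100 · (rate<sub>cell</sub> ·
  *N*<sub>cell</sub>)/rate<sub>bulk</sub>, with *N*<sub>cell</sub> the
  active-cell abundance (cells L⁻¹); its one-sigma uncertainty combines the
  relative SDs of the three factors in quadrature.

Pool excess after tracer addition is the concentration-weighted mixture of
the label and the ambient pool; end-of-incubation rates use the mean pool
excess of the two sampling points. Cellular carbon quotas follow biovolume
(cylinder) → dry weight (buoyant density 1160 kg m⁻³ × dry fraction 0.28) →
content (median dry-mass fractions C 0.72, N 0.04, P 0.04 over atomic
masses). A cell counts as active when its ¹³C atom% exceeds the natural
mean plus 3 SD of unlabelled cells (1.158 atom% with the default baseline).

## Worked example

```python
import cryosip as cs

# mix 10 µM of 98 atom% 15N tracer into a 0.05 µM ambient NO3- pool
pool = cs.tracer_pool_mixing(0.05, 0.36, cs.TracerAddition("N", 10.0, 98.0))
print(round(pool.atom_percent_excess, 2))      # 97.15

# bulk growth from a POM excess of 1.64 atom% against a 3.9 atom% pool
mu = cs.growth_rate(excess_pool=3.9, excess_biomass=1.64, dt=1.25)
print(round(mu, 3), round(cs.doubling_time(mu), 2))   # 0.63  1.59

# bulk C assimilation at 2849 µmol C L^-1 POC
print(round(cs.bulk_assimilation_rate(1.64, 3.9, 2849.0, 1.25), 1))  # 958.4

# algal share of bulk DIC uptake, with propagated uncertainty
n_active, _ = cs.active_abundance(cs.AbundanceEstimate())   # 16.2e3/ml, 90%
pct = cs.contribution(4.6, n_active, 448.0)
sd = cs.propagate_contribution_uncertainty(
    pct, (4.6, 3.46), (16.2e3, 1.2e3), (448.0, 101.0))
print(f"{pct:.1f} +/- {sd:.1f} %")             # 15.0 +/- 11.8 %
```

A full synthetic experiment through the pipeline:

```python
sim = cs.simulate_experiment(cs.SimulationConfig(seed=42))
cs.write_experiment(sim, "exp")
res = cs.run_pipeline(cs.RunConfig(), "exp", "exp/out")
print(res["contribution"].round(2).head(4).to_string(index=False))
```

```
substrate timepoint abundance_source  percent  sd_percent
      DIC        T1           counts    12.08        7.87
      DIC        T1    poc_corrected    11.03        7.18
      DIC        T2           counts    12.62        5.68
      DIC        T2    poc_corrected    11.82        5.33
```

The active-population summary for the unamended treatment at the end of the
incubation (mean cell fixation 7.2 pmol C cell⁻¹ day⁻¹, growth
0.50 ± 0.22 day⁻¹ over 31 cells for this seed) mirrors how single-cell SIP
results are reported: means ± SD over the active fraction, with the
all-cells variant written alongside.

The same stages are available from a shell:

```bash
cryosip simulate --seed 42 --out exp
cryosip run --input-dir exp --out exp/out
cryosip compare --table exp/out/cell_rates.csv --value-col c_growth_d
```

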
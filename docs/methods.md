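# Methods

## Isotope model and its assumptions

Every rate in cryosip derives from a two-member mixing model: biomass built
before tracer addition carries the natural heavy-isotope abundance, biomass
built during the incubation carries the source pool's atom%. With pool
atom% excess *E*_pool and biomass excess *E*_bio after Δt days,

    assimilation = (E_bio / E_pool) · B / Δt
    µ = log2[E_pool / (E_pool − E_bio)] / Δt,     doubling time = 1/µ

The growth form assumes (i) exponential growth, (ii) that all newly
incorporated label reflects biomass increase (no correction for storage,
turnover or repair), and (iii) a well-mixed source pool whose uptake does
not fractionate isotopes. Rates are net over the incubation window; any
label fixed and re-respired within Δt is invisible. Atom% lives on the
0–100 scale everywhere in the package; isotope fractions (0–1) appear only
at SIMS I/O boundaries and are converted on read.

When the pool label declines between the two samplings, end-of-incubation
(T2) rates use the arithmetic mean of the T1 and T2 pool excess, while T1
rates use the T1 value. This two-point average is an approximation to the
flux-weighted mean label actually experienced by the cells; the synthetic
generator lets tests quantify the resulting bias (≈1–2% on recovered µ
under the default decline).

Negative excess values (measurement noise on unlabelled material) are
never clipped — clipping would bias population means upward — but are
flagged through the warnings channel, and cells whose excess falls outside
[0, E_pool) get NaN growth with a logged reason.

## Activity classification

A cell is active when its ¹³C atom% exceeds the natural-abundance mean
plus k standard deviations of unlabelled cells (defaults 1.11%, 0.016
percentage points, k = 3 → threshold 1.158 atom%). The threshold is always
returned alongside the labels. The implied false-positive rate for
Gaussian baseline variability is the one-sided 3σ tail (≈0.13%); a
property test checks ≤0.5% on simulated unlabelled populations. Population
summaries are computed twice — active-only (how headline rates are
reported) and all-cells — so the inactive fraction is never silently
discarded.

## ROI quantification

Per ROI the isotope fraction is the mean of per-pixel ratios
13C14N/(13C14N+12C14N) (and 12C15N/(12C15N+12C14N)), matching how SIMS
ROI means are conventionally computed; pixels with a zero denominator are
excluded, and an ROI with no usable pixels is skipped with a warning. A
count-sum estimator (ratio of summed counts) is available behind
`estimator="count_sum"`: conditional on the pixel totals both are
unbiased, but the sum estimator has lower variance at low per-pixel
counts. The default follows convention; the switch exists for low-dose
data.

## Cell composition chain

biovolume = π/4 · width² · length (cylinder), dry weight = biovolume ×
buoyant density (1160 kg m⁻³) × dry fraction (0.28), content_X = dry
weight × mass fraction (C 0.72, N 0.04, P 0.04) / atomic mass. The chain
is linear in biovolume. Per-cell fixation rates use the population-mean C
(or N) quota by default — individual quotas are usually unknown for the
exact imaged cells — with `content_basis="per_cell"` as the alternative;
cells without usable geometry fall back to the population mean and are
flagged. SEM-EDS stoichiometry consumes already-quantified atom% (spectrum
quantification is upstream of this package); note that the three Redfield
reference ratios carried for comparison (C:N 6.6, C:P 116, N:P 16) are
independent literature constants and are not mutually consistent
(116/6.6 ≈ 17.6).

## Contribution and uncertainty

contribution (%) = 100 · rate_cell · N_active / rate_bulk, with unit
reconciliation (pmol or fmol per cell vs µmol L⁻¹). Uncertainty is
first-order (delta-method) propagation for a product/quotient of
independent factors: relative SDs in quadrature, scaled by the point
estimate. The active fraction (default 0.90) scales the abundance mean and
SD identically; its own binomial uncertainty is not propagated because no
SD accompanies it. A POC-corrected abundance variant rescales the T0 count
by the fractional POC change to the rate's timepoint, absorbing
bottle-to-bottle biomass heterogeneity. Because the bulk rate enters as a
noisy denominator, the contribution is a ratio estimator and carries a
small positive Jensen bias of order CV²(rate_bulk); the end-to-end
recovery test therefore runs at modest bottle noise, where the pipeline's
mechanics — not the irreducible ratio bias — are under test.

## Group comparisons

Treatment effects use the Kruskal-Wallis omnibus (scipy, chi-squared
approximation, df = groups − 1; all-tied data short-circuits to H = 0,
p = 1), followed by pairwise mean-rank comparisons in the style of
Fisher's LSD applied to ranks: t = |R̄_i − R̄_j| / √(S²·(N−1−H)/(N−k)·
(1/n_i+1/n_j)) on N−k degrees of freedom, Holm-adjusted. Tie-corrected H
can exceed N−1; a non-positive residual factor is treated as complete
separation (p = 0 for unequal mean ranks). Holm ties keep their original
comparison order. Compact letters come from an insert-absorb pass over
groups ordered by mean rank.

## The synthetic experiment generator

The generator emulates a five-treatment nutrient-amendment incubation
(control, NH₄⁺, NO₃⁻, PO₄³⁻, NH₄⁺+PO₄³⁻; all with ¹³C-DIC, the N
treatments with a ¹⁵N tracer) sampled at 6 h and 30 h. Defaults are the
study conditions:

- **Cells.** 244 cells split over the imaged treatment × timepoint groups;
  10% inactive (µ = 0, label drawn from the natural-abundance
  distribution). Active growth is lognormal, median 0.42 day⁻¹, GSD 1.62,
  giving a mean ≈ 0.47 and SD ≈ 0.24 day⁻¹; P-amended treatments carry
  growth multipliers (0.43, 0.49) reflecting the observed suppression.
  Geometry is lognormal (length median 15 µm GSD 1.35, width median
  10.3 µm GSD 1.25), reproducing the observed mean biovolume
  ≈ 1414 ± 873 µm³.
- **Labelling.** excess_cell(t) = Ē_pool(t) · (1 − 2^(−µt)) with Ē the
  integral-average pool excess over [0, t] — the exact inverse of the
  growth equation under a declining pool label.
- **Pools.** Initial excess from concentration-weighted tracer mixing
  (DIC: 30 µM at 98% into 630 µM ambient → 4.40 atom% excess; NH₄⁺/NO₃⁻:
  10 µM at 98% into 0.078/0.05 µM → ≈97). The DIC label declines with a
  104 h half-life (≈4.3 → ≈3.6 atom% excess between samplings); N-tracer
  concentrations deplete with 1.1 h (NH₄⁺) and 4.0 h (NO₃⁻) half-lives so
  that <3% and <37% remain at 6 h. `depletion_mode="uptake"` instead
  derives pool concentrations from community uptake and conserves tracer
  atoms exactly (the mass-balance invariant); under the default DIC
  conditions strict conservation is impossible because realistic bulk C
  uptake exceeds the dissolved pool (supersaturation dynamics are out of
  scope), so that mode is exercised on slow, small-biomass configurations.
- **Bulk POM.** POC 2849 ± 1015 µmol C L⁻¹ per bottle (lognormal),
  POC:PON 20.06. The non-algal fraction is derived from abundance
  (16.2 × 10³ cells ml⁻¹) × mean cell quota / POC (≈85%) so cells, counts
  and bulk are mutually consistent; the background grows at 0.65 day⁻¹.
  Bulk excess is the content-weighted mixture of the algal population and
  the background. Biomass concentrations are held constant over the 30 h
  (labelling, not accrual, carries the signal) — a simplification that
  makes the POC-corrected abundance variant a near no-op on simulated
  data; tests exercise it with explicit POC ratios instead.
- **Images.** Cells are axis-aligned rectangles (cylinder projections)
  shelf-packed into 256 × 256 rasters at 0.273 µm px⁻¹; per-pixel Poisson
  counts in the three isotopologue channels, background ≈ 0. The expected
  ¹²C¹⁴N total is 10⁶ counts per cell: the activity threshold is defined
  by *biological* baseline variability (SD 0.00016), which presumes
  counting error is subdominant — that requires roughly ≥10⁶ CN⁻ counts
  per ROI, as real high-resolution SIMS measurements of cells this size
  deliver. Noise-free mode replaces all draws with their expectations,
  enabling exact algebraic round-trip tests.
- **EDS.** Atom% ratios are lognormal around C:N 19 ± 2.9 and N:P 26 ± 5
  (so C:P centres near 19 × 26 ≈ 494); mass% columns are generated
  independently around the 0.72/0.04/0.04 dry-mass fractions, mirroring
  the fact that the two measurement bases are reported independently (the
  mass fractions imply atomic C:P ≈ 46, far from the measured ≈509 —
  P-rich inclusions and matrix effects decouple them).

Everything is drawn from one seeded generator: a fixed seed fixes every
output byte, tables and rasters alike.

What the generator does **not** emulate: instrument drift, detector dead
time and quasi-simultaneous-arrival effects, EDS spectra, chemical-fixation
label loss (measurements are ingested uncorrected, as is conventional),
fungal infection dynamics, cell division during the incubation, and
spatially structured within-cell label. Passing recovery tests therefore
demonstrate correctness of the calculation chain under the stated model,
not robustness to those instrument- and biology-level effects.

## Numerical and interface choices

- Δt converts from hours to days at the `Incubation` boundary; all rates
  are day⁻¹.
- Rate equations raise on a non-positive pool excess ("tracer accounting
  broken") and on biomass more labelled than its source; doubling time of
  non-positive growth is NaN with a warning so summary tables keep shape.
- Replicate aggregation is mean ± SD (ddof = 1) with n recorded; bottles
  with missing atom% are dropped with a logged reason.
- Table readers skip unparseable rows with logged line numbers but *raise*
  on parseable out-of-range values (e.g. an atom% in a fraction column),
  since those indicate unit errors rather than data corruption.
- CSV output uses `%.10g` floats, making reruns byte-identical.
- CLI exit codes: 0 ok, 2 validation error, 3 stage failure.

## Known limitations

- The quadrature uncertainty treats the three contribution factors as
  independent; covariance between bulk POC and cell abundance is ignored.
- The pairwise rank-LSD post hoc is a pragmatic reading of a loosely
  specified convention; it is not the studentized-range (Tukey/Nemenyi)
  procedure and is slightly anti-conservative for many groups, which the
  Holm adjustment partially offsets.
- Per-cell rates inherit the population-mean quota by default, so
  between-cell rate variability reflects labelling variability only, not
  size variability (switchable).
- The exponential-growth inversion is undefined as E_bio → E_pool;
  near-saturated cells produce unstable µ estimates, which matters for
  fast growers in long incubations.
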
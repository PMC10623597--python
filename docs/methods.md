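# Methods

## Model

The classical twin design decomposes phenotypic variance into additive
genetic (A), shared-environment (C) and nonshared-environment (E) shares
from the MZ and DZ twin–cotwin correlations, under the standard assumptions
(additivity, no assortative mating, equal environments across zygosities,
MZ pairs sharing all and DZ pairs half of the additive genetic variance):

    r_MZ = a² + c²,   r_DZ = a²/2 + c²
    A = 2(r_MZ − r_DZ),   C = 2 r_DZ − r_MZ,   E = 1 − r_MZ

The three components sum to one identically; the implementation asserts this
as an exact algebraic property and never truncates a negative C (sampling
noise can push it slightly below zero, and unbiased Monte Carlo summaries
require keeping it).

The worldwide design pools per-country twin samples.  Per country c with
well-being mean μ_c and SD σ_c (0–10 Cantril Ladder), twin pairs are drawn
from a bivariate normal with both margins (μ_c, σ_c) and the zygosity's
target correlation.  Pooling with country weights w_c adds the
between-country mean variance V_b = Σ w_c (μ_c − μ̄)² to both the
covariance and the variance of a twin pair, because the country mean loads
identically on both twins:

    E[r_pooled] = (Σ w_c σ_c² r_within + V_b) / (Σ w_c σ_c² + V_b)

Writing B for the normalized between share and W = 1 − B, composing this
with Falconer's equations gives the closed-form expectations

    A_world = a²·W,   C_world = c²·W + B,   E_world = e²·W

implemented in `twinworld.oracle` and used as the verification surface for
the simulation pipeline.  The oracle assumes a common within-country
correlation and normal margins; since moment matching (below) makes country
moments exact, its within/between decomposition is exact for matched runs
and the only stochastic gap is within-country correlation noise.

## Simulation pipeline

Each scenario repetition: build a sampling plan → map within-country
(a², c²) to target correlations → simulate every country → pool → Pearson
twin–cotwin correlation per zygosity on the *raw* pooled scores → Falconer →
optional reliability disattenuation.  Repetitions (default 100) are
summarized by their mean, with normal-theory 95% intervals
(mean ± 1.96 × SD across repetitions; percentile intervals behind a flag).

Standardizing scores within country before pooling is deliberately not
offered in the estimation path: it would delete the between-country signal
the design exists to measure.

**Moment matching.** Each twin column within each country-zygosity cell is
affine-rescaled so its sample mean and SD (ddof = 1) equal the country's
values exactly (to ≤1e-9).  Pearson correlations are invariant under
per-variable affine maps, so the realized twin correlation keeps its
sampling noise while the between/within variance decomposition of the
pooled sample becomes exact.  Matching is on by default.

**Sampling plans.** Equal mode gives every country the configured pairs per
zygosity (1,000 by default; 157 countries → 314,000 pairs).  Population
weighting apportions the same per-zygosity grand totals proportionally to
population by the largest-remainder (Hamilton) method with a floor of one
pair per country; ties break by descending population, then name.  This
conserves totals exactly and keeps MZ/DZ balance identical across
scenarios.  When all populations are equal the two modes coincide exactly,
which the tests exploit.

**Seeding.** The root seed derives per-repetition sub-seeds via
`numpy.random.SeedSequence([seed, rep])`; inside a repetition every country
runs on a named substream keyed by the CRC-32 of its name, so results are
bit-reproducible and independent of country iteration order.  Per-year runs
derive their root from (seed, year).

## Scenario presets

| preset | within a²/c²/e² | sampling | extra |
|--------|-----------------|----------|-------|
| S1 | .38 / 0 / .62 | equal, 1,000 pairs/zygosity/country | — |
| S2 | .38 / 0 / .62 | population-weighted, same totals | — |
| S3 | .38 / .05 / .57 | equal | within-country C for regional differences |
| S4 | .32 / 0 / .68 | population-weighted | life-satisfaction heritability input |
| S5 | .38 / 0 / .62 | population-weighted | reliability-.80 disattenuation |

S3 uses equal sampling: its published worldwide C (.23) is only consistent
with the unweighted between-country share, while the per-year variant is
run population-weighted.  S4's e² = .68 is inferred from the heritability
input with no shared environment (only the heritability is reported
upstream).  S5's disattenuation subtracts the error share 1 − ρ from E and
renormalizes all components by ρ, preserving the sum-to-one constraint; it
is applied per repetition, and because the map is affine this equals
adjusting the summary.

## Synthetic worlds

`generate_world` emulates the structure of published national well-being
tables: country means uniform on [2.4, 7.8] (the span of published national
means), SDs uniform on [1.5, 3.0] ladder points (bracketing typical
national SDs of ~1.7–2.7), populations log-normal with ln-mean 16.0 and
ln-SD 2.0 (median country ≈ 9 million people with a heavy right tail,
realistic for UN country estimates — neither moment is prescribed
upstream, so these were fixed once on that rationale).  It does **not**
mimic the empirical distribution's shape, country identities, skewness of
national means, or mean–SD correlation; a green test on a synthetic world
establishes that the pipeline measures what the generative model contains,
not that any real-world number is reproduced.

`calibrated_world` is deterministic: evenly spaced means standardized so
the equal-weight between-country variance share is exact (default .19, the
share at which within-country inputs a²=.38/c²=0 map to the worldwide
decomposition A=.3078, C=.1900, E=.5022 and pooled correlations .4978 /
.3439).  It stands in for the real 157-country table, whose download is
outside this package's scope; with equal populations its weighted scenarios
collapse onto the equal-sampling ones by construction.

## Numerical choices and degenerate inputs

- Twin pairs are kept in generated order and correlated with the plain
  Pearson estimator (no double entry, no intraclass estimator): twins are
  exchangeable by construction.
- Phenotypes are unbounded normals; no censoring at the 0–10 ladder limits.
- Year aggregation is the unweighted mean of yearly means and of yearly SDs.
- Moment matching requires ≥2 pairs and nonzero sample variance; perfect
  target correlations (r = 1) are supported and produce identical twins.
- Reliability ρ must satisfy e² ≥ 1 − ρ, otherwise the adjustment would
  produce a negative true-score E and the call raises.
- Sum-to-one tolerance 1e-12; moment-match tolerance 1e-9 (accumulated
  float error in mean/SD at n = 10⁵ stays well under it).

## Known limitations

- Large-sample expectations only: the oracle does not provide finite-sample
  distributions of Falconer estimates.
- No sex differences, assortative mating, gene–environment interplay,
  nonadditive (dominance/epistasis) components, or structural-equation
  fitting — the design is the transparent Falconer arithmetic.
- Monte Carlo point estimates are means across repetitions (medians are a
  plausible alternative; means were chosen as the conventional summary).
- All twin pairs are assumed to reside in a single country.
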
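# Methods

## Valuation model

The package monetizes disease burden with the value-of-lost-welfare
framework. A value of a statistical life (VSL) benchmark is divided by a
life expectancy to give a value per statistical life year (VSLY); burden
counts (DALYs or YLLs) are multiplied by the VSLY and summed over age
groups. Three benchmarks are configured by default, all in 2021 USD: a
native wage-based Indonesian VSL of US$950,000, and OECD- and US
DOT-derived values of US$1.2M and US$1.77M obtained by income transfer
(`VSL_ref * (GDPpc_target/GDPpc_ref)**elasticity`, elasticity 1.0).
Transferred benchmarks may store their transfer parameters, in which case
consistency with the stored VSL is validated; the defaults take the
transferred values as given, since estimating or re-deriving reference
VSLs is outside this package's scope.

### Life expectancy granularity

Only flat sex-specific life expectancies are used as VSLY divisors
(male 60.67 y, female 73.55 y, combined 73.5 y, 2021 Indonesian values).
An age-specific divisor schedule would be the purist reading of
"life expectancy at age of death", but the flat sex-specific divisors are
what exactly reproduce the combined/male/female accounting of published
national tables, and they keep the model linear in the counts. The
`LifeExpectancyTable` accepts any positive values, so a user can swap in
conditional life expectancies if they have them.

### Combined-sex accounting

Combined-sex losses are computed from combined-sex counts with the
combined divisor. Summing the male and female losses instead would
overstate the combined value whenever `LE_male < LE_female` (the male
life-years are priced higher per year); the identity

    VLW_both * LE_both = VLW_male * LE_male + VLW_female * LE_female

holds exactly under shared counts and is exercised by the tests and by
the acceptance script, which uses it to recover published national
combined totals from the published sex-specific values.

### DALY-YLL gap

The gap is `100 * (VLW_DALY - VLW_YLL) / VLW_DALY`, i.e. the morbidity
(YLD) share of the monetized burden. The DALY denominator is the
definition that reconciles the published provincial gap figures (12% for
the largest gap, ~6% for mid-range provinces, ~4% nationally) with the
published loss tables.

## Disparity statistics

* **Gender relative difference** `100*(VLW_m - VLW_f)/VLW_f` — undefined
  (error) at zero female loss. At full precision it is invariant to the
  VSL benchmark, since both losses scale by the same VSLY factor; a
  `rounded_inputs` mode first rounds losses to 3 decimals (billion USD)
  to reproduce statistics computed from printed table values, which are
  *not* benchmark-invariant because the rounding error differs by column.
* **Location quotient** — province share of national loss over province
  share of national population. Its population-weighted mean over a full
  partition is identically 1, which the tests assert.
* **Disparity index** — provincial loss-to-GDP ratio over a national
  reference. The default reference is the national aggregate ratio; an
  unweighted mean of provincial ratios is available
  (`disparity_reference="province_mean"`) because the published index
  values do not reconcile exactly with the aggregate reading and the
  intended reference is ambiguous. No test asserts the published index
  values for that reason.

### Clustering

Provinces are grouped by a one-dimensional k-means with k=4. Optimal 1-D
k-means partitions are contiguous in sorted order, so the problem is
solved exactly by dynamic programming over contiguous partitions
(O(k n²) with prefix-sum costs) rather than by Lloyd iterations, which
can stall in local optima and depend on initialization. The result is
deterministic and globally optimal in within-cluster sum of squares; the
`seed` argument is accepted for interface stability but unused. Ties in
the DP are broken toward the earliest boundary. Clusters are relabelled
by ascending centroid onto ordered label sets ("very low/low/high/very
high" for geographic statistics, "low/moderate/high/very high" for
gender). k-means clusters are generally not size-balanced quartiles;
occupancy counts are reported by the analysis scripts so the imbalance is
visible. Fewer distinct values than k is an error, not a silent merge.

## Synthetic data generator

The generator emulates the statistical structure of a 34-province,
two-sex, five-age-group burden table so the pipeline is testable without
external data:

| parameter | default | meaning |
|---|---|---|
| `n_provinces` | 34 | province-like units on a west-east axis |
| `age_groups` / `age_weights` | 5 bins, weights (.60,.15,.10,.10,.05) | infancy-dominated burden, as for congenital heart disease |
| `base_daly_rate` | 113 / 100k | female baseline rate before province effects (the 2021 national CHD DALY rate) |
| `male_excess` | 0.7 | male rate = female rate × 1.7, implied by the published national male/female loss ratio and the LE ratio |
| `yld_share` | 0.04 | YLL = DALY × 0.96 cell-wise (the ~4% national DALY-YLL gap) |
| `gdp_gradient` | 1.0 | log-spread of GDP per capita along the axis |
| `burden_gdp_correlation` | −0.5 | poorer provinces carry higher rates; ±1 gives exact (anti)alignment of ranks |
| `population_range` | 7×10⁵–4.8×10⁷ | log-uniform, the span of Indonesian provinces |
| `noise_cv` | 0.2 | mean-one multiplicative lognormal noise on rates only |

Populations are noise-free and split equally between the sexes, so with
`noise_cv=0` the male/female count ratio is exactly `1+male_excess` and
downstream gender disparity recovers
`100*((1+male_excess)*LE_f/LE_m − 1)` uniformly — the known-parameter
recovery the tests assert. YLL rates share the DALY noise draw, so
YLL ≤ DALY holds cell by cell. Combined-sex rows are derived from summed
counts, never drawn independently. The same seeded province stream feeds
both the burden and the economy table, so GDP = GDP per capita ×
population exactly and the two tables join consistently.

What the generator does **not** emulate: the actual Indonesian provincial
values (labels are `Province-01`…), uncertainty intervals, age-varying
sex ratios, within-province heterogeneity, or reporting artefacts of real
GBD exports. Passing tests on synthetic data therefore demonstrate the
correctness of the arithmetic and the invariances, not the realism of any
particular provincial estimate; reproduction of real published numbers is
covered separately by the bundled printed tables.

## Numerical choices

* Full precision is kept internally everywhere; presentation rounding is
  half-away-from-zero to 3 decimals (billion USD) and 2 decimals
  (percent), applied only in the wide output tables and in tests that
  compare against printed values.
* Rates and counts interconvert as `count = rate/1e5 * population`;
  whichever metric a file supplies is recorded and the other derived when
  a population is joinable.
* CSV output uses pandas' shortest-repr float formatting, so written
  tables round-trip bit-exactly.
* Determinism: all randomness flows through `numpy.random.default_rng`
  seeded from the config; identical config and seed give byte-identical
  tables. Problem sizes in the tests and analysis scripts (34 provinces,
  5 age bins, ≤10 seeds) keep the full suite under a minute.

## Known limitations

* No uncertainty propagation: point estimates only.
* No discounting or age-weighting of life years.
* The disparity-index national reference ambiguity noted above.
* GDP enters only as a denominator; no real exchange-rate or PPP
  adjustment beyond a single configured rate.
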
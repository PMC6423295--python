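# Methods

This note documents the models, estimators and design choices behind
`pollinet`, in the spirit of a package vignette: what is computed, under
which assumptions, and where the genuinely open choices were resolved.

## Data model

The unit of observation is the **census**: one timed watch of one
individual plant, with a count of visits per pollinator species. Censuses
come in three kinds — 5-minute focal watches, short (~1–2 min) spot checks
used for vertebrate visitors, and opportunistic presence-only "extra"
records. The canonical storage is a long CSV (one row per census ×
pollinator); a census with no visits is kept as a single sentinel row with
an empty pollinator field, because such censuses still enter the
denominator of every visit rate. How zero-visit censuses were recorded in
the motivating field protocol is not documented; the sentinel-row
convention is this package's choice and is preserved through round trips.

## Interaction matrices

`W[i, j]` is the mean number of visits of pollinator *j* per census on
plant species *i*. Because focal and spot censuses differ in duration,
each census type keeps its own denominator (visits ÷ censuses of that type
on that plant) and the per-type rates are summed; mixing both types into
one denominator would bias rates for plants with many spot checks. Whether
the original analysis mixed the denominators is not stated; the separation
is documented here as our choice. Two rate modes exist:

- `pooled` (default): total visits ÷ total censuses per plant — weights
  observation effort;
- `individual_mean`: the mean over plant individuals of each individual's
  own mean rate — weights individuals equally.

The qualitative matrix `B` is `W > 0` plus any pair recorded in an extra
census; extras never contribute to `W`. A matrix is restricted to species
with at least one link (the observed network); fixed-dimension variants
are used internally where replicate matrices must align (spectra
envelopes).

Interaction accumulation curves are sample-based rarefaction: censuses are
accumulated in random order (default 1000 permutations) and the mean ± SD
of distinct links after each census is reported. The final point equals
the total link count by construction.

## Network descriptors

- **Connectance** `C = I/(P·A)`.
- **Interaction diversity** `H' = −Σ p_ij ln p_ij` over realised links,
  with `p_ij = W_ij / ΣW`. Natural logarithms throughout; the
  exponential-entropy quantities below are base-invariant, but `H'` itself
  is reported in nats.
- **Linkage density** (quantitative, Bersier-style):
  `LD = ½[Σ_j (w_:j/w_::)·exp(H_j) + Σ_i (w_i:/w_::)·exp(H_i)]`, the
  abundance-weighted mean effective number of partners.
- **Matrix temperature / nestedness.** The binary matrix is packed
  (rows/columns sorted by marginal totals, ties broken by cross-marginal
  weights so packing is order-invariant), an isocline of perfect
  nestedness `x^p + y^p = 1` is drawn with `p` solved so the area under
  the curve equals the observed fill, and every unexpected presence/absence
  contributes its squared distance to the isocline measured along the
  cell's diagonal, normalised by the diagonal length. `T` is the mean
  squared normalised distance scaled by the conventional maximum
  (0.04145) to [0, 100]; `N = 1 − T/100` so that 1 means perfectly nested.
  Exact numeric agreement with any particular legacy temperature program is
  not promised — isocline details differ between implementations — only
  the scale, packing invariance and endpoint behaviour.
- **Weighted NODF**: for every unordered pair of rows, the row with the
  strictly larger marginal total is the reference and the pair scores the
  percentage of the other row's filled cells that are strictly smaller
  than the reference's; ties in marginal totals score 0 (strict
  inequality, following the published index). Same over columns; the index
  is the mean over all pairs. A consequence worth knowing: a plain 0/1
  matrix scores 0 — the weighted index requires frequency information.
- **Interaction strength asymmetry**: per link,
  `(d^A − d^P)/max(d^A, d^P)` with `d^A = W_ij/column total` (pollinator's
  dependence) and `d^P = W_ij/row total`; ISA is the mean over links.
  Positive means the pollinator guild depends more on plants. Other
  dependence-asymmetry variants exist in the literature; this
  max-normalised form is the default because it matches the sign
  convention above.

## Modularity and species roles

Modularity is Barber's weighted bipartite
`Q = (1/F) Σ_ij [W_ij − r_i s_j/F]·δ(m_i, m_j)` over plant–pollinator
pairs. The optimiser is a QuanBiMo-style simulated annealing: every
species starts in its own module; each step reassigns one species to any
module slot (which doubles as a split move) or, with probability 0.05,
merges two occupied modules; worse moves are accepted with Boltzmann
probability under geometric cooling (start temperature 1 scaled by 1/(P+A),
factor 0.995, default 10⁴ steps). A deterministic polish then applies
best single moves, best pairwise merges and best (plant, pollinator) pair
extractions until none improves Q, so every returned partition is a local
optimum under all three move classes. The schedule is this package's
choice — the algorithm family is named in the literature but not its
parameters.

Because module counts vary between runs, `consensus_modules` repeats the
search (default 50 runs), reports mean ± SD of the number of non-empty
modules, aligns module labels across runs by greedy maximal species
overlap with the best run (a heuristic, documented as such), and assigns
each species its modal module, breaking ties toward the lowest module id.

Species roles: participation coefficient `c_i = 1 − Σ_s (k_is/k_i)²`
(spread of species *i*'s links over modules of the opposite guild) and
within-module degree `z_i`, the species' own-module degree standardised
against same-guild members of its module (singleton or zero-variance
modules give z = 0, flagged). Whether the original study used weighted or
binary degrees is unstated; weighted is the default and binary is exposed.
Role classes use empirical 0.95-percentile thresholds on c and z with the
usual quadrant naming (peripheral / connector / module hub / network hub);
species must lie strictly above a threshold to leave the peripheral class.
Trends in c and z between periods are tested per species with exact
two-sided binomial sign tests, zero changes dropped.

## Eigenvalue spectra

The bipartite matrix is embedded as the symmetric block matrix
`[[0, M], [Mᵀ, 0]]`, whose spectrum is real, symmetric about zero, and
consists of ± the singular values of `M` plus zeros. λ₁ (spectral radius)
equals the largest singular value; a large λ₁ signals a dominant core,
and the zero-eigenvalue mass grows with interaction redundancy (low
rank). The weighted matrix is the default mode — invader dominance is a
property of visit *frequencies* — with the binary mode available.
Envelope profiles come from the same stratified census bootstrap as the
contrast module, with replicate matrices kept at fixed dimensions so
per-rank 2.5/97.5 percentiles are well defined. Densities are Gaussian
kernel estimates over a grid wide enough that the trapezoid integral is 1
to numerical tolerance.

## Period contrasts

The resampling unit is the census, stratified by (plant species, plant
individual, census type) with stratum sizes preserved exactly — spot
censuses resample among themselves. Two schemes are implemented because
the motivating description admits both readings:

- `label_permutation` (default for p-values): period labels are permuted
  within strata; a proper exchangeability null.
- `bootstrap`: each period's censuses are resampled with replacement; the
  null distribution describes sampling variability of the difference (the
  z-score construction of the original analysis).

Differences are `apis − pre`. Reported: `z = (obs − mean(null))/SD(null)`,
the empirical two-sided rank p-value with +1 continuity
(`p = (#{|null − mean| ≥ |obs − mean|} + 1)/(N + 1)`), and the normal tail
area of z (the original analysis does not say which it used, so both are
emitted). The default is N = 5000 resamples, as in the motivating study;
batteries share one resample stream so all metrics see identical
resamples. A metric failure on a resample triggers a redraw; more than 5%
failures aborts. Integer-valued metrics (module counts) use the raw
integer differences with no continuity correction beyond the rank +1. No
multiple-testing correction is applied across a battery — raw per-metric
p-values are emitted and adjustment is left to the user.

## Reproductive success

Paired design: values are averaged within individual plants first
(fruit-set = fruits/flowers from branch totals; seeds = mean per fruit),
then compared across periods with a paired *t* test on plants measured in
both periods (unmatched plants dropped and counted). Seed counts are
log-transformed; when zeros occur the transform switches to log(x+1) and
the result is flagged — fruit-set is tested untransformed, since only the
seed variable is described as log-transformed in the motivating design.

Distance gradient: per-plant means at distance classes
{0, 100, 500, 1000, 2000, 4000} m are fitted with GLMs — Poisson log-link
for seeds per fruit; binomial logit for seed-set with mean ovules per
fruit as a (centred) covariate; Gaussian on log mass ("lognormal", the
common reading of a log error family for mass; a gamma-log alternative
would be a one-line change) with mean seeds as covariate. All pairwise
class contrasts are adjusted with the single-step max-|t| method: the
contrast statistics are jointly normal with a known low-rank correlation,
and the adjusted p-value `P(max_j |T_j| ≥ |t_k|)` is evaluated by Monte
Carlo through the low-rank factor (2×10⁵ fixed-seed draws, ~0.1%
accuracy, exact at t = 0); a Holm step-down is the fallback if the
contrast covariance is degenerate. Heteroskedasticity-consistent (HC1)
standard errors are available as an option that emits a second contrast
table rather than replacing the first.

## Synthetic data generator

The generator produces the statistical structure the analysis assumes,
not a mechanistic foraging model. Per-pair base visit rates are
`λ_ij = a_i · b_j · ε_ij` with Zipf-like plant attractiveness `a` and
pollinator activity `b` (exponent `nestedness_skew`, default 1 — strong
marginal heterogeneity, hence nested webs) and lognormal noise `ε`
(default μ = −4.8, σ = 1.5, calibrated so a field-scale community of 17
plants × 98 wild pollinators yields ≈2.5 visits per census and a
connectance of the observed order). Counts per census are Poisson
(negative-binomial optionally). Defaults mirror the motivating study
where it states a value: 17 plant species, 10 individuals per plant, 86
censuses per plant species per period, and an apis-period with wild rates
multiplied by `suppression = 0.5`, a 40% invader visit share concentrated
on the top-4 plants (80% of invader visits), and `dropout_k = 3` wild
species absent. Dropout removes the *most active* wild species:
exploitative competition for nectar hits the large generalist foragers
hardest, and losing their connector links is the mechanism behind the
structural changes of interest. The invader's per-plant rate is
calibrated so its expected visit share equals `apis_share` exactly.

The reproduction generator shares a per-plant random effect across
periods (binomial fruit-set, Poisson seeds, lognormal seed mass); the
distance generator decays invader pressure as `exp(−d/L)` (default
L = 300 m) with near-hive effects on the empty-fruit probability, seeds
per fruit, seed mass and aborted ovules, at the motivating design's
per-class plant numbers and 50 fruits per plant.

What the generator does **not** emulate: phenological turnover between
periods, observer effects, taxonomic misassignment, spatial structure
within the plot, and — important for interpretation — *latent modular
structure in the wild community*. Wild rates are rank-1 × noise, so the
pre-period web is nested but not modular. Consequently a passing test
suite shows that the pipeline detects link loss, connectance and weighted
nestedness declines it was pointed at; it does not show that module
counts must rise under invasion. In this generator the invader acts as a
module-merging hub and the mean module count is as likely to fall as to
rise — the module-fragmentation route to higher modularity requires
selective loss of among-module connector links, which presupposes modules
to begin with. The corresponding direction check is therefore expected to
fail under this generator, and is kept as an explicit, honest record of
that model limitation.

## Problem sizes and numerical choices

Simulation-based tests run at scaled-down community sizes chosen as this
package's test conditions: the null-calibration study uses 6 plants × 14
wild species × 12 censuses per plant per period (exchangeability holds at
any size), and the effect-recovery study 12 × 40 × 60 (≈70% of the
field-scale census effort; effect parameters as above). Annealing inside
resampling loops runs at reduced effort (3–10 runs, 2000–5000 steps)
because a 50-run consensus per resample would be prohibitive; reduced
effort adds noise to module counts but no bias, and the polish step keeps
every run a genuine local optimum. Degenerate inputs are defined rather
than rejected where a convention exists: single-row/column matrices have
temperature 0; species with no links have c = 0; zero-variance paired
differences are flagged degenerate instead of producing a spurious t.
All stochastic components take explicit seeds and are bit-reproducible.
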
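# pollinet

Analysis toolkit for **plant–pollinator interaction networks under
beekeeping pressure**. It is written for pollination ecologists who record
flower-visitation censuses on focal plants before and after a perturbation
— the motivating case is the installation of high-density honeybee
(*Apis mellifera*) apiaries halfway through a flowering season — and who
want to test whether the perturbation changed the *structure* of the
pollination web and the *reproductive success* of the plants.

## What it computes

From long-format census tables (one row per census × pollinator, with visit
counts) the package builds quantitative interaction matrices **W** (mean
visits per census of pollinator *j* on plant species *i*; 5-min focal and
short spot censuses keep separate effort denominators) and qualitative
matrices **B** (presence, including opportunistic "extra" records). On a
matrix it computes the standard descriptor suite:

- connectance *C* = *I*/(*P·A*), the realised fraction of possible links;
- Shannon interaction diversity *H′* = −Σ *p*ᵢⱼ ln *p*ᵢⱼ;
- quantitative linkage density *LD* (mean effective partners per species,
  exponential-entropy weighted);
- matrix temperature *T* and nestedness *N* = 1 − *T*/100;
- weighted nestedness **wNODF** (strict decreasing-fill / decreasing-frequency
  pairs over rows and columns, 0–100);
- interaction strength asymmetry *ISA* ∈ [−1, 1] (Bascompte-style dependence
  asymmetry, positive when pollinators depend more on plants);
- weighted bipartite modularity *Q* (Barber) via a QuanBiMo-style
  simulated-annealing optimiser with multi-run consensus module counts *nM*,
  plus species roles (*c* participation coefficient, *z* within-module
  degree) and their 0.95-percentile classification;
- eigenvalue spectra of the symmetric adjacency embedding [[0, W], [Wᵀ, 0]],
  spectral radius λ₁, and census-bootstrap confidence envelopes.

Period differences are tested with the study's resampling framework:
censuses are resampled within (plant species, individual, census type)
strata — either bootstrapped within each period or with period labels
permuted — the metric battery is recomputed on every resample, and the
observed difference is reported with a z-score and an empirical two-sided
p-value. Reproductive success is analysed with per-plant paired *t* tests
(fruit-set, log seeds/fruit) and distance-from-apiary GLMs (Poisson seeds,
binomial seed-set with ovule covariate, lognormal seed mass with seed
covariate) with single-step Tukey-type contrasts.

A seeded synthetic-data module (`pollinet.synthetic`) generates census,
paired-reproduction and distance-gradient datasets with the structure the
analysis assumes — heterogeneous visit rates, a super-generalist invader
entering only in the second period, suppression and dropout of wild
species — so the entire pipeline runs end-to-end with no field data.

## Worked example

```python
import pollinet as pn

params = pn.CommunityParams(P=12, A=40, individuals_per_plant=5,
                            censuses_per_plant_per_period=60,
                            suppression=0.5, apis_share=0.4, dropout_k=3,
                            seed=11)
data = pn.generate_censuses(params)

m_pre = pn.build_matrix(data, period="pre")
m_apis = pn.build_matrix(data, period="apis")
print(f"pre:  {m_pre.P} plants x {m_pre.A} pollinators, I={m_pre.I}, "
      f"C={pn.connectance(m_pre):.3f}")
print(f"apis: {m_apis.P} plants x {m_apis.A} pollinators, I={m_apis.I}, "
      f"C={pn.connectance(m_apis):.3f}")

res = pn.contrast_metric(data, pn.connectance, "C",
                         n_resamples=500, mode="label_permutation", seed=5)
print(f"delta C = {res.observed_diff:+.4f}, z = {res.z_score:.2f}, "
      f"p = {res.p_value:.4f}")
```

prints

```
pre:  12 plants x 37 pollinators, I=162, C=0.365
apis: 12 plants x 33 pollinators, I=99, C=0.250
delta C = -0.1149, z = -4.43, p = 0.0020
```

i.e. halving wild visit rates and adding a 40%-share invader removed more
than a third of the links and produced a connectance drop far outside the
permutation null (p = 0.002 is the smallest value 500 resamples can
resolve with the +1 continuity correction). The same `data` object feeds `contrast_battery` (all
descriptors on shared resamples), `consensus_modules`, `spectrum_ci` and
the `pollinet` command-line interface (`pollinet simulate | build |
metrics | contrast | modules | spectra | repro | full-study`).

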
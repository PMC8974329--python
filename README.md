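# famlong

Family-based longevity study methodology at desk scale.

Multigenerational studies of exceptional longevity recruit families in
which survival clusters far beyond what life tables predict, then ask
which healthy-aging phenotypes are heritable — both in level and in
*rate of change* — and whether rare protective variants segregating in
particular lineages explain the familial signal.  `famlong` implements
that methodological core as a reusable, tested pipeline for
biostatisticians and genetic epidemiologists:

* **FLoSS** (Family Longevity Selection Score): per-sibling survival
  exceptionality −log S(age) under a sex/birth-cohort life table,
  centred so a sibship surviving "exactly as expected" scores 0
  regardless of size, plus a bonus per living sibling; eligibility
  screening (score ≥ 7, proband + living sibling + offspring).
* **Growth-curve change phenotypes**: the random-coefficient model
  y_ij = (β₀+u_i0) + (β₁+u_i1)t_ij + e_ij with (u_i0,u_i1) ~ N(0, G),
  fitted by REML (log-Cholesky parameterization, quasi-Newton), giving
  empirical-Bayes (BLUP) personal slopes — alongside the naive OLS
  change score Δ = (P2−P1)/years, years = days/365.25.
* **Kinship heritability**: h² = σ²_g/(σ²_g+σ²_e) under
  y ~ N(μ, 2Φσ²_g + Iσ²_e), with Φ from the recursive pedigree kinship
  algorithm; REML profiled to a one-dimensional search per trait with a
  boundary-mixture likelihood-ratio test.
* **Gene-dropping linkage**: simulation-true IBD at an abstract locus,
  variance-component LODs y ~ N(μ, Πσ²_q + 2Φσ²_g + Iσ²_e), the
  admixture heterogeneity LOD (HLOD) with driving families flagged at
  LOD > 0.2, and single-variant association comparators (plain and
  kinship-adjusted) for the rare-lineage-variant demonstration.
* **Synthetic cohort generator**: seeded two-generation families
  (enrolled size mean ≈ 9, range 3–79), life-table lifespans, and
  two-visit phenotypes 8–10 years apart with heritable, kinship-
  correlated intercepts and slopes plus per-visit measurement error.

The central methodological point the pipeline demonstrates: with two
visits, measurement errors *accumulate* in per-person change scores, so
the heritability of OLS slopes collapses toward zero, while the
growth-curve BLUP slopes — which model the visit-level error — retain
it; and clusters of rare, family-private causal variants can produce a
strong linkage peak that single-variant association scans miss entirely.

## Worked example

```python
from famlong.pipeline import run_experiment
from famlong.synthetic import SimConfig

res = run_experiment(SimConfig(n_families=150, seed=3))
print(res.table[["n", "h2", "se_h2"]])
```

prints (the four phenotype rows of the heritability report):

```
              n        h2     se_h2
trait
visit1     1384  0.336234  0.053280
visit2     1384  0.338007  0.055733
gc_slope   1384  0.386309  0.055225
ols_slope  1384  0.030513  0.046665
```

Here the generator used heritability 0.5 for both intercepts and slopes,
per-visit error variance 4, and an intercept–slope correlation of 0.6.
Cross-sectional heritability is attenuated to ≈ 0.34 by measurement
error; the growth-curve slope heritability (0.39) stays near the
cross-sectional magnitude while the OLS change-score heritability
(0.03) is essentially zero — the attenuation-and-recovery contrast the
pipeline exists to show.  `res.gc_correlations` gives the
measured-vs-fitted correlations per visit (≈ 0.90/0.95 here), and
`res.recovery` compares both slope estimates against the simulated
truth (BLUP slopes correlate 0.65 with true slopes vs 0.34 for OLS).

The rare-variant demonstration:

```python
from famlong.pipeline import run_raredrop_demo
print(run_raredrop_demo(seed=0).summary())
```

```
{'hlod': 4.467, 'alpha_hat': 0.23, 'overall_lod': -11.47, 'n_driving': 37,
 'min_p': 8.35e-06, 'min_p_naive': 2.90e-08, 'n_variants': 45,
 'max_carrier_freq': 0.0033, 'dissociation': True, 'seed': 0}
```

45 family-private variants (each carried by < 0.5% of the pooled
sample, carriers shifted 3 SD) yield an HLOD of 4.5, while the best
kinship-adjusted single-variant p value (8.4e-06) is nowhere near
genome-wide significance — the linkage signal exists and association
cannot see it.  The negative homogeneity LOD (−11.5) is the point of
the admixture model: most families are unlinked and argue against
linkage, so only the heterogeneity-aware score finds the locus.
(`min_p_naive` is the unadjusted pooled test, which is confounded by
family structure.)

## Command line

```
famlong simulate --seed 5 --out sim/          # PED + phenotypes + life table
famlong score --ped sim/families.ped --lifetable sim/lifetable.csv
famlong slopes --pheno sim/phenotypes.csv --out slopes.csv
famlong h2 --pheno slopes.csv --ped sim/families.ped --traits gc_slope,ols_slope
famlong hlod --lods family_lods.csv
famlong raredrop-demo --seed 0
famlong experiment --seed 3 --out exp/
```

Exit codes: 0 success, 2 validation error, 3 convergence failure.

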
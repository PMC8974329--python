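# Methods

This note documents the models, parameter choices, numerical decisions
and known limitations behind `famlong`.

## Life tables and FLoSS

A life table stores S(age) per (sex, birth-cohort) stratum on an
integer age grid.  Between grid ages we interpolate linearly in
log S — equivalently a piecewise-constant hazard within each year, the
standard actuarial convention, and exact for exponential segments.
Beyond the last grid age the cumulative hazard H = −log S is
extrapolated with a Gompertz tail whose growth rate is fitted to the
last two grid points; survival is clamped to (1e−12, 1].  A birth year
outside every stratum maps to the nearest stratum with a warning,
because real national tables have coarse cohorts.  Lifespans are drawn
by inverse transform of H (solve m·H(T) = E, E ~ Exp(1)); the hazard
multiplier m < 1 models familial survival exceptionality.

FLoSS exploits the fact that −log S(T) is unit-exponential when T
follows the table.  A deceased sibling contributes −log S(age at
death); a living sibling of age t contributes the conditional mean
E[−log S(T) | T > t] = −log S(t) + 1, which follows from the
memorylessness of the exponential on the −log S scale (a quadrature
oracle guards this identity in the tests).  Subtracting the sibship
size centres the component at zero for survival "exactly as expected"
and makes its expectation independent of sibship size; by the tower
property this centring survives independent censoring, which is why the
Monte-Carlo calibration holds with a mix of living and deceased sibs.
The living-sib bonus coefficient defaults to 0.5 per living sibling; it
is a configuration value (the defining methodology reference for the
score is not restated here), as is the eligibility threshold of 7 and
the minimum structure of proband + living sibling + offspring.

## Pedigrees and kinship

PED-style files (FID IID PAT MAT SEX + optional named columns) are
validated strictly: both-or-neither parents (a flag can auto-create
dummy founders), parent sexes, acyclicity, at least one founder.
Kinship uses the classical recursion in a parents-first topological
order; families are independent sampling units, so the matrix is block
diagonal and cross-family kinship is identically zero.  The
gene-dropping module provides the independent Monte-Carlo oracle:
transmitting uniquely labelled founder alleles down the pedigree and
averaging locus IBD over replicates recovers 2φ.

## Growth-curve (random-coefficient) model

Per trait we fit y_ij = (β₀+u_i0) + (β₁+u_i1)·t_ij + e_ij, with t the
years since the person's own Visit 1 (so the intercept is the expected
baseline value), (u_i0, u_i1) ~ N(0, G), e_ij ~ N(0, σ²_e).  The REML
objective is maximized by L-BFGS-B over a log-Cholesky parameterization
of G (PSD by construction) plus log σ_e, with two extra starts and a
Nelder-Mead polish if the quasi-Newton pass does not converge;
convergence tolerance 1e−8, 500 iterations.  Per-person computations
are closed-form 2×2 algebra vectorized over persons (a general path
handles other visit counts).  BLUPs are u_i = G Z_i' V_i^{-1} r_i; when
the fitted σ²_e is negligible this expression cancels catastrophically,
so the code switches to its analytic limit, the person's own
least-squares line.

Covariates are handled by pre-residualization (sex and field site
categorical, age and age² continuous; same-visit age for visit values,
baseline age for slope phenotypes), then the RCM is fitted to the
residuals.  Fitting covariates inside the mixed model would also be
defensible; the two-stage route keeps the REML kernel small and matches
the adjust-then-estimate workflow of the study design.

**Identifiability with two visits.** With t₁ = 0 for everyone and gaps
confined to 8–10 years, the observable covariance structure —
Var(y₁) = g₀₀+σ², Cov(y₁,y₂) = g₀₀+g₀₁Δ, Var(y₂) quadratic in Δ —
determines the individual parameters only through extrapolation of the
Δ-lines back to Δ = 0.  The totals are tightly estimated but the
split between g₀₀ and σ²_e (and between g₁₁ and σ²_e) is noisy, and in
some regimes the REML optimum sits at the σ²_e = 0 corner (verified
against lme4, which finds the same optima and issues the same
identifiability warning).  Consequently the tests assert recovery of
the identifiable covariance functionals rather than the raw G entries,
a warning is raised when all persons share an identical two-visit
layout (escalated to an error if the Hessian is numerically singular),
and the zero-measurement-error limit (σ²_e → 0, BLUP = per-person OLS
to 1e−6) is exercised with three visits per person — two exact points
carry no information that the data are noise-free.

## Heritability

For a person-level phenotype y (visit value, OLS slope, or GC slope)
the polygenic model is y ~ N(μ1, 2Φσ²_g + Iσ²_e).  Each family block
of 2Φ is eigendecomposed once; in the rotated basis the covariance is
diagonal with weights h·λ + (1−h), so the REML log-likelihood profiles
down to a one-dimensional search over h² ∈ [0,1] (total variance has a
closed-form profile; the grand mean is the only fixed effect, removed
REML-style).  A 21-point grid localizes the optimum, bounded scalar
minimization refines it (tolerance 1e−8), and endpoints are checked
explicitly so boundary estimates are reported as exactly 0 or 1.  The
LRT against σ²_g = 0 uses the ½χ²₀+½χ²₁ boundary mixture (p = 1 at the
boundary); the standard error comes from the numerical curvature of the
profiled likelihood (undefined at the boundary).  Eigenvalues are
floored at 1e−10; a sample in which 2Φ = I raises an explicit
"confounded" error.  Following the study's stated assumptions, mortality
selection and ascertainment are ignored, heritabilities are conditional
on having both visits when the caller applies that restriction, and no
household/shared-environment component is fitted — spouses therefore
act as genetically unrelated in-family controls.  Estimates are
invariant to affine transformations of the phenotype.

## Linkage and the rare-variant demonstration

Gene dropping assigns founders uniquely labelled alleles and transmits
one allele per parent uniformly at random; locus IBD proportions π̂ ∈
{0, ½, 1} come from label matching.  Causal variants can be placed in
founders (explicitly or at a given allele frequency) or introduced as
lineage-founding mutations in a named descendant.

`family_vc_lod` is the single-family building block: the log10
likelihood ratio of y ~ N(μ, Πσ²_q + 2Φσ²_g + Iσ²_e) against σ²_q = 0,
each side maximized for that family (L-BFGS-B with non-negativity
bounds, multi-start; LODs below 1e−6 snap to exactly 0, giving the
expected boundary mass of ~½ under no linkage).  Summing *per-family
maximized* LODs over a whole study is however strongly null-biased —
every family spends a free boundary parameter — so the study-level scan
(`study_vc_lods`) instead fits the background (σ²_g, σ²_e) jointly
under no linkage, forms per-family LOD curves over a shared σ²_q, and
maximizes the admixture likelihood Σ_f log10(α·10^{lod_f(σ²_q)} + 1−α)
over both α and σ²_q.  Per-family LODs are reported at the maximizing
σ²_q and may be negative (families arguing against linkage), exactly
the behaviour family-specific heterogeneity LOD scores rely on;
families with LOD > 0.2 are flagged as driving families.  The profiled
family mean carries a REML correction (−½ log 1'V⁻¹1); without it the
many small-family means make the null anti-conservative.  The reported
HLOD is evaluated exactly on a 1001-point α grid (ties to the smallest
α); a bounded local refinement exists behind `refine=True` but is off
by default so the value agrees with the brute-force grid oracle to
machine precision.

Two association comparators are provided.  The plain pooled score test
regresses the phenotype on carrier dosage and is calibrated under
permutation, but in a strongly familial cohort it is confounded:
carrier lineages share polygenic values, inflating the statistic.  The
kinship-adjusted test — the standard family-GWAS analysis — score-tests
each variant under the fitted polygenic covariance by GLS.  The
demonstration scenario judges "missed by association" on the adjusted
test and reports both.

**Demonstration scenario defaults** (a designed illustration, not a
cohort reproduction): 250 families of the default structure; 45 linked
families drawn from the mid-size band of 12–20 enrolled members; one
private causal variant per linked family, a single copy in one
ancestral founder, so about half the proband sibship and a quarter of
the offspring carry it while its pooled frequency stays below 0.5%;
carriers shifted by 3 residual SD; polygenic variance 3 and residual
variance 1 (a trait with strong familial clustering, h² = 0.75).  The
band matters in both directions: families must be large enough for
informative within-family IBD contrasts (sib-private mutations with
only 2–3 carriers carry almost no linkage information, because
parent-offspring IBD is constant at ½), yet small enough that no single
variant accumulates the dozen carriers that would let a direct
single-variant test reach genome-wide significance.  At these settings
the HLOD exceeds 3 in roughly 85–90% of seeds, the minimum adjusted
single-variant p stays above 5e−8 in over 90%, and the no-variant null
keeps HLOD ≤ 1 in ≥ 95% of seeds.

## Synthetic cohort

Each family is built around an unphenotyped ancestral founder couple
(generation "ancestor") whose children form the proband sibship —
without them the siblings would be genetically unrelated in the
pedigree.  Sibship size is 2 + negative-binomial(mean 1.1,
dispersion 2); offspring per sibling Poisson(1); a sibling with
offspring always has an enrolled spouse (the both-parents rule),
childless siblings with probability 0.3; offspring spouses with
probability 0.2.  These values were calibrated once so 500 default
families average ≈ 9.3 enrolled members (study target ≈ 9.1), with
totals truncated to [3, 79].  Proband lifespans come from a two-sex
Gompertz table with a female advantage (life expectancy in the low
80s); a censoring age ~ N(93, 4) converts survivors to "alive at c".
Every family draws from a deterministic substream seeded by
(seed, family index), so outputs are byte-identical across runs and
independent of iteration order.

Phenotypes: true intercept/slope = β + genetic + environmental
deviations; genetic deviations across a family have covariance
2Φ ⊗ G_g via the matrix square root of the kinship block, with
G_g/G_e built from per-component heritabilities and intercept–slope
correlations ρ_g, ρ_e.  Defaults describe a generic aging phenotype:
σ²_int = 10, σ²_slope = 0.01 /y², h² = 0.5 for both components,
ρ_g = ρ_e = 0.6, per-visit error variance σ²_e = 4, visits 8–10 years
apart, β = (50, −0.4).  Two of these choices carry the experiment:
σ²_e = 4 is large relative to the slope signal accumulated over the
visit window (0.01·81 ≈ 0.8), which is the regime where OLS change
scores lose their heritability; and the intercept–slope correlation is
what lets the growth-curve slope keep its heritability there — with
only two visits and *independent* components, BLUP shrinkage is nearly
uniform across persons and would scale the genetic and error parts of
the OLS slope equally, leaving its heritability unchanged.  With
correlated components (empirically reasonable: level predicts rate of
change in aging phenotypes) the BLUP slope legitimately borrows the
heritable level signal, and its heritability stays near the
cross-sectional magnitude while the OLS slope's collapses.

What the generator does **not** emulate: trait-specific means and
variances of the real cohort; mortality-driven attrition between visits
(a missing-at-random Visit-2 dropout flag exists instead, default 0);
ascertainment of families through the selection score (families are
simulated unconditionally); household environment; assortative mating.
Passing tests therefore show that the estimators recover the generating
model at realistic sizes — not that the real cohort's numbers would be
reproduced.

## Problem sizes

The test and acceptance runs use ~150 families (n ≈ 1,450 phenotyped)
for heritability and attenuation experiments with 20 seeds, 5 random
pedigrees × 200,000 gene drops for the kinship oracle, 10,000 sibships
for FLoSS calibration, and 250-family scans for the linkage
demonstration — sizes chosen so every stage is exercised at the study's
scale while a full run completes in about a minute on one CPU.

## Known limitations

* Linear time trends only; no multivariate-trait growth models; no
  informative dropout.
* Autosomal kinship only; no genotype-based (realized) kinship, no
  X-linked kinship, no inbreeding in the generator (the kinship code
  itself handles inbred pedigrees).
* Linkage uses simulation-true IBD, not marker-inferred IBD
  (no Lander-Green); the locus is abstract and VCF ingestion is out of
  scope.
* The heritability model has no dominance, household, or
  gene-environment components.
* The HLOD's α grid resolution (0.001) bounds the reported α̂, which is
  adequate for screening but not for interval estimation of α.
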
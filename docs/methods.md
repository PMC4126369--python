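# Methods

This note documents the statistical model, the estimators and their
numerical details, the synthetic-data generator, and the design choices
made where the design was genuinely open.  It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Score tests from within-family contrasts

**Model.**  The outcome Y takes unordered values 1…K; category K is the
reference.  For subject *i*, log( P[Y=k|X] / P[Y=K|X] ) = μ_k + β̃_k' X_ki,
where X collects genotype terms at up to two unlinked marker loci, each
marker coded as the *proportion* of a counted allele in the genotype
(0, ½, 1).  The term vocabulary is {x1, x2, x1·x2, x1·(1−x2)}; coefficients
may be shared across categories (shared labels must keep one term function).
Presets: full two-locus (K=4, nine slope labels), one-locus (one slope per
category), endophenotype-to-disease (locus 2 acts only in locus-1 carriers),
and the dichotomous two-locus logistic model.

**Scores.**  Within each family the n genotyped, phenotyped members are
ordered by category.  For a coefficient attached to category *a* the family
score is S_f = Σ_{i∈E_a} Σ_{j∉E_a} C_ij (x_i − x_j) with E_a the members in
category *a*; a shared coefficient pools the per-category double sums.
Families whose retained members all fall in one category contribute exactly
zero (non-informative).  Under a *global* null there are no free
coefficients and every weight is C_ij = 1/n.  Under a *conditional* null
the weights are logistic functions of u_ij = (X_i^c − X_j^c)'(α̃_{Y_i} −
α̃_{Y_j}): the default (`eq6`) C_ij = 2/(N(1+e^u)), the alternative (`eq7`)
C_ij = 8e^u/(N(1+e^u)³).  Intercepts cancel in u, so only nuisance slopes
enter.  The normalizer is N = n, the family's retained member count — the
model leaves N open, and this choice makes the α̃ = 0 reduction to the
equal-weight 1/n form exact (verified to 1e−14 in the tests).

**Nuisance coefficients α̃** are the pooled multinomial-logit fit of Y on
the free predictors (GEE with an independence working correlation has the
same estimating equations).  Their sampling variability is deliberately
neglected downstream — the weights treat α̃ as fixed — which is known to
make conditional tests somewhat conservative.  One fit serves a whole scan
(the free predictors involve only the conditioning locus), not one fit per
tested marker.

**Variances.**  For a main-effect term at locus L the family contribution
to Var[S] is the quadruple sum Σ C_ij C_kl (π_ik + π_jl − π_il − π_jk) σ²,
where π is the IBD sharing proportion at L and σ² the pooled within-family
variance of the term column, σ̂² = Σ_f Σ_i (x_fi − x̄_f)² / Σ_f (n_f − 1)
over families with n_f ≥ 2.  Product terms use the per-locus product
π1_ik·π2_ik as kernel with the pooled variance of the product column.
Model-based *covariances* between labels use: the shared locus' π for two
main effects at one locus, zero for main effects at different (unlinked)
loci, π1·π2 for two product terms, and the main term's locus π for a
main–product pair, each scaled by the pooled within-family covariance of
the two columns.  Two algebraically identical implementations exist: a
naive O(n⁴) quadruple sum and a grouped O(n²) path through per-member
weight margins; they agree to 1e−10 relative on random families and the
naive path is kept as a permanent cross-check.

**Null modes.**  Under the association-only null (linkage permitted) the
variance must use the realized IBD sharing π at the tested locus; under the
no-linkage-and-no-association null, or when IBD is unavailable, 2φ (twice
the kinship coefficient) substitutes, with a mandatory warning in the
unavailable case since conservativeness is then not guaranteed.

**Joint statistics.**  For a label set, T = S' v[S]⁻¹ S with a pseudo-
inverse when v[S] is singular; degrees of freedom are the numerical rank
(eigenvalues above 1e−8 of the largest).  An all-zero v[S] is flagged
untestable rather than producing a p-value.  For joint tests whose labels
span several outcome categories, the default v[S] is the *empirical*
between-family sum Σ_f S_f S_f′ — each family contribution has zero
expectation under the null, making this estimator consistent without
requiring the cross-category covariance algebra; for single labels the
model-based variance is the default.  The empirical kernel needs enough
informative families per category: with fewer families than labels a
rank-deficiency warning is emitted, and with nearly empty categories the
χ² approximation degrades (see Limitations).

**Comparators.**  The dichotomous GDT variants are the K = 2 case of the
same machinery: GDT (disease), GDTe (endophenotype), GDTc (disease among
endophenotype-impaired members, everyone else's phenotype set to missing —
variance components are recomputed within that subset, which *is* the
analysis sample), and the 2-df conditional tests of the dichotomous
two-locus model (cdisease/cendo).  The GEE-based Wald test uses the pooled
multinomial fit with a family-clustered sandwich covariance B⁻¹MB⁻¹; for
families of size one this reduces to the ordinary robust (Huber) variance,
which the tests verify against an independent implementation.

## Numerical choices

* Multinomial fits: damped Newton with analytic gradient/Hessian,
  step-halving line search, convergence when max|score| < 1e−8 or the
  relative log-likelihood change < 1e−10; deterministic given data order.
  A singular Hessian, non-convergence, or coefficients beyond ±15 (complete
  separation) trigger one refit with ridge penalty 1e−6 and a logged
  warning.  An empty outcome category is an error.
* Model-based variances below −1e−10 (relative) raise an error — they
  indicate inconsistent IBD input; tiny negative diagonals are clamped to 0.
* Members are ordered by category with a stable sort; all statistics are
  invariant to the input order of families.
* Replicate seeds derive from one master seed through a counter-based
  splitter (`numpy` SeedSequence), each below 2³¹.

## The synthetic-data generator

The generator emulates the two-locus study design the tests were built
for.  The canonical family is a 3-generation, 16-member pedigree: two
grandparents, four of their children each with an unrelated spouse, and six
grandchildren (two in each of three sibships), giving twelve first-cousin
pairs and six founders.  Founder alleles at the two causal loci are drawn
under Hardy–Weinberg equilibrium (risk allele frequencies 0.1 at locus 1,
0.3 at locus 2) and transmitted by Mendelian rules; distinct founder-allele
labels make every pair's realized IBD sharing exact.  A *null marker* at
locus 2 re-uses the locus-2 transmission pattern (so it is fully linked)
with independently drawn founder alleles (so it is in linkage equilibrium
with the causal variant) — association tests on it are null by
construction while IBD-dependent variances still see linkage.

Phenotypes follow a two-step scheme.  Step 1: the endophenotype indicator
Y1 is Bernoulli with P[(1,0)|X] + P[(1,1)|X] from the four-category model
(default coefficient table: intercepts −2, −5.5, −5.5; an x1 effect log 2
and x1·x2 effect −log 2 on the endophenotype-only category; an x1·x2
effect log 16 on the disease-plus-endophenotype category).  Step 2: the
disease indicator Y2 is Bernoulli on the logit scale with
γ(X, Y1) + U_i + α Σ_{h≠i}(Y1_h − ν)φ_ih, where γ(X, y1) is the
within-stratum log-odds implied by the same polytomous table — the unique
choice making the joint (Y1, Y2) distribution collapse exactly to the
polytomous model when σ² = α = 0, which the tests verify distributionally —
U ~ N(0, σ²Φ) is an additive polygenic effect (Φ the kinship matrix), and
the α term couples disease risk to relatives' endophenotype status.
Because genotype proportions take only the values {0, ½, 1} and intercept
shifts come from a small set, the per-member probabilities are evaluated on
a lookup grid — exact, and fast enough for the rejection sampling below.

Families are *ascertained*: kept only if some first-cousin pair has both
members disease-affected.  Under the two-population mixture, intercepts
shift by −0.5 / +0.5 and the null-marker allele frequency is 0.1 / 0.5 by
population; the two populations contribute **equal numbers of ascertained
families**, interleaved so any contiguous block of families keeps the mix.
The mixture describes the analyzed sample — if populations were mixed
before ascertainment, the higher-prevalence population would dominate the
kept families and most of the stratification contrast would vanish.

Unstated dependence parameters default to σ² = 1 (logit-scale polygenic
variance), α = 1 (relative-endophenotype coupling), ν = 0.128 (the
endophenotype population prevalence, so an unimpaired relative is mildly
protective and an impaired one risk-increasing).  Type I error of the valid
tests is insensitive to these; they are configuration-exposed, and every
experiment report records the scenario used.

**What the generator does not emulate:** genotyping error and missing
data, Mendelian inconsistencies, varying pedigree structures within one
sample, phenocopies or liability-threshold disease models, linkage
disequilibrium between the two loci, and real ascertainment complexity
beyond the single cousin-pair rule.  Passing tests therefore demonstrate
the statistical properties of the tests under this generating model, not
robustness to data-quality artifacts.

## Experiment harness

Type-I-error runs simulate replicates of 100 ascertained families and test
the null marker at locus 2 under the association-only null (true simulated
IBD), with conditional tests conditioning on the causal locus-1 variant and
pair weights from the default logistic expression; power runs test the
causal locus-2 variant on the same replicates.  The acceptance experiments
use 250 replicates — enough for 3-binomial-SE bands of a few hundredths at
the 0.05 level while keeping a full run in minutes on one CPU; replicate
counts are configurable.  Scans of file-based data emit one TSV row per
marker per test with raw p-values only (no multiplicity adjustment); a
tested marker equal to the conditioning marker is flagged degenerate
rather than tested.

## Known limitations

* Score tests provide no estimates of the tested coefficients.
* Conditional tests are conservative (the α̃ variability is neglected);
  the 6-df conditional test is noticeably below nominal.
* The empirical covariance kernel needs informative families in every
  involved category: in unascertained samples of a rare phenotype the
  joint-test χ² approximation degrades long before the single-coefficient
  tests do.
* The one-sided restricted alternative for the endophenotype-to-disease
  conditional test (both coefficients of common sign) is noted but not
  implemented; tests are two-sided/general.
* Only two loci are supported in the term vocabulary; environmental
  covariates are out of scope.
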
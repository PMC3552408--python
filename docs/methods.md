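# Methods

## The analysis in one paragraph

Local adaptation is read off a paired transplant design: for each of several
local/foreign population pairs, seed from both populations is grown under the
local population's conditions and the local-minus-foreign fitness
differential is measured. The differentials are then regressed on candidate
pair-level predictors — geographic distance, environmental distance,
quantitative genetic differentiation (Q_ST), neutral differentiation (F_ST)
and the sizes of the two populations — while Mantel tests relate the
predictor matrices to each other. Everything in this package serves one of
those stages.

## Quantitative differentiation (Q_ST)

For each unordered population pair and trait, a two-level nested random
model (population / maternal family within population / residual) is fitted
on the two-population subset by Henderson's method of moments: the observed
mean squares are equated to their expectations under the unbalanced nested
ANOVA (Searle's coefficients), and the resulting linear system is solved
sequentially for V_res, V_fam and V_B. Method of moments was chosen over
REML deliberately: it is closed-form, transparent, and exactly checkable
against hand-solved expected-mean-square systems, which the test suite does
on balanced fixtures. Negative solutions are truncated to zero after
solving. Populations contributing fewer than two families with data for a
trait are excluded from that trait's pairs with a warning.

Q_ST = V_B / (V_B + 2·V_GW). Two readings of the within-population additive
variance V_GW are implemented because maternal (open-pollinated,
predominantly half-sib) designs support both:

* `heritability_scaled` (default): V_GW = h²·V_W with V_W = V_fam + V_res,
  the total within-population phenotypic variance — the natural definition
  when h² is measured against total phenotypic variance. h² is a required
  user input per trait (no default other than 1.0, which reduces to the
  classical V_B/(V_B + 2V_A) form when V_W is additive). Under this variant
  the half- and full-sib models coincide given the same component fit.
* `literal_4x`: the classical sib identity, V_A = 4·V_fam for half-sibs and
  2·V_fam for full-sibs, ignoring h². Here the sib models genuinely differ;
  the `half_full_sib_concordance` diagnostic correlates the two pairwise
  vectors and is near 1 whenever family variance is moderate.

Estimates are clamped to [0, 1], and 0/0 is defined as 0.

**What pairwise Q_ST estimates.** With only two populations the
between-population mean square has a single degree of freedom, so a pairwise
estimate is extremely noisy and the ratio is biased toward zero relative to
the *parameter* V_B/(V_B + 2V_GW) (Jensen's inequality on a χ²₁-scale
numerator; we measure the effect at roughly −0.09 at a parameter truth of
1/3 under the default study sizes). The estimand a pairwise estimate tracks
is the *realized* differentiation of the two drawn populations,
s²/(s² + 2V_GW) with s² = (e_a − e_b)²/2. The synthetic-data truth records
therefore store realized pairwise Q_ST alongside the parameter value, and
recovery tests score the estimator against the realized truth. Against that
estimand the estimator is nearly unbiased (measured tracking error ≈
−0.006 ± 0.016 per replicate at the default sizes).

## Neutral differentiation (θ) and diversity

Weir & Cockerham's (1984) θ is computed per locus and allele from the a
(among-population), b (among-individual) and c (within-individual) variance
components, multi-allelic, with missing genotypes excluded per locus and
pairwise-complete loci only; components are summed over alleles and loci
before the single ratio θ = Σa/Σ(a+b+c) is taken (ratio of sums — the test
suite asserts this differs from the mean of per-locus ratios on a fixture
where they disagree). Slightly negative θ is a legitimate estimator outcome
and passes through, including into Rousset's F_ST/(1−F_ST) linearization.

Diversity per population: H_O as the fraction of heterozygotes, Nei's
unbiased H_E = (2n/(2n−1))(1−Σp̂²), A_e = 1/Σp̂², and F_IS = 1 − H_O/H_E
averaged over polymorphic loci. The simple F_IS form (rather than Weir &
Cockerham's f) is a documented divergence risk against variance-component
implementations.

ΔK consumes externally produced clustering log-likelihood traces (K,
replicate, lnL): ΔK(K) = |L̄(K+1) − 2L̄(K) + L̄(K−1)| / sd(L(K)), sample sd
over replicates; the best K maximizes ΔK over interior K, and
zero-curvature traces are flagged ambiguous rather than assigned a winner.
The clustering MCMC itself is out of scope.

## Environmental distance

Variable filtering is greedy: among all pairs with Pearson-correlation
p < 0.001 (two-tailed t approximation), the variable in the most offending
pairs is dropped (ties: larger mean |r|, then alphabetical) until no pair
offends; constant variables are dropped first as zero-variance. The rule is
idempotent. Ordination is PCA on the correlation matrix (variables
standardized), components retained by the Kaiser eigenvalue-greater-than-one
rule or a fixed count, and loadings varimax-rotated (Kaiser-normalized,
tolerance 1e-8, at most 1000 iterations) with scores rotated consistently —
communalities and all-component score distances are invariant to the
rotation, which the tests check. Whether to standardize and which rotation
to use were genuinely open choices; z-scoring plus varimax are the
conventional defaults and both are configurable (`rotation="none"`,
`retain="fixed:k"`). Environmental distance is the Euclidean distance
between rotated factor scores; composite, soil-only and climate-only
matrices come from the same sites by variable selection.

## Mantel tests

r is the Pearson correlation of upper-triangle entries; the null permutes
rows and columns of one matrix simultaneously (object relabeling — the only
exchangeable null for distance matrices). p = (#extreme + 1)/(n_perm + 1),
never zero, two-tailed by default (tails are configurable since report
conventions differ). Permutations are generated from a seeded NumPy
generator in vectorized batches; 10 000 permutations is the default. The
implementation is validated against full 4!-enumeration, checked for
type-I calibration at α = 0.05 over 1000 null datasets, and cross-checked
for r against scikit-bio.

## Transplant analysis

Differentials: delta_pct = 100·(local − foreign)/foreign, positive = local
adaptation. Survival uses family-pooled proportions (among germinated pots);
biomass and inflorescence counts use means over survivors. A zero foreign
mean yields the absolute difference with an explicit flag. The denominator
convention (foreign vs local mean) is configurable in effect by swapping
labels; the default is foreign.

Origin tests: the original design's random block/row/column/family GLMM
structure is deliberately replaced by a fixed-effects two-way ANOVA (origin,
pair, origin × pair) on family means — biomass as the family mean over
survivors, survival as the empirical logit log((s+0.5)/(n−s+0.5)) of pooled
family counts, reproduction as log(mean + 1). Aggregating to family means
removes the within-family design strata while preserving the origin × pair
inference target, and keeps the machinery transparent at desk scale; it is
the package's main modeling divergence from a full REML/GLMM treatment.
Family seed weight can optionally be residualized out first (maternal-effect
adjustment). Per-pair local/foreign contrasts use LSD with the pooled
residual mean square at a corrected α, default 0.034 — the constant
appropriate for three correlated fitness traits — kept as configuration, not
derived.

Regressions: forward selection from the intercept-only model over
{log₁₀ local N, log₁₀ foreign N, log₁₀ distance, environmental distance,
Q_ST, F_ST}, adding the predictor that minimizes AIC = n·ln(RSS/n) + 2k
(k counts all mean parameters) while AIC decreases, capped at two terms
because twelve pairs cannot support more. Logarithms are base 10. Candidates
that push the design-matrix condition number above 1e8 are refused. The
final OLS model's overall F-test is judged at α = 0.025 (Bonferroni 0.05/2
for pairs sharing a home population). Post-selection inference is biased
under the null — the test suite measures the inflation and brackets it
between the nominal α and the union bound over candidate models — which is
precisely why the conservative α is the default.

## Synthetic data: what it emulates and what it does not

The generators mirror the emulated study system's design constants: 15
populations, 22–30 (default 25) maternal families each, 1–4 (default 4)
measured offspring per family, 10 multi-allelic microsatellite loci, two
climate zones ~500 km apart with within-zone spreads to ~80 km, mosaic
(geography-independent) soil variation with planted collinear blocks, and 12
transplant pairs × 15 family pairs × 2 origins × 4 blocks = 1440 pots with
three seeds sown per pot and thinning to one seedling. Traits are Gaussian
with additive population, family and residual effects; markers follow
Balding–Nichols Dirichlet divergence (chosen because it gives a closed-form
frequency-level θ target; default F = 0.05, matching weak neutral structure
under high gene flow); biomass is log-normal (strictly positive,
right-skewed); inflorescence counts are Poisson; germination and survival
are Bernoulli with logit-scale origin effects (defaults 0.85 and 0.95).
Population sizes are log-uniform over 10²–10⁵ and pair distances log-uniform
over 0.7–600 km, the ranges of the emulated system. Every generator is a
pure function of (config, seed).

Not emulated: pedigrees beyond half-sib family effects, self-incompatibility
dynamics, spatially explicit dispersal or isolation by distance in the
markers, genotype × environment interaction in the traits, and maternal
environmental carry-over beyond a family seed-weight covariate. Passing
tests therefore demonstrate correctness of the estimators and calibration of
the tests under these idealized conditions, not robustness to the
correlated, non-Gaussian structure of real field data.

## Numerical and degenerate-input choices

Distance matrices are symmetrized exactly at construction and reject
asymmetry beyond 1e-9 and any nonzero diagonal; F_ST matrices may carry
negative entries, geographic matrices may not. Zero total trait variance
yields all-zero components with a warning; a population with one family is
an error naming the population; θ with no co-polymorphic locus, Mantel with
a constant triangle, ΔK with zero replicate sd, and linearization at
F_ST = 1 are all errors naming the offending input. Mantel p-values use the
+1 convention; AIC ties keep the earlier candidate; variance-component
truncation happens after the full solve.

## Problem sizes used in the checks

Recovery and calibration checks run at the design's own scale where that is
cheap (15 populations → 105 pairs; 1440 pots) and at reduced replicate
counts elsewhere, chosen as the package's own testing budget: 200 replicates
for Q_ST recovery and variance-component unbiasedness, 50 seeds per
divergence level for θ recovery, 10⁵ permutations against the exact 4!
Mantel enumeration, 1000 null datasets (199 permutations each) for type-I
calibration, and 60–200 replicates for the transplant ANOVA null and power
simulations.

## Known limitations

REML/GLMM estimation, partial Mantel tests, Hardy–Weinberg and linkage
diagnostics, null-allele inference, admixture MCMC, and bioclimatic raster
extraction are out of scope; environment variables arrive as numbers.
Pairwise Q_ST at two populations is intrinsically low-precision (one df
between populations) — matrices built from it are meaningful in aggregate
(Mantel tests, regressions) but individual entries carry wide sampling
error. The greedy correlation filter is order-deterministic but, like any
greedy rule, not guaranteed to keep the globally least-correlated subset.
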
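# Methods

`seqdesign` implements the statistical machinery for planning and analyzing
next-generation sequencing studies built on top of an existing GWAS or a
family registry: a haplotype-pool simulator, rare-variant disease models,
two-phase (subsample-sequencing) burden estimators with design optimization,
pedigree gene dropping with four variant-prioritization criteria, and an
analytic two-stage power/cost engine.  This note records the models, their
assumptions, the numerical choices, and what the simulations do and do not
establish.

## Haplotype pool

All simulators draw from a single phased pool of binary haplotypes over one
contiguous region.  The default demography is the two-deme calibrated human
model (cosi "bestfit" parameterization): an African lineage (ancient size
12,500 diploids, growing to 24,000 and then 100,000), a European lineage
splitting off 3,500 generations ago through an out-of-Africa bottleneck
(F = 0.085), a second European bottleneck (F = 0.02) 2,000 generations ago,
agricultural-era size 7,700, expansion to 100,000 in the last 350
generations, and symmetric Africa–Europe migration (3.2e-5/generation)
while both demes exist.  Mutation rate 1.5e-8/bp/generation, recombination
1e-8.  The model runs on msprime with bottlenecks expressed as
instantaneous-bottleneck events of strength −2N·log(1−F) equivalent
generations; the merge of Europe into Africa is a mass migration so both
demes stay active during the migration epoch.  Population sizes are diploid
and samples are diploid individuals (two haplotypes each); a haploid sample
size is honored by truncation.

At the working scale (10,000 haplotypes × 250 kb) a realization carries
roughly 5,000 segregating sites, of which about 94% of the rare
(MAF < 0.05) variants are below MAF 0.01 and about 78% below 0.001 — the
heavy rare-variant excess that drives every design question downstream.
A constant-size coalescent (`demography="constant"`) is available for unit
testing and neutral baselines; its segregating-site count follows the
Watterson expectation with θ = 4Nμ per bp.  ms-format read/write round-trips
the allele matrix exactly; duplicate positions on import are retained in
column order by default.

## Disease models

**Flat rare-variant model.**  Each variant is causal with probability
π(q) = π₀·min(1, q₀/q) (defaults π₀ = 0.05, q₀ = 0.001) and causal variants
receive a log relative risk |N(0, τ(q)²)| with τ(q) = c/√q capped at
log 20 (the cap binding at q = 1e-4).  These curves reproduce the intended
qualitative structure — both the probability and the size of an effect
decrease with MAF — but the exact published generating distributions are
not recoverable, so the defaults are explicit, configurable stand-ins.
A subject's genetic log RR is the per-allele sum Σ β_v g_v (g ∈ {0,1,2});
disease is Bernoulli(expit(intercept + log RR)).  The intercept is
calibrated to a target prevalence (default 5%) by bisection on a
Monte-Carlo prevalence curve (200,000 diplotypes), exact in closed form
when no variant is causal.

**Multilevel model.**  100 pathways of 1–20 genes, each gene split into
three region classes; pathways, genes, and variants are flagged causal
independently and a variant has an effect only if all three levels are
flagged (AND rule).  Causal log RRs are sums of half-normal pathway-, gene-
and variant-level draws, the variant scale depending on region class and
MAF.  Cohorts are sampled to per-(age, family-history, disease-state)
stratum targets, with a three-category outcome (unaffected / unilateral /
bilateral) whose "case" is the bilateral category.  Disease rates scale
the base rates by exp(log RR − population mean log RR), so the base rates
refer to a subject of average genetic load; family history is Bernoulli
with log-odds increasing in the centered genetic RR (a single-relative
liability stand-in — no published formula exists).  The default stratum
table is likewise a stand-in, since the original's is unavailable.

## Two-phase estimation

Phase 1 is a parent case-control study with common-SNP genotypes.  A
replicate enters the sequencing stage only if some common SNP (MAF > 5%)
passes Bonferroni-corrected association at family α = 0.05 (allelic
two-proportion test).  The risk index is a multiple logistic regression of
disease on greedily r² < 0.8-pruned common SNPs, cut at its 25th/75th
percentiles into three strata V.  The expensive covariate X is the
Madsen–Browning burden: rare-allele counts weighted by 1/√q, with q taken
from parent-study controls floored at 1/(2·n_controls) and a 0.05 rare
threshold.

Four estimators of the burden log-odds ratio are fitted to the (Y, V)
frame plus the sequenced subsample:

- **Imputation**: linear X|V on the subsample, logistic Y on X̂ over the
  cohort (observed X used where measured, which makes the estimator
  collapse to the complete-data MLE under full sampling); robust sandwich
  SE.
- **Weighted likelihood**: Horvitz–Thompson weighted score equation with
  weights N_yv/n_yv; stratified, finite-population-corrected sandwich SE.
  Extreme weights (> 100) are flagged.
- **Pseudo-likelihood (Breslow–Cain)**: offset logistic regression on the
  subsample with fixed stratum offsets log(n1v/n0v) − log(N1v/N0v);
  variance = conditional sandwich plus a delta-method term for the
  estimated phase-1 log odds.
- **Semiparametric ML**: the profile likelihood of the full two-phase
  model with X|V nonparametric.  The fit alternates a weighted logistic
  maximization against updates of the per-stratum covariate masses and the
  implied stratum case probabilities from their constraint equations; we
  run this alternation in its EM form (phase-1-only subjects spread over
  the observed covariate support with posterior weights), which increases
  the true semiparametric likelihood monotonically — the raw offset
  iteration can diverge because the offset objective is unbounded in the
  nuisance probabilities away from self-consistency.  SEs come from the
  numerical curvature of the profile log-likelihood (inner maximization by
  EM to 1e-14).  Convergence tolerance 1e-8 on the burden coefficient,
  200 outer iterations maximum.

All four coincide with the ordinary logistic MLE when the subsample is the
cohort, and the SPML is verified against brute-force numerical
maximization of the full semiparametric likelihood on a binary-X toy.

A note on the efficiency comparison: with the continuous risk index in the
linear predictor, the three-stratum summary V is nearly ancillary and the
pseudo-likelihood is already close to fully efficient, so adjusted PL and
SPML differ by less than Monte-Carlo noise at test scale.  The shipped
efficiency-ordering experiment therefore runs the unadjusted burden fit,
where the phase-1 stratum margins are genuinely informative and the
ranking (SPML above PL and imputation) is identifiable; it uses 250 gated
replicates of a 400-subject cohort with 120 sequenced, effects strong
enough that the complete-data Wald Z is near 2, comparable to the
published full-study signal.  The reported summary is the mean estimate
divided by its empirical SD across replicates, the same standardization
used in the published table.

## Design optimization

The design objective is the likelihood-ratio non-centrality parameter
λ = 2·E[l(θ_A) − l(θ̂₀)] of the semiparametric burden test, evaluated on
the expected data of a super-population specification (expected cell sizes
N_yv, empirical conditional laws Pr(X|Y,V)).  Both the unrestricted and
the null (no burden effect) expected log-likelihoods are maximized by the
same EM used for estimation, on probability-weighted rows.  λ is zero when
X carries no outcome information, linear under joint scaling of N and n,
and monotone in each cell size.  Allocation search is a multi-start SLSQP
on the sampling fractions under the budget constraint, with candidates
judged only after largest-remainder rounding to feasible integer counts;
among allocations within 0.1% of the best, the representative balanced
across exchangeable strata is preferred (the NCP surface is flat across
strata with identical frames, so this is a deterministic tie-break, not a
sacrifice of the optimum).

## Expected-yield calculator

Over a geometric (MAF, RR) grid, the probability that a variant is seen at
least c times in an enriched sequencing subsample uses a Poisson count
with rate 2nq′, where q′ mixes the case allele frequency
qRR/(1 − q + qRR) by the subsample's case fraction; novelty against a
reference panel is the Poisson probability of at most c′ copies in 1,000
controls.  Both approximations are within 0.01 of the exact binomial for
q ≤ 0.01.  Association power in the main study uses the stratified
Mantel–Haenszel normal approximation,
power = Φ(√NCP − z) + Φ(−√NCP − z) with z at the Bonferroni-corrected
two-sided level, the correction spanning the *expected* prioritized count;
the NCP is the inverse-variance-weighted squared allele-frequency
contrast, reducing to the standard two-proportion formula with one
stratum.  Yield tables are linear in per-bin variant counts and monotone
in both filters.  The aggregate path (variant / gene-region / gene /
pathway) screens subsample rare-allele burdens against their population
expectation by a one-sided Poisson exceedance test at α₁ (default 0.01
over the discovered count) and CMH-tests survivors in the main cohort,
stratified on age and family history.

## Pedigree simulation and prioritization

The working pedigree is fixed: 4 generations, two offspring per couple,
spouses marrying in for every non-terminal child — 22 members, 7 nuclear
families, 8 founders.  The published structure gives only these counts;
this tree is one consistent realization, and an 11-member sub-pedigree
(grandparental couple, sibships of 3 and 2, mutual first cousins) supports
exhaustive enumeration.  Founders draw two pool haplotypes; descendants
inherit one complete parental haplotype by a fair coin (no recombination
within the region, so single-variant transmission is exactly Mendelian).
Families are rejection-sampled until the target number with ≥ min_cases
(default 4) affected members is reached; a progress guard raises when the
ascertainment probability is effectively zero.  Sequencing subsets are
selected by a relationship-pattern code (S sib, C cousin, 2 cousin once
removed, U uncle/aunt, G grandparent, P parent; upper case affected),
matched against the pedigree by backtracking with seeded tie-breaks.

Prioritization criteria:

- **Rule count** — families where every sequenced case carries the variant
  and no sequenced control does.
- **Retrospective likelihood ratio** — Pr(G_obs|Y; β, q)/Pr(G_obs|q) with
  unobserved genotypes summed out by pedigree peeling (vectorized across
  families and parameter draws; validated against 3^11 enumeration on the
  sub-pedigree to 1e-10).  The null is genotype–phenotype independence, so
  the marginal disease rate cancels and LR(β = 0) ≡ 1 exactly.
- **Bayes factor** — the same ratio with (q, β) averaged over 100 prior
  draws under the alternative and null; one draw set is shared across
  variants (common random numbers) so prior noise does not churn
  rankings.  A point-mass prior collapses the BF onto the LR exactly.
  Default priors resample q from the pool's rare-MAF spectrum with the
  generating half-normal for β|q.
- **Kinship score test** — T_v = Σ_f Σ_{ij} (Y_fi − p_f) K_fij (G_fjv −
  q_fv), genotype deviations zeroed for untyped members so their
  phenotypes still enter through kinship cross terms; var(T) = Σ_f t².
  The published display gives both a K⁻¹ matrix form and an expanded
  K-entry form; the K-entry form is the default because it is the one
  consistent with the stated zero-deviation convention for untyped
  members, and a flag switches to K⁻¹.  "Within" mode centers by
  family-specific prevalence and sequenced-genotype mean (families whose
  sequenced members are all carriers or all non-carriers drop out);
  "combined" centers by ensemble grand means.
- **Regional test** — Q = Σ_v T_v², referred to the exact null of a
  weighted sum of chi-squares (weights = eigenvalues of the per-family
  contribution covariance) by Imhof's inversion integral, with a
  Satterthwaite moment match as numerical fallback.  The published
  regional display is typographically garbled; this is the standard
  family-data quadratic-form reduction, and a single-variant region
  reproduces the score test's chi-square p-value exactly.  Under null
  gene dropping the single-variant size at α = 0.05 sits inside the
  binomial 95% band and the regional p-values pass a
  Kolmogorov–Smirnov uniformity check over 2,000 replicates.

## Two-stage power and cost

Per (MAF, RR) bin, a calibration simulation (or the closed form, for
case-control sampling) supplies the expected number of sampling units
carrying the variant among sequenced members and the score-test
non-centrality, both per unit so that rescaling to a proposed design is
linear.  Discovery is the Poisson tail at c_min of the rescaled carriage;
prioritization the non-central chi-square tail at the stage-1 threshold;
replication the non-central chi-square tail at the Bonferroni-corrected
critical value, the correction spanning the expected prioritized count
with null variants scaled to a genome of 20 million variants (1,000
causal) by default.  Overall power is the product of the three — valid
because the stages use independent samples — and is verified against a
full joint gene-dropping Monte-Carlo at a reduced scale (one causal
variant q = 0.05, RR = 3, 150 + 150 families) where the normal/chi-square
approximations themselves are accurate; at very small family counts or
with near-deterministic penetrance the self-normalized score statistic is
lighter-tailed than its non-central chi-square reference, so analytic
power is optimistic there (a limitation shared by the rescaling method
itself).  The cost model is itemized — enrollment per family or subject,
sequencing per stage-1 genome, stage-2 genotyping per member × prioritized
variant — because the published cost arithmetic is not decomposed; ARCE
(true positives weighted by 1/√MAF over total cost) ranks designs and is
invariant to uniform cost rescaling.

## Problem sizes and reproducibility

Default test and acceptance scales: 10 replicate coalescent simulations at
10,000 × 250 kb for the spectrum; 250 gated two-phase replicates at
400/120; 2,000 null family replicates of 150 families each for score-test
calibration; 500 variants × 300 families for the ROC comparison; 200
joint-MC replicates for the two-stage product rule.  Every stochastic
routine takes an explicit seed and identical seed + configuration
reproduce outputs bit-for-bit; the CLI writes the resolved configuration
next to every artifact.

## Known limitations

- The exact published effect-size distributions, stratum tables, and the
  original haplotype realization are unavailable; all corresponding
  defaults are documented stand-ins, so published table *values* are not
  reproduced — only the structural and qualitative behavior.
- The generator draws diplotypes from a finite simulated pool, so strong
  short-range LD (and at small pool sizes, repeated haplotypes) is part of
  the test conditions; passing tests demonstrate correctness of the
  estimators and calibrations under these conditions, not performance on
  any particular real cohort.
- Peeling assumes marry-in founder spouses (true of the shipped
  pedigrees); looped pedigrees are not supported.
- Calibrated/estimated-weight WL variants and simultaneous nuisance/effect
  pseudo-likelihood estimation are out of scope.
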
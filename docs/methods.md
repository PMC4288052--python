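# Methods

`locusfine` re-implements, as a tested library, the complete statistical
analysis of a fine-mapping study of a single autoimmune-disease risk locus:
quality control, ancestry adjustment, frequentist and Bayesian association,
conditional modelling, LD/haplotype structure, a rare-variant burden test,
and the quantification formulas of the accompanying functional assays.  The
original cohort is not deposited anywhere, so every stage is exercised on
synthetic admixed case-control cohorts whose design mirrors the study:
four ancestral groups, a European-ancestry arm of 4220 cases and 3803
controls, ~57 genotyped variants across a ~400 kb region, a single causal
variant with risk-allele frequency 0.30 and odds ratio 0.81, missingness
below 5%, cryptic relatedness, and rare variants below 1% frequency.

## The synthetic cohort generator

**Haplotype pools.** A pool is a set of distinct haplotypes with sampling
probabilities.  Haplotypes are emitted by copying from a small set of
*template* haplotypes with a per-step template re-draw ("recombination")
probability: near zero inside an LD block, larger (default 0.5) at block
boundaries.  Template alleles follow an infinite-sites mutation tree, so
carrier sets are laminar and no variant pair among templates ever shows all
four gametes — within a block, |D'| = 1 throughout, which is exactly the
signal the four-gamete block finder keys on.  This is deliberately not a
coalescent: it is the minimal seedable structure that produces block LD,
and it makes no claim of recombination-map realism.

**Shared templates across ancestries.** The four ancestral pools share one
template structure per block and differ in template *frequencies* (drawn
independently per pool from a flat Dirichlet).  Continental populations
share old common haplotypes at different frequencies, and the emulated
locus is reported as one large common risk haplotype with many r² > 0.9
proxies; sharing the structure reproduces that tight cohort-level LD.  (An
earlier variant of the generator drew independent template trees per
ancestry; admixture then produced dozens of only weakly-correlated
genotype columns, so conditioning on the causal variant left spurious
residual hits from sheer multiplicity — a diffuse structure the emulated
locus does not have.)

**Disease model.** Status is drawn from logit P(case) = mu + beta*G + s·q,
with beta = log(OR) on the causal allele count, q the individual's
Dirichlet admixture proportions, and s an optional per-ancestry baseline
shift (zero by default; used to build stratified-null experiments).  The
intercept mu is solved by bisection (tolerance 1e-6) so the expected case
fraction matches the design ratio on a 20 000-draw calibration sample;
exact case/control counts are then filled by rejection sampling, which
fails loudly after a bounded number of batches if the configuration makes
one class too rare.  The generator treats the case:control ratio as a
design parameter, not an epidemiological prevalence, matching the
retrospective ascertainment of the study.  Because logistic regression is
collapsible-with-intercept under outcome-dependent sampling, the
odds-ratio scale is preserved, and the causal variant's pool frequency is
rescaled exactly to the target risk-allele frequency, so the empirical
cohort MAF lands within sampling error of 0.30.

**AIMs.** Ancestry-informative markers are simulated unlinked: each allele
copy draws its ancestral origin per marker from q, then the allele from
that population's panel frequency.  Panel frequencies come from a bimodal
Beta(0.25, 0.25) — AIMs are, by definition, markers near-fixed for
different alleles in different populations; with flat-uniform frequencies a
single individual's admixture MLE is too noisy to be useful (we verified
with a grid-search oracle that the noise is in the MLE, not the EM).

**Other features.** Missingness is masked uniformly at a configurable rate
(default 2%), optionally with excess case missingness at flagged variants.
Imputation-style genotype probabilities put mass `certainty` on the true
genotype and split the remainder randomly.  Relatedness is injected by
overwriting one member of a pair (duplicates copy genotypes;
parent-offspring transmit one allele; full sibs share each parental allele
with probability 1/2).  Rare variants are independent sites with MAF
uniform on [0.0005, 0.01], optionally case-enriched for burden-test power
experiments.  Assay tables put the protective group on a saturating
percent-internalization curve 70·(1−exp(−t/10)) and scale the risk group
by a multiplicative `effect` before Gaussian noise; gMFI columns are
reconstructed so the percent-internalization formula recovers the
simulated values exactly.

What the generator does *not* emulate: coalescent genealogies, genotyping
batch effects, imputation-panel mismatch, X-chromosome inheritance, or
linkage between the rare sites and the common haplotypes.  Passing tests
therefore demonstrate correctness of the statistical machinery under the
stated model, not robustness to artefacts real data may carry.

## Quality control

Variant filters run in a fixed, recorded order — call rate ≥ 0.90, MAF >
0.01, differential case/control missingness p > 0.05, Hardy-Weinberg exact
p ≥ 1e-4 in controls — and each removed variant carries the first reason
that failed, making `variant_qc` idempotent.  The HWE test conditions on
the allele-count margin and sums the probabilities of all heterozygote
counts no more probable than the observed one (the standard two-sided
exact convention; the source analysis names only the threshold).
Differential missingness uses a 2×2 chi-square without continuity
correction, replaced by Fisher's exact test when any expected cell is ≤ 5
(≤ rather than < so that the boundary case lands on the exact side).
MAF for the filter is computed on the post-sample-QC cohort, cases plus
controls — the same denominator used for minor-allele orientation.

IBD uses the method-of-moments identity-state estimator on variants with
MAF ≥ 0.05 (≥ 100 informative pairs required): observed IBS counts are
matched to their expectations under IBD states 0/1/2, negative estimates
clamped and renormalized, pi-hat = P(IBD2) + P(IBD1)/2.  Pairs with pi-hat
> 0.4 are pruned greedily in descending pi-hat; within a pair the first
discriminating rule of five decides (lower call rate; control before case;
male before female; younger control before older; case with less complete
phenotype data), with a deterministic id-based fallback.  The prune never
removes both members of a pair.

Sample QC removes call rate < 0.90 and heterozygosity beyond 3 SD of the
cohort mean heterozygous fraction.  The study's X-based sex check is
reduced to a metadata consistency check because the region is autosomal.

Imputed variants carry the ratio-of-variances information score
info = 1 − Σ(f_i − e_i²) / (2N·θ(1−θ)), clamped to [0, 1] and defined as 0
for an expected-monomorphic site; the hard-call rule calls the genotype
whose posterior reaches 0.5, leaves ties and sub-threshold triplets
missing, and dosages are e_i = P(het) + 2·P(hom-minor).

## Ancestry

PCA standardizes AIM genotypes by (g − 2p)/sqrt(p(1−p)) with mean
imputation of missing cells, takes the SVD, and fixes each component's
sign by its largest-magnitude loading, so scores are fully deterministic.
Admixture proportions are supervised maximum likelihood against the known
ancestral panel under binomial allele sampling, fitted by EM on the mixing
weights to 1e-7; a panel with identical rows is flagged unidentifiable and
returns the uniform simplex point.  Supervised rather than unsupervised
estimation matches the AIM-based design, and the synthetic generator knows
its pools.  Outliers are flagged by an iterated SD rule (default 6 SD on
any of the first three PCs, recomputing moments after each removal, at
most 5 rounds) — a reproducible stand-in for the study's visual
inspection; the threshold is exposed because the study does not state one.

## Frequentist association

Logistic regression is fitted in-house by Newton/IRLS with step halving,
gradient tolerance 1e-8.  Collinear columns are dropped by sequential
Gram-Schmidt keeping the *earliest* columns; single-variant tests place
the tested genotype term last, so a variant perfectly collinear with its
conditioning set is reported as such instead of silently displacing the
conditioning column (a pivoted-QR dropping rule does exactly that wrong
thing, and it matters constantly in high-LD regions).  A coefficient above
15 on an unpenalized column is reported as (quasi-)separation with an
infinite-SE sentinel.

Codings: additive {0,1,2} (the primary model), dominant, recessive,
genotypic (two indicators, 2-df LRT), Cochran-Armitage trend (the score
test of the additive model without covariates), and dosages in [0, 2] for
imputed variants.  Wald p-values for 1-df tests, LRT for the genotypic
test.  Model comparison is reported, never auto-selected.

Stepwise conditioning adds the most significant variant's allelic dosage
to the model until no variant reaches p_in = 0.01, and emits for every
candidate conditioning variant the strongest residual signal left in the
region — the profile of each variant's ability to account for the
association.

The power calculator computes the trend-test operating characteristics
under Hardy-Weinberg genotype frequencies and the same retrospective
logistic sampling the generator uses: genotype distributions in cases and
controls follow from the solved intercept, and power is a normal
approximation with the alternative-hypothesis variance.  It agrees with a
multinomial simulation of the test within Monte-Carlo error.

## Bayesian fine-mapping

Per variant, H1 is logit P(case) = mu + beta*G (+ covariates), with
mu ~ N(0,1), beta ~ N(0, 0.2²), covariate coefficients flat; H0 omits
beta.  Marginal likelihoods are Laplace approximations at the penalized
posterior mode (the flat covariates are profiled in the same quadratic
expansion, keeping H0 and H1 comparable); log BF is their difference.  A
variant with zero genotype variance returns log BF = 0 exactly — the
likelihood is free of beta and the prior integrates to one.  If the
penalized Newton solve fails, a Gauss-Hermite quadrature over (mu, beta)
at the H0 covariate estimates is the fallback; irrecoverable fits return a
NaN sentinel and zero posterior.  Against a dense mode-centered quadrature
oracle the Laplace log BF is accurate to well under 0.05 at n = 200.

Posterior probabilities assume a single causal variant with equal prior
odds: posterior_j = exp(logBF_j − logsumexp(logBF)), stable for arbitrary
spreads.  A per-variant prior weight vector could be added trivially but
equal odds is the default.  The credible set sorts by descending
posterior, ties broken by ascending position, and accumulates until the
level (default 0.95) is reached, including the crossing variant.  With
many exactly tied posteriors this keeps the set minimal and deterministic
(ceil(level·N) members for a uniform posterior) rather than conservatively
including every tied variant — the minimal-set reading is the one
consistent with a "smallest set" definition.  Dosages or hard calls both
feed the BF; hard calls are the default in the simulation experiments.

Calibration: over 500 simulated cohorts (n = 2000, 60 variants in 3
blocks, OR 0.7, RAF 0.3, three admixture covariates) the 95% credible set
contains the causal variant in over 97% of replicates — above the nominal
level because LD ties pull correlated partners in with the causal variant.

## LD and haplotypes

Haplotype frequencies over windows of at most 12 variants come from the
standard EM over unphased genotypes (monotone log-likelihood, frequencies
on the simplex, three seeded restarts against local maxima).  r² and D'
derive from two-locus EM frequencies.  Blocks combine the four-gamete rule
with an r² floor: a boundary is evidenced between adjacent variants
whenever all four two-locus gametes exceed frequency 0.01; a valid block
is a contiguous run of ≥ 2 variants with no internal boundary and mean
pairwise r² ≥ 0.8; the reported partition is the exact optimum (most
variants covered, then fewest blocks, then lexicographically earliest),
computed by dynamic programming and verified against exhaustive partition
enumeration.  The conjunction is this package's concrete definition —
the GUI tools the study used do not document theirs precisely.  Haplotypes
above 3% frequency are reported per block.

Window association slides a 200 kb window in 100 kb steps (step = half
window), thins windows above the EM cap to 12 evenly spaced variants,
drops haplotypes under 3%, uses expected haplotype dosages (posterior
counts, propagating phase uncertainty) in a logistic model beside the
admixture covariates, takes the rarest retained haplotype as reference,
and tests the window by an (H−1)-df likelihood ratio against the
covariates-only model.  In single-causal simulations the best window never
beats the best single-variant test in expectation, matching the study's
negative haplotype finding.

## Rare variants: KBAC

Rare variants (MAF strictly below 0.01, call rate ≥ 0.90) are collapsed
into distinct multi-site carrier patterns.  Pattern i with n_i carriers
and k_i case carriers gets the hypergeometric-kernel weight
w_i = P(X ≤ k_i), X ~ Hypergeom(N, n_i, N_cases); the statistic is
Σ w_i (k_i/N_cases − (n_i−k_i)/N_controls).  Inference is one-sided for
case enrichment by label permutation with the observed statistic in the
numerator: p = (b+1)/(B+1), default B = 1000, exact (non-adaptive) for
determinism, the seed recorded in the result.  Missing rare genotypes are
treated as non-carrier.  The permutation p matches exhaustive enumeration
on small cores and the type-I error at 5% sits in [0.03, 0.07] over 1000
null datasets at 200 permutations.

## Assay quantification

Percent internalization = ((gMFI_4C − gMFI_37C)/gMFI_4C)·100 — scale
invariant, negative values reported rather than clamped.  Comparative-CT
relative expression averages replicate wells on the Ct scale, normalizes
target Ct to the 18S reference in the same well (ΔCt), re-normalizes to a
calibrator sample (ΔΔCt), and exponentiates: fold = 2^(−ΔΔCt); the
calibrator's fold is exactly 1 and refolding to a new calibrator divides
all folds by that sample's fold.  Group time-courses are compared by a
permutation test at the cell-line level (repeated measures stay together;
statistic = difference in group mean percent internalization, overall and
per timepoint; one- and two-sided p) — an assumption-light replacement for
the off-the-shelf linear mixed model the study fitted, whose random-effect
structure is not printed and is not reproduced here.

## Pipeline

`run_pipeline` executes the stages in the study's workflow order —
simulate (or ingest), sample QC + relatedness, variant QC, ancestry,
single-variant association, stepwise conditioning, Bayesian fine-mapping,
LD/haplotypes, KBAC, assays, plots — each stage skippable, all outputs
TSV/PNG, and writes a JSON manifest with the config snapshot, seeds, and
per-stage record counts sufficient to reproduce the run.  All-pairs IBD is
O(n²·V) and runs when the cohort is at most `ibd_sample_cap` (default
2000) samples.  The `locusfine` CLI wraps the pipeline with a flat TOML
config; the library functions are the primary interface.

## Problem sizes in the test suite

The default suite simulates cohorts of 240–2000 samples for most unit
tests and runs the full calibration experiments at the sizes stated above
(500 replicates of n = 2000 for credible-set coverage; 100 replicates each
for conditional analysis and for effect recovery at the full 8023-sample
design; 1000 null variants at n = 4000 for stratification; 1000 null
datasets at 200 permutations for KBAC).  These sizes were chosen so each
property is measured with useful Monte-Carlo precision while the whole
suite completes in minutes.

## Known limitations

- Single-causal fine-mapping only; no multi-causal stochastic search and
  no functional priors.
- Supervised admixture against a known panel; no STRUCTURE-style
  unsupervised inference or kinship-adjusted PCA.
- The EM window cap (12 variants) bounds exact haplotype enumeration;
  longer blocks report boundaries without a haplotype list.
- The imputation algorithm itself is out of scope: probabilities are
  consumed (dosage, info score, hard calls), never produced from a
  reference panel.
- Exact logistic regression, meta-analysis across ancestries, and
  genome-wide operation are out of scope.
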
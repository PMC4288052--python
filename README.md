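# locusfine

Statistical fine-mapping of a disease-risk locus from case-control
genotypes, built for analysts who need the *entire* published analysis
chain — quality control, ancestry adjustment, frequentist and Bayesian
association, conditional modelling, LD/haplotype structure, rare-variant
burden testing — as reproducible, tested code rather than a trail of GUI
tools, plus the quantification formulas of the accompanying functional
assays (flow-cytometry receptor internalization, comparative-CT qPCR).

Because cohorts of this kind are not publicly deposited, the package ships
a first-class synthetic-cohort generator that emulates the study design it
re-implements: four ancestral haplotype pools mixed per individual with
Dirichlet proportions, ~57 variants in LD blocks across a ~400 kb region,
one causal variant acting additively on the logit of disease risk
(risk-allele frequency 0.30, OR 0.81 at the European-ancestry design scale
of 4220 cases / 3803 controls), missingness, cryptic relatedness,
ancestry-informative markers, and rare variants below 1% frequency.

## The model at the core

Each variant is tested with the logistic model

    logit P(case_i) = mu + beta * G_i + gamma' * q_i

where `G_i` is the minor-allele count (or imputed dosage in [0, 2]) and
`q_i` are three admixture-proportion covariates.  The frequentist engine
fits this by IRLS (additive, dominant, recessive, genotypic and
Cochran-Armitage trend codings; Wald and LRT inference; stepwise
conditional analysis on allelic dosage).  The Bayesian engine evaluates
the same model under the priors `mu ~ N(0, 1)`, `beta ~ N(0, 0.2^2)` by a
Laplace-approximate Bayes factor per variant, converts Bayes factors to
single-causal posterior probabilities

    P(causal = j) = BF_j / sum_k BF_k

and reports the smallest set of top-ranked variants holding 95% of that
posterior — the credible set.  Rare variants are aggregated by the
one-sided kernel-based adaptive cluster (KBAC) test with the
hypergeometric kernel and permutation inference.

## Worked example

```python
import numpy as np
from locusfine.synthetic_cohort import build_study_pools, SimulationConfig, simulate_cohort
from locusfine import assoc, finemap_bayes as fb

pools = build_study_pools(n_variants=60, block_sizes=(20, 20, 20), seed=5)
cfg = SimulationConfig(n_cases=1000, n_controls=1000, causal_index=30,
                       causal_or=0.7, causal_raf=0.30,
                       rare_variant_count=0, seed=42)
gm, samples = simulate_cohort(pools, cfg)
covars = gm.admixture_covariates()

res = assoc.test_variant(gm, 30, covars, "additive")
print(f"causal variant: OR {res.or_:.3f} (95% CI {res.ci95[0]:.3f}-{res.ci95[1]:.3f}), p = {res.p:.3g}")

cs = fb.finemap_region(gm, covars, level=0.95)
print(f"credible set: {cs.size} variants, span {cs.span_bp} bp, "
      f"causal included: {'var0031' in cs.member_ids}")
```

prints

```
causal variant: OR 0.675 (95% CI 0.590-0.772), p = 1.12e-08
credible set: 15 variants, span 142267 bp, causal included: True
```

The estimated odds ratio (0.675) recovers the simulated protective effect
(0.7) within its confidence interval, and the 95% credible set narrows 60
variants down to the 15 the posterior cannot distinguish — the causal
variant and its LD partners inside the carrying block.

The same analysis, end to end with QC, ancestry estimation, conditional
modelling, haplotype windows, KBAC and plots:

```bash
locusfine run --config sim.toml --seed 17 --out results/
```

which writes TSVs per stage (`association.tsv`, `signals.tsv`,
`credible_set.tsv`, `blocks.tsv`, `kbac.tsv`, ...), a region plot, and a
`manifest.json` recording seeds and per-stage record counts.

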
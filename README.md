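# prspower

Analytic power and predictive accuracy of polygenic scores.

A polygenic score is built in two stages: marker effects are estimated one
at a time in a *training* GWAS of size n₁, markers whose two-sided P-value
falls in a window (q₀, q₁] are retained, and the weighted sum of their
trait-associated alleles is formed for each subject of an independent
*replication* sample of size n₂, where the score is tested for association
and used to predict individual trait values or disease risk.  Whether this
works depends jointly on the genetic architecture and on both sample sizes:
estimation error on tens of thousands of small effects accumulates in the
score, so a panel that explains a third of the liability variance can still
yield an AUC barely above 0.5 when the training sample is a few thousand
subjects.

`prspower` computes these quantities exactly rather than by simulation, for
quantitative and binary traits (prospective or case/control sampling under
a liability-threshold model), for three weighting schemes (per-marker least
squares, common-factor shrinkage, and the unweighted allele count), and for
cross-trait analyses where the score is trained on one trait and tested on
a genetically correlated one.  It also inverts the relation — estimating
the explained variance, effect correlation or null-marker fraction from an
observed score association — and solves design questions: required sample
size, optimal training/testing split, optimal inclusion threshold.  A
genotype-level simulator provides an empirical counterpart of every
analytic value.

## Model

Traits follow a linear polygenic model over m independent standardised
markers, y = Σⱼ βⱼ xⱼ + ε.  Per-marker effects are exchangeable with a
point mass π₀ at zero and a (bivariate, across traits) normal distribution
otherwise; the panel explains total variance vg_t of trait t (per-marker
non-null variance vg_t / (m(1−π₀))), with cross-trait effect correlation
ρ₁₂.  The estimated coefficient of marker j is normal around βⱼ with
sampling variance Var(y)/n₁.  Writing Var(Ŝ) and Cov(Ŝ, y₂) for the first
two moments of the score over markers, selection and samples — truncated
normal moments under the P-value window — the headline quantities are

- R² = Cov(Ŝ, y₂)² / (Var(Ŝ) Var(y₂)), the squared score–trait correlation;
- MSE = Var(y₂) − 2 Cov(Ŝ, y₂) + Var(Ŝ);
- λ = n₂ R², the non-centrality of the 1-df χ² association test, giving
  the two-tailed power at level α;
- AUC = Φ((i + i′)ρ / √(2 − ρ²[i(i−T) + i′(i′+T)])), for a binary trait
  with threshold T and case/control selection intensities i, i′, where ρ²
  is the liability-scale variance explained by the score.

Binary traits are handled by the standard linear map between effects on
liability and on the observed 0/1 trait (factor z, the normal density at
the threshold, for cohort sampling; z·P(1−P)/(K(1−K)) under case/control
ascertainment with case fraction P and prevalence K).  An observed
association statistic S yields an estimate of any one free architecture
parameter θ by solving λ(θ) = S, with a 95% CI from
√λ(θ) = √S ∓ 1.96.

## Worked example

The classic two-sample schizophrenia score analysis: odds ratios for
74,062 near-independent SNPs estimated in 3,322 cases / 3,587 controls,
score tested in 2,687 cases / 2,656 controls, prevalence 1%, SNPs with
training P < 0.5 included.  With the panel explaining 28.7% of liability
variance (`docs/example-config.yaml`):

```
$ prspower power --config docs/example-config.yaml
r2_obs      ncp     power  exp_neglog10p  mse      r2_liab    auc
0.0224184   119.781 1      27.3699        2.62576  0.0123733  0.584097
```

The score explains 2.2% of the observed-scale variance (1.2% on the
liability scale), which at n₂ = 5,343 gives a non-centrality of 120 —
essentially unbounded power, and an expected association P-value near
10⁻²⁷.  Yet the AUC of 0.584 is far from clinically useful: association
and individual prediction make very different demands on sample size.

Inverting the observed association (P = 2×10⁻²⁸) estimates how much
liability variance the panel explains:

```
$ prspower estimate --config docs/example-config.yaml --param vg --pvalue 2e-28
param  estimate  ci_lower  ci_upper  observed_stat  level  flags
vg     0.290047  0.237732  0.342759  122.285        0.95
```

about 29% (95% CI 24–34%).  Finally, the sample size at which this
architecture reaches 80% power with equal-sized samples of half cases,
half controls, all SNPs included:

```
$ prspower design --config docs/example-config.yaml --objective power \
      --target 0.8 --count cases --q1 1.0 --trait1-p 0.5 --trait2-p 0.5
objective  target  count  required_n  threshold
power      0.8     cases  737         NA
```

737 cases and as many controls per sample suffice — polygenic association
testing is comfortably powered at modern GWAS sizes even when no single
marker is significant.

The same machinery is available as a library (`prspower.accuracy_report`,
`estimate_parameter`, `required_n`, `optimal_split`, `optimal_threshold`,
`reproduce_tables`) and the simulator as `prspower.evaluate_replicates` or
`prspower simulate` on the command line.

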
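# Methods

This note records the model, the derivations the package implements, the
numerical and design choices that were genuinely open, and what the
simulator does and does not establish.

## Quantitative model

Two traits (y₁, y₂) are linear in m independent standardised markers,
yₜ = Σⱼ βₜⱼ xⱼ + εₜ.  Genotypes are Hardy–Weinberg counts standardised by
allele frequency, x = (g − 2p)/√(2p(1−p)).  Effects are random over
markers: a fraction π₀ is exactly zero in both traits; the rest are
(bivariate) normal with variances σ₁², σ₂² and covariance σ₁₂ = ρ₁₂σ₁σ₂.
The package parameterises by the *total* explained variances vg₁ = m(1−π₀)σ₁²
and vg₂ (and ρ₁₂), so that vg is invariant to π₀ — matching the exact
invariance of all score moments to π₀ when every marker is included.

The training sample (size n₁) yields per-marker least-squares estimates
β̂ⱼ, asymptotically N(βⱼ, Var(y₁)/n₁); the residual variance is
conservatively taken as the full trait variance (effects are small).  A
marker enters the score iff its two-sided Wald P-value lies in (q₀, q₁],
equivalently c₀ ≤ |β̂ⱼ| ≤ c₁ with c = Φ⁻¹(1 − q/2)·se.  The score for a
replication subject is Ŝ = Σ_selected wⱼ xⱼ.

### Score moments

For the least-squares weights (wⱼ = β̂ⱼ), with marginal non-null estimate
variance s² = σ₁² + Var(y₁)/n₁ and the doubly-truncated standard-normal
second moment
T(a, b) = [Φ(b) − Φ(a) + aφ(a) − bφ(b)] / [Φ(b) − Φ(a)]:

- Var(Ŝ) = m π₀ (q₁−q₀) · (Var(y₁)/n₁) T(c₀/se, c₁/se)
  + m(1−π₀) p_sel · s² T(c₀/s, c₁/s), where p_sel = 2[Φ(c₁/s) − Φ(c₀/s)];
- Cov(Ŝ, y₂) = m(1−π₀) p_sel σ₁₂ T(c₀/s, c₁/s), because the regression of
  β₂ on β̂₁ has slope σ₁₂/s² regardless of selection on β̂₁.

The infinite-training-sample limit (n₁ = ∞) is implemented analytically:
estimates equal true effects, every non-null marker has P → 0 (selected
iff q₀ = 0), null markers contribute nothing.

Shrinkage weights multiply every estimate by the common posterior factor
ν = σ₁²/(σ₁² + Var(y₁)/n₁) (single-normal prior with the non-null
per-marker variance; the point mass at zero is deliberately not mixed into
the prior — a mixture prior would shrink non-uniformly and break the
"same correlation" property that defines this estimator here).  Var and
Cov scale by ν² and ν, so R², NCP, power and AUC are identical to least
squares; only the MSE improves.

Allele-count weights are ±c with the sign of β̂ⱼ.  The constant c is fixed
at the non-null per-marker effect SD on the analysis scale; every
correlation-based metric is invariant to this choice, and the MSE — the
only quantity that is not — is reported as unavailable for this estimator
(it has no meaning without an arbitrary rescaling of the score).
Cov(Ŝ, y₂) requires one numerical integral over the non-null effect
density of [P(sign agrees, selected | β) − P(sign disagrees, selected | β)]
× (σ₁₂/σ₁²)β, evaluated with adaptive quadrature (absolute tolerance
1e−10, range 8 marginal SDs — integrand mass beyond is < 1e−15; achieved
tolerance is checked and a failure raises rather than returning silently).

### Metrics

R² = Cov²/(Var(Ŝ)Var(y₂)); MSE = Var(y₂) − 2Cov + Var(Ŝ); the 1-df χ²
association test of the score has non-centrality λ = n₂R², power from the
non-central χ² tail beyond the central critical value; the "expected
−log₁₀P" used for threshold curves is the P-value of the statistic at its
mean 1 + λ (an exact-median variant is exposed as an option; the mean
variant is the default because the curves it draws are the familiar
ones).

## Binary traits

A binary trait has a standard-normal liability with threshold
T = Φ⁻¹(1−K); effects act on liability.  Analysis is linear regression on
the 0/1 trait, so effects are mapped to the observed scale: factor z = φ(T)
for prospective sampling, z·P(1−P)/(K(1−K)) under case/control
ascertainment (derived by composing the ascertainment-stable regression of
genotype on status with the binomial status variance, assuming the
genotype variance stays ≈1 in the ascertained sample).  The machinery
above then applies with sampling variance P₁(1−P₁)/n₁ and trait variance
P₂(1−P₂).  The two transforms coincide at P = K, which the suite asserts
to 1e−10 across every metric.

Liability-scale R² rescales effects through the inverse transform and
replaces the binomial variance with the unit liability variance:
R²_liab = R²_obs·P(1−P)/f², invariant to P by construction.

AUC uses the joint normality of score and liability: with i = z/K,
i′ = z/(1−K) and ρ² the liability-scale R²,
AUC = Φ((i+i′)ρ / √(2 − ρ²[i(i−T) + i′(i′+T)])).  AUC is invariant to
linear rescaling of the score and to case/control sampling, so one formula
serves both designs once ρ² is computed with the appropriate transform;
the infinite-sample AUC uses the n₁ → ∞ moment limit rather than a
separate formula.

Sibling recurrence risk λs is converted to heritability of liability with
the classical threshold formula (Falconer with the Reich curvature
correction), a = [T − T_R√(1 − (T²−T_R²)(1−T/i))]/[i + T_R²(i−T)],
h² = 2a with T_R the threshold at prevalence λsK.  The suite checks it
against the exact bivariate-normal solution (agreement ~1e−3 at common
prevalences).  The alternative log-risk model (logistic in the
rare-disease limit) is also provided: total log-risk variance v = 2 ln λs,
and a score of variance v_s separates cases from controls by exactly v_s
with equal variances, giving AUC = Φ(√(v_s/2)).

Known approximation limits, deliberately reported rather than patched:
under extreme ascertainment (rare disease, half cases, large explained
variance) the observed-scale moments can leave the small-effect regime —
Cov² may exceed Var(Ŝ)Var(y₂) and the observed-scale R² may exceed 1.
Constructors warn and the raw values propagate, because the
liability-scale quantities derived from them remain correct; clipping
would corrupt the AUC.  Likewise the assumption that genotype variance
stays 1 under ascertainment biases the analytic Var(Ŝ) low by ~10% in the
simulator's K = 0.001, P = 0.5 runs (correlation-based metrics and AUC are
unaffected); the simulator quantifies this residual rather than hiding it.

## Estimating equation

The score-association coefficient scaled by its standard error is normal
with mean √λ(θ), so an observed χ² statistic S estimates any single free
parameter θ (explained variance, effect correlation, null fraction) by
solving λ(θ) = S, with 95% CI from √λ(θ) = √S ∓ 1.96.  λ must be monotone
in θ, which is checked numerically on a 17-point grid before bracketed
root-finding (brentq, xtol 1e−12); a flat or non-monotone profile (e.g.
π₀ with the full inclusion window) is a hard error naming the parameter.
Because the statistic is signless, the correlation parameter is estimated
on [0, 1] (its magnitude).  Statistics below the no-signal point or CI
equations with no in-domain solution clamp to the domain edge and set an
explicit flag.  P-values are accepted directly, or as −log₁₀P below float
range (converted through the normal quantile for stability).

## Design solvers

Association power depends on both samples; prediction accuracy
(correlation, AUC) only on the training sample.  `required_n` therefore
varies n₁ = n₂ = n for the power objective and n₁ alone otherwise, after
checking the target against the n → ∞ maximum (unreachable targets raise,
reporting that maximum).  The search is exponential bracketing plus
integer bisection on the monotone objective, in units of the rounding
granularity; "cases and controls per sample" designs solve directly over
the case count with half cases per sample.

The inclusion-threshold maximisation is a bounded Brent search on the raw
probability scale with absolute tolerance ~1.2e−4 (eps^0.25, the classic
default of scalar optimisers), followed by an explicit boundary check so
that architectures with no null markers return q₁ = 1 exactly.  The
coarse tolerance is a deliberate reproduction choice: for sparse
architectures the objective is extremely flat over an order of magnitude
in q₁ (values differ in the fourth decimal), and the solver granularity
determines which threshold in that plateau is reported and, through it,
table-level sample sizes rounded to thousands.  A dense log-grid search
with local refinement (`method="grid"`) is available when the sharper
optimum is wanted; the suite verifies it against a brute-force dense grid.
`optimal_split` maximises the NCP over the training fraction by bounded
search and returns the full fraction–NCP curve for symmetry inspection.

Table regeneration (`reproduce_tables`) rebuilds the published-style
grids: required cases/controls (thousands, rounded up) for target AUC
under 100k-marker/half-heritability and 1M-marker/full-heritability
panels, required subjects for target correlation with a quantitative
trait, analytic AUC for the WTCCC-style designs, and liability-R² for
published designs.  The lower threshold is fixed at q₀ = 0 throughout
(noted in the output); the liability-R² grid is restricted to the four
studies whose sample sizes are recorded in `prspower.studies`.

## Simulator

The simulator is the package's empirical oracle.  Genotypes are
Binomial(2, MAF) counts at MAFs uniform on (0.01, 0.5), standardised by
the true MAF (the model's definition, not the sample estimate), generated
from a single uniform draw per entry in float32 for speed.  Quantitative
traits follow the linear model with unit total variance; binary traits
threshold the liability (prospective), or use a conditional scheme for
case/control sampling at low prevalence: draw each subject's liability
truncated at T according to its label, the aggregate genetic liability
from its normal law given that liability, and the genotype vector from the
joint-normal law conditioned on the aggregate (x = z + β(g − βᵀz)/vg,
which pins βᵀx = g exactly).  The scheme is validated against brute-force
rejection sampling at K = 0.2, where both are feasible, and against the
analytic observed-scale effect transform at K = 0.001.

Each replicate redraws effects, genotypes and traits, fits the per-marker
regressions, applies the window, builds the score with the configured
estimator and evaluates χ², R², MSE and AUC in the replication sample;
means over replicates are compared to analytic values in units of the
Monte-Carlo standard error.  The empirical counterpart of R² is the
bias-adjusted sample value r² − (1−r²)/(n₂−2): the raw squared sample
correlation exceeds the population value by ≈ 1/n₂, the same bias the
mean-χ²-minus-one NCP estimate removes.

A marker-summary mode (quantitative designs) draws estimates directly
from their sampling law around the drawn effects and subject-level
(score, trait) pairs from their joint normal given the realised weights.
It preserves the finite-panel dispersion of realised effect variances —
the driver of confidence-interval behaviour — at ~1/1000 the cost, and is
cross-validated against the genotype-level mode.  It shares the analytic
model's Gaussian sampling assumptions, so it is used for
confidence-interval calibration experiments, not as evidence about those
assumptions themselves.

Default validation scales, chosen to exercise the same per-marker
signal-to-noise regime as full-size studies at a fraction of the cost:
moment agreement at m = 20,000, n₁ = n₂ = 2,000, 200 replicates
(100 for the binary variant); CI calibration at 500 replicates in summary
mode, with the under-coverage scenario using n = 8,000 and q₁ = 1e−4
because realised-effect dispersion only matters relative to the CI width
when the association is strong.  The full-scale scenario (m = 10⁵,
n = 4,000, 1000 replicates) is a configuration choice away
(`SimConfig(model=..., replicates=1000)`), not a separate code path.

What passing simulations do and do not show: agreement validates the
truncated-normal selection algebra, the liability transforms and the
estimating equation under the model's own assumptions (independent
markers, unrelated subjects, normal or variance-matched heavy-tailed
effects).  They say nothing about linkage disequilibrium, relatedness,
allele-frequency-dependent architectures, or major-gene effects, none of
which the model represents; with heavy-tailed (Laplace) effects the
analytic values remain exact for the full inclusion window but
underestimate power and accuracy under stringent selection, and the suite
asserts that direction rather than pretending agreement.

## Known limitations

- m is an effective number of independent markers; mapping a real panel
  with LD onto m is the caller's responsibility and is heuristic.
- The CI of the inverted parameter under-covers when the number of
  causal markers is small (realised effect variances disperse around the
  values the estimating equation assumes); the suite reproduces this
  rather than correcting it.
- Case/control designs at very low prevalence with strong architectures
  push the observed-scale approximations; score-variance-based quantities
  (MSE) carry a visible residual there, correlation-based ones do not.
- No multiple-threshold multiplicity correction: each inclusion threshold
  is evaluated marginally, as in practice.
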
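# Methods

This note records the models the package implements, the estimators and
numerical choices behind them, what the synthetic-data generator does and
does not emulate, and the design decisions taken where more than one
reasonable construction existed.

## 1. Entropy family

For order α > 0 the Havrda–Charvat entropy of a density or mass function
f is `HC_α(X) = E[φ_α(f(X))]` with `φ_α(x) = (x^{α−1} − 1)/(1 − α)` and
`φ₁ = −log`. The Shannon branch is taken exactly at α = 1 and for
|α − 1| < 1e−8, where the generic branch divides by a vanishing `1 − α`;
a notice is logged when an order is silently rerouted. Summands with
zero mass contribute zero for every order (the `0·log 0 = 0`
convention), so degenerate distributions have entropy exactly 0.

φ_α converges to −log pointwise at the linear rate
`|φ_α(x) + log x| = |α−1| (log x)²/2 + O((α−1)²)`; tests assert this
exact rate rather than a flat tolerance, since no constant tolerance can
hold uniformly in x at a fixed |α − 1|.

**Continuous entropy quadrature.** For α ≠ 1 the entropy is
`(∫f^α − 1)/(1 − α)`; the ∫f^α form is used because the pointwise
integrand `(f^α − f)/(1−α)` carries the slowly decaying −f term that
defeats adaptive quadrature on heavy tails. The integral is attempted
over the full support (split at declared breakpoints, scipy `quad`,
epsabs 1e−12). If the integrator signals trouble, a truncation scan
integrates over [−M, M] with M doubling: a relative change below 1e−9
between doublings is accepted as convergence, persistent growth above
1e−3 at M = 2²⁰ is classified as analytic divergence (returned as
`inf`; for α > 1 a divergent ∫f^α means `−inf`), and anything in between
raises a distinct quadrature-failure error. On the heavy-tailed example
density the Shannon integrand grows like `c₂ log log M` — the scan's
relative change at M = 2²⁰ is ≈2.7e−3, safely above the divergence
threshold, while convergent cases sit many orders below it. (Because the
divergence rate is log log M, no feasible truncation exhibits a large
absolute value; growth-without-plateau is the only observable signature.)

**Entropy power** `e^{2h/n}/(2πe)` retains the dimension parameter n for
interface completeness; every use in this package is univariate (n = 1).
Note that the entropy-power uncertainty-reduction ratio
`(EP_α(T) − EP_α(T|S))/EP_α(T)` equals `1 − e^{−2I_α}` only at α = 1;
a test exhibits the inequality numerically at α = 2.

## 2. Closed forms and their normalizations

**Gaussian pair.** For α ≠ 1,
`I_α = (2π σ_T σ_S)^{1−α}/(α(1−α)) · [1 − (1−ρ²)^{(1−α)/2}]`, with the
Shannon branch `−½ log(1−ρ²)`. The exponent (1−α)/2 on (1−ρ²) is forced
by the joint-Gaussian `∫∫f^α = (2π σ_T σ_S)^{1−α}(1−ρ²)^{(1−α)/2}/α` and
is the unique reading continuous with the α = 1 branch; it is confirmed
by the Monte-Carlo oracle in the test-suite. Unlike Shannon mutual
information, the α ≠ 1 value depends on the marginal scales through the
prefactor. For α < 1 the value stays bounded as |ρ| → 1, with supremum
equal to the prefactor; the normalized ITMA divides by
`1 − e^{−2·sup}`, which reduces to the conventional `R²/(1 − e^{−2})`
exactly when the prefactor is 1 (σ_T σ_S = 1/2π). For α ≥ 1 the value
diverges at |ρ| = 1 and no normalization is reported.

**Binary pair.** `I_α = [(Σ_t p_{t+}^α)(Σ_s p_{+s}^α) − Σ_{ts} p_{ts}^α]/(1−α)`
for α ≠ 1; the Shannon branch is computed exactly by the discrete
entropy decomposition. The 2×2 table is parameterized by its margins and
the indicator correlation ρ, whose feasible interval comes from cell
nonnegativity; construction outside the interval raises an error naming
the admissible range, and the margins/ρ round-trip is exact. The
attainable maximum I_α,max for fixed margins subtracts the minimum joint
entropy over feasible ρ: each cell is linear in ρ, so HC_α(T,S) is
concave in ρ for every order and its minimum lies at an interval
endpoint; both endpoints are evaluated and the smaller taken, which also
resolves the degenerate symmetric-margin case without a derivative sign
test. Normalized ITMA divides by `1 − e^{−2 I_α,max}`.

Two caveats discovered during implementation and covered by tests:

* For α > 1, strongly *discordant* tables can make I_α genuinely
  negative (cells (0.5, 0.25, 0.25, 0) give I₂ = −1/64). Nonnegativity
  holds for the Gaussian and probit families at all orders and for all
  families at α ≤ 1, but not here; negative values are reported as
  computed (with a negative ITMA and no normalization) rather than
  clamped, because masking them would hide a real property of the
  family.
* The tempting lower bound "I_α ≥ max of the marginal entropies for
  α < 1" is false — independence is an immediate counterexample, and it
  fails even for strongly concordant tables; a test documents a concrete
  refutation. The valid bound in the other direction (α > 1:
  I_α ≤ min marginal entropy) is asserted over 1000 random tables.

**Latent-probit pair** (binary T = 1{U ≥ 0}, U ~ N(Φ⁻¹(p₁), 1),
Gaussian S, latent correlation ρ). For α ≠ 1,

    I_α = (2πσ_S²)^{(1−α)/2} / ((1−α)√α) · Σ_t [ p_t^α − ℑ_α(a_t, b_t) ],
    a_t = Φ⁻¹(p_t)/√(1−ρ²),  b_t = (−1)^{1−t} ρ / (√α √(1−ρ²)),

with `ℑ_α(a,b) = ∫ Φ^α(a + by) φ(y) dy`. The kernel is integrated
adaptively (epsabs 1e−13): Gauss–Hermite rules — the natural choice for
a Gaussian-weighted integrand — lose accuracy once |b| exceeds ~2
because Φ(a + by) steepens toward a step (error up to 3e−4 at 128 nodes,
still ~4e−9 at 512), short of the 1e−10 the package promises; a Hermite
evaluator is kept as an independent cross-check at moderate slopes. The
Shannon branch integrates the conditional Bernoulli entropy directly.
At α = 2 the Owen's-T closed form
`I₂ = [1 − 4T(Φ⁻¹(p₀)/√(1−ρ²/2), √(1−ρ²)) − p₁² − p₀²]/(2√π σ_S)` is
implemented and agrees with the general quadrature to 1e−14 over a
(p₁, ρ) grid, which fixes its prefactor unambiguously. The ρ → ±1 limit
`pref · {Σ p_t^α − Φ(√α Φ⁻¹(p₁)) − Φ(√α Φ⁻¹(p₀))}` is exposed
separately (the Shannon value diverges there).

**Oracle.** Every closed form is cross-checked against a Monte-Carlo
plug-in built only from the entropy primitives: sample the joint law,
average φ_α of the true marginal/joint densities, combine through the
non-additive rule. Standard errors come from 50-batch resampling of the
combined statistic. The acceptance tests run 10⁶ samples per setting
(five parameter settings per family at α ∈ {0.5, 2}) with a 3-SE
criterion.

## 3. Probit estimation

Univariate probit regression is delegated to statsmodels, wrapped with
explicit rank and single-predictor separation checks (an error names the
offending column) and a post-fit guard against boundary fitted
probabilities.

The bivariate probit — two binary outcomes as signs of correlated latent
normal linear predictors — is maximized directly: the likelihood of an
observation is `Φ₂(q_T w_T, q_Z w_Z, q_T q_Z ρ)` with q = 2y − 1, and
the analytic gradient uses
`∂Φ₂/∂h = φ(h) Φ((k − ρh)/√(1−ρ²))` and `∂Φ₂/∂ρ = φ₂(h, k; ρ)`.
ρ is optimized as atanh ρ (the constraint is automatic and the Wald
interval is built on that scale and mapped back); starting values are
the univariate fits with ρ = 0; predictors are standardized internally
for conditioning and estimates mapped back. Convergence requires a
per-observation gradient norm below 1e−6, with up to three jittered
restarts. Standard errors come from the inverse numerical Hessian of the
total negative log-likelihood, transformed to the raw predictor scale.
Cell probabilities are floored at 1e−300 inside the log-likelihood.

The bivariate normal CDF itself is computed from Owen's T via
`Φ₂(h,k,ρ) = ½(Φ(h)+Φ(k)) − T(h,a_h) − T(k,a_k) − β`, vectorized with
explicit closed forms for the ρ ∈ {0, ±1}, h = 0, k = 0 and origin
cases; it matches scipy's generic (but per-point, hence likelihood-
prohibitive) multivariate normal CDF to 1e−10 in tests. Recovery
checks: ρ̂ bias < 0.02 and 95% CI coverage within [90%, 99%] over 100
replicates at n = 2000, and 3-SE parameter recovery at n = 5000.

## 4. Longitudinal surrogacy

Data model: one binary endpoint per subject, arm Z ∈ {0,1}, and a
continuous surrogate on a common visit schedule (weeks, baseline 0
required in every design). Subjects missing any visit of a design are
dropped from that design (complete-case; counts logged).

**Trial-level `I_α(T, S | Z)`.** Within each arm the surrogate vector is
reduced to a scalar by the *single-index probit reduction*: fit a probit
of T on the visit vector, form the index V = γ̂'S, standardize it, refit
a probit of T on the standardized index to get slope b, and set
ρ̂ = b/√(1+b²), p̂₁ = the arm's endpoint rate, (μ_S, σ_S) = the moments
of V. This is the unique single-index Gaussian latent model consistent
with the fitted probit (a linear combination of jointly Gaussian visits
is Gaussian), and it is flagged prominently because the reduction is a
modeling choice: whether one should instead integrate the full
multivariate latent model is genuinely open. Note that at α ≠ 1 the
resulting value inherits the scale of the fitted index through σ_S;
comparisons across designs are made under the same convention, and the
Shannon order is scale-free. Arm values are averaged with empirical arm
weights. On synthetic data with a known latent correlation the plug-in
converges to the known-parameter value as n grows (tested at the
scale-free order).

**Prentice check `I_α(T, Z | S)`.** A bivariate probit of (T, Z) on the
design's surrogate vector supplies conditional margins and joint cells
per subject; the conditional 2×2 mutual information (α ≠ 1 double-sum or
Shannon form) is averaged over the observed surrogate vectors — the
empirical law of S is the integrating measure. A valid surrogate should
leave this near zero.

**Calibrating "near zero".** The implemented null *resamples the
endpoint from its fitted conditional law given the surrogate*
(T* ~ Bernoulli(p̂(T=1|S)), probit fit without Z) and recomputes the
measure. A simpler within-arm permutation of T was evaluated first and
found miscalibrated for this statistic: the plug-in measure is driven by
the fitted residual latent correlation, whose sampling spread is about
five times larger in the presence of a real T–S association (sd ≈ 0.145
across fresh Markov replicates at n = 200 vs ≈ 0.03 under permutation),
because permutation destroys the very association that inflates it. The
conditional resampling null preserves the T–S signal and is exactly the
Prentice hypothesis. Within-arm permutation remains available — and
appropriate — as the no-association null for the arm-level
`I_α(T, S | Z)` measure.

Reports (`design_sweep`) cross designs with orders, carry both measures
plus their ITMAs, record per-design failures without aborting the sweep,
and are bit-reproducible; CSV output stores full precision under a
provenance header while the text rendering rounds to 4 decimals.

## 5. Synthetic trial generator

The generator emulates the *structure* of a two-arm phase II progressive
multiple sclerosis trial: 104/99 subjects, surrogate mean ≈0.8023 with
SD ≈0.0301 at baseline, per-24-week drift −0.0008 (control) vs −0.0004
(treatment), visits at weeks 0/24/48/72/96, endpoint response ≈48% vs
≈71%. Within-subject dependence is compound-symmetric with correlation
0.9 — the real trial's correlation structure is not recoverable from its
published summaries, so this is a calibration choice, not an estimate.

Surrogate: `S_ij = μ_S + α₁Z + α₂t_j + α₃Z t_j + β_j T + ε_ij` with
ε_i ~ MVN(0, compound symmetry). Endpoint: a latent probit
`U = a₀ + a₁Z + a₂X + e` on the standardized visit-mean index X of the
endpoint-free surrogate, T = 1{U ≥ 0}. Because (X, U) are jointly
Gaussian given Z, the implied arm-wise endpoint rates and the latent
index correlation `a₂/√(1+a₂²)` are available in closed form, making
truth-recovery tests exact. The defaults a₀ = −0.028, a₁ = 0.767,
a₂ = 1.0 reproduce the 48%/71% rates analytically. The endpoint effects
β_j rise linearly to 0.004 at week 96 (zero at baseline).

`generate_markov_trial` sets a₁ = 0, so the treatment affects the
endpoint only through the surrogate (Z → S → T). Two subtleties matter
for conditional-independence testing and are respected by the tests:
the Markov property is with respect to the *full* endpoint-free
surrogate process, so (i) conditioning on a proper visit subset leaves
an unblocked Z → S(later visits) → T path, and (ii) a nonzero β_j makes
the observed surrogate a collider child of T. Exact T ⊥ Z | S scenarios
therefore use the full schedule with β_j = 0.

What the generator does **not** emulate: dropout/missingness,
measurement error beyond the Gaussian residual, non-Gaussian biomarker
distributions, site effects, or the real trial's unknown joint
dependence structure. Passing tests demonstrate correctness of the
estimators under the stated latent-probit data-generating process, not
performance on real MRI data.

## 6. Heavy-tailed example density

`f(x) = φ(x)` for |x| ≤ c₁ and `c₂/(|x|(log|x|)²)` beyond, with
continuity and unit mass enforced. Since the tail mass beyond m is
exactly `c₂/log m`, the system collapses to one equation,
`φ(c)·c·log c = 1 − Φ(c)`, bracketed on (1.05, 3) and solved by Brent's
method; then `c₂ = (1 − Φ(c₁)) log c₁`. Both residuals are verified
below 1e−10. The solution is c₁ = 1.4429, c₂ = 0.0273 (1.44 / 0.027 at
quoted precision). This density is the canonical witness that the
Shannon-based measure can fail to exist while every α > 1 member of the
H-C family is finite.

## 7. Problem sizes and reproducibility

Simulation-based checks use sizes chosen to make their statistical
criteria sharp at interactive runtimes: 10⁶ Monte-Carlo samples per
oracle comparison (3-SE criterion), 200 conditional-null resamples at
n = 200 for the Prentice calibration, 100 replicates at n = 2000 for
bias/coverage, 20 replicates at n = 5000 for 3-SE recovery. All
randomness flows through explicit integer seeds (generator default
20220131, recorded in outputs); reports and fits are deterministic given
data and configuration.

## 8. Known limitations

* The single-index reduction makes the α ≠ 1 trial-level measure depend
  on the fitted index scale; only cross-design comparisons under the
  same convention (or the Shannon order) are scale-free.
* The generalized MI for binary pairs can be negative at α > 1
  (discordant tables); downstream code must not assume nonnegativity.
* The bivariate probit models P(Z | S) with a probit link; when Z is a
  randomized assignment and S a Gaussian mixture across arms, the true
  inverse link is logistic — the misspecification is mild at realistic
  arm effects but present.
* Single-trial surrogacy only: no meta-analytic (multi-trial) layer,
  time-to-event endpoints, or missing-data mechanisms.
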
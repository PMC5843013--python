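# Methods

This note documents the models, estimators, numerical choices and known
limitations of `trajlca`.

## Measurement model

Each symptom process (soiling, constipation) is a longitudinal latent
class model for repeated binary indicators: child *i* belongs to one of C
classes with probability π_c, and given the class the wave-*t* indicator
is Bernoulli(ρ_ct), independent across waves (local independence). A
child's likelihood is evaluated over their observed waves only, which is
full-information maximum likelihood and is valid when missingness is
at random (MAR). The headline pipeline fixes C = 4 per process — the
class count with clear BIC support on both the motivating cohort data and
the calibrated generator — and `enumerate_classes` remains available as a
diagnostic.

The parallel-process model couples the two processes through the joint
class distribution π_ab only: given the pair (a, b), soiling items depend
on a alone and constipation items on b alone. It is therefore a
16-component mixture whose free parameters are the 15-dimensional joint
simplex plus the two measurement blocks (4×5 and 4×6 item probabilities).
Measurement parameters are *re-estimated* in the parallel model rather
than fixed from the single-process fits; the warm start (below) keeps the
solutions comparable.

## Estimation

EM throughout.

* E-step and likelihood run on the unique observed response patterns with
  multiplicity weights; at T ≤ 11 binary-with-missing waves this collapses
  a cohort of ~10⁴ children to a few hundred patterns and makes fits
  effectively instantaneous.
* Single-process fits default to 50 random starts (class weights from a
  flat Dirichlet, item probabilities Uniform(0.05, 0.95)), relative
  log-likelihood tolerance 1e-8, at most 5000 iterations. Item
  probabilities are clamped to [1e-6, 1−1e-6] so sparse cells cannot
  produce −∞ likelihoods.
* The parallel model adds a warm start built from the two single-process
  fits (product-of-marginals joint weights); because that initialisation
  reproduces the independent fits exactly, EM ascent guarantees the joint
  log-likelihood is at least the sum of the single-process ones. A small
  number of random starts (default 4) guards against the warm start being
  a poor basin.
* The reported log-likelihood is recomputed at the returned (post-M-step)
  parameters, so external comparisons (e.g. against direct numerical
  maximisation) are exact rather than one M-step stale.
* Label switching is resolved by ordering classes by mean item
  probability ascending — the lowest-burden class is "normative" — with
  near-ties broken by the wave at which the profile first crosses 0.5
  (early onset before late onset), then by class weight. The parallel
  model orders each process through its implied marginal model.

## Composite groups and the three-step regression

The 16 joint cells collapse deterministically: (normative, normative) →
normative; normative soiling with non-normative constipation →
constipation alone; the transpose → soiling alone; the remaining nine
cells → constipation with soiling. Collapse conserves posterior mass
exactly; modal assignment breaks ties toward the less severe group in the
order above (deterministic, conservative).

The regression of composite membership on risk factors uses the
maximum-likelihood bias-adjusted three-step estimator: with modal labels
m_i and the classification-error matrix D[t, m] = Σ_i p_it 1[m_i=m] / Σ_i
p_it computed from the composite posterior, step 3 maximises

    ℓ(γ) = Σ_i log Σ_t P(t | x_i; γ) · D[t, m_i]

over a multinomial logit P(t | x; γ) with the normative class as
reference. D is treated as fixed; standard errors come from the observed
information of ℓ (central differences of the analytic gradient). With
D = I the estimator reduces *exactly* to ordinary multinomial logistic
regression on the modal labels (verified against statsmodels MNLogit to
1e-6). Optimisation is L-BFGS with analytic gradient, polished by BFGS
when the gradient max-norm exceeds 1e-8; quasi-complete separation is
flagged (|γ| > 15) rather than raised. Univariable models per risk factor
are the default; any covariate list can be supplied for adjusted models.
Missing covariates are dropped listwise per model.

Omnibus tests are Wald χ² on the factor's full coefficient block across
the three non-reference classes (df = design columns × 3). In a null
simulation with labels drawn through a moderate-error D at n = 8435, the
test's empirical size is ≈4.5% (1200 replicates); at much smaller n it
runs conservative (≈3.3% at n = 2000), a finite-sample property of the
low-information rare classes.

## The synthetic-cohort generator

The generator is the validation harness: it draws (soiling, constipation)
class pairs from a 4×4 joint distribution, simulates indicators from
class profiles, and can tilt composite-group membership by covariates.

* **Joint weights** default to the published ALSPAC parallel-model
  estimates; the one cell published as "<0.1" is carried as 0 (the
  printed cells already sum to 100 within rounding) and the matrix is
  renormalised.
* **Profiles** are chosen to match the published trajectory shapes and
  produce per-wave marginal prevalences near the reported ones (soiling
  ≈6–9%, constipation ≈9–14%), with class mean levels separated enough
  that the canonical ordering is stable across replicates. Normative
  profiles stay at or below 0.05, persistent at or above 0.7.
* **Covariate effects** act on the four *composite* groups through a
  multinomial logit whose intercepts are the log base shares, so zero
  effects recover the base distribution exactly and a single binary
  covariate's generating coefficient equals its population 2×2 odds
  ratio. Within a composite group the joint cell is drawn with the base
  weights' within-group proportions. Effects at the 16-cell level are not
  supported — the downstream regressions are defined at composite level.
* **Missingness** is wave-wise missing-completely-at-random (per-wave
  response probability, default 0.95 when enabled) plus a monotone
  geometric dropout (default hazard 0.03), chosen to roughly reproduce
  the reported attrition gradient across the ≥1-wave / ≥3-wave /
  complete-case nested samples. MCAR trivially satisfies the estimator's
  MAR requirement; informative missingness is deliberately out of scope.
* Wave ages are display labels only; no within-wave age variation is
  simulated, and the pre-dichotomisation questionnaire response options
  are not modelled.

Consequently, passing recovery tests demonstrates correctness of the
estimators under local independence, MAR missingness and a clean 4+4
class structure. They do not speak to violations real cohort data may
carry: informative dropout, sibling clustering, within-class
heterogeneity, or reporting error correlated over waves.

## Validation study sizes

The replicated studies in `trajlca.experiments` use 25 replicates each:
joint-table and composite-share recovery at n = 8435, the unconditional
constipation split at n = 8979 with 50 EM starts, and the
male→soiling-alone odds-ratio chain at n = 8435 (parallel fits warm-started
from 10-start single-process fits plus 2 random starts). These sizes give
Monte-Carlo error comfortably inside the tolerances asserted in the test
suite while keeping a full run to a few minutes on one CPU.

## Known limitations

* Standard errors do not propagate the estimation uncertainty in D (or in
  the step-1 measurement model) — standard practice for this estimator,
  but CIs are slightly anti-conservative when classification quality is
  poor.
* BIC-based enumeration is reported, not argued; with weak separation the
  selected class count is sample-size dependent.
* The censored "<0.1" display convention means a fitted cell in (0, 0.05)
  percent prints as "<0.1" while arithmetic uses its exact value.
* The weighting-based (non-ML) three-step variant and 16-cell-level
  covariate effects are not implemented.
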
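# trajlca

Parallel-process longitudinal latent class analysis (LLCA) of childhood
constipation and soiling trajectories, with bias-adjusted three-step
regression of trajectory-class membership on early-childhood risk factors.

## The problem

Constipation and soiling are common, frequently comorbid childhood bowel
problems. Population cohorts such as ALSPAC (the Avon Longitudinal Study of
Parents and Children) measure them as repeated maternally reported binary
indicators — soiling at five waves between ages 4½ and 9½, constipation at
six waves between 4¾ and 10¾ — with substantial wave-level missingness.
Three questions drive the analysis this package implements:

1. What longitudinal *trajectory classes* of each symptom exist (normative,
   early, late, persistent patterns)?
2. How strongly are the two processes linked over childhood — in
   particular, how many soilers are constipated?
3. Which early-childhood risk factors (sex, hard stools at 2½ y,
   breastfeeding, socioeconomic position, gestation, birth weight,
   developmental level, toilet-training age) predict membership of the
   clinically meaningful composite groups?

The package is aimed at biostatisticians and epidemiologists who want these
models as a tested, scriptable Python pipeline, together with a calibrated
synthetic-cohort generator that provides ground truth for validation.

## The models

**Single-process LLCA.** Child *i*'s binary responses
*y<sub>i1</sub> … y<sub>iT</sub>* follow a C-class finite mixture with class
weights π<sub>c</sub> and class/wave-specific item probabilities
ρ<sub>ct</sub>, with local independence given class:

&nbsp;&nbsp;&nbsp;&nbsp;P(y<sub>i</sub>) = Σ<sub>c</sub> π<sub>c</sub>
Π<sub>t∈obs(i)</sub> ρ<sub>ct</sub><sup>y<sub>it</sub></sup>
(1−ρ<sub>ct</sub>)<sup>1−y<sub>it</sub></sup>

Missing waves are skipped (full-information ML under MAR). Estimation is EM
with multiple random starts; classes are enumerated by BIC and ordered
canonically (lowest mean ρ first = "normative").

**Parallel-process model.** Two latent class variables — soiling class *a*
and constipation class *b*, four classes each — are measured by their own
indicators and linked *only* through the 4×4 joint distribution
π<sub>ab</sub> (a 16-component mixture). The fitted joint table quantifies
longitudinal comorbidity.

**Composite collapse.** The 16 cells collapse deterministically into four
clinical groups: *normative* (both normative), *constipation alone*,
*soiling alone*, and *constipation with soiling*.

**Bias-adjusted three-step regression.** Children are assigned to their
modal composite group; the assignment error is summarised by
D[t,m] = P(assigned m | true t); and a multinomial logit for the *true*
class is maximised on the misclassified labels,
ℓ(γ) = Σ<sub>i</sub> log Σ<sub>t</sub> P(t|x<sub>i</sub>;γ) D[t,m<sub>i</sub>],
removing the attenuation of naive modal-label regression. Odds ratios get
Wald 95% CIs and per-factor omnibus χ² tests.

## Worked example

```python
import numpy as np
from trajlca import (GeneratorConfig, generate_cohort, fit_parallel,
                     collapse_posterior, modal_assign, error_matrix,
                     fit_threestep, wald_intervals)
from trajlca.simulate import CovariateSpec

spec = CovariateSpec(name="male", prevalence=0.48,
                     effects=[0, 0, np.log(1.78), 0])  # soiling-alone OR 1.78
cohort = generate_cohort(GeneratorConfig(n_children=8435, seed=21,
                                         covariate_specs=[spec]))
params, joint_post = fit_parallel(cohort.soiling, cohort.constipation,
                                  n_starts=2, seed=22)
comp = collapse_posterior(joint_post)
result = fit_threestep(modal_assign(comp), error_matrix(comp),
                       cohort.covariates, ["male"])
print(wald_intervals(result).query("term == 'male'")[["class", "or"]])
```

Running this (it is `examples/05_risk_factors.py`) prints

```
Odds ratios for male sex (reference: normative class):
  constipation_alone         OR 1.11 (0.96 to 1.29)
  soiling_alone              OR 1.87 (1.56 to 2.25)
  constipation_with_soiling  OR 1.16 (0.91 to 1.47)
```

— the generated soiling-alone effect (1.78) is recovered within sampling
error while the null effects stay near 1. The other scripts in `examples/`
walk through cohort simulation, single-process fitting with BIC
enumeration, the parallel model, the composite collapse (which yields the
74.5 / 13.2 / 7.5 / 4.8 group shares, the 61/39 soiler split and the 18%
overall constipation prevalence from the published joint table), and the
full pipeline. The same stages are available from a shell via the `trajlca`
CLI (`simulate`, `filter`, `fit-lca`, `fit-parallel`, `collapse`,
`regress`, `report`, `all`).

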
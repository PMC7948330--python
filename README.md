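# mgrlmm

Bayesian **m**ultidimensional **g**raded-**r**esponse **l**inear **m**ixed
**m**odels for longitudinal cohort analysis: does overall diet quality move
*latent profiles* of cardiovascular risk factors?

Epidemiological cohorts measure many correlated cardiometabolic markers —
blood pressure, BMI, waist circumference, glucose, lipids, inflammation —
repeatedly over years.  Analysing them one at a time ignores their
interdependence and the measurement error in categorised readings.  This
package implements the alternative: the eight risk factors, coded into the
ATP-III ordinal bands *normal / borderline / impaired*, are treated as
indicators of a small number of continuous latent profiles, and those
profiles are regressed jointly on a time-varying diet quality index (DQI)
with confounders and correlated subject random effects.

## The model

Measurement part (graded response model, logistic link; item *j*, subject
*i*, wave *t*):

    P(Y_itj ≥ k) = s(a_j · θ_it − b_jk),   k ∈ {1,2},   b_j1 < b_j2

with one anchor item per latent dimension (loading fixed at 1) for
identification.  Structural part:

    θ_itd = γ_d · x_it + u_id,   u_i ~ N_D(0, diag(σ) R diag(σ))

where x contains the DQI and covariates.  The γ coefficient of DQI per
profile is the quantity of interest; a 95% credible interval excluding 0 is
read as a significant association.  Fitting is by a No-U-Turn Hamiltonian
Monte Carlo sampler with exact analytic gradients; the number of profiles is
chosen among candidates by WAIC and PSIS-LOO with a one-standard-error
parsimony rule, after a polychoric-correlation eigenvalue screen rejects
unidimensionality.  See `docs/methods.md` for the full account.

The package also provides the surrounding pipeline: DQI scoring from weekly
food-group frequencies, coping-strategy scores, per-wave tertiles, ATP-III
coding, descriptive category tabulations, the five-model covariate
adjustment ladder, and a synthetic cohort generator with known ground truth
for validation.

## Worked example

```python
from mgrlmm import (MgrlmmSpec, SamplerSettings, fit_mgrlmm, summarize_fit,
                    make_default_truth, generate_cohort)

truth = make_default_truth(3)            # 3-profile truth, known loadings
table = generate_cohort(truth, n_subjects=300, seed=1)
spec = MgrlmmSpec(n_dims=3, covariates=("dqi", "age", "sex"),
                  sampler=SamplerSettings(chains=4, warmup=1000, draws=1000))
fit = summarize_fit(fit_mgrlmm(table, spec, seed=1))
print(f"max split R-hat: {fit.max_rhat:.4f}; divergences: {fit.n_divergent}")
print(fit.coefficient("dqi")[["parameter", "mean", "sd", "q2.5", "q97.5"]])
```

prints (a few minutes on one CPU):

```
max split R-hat: 1.0043; divergences: 0
      parameter      mean        sd      q2.5     q97.5
0  gamma[1,dqi]  0.404029  0.250483 -0.083804  0.895720
1  gamma[2,dqi] -0.122407  0.288159 -0.695719  0.435450
2  gamma[3,dqi]  0.034595  0.279959 -0.515585  0.581806
```

`gamma[d,dqi]` is the change in latent profile *d* (in anchor-item logit
units) per unit DQI; the chains mix (R-hat ≪ 1.1) and every generating
parameter class is covered by its credible interval at the ~92% rate
expected at this deliberately small cohort size — note the posterior sds
(~0.27) exceed the generating effects (0.26, 0.14, 0.24), so sign
conclusions need the full-size cohort (see `docs/methods.md`).

A command line mirrors the library:

```
mgrlmm simulate --n-subjects 300 --dims 3 --seed 1 --out cohort.csv
mgrlmm efa --input cohort.csv --wave 1
mgrlmm fit --input cohort.csv --dims 3 --seed 1 --out fitdir/
mgrlmm ladder --input cohort.csv --dims 3 --seed 1 --out ladder.csv
mgrlmm run --config config.yaml        # full pipeline
mgrlmm show-cutoffs
```

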
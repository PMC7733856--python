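# infoseek

Simulation and hierarchical Bayesian analysis of confidence-guided, costed
information seeking.

## The problem

How do people use their own sense of uncertainty to decide whether to gather
more evidence before committing to a decision — and do rigid, dogmatic
thinkers use it less? `infoseek` implements the complete computational
pipeline for studying this question with a perceptual information-seeking
task: observers judge which of two flickering-dot boxes holds more dots,
rate their confidence, and may pay points (5 or 20, varying by block) to see
a stronger stimulus before a final, incentivized decision (100 points
correct / 0 incorrect). Because participant-level data for such studies are
typically not deposited, the package ships a first-class synthetic-cohort
generator with the full statistical structure the analyses assume, so every
stage is testable end to end by parameter recovery.

## The model

The trial-by-trial decision to seek information is logistic in confidence
and cost:

    P(seek) = 1 / (1 + exp(−(β0 + β1·Confidence + β2·Cost)))

β0 is the baseline willingness to seek, β1 the coupling of seeking to
confidence (typically negative), β2 the cost sensitivity. Individual
differences are estimated hierarchically with a dogmatism covariate
embedded directly in the group-level priors:

    β_{k,i} ~ N(µ_Bk + ρ_k · Dogmatism_i, σ_Bk)

so the embedding slopes ρ are estimated jointly with everything else; a
95% credible interval for ρ_k excluding zero flags a significant
association between dogmatism and that facet of information seeking.
Downstream, the package provides standardized covariate-adjusted
regressions with ΔR², BIC-selected polynomial fits between factor scores,
sample pooling for internal meta-analysis, and quasi-Bayesian Monte Carlo
mediation (dogmatism → seeking → final accuracy). See `docs/methods.md`
for the full model description.

## Worked example

```python
from infoseek import (simulate_cohort, encode_predictors, filter_inclusion,
                      fit_hierarchical, summarize_embedding)

trials, subjects = simulate_cohort(n_subjects=200, seed=11)
su = subjects.set_index("subject_id")
keep = sorted(su.index[filter_inclusion(su["seek_rate"].to_numpy())])
design = encode_predictors(trials[trials.subject_id.isin(keep)])
dog = su.loc[keep, "dogmatism"]
dog = (dog - dog.mean()) / dog.std(ddof=0)

post = fit_hierarchical(design, dog, n_chains=2, n_warmup=400, n_draws=400, seed=5)
for name, info in summarize_embedding(post).items():
    lo, hi = info["interval"]
    print(name, f"{info['mean']:+.3f} [{lo:+.3f}, {hi:+.3f}]",
          "*" if info["excludes_zero"] else "")
```

prints

```
rho_0 -0.297 [-0.453, -0.121] *
rho_1 +0.179 [+0.097, +0.258] *
rho_2 +0.087 [-0.029, +0.191]
```

The cohort was generated with ρ = (−0.24, +0.15, 0): dogmatic subjects seek
less at baseline (ρ0 < 0) and tie their seeking less to confidence
(ρ1 > 0, against generally negative β1), with no effect on cost
sensitivity — and the fit recovers exactly that pattern, flagging ρ0 and ρ1
but not ρ2. The `examples/` directory walks through each capability
(cohort simulation, hierarchical fitting, regressions, mediation, the full
pipeline); `infoseek run --config cfg.yaml` drives the same pipeline from
the shell.

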
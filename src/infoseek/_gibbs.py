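"""MCMC sampler for the embedded-covariate hierarchical logistic model.

Model, for subject i and coefficient k in {0: intercept, 1: confidence,
2: cost}:

    sought_t            ~ Bernoulli(logistic(b[i,0] + b[i,1]*conf_t + b[i,2]*cost_t))
    b[i, k]             ~ Normal(mu[k] + rho[k] * dogmatism_i, sigma[k])
    mu[k], rho[k]       ~ Normal(0, mu_prior_sd)
    sigma[k]            ~ HalfNormal(sigma_prior_scale)

Sampling is Metropolis-within-Gibbs, vectorized across subjects:

* subject coefficients: component-wise Gaussian random-walk Metropolis with
  per-subject step sizes adapted during warmup (all subjects proposed and
  accepted/rejected in parallel — they are conditionally independent given
  the group level);
* (mu_k, rho_k): exact conjugate draw — given the subject coefficients this
  block is a Bayesian linear regression of b[:, k] on dogmatism;
* sigma_k: random-walk Metropolis on log sigma, adapted during warmup.

Data dominate the subject-level conditionals (100 trials per subject), so
the alternation mixes quickly; convergence is still checked externally via
rank-normalized R-hat and effective sample size.
"""

from __future__ import annotations

import numpy as np

_ADAPT_BLOCK = 50
_TARGET_ACCEPT = 0.44  # optimal for one-dimensional random-walk Metropolis


def _subject_loglik(eta, y, subj_idx, n_subjects):
    ll = y * eta - np.logaddexp(0.0, eta)
    return np.bincount(subj_idx, weights=ll, minlength=n_subjects)


def _run_chain(y, X, subj_idx, n_subjects, dog, n_warmup, n_draws, rng,
               mu_prior_sd, sigma_prior_scale, n_sweeps):
    n_trials, _ = X.shape
    # initialize: intercept at the (clipped) empirical logit of the seek rate
    rate = np.bincount(subj_idx, weights=y, minlength=n_subjects) / np.maximum(
        np.bincount(subj_idx, minlength=n_subjects), 1
    )
    rate = np.clip(rate, 0.02, 0.98)
    b = np.zeros((n_subjects, 3))
    b[:, 0] = np.log(rate / (1 - rate))
    b += 0.5 * rng.standard_normal(b.shape)  # overdispersed chain starts
    mu = b.mean(axis=0)
    rho = np.zeros(3)
    sigma = np.maximum(b.std(axis=0), 0.3)

    eta = X[:, 0] * b[subj_idx, 0] + X[:, 1] * b[subj_idx, 1] + X[:, 2] * b[subj_idx, 2]
    ll_subj = _subject_loglik(eta, y, subj_idx, n_subjects)

    step_b = np.full((n_subjects, 3), 0.4)
    step_s = np.full(3, 0.3)
    acc_b = np.zeros((n_subjects, 3))
    acc_s = np.zeros(3)

    Zd = np.column_stack([np.ones(n_subjects), dog])
    ZtZ = Zd.T @ Zd
    prior_prec = np.eye(2) / mu_prior_sd**2

    out_b = np.empty((n_draws, n_subjects, 3))
    out_mu = np.empty((n_draws, 3))
    out_rho = np.empty((n_draws, 3))
    out_sigma = np.empty((n_draws, 3))

    total = n_warmup + n_draws
    for it in range(total):
        # --- subject coefficients, one column at a time, all subjects in parallel
        for k in [k for _ in range(n_sweeps) for k in range(3)]:
            prop = b[:, k] + step_b[:, k] * rng.standard_normal(n_subjects)
            delta = (prop - b[:, k])[subj_idx] * X[:, k]
            eta_new = eta + delta
            ll_new = _subject_loglik(eta_new, y, subj_idx, n_subjects)
            m = mu[k] + rho[k] * dog
            lp_old = -0.5 * ((b[:, k] - m) / sigma[k]) ** 2
            lp_new = -0.5 * ((prop - m) / sigma[k]) ** 2
            accept = np.log(rng.random(n_subjects)) < (ll_new - ll_subj + lp_new - lp_old)
            b[accept, k] = prop[accept]
            ll_subj = np.where(accept, ll_new, ll_subj)
            eta = eta + np.where(accept[subj_idx], delta, 0.0)
            acc_b[:, k] += accept

        # --- (mu_k, rho_k): conjugate bivariate normal draw
        for k in range(3):
            prec = ZtZ / sigma[k] ** 2 + prior_prec
            mean = np.linalg.solve(prec, Zd.T @ b[:, k] / sigma[k] ** 2)
            chol = np.linalg.cholesky(np.linalg.inv(prec))
            draw = mean + chol @ rng.standard_normal(2)
            mu[k], rho[k] = draw

        # --- sigma_k: Metropolis on log sigma
        resid = b - (mu[None, :] + np.outer(dog, rho))
        ss = (resid**2).sum(axis=0)
        for k in range(3):
            ls_old = np.log(sigma[k])
            ls_new = ls_old + step_s[k] * rng.standard_normal()
            s_new = np.exp(ls_new)

            def logpost(s, ls):
                return (
                    -n_subjects * ls
                    - ss[k] / (2 * s**2)
                    - s**2 / (2 * sigma_prior_scale**2)
                    + ls  # Jacobian of the log transform
                )

            if np.log(rng.random()) < logpost(s_new, ls_new) - logpost(sigma[k], ls_old):
                sigma[k] = s_new
                acc_s[k] += 1

        # --- warmup adaptation
        if it < n_warmup and (it + 1) % _ADAPT_BLOCK == 0:
            rate_b = acc_b / (_ADAPT_BLOCK * n_sweeps)
            step_b *= np.exp(np.clip(rate_b - _TARGET_ACCEPT, -0.5, 0.5))
            step_b = np.clip(step_b, 1e-3, 10.0)
            rate_s = acc_s / _ADAPT_BLOCK
            step_s *= np.exp(np.clip(rate_s - _TARGET_ACCEPT, -0.5, 0.5))
            step_s = np.clip(step_s, 1e-3, 10.0)
            acc_b[:] = 0.0
            acc_s[:] = 0.0

        if it >= n_warmup:
            j = it - n_warmup
            out_b[j] = b
            out_mu[j] = mu
            out_rho[j] = rho
            out_sigma[j] = sigma

    return {"mu": out_mu, "rho": out_rho, "sigma": out_sigma, "beta": out_b}


def sample_hierarchical(
    y,
    conf,
    cost,
    subj_idx,
    n_subjects,
    dogmatism,
    n_chains=4,
    n_warmup=1000,
    n_draws=1000,
    seed=0,
    mu_prior_sd=5.0,
    sigma_prior_scale=2.5,
    n_sweeps=3,
):
    """Run the sampler; returns stacked draws per parameter.

    ``n_sweeps`` subject-level Metropolis sweeps are run per Gibbs scan to
    cut autocorrelation between the subject and group levels.

    Returns a dict with arrays shaped ``(n_chains, n_draws, ...)`` for keys
    ``mu``, ``rho``, ``sigma`` (trailing dim 3) and ``beta`` (trailing dims
    ``(n_subjects, 3)``).
    """
    y = np.asarray(y, dtype=float)
    X = np.column_stack([np.ones_like(y), np.asarray(conf, float), np.asarray(cost, float)])
    subj_idx = np.asarray(subj_idx, dtype=np.intp)
    dog = np.asarray(dogmatism, dtype=float)
    seeds = np.random.SeedSequence(seed).spawn(n_chains)
    chains = [
        _run_chain(y, X, subj_idx, n_subjects, dog, n_warmup, n_draws,
                   np.random.default_rng(s), mu_prior_sd, sigma_prior_scale, n_sweeps)
        for s in seeds
    ]
    return {k: np.stack([c[k] for c in chains]) for k in chains[0]}
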
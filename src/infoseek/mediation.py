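"""Quasi-Bayesian Monte Carlo mediation analysis.

Tests whether the effect of a treatment (dogmatism) on an outcome (final
accuracy) runs through a mediator (information-seeking rate).  Two linear
models are fit by OLS,

    M = a*X + covariates            (mediator model)
    Y = c'*X + b*M + covariates     (outcome model)

then coefficient vectors are drawn from the multivariate normal
approximation to their sampling distributions.  Per draw the average causal
mediation effect is ACME = a*b, the average direct effect ADE = c', and the
total effect their sum (exact for linear models).  Uncertainty intervals are
Monte Carlo percentiles of the draws.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import InvalidArgumentError
from .group_analysis import _build_design, zscore


@dataclass
class Effect:
    point: float
    ci_low: float
    ci_high: float
    p: float


@dataclass
class MediationResult:
    acme: Effect
    ade: Effect
    total: Effect
    prop_mediated: Effect
    n_draws: int
    seed: int
    draws: pd.DataFrame  # per-draw acme / ade / total


def _effect(draws, alpha=0.05, tails="two"):
    draws = np.asarray(draws)
    point = float(draws.mean())
    if tails == "one":
        # directional interval on the side favoured by the point estimate
        if point >= 0:
            lo, hi = float(np.quantile(draws, alpha)), float("inf")
        else:
            lo, hi = float("-inf"), float(np.quantile(draws, 1 - alpha))
        p = float(np.mean(draws <= 0) if point >= 0 else np.mean(draws >= 0))
    else:
        lo = float(np.quantile(draws, alpha / 2))
        hi = float(np.quantile(draws, 1 - alpha / 2))
        p = float(2 * min(np.mean(draws <= 0), np.mean(draws >= 0)))
    return Effect(point=point, ci_low=lo, ci_high=hi, p=min(1.0, p))


def quasi_bayes_mediation(
    subjects,
    treatment="dogmatism",
    mediator="seek_rate",
    outcome="final_accuracy",
    covariates=(),
    n_draws=1000,
    seed=0,
    tails="two",
):
    """Monte Carlo mediation of treatment -> mediator -> outcome.

    Covariates enter both the mediator and the outcome model.  Continuous
    variables are z-scored (so effects are standardized); results are
    deterministic given ``seed``.
    """
    if n_draws < 1000:
        raise InvalidArgumentError("n_draws must be >= 1000")
    for col in (treatment, mediator, outcome):
        if subjects[col].std(ddof=0) == 0:
            raise InvalidArgumentError(f"column '{col}' has zero variance")
    X_cov = _build_design(subjects, list(covariates)) if covariates else \
        pd.DataFrame(index=subjects.index)
    x = zscore(subjects[treatment])
    m = zscore(subjects[mediator])
    y = zscore(subjects[outcome])
    n = len(subjects)
    if n <= X_cov.shape[1] + 3:
        raise InvalidArgumentError("too few subjects for the covariate set")

    Xm = sm.add_constant(pd.concat([pd.Series(x, name=treatment, index=subjects.index),
                                    X_cov], axis=1))
    fit_m = sm.OLS(m, Xm).fit()
    Xy = sm.add_constant(pd.concat([pd.Series(x, name=treatment, index=subjects.index),
                                    pd.Series(m, name=mediator, index=subjects.index),
                                    X_cov], axis=1))
    fit_y = sm.OLS(y, Xy).fit()

    rng = np.random.default_rng(seed)
    draws_m = rng.multivariate_normal(fit_m.params, fit_m.cov_params(), size=n_draws,
                                      method="cholesky")
    draws_y = rng.multivariate_normal(fit_y.params, fit_y.cov_params(), size=n_draws,
                                      method="cholesky")
    a = draws_m[:, list(Xm.columns).index(treatment)]
    b = draws_y[:, list(Xy.columns).index(mediator)]
    cprime = draws_y[:, list(Xy.columns).index(treatment)]
    acme = a * b
    ade = cprime
    total = acme + ade
    with np.errstate(divide="ignore", invalid="ignore"):
        prop = np.where(total != 0, acme / total, np.nan)
    draws = pd.DataFrame({"acme": acme, "ade": ade, "total": total})
    prop_eff = _effect(prop[np.isfinite(prop)], tails=tails)
    prop_eff.point = float(np.nanmedian(prop))  # ratio: median is the stabler point estimate
    return MediationResult(
        acme=_effect(acme, tails=tails),
        ade=_effect(ade, tails=tails),
        total=_effect(total, tails=tails),
        prop_mediated=prop_eff,
        n_draws=n_draws,
        seed=seed,
        draws=draws,
    )
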
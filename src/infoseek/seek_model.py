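"""Trial-by-trial logistic model of information seeking and its estimation.

The seek decision is modelled as

    P(seek) = 1 / (1 + exp(-(b0 + b1 * Confidence + b2 * Cost)))

with Confidence the pooled z-score of the 3-level initial confidence rating
and Cost a high-cost indicator (1 for the 20-point blocks).  b0 captures the
baseline willingness to seek, b1 how strongly seeking tracks confidence
(typically negative: less seeking when confident), b2 cost sensitivity.

Estimation is hierarchical: each subject's coefficient vector is drawn from
a population whose mean shifts linearly with the subject's standardized
dogmatism score, ``b[i,k] ~ N(mu_B[k] + rho[k]*Dogmatism_i, sigma_B[k])``.
The embedding slopes rho are the quantities of scientific interest: a 95%
credible interval for rho_k excluding zero flags a significant association
between dogmatism and that facet of information seeking.  A per-subject
maximum-likelihood fit is provided as a non-hierarchical comparator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import arviz as az
import numpy as np
import pandas as pd
from scipy.optimize import minimize

from . import _gibbs
from .errors import InvalidArgumentError, SchemaError

logger = logging.getLogger(__name__)

_BOUNDARY_CLIP = 10.0  # |b0| reported when a subject never / always seeks
_SEPARABLE_NORM = 15.0

GROUP_PARAM_NAMES = tuple(
    f"{base}{k}" for base in ("mu_B", "sigma_B", "rho_") for k in range(3)
)


def seek_probability(betas, confidence_encoded, cost_encoded):
    """Logistic probability of seeking; vectorized, overflow-safe."""
    b = np.asarray(betas, dtype=float)
    eta = b[..., 0] + b[..., 1] * np.asarray(confidence_encoded, float) \
        + b[..., 2] * np.asarray(cost_encoded, float)
    eta = np.clip(eta, -500.0, 500.0)
    p = 1.0 / (1.0 + np.exp(-eta))
    return np.clip(p, 1e-300, 1.0 - 1e-16)


def encode_predictors(trials):
    """Build the seek-model design table from a trial table.

    ``confidence_encoded`` is the z-score of the 3-level initial confidence
    across all pooled trials (population SD, ddof=0); if confidence has zero
    variance it is encoded as 0 with a logged warning.  ``cost_encoded`` is
    1 for 20-point trials, 0 for 5-point trials.  Row order is preserved.
    """
    conf = trials["initial_conf_level"].to_numpy()
    cost = trials["cost_points"].to_numpy()
    bad = ~np.isin(conf, (1, 2, 3))
    if bad.any():
        row = trials.index[bad][0]
        raise SchemaError(f"unknown confidence level {conf[bad][0]} at row {row}")
    bad = ~np.isin(cost, (5, 20))
    if bad.any():
        row = trials.index[bad][0]
        raise SchemaError(f"unknown cost value {cost[bad][0]} at row {row}")
    sd = conf.std()
    if sd == 0:
        logger.warning("confidence has zero variance; encoding the predictor as 0")
        enc = np.zeros(len(conf))
    else:
        enc = (conf - conf.mean()) / sd
    return pd.DataFrame(
        {
            "subject_id": trials["subject_id"].to_numpy(),
            "sought": trials["sought"].to_numpy().astype(int),
            "confidence_encoded": enc,
            "cost_encoded": (cost == 20).astype(float),
        },
        index=trials.index,
    )


def subject_nll(betas, design):
    """Negative Bernoulli log-likelihood of one subject's seek choices."""
    if len(design) == 0:
        raise InvalidArgumentError("subject_nll requires at least one design row")
    y = design["sought"].to_numpy(dtype=float)
    p = seek_probability(betas, design["confidence_encoded"].to_numpy(),
                         design["cost_encoded"].to_numpy())
    return float(-(y * np.log(p) + (1 - y) * np.log1p(-p)).sum())


@dataclass
class SubjectBetas:
    """Per-subject seek-policy coefficients with a fit-status flag."""

    b0: float
    b1: float
    b2: float
    fit_flag: str = "ok"  # ok | separable | boundary

    @property
    def vector(self):
        return np.array([self.b0, self.b1, self.b2])


def fit_subject_mle(design):
    """Per-subject maximum-likelihood fit of the seek model.

    Classical ML on ~100 trials is noisy and degenerates when outcomes are
    perfectly predictable; the flag records those cases.  ``boundary`` means
    the subject never or always sought (intercept clipped to +-10);
    ``separable`` means the predictors perfectly separate seek from no-seek
    trials (coefficients diverging).
    """
    if len(design) < 10:
        raise InvalidArgumentError("fit_subject_mle requires at least 10 rows")
    y = design["sought"].to_numpy(dtype=float)
    if y.min() == y.max():
        return SubjectBetas(_BOUNDARY_CLIP if y[0] == 1 else -_BOUNDARY_CLIP,
                            0.0, 0.0, fit_flag="boundary")
    X = np.column_stack([
        np.ones(len(y)),
        design["confidence_encoded"].to_numpy(dtype=float),
        design["cost_encoded"].to_numpy(dtype=float),
    ])

    def nll_grad(b):
        eta = np.clip(X @ b, -500, 500)
        p = 1.0 / (1.0 + np.exp(-eta))
        nll = -(y * np.log(np.clip(p, 1e-300, 1)) +
                (1 - y) * np.log(np.clip(1 - p, 1e-300, 1))).sum()
        return nll, X.T @ (p - y)

    res = minimize(nll_grad, np.zeros(3), jac=True, method="BFGS",
                   options={"gtol": 1e-8, "maxiter": 500})
    b = res.x
    p = 1.0 / (1.0 + np.exp(-np.clip(X @ b, -500, 500)))
    separable = np.linalg.norm(b) > _SEPARABLE_NORM and np.all((p > 0.5) == (y == 1))
    return SubjectBetas(*b, fit_flag="separable" if separable else "ok")


def filter_inclusion(seek_rates):
    """Inclusion mask: keep subjects seeking on 5%-95% of trials (inclusive)."""
    r = np.asarray(seek_rates, dtype=float)
    if np.any((r < 0) | (r > 1) | ~np.isfinite(r)):
        raise InvalidArgumentError("seek rates must lie in [0, 1]")
    return (r >= 0.05) & (r <= 0.95)


@dataclass
class PosteriorSummary:
    """Posterior summary of the hierarchical fit.

    ``table`` has one row per parameter (group-level mu_B/sigma_B/rho plus
    every subject-level coefficient) with posterior mean, SD, central 95%
    interval bounds, rank-normalized R-hat and bulk effective sample size.
    ``draws`` keeps the raw group-level draws, shape (chain, draw, 3) per key.
    """

    table: pd.DataFrame
    draws: dict
    subject_ids: list
    n_chains: int
    n_draws: int
    beta_means: np.ndarray = field(repr=False, default=None)

    def group_row(self, name):
        return self.table.loc[self.table["parameter"] == name].iloc[0]


def _summary_rows(name, arr):
    """Summaries for draws shaped (chain, draw) -> one dict."""
    flat = arr.reshape(-1)
    rhat = float(az.rhat(az.convert_to_dataset(arr[..., None]))["x"].values[0])
    ess = float(az.ess(az.convert_to_dataset(arr[..., None]))["x"].values[0])
    return {
        "parameter": name,
        "mean": float(flat.mean()),
        "sd": float(flat.std(ddof=1)),
        "q2.5": float(np.quantile(flat, 0.025)),
        "q97.5": float(np.quantile(flat, 0.975)),
        "rhat": rhat,
        "ess_bulk": ess,
    }


def fit_hierarchical(
    design,
    dogmatism,
    n_chains=4,
    n_warmup=1000,
    n_draws=1000,
    seed=0,
    mu_prior_sd=5.0,
    sigma_prior_scale=2.5,
    rhat_threshold=1.01,
    n_sweeps=3,
):
    """Hierarchical Bayesian fit with dogmatism embedded in the priors.

    Parameters
    ----------
    design
        Output of :func:`encode_predictors`; subjects should already be
        restricted with :func:`filter_inclusion`.
    dogmatism
        Standardized dogmatism score per subject.  Either a mapping /
        Series indexed by subject_id, or an array aligned with the sorted
        unique subject ids of ``design``.

    Notes
    -----
    Exceeding ``rhat_threshold`` raises a logged warning, not an error; with
    ``n_chains=1`` split-R-hat is still computed but is a weaker diagnostic.
    """
    subject_ids = sorted(design["subject_id"].unique())
    n_subjects = len(subject_ids)
    if n_subjects < 20:
        raise InvalidArgumentError(f"need >= 20 subjects, got {n_subjects}")
    if isinstance(dogmatism, (pd.Series, dict)):
        dog = np.array([float(pd.Series(dogmatism)[s]) for s in subject_ids])
    else:
        dog = np.asarray(dogmatism, dtype=float)
        if len(dog) != n_subjects:
            raise InvalidArgumentError("dogmatism length does not match subject count")
    if len(np.unique(dog)) < 2:
        raise InvalidArgumentError(
            "embedding unidentifiable: fewer than 2 distinct dogmatism values"
        )

    idx_of = {s: i for i, s in enumerate(subject_ids)}
    subj_idx = design["subject_id"].map(idx_of).to_numpy()
    draws = _gibbs.sample_hierarchical(
        design["sought"].to_numpy(dtype=float),
        design["confidence_encoded"].to_numpy(dtype=float),
        design["cost_encoded"].to_numpy(dtype=float),
        subj_idx,
        n_subjects,
        dog,
        n_chains=n_chains,
        n_warmup=n_warmup,
        n_draws=n_draws,
        seed=seed,
        mu_prior_sd=mu_prior_sd,
        sigma_prior_scale=sigma_prior_scale,
        n_sweeps=n_sweeps,
    )

    rows = []
    for k in range(3):
        rows.append(_summary_rows(f"mu_B{k}", draws["mu"][:, :, k]))
    for k in range(3):
        rows.append(_summary_rows(f"sigma_B{k}", draws["sigma"][:, :, k]))
    for k in range(3):
        rows.append(_summary_rows(f"rho_{k}", draws["rho"][:, :, k]))
    # subject-level summaries: vectorized arviz call over all beta columns
    beta = draws["beta"]  # (chain, draw, n_subjects, 3)
    ds = az.convert_to_dataset(beta.reshape(beta.shape[0], beta.shape[1], -1))
    rhat_b = np.asarray(az.rhat(ds)["x"]).reshape(n_subjects, 3)
    ess_b = np.asarray(az.ess(ds)["x"]).reshape(n_subjects, 3)
    mean_b = beta.reshape(-1, n_subjects, 3).mean(axis=0)
    sd_b = beta.reshape(-1, n_subjects, 3).std(axis=0, ddof=1)
    q_lo = np.quantile(beta.reshape(-1, n_subjects, 3), 0.025, axis=0)
    q_hi = np.quantile(beta.reshape(-1, n_subjects, 3), 0.975, axis=0)
    for i, sid in enumerate(subject_ids):
        for k in range(3):
            rows.append(
                {
                    "parameter": f"beta[{sid},{k}]",
                    "mean": float(mean_b[i, k]),
                    "sd": float(sd_b[i, k]),
                    "q2.5": float(q_lo[i, k]),
                    "q97.5": float(q_hi[i, k]),
                    "rhat": float(rhat_b[i, k]),
                    "ess_bulk": float(ess_b[i, k]),
                }
            )
    table = pd.DataFrame(rows)
    worst = table["rhat"].max()
    if worst > rhat_threshold:
        logger.warning(
            "convergence warning: max R-hat %.4f exceeds threshold %.3f", worst, rhat_threshold
        )
    return PosteriorSummary(
        table=table,
        draws={k: draws[k] for k in ("mu", "sigma", "rho")},
        subject_ids=subject_ids,
        n_chains=n_chains,
        n_draws=n_draws,
        beta_means=mean_b,
    )


def summarize_embedding(posterior):
    """Significance flags for the embedding slopes rho.

    A slope is flagged iff its central 95% credible interval excludes zero;
    intervals are treated as closed, so an endpoint exactly at zero does not
    count as exclusion.
    """
    out = {}
    for k in range(3):
        row = posterior.group_row(f"rho_{k}")
        lo, hi = float(row["q2.5"]), float(row["q97.5"])
        out[f"rho_{k}"] = {
            "mean": float(row["mean"]),
            "interval": (lo, hi),
            "excludes_zero": bool(lo > 0.0 or hi < 0.0),
        }
    return out


def predict_group_curves(betas, dogmatism, trials=None, split_quantile=0.90):
    """Seek rate by confidence level: top-dogmatism decile vs the remainder.

    ``betas`` is an (n_subjects, 3) array (e.g. posterior means).  Predicted
    rates evaluate the logistic policy at the three encoded confidence
    levels, averaged over both cost levels; medians and quartiles are taken
    across subjects within each group.  When a trial table is supplied the
    empirical per-subject seek rates per confidence level are summarized the
    same way.

    Returns a dataframe with columns group, confidence_level, predicted_q25 /
    predicted_median / predicted_q75 and (if trials given) empirical ones.
    """
    betas = np.asarray(betas, dtype=float)
    dog = np.asarray(dogmatism, dtype=float)
    if betas.shape[0] != len(dog):
        raise InvalidArgumentError("betas and dogmatism are not aligned")
    if betas.shape[0] < 10:
        raise InvalidArgumentError("need at least 10 subjects to split groups")
    cut = np.quantile(dog, split_quantile)
    top = dog >= cut
    from .cohort import encode_confidence_level

    rows = []
    for group, mask in (("top_decile", top), ("remainder", ~top)):
        for level in (1, 2, 3):
            enc = encode_confidence_level(level)
            p = 0.5 * (seek_probability(betas[mask], enc, 0.0)
                       + seek_probability(betas[mask], enc, 1.0))
            row = {
                "group": group,
                "confidence_level": level,
                "predicted_q25": float(np.quantile(p, 0.25)),
                "predicted_median": float(np.median(p)),
                "predicted_q75": float(np.quantile(p, 0.75)),
            }
            rows.append(row)
    out = pd.DataFrame(rows)
    if trials is not None:
        order = sorted(trials["subject_id"].unique())
        if len(order) != len(dog):
            raise InvalidArgumentError("trial table subjects do not match dogmatism vector")
        top_ids = {s for s, t in zip(order, top) if t}
        emp = (
            trials.assign(_grp=trials["subject_id"].isin(top_ids))
            .groupby(["_grp", "initial_conf_level", "subject_id"])["sought"]
            .mean()
        )
        for i, row in out.iterrows():
            grp = row["group"] == "top_decile"
            try:
                rates = emp.loc[grp, row["confidence_level"]]
            except KeyError:
                continue
            out.loc[i, "empirical_q25"] = float(np.quantile(rates, 0.25))
            out.loc[i, "empirical_median"] = float(np.median(rates))
            out.loc[i, "empirical_q75"] = float(np.quantile(rates, 0.75))
    return out
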
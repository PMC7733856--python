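"""Subject-level statistics linking task behaviour to factor scores.

Covers the three analysis families run on the subject table: standardized
covariate-adjusted OLS regressions with a delta-R^2 for the focal predictor,
polynomial (linear / quadratic / combined) fits between factor scores
selected by BIC, and pooling of independent samples for an internal
meta-analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import CollinearityError, InvalidArgumentError, SchemaError
from .io import CONTINUOUS_SUBJECT_COLUMNS

#: Columns dummy-coded rather than z-scored (reference level 0 = female).
CATEGORICAL_COLUMNS = ("gender",)


def zscore(x):
    x = np.asarray(x, dtype=float)
    sd = x.std(ddof=0)
    if sd == 0:
        raise InvalidArgumentError("cannot standardize a zero-variance column")
    return (x - x.mean()) / sd


def _build_design(df, columns):
    """z-score continuous columns, dummy-code categorical ones."""
    parts = {}
    for col in columns:
        if col in CATEGORICAL_COLUMNS:
            values = df[col].to_numpy()
            for level in sorted(set(values) - {0}):
                parts[f"{col}_{level}"] = (values == level).astype(float)
        else:
            parts[col] = zscore(df[col])
    return pd.DataFrame(parts, index=df.index)


def _check_rank(X):
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        # identify offending columns: those whose removal restores full rank
        offenders = []
        for col in X.columns:
            rest = X.drop(columns=[col]).to_numpy()
            if np.linalg.matrix_rank(rest) == np.linalg.matrix_rank(X.to_numpy()):
                offenders.append(col)
        raise CollinearityError(offenders or list(X.columns))


@dataclass
class RegressionResult:
    """Standardized OLS fit with the focal predictor's incremental R^2."""

    outcome: str
    focal: str
    coefficients: pd.DataFrame  # term, beta, se, p
    r2_full: float
    r2_reduced: float
    delta_r2: float
    n: int
    tails: str = "two"

    @property
    def focal_beta(self):
        return float(self.coefficients.set_index("term").loc[self.focal, "beta"])

    @property
    def focal_p(self):
        return float(self.coefficients.set_index("term").loc[self.focal, "p"])


def standardized_regression(subjects, outcome, focal, covariates=(), tails="two",
                            direction=None):
    """Standardized OLS of ``outcome`` on ``focal`` plus covariates.

    Continuous variables are z-scored so coefficients are standardized
    betas; categorical covariates are dummy-coded.  ``delta_r2`` compares
    the full model against the same model without the focal predictor.
    ``tails='one'`` halves the p-value when the coefficient's sign matches
    ``direction`` (+1 or -1), mirroring a directional replication test.
    """
    cols = [outcome, focal, *covariates]
    missing = [c for c in cols if c not in subjects.columns]
    if missing:
        raise SchemaError(f"subject table is missing columns: {missing}")
    if subjects[cols].isna().any().any():
        raise InvalidArgumentError("missing values in analysis columns")
    if tails == "one" and direction not in (-1, 1):
        raise InvalidArgumentError("one-tailed tests need direction=+1 or -1")
    y = zscore(subjects[outcome])
    X = _build_design(subjects, [focal, *covariates])
    n, k = len(y), X.shape[1]
    if n <= k + 2:
        raise InvalidArgumentError(f"n={n} too small for {k} predictors")
    _check_rank(X)
    Xc = sm.add_constant(X)
    fit = sm.OLS(y, Xc).fit()
    dof = n - Xc.shape[1]
    pvals = 2 * stats.t.sf(np.abs(fit.tvalues), dof)
    coeffs = pd.DataFrame(
        {"term": Xc.columns, "beta": fit.params.to_numpy(),
         "se": fit.bse.to_numpy(), "p": pvals}
    )
    if tails == "one":
        one = np.where(np.sign(fit.params.to_numpy()) == direction,
                       pvals / 2, 1 - pvals / 2)
        coeffs["p"] = one
    focal_cols = [c for c in X.columns if c == focal or c.startswith(f"{focal}_")]
    X_red = X.drop(columns=focal_cols)
    fit_red = sm.OLS(y, sm.add_constant(X_red) if X_red.shape[1] else
                     np.ones((n, 1))).fit()
    return RegressionResult(
        outcome=outcome,
        focal=focal,
        coefficients=coeffs,
        r2_full=float(fit.rsquared),
        r2_reduced=float(fit_red.rsquared),
        delta_r2=float(fit.rsquared - fit_red.rsquared),
        n=n,
        tails=tails,
    )


@dataclass
class PolyFitResult:
    """BIC comparison of linear / quadratic / combined polynomial fits."""

    fits: dict  # label -> {"coefficients": array, "bic": float}
    selected: str = field(init=False)

    def __post_init__(self):
        # minimum BIC; ties (within float noise) go to the model with fewer terms
        order = ["linear", "quadratic", "combined"]
        best = min(order, key=lambda m: (round(self.fits[m]["bic"], 9), order.index(m)))
        self.selected = best


def polynomial_factor_fit(x, y):
    """Fit y on x with linear, quadratic and combined models; select by BIC."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 10:
        raise InvalidArgumentError("need at least 10 observations")
    if x.std() == 0:
        raise InvalidArgumentError("zero variance in x")
    designs = {
        "linear": np.column_stack([np.ones_like(x), x]),
        "quadratic": np.column_stack([np.ones_like(x), x**2]),
        "combined": np.column_stack([np.ones_like(x), x, x**2]),
    }
    fits = {}
    for label, X in designs.items():
        fit = sm.OLS(y, X).fit()
        fits[label] = {"coefficients": fit.params.copy(), "bic": float(fit.bic)}
    return PolyFitResult(fits=fits)


def pool_samples(tables, restandardize=True):
    """Concatenate study samples for an internal meta-analysis.

    Adds/normalizes a ``study`` label and re-standardizes the continuous
    subject columns on the pooled sample so pooled regressions report
    standardized coefficients on the combined population.
    """
    tables = list(tables)
    if not tables:
        raise InvalidArgumentError("no tables to pool")
    ref_cols = list(tables[0].columns)
    for i, t in enumerate(tables[1:], start=2):
        if list(t.columns) != ref_cols:
            diff = set(t.columns) ^ set(ref_cols)
            raise SchemaError(f"table {i} schema mismatch; differing columns: {sorted(diff)}")
    out = []
    for i, t in enumerate(tables, start=1):
        t = t.copy()
        if "study" not in t.columns or t["study"].nunique() == 0:
            t["study"] = f"study{i}"
        out.append(t)
    pooled = pd.concat(out, ignore_index=True)
    if restandardize:
        for col in CONTINUOUS_SUBJECT_COLUMNS:
            if col in pooled.columns and pooled[col].std(ddof=0) > 0:
                pooled[col] = zscore(pooled[col])
    return pooled
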
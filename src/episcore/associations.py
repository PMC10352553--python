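"""Cross-sectional and longitudinal association battery.

Thin, opinionated wrappers around statsmodels fits that return a uniform
estimate record:

* :func:`pearson_corr` — sample correlation between two markers.
* :func:`linear_assoc` — OLS of a standardized response on a categorical or
  continuous exposure, adjusted for age and sex; coefficients are changes in
  the standardized response per level (or per 1 SD).
* :func:`logistic_assoc` — odds ratio (with Wald 95% CI) per 1-SD increase
  in a standardized exposure, adjusted for age and sex.
* :func:`multinomial_assoc` — multinomial logit of a frailty-change class on
  one or two standardized exposures, adjusted for age, sex and continuous
  baseline frailty; per-class ORs relative to the "no increase" class.
* :func:`delta_age` — standardized residual of an epigenetic clock estimate
  regressed on chronological age (age acceleration).

All models are complete-case: rows with a missing value in any used column
are dropped, and the number actually used is reported on each estimate.
Confidence intervals are Wald intervals (± 1.96 SE) on the estimation
scale; odds ratios are exponentiated afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .exceptions import (
    CollinearityError,
    ConvergenceError,
    DegenerateOutcomeError,
    EmptyInputError,
    ParameterError,
    SeparationError,
    ZeroVarianceError,
)
from .panels import standardize

_Z = 1.959963984540054  # normal 97.5% quantile


@dataclass
class AssocEstimate:
    """One coefficient from an association model.

    ``estimate`` / ``ci_low`` / ``ci_high`` are on the reported scale:
    standardized-beta for ``scale == "beta"``, odds ratio for
    ``scale == "OR"``.  ``level`` names the exposure level (categorical
    exposures) or outcome class (multinomial models); empty otherwise.
    """

    term: str
    level: str
    estimate: float
    ci_low: float
    ci_high: float
    p: float
    scale: str
    n_used: int

    def to_dict(self) -> dict:
        return {
            "term": self.term,
            "level": self.level,
            "estimate": self.estimate,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p": self.p,
            "scale": self.scale,
            "n_used": self.n_used,
        }


def estimates_frame(estimates: list[AssocEstimate], model: str = "") -> pd.DataFrame:
    """Long-format table of estimates, optionally tagged with a model name."""
    df = pd.DataFrame([e.to_dict() for e in estimates])
    if model:
        df.insert(0, "model", model)
    return df


def pearson_corr(x, y) -> float:
    """Sample Pearson correlation; errors on constant input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ParameterError("x and y must be 1-D vectors of equal length")
    if x.size < 3:
        raise EmptyInputError("correlation requires at least 3 observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ParameterError("inputs must be finite")
    if x.std() == 0 or y.std() == 0:
        raise ZeroVarianceError("correlation undefined for a constant vector")
    return float(np.corrcoef(x, y)[0, 1])


def _expand_categorical(
    data: pd.DataFrame, column: str, reference: str | None
) -> tuple[pd.DataFrame, list[str]]:
    """Dummy-code one categorical column, dropping the reference level."""
    levels = [str(v) for v in pd.unique(data[column].dropna())]
    if reference is None:
        reference = levels[0]
    if reference not in levels:
        raise ParameterError(
            f"reference level '{reference}' not observed in '{column}'"
        )
    others = [lv for lv in levels if lv != reference]
    cols = {}
    for lv in others:
        cols[f"{column}[{lv}]"] = (data[column].astype(str) == lv).astype(float)
    return pd.DataFrame(cols, index=data.index), others


def _build_design(
    data: pd.DataFrame,
    exposure: str,
    covariates: list[str],
    reference_level: str | None,
) -> tuple[pd.DataFrame, list[str], bool]:
    """Design matrix with intercept; returns (X, exposure column names, is_categorical)."""
    categorical = not pd.api.types.is_numeric_dtype(data[exposure])
    if categorical:
        dummies, _levels = _expand_categorical(data, exposure, reference_level)
        X = dummies
        exp_cols = list(dummies.columns)
    else:
        X = data[[exposure]].astype(float)
        exp_cols = [exposure]
    for cov in covariates:
        if pd.api.types.is_numeric_dtype(data[cov]):
            X[cov] = data[cov].astype(float)
        else:
            dummies, _ = _expand_categorical(data, cov, None)
            X = pd.concat([X, dummies], axis=1)
    X = sm.add_constant(X, has_constant="add")
    return X, exp_cols, categorical


def _check_rank(X: pd.DataFrame) -> None:
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # name columns linearly dependent on the preceding ones
        offenders = []
        seen = X.iloc[:, :1]
        for col in X.columns[1:]:
            cand = pd.concat([seen, X[[col]]], axis=1)
            if np.linalg.matrix_rank(cand.to_numpy()) == seen.shape[1]:
                offenders.append(col)
            else:
                seen = cand
        raise CollinearityError(
            f"design matrix rank {rank} < {X.shape[1]} columns; "
            f"dependent columns: {offenders or list(X.columns)}"
        )


def linear_assoc(
    data: pd.DataFrame,
    response: str,
    exposure: str,
    covariates: list[str] = ("age", "sex"),
    reference_level: str | None = None,
) -> list[AssocEstimate]:
    """OLS of a (standardized) response on an exposure plus covariates.

    Categorical exposures yield one estimate per non-reference level — the
    mean difference in the standardized response relative to the reference
    level; continuous exposures yield a single slope.
    """
    cols = [response, exposure, *covariates]
    d = data[cols].dropna()
    if d.empty:
        raise EmptyInputError("no complete cases for linear model")
    X, exp_cols, _cat = _build_design(d, exposure, list(covariates), reference_level)
    _check_rank(X)
    fit = sm.OLS(d[response].astype(float), X).fit()
    out = []
    for col in exp_cols:
        b, se = fit.params[col], fit.bse[col]
        level = col[len(exposure) + 1 : -1] if col.startswith(f"{exposure}[") else ""
        out.append(
            AssocEstimate(
                term=exposure,
                level=level,
                estimate=float(b),
                ci_low=float(b - _Z * se),
                ci_high=float(b + _Z * se),
                p=float(fit.pvalues[col]),
                scale="beta",
                n_used=int(fit.nobs),
            )
        )
    return out


def logistic_assoc(
    data: pd.DataFrame,
    outcome: str,
    exposure: str,
    covariates: list[str] = ("age", "sex"),
    maxiter: int = 50,
    tol: float = 1e-8,
) -> AssocEstimate:
    """Odds ratio per 1-SD of a standardized exposure for a binary outcome.

    Fit by iteratively reweighted least squares (statsmodels Logit/Newton);
    non-convergence with a diverging coefficient is reported as separation.
    """
    cols = [outcome, exposure, *covariates]
    d = data[cols].dropna()
    if d.empty:
        raise EmptyInputError("no complete cases for logistic model")
    y = d[outcome].astype(float)
    if y.nunique() < 2:
        raise DegenerateOutcomeError(
            f"outcome '{outcome}' has a single observed class"
        )
    X, exp_cols, cat = _build_design(d, exposure, list(covariates), None)
    if cat:
        raise ParameterError("logistic_assoc expects a continuous exposure")
    _check_rank(X)
    try:
        fit = sm.Logit(y, X).fit(
            method="newton", maxiter=maxiter, tol=tol, disp=False, warn_convergence=False
        )
    except Exception as exc:  # singular Hessian under separation
        raise SeparationError(f"logistic fit failed: {exc}") from exc
    if not fit.mle_retvals["converged"]:
        if np.abs(fit.params).max() > 15:
            raise SeparationError(
                f"apparent separation on '{exposure}': |coef| = "
                f"{np.abs(fit.params).max():.1f} without convergence"
            )
        raise ConvergenceError("logistic fit did not converge")
    b, se = fit.params[exposure], fit.bse[exposure]
    return AssocEstimate(
        term=exposure,
        level="",
        estimate=float(np.exp(b)),
        ci_low=float(np.exp(b - _Z * se)),
        ci_high=float(np.exp(b + _Z * se)),
        p=float(fit.pvalues[exposure]),
        scale="OR",
        n_used=int(fit.nobs),
    )


def multinomial_assoc(
    data: pd.DataFrame,
    outcome: str,
    exposures: str | list[str],
    covariates: list[str] = ("age", "sex", "fi_baseline"),
    reference_class: str = "none",
    class_order: list[str] | None = None,
    maxiter: int = 200,
) -> list[AssocEstimate]:
    """Per-class odds ratios from a multinomial logit of a change class.

    ``exposures`` may name one column or two (joint entry of, e.g., the
    methylation score and log-CRP).  Each returned estimate is the OR for
    membership in one non-reference class, relative to ``reference_class``,
    per 1-SD increase of one exposure.  CIs are Wald intervals from the
    observed-information inverse.
    """
    if isinstance(exposures, str):
        exposures = [exposures]
    cols = [outcome, *exposures, *covariates]
    d = data[cols].dropna()
    if d.empty:
        raise EmptyInputError("no complete cases for multinomial model")
    observed = [str(v) for v in pd.unique(d[outcome])]
    if reference_class not in observed:
        raise DegenerateOutcomeError(
            f"reference class '{reference_class}' not observed"
        )
    if len(observed) < 2:
        raise DegenerateOutcomeError("multinomial outcome has a single class")
    if class_order is None:
        class_order = [reference_class] + sorted(
            c for c in observed if c != reference_class
        )
    else:
        missing = [c for c in class_order if c not in observed]
        if missing:
            raise DegenerateOutcomeError(f"classes with no observations: {missing}")
    codes = d[outcome].astype(str).map({c: i for i, c in enumerate(class_order)})
    X = d[list(exposures)].astype(float).copy()
    for cov in covariates:
        if pd.api.types.is_numeric_dtype(d[cov]):
            X[cov] = d[cov].astype(float)
        else:
            dummies, _ = _expand_categorical(d, cov, None)
            X = pd.concat([X, dummies], axis=1)
    X = sm.add_constant(X, has_constant="add")
    _check_rank(X)
    fit = sm.MNLogit(codes.to_numpy(), X).fit(
        method="newton", maxiter=maxiter, disp=False
    )
    if not fit.mle_retvals["converged"]:
        gnorm = np.linalg.norm(fit.model.score(fit.params.to_numpy().ravel(order="F")))
        raise ConvergenceError(
            f"multinomial fit did not converge (gradient norm {gnorm:.3g})"
        )
    out = []
    # MNLogit parameter columns are classes 1..K-1 relative to class 0
    for j, cls in enumerate(class_order[1:]):
        for exp_name in exposures:
            b = float(fit.params.loc[exp_name, j])
            se = float(fit.bse.loc[exp_name, j])
            out.append(
                AssocEstimate(
                    term=exp_name,
                    level=cls,
                    estimate=float(np.exp(b)),
                    ci_low=float(np.exp(b - _Z * se)),
                    ci_high=float(np.exp(b + _Z * se)),
                    p=float(fit.pvalues.loc[exp_name, j]),
                    scale="OR",
                    n_used=int(fit.nobs),
                )
            )
    return out


def delta_age(clock, age) -> np.ndarray:
    """Age acceleration: standardized residual of clock regressed on age."""
    clock = np.asarray(clock, dtype=float)
    age = np.asarray(age, dtype=float)
    if clock.shape != age.shape or clock.ndim != 1:
        raise ParameterError("clock and age must be 1-D vectors of equal length")
    if clock.size < 3:
        raise EmptyInputError("delta_age requires at least 3 observations")
    if np.std(age) == 0:
        raise ZeroVarianceError("chronological age is constant; regression degenerate")
    X = sm.add_constant(age)
    resid = sm.OLS(clock, X).fit().resid
    if resid.std(ddof=1) < 1e-12:
        raise ZeroVarianceError(
            "clock is an exact linear function of age; residuals are zero "
            "(exact-fit condition)"
        )
    return standardize(resid)
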
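"""Unpenalized model fits: linear, logistic, Cox proportional hazards.

Every downstream stage (the exposure-wide scan, backward stepwise
calibration, recalibration of interaction models, assessment) funnels
through the three ``fit_*`` functions here, which return a uniform
:class:`FitResult` with per-term coefficients, standard errors, Wald
p-values and the maximized (partial) log-likelihood.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import CoxPHFitter
from scipy import stats

from .cohort import CohortError


class FitError(ValueError):
    """Raised when a model cannot be fitted under its preconditions."""


@dataclass
class FitResult:
    family: str
    terms: list[str]
    beta: np.ndarray
    se: np.ndarray
    wald_p: np.ndarray
    loglik: float
    n_used: int
    converged: bool
    diagnostics: dict = field(default_factory=dict)

    def coef(self, term: str) -> float:
        return float(self.beta[self.terms.index(term)])

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"term": self.terms, "beta": self.beta,
                             "se": self.se, "p": self.wald_p})


def _as_design(design) -> tuple[np.ndarray, list[str]]:
    if isinstance(design, pd.DataFrame):
        return design.to_numpy(dtype=float), list(design.columns)
    X = np.asarray(design, dtype=float)
    return X, [f"x{j}" for j in range(X.shape[1])]


def _check_rank(X: np.ndarray, terms: list[str]) -> None:
    if X.shape[0] < X.shape[1]:
        raise FitError(f"fewer rows ({X.shape[0]}) than design columns ({X.shape[1]})")
    r = np.linalg.qr(X, mode="r")
    d = np.abs(np.diag(r))
    bad = d <= max(X.shape) * np.finfo(float).eps * (d.max() if d.size else 1.0)
    if bad.any():
        names = [terms[j] for j in np.flatnonzero(bad)]
        raise FitError(f"design is rank deficient; collinear terms: {names}")


def fit_linear(design, y) -> FitResult:
    """Ordinary least squares. ``design`` must already carry its intercept
    column; standard errors use the unbiased residual variance and Wald
    p-values the t distribution with n-p degrees of freedom."""
    X, terms = _as_design(design)
    y = np.asarray(y, dtype=float)
    if X.shape[0] != y.shape[0]:
        raise FitError("design and response lengths differ")
    _check_rank(X, terms)
    if X.shape[0] < X.shape[1] + 1:
        raise FitError("need at least p+1 rows for residual variance")
    res = sm.OLS(y, X).fit()
    return FitResult("lm", terms, np.asarray(res.params), np.asarray(res.bse),
                     np.asarray(res.pvalues), float(res.llf), X.shape[0], True)


def fit_logistic(design, y, maxiter: int = 100, tol: float = 1e-8) -> FitResult:
    """Binomial MLE via Newton iterations.

    Complete separation is reported, not repaired: the result comes back
    with ``converged=False`` and a ``separation`` diagnostic, and callers
    must treat it as unusable.
    """
    X, terms = _as_design(design)
    y = np.asarray(y, dtype=float)
    classes = set(np.unique(y))
    if not classes <= {0.0, 1.0}:
        raise FitError("logistic response must be 0/1")
    if len(classes) < 2:
        raise FitError("logistic response contains a single class")
    _check_rank(X, terms)
    nan = np.full(X.shape[1], np.nan)
    failed = FitResult("logistic", terms, nan, nan.copy(), nan.copy(),
                       np.nan, X.shape[0], False, {"separation": True})
    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            res = sm.Logit(y, X).fit(disp=0, maxiter=maxiter, tol=tol, method="newton")
    except np.linalg.LinAlgError:
        # Newton hit a singular Hessian: the perfectly-predicted limit
        return failed
    except Exception as exc:  # PerfectSeparationError location varies by version
        if "erfect" in type(exc).__name__ or "erfect" in str(exc):
            return failed
        raise
    separated = any("erfectSeparation" in type(w.message).__name__ for w in caught)
    # a diverging coefficient norm on the standardized scale also flags separation
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0
    if separated or np.linalg.norm(res.params * scale) > 50:
        return failed
    converged = bool(res.mle_retvals.get("converged", False))
    return FitResult("logistic", terms, np.asarray(res.params), np.asarray(res.bse),
                     np.asarray(res.pvalues), float(res.llf), X.shape[0], converged)


def fit_cox(design, time, event, penalizer: float = 0.0) -> FitResult:
    """Cox proportional hazards by Newton maximization of the partial
    likelihood with the Efron approximation for tied event times. No
    intercept term; ``loglik`` is the maximized partial log-likelihood."""
    X, terms = _as_design(design)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=float)
    if (time <= 0).any():
        raise FitError("event/censoring times must be positive")
    if event.sum() < 1:
        raise FitError("no events: cannot fit a Cox model")
    const = X.std(axis=0) == 0
    if const.any():
        names = [terms[j] for j in np.flatnonzero(const)]
        raise FitError(f"constant design column(s) give a flat partial likelihood: {names}")
    _check_rank(X, terms)
    df = pd.DataFrame(X, columns=terms)
    df["_time"], df["_event"] = time, event
    cph = CoxPHFitter(penalizer=penalizer)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            cph.fit(df, duration_col="_time", event_col="_event",
                    fit_options={"precision": 1e-9, "max_steps": 500})
        except Exception as exc:
            raise FitError(f"Cox fit failed: {exc}") from exc
    beta = cph.params_.reindex(terms).to_numpy()
    se = cph.standard_errors_.reindex(terms).to_numpy()
    p = cph.summary["p"].reindex(terms).to_numpy()
    return FitResult("cox", terms, beta, se, p, float(cph.log_likelihood_),
                     X.shape[0], True)


def likelihood_ratio_test(full: FitResult, reduced: FitResult) -> float:
    """Chi-square LRT p-value of a reduced model nested in a full model.

    Supplies one p-value per multi-level categorical exposure, whose dummy
    terms are tested jointly.
    """
    if full.family != reduced.family:
        raise FitError("likelihood ratio test requires the same model family")
    if full.n_used != reduced.n_used:
        raise FitError("models were fitted on different numbers of rows")
    if not set(reduced.terms) <= set(full.terms):
        raise FitError("reduced model is not nested in the full model")
    df = len(full.terms) - len(reduced.terms)
    if df == 0:
        return 1.0
    dev = 2.0 * (full.loglik - reduced.loglik)
    return float(stats.chi2.sf(max(dev, 0.0), df))
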
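"""Exposure-wide association scan (XWAS).

One covariate-adjusted regression per exposure: individuals with a missing
or unwanted response for that exposure (or any covariate) are removed, the
phenotype is regressed on the exposure plus covariates in the designated
family, and one p-value per exposure is stored — the slope's Wald p for a
continuous or binary-coded exposure, a joint likelihood-ratio p for a
multi-level categorical. After the loop the p-values are corrected for
multiple testing, by Benjamini–Yekutieli by default (valid under arbitrary
dependence between exposures, the realistic situation for exposomic data).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .cohort import CohortError, CohortTable, check_family, complete_cases
from .design import expand_columns, term_names
from .fitting import FitError, FitResult, fit_cox, fit_linear, fit_logistic, likelihood_ratio_test

logger = logging.getLogger(__name__)

_METHODS = {"BY": "fdr_by", "BH": "fdr_bh", "bonferroni": "bonferroni"}


def adjust_pvalues(p, method: str = "BY") -> np.ndarray:
    """Multiple-testing adjustment (BY step-up by default; also BH and
    Bonferroni), returned in the original order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if method not in _METHODS:
        raise ValueError(f"unknown correction {method!r}; choose from {sorted(_METHODS)}")
    return multipletests(p, method=_METHODS[method])[1]


def _cox_null_loglik(time, event) -> float:
    """Efron partial log-likelihood at beta = 0 (reduces to risk-set counts)."""
    time = np.asarray(time, float)
    event = np.asarray(event, float)
    ll = 0.0
    for t in np.unique(time[event == 1]):
        n_risk = int((time >= t).sum())
        d = int(((time == t) & (event == 1)).sum())
        ll -= sum(np.log(n_risk - l) for l in range(d))
    return ll


def _fit_family(family: str, design: pd.DataFrame, cohort: CohortTable) -> FitResult:
    if family == "lm":
        return fit_linear(design, cohort.pheno.to_numpy(float))
    if family == "logistic":
        return fit_logistic(design, cohort.pheno.to_numpy(float))
    return fit_cox(design, cohort.time.to_numpy(float), cohort.event.to_numpy(float))


def _null_fit(family: str, design_cov: pd.DataFrame, cohort: CohortTable) -> FitResult:
    """Reduced model with covariates only (intercept-only / null partial
    likelihood when there are none)."""
    if family == "cox" and design_cov.shape[1] == 0:
        ll = _cox_null_loglik(cohort.time, cohort.event)
        return FitResult("cox", [], np.array([]), np.array([]), np.array([]),
                         ll, cohort.n, True)
    return _fit_family(family, design_cov, cohort)


@dataclass
class XWASResults:
    """Scan results: a per-exposure summary and a per-term table."""

    table: pd.DataFrame       # exposure, beta, se, p, p_adjusted, n_used, converged
    terms: pd.DataFrame       # exposure, term, beta, se, p, n_used, converged
    correction: str
    family: str
    covariate_effects: pd.DataFrame | None = None

    def significant(self, q: float = 0.05) -> list[str]:
        t = self.table
        return list(t.loc[t["converged"] & (t["p_adjusted"] <= q), "exposure"])

    def summary(self) -> str:
        t = self.table.sort_values("p").reset_index(drop=True)
        lines = [f"XWAS ({self.family}, {self.correction} correction): "
                 f"{len(t)} exposures, {int(t['converged'].sum())} converged",
                 t.to_string(index=False, float_format=lambda v: f"{v:.4g}")]
        return "\n".join(lines)

    def to_tsv(self, path: str) -> None:
        """Long format: one row per exposure term plus a summary row."""
        term_rows = self.terms.assign(p_adjusted=np.nan, row="term")
        summ_rows = self.table.assign(term="(overall)", row="summary")
        cols = ["exposure", "term", "beta", "se", "p", "p_adjusted",
                "n_used", "converged", "row"]
        pd.concat([term_rows, summ_rows])[cols].to_csv(path, sep="\t", index=False)


def run_xwas(cohort: CohortTable, exposures: list[str] | None = None,
             covariates: list[str] = (), family: str | None = None,
             unwanted: dict[str, set] | None = None, correction: str = "BY",
             save_covariate_effects: bool = False) -> XWASResults:
    """Run the exposure-wide scan. Each exposure's model uses its own
    complete-case subset, so ``n_used`` varies across rows. Exposures whose
    fit fails (for example by separation) are reported flagged and excluded
    from the multiple-testing correction."""
    family = check_family(family or cohort.family)
    exposures = list(exposures if exposures is not None else cohort.exposures)
    covariates = list(covariates)
    if not exposures:
        raise CohortError("empty exposure list")
    clash = set(exposures) & set(covariates)
    if clash:
        raise CohortError(f"exposure(s) also listed as covariates: {sorted(clash)}")

    summaries, term_rows, cov_rows = [], [], []
    for exp in exposures:
        cc = complete_cases(cohort, [exp] + covariates, unwanted)
        exp_terms = term_names(exp, cc.kinds[exp], cc.levels.get(exp))
        design = expand_columns(cc, [exp] + covariates)
        if family != "cox":
            design.insert(0, "Intercept", 1.0)
        row = {"exposure": exp, "beta": np.nan, "se": np.nan, "p": np.nan,
               "n_used": cc.n, "converged": False}
        try:
            full = _fit_family(family, design, cc)
            if not full.converged:
                raise FitError("did not converge")
            if len(exp_terms) == 1:
                t = exp_terms[0]
                row.update(beta=full.coef(t), se=full.se[full.terms.index(t)],
                           p=float(full.wald_p[full.terms.index(t)]), converged=True)
            else:
                reduced = _null_fit(family, design.drop(columns=exp_terms), cc)
                row.update(p=likelihood_ratio_test(full, reduced), converged=True)
            for t in exp_terms:
                j = full.terms.index(t)
                term_rows.append({"exposure": exp, "term": t,
                                  "beta": float(full.beta[j]), "se": float(full.se[j]),
                                  "p": float(full.wald_p[j]), "n_used": cc.n,
                                  "converged": True})
            if save_covariate_effects:
                for t in full.terms:
                    if t not in exp_terms and t != "Intercept":
                        j = full.terms.index(t)
                        cov_rows.append({"exposure": exp, "term": t,
                                         "beta": float(full.beta[j]),
                                         "se": float(full.se[j]),
                                         "p": float(full.wald_p[j])})
        except FitError as exc:
            logger.warning("XWAS fit failed for %s: %s", exp, exc)
            term_rows.append({"exposure": exp, "term": "", "beta": np.nan,
                              "se": np.nan, "p": np.nan, "n_used": cc.n,
                              "converged": False})
        summaries.append(row)

    table = pd.DataFrame(summaries)
    table["p_adjusted"] = np.nan
    ok = table["converged"].to_numpy()
    if ok.any():
        table.loc[ok, "p_adjusted"] = adjust_pvalues(table.loc[ok, "p"], correction)
    table = table[["exposure", "beta", "se", "p", "p_adjusted", "n_used", "converged"]]
    cov_eff = pd.DataFrame(cov_rows) if save_covariate_effects else None
    return XWASResults(table, pd.DataFrame(term_rows), correction, family, cov_eff)


class XWAS:
    """Model-style front end for the scan.

    Examples
    --------
    >>> scan = XWAS(cohort, covariates=["age", "sex"])   # doctest: +SKIP
    >>> res = scan.fit()                                 # doctest: +SKIP
    >>> res.significant(q=0.05)                          # doctest: +SKIP
    """

    def __init__(self, cohort: CohortTable, exposures=None, covariates=(),
                 family=None, unwanted=None, correction="BY"):
        self.cohort = cohort
        self.exposures = exposures
        self.covariates = list(covariates)
        self.family = family or cohort.family
        self.unwanted = unwanted
        self.correction = correction

    def fit(self, save_covariate_effects: bool = False) -> XWASResults:
        return run_xwas(self.cohort, self.exposures, self.covariates,
                        self.family, self.unwanted, self.correction,
                        save_covariate_effects)
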
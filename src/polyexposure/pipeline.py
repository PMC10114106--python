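"""Three-group polyexposure risk score (PXS) derivation.

The cohort is split into disjoint groups A, B and C. Group A drives
variable selection by cross-validated shrinkage; Group B calibrates the
model (backward stepwise elimination for the main-effects variant, a plain
unpenalized recalibration of the designated family for the interaction
variant); Group C is held out entirely for scoring and assessment. The PXS
of an individual is the weighted sum of their (standardized) exposure
terms, with weights from the final calibrated model; covariates adjust the
models but never contribute to the score.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import CohortError, CohortTable, GroupSplit, check_family, complete_cases
from .compare import bootstrap_metric_ci
from .design import TermCoding
from .fitting import FitError, FitResult, fit_cox, fit_linear, fit_logistic, likelihood_ratio_test
from .penalized import DesignSpec, build_design, cv_elastic_net, cv_hier_interaction_lasso

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class StepwiseConfig:
    """Backward-elimination settings: retain an exposure only while its
    p-value in the joint model stays below ``p_threshold``."""

    p_threshold: float = 0.05
    max_iterations: int = 200

    def __post_init__(self):
        if not 0.0 < self.p_threshold <= 1.0:
            raise ValueError("p_threshold must lie in (0, 1]")


@dataclass
class PxsModel:
    """The final calibrated score model.

    ``weights`` map exposure (and product) terms to the final fit's
    coefficients on the training-standardized scale; ``coding`` carries the
    dummy layout and the Group-A centers/scales needed to reproduce that
    scale for new individuals.
    """

    family: str
    exposures: list[str]
    interactions: list[tuple[str, str]]
    weights: dict[str, float]
    covariates: list[str]
    coding: TermCoding
    product_terms: dict[str, tuple[str, str]]
    unwanted: dict[str, list[str]]
    final_fit: FitResult
    provenance: dict = field(default_factory=dict)

    def to_json(self, path: str | None = None) -> str:
        doc = {
            "family": self.family,
            "exposures": self.exposures,
            "interactions": [list(p) for p in self.interactions],
            "weights": self.weights,
            "covariates": self.covariates,
            "product_terms": {k: list(v) for k, v in self.product_terms.items()},
            "unwanted": {k: sorted(v) for k, v in self.unwanted.items()},
            "coding": {
                "exposures": self.coding.exposures,
                "kinds": self.coding.kinds,
                "levels": self.coding.levels,
                "terms": self.coding.terms,
                "term_exposure": self.coding.term_exposure,
                "center": self.coding.center,
                "scale": self.coding.scale,
            },
            "provenance": self.provenance,
        }
        s = json.dumps(doc, indent=2)
        if path:
            with open(path, "w") as fh:
                fh.write(s)
        return s

    @classmethod
    def from_json(cls, text_or_path: str) -> "PxsModel":
        try:
            doc = json.loads(text_or_path)
        except (json.JSONDecodeError, ValueError):
            with open(text_or_path) as fh:
                doc = json.load(fh)
        c = doc["coding"]
        coding = TermCoding(c["exposures"], c["kinds"], c["levels"], c["terms"],
                            c["term_exposure"], c["center"], c["scale"])
        return cls(doc["family"], doc["exposures"],
                   [tuple(p) for p in doc["interactions"]], doc["weights"],
                   doc["covariates"], coding,
                   {k: tuple(v) for k, v in doc["product_terms"].items()},
                   {k: set(v) for k, v in doc["unwanted"].items()},
                   final_fit=None, provenance=doc["provenance"])


@dataclass
class PxsScores:
    """Per-individual scores plus the count of unscoreable individuals
    (missing value, unwanted response, or unseen categorical level in any
    term the model needs)."""

    scores: pd.DataFrame          # columns ID, PXS
    n_unscoreable: int

    def to_tsv(self, path: str) -> None:
        self.scores.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# calibration-group machinery
# ---------------------------------------------------------------------------

def _term_matrix(cohort: CohortTable, coding: TermCoding,
                 product_terms: dict[str, tuple[str, str]],
                 covariates: list[str], family: str,
                 unwanted: dict[str, set] | None):
    """Complete-case standardized term matrix (plus products, covariates,
    and an intercept for non-survival families) for calibration or
    assessment rows."""
    from .design import expand_columns, term_names

    cc = complete_cases(cohort, list(coding.exposures) + list(covariates), unwanted)
    Z = coding.transform(cc)
    for name, (ta, tb) in product_terms.items():
        Z[name] = Z[ta] * Z[tb]
    cov_terms = []
    if covariates:
        cov = expand_columns(cc, list(covariates))
        for c in covariates:
            cov_terms.extend(term_names(c, cc.kinds[c], cc.levels.get(c)))
        Z = pd.concat([Z, cov[cov_terms]], axis=1)
    ok = Z.notna().all(axis=1)
    cc = CohortTable(cc.frame.loc[ok].reset_index(drop=True), cc.family,
                     cc.roles, cc.kinds, cc.levels)
    Z = Z.loc[ok].reset_index(drop=True)
    if family != "cox":
        Z.insert(0, "Intercept", 1.0)
    return cc, Z, cov_terms


def _fit_design(family, Z, cc):
    if family == "lm":
        return fit_linear(Z, cc.pheno.to_numpy(float))
    if family == "logistic":
        return fit_logistic(Z, cc.pheno.to_numpy(float))
    return fit_cox(Z, cc.time.to_numpy(float), cc.event.to_numpy(float))


def _exposure_pvalue(fit: FitResult, terms: list[str], family, Z, cc) -> float:
    """One p-value per exposure: Wald for a single term, joint LRT for a
    multi-level categorical."""
    if len(terms) == 1:
        return float(fit.wald_p[fit.terms.index(terms[0])])
    reduced = _fit_design(family, Z.drop(columns=terms), cc)
    return likelihood_ratio_test(fit, reduced)


def backward_stepwise(cohort_b: CohortTable, candidates: list[str],
                      covariates: list[str], family: str,
                      config: StepwiseConfig = StepwiseConfig(),
                      coding: TermCoding | None = None,
                      unwanted: dict[str, set] | None = None):
    """Backward elimination on the calibration group.

    Fits the joint model of all current candidates plus covariates, removes
    the single worst exposure whose p-value is at or above the threshold
    (ties broken by removing the later-listed exposure first), and refits
    until every remaining exposure is independently significant. Covariates
    are never removed. The complete-case rows are fixed at the initial
    candidate set so successive fits stay nested and comparable.

    Returns ``(final FitResult, retained exposures)``.
    """
    if not candidates:
        raise CohortError("backward stepwise needs a non-empty candidate set")
    family = check_family(family)
    if coding is None:
        cc0 = complete_cases(cohort_b, list(candidates) + list(covariates), unwanted)
        coding, _ = TermCoding.fit(cc0, list(candidates))
    cc, Zfull, _ = _term_matrix(cohort_b, coding, {}, list(covariates),
                                family, unwanted)
    current = [e for e in candidates if coding.terms_of(e)]
    prev_p: dict[str, float] = {}
    for _ in range(config.max_iterations):
        if not current:
            raise CohortError("no exposure survives calibration")
        keep_terms = (["Intercept"] if "Intercept" in Zfull else [])
        exp_terms = {e: coding.terms_of(e) for e in current}
        cols = keep_terms + [t for e in current for t in exp_terms[e]] + \
            [c for c in Zfull.columns if c not in coding.terms and c not in keep_terms]
        Z = Zfull[cols]
        try:
            fit = _fit_design(family, Z, cc)
            if not fit.converged:
                raise FitError("model did not converge")
        except FitError as exc:
            if not prev_p:
                raise CohortError(f"initial calibration fit failed: {exc}") from exc
            worst = max(current, key=lambda e: (prev_p.get(e, 1.0), current.index(e)))
            logger.warning("refit failed (%s); removing %s", exc, worst)
            current = [e for e in current if e != worst]
            continue
        pvals = {e: _exposure_pvalue(fit, exp_terms[e], family, Z, cc)
                 for e in current}
        prev_p = pvals
        worst, worst_p = None, -1.0
        for e in current:             # later input order wins ties
            if pvals[e] >= worst_p:
                worst, worst_p = e, pvals[e]
        if worst_p < config.p_threshold:
            return fit, current
        current = [e for e in current if e != worst]
    raise CohortError("backward stepwise did not terminate")


# ---------------------------------------------------------------------------
# derivation
# ---------------------------------------------------------------------------

def _nonempty_groups(cohort, split, need_c=False):
    a = cohort.subset_ids(split.ids_a)
    b = cohort.subset_ids(split.ids_b)
    if a.n == 0 or b.n == 0:
        raise CohortError("groups A and B must be non-empty")
    if need_c and not split.ids_c:
        raise CohortError("group C is empty: no individuals to score")
    return a, b


def _unwanted_as_lists(unwanted):
    return {k: sorted(map(str, v)) for k, v in (unwanted or {}).items()}


def derive_pxs(cohort: CohortTable, split: GroupSplit, exposures: list[str],
               covariates: list[str] = (), family: str | None = None,
               unwanted: dict[str, set] | None = None, alpha: float = 1.0,
               k: int = 10, stepwise: StepwiseConfig = StepwiseConfig(),
               seed: int = 0, n_lambda: int = 100) -> PxsModel:
    """Main-effects PXS derivation.

    Step 1 (Group A): cross-validated elastic net (lasso by default) over
    the complete cases; exposures with any nonzero coefficient at
    lambda_min are carried forward. Step 2 (Group B): backward stepwise
    calibration at ``stepwise.p_threshold``. The returned model's weights
    are the final fit's exposure-term coefficients.
    """
    family = check_family(family or cohort.family)
    a, b = _nonempty_groups(cohort, split)
    cc_a = complete_cases(a, list(exposures) + list(covariates), unwanted)
    design = build_design(cc_a, list(exposures), list(covariates))
    kw = (dict(time=cc_a.time.to_numpy(float), event=cc_a.event.to_numpy(float))
          if family == "cox" else dict(y=cc_a.pheno.to_numpy(float)))
    fit1 = cv_elastic_net(design, family=family, alpha=alpha, k=k, seed=seed,
                          n_lambda=n_lambda, **kw)
    if not fit1.selected_exposures:
        raise CohortError("shrinkage step selected no exposures")
    coding_sel = design.coding.restrict(fit1.selected_exposures)
    final, retained = backward_stepwise(b, fit1.selected_exposures,
                                        list(covariates), family, stepwise,
                                        coding=coding_sel, unwanted=unwanted)
    coding_final = coding_sel.restrict(retained)
    weights = {t: final.coef(t) for t in coding_final.terms}
    prov = {"variant": "main_effects", "alpha": alpha, "k": k, "seed": seed,
            "lambda_min": fit1.lambda_min, "p_threshold": stepwise.p_threshold,
            "n_group_a": int(a.n), "n_group_b": int(b.n),
            "n_step1": int(cc_a.n), "n_step2": int(final.n_used),
            "step1_selected": fit1.selected_exposures}
    return PxsModel(family, retained, [], weights, list(covariates),
                    coding_final, {}, _unwanted_as_lists(unwanted), final, prov)


def derive_pxs_interactions(cohort: CohortTable, split: GroupSplit,
                            exposures: list[str], covariates: list[str] = (),
                            family: str | None = None,
                            unwanted: dict[str, set] | None = None,
                            k: int = 10, seed: int = 0,
                            n_lambda: int = 100) -> PxsModel:
    """Interaction-aware PXS derivation with the strong-hierarchy guarantee.

    Step 1 (Group A): hierarchical group lasso over main effects and all
    pairwise interactions — run on the event indicator with a logistic loss
    when the designated family is survival. Step 2 (Group B): unpenalized
    recalibration of the designated family with exactly the selected main
    and product terms plus covariates (no stepwise pruning).
    """
    family = check_family(family or cohort.family)
    a, b = _nonempty_groups(cohort, split)
    cc_a = complete_cases(a, list(exposures) + list(covariates), unwanted)
    design = build_design(cc_a, list(exposures), list(covariates), interactions=True)
    family_eff = "lm" if family == "lm" else "logistic"
    y_a = (cc_a.event if family == "cox" else cc_a.pheno).to_numpy(float)
    fit1 = cv_hier_interaction_lasso(design, y_a, family_eff, k=k, seed=seed,
                                     n_lambda=n_lambda)
    if not fit1.selected_exposures:
        raise CohortError("group-lasso step selected no exposures")
    coding_sel = design.coding.restrict(fit1.selected_exposures)
    prods = {}
    for (ea, eb) in fit1.selected_interactions:
        for ta in coding_sel.terms_of(ea):
            for tb in coding_sel.terms_of(eb):
                prods[f"{ta}:{tb}"] = (ta, tb)
    cc_b, Z, _ = _term_matrix(b, coding_sel, prods, list(covariates),
                              family, unwanted)
    try:
        final = _fit_design(family, Z, cc_b)
    except FitError as exc:
        aliased = [t for t in prods if t in str(exc)]
        if not aliased:
            raise
        logger.warning("dropping aliased product term(s) %s", aliased)
        for t in aliased:
            prods.pop(t)
        Z = Z.drop(columns=aliased)
        final = _fit_design(family, Z, cc_b)
    score_terms = list(coding_sel.terms) + list(prods)
    weights = {t: final.coef(t) for t in score_terms}
    prov = {"variant": "interactions", "k": k, "seed": seed,
            "lambda_min": fit1.lambda_min,
            "surrogate_family": family_eff,
            "n_group_a": int(a.n), "n_group_b": int(b.n),
            "n_step1": int(cc_a.n), "n_step2": int(final.n_used)}
    return PxsModel(family, fit1.selected_exposures,
                    fit1.selected_interactions, weights, list(covariates),
                    coding_sel, prods, _unwanted_as_lists(unwanted), final, prov)


# ---------------------------------------------------------------------------
# scoring and assessment
# ---------------------------------------------------------------------------

def score_pxs(model: PxsModel, cohort_subset: CohortTable) -> PxsScores:
    """Weighted sum of exposure (and product) terms on the training scale.

    Individuals with a missing value, an unwanted response, or an unseen
    categorical level in any required term are unscoreable and counted.
    Covariates do not enter the score.
    """
    sub = cohort_subset
    if model.unwanted:
        frame = sub.frame.copy()
        for col, codes in model.unwanted.items():
            if col in frame.columns:
                frame[col] = frame[col].where(
                    ~frame[col].astype(str).isin(set(map(str, codes))))
        sub = CohortTable(frame, sub.family, sub.roles, sub.kinds, sub.levels)
    Z = model.coding.transform(sub)
    for name, (ta, tb) in model.product_terms.items():
        Z[name] = Z[ta] * Z[tb]
    needed = list(model.weights)
    ok = Z[needed].notna().all(axis=1) if needed else pd.Series(True, index=Z.index)
    w = np.array([model.weights[t] for t in needed])
    vals = Z.loc[ok, needed].to_numpy(float) @ w if needed else np.zeros(int(ok.sum()))
    out = pd.DataFrame({"ID": sub.ids[ok].to_numpy(), "PXS": vals})
    return PxsScores(out, int((~ok).sum()))


def assess_prediction(model: PxsModel, scores: PxsScores,
                      cohort_c: CohortTable, family: str | None = None,
                      B: int = 1000, ci_level: float = 0.95, seed: int = 0):
    """Held-out goodness of fit of the score: fit PHENO ~ PXS + covariates
    on the scored Group-C individuals and report R^2 / AUC / C-index with a
    percentile-bootstrap CI."""
    family = check_family(family or model.family)
    if cohort_c.n == 0:
        raise CohortError("group C is empty")
    merged = cohort_c.frame.merge(scores.scores, on="ID", how="inner")
    if merged.empty:
        raise CohortError("no scored individuals in the assessment cohort")
    sub = CohortTable(merged, cohort_c.family, cohort_c.roles, cohort_c.kinds,
                      cohort_c.levels)
    sub.roles = dict(sub.roles)
    cc = complete_cases(sub, list(model.covariates)) if model.covariates else sub
    from .design import expand_columns, term_names
    Z = pd.DataFrame({"PXS": cc.frame["PXS"].to_numpy(float)})
    if model.covariates:
        cov = expand_columns(cc, list(model.covariates))
        cov_terms = [t for c in model.covariates
                     for t in term_names(c, cc.kinds[c], cc.levels.get(c))]
        Z = pd.concat([Z, cov[cov_terms]], axis=1)
    if family != "cox":
        Z.insert(0, "Intercept", 1.0)
    fit = _fit_design(family, Z, cc)
    if family == "lm":
        pred = Z.to_numpy(float) @ fit.beta
        kw = dict(y=cc.pheno.to_numpy(float))
    elif family == "logistic":
        from scipy.special import expit
        pred = expit(Z.to_numpy(float) @ fit.beta)
        kw = dict(y=cc.pheno.to_numpy(float))
    else:
        pred = Z.to_numpy(float) @ fit.beta
        kw = dict(time=cc.time.to_numpy(float), event=cc.event.to_numpy(float))
    point, ci = bootstrap_metric_ci(pred, family, B=B, ci_level=ci_level,
                                    seed=seed, **kw)
    metric = {"lm": "R2", "logistic": "AUC", "cox": "C-index"}[family]
    return {"metric": metric, "value": point, "ci": ci, "ci_level": ci_level,
            "B": B, "seed": seed, "n": int(cc.n), "fit": fit, "pred": pred}


# ---------------------------------------------------------------------------
# model-style front end
# ---------------------------------------------------------------------------

@dataclass
class PXSResults:
    """Derivation + held-out validation bundle."""

    model: PxsModel
    scores: PxsScores
    assessment: dict

    def summary(self) -> str:
        m = self.model
        lines = [f"PXS ({m.family}, {m.provenance.get('variant')}): "
                 f"{len(m.exposures)} exposures"
                 + (f", {len(m.interactions)} interaction pairs" if m.interactions else ""),
                 "weights:"]
        for t, w in m.weights.items():
            lines.append(f"  {t:30s} {w:+.4f}")
        a = self.assessment
        lines.append(f"held-out {a['metric']}: {a['value']:.4f} "
                     f"(95% CI {a['ci'][0]:.4f} to {a['ci'][1]:.4f}, "
                     f"n={a['n']}, unscoreable={self.scores.n_unscoreable})")
        return "\n".join(lines)


class PXS:
    """Polyexposure-risk-score model: selection on A, calibration on B,
    held-out scoring and assessment on C.

    Set ``interactions=True`` for the hierarchical pairwise-interaction
    variant (group-lasso selection, plain recalibration, no stepwise).
    """

    def __init__(self, cohort: CohortTable, split: GroupSplit,
                 exposures=None, covariates=(), family=None, unwanted=None,
                 interactions: bool = False, alpha: float = 1.0, k: int = 10,
                 p_threshold: float = 0.05, seed: int = 0, n_lambda: int = 100):
        self.cohort = cohort
        self.split = split
        self.exposures = list(exposures if exposures is not None else cohort.exposures)
        self.covariates = list(covariates)
        self.family = family or cohort.family
        self.unwanted = unwanted
        self.interactions = interactions
        self.alpha = alpha
        self.k = k
        self.p_threshold = p_threshold
        self.seed = seed
        self.n_lambda = n_lambda

    def fit(self, B: int = 1000) -> PXSResults:
        if self.interactions:
            model = derive_pxs_interactions(
                self.cohort, self.split, self.exposures, self.covariates,
                self.family, self.unwanted, k=self.k, seed=self.seed,
                n_lambda=self.n_lambda)
        else:
            model = derive_pxs(
                self.cohort, self.split, self.exposures, self.covariates,
                self.family, self.unwanted, alpha=self.alpha, k=self.k,
                stepwise=StepwiseConfig(self.p_threshold), seed=self.seed,
                n_lambda=self.n_lambda)
        if not self.split.ids_c:
            raise CohortError("group C is empty: cannot score or assess")
        c = self.cohort.subset_ids(self.split.ids_c)
        scores = score_pxs(model, c)
        assessment = assess_prediction(model, scores, c, self.family,
                                       B=B, seed=self.seed)
        return PXSResults(model, scores, assessment)
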
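"""Goodness-of-fit metrics and paired-bootstrap model comparison.

The metric is chosen by family: R^2 for linear models, AUC for logistic
models, Harrell's C-index for Cox models. ``delta_pred`` compares two sets
of predictions for the same individuals with a paired bootstrap — each
replicate resamples individuals once and evaluates both models on that same
replicate, the variance-correct way to bootstrap a difference.
``risk_stratify`` reproduces the top-decile-versus-rest hazard-ratio
contrast and the percentile-incidence table behind it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .fitting import FitError, fit_cox, fit_logistic


class MetricError(ValueError):
    pass


def r_squared(y, yhat) -> float:
    """Coefficient of determination 1 - SS_res/SS_tot (can be negative for
    predictions worse than the mean)."""
    y = np.asarray(y, float)
    yhat = np.asarray(yhat, float)
    if y.shape != yhat.shape or y.size < 2:
        raise MetricError("need two equal-length vectors of length >= 2")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise MetricError("constant outcome: R^2 undefined")
    return 1.0 - float(np.sum((y - yhat) ** 2)) / ss_tot


def auc(labels, scores) -> float:
    """Probability a random positive outscores a random negative, ties
    counted one half (the Mann-Whitney form of the ROC area)."""
    labels = np.asarray(labels, float)
    if len(np.unique(labels)) < 2:
        raise MetricError("AUC needs both classes present")
    return float(roc_auc_score(labels, np.asarray(scores, float)))


def _c_counts(time, event, risk):
    """Concordant weight and comparable-pair count, Harrell conventions."""
    t = np.asarray(time, float)
    e = np.asarray(event, float).astype(bool)
    r = np.asarray(risk, float)
    # ordered pair (i, j) usable when i is an event observed strictly before
    # j's time, or at j's censoring time (j then outlived i)
    ti, tj = t[:, None], t[None, :]
    ei, ej = e[:, None], e[None, :]
    usable = ei & ((ti < tj) | ((ti == tj) & ~ej))
    np.fill_diagonal(usable, False)
    ri, rj = r[:, None], r[None, :]
    conc = usable & (ri > rj)
    tied = usable & (ri == rj)
    return float(conc.sum() + 0.5 * tied.sum()), int(usable.sum())


def c_index(time, event, risk) -> float:
    """Harrell's concordance index: among usable pairs, the fraction where
    the earlier-failing individual carries the higher predicted risk, ties
    in risk counting one half. Pairs of two events with tied times, and
    pairs whose earlier time is censored, are not usable."""
    if np.asarray(event, float).sum() < 1:
        raise MetricError("C-index needs at least one event")
    num, den = _c_counts(time, event, risk)
    if den == 0:
        raise MetricError("no comparable pairs")
    return num / den


def _metric(family, pred, y=None, time=None, event=None) -> float:
    if family == "lm":
        return r_squared(y, pred)
    if family == "logistic":
        return auc(y, pred)
    return c_index(time, event, pred)


@dataclass
class GofComparison:
    """Paired-bootstrap comparison of two prediction sets."""

    metric: str
    value_model1: float
    value_model2: float
    delta: float
    deltas: np.ndarray
    ci_level: float
    ci_lower: float
    ci_upper: float
    B: int
    seed: int

    def to_json(self, path: str | None = None) -> str:
        doc = {"metric": self.metric, "value1": self.value_model1,
               "value2": self.value_model2, "delta": self.delta,
               "ci": [self.ci_lower, self.ci_upper], "ci_level": self.ci_level,
               "B": self.B, "seed": self.seed}
        s = json.dumps(doc, indent=2)
        if path:
            with open(path, "w") as fh:
                fh.write(s)
        return s


_METRIC_NAMES = {"lm": "R2", "logistic": "AUC", "cox": "C-index"}


def delta_pred(pred1, pred2, family: str, y=None, time=None, event=None,
               B: int = 1000, ci_level: float = 0.95, seed: int = 0,
               max_redraw: int = 100) -> GofComparison:
    """Difference in goodness of fit (model2 minus model1) with a paired
    percentile-bootstrap confidence interval. Replicates on which the
    metric is undefined (single class, no comparable pairs) are redrawn."""
    if B < 1:
        raise MetricError("B must be at least 1")
    pred1 = np.asarray(pred1, float)
    pred2 = np.asarray(pred2, float)
    if pred1.shape != pred2.shape:
        raise MetricError("prediction sets must cover the same individuals")
    n = pred1.shape[0]
    kw = dict(y=y, time=time, event=event)
    v1 = _metric(family, pred1, **kw)
    v2 = _metric(family, pred2, **kw)
    rng = np.random.default_rng(seed)
    deltas = np.empty(B)
    y_ = None if y is None else np.asarray(y, float)
    t_ = None if time is None else np.asarray(time, float)
    e_ = None if event is None else np.asarray(event, float)
    for b in range(B):
        for attempt in range(max_redraw + 1):
            idx = rng.integers(0, n, n)
            sub = dict(y=None if y_ is None else y_[idx],
                       time=None if t_ is None else t_[idx],
                       event=None if e_ is None else e_[idx])
            try:
                deltas[b] = (_metric(family, pred2[idx], **sub)
                             - _metric(family, pred1[idx], **sub))
                break
            except MetricError:
                if attempt == max_redraw:
                    raise MetricError(
                        f"bootstrap replicate undefined after {max_redraw} redraws")
    lo, hi = np.quantile(deltas, [(1 - ci_level) / 2, 1 - (1 - ci_level) / 2])
    return GofComparison(_METRIC_NAMES[family], v1, v2, v2 - v1, deltas,
                         ci_level, float(lo), float(hi), B, seed)


def bootstrap_metric_ci(pred, family: str, y=None, time=None, event=None,
                        B: int = 1000, ci_level: float = 0.95, seed: int = 0):
    """Percentile bootstrap CI for a single model's goodness of fit."""
    point = _metric(family, np.asarray(pred, float), y=y, time=time, event=event)
    n = len(pred)
    rng = np.random.default_rng(seed)
    pred = np.asarray(pred, float)
    y_ = None if y is None else np.asarray(y, float)
    t_ = None if time is None else np.asarray(time, float)
    e_ = None if event is None else np.asarray(event, float)
    vals = []
    for _ in range(B):
        for _att in range(101):
            idx = rng.integers(0, n, n)
            try:
                vals.append(_metric(family, pred[idx],
                                    y=None if y_ is None else y_[idx],
                                    time=None if t_ is None else t_[idx],
                                    event=None if e_ is None else e_[idx]))
                break
            except MetricError:
                continue
    lo, hi = np.quantile(vals, [(1 - ci_level) / 2, 1 - (1 - ci_level) / 2])
    return point, (float(lo), float(hi))


def risk_stratify(scores, y=None, time=None, event=None, family: str = "cox",
                  top_fraction: float = 0.10):
    """Top-fraction versus rest risk contrast plus the percentile table.

    For survival outcomes, fits a Cox model on the top-decile indicator and
    returns the hazard ratio with its 95% Wald CI; for binary outcomes an
    odds ratio. Also returns the 100-bin percentile table with per-bin
    event counts and incidence (events divided by bin size).
    """
    s = np.asarray(scores, float)
    n = s.size
    if n < 10:
        raise MetricError("need at least 10 individuals to stratify")
    cut = np.quantile(s, 1.0 - top_fraction)
    top = (s > cut).astype(float)
    if top.sum() == 0 or top.sum() == n:
        raise MetricError("degenerate top-fraction split")
    design = pd.DataFrame({"top": top})
    if family == "cox":
        fit = fit_cox(design, time, event, penalizer=0.0)
        outcome = np.asarray(event, float)
    elif family == "logistic":
        design.insert(0, "Intercept", 1.0)
        fit = fit_logistic(design, y)
        outcome = np.asarray(y, float)
        if not fit.converged:
            raise FitError("stratification fit did not converge")
    else:
        raise MetricError("risk_stratify supports cox and logistic families")
    j = fit.terms.index("top")
    beta, se = float(fit.beta[j]), float(fit.se[j])
    ratio = float(np.exp(beta))
    ci = (float(np.exp(beta - 1.959963984540054 * se)),
          float(np.exp(beta + 1.959963984540054 * se)))
    # percentile-incidence table: 100 equal-count bins of the score
    order = np.argsort(s, kind="stable")
    bins = np.minimum((np.arange(n)[np.argsort(order)] * 100) // n, 99)
    tab = pd.DataFrame({"bin": bins, "outcome": outcome}).groupby("bin").agg(
        n=("outcome", "size"), events=("outcome", "sum")).reset_index()
    tab["incidence"] = tab["events"] / tab["n"]
    return {"ratio": ratio, "ci": ci, "p": float(fit.wald_p[j]),
            "beta": beta, "se": se, "top_fraction": top_fraction,
            "table": tab}
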
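"""Cross-validated penalized regression for exposure selection.

Two solvers, both written here because the selection machinery is the core
of the method:

* an elastic-net (lasso by default) path solver by cyclic coordinate
  descent, for linear, logistic and Cox families, with per-column penalty
  factors so covariates can be forced into every model unpenalized;
* an overlapped group lasso for pairwise exposure interactions, solved by
  FISTA with group soft-thresholding. Each interaction group's latent
  coefficient block contains both parents' main-effect columns as well as
  their products, so a nonzero interaction necessarily brings its main
  effects into the model — the strong-hierarchy guarantee holds by
  construction of the convex program.

Objective conventions: the smooth loss is the average negative
log-likelihood (for ``lm``: ``(1/2n)||y - Xb||^2``); the elastic penalty is
``lambda * sum_j w_j (alpha |b_j| + (1-alpha)/2 b_j^2)``; the group penalty
is ``lambda * sum_g sqrt(|g|) ||theta_g||_2``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .cohort import CohortError, CohortTable
from .design import TermCoding, expand_columns, term_names

logger = logging.getLogger(__name__)

_ETA_CLIP = 30.0
_W_FLOOR = 1e-5


def soft_threshold(z: float, t: float) -> float:
    return np.sign(z) * max(abs(z) - t, 0.0)


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

@dataclass
class Group:
    kind: str                      # "main" | "interaction"
    exposures: tuple[str, ...]
    cols: np.ndarray               # design-column indices
    weight: float                  # sqrt(group size)


@dataclass
class DesignSpec:
    """Term-expanded numeric design: standardized penalized exposure columns
    first, then raw unpenalized covariate columns, then (with interactions)
    product columns. ``coding`` stores the dummy layout and centers/scales
    so coefficients can be mapped back to the original scale."""

    X: np.ndarray
    terms: list[str]
    penalty_factor: np.ndarray
    coding: TermCoding
    covariates: list[str]
    cov_terms: list[str]
    groups: list[Group] | None = None
    product_parents: dict[str, tuple[str, str]] = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.X.shape[0]

    def col(self, term: str) -> int:
        return self.terms.index(term)


def build_design(cohort: CohortTable, exposures: list[str],
                 covariates: list[str] = (), interactions: bool = False) -> DesignSpec:
    """Build the penalized design from complete-case rows.

    Exposure terms (dummy-expanded, reference level dropped) are
    standardized to mean 0 / unit variance; constant terms are dropped with
    a warning. Covariate terms are unpenalized and left on their raw scale.
    With ``interactions`` every exposure pair gets a group holding both
    mains' columns plus their element-wise products.
    """
    coding, Z = TermCoding.fit(cohort, list(exposures))
    cov_terms: list[str] = []
    cov_mat = expand_columns(cohort, list(covariates)) if covariates else pd.DataFrame(index=Z.index)
    for c in covariates:
        cov_terms.extend(term_names(c, cohort.kinds[c], cohort.levels.get(c)))
    if cov_mat.isna().any().any():
        raise CohortError("covariates contain missing values after filtering")

    terms = list(coding.terms) + cov_terms
    blocks = [Z.to_numpy(float)]
    if cov_terms:
        blocks.append(cov_mat[cov_terms].to_numpy(float))
    X = np.column_stack(blocks) if len(blocks) > 1 else blocks[0]
    pf = np.concatenate([np.ones(len(coding.terms)), np.zeros(len(cov_terms))])

    groups = None
    product_parents: dict[str, tuple[str, str]] = {}
    kept = [e for e in exposures if coding.terms_of(e)]
    if interactions:
        groups = []
        col_of = {t: j for j, t in enumerate(terms)}
        for e in kept:
            cols = np.array([col_of[t] for t in coding.terms_of(e)])
            groups.append(Group("main", (e,), cols, float(np.sqrt(len(cols)))))
        prod_cols = []
        for i, a in enumerate(kept):
            for b in kept[i + 1:]:
                a_cols = [col_of[t] for t in coding.terms_of(a)]
                b_cols = [col_of[t] for t in coding.terms_of(b)]
                p_idx = []
                for ta in coding.terms_of(a):
                    for tb in coding.terms_of(b):
                        name = f"{ta}:{tb}"
                        product_parents[name] = (a, b)
                        prod_cols.append(X[:, col_of[ta]] * X[:, col_of[tb]])
                        terms.append(name)
                        p_idx.append(len(terms) - 1)
                cols = np.array(a_cols + b_cols + p_idx)
                groups.append(Group("interaction", (a, b), cols,
                                    float(np.sqrt(len(cols)))))
        if prod_cols:
            X = np.column_stack([X] + prod_cols)
            pf = np.concatenate([pf, np.ones(len(prod_cols))])
    return DesignSpec(X, terms, pf, coding, list(covariates), cov_terms,
                      groups, product_parents)


# ---------------------------------------------------------------------------
# coordinate descent core
# ---------------------------------------------------------------------------

def _cd_quadratic(G, b, beta, lam, alpha, pf, tol=1e-10, max_iter=1000):
    """Cyclic coordinate descent on (1/2) b'Gb - b'beta + elastic penalty.

    For the Gaussian family G = X'X/n and b = X'y/n, so this minimizes the
    average-loss elastic-net objective exactly; the other families call it
    on their IRLS quadratic approximations. The quadratic-form objective is
    non-increasing across coordinate updates by construction (each update
    is the exact 1-D minimizer).
    """
    p = len(b)
    q = G @ beta
    diag = np.diag(G)
    active = np.arange(p)
    for it in range(max_iter):
        max_delta = 0.0
        for j in active:
            if diag[j] <= 0:
                continue
            rho = b[j] - q[j] + diag[j] * beta[j]
            if pf[j] > 0:
                new = soft_threshold(rho, lam * alpha * pf[j]) / (
                    diag[j] + lam * (1.0 - alpha) * pf[j])
            else:
                new = rho / diag[j]
            d = new - beta[j]
            if d != 0.0:
                beta[j] = new
                q += G[:, j] * d
                max_delta = max(max_delta, diag[j] * d * d)
        if max_delta < tol:
            if len(active) == p:
                break
            active = np.arange(p)   # converged on active set; verify full sweep
        else:
            active = np.flatnonzero((beta != 0) | (pf == 0))
            if len(active) == 0:
                break
    return beta


def enet_path_gaussian(X, y, lambdas, alpha=1.0, penalty_factor=None,
                       tol=1e-10) -> np.ndarray:
    """Elastic-net path for the Gaussian loss (1/2n)||y - Xb||^2.
    ``X`` is used exactly as given (no internal standardization); returns
    a (len(lambdas), p) coefficient array, warm-started down the path."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n, p = X.shape
    pf = np.ones(p) if penalty_factor is None else np.asarray(penalty_factor, float)
    G = X.T @ X / n
    b = X.T @ y / n
    beta = np.zeros(p)
    out = np.empty((len(lambdas), p))
    for i, lam in enumerate(lambdas):
        beta = _cd_quadratic(G, b, beta, lam, alpha, pf, tol=tol)
        out[i] = beta
    return out


def _logistic_working(X, y, beta):
    eta = np.clip(X @ beta, -_ETA_CLIP, _ETA_CLIP)
    mu = expit(eta)
    w = np.maximum(mu * (1.0 - mu), _W_FLOOR)
    z = eta + (y - mu) / w
    return w, z, mu


def enet_path_logistic(X, y, lambdas, alpha=1.0, penalty_factor=None,
                       tol=1e-9, max_irls=30) -> np.ndarray:
    """Elastic-net path for the binomial loss, via IRLS with an inner
    weighted coordinate descent (the standard penalized-GLM scheme)."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n, p = X.shape
    pf = np.ones(p) if penalty_factor is None else np.asarray(penalty_factor, float)
    beta = np.zeros(p)
    out = np.empty((len(lambdas), p))
    for i, lam in enumerate(lambdas):
        for _ in range(max_irls):
            w, z, _ = _logistic_working(X, y, beta)
            Xw = X * w[:, None]
            G = X.T @ Xw / n
            bvec = X.T @ (w * z) / n
            old = beta.copy()
            beta = _cd_quadratic(G, bvec, beta, lam, alpha, pf, tol=tol)
            if np.max(np.abs(beta - old)) < 1e-8:
                break
        out[i] = beta
    return out


def _cox_order(time, event):
    time = np.asarray(time, float)
    event = np.asarray(event, float)
    et = np.unique(time[event == 1])
    return time, event, et


def _cox_working(eta, time, event, event_times):
    """Breslow-approximation gradient and diagonal-Hessian working terms of
    the partial likelihood, per individual (suffix-sum risk sets)."""
    eta = eta - eta.max()
    r = np.exp(eta)
    order = np.argsort(time, kind="stable")
    st, r_sorted = time[order], r[order]
    suffix = np.cumsum(r_sorted[::-1])[::-1]
    # S(t_e) = sum of r over the risk set {j: time_j >= t_e}
    S = suffix[np.searchsorted(st, event_times, side="left")]
    d = np.bincount(np.searchsorted(event_times, time[event == 1]),
                    minlength=len(event_times)).astype(float)
    c1 = np.cumsum(d / S)
    c2 = np.cumsum(d / S ** 2)
    pos = np.searchsorted(event_times, time, side="right")
    A = np.where(pos > 0, c1[np.maximum(pos - 1, 0)], 0.0)
    B = np.where(pos > 0, c2[np.maximum(pos - 1, 0)], 0.0)
    grad = event - r * A
    h = np.maximum(r * A - r * r * B, _W_FLOOR)
    loglik = float((event * eta).sum() - (d * np.log(S)).sum())
    return grad, h, loglik


def enet_path_cox(X, time, event, lambdas, alpha=1.0, penalty_factor=None,
                  tol=1e-9, max_outer=30) -> np.ndarray:
    """Elastic-net path for the Cox partial likelihood (Breslow ties inside
    the working approximation), same outer IRLS / inner coordinate-descent
    loop as the logistic family. No intercept."""
    X = np.asarray(X, float)
    n, p = X.shape
    pf = np.ones(p) if penalty_factor is None else np.asarray(penalty_factor, float)
    time, event, et = _cox_order(time, event)
    beta = np.zeros(p)
    out = np.empty((len(lambdas), p))
    for i, lam in enumerate(lambdas):
        for _ in range(max_outer):
            eta = X @ beta
            grad, h, _ = _cox_working(eta, time, event, et)
            z = eta + grad / h
            Xw = X * h[:, None]
            G = X.T @ Xw / n
            bvec = X.T @ (h * z) / n
            old = beta.copy()
            beta = _cd_quadratic(G, bvec, beta, lam, alpha, pf, tol=tol)
            if np.max(np.abs(beta - old)) < 1e-8:
                break
        out[i] = beta
    return out


# ---------------------------------------------------------------------------
# lambda path and cross-validation
# ---------------------------------------------------------------------------

def _null_beta(X, pf, family, y=None, time=None, event=None):
    """Unpenalized fit restricted to the penalty-free columns (covariates
    and, for lm/logistic, the intercept)."""
    p = X.shape[1]
    beta = np.zeros(p)
    free = np.flatnonzero(pf == 0)
    if free.size:
        sub = X[:, free]
        lam0 = np.array([0.0])
        if family == "lm":
            beta[free] = enet_path_gaussian(sub, y, lam0, 1.0, np.zeros(free.size))[0]
        elif family == "logistic":
            beta[free] = enet_path_logistic(sub, y, lam0, 1.0, np.zeros(free.size))[0]
        else:
            beta[free] = enet_path_cox(sub, time, event, lam0, 1.0, np.zeros(free.size))[0]
    return beta


def _loss_gradient(X, beta, family, y=None, time=None, event=None):
    n = X.shape[0]
    if family == "lm":
        return X.T @ (X @ beta - y) / n
    if family == "logistic":
        mu = expit(np.clip(X @ beta, -_ETA_CLIP, _ETA_CLIP))
        return X.T @ (mu - y) / n
    time, event, et = _cox_order(time, event)
    grad, _, _ = _cox_working(X @ beta, time, event, et)
    return -X.T @ grad / n


def lambda_max_enet(X, pf, alpha, family, y=None, time=None, event=None) -> float:
    """Smallest lambda at which every penalized coefficient is zero, from
    the KKT stationarity bound at the covariate-only null fit. For
    alpha < 0.001 (including ridge) the bound is anchored at alpha = 0.001,
    where the pure-L2 bound would be infinite."""
    beta0 = _null_beta(X, pf, family, y, time, event)
    g = _loss_gradient(X, beta0, family, y, time, event)
    pen = pf > 0
    if not pen.any():
        raise ValueError("no penalized columns")
    a = max(alpha, 1e-3)
    return float(np.max(np.abs(g[pen]) / pf[pen]) / a)


def make_lambda_path(lam_max: float, n_lambda: int = 100,
                     ratio: float = 1e-3) -> np.ndarray:
    return np.geomspace(lam_max, lam_max * ratio, n_lambda)


def make_folds(n: int, k: int, seed: int, strat=None) -> np.ndarray:
    """Deterministic fold labels in [0, k); when ``strat`` is given the
    labels are dealt round-robin within each stratum so folds are balanced
    on the outcome."""
    if k > n:
        raise ValueError(f"k={k} exceeds n={n}")
    if k < 3:
        raise ValueError("need at least 3 folds")
    rng = np.random.default_rng(seed)
    fold = np.empty(n, dtype=int)
    if strat is None:
        strat = np.zeros(n)
    strat = np.asarray(strat)
    start = 0
    for s in np.unique(strat):
        idx = np.flatnonzero(strat == s)
        idx = idx[rng.permutation(len(idx))]
        fold[idx] = (np.arange(len(idx)) + start) % k
        start += len(idx)
    return fold


def _cv_deviance(family, X, beta, y=None, time=None, event=None) -> float:
    if family == "lm":
        return float(np.mean((y - X @ beta) ** 2))
    if family == "logistic":
        mu = np.clip(expit(np.clip(X @ beta, -_ETA_CLIP, _ETA_CLIP)), 1e-10, 1 - 1e-10)
        return float(-2.0 * np.mean(y * np.log(mu) + (1 - y) * np.log(1 - mu)))
    t, e, et = _cox_order(time, event)
    if e.sum() == 0:
        return 0.0
    _, _, ll = _cox_working(X @ beta, t, e, et)
    return float(-2.0 * ll / e.sum())


@dataclass
class CvPenalizedFit:
    """A fitted cross-validated penalized model at lambda_min."""

    family: str
    alpha: float
    lambda_path: np.ndarray
    cv_mean: np.ndarray
    cv_se: np.ndarray
    lambda_min: float
    beta: dict                      # term -> coefficient on the design scale
    intercept: float
    beta_original: dict             # term -> coefficient on the original scale
    intercept_original: float
    selected_exposures: list[str]
    selected_interactions: list[tuple[str, str]]
    k: int
    seed: int
    design: DesignSpec

    def cv_table(self) -> pd.DataFrame:
        return pd.DataFrame({"lambda": self.lambda_path,
                             "cv_error": self.cv_mean, "cv_se": self.cv_se})


def _path_for(family):
    return {"lm": enet_path_gaussian, "logistic": enet_path_logistic,
            "cox": enet_path_cox}[family]


def _back_transform(design: DesignSpec, beta_terms: dict, intercept: float):
    """Map standardized-scale coefficients back to the original exposure
    scale (product terms stay on the standardized-term scale; scoring always
    uses the training standardization)."""
    orig = {}
    b0 = intercept
    cod = design.coding
    for t, v in beta_terms.items():
        if t in cod.center:
            orig[t] = v / cod.scale[t]
            b0 -= v * cod.center[t] / cod.scale[t]
        else:
            orig[t] = v
    return orig, b0


def cv_elastic_net(design: DesignSpec, y=None, family: str = "lm",
                   alpha: float = 1.0, k: int = 10, seed: int = 0,
                   n_lambda: int = 100, lambda_min_ratio: float = 1e-3,
                   time=None, event=None, tol: float = 1e-9) -> CvPenalizedFit:
    """K-fold cross-validated elastic net on a built design.

    The lambda path runs log-spaced from the analytic all-zero bound down
    by ``lambda_min_ratio``; folds are seeded and stratified on the outcome
    for logistic/cox; ``lambda_min`` minimizes mean held-out deviance, and
    coefficients are reported at ``lambda_min`` on both the design and the
    original scales.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    X0, pf0 = design.X, design.penalty_factor
    n = X0.shape[0]
    if family in ("lm", "logistic"):
        X = np.column_stack([X0, np.ones(n)])
        pf = np.append(pf0, 0.0)
        has_int = True
    else:
        X, pf, has_int = X0, pf0, False
    y = None if y is None else np.asarray(y, float)

    lam_max = lambda_max_enet(X, pf, alpha, family, y=y, time=time, event=event)
    path = make_lambda_path(lam_max, n_lambda, lambda_min_ratio)
    solver = _path_for(family)

    strat = y if family == "logistic" else (event if family == "cox" else None)
    folds = make_folds(n, k, seed, strat)
    dev = np.empty((k, len(path)))
    for f in range(k):
        tr, te = folds != f, folds == f
        kw_tr = dict(y=y[tr]) if family != "cox" else dict(
            time=np.asarray(time)[tr], event=np.asarray(event)[tr])
        kw_te = dict(y=y[te]) if family != "cox" else dict(
            time=np.asarray(time)[te], event=np.asarray(event)[te])
        if family == "cox":
            betas = solver(X[tr], kw_tr["time"], kw_tr["event"], path, alpha, pf, tol=tol)
        else:
            betas = solver(X[tr], kw_tr["y"], path, alpha, pf, tol=tol)
        for i in range(len(path)):
            dev[f, i] = _cv_deviance(family, X[te], betas[i], **kw_te)
    cv_mean = dev.mean(axis=0)
    cv_se = dev.std(axis=0, ddof=1) / np.sqrt(k)
    i_min = int(np.argmin(cv_mean))
    lam_min = float(path[i_min])

    if family == "cox":
        full = solver(X, np.asarray(time, float), np.asarray(event, float),
                      path, alpha, pf, tol=tol)
    else:
        full = solver(X, y, path, alpha, pf, tol=tol)
    b = full[i_min]
    intercept = float(b[-1]) if has_int else 0.0
    beta_terms = {t: float(b[j]) for j, t in enumerate(design.terms)}
    nz = {t for t, v in beta_terms.items() if v != 0.0 and pf0[design.col(t)] > 0}
    selected = [e for e in design.coding.exposures
                if any(t in nz for t in design.coding.terms_of(e))]
    orig, b0 = _back_transform(design, beta_terms, intercept)
    return CvPenalizedFit(family, alpha, path, cv_mean, cv_se, lam_min,
                          beta_terms, intercept, orig, b0, selected, [],
                          k, seed, design)


# ---------------------------------------------------------------------------
# hierarchical (overlapped) group lasso for pairwise interactions
# ---------------------------------------------------------------------------

def _latent_layout(design: DesignSpec, include_intercept: bool):
    """Concatenate group column-blocks into one latent vector; the final
    block holds unpenalized covariate columns (and the intercept slot)."""
    idx, blocks = [], []
    for g in design.groups:
        blocks.append((len(idx), len(idx) + len(g.cols), g))
        idx.extend(g.cols.tolist())
    free_cols = np.flatnonzero(design.penalty_factor == 0)
    free_start = len(idx)
    idx.extend(free_cols.tolist())
    n_int = 1 if include_intercept else 0
    return np.array(idx, int), blocks, free_start, n_int


def _fista_group_lasso(Xt, y, family, lam_path, blocks, free_start, n_free_tail,
                       tol=1e-8, max_iter=2000, theta0=None):
    """FISTA with adaptive restart on the overlapped-group objective.
    ``Xt`` already has duplicated columns per group plus an intercept column
    last; blocks index latent ranges that receive the group prox."""
    n, q = Xt.shape
    # Lipschitz bound of the smooth part via power iteration
    v = np.ones(q) / np.sqrt(q)
    for _ in range(50):
        v2 = Xt.T @ (Xt @ v)
        nv = np.linalg.norm(v2)
        if nv == 0:
            break
        v = v2 / nv
    sigma2 = float(v @ (Xt.T @ (Xt @ v)))
    L = sigma2 / n * (0.25 if family == "logistic" else 1.0) + 1e-12

    def smooth(theta):
        eta = Xt @ theta
        if family == "lm":
            r = eta - y
            return 0.5 * float(r @ r) / n, Xt.T @ r / n
        eta = np.clip(eta, -_ETA_CLIP, _ETA_CLIP)
        mu = expit(eta)
        loss = float(np.mean(np.log1p(np.exp(-np.abs(eta))) + np.maximum(eta, 0) - y * eta))
        return loss, Xt.T @ (mu - y) / n

    def penalty(theta, lam):
        return lam * sum(g.weight * np.linalg.norm(theta[a:b])
                         for a, b, g in blocks)

    def prox(theta, step, lam):
        out = theta.copy()
        for a, b, g in blocks:
            nrm = np.linalg.norm(theta[a:b])
            if nrm <= step * lam * g.weight:
                out[a:b] = 0.0
            else:
                out[a:b] = theta[a:b] * (1.0 - step * lam * g.weight / nrm)
        return out

    theta = np.zeros(q) if theta0 is None else theta0.copy()
    results = np.empty((len(lam_path), q))
    for i, lam in enumerate(lam_path):
        z, tk = theta.copy(), 1.0
        f_prev = np.inf
        for it in range(max_iter):
            loss_z, grad_z = smooth(z)
            theta_new = prox(z - grad_z / L, 1.0 / L, lam)
            loss_new, _ = smooth(theta_new)
            obj = loss_new + penalty(theta_new, lam)
            if obj > f_prev + 1e-14:          # adaptive restart
                z, tk = theta.copy(), 1.0
                loss_z, grad_z = smooth(z)
                theta_new = prox(z - grad_z / L, 1.0 / L, lam)
                loss_new, _ = smooth(theta_new)
                obj = loss_new + penalty(theta_new, lam)
            t_next = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * tk * tk))
            z = theta_new + ((tk - 1.0) / t_next) * (theta_new - theta)
            theta, tk = theta_new, t_next
            if abs(f_prev - obj) <= tol * max(1.0, abs(obj)):
                break
            f_prev = obj
        results[i] = theta
    return results


def lambda_max_group(Xt, y, family, blocks, free_start) -> float:
    """All-groups-zero bound: max over penalized groups of the null-fit
    gradient norm divided by the group weight."""
    q = Xt.shape[1]
    theta0 = np.zeros(q)
    free = np.arange(free_start, q)
    if free.size:
        sub = Xt[:, free]
        pf = np.zeros(free.size)
        if family == "lm":
            theta0[free] = enet_path_gaussian(sub, y, np.array([0.0]), 1.0, pf)[0]
        else:
            theta0[free] = enet_path_logistic(sub, y, np.array([0.0]), 1.0, pf)[0]
    if family == "lm":
        g = Xt.T @ (Xt @ theta0 - y) / Xt.shape[0]
    else:
        mu = expit(np.clip(Xt @ theta0, -_ETA_CLIP, _ETA_CLIP))
        g = Xt.T @ (mu - y) / Xt.shape[0]
    return float(max(np.linalg.norm(g[a:b]) / grp.weight for a, b, grp in blocks))


def cv_hier_interaction_lasso(design: DesignSpec, y, family_effective: str = "lm",
                              k: int = 10, seed: int = 0, n_lambda: int = 100,
                              lambda_min_ratio: float = 1e-3,
                              tol: float = 1e-8) -> CvPenalizedFit:
    """Cross-validated hierarchical interaction selection.

    Survival callers must pass the event indicator with
    ``family_effective="logistic"``; the designated-family recalibration
    happens downstream on the held-out calibration group.
    """
    if family_effective not in ("lm", "logistic"):
        raise ValueError("interaction selection supports lm and logistic losses only")
    if design.groups is None:
        raise ValueError("design was built without interaction groups")
    y = np.asarray(y, float)
    idx, blocks, free_start, n_int = _latent_layout(design, include_intercept=True)
    Xt = np.column_stack([design.X[:, idx], np.ones(design.n)])
    free_start_full = free_start  # unpenalized block begins here; intercept last

    lam_max = lambda_max_group(Xt, y, family_effective, blocks, free_start_full)
    path = make_lambda_path(lam_max, n_lambda, lambda_min_ratio)

    strat = y if family_effective == "logistic" else None
    folds = make_folds(design.n, k, seed, strat)
    dev = np.empty((k, len(path)))
    for f in range(k):
        tr, te = folds != f, folds == f
        thetas = _fista_group_lasso(Xt[tr], y[tr], family_effective, path,
                                    blocks, free_start_full, n_int, tol=tol)
        for i in range(len(path)):
            dev[f, i] = _cv_deviance(family_effective, Xt[te], thetas[i], y=y[te])
    cv_mean = dev.mean(axis=0)
    cv_se = dev.std(axis=0, ddof=1) / np.sqrt(k)
    i_min = int(np.argmin(cv_mean))

    thetas = _fista_group_lasso(Xt, y, family_effective, path, blocks,
                                free_start_full, n_int, tol=tol)
    theta = thetas[i_min]
    # collapse latent blocks back onto design columns
    beta_cols = np.zeros(design.X.shape[1])
    np.add.at(beta_cols, idx, theta[:-1])
    intercept = float(theta[-1])
    beta_terms = {t: float(beta_cols[j]) for j, t in enumerate(design.terms)}

    sel_pairs = [g.exposures for a, b, g in blocks
                 if g.kind == "interaction" and np.linalg.norm(theta[a:b]) > 0]
    sel_mains = {g.exposures[0] for a, b, g in blocks
                 if g.kind == "main" and np.linalg.norm(theta[a:b]) > 0}
    for pair in sel_pairs:   # strong hierarchy: parents are mains
        sel_mains.update(pair)
    selected = [e for e in design.coding.exposures if e in sel_mains]
    orig, b0 = _back_transform(design, beta_terms, intercept)
    return CvPenalizedFit(family_effective, 1.0, path, cv_mean, cv_se,
                          float(path[i_min]), beta_terms, intercept, orig, b0,
                          selected, [tuple(p) for p in sel_pairs], k, seed, design)
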
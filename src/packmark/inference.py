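"""Model fitting for the three scent-marking analyses.

* ``fit_rsf`` — used/available resource selection: a Bernoulli likelihood
  with logit link, maximized with case weights (used W=1, available W=100)
  and fixed pack intercepts.  The slope estimates parameterize the
  exponential selection function exp(alpha_j + x.beta) and are interpreted
  as relative selection strength.
* ``fit_rpsf`` — used/unused scent-marking probability along follows:
  ordinary logistic regression with one intercept per pack-follow
  combination (fixed dummies by default; a random-intercept variant is
  available for sensitivity analysis).
* ``fit_logratio`` — Gaussian linear mixed model for the log
  marking:hunting ratio with a random intercept on pack, estimated by
  REML with the profiled likelihood optimized over the variance ratio.

The logistic fits use Newton-Raphson with step halving (likelihood never
decreases across iterations); interaction terms are written "a:b" and
expanded as elementwise products of the named columns.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "FitResult",
    "SeparationError",
    "NonConvergenceWarning",
    "expand_terms",
    "fit_rsf",
    "fit_rpsf",
    "fit_logratio",
]

NEWTON_TOL = 1e-10
NEWTON_MAX_ITER = 100


class SeparationError(RuntimeError):
    """Complete separation: a term perfectly predicts the response."""


class NonConvergenceWarning(UserWarning):
    pass


@dataclass
class FitResult:
    """Fitted-model summary shared by all three families."""

    model: str
    terms: list[str]
    beta: dict[str, float]
    se: dict[str, float]
    intercepts: dict[str, float]
    loglik: float
    k: int
    n: int
    converged: bool
    extra: dict = field(default_factory=dict)

    def coef(self, term: str) -> float:
        return self.beta[term]

    def to_json(self) -> str:
        payload = {
            "model": self.model,
            "terms": self.terms,
            "beta": self.beta,
            "se": self.se,
            "intercepts": {str(k): v for k, v in self.intercepts.items()},
            "loglik": self.loglik,
            "k": self.k,
            "n": self.n,
            "converged": self.converged,
            "extra": {
                k: v for k, v in self.extra.items()
                if isinstance(v, (int, float, str, bool, list, dict))
            },
        }
        return json.dumps(payload, indent=1, sort_keys=True)


def expand_terms(df: pd.DataFrame, terms) -> np.ndarray:
    """Design columns for main effects and ':'-separated interactions."""
    cols = []
    for term in terms:
        parts = term.split(":")
        col = np.ones(len(df))
        for p in parts:
            if p not in df.columns:
                raise KeyError(f"term component {p!r} not in design columns")
            col = col * df[p].to_numpy(dtype=float)
        cols.append(col)
    if not cols:
        return np.empty((len(df), 0))
    return np.column_stack(cols)


def _group_dummies(groups: pd.Series) -> tuple[np.ndarray, list]:
    codes, uniques = pd.factorize(groups, sort=True)
    D = np.zeros((len(groups), len(uniques)))
    D[np.arange(len(groups)), codes] = 1.0
    return D, list(uniques)


def _newton_logistic(
    X: np.ndarray,
    y: np.ndarray,
    w: np.ndarray,
    names: list[str],
) -> dict:
    """Weighted Bernoulli log-likelihood maximized by Newton-Raphson.

    Step halving guarantees the log-likelihood is non-decreasing; the
    trace of per-iteration log-likelihoods is returned for diagnostics.
    """

    def loglik(beta):
        eta = X @ beta
        # log-likelihood in a numerically safe form
        return float(np.sum(w * (y * eta - np.logaddexp(0.0, eta))))

    beta = np.zeros(X.shape[1])
    ll = loglik(beta)
    trace = [ll]
    converged = False
    for _ in range(NEWTON_MAX_ITER):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        grad = X.T @ (w * (y - p))
        wvar = w * p * (1.0 - p)
        H = (X * wvar[:, None]).T @ X
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        # step halving: never accept a likelihood decrease
        scale = 1.0
        for _half in range(30):
            cand = beta + scale * step
            ll_new = loglik(cand)
            if ll_new >= ll - 1e-13:
                break
            scale /= 2.0
        beta = beta + scale * step
        delta = ll_new - ll
        ll = ll_new
        trace.append(ll)
        if abs(delta) < NEWTON_TOL:
            converged = True
            break

    eta = X @ beta
    p = 1.0 / (1.0 + np.exp(-eta))
    # separation: the classes are perfectly split and the likelihood has no
    # interior maximum (all fitted probabilities pinned at 0/1)
    if np.max(np.abs(beta)) > 10.0:
        sep = p[y == 1].min() > 1 - 1e-5 and p[y == 0].max() < 1e-5
        if sep:
            worst = names[int(np.argmax(np.abs(beta)))]
            raise SeparationError(
                f"complete separation detected on term {worst!r}"
            )
    wvar = w * p * (1.0 - p)
    H = (X * wvar[:, None]).T @ X
    cov = np.linalg.pinv(H)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    if not converged:
        warnings.warn(
            "Newton-Raphson did not converge within "
            f"{NEWTON_MAX_ITER} iterations", NonConvergenceWarning,
            stacklevel=3,
        )
    return {
        "beta": beta, "se": se, "loglik": ll, "converged": converged,
        "fitted": p, "trace": trace, "cov": cov,
    }


def fit_rsf(
    design: pd.DataFrame,
    terms,
    weight_col: str = "weight",
    group_col: str = "pack_id",
) -> FitResult:
    """Weighted used/available resource selection function.

    ``design`` needs a binary ``response`` (1 used, 0 available), a case
    weight column, a pack column for the fixed pack intercepts, and the
    covariate columns named by ``terms``.
    """
    terms = list(terms)
    y = design["response"].to_numpy(dtype=float)
    if not (y.min() == 0 and y.max() == 1):
        raise ValueError("design must contain both used and available rows")
    w = (
        design[weight_col].to_numpy(dtype=float)
        if weight_col in design.columns
        else np.ones(len(design))
    )
    D, groups = _group_dummies(design[group_col])
    Xt = expand_terms(design, terms)
    X = np.hstack([D, Xt])
    names = [f"alpha[{g}]" for g in groups] + terms
    res = _newton_logistic(X, y, w, names)
    nb = len(groups)
    return FitResult(
        model="rsf",
        terms=terms,
        beta=dict(zip(terms, res["beta"][nb:].tolist())),
        se=dict(zip(terms, res["se"][nb:].tolist())),
        intercepts=dict(zip(groups, res["beta"][:nb].tolist())),
        loglik=res["loglik"],
        k=X.shape[1],
        n=len(design),
        converged=res["converged"],
        extra={"loglik_trace": res["trace"], "fitted": res["fitted"]},
    )


def _fit_logistic_random_intercept(design, terms, group_key, n_quad=31):
    """Logistic regression with a Gaussian random intercept per group.

    Marginal likelihood integrated by Gauss-Hermite quadrature and
    maximized over (intercept, beta, log sd) with BFGS.  Sensitivity
    variant for the nested-intercept model; slower and approximate
    relative to the fixed-dummy default.
    """
    y = design["response"].to_numpy(dtype=float)
    Xt = expand_terms(design, terms)
    X = np.hstack([np.ones((len(design), 1)), Xt])
    codes, groups = pd.factorize(design[group_key], sort=True)
    nodes, wts = np.polynomial.hermite_e.hermegauss(n_quad)  # N(0,1) weights
    wts = wts / np.sqrt(2.0 * np.pi)

    def nll(theta):
        beta, log_sd = theta[:-1], theta[-1]
        sd = np.exp(log_sd)
        eta = X @ beta
        # (rows, quad): conditional log-lik at each quadrature offset
        cond = (
            y[:, None] * (eta[:, None] + sd * nodes[None, :])
            - np.logaddexp(0.0, eta[:, None] + sd * nodes[None, :])
        )
        total = 0.0
        for j in range(len(groups)):
            m = codes == j
            lg = cond[m].sum(axis=0)  # per-node group log-lik
            mx = lg.max()
            total += mx + np.log(np.sum(wts * np.exp(lg - mx)))
        return -total

    theta0 = np.zeros(X.shape[1] + 1)
    opt = optimize.minimize(nll, theta0, method="BFGS")
    beta = opt.x[:-1]
    sd = float(np.exp(opt.x[-1]))
    # SEs from the inverse numerical Hessian BFGS approximation
    se = np.sqrt(np.clip(np.diag(opt.hess_inv), 0.0, np.inf))[:-1]
    names = ["(intercept)"] + list(terms)
    return FitResult(
        model="rpsf_random",
        terms=list(terms),
        beta=dict(zip(names, beta.tolist())),
        se=dict(zip(names, se.tolist())),
        intercepts={},
        loglik=-float(opt.fun),
        k=X.shape[1] + 1,
        n=len(design),
        converged=bool(opt.success),
        extra={"random_intercept_sd": sd},
    )


def fit_rpsf(
    design: pd.DataFrame,
    terms,
    pack_col: str = "pack_id",
    follow_col: str = "follow_id",
    intercepts: str = "fixed",
) -> FitResult:
    """Used/unused scent-marking probability model along follows.

    One intercept per pack-follow combination absorbs within-follow
    autocorrelation and per-follow observation effort.  Follows whose
    response is single-class are dropped with a warning (their intercept
    is not identifiable).  Fitted per-row probabilities are returned in
    ``extra["fitted"]``.
    """
    terms = list(terms)
    design = design.copy()
    key = list(zip(design[pack_col], design[follow_col]))
    design["_pf"] = pd.Series(key, index=design.index).astype(str)
    keep_groups = []
    for g, grp in design.groupby("_pf", sort=True):
        if grp["response"].nunique() == 2:
            keep_groups.append(g)
        else:
            warnings.warn(
                f"pack-follow {g} has a single-class response; dropped",
                stacklevel=2,
            )
    design = design[design["_pf"].isin(keep_groups)].reset_index(drop=True)
    if len(design) == 0:
        raise ValueError("no pack-follow with both used and unused rows")
    if intercepts == "random":
        return _fit_logistic_random_intercept(design, terms, "_pf")
    if intercepts != "fixed":
        raise ValueError("intercepts must be 'fixed' or 'random'")
    y = design["response"].to_numpy(dtype=float)
    D, groups = _group_dummies(design["_pf"])
    Xt = expand_terms(design, terms)
    X = np.hstack([D, Xt])
    names = [f"alpha[{g}]" for g in groups] + terms
    res = _newton_logistic(X, y, np.ones(len(design)), names)
    nb = len(groups)
    return FitResult(
        model="rpsf",
        terms=terms,
        beta=dict(zip(terms, res["beta"][nb:].tolist())),
        se=dict(zip(terms, res["se"][nb:].tolist())),
        intercepts=dict(zip(groups, res["beta"][:nb].tolist())),
        loglik=res["loglik"],
        k=X.shape[1],
        n=len(design),
        converged=res["converged"],
        extra={
            "fitted": res["fitted"],
            "response": y,
            "loglik_trace": res["trace"],
        },
    )


def _reml_pieces(y, X, groups_codes, n_groups, lam):
    """Per-group GLS quantities for V_j = I + lam * 11' (random intercept).

    Uses the closed-form inverse V^-1 = I - (lam / (1 + lam n_j)) 11'.
    """
    p = X.shape[1]
    XtVX = np.zeros((p, p))
    XtVy = np.zeros(p)
    logdetV = 0.0
    for j in range(n_groups):
        m = groups_codes == j
        Xj, yj = X[m], y[m]
        nj = int(m.sum())
        c = lam / (1.0 + lam * nj)
        sx = Xj.sum(axis=0)
        sy = yj.sum()
        XtVX += Xj.T @ Xj - c * np.outer(sx, sx)
        XtVy += Xj.T @ yj - c * sx * sy
        logdetV += np.log1p(lam * nj)
    return XtVX, XtVy, logdetV


def _reml_criterion(lam, y, X, codes, n_groups):
    n, p = X.shape
    XtVX, XtVy, logdetV = _reml_pieces(y, X, codes, n_groups, lam)
    beta = np.linalg.solve(XtVX, XtVy)
    # r' V^-1 r = y'V^-1 y - 2 beta' X'V^-1 y + beta' X'V^-1 X beta
    yVy = 0.0
    for j in range(n_groups):
        m = codes == j
        yj = y[m]
        nj = int(m.sum())
        c = lam / (1.0 + lam * nj)
        yVy += yj @ yj - c * yj.sum() ** 2
    quad = yVy - 2 * beta @ XtVy + beta @ XtVX @ beta
    # floor the residual variance so a perfect (noiseless) fit yields a
    # finite, strongly favorable likelihood instead of log(0)
    sigma2 = max(quad / (n - p), 1e-30)
    sign, logdetXVX = np.linalg.slogdet(XtVX)
    ll = -0.5 * (
        (n - p) * np.log(2 * np.pi * sigma2) + logdetV + logdetXVX + (n - p)
    )
    return ll, beta, sigma2, XtVX


def fit_logratio(
    af: pd.DataFrame,
    terms,
    response_col: str = "log_ratio",
    group_col: str = "pack_id",
) -> FitResult:
    """Gaussian LMM for the log marking:hunting ratio, random pack intercept.

    REML: the likelihood is profiled over beta and the residual variance,
    then maximized over the variance ratio lambda = tau^2/sigma^2 by 1-D
    bounded optimization on log(lambda), with the boundary lambda = 0
    (ordinary least squares) checked explicitly.  A boundary estimate is
    returned with ``extra["zero_variance"] = True``.
    """
    terms = list(terms)
    codes, groups = pd.factorize(af[group_col], sort=True)
    n_groups = len(groups)
    if n_groups < 2:
        raise ValueError("need >= 2 packs to estimate a between-pack variance")
    y = af[response_col].to_numpy(dtype=float)
    Xt = expand_terms(af, terms)
    X = np.hstack([np.ones((len(af), 1)), Xt])
    names = ["(intercept)"] + terms

    def neg(loglam):
        return -_reml_criterion(np.exp(loglam), y, X, codes, n_groups)[0]

    opt = optimize.minimize_scalar(neg, bounds=(-12.0, 12.0), method="bounded")
    lam = float(np.exp(opt.x))
    ll_lam = -float(opt.fun)
    ll_zero = _reml_criterion(0.0, y, X, codes, n_groups)[0]
    zero_variance = ll_zero >= ll_lam - 1e-9
    if zero_variance:
        lam = 0.0
    ll, beta, sigma2, XtVX = _reml_criterion(lam, y, X, codes, n_groups)
    cov = sigma2 * np.linalg.inv(XtVX)
    se = np.sqrt(np.diag(cov))
    tau2 = lam * sigma2

    # BLUPs of the pack intercept deviations
    resid = y - X @ beta
    blups = {}
    for j, g in enumerate(groups):
        m = codes == j
        nj = int(m.sum())
        shrink = (lam * nj) / (1.0 + lam * nj) if lam > 0 else 0.0
        blups[g] = float(shrink * resid[m].mean())

    return FitResult(
        model="logratio_lmm",
        terms=terms,
        beta=dict(zip(names, beta.tolist())),
        se=dict(zip(names, se.tolist())),
        intercepts=blups,
        loglik=float(ll),
        k=X.shape[1] + 2,  # fixed effects + two variance components
        n=len(af),
        converged=bool(opt.success or zero_variance),
        extra={
            "sigma2": float(sigma2),
            "tau2": float(tau2),
            "variance_ratio": float(lam),
            "zero_variance": bool(zero_variance),
            "fitted_fixed": (X @ beta),
        },
    )
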
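"""Latent-class logit with covariate-driven class membership.

The observed-data likelihood for respondent ``n`` with covariates ``z`` is

    sum_c pi_c(z; theta) * prod_t P(y_nt | x_nt; beta_c)

maximized by EM (E-step: posterior responsibilities; M-step: one weighted
logit per class plus a multinomial logit of responsibilities on covariates)
followed by a quasi-Newton polish of the full likelihood.  The best of
several random starts is returned, with classes relabelled by descending
share so repeated fits are reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import logsumexp

from .covariates import code_covariates
from .errors import ConvergenceError, DataError, EstimationError
from .estimation import CodedData, LogitFit, fit_logit
from .relative_importance import attribute_ranges, relative_importance

__all__ = [
    "LatentClassFit",
    "fit_latent_class",
    "select_classes",
    "membership_effects",
    "class_ri_profiles",
]


@dataclass
class LatentClassFit:
    n_classes: int
    class_betas: np.ndarray  # C x K
    membership_theta: np.ndarray  # (C-1) x P, reference class = last
    theta_vcov: np.ndarray | None  # (C-1)P x (C-1)P, or None if unavailable
    shares: np.ndarray  # average posterior class probabilities
    posterior: np.ndarray  # N x C
    respondent_ids: np.ndarray
    loglik: float
    aic: float
    bic: float
    n_params: int
    n_starts_used: int
    best_start_seed: int
    columns: list[str]
    covariate_names: list[str]
    class_labels: list[str]
    loglik_history: list[float]
    converged: bool

    def beta_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.class_betas.T, index=self.columns, columns=self.class_labels
        )


def _respondent_index(cluster_ids: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ids = pd.unique(cluster_ids)
    lookup = {v: i for i, v in enumerate(ids)}
    idx = np.fromiter((lookup[v] for v in cluster_ids), dtype=np.int64)
    return ids, idx


def _class_loglik(
    X: np.ndarray, y: np.ndarray, idx: np.ndarray, n_resp: int, betas: np.ndarray
) -> np.ndarray:
    """Respondent x class log-likelihood matrix."""
    eta = X @ betas.T  # rows x C
    row_ll = y[:, None] * eta - np.logaddexp(0.0, eta)
    L = np.zeros((n_resp, betas.shape[0]))
    np.add.at(L, idx, row_ll)
    return L


def _log_pi(Z: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Respondent x class log membership probabilities (reference = last)."""
    util = Z @ theta.T if theta.size else np.zeros((Z.shape[0], 0))
    util = np.column_stack([util, np.zeros(Z.shape[0])])
    return util - logsumexp(util, axis=1, keepdims=True)


def _fit_theta(
    Z: np.ndarray, W: np.ndarray, theta0: np.ndarray
) -> np.ndarray:
    """Weighted multinomial logit of responsibilities on covariates."""
    n, P = Z.shape
    C = W.shape[1]
    if C < 2:
        return np.zeros((0, P))

    def negll(flat: np.ndarray) -> tuple[float, np.ndarray]:
        theta = flat.reshape(C - 1, P)
        logpi = _log_pi(Z, theta)
        val = -float(np.sum(W * logpi))
        pi = np.exp(logpi)
        grad = -(Z.T @ (W[:, : C - 1] - pi[:, : C - 1])).T.ravel()
        return val, grad

    res = optimize.minimize(
        negll, theta0.ravel(), jac=True, method="L-BFGS-B",
        options={"maxiter": 200, "ftol": 1e-12},
    )
    return res.x.reshape(C - 1, P)


def _mixture_loglik_grad(
    params: np.ndarray,
    X: np.ndarray,
    y: np.ndarray,
    idx: np.ndarray,
    Z: np.ndarray,
    C: int,
) -> tuple[float, np.ndarray]:
    """Observed-data log-likelihood and gradient (for the polish step)."""
    n_resp, P = Z.shape
    K = X.shape[1]
    betas = params[: C * K].reshape(C, K)
    theta = params[C * K :].reshape(C - 1, P) if C > 1 else np.zeros((0, P))
    L = _class_loglik(X, y, idx, n_resp, betas)
    logpi = _log_pi(Z, theta)
    joint = logpi + L
    lse = logsumexp(joint, axis=1)
    ll = float(np.sum(lse))
    W = np.exp(joint - lse[:, None])  # posteriors, rows sum to 1
    eta = X @ betas.T
    p = 1.0 / (1.0 + np.exp(-eta))
    w_rows = W[idx]  # rows x C
    gbeta = (X.T @ (w_rows * (y[:, None] - p))).T.ravel()  # C*K
    if C > 1:
        pi = np.exp(logpi)
        gtheta = (Z.T @ (W[:, : C - 1] - pi[:, : C - 1])).T.ravel()
        grad = np.concatenate([gbeta, gtheta])
    else:
        grad = gbeta
    return ll, grad


def fit_latent_class(
    coded: CodedData,
    covariates: pd.DataFrame | None,
    n_classes: int,
    n_starts: int = 20,
    tol: float = 1e-6,
    max_iter: int = 300,
    seed: int = 0,
    covariate_terms: Sequence[str] | None = None,
    degeneracy_floor: float = 0.01,
    polish: bool = True,
) -> LatentClassFit:
    """EM with random restarts for the latent-class logit.

    ``covariates`` must carry one row per respondent (matched on
    ``respondent_id``); pass ``covariate_terms=["intercept"]`` for a
    shares-only membership model.  Starts whose smallest class collapses below
    ``degeneracy_floor`` of respondents are discarded.
    """
    C = int(n_classes)
    if C < 1:
        raise DataError("n_classes must be >= 1")
    X, y = coded.X, coded.y
    K = X.shape[1]
    resp_ids, idx = _respondent_index(coded.cluster_ids)
    n_resp = resp_ids.size

    if C == 1:
        base = fit_logit(coded, cluster_robust=False)
        n_params = K
        return LatentClassFit(
            n_classes=1,
            class_betas=base.beta[None, :],
            membership_theta=np.zeros((0, 0)),
            theta_vcov=None,
            shares=np.array([1.0]),
            posterior=np.ones((n_resp, 1)),
            respondent_ids=resp_ids,
            loglik=base.loglik,
            aic=-2 * base.loglik + 2 * n_params,
            bic=-2 * base.loglik + n_params * math.log(coded.y.size),
            n_params=n_params,
            n_starts_used=1,
            best_start_seed=seed,
            columns=list(coded.columns),
            covariate_names=[],
            class_labels=["class_1"],
            loglik_history=[base.loglik],
            converged=base.converged,
        )

    if covariates is None:
        raise DataError("covariates are required when n_classes >= 2")
    cov = covariates.set_index("respondent_id").loc[resp_ids].reset_index()
    terms = list(covariate_terms) if covariate_terms else None
    if terms is None:
        from .covariates import MEMBERSHIP_TERMS

        terms = list(MEMBERSHIP_TERMS)
    Z, term_names = code_covariates(cov, terms=terms)
    P = Z.shape[1]

    best: dict | None = None
    n_used = 0
    for s in range(n_starts):
        start_seed = seed + s
        rng = np.random.default_rng(start_seed)
        try:
            result = _em_once(
                X, y, idx, n_resp, Z, C, rng, tol, max_iter, degeneracy_floor
            )
        except _DegenerateStart:
            continue
        n_used += 1
        if best is None or result["loglik"] > best["loglik"]:
            result["seed"] = start_seed
            best = result
    if best is None:
        raise EstimationError(
            f"all {n_starts} starts degenerated below the "
            f"{degeneracy_floor:.0%} class-mass floor"
        )

    betas, theta = best["betas"], best["theta"]
    history = best["history"]
    ll = best["loglik"]
    if polish:
        params0 = np.concatenate([betas.ravel(), theta.ravel()])

        def neg(params):
            val, grad = _mixture_loglik_grad(params, X, y, idx, Z, C)
            return -val, -grad

        res = optimize.minimize(
            neg, params0, jac=True, method="L-BFGS-B",
            options={"maxiter": 500, "ftol": 1e-12},
        )
        if -res.fun >= ll - 1e-9:
            betas = res.x[: C * K].reshape(C, K)
            theta = res.x[C * K :].reshape(C - 1, P)
            ll = float(-res.fun)
            history = history + [ll]

    # posterior, shares, relabelling by descending share
    L = _class_loglik(X, y, idx, n_resp, betas)
    logpi = _log_pi(Z, theta)
    joint = logpi + L
    W = np.exp(joint - logsumexp(joint, axis=1, keepdims=True))
    shares = W.mean(axis=0)
    order = sorted(
        range(C), key=lambda c: (-shares[c], betas[c, 0] if K else 0.0)
    )
    betas = betas[order]
    W = W[:, order]
    shares = shares[order]
    theta_full = np.vstack([theta, np.zeros((1, P))])[order]
    theta_new = theta_full[:-1] - theta_full[-1]  # re-reference to new last class

    theta_vcov = _theta_vcov(
        np.concatenate([betas.ravel(), theta_new.ravel()]), X, y, idx, Z, C, K, P
    )

    n_params = C * K + (C - 1) * P
    return LatentClassFit(
        n_classes=C,
        class_betas=betas,
        membership_theta=theta_new,
        theta_vcov=theta_vcov,
        shares=shares,
        posterior=W,
        respondent_ids=resp_ids,
        loglik=ll,
        aic=-2 * ll + 2 * n_params,
        bic=-2 * ll + n_params * math.log(coded.y.size),
        n_params=n_params,
        n_starts_used=n_used,
        best_start_seed=best["seed"],
        columns=list(coded.columns),
        covariate_names=term_names,
        class_labels=[f"class_{c + 1}" for c in range(C)],
        loglik_history=history,
        converged=True,
    )


class _DegenerateStart(Exception):
    pass


def _em_once(
    X: np.ndarray,
    y: np.ndarray,
    idx: np.ndarray,
    n_resp: int,
    Z: np.ndarray,
    C: int,
    rng: np.random.Generator,
    tol: float,
    max_iter: int,
    degeneracy_floor: float,
) -> dict:
    K = X.shape[1]
    P = Z.shape[1]
    W = rng.dirichlet(np.ones(C), size=n_resp)
    betas = np.zeros((C, K))
    theta = np.zeros((C - 1, P))
    history: list[float] = []
    prev = -np.inf
    for _ in range(max_iter):
        # M-step
        for c in range(C):
            coded_c = CodedData(
                y=y, X=X, cluster_ids=idx, columns=[str(j) for j in range(K)],
                model="admit",
            )
            try:
                fit = fit_logit(
                    coded_c,
                    tol=1e-6,
                    max_iter=60,
                    weights=W[idx, c] + 1e-10,
                    beta0=betas[c],
                    check_rank=False,
                )
                betas[c] = fit.beta
            except (ConvergenceError, EstimationError):
                pass  # keep previous iterate; full-likelihood polish follows
        theta = _fit_theta(Z, W, theta)
        # E-step
        L = _class_loglik(X, y, idx, n_resp, betas)
        logpi = _log_pi(Z, theta)
        joint = logpi + L
        lse = logsumexp(joint, axis=1)
        ll = float(np.sum(lse))
        W = np.exp(joint - lse[:, None])
        if W.sum(axis=0).min() < degeneracy_floor * n_resp:
            raise _DegenerateStart
        if history and ll < prev - 1e-6 * (1.0 + abs(prev)):
            raise EstimationError("EM decreased the observed-data log-likelihood")
        history.append(ll)
        if abs(ll - prev) < tol * (1.0 + abs(ll)):
            break
        prev = ll
    return {"betas": betas, "theta": theta, "loglik": history[-1], "history": history}


def _theta_vcov(
    params: np.ndarray,
    X: np.ndarray,
    y: np.ndarray,
    idx: np.ndarray,
    Z: np.ndarray,
    C: int,
    K: int,
    P: int,
) -> np.ndarray | None:
    """Theta block of the inverse observed-information (finite-diff Hessian)."""
    n = params.size

    def grad(p: np.ndarray) -> np.ndarray:
        return _mixture_loglik_grad(p, X, y, idx, Z, C)[1]

    H = np.empty((n, n))
    eps = 1e-5
    for j in range(n):
        dp = np.zeros(n)
        dp[j] = eps
        H[:, j] = (grad(params + dp) - grad(params - dp)) / (2 * eps)
    H = 0.5 * (H + H.T)
    try:
        cov = np.linalg.inv(-H)
    except np.linalg.LinAlgError:
        return None
    block = cov[C * K :, C * K :]
    if not np.all(np.isfinite(block)):
        return None
    return block


def select_classes(
    coded: CodedData,
    covariates: pd.DataFrame | None,
    class_range: Sequence[int],
    n_starts: int = 10,
    seed: int = 0,
    **kwargs,
) -> pd.DataFrame:
    """Fit a range of class counts and tabulate information criteria."""
    if not list(class_range):
        raise DataError("class_range is empty")
    rows = []
    for C in class_range:
        try:
            fit = fit_latent_class(
                coded, covariates, C, n_starts=n_starts, seed=seed, **kwargs
            )
            rows.append(
                {
                    "n_classes": C,
                    "loglik": fit.loglik,
                    "n_params": fit.n_params,
                    "aic": fit.aic,
                    "bic": fit.bic,
                    "converged": fit.converged,
                }
            )
        except (EstimationError, ConvergenceError):
            rows.append(
                {
                    "n_classes": C,
                    "loglik": np.nan,
                    "n_params": np.nan,
                    "aic": np.nan,
                    "bic": np.nan,
                    "converged": False,
                }
            )
    table = pd.DataFrame(rows)
    ok = table["converged"] & table["bic"].notna()
    table["best_bic"] = False
    if ok.any():
        table.loc[table.loc[ok, "bic"].idxmin(), "best_bic"] = True
    return table


def membership_effects(fit: LatentClassFit) -> pd.DataFrame:
    """Theta coefficients with SEs from the polished full-likelihood Hessian."""
    if fit.n_classes < 2:
        raise DataError("membership effects need at least two classes")
    P = len(fit.covariate_names)
    ref = fit.class_labels[-1]
    rows = []
    for ci in range(fit.n_classes - 1):
        for pj, name in enumerate(fit.covariate_names):
            j = ci * P + pj
            coef = float(fit.membership_theta[ci, pj])
            if fit.theta_vcov is not None and fit.theta_vcov[j, j] > 0:
                se = math.sqrt(float(fit.theta_vcov[j, j]))
                z = coef / se
                p = float(2 * stats.norm.sf(abs(z)))
            else:
                se, z, p = np.nan, np.nan, np.nan
            rows.append(
                {
                    "covariate": name,
                    "class": f"{fit.class_labels[ci]} vs {ref}",
                    "coef": coef,
                    "se": se,
                    "z": z,
                    "p": p,
                    "significant_5pct": bool(p < 0.05) if np.isfinite(p) else False,
                }
            )
    return pd.DataFrame(rows)


def class_ri_profiles(fit: LatentClassFit) -> dict[str, pd.DataFrame]:
    """Relative-importance table for each class's coefficient vector."""
    out = {}
    for c, label in enumerate(fit.class_labels):
        ranges = attribute_ranges(fit.class_betas[c], fit.columns)
        out[label] = relative_importance(ranges)
    return out
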
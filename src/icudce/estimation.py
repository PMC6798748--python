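"""Logit estimation for the choice data.

Two codings are supported: the admit model (one row per respondent x task x
alternative, intercept plus level dummies, binary admit outcome) and the
priority model (one row per respondent x task, difference coding of the two
profiles, no intercept, outcome = profile A prioritized).  Fitting is plain
Newton-Raphson with step-halving; uncertainty is a sandwich estimator
clustered on respondent.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import AttributeSpec, column_names
from .design import PatientProfile, profile_vector
from .errors import ConvergenceError, DataError, EstimationError, SeparationError

__all__ = [
    "CodedData",
    "LogitFit",
    "code_dataset",
    "decode_rows",
    "fit_logit",
    "level_contrasts",
    "odds_ratios",
    "predict_admission",
    "fit_to_json",
    "fit_from_json",
]

DEFAULT_TASK_TYPES = ("standard",)


@dataclass
class CodedData:
    """Design matrix + outcome + respondent cluster ids for one model."""

    y: np.ndarray
    X: np.ndarray
    cluster_ids: np.ndarray
    columns: list[str]
    model: str  # "admit" or "priority"

    def __post_init__(self) -> None:
        if self.X.shape[1] != len(self.columns):
            raise DataError("column metadata does not match design matrix width")
        if self.X.shape[0] != self.y.size or self.y.size != self.cluster_ids.size:
            raise DataError("row count mismatch between y, X and cluster ids")


def _row_vector(
    row: pd.Series, attributes: Sequence[AttributeSpec], row_label: object
) -> np.ndarray:
    out = []
    for a in attributes:
        if a.name not in row.index:
            raise DataError(f"row {row_label}: missing attribute column {a.name!r}")
        lev = str(row[a.name])
        if lev not in a.levels:
            raise DataError(
                f"row {row_label}: unknown level {lev!r} for attribute {a.name!r}"
            )
        out.extend(1.0 if lev == l else 0.0 for l in a.non_reference_levels())
    return np.asarray(out)


def code_dataset(
    responses: pd.DataFrame,
    attributes: Sequence[AttributeSpec],
    model: str = "admit",
    task_types: Sequence[str] = DEFAULT_TASK_TYPES,
) -> CodedData:
    """Dummy-code a long-format response table.

    Warm-up and quality-check tasks are excluded by default; pass
    ``task_types`` to change which task types enter the likelihood.
    """
    if model not in ("admit", "priority"):
        raise DataError(f"unknown model {model!r}")
    rows = responses[responses["task_type"].isin(task_types)]
    if rows.empty:
        raise DataError("no rows left after task-type filtering")
    if model == "admit":
        X = np.vstack(
            [
                np.concatenate(([1.0], _row_vector(row, attributes, idx)))
                for idx, row in rows.iterrows()
            ]
        )
        return CodedData(
            y=rows["admit"].to_numpy(dtype=float),
            X=X,
            cluster_ids=rows["respondent_id"].to_numpy(),
            columns=column_names(attributes, intercept=True),
            model="admit",
        )
    # priority: one row per respondent x task, difference coding A - B
    recs, ys, clusters = [], [], []
    for (rid, tid), grp in rows.groupby(["respondent_id", "task_id"], sort=True):
        grp = grp.set_index("alternative")
        if not {"A", "B"} <= set(grp.index):
            raise DataError(f"respondent {rid} task {tid}: missing an alternative row")
        xa = _row_vector(grp.loc["A"], attributes, (rid, tid, "A"))
        xb = _row_vector(grp.loc["B"], attributes, (rid, tid, "B"))
        recs.append(xa - xb)
        ys.append(float(grp.loc["A", "priority_chosen"]))
        clusters.append(rid)
    return CodedData(
        y=np.asarray(ys),
        X=np.vstack(recs),
        cluster_ids=np.asarray(clusters),
        columns=column_names(attributes, intercept=False),
        model="priority",
    )


def decode_rows(
    X: np.ndarray, columns: Sequence[str], attributes: Sequence[AttributeSpec]
) -> pd.DataFrame:
    """Invert admit-model dummy coding back to level labels (round-trip check)."""
    col_index = {c: j for j, c in enumerate(columns)}
    out = []
    for i in range(X.shape[0]):
        row = {}
        for a in attributes:
            level = a.reference
            for l in a.non_reference_levels():
                if X[i, col_index[f"{a.name}:{l}"]] == 1.0:
                    level = l
            row[a.name] = level
        out.append(row)
    return pd.DataFrame(out)


@dataclass
class LogitFit:
    beta: np.ndarray
    vcov: np.ndarray
    loglik: float
    n_obs: int
    n_clusters: int
    converged: bool
    iterations: int
    columns: list[str]
    model: str
    loglik_null: float | None = None
    attributes: list[AttributeSpec] | None = None

    def coef(self, column: str) -> float:
        return float(self.beta[self.columns.index(column)])

    def se(self, column: str) -> float:
        j = self.columns.index(column)
        return float(math.sqrt(self.vcov[j, j]))

    def coef_table(self) -> pd.DataFrame:
        se = np.sqrt(np.diag(self.vcov))
        z = np.where(se > 0, self.beta / np.where(se > 0, se, 1.0), np.nan)
        return pd.DataFrame(
            {
                "column": self.columns,
                "coef": self.beta,
                "se": se,
                "z": z,
                "p": 2 * stats.norm.sf(np.abs(z)),
            }
        )


def _loglik(y: np.ndarray, eta: np.ndarray) -> float:
    # numerically stable Bernoulli-logit log-likelihood
    return float(-np.sum(np.logaddexp(0.0, eta)) + np.sum(y * eta))


def fit_logit(
    coded: CodedData,
    tol: float = 1e-8,
    max_iter: int = 100,
    weights: np.ndarray | None = None,
    cluster_robust: bool = True,
    beta0: np.ndarray | None = None,
    compute_null: bool = False,
    check_rank: bool = True,
) -> LogitFit:
    """Maximize the Bernoulli-logit log-likelihood by Newton with step-halving.

    Convergence means gradient max-norm <= ``tol``.  The covariance is a
    respondent-clustered sandwich (model-based when ``cluster_robust`` is
    False or row weights are supplied, as in mixture M-steps).
    """
    y, X = coded.y, coded.X
    n, k = X.shape
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    if w.size != n:
        raise DataError("weights length mismatch")
    if check_rank and np.linalg.matrix_rank(X) < k:
        # identify a collinear column for the error message
        _, r = np.linalg.qr(X)
        bad = [coded.columns[j] for j in range(k) if abs(r[j, j]) < 1e-10]
        raise EstimationError(f"design matrix rank-deficient; suspect columns {bad}")
    beta = np.zeros(k) if beta0 is None else np.asarray(beta0, dtype=float).copy()
    eta = X @ beta
    ll = _weighted_ll(y, eta, w)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        p = 1.0 / (1.0 + np.exp(-eta))
        grad = X.T @ (w * (y - p))
        if np.max(np.abs(grad)) <= tol:
            converged = True
            break
        if np.max(np.abs(beta)) > 30.0:
            j = int(np.argmax(np.abs(beta)))
            raise SeparationError(coded.columns[j])
        W = w * p * (1.0 - p)
        H = X.T @ (X * W[:, None])
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError as exc:
            raise EstimationError("singular Hessian during Newton step") from exc
        # step-halving line search
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            eta_c = X @ cand
            ll_c = _weighted_ll(y, eta_c, w)
            if ll_c >= ll - 1e-12:
                beta, eta, ll = cand, eta_c, ll_c
                break
            scale *= 0.5
        else:
            raise ConvergenceError("step-halving failed to improve", last_beta=beta)
    else:
        p = 1.0 / (1.0 + np.exp(-eta))
        grad = X.T @ (w * (y - p))
        if np.max(np.abs(grad)) <= tol:
            converged = True
        else:
            raise ConvergenceError(
                f"no convergence in {max_iter} Newton iterations", last_beta=beta
            )

    p = 1.0 / (1.0 + np.exp(-eta))
    W = w * p * (1.0 - p)
    H = X.T @ (X * W[:, None])
    bread = np.linalg.inv(H)
    clusters = pd.unique(coded.cluster_ids)
    if cluster_robust and weights is None:
        score_rows = X * (w * (y - p))[:, None]
        frame = pd.DataFrame(score_rows)
        frame["_g"] = coded.cluster_ids
        S = frame.groupby("_g").sum().to_numpy()
        meat = S.T @ S
        g = len(clusters)
        factor = g / (g - 1) if g > 1 else 1.0
        vcov = factor * bread @ meat @ bread
    else:
        vcov = bread
    vcov = 0.5 * (vcov + vcov.T)
    fit = LogitFit(
        beta=beta,
        vcov=vcov,
        loglik=ll,
        n_obs=n,
        n_clusters=len(clusters),
        converged=converged,
        iterations=it,
        columns=list(coded.columns),
        model=coded.model,
    )
    if compute_null and "intercept" in coded.columns:
        null_coded = CodedData(
            y=y,
            X=np.ones((n, 1)),
            cluster_ids=coded.cluster_ids,
            columns=["intercept"],
            model=coded.model,
        )
        fit.loglik_null = fit_logit(
            null_coded, tol=tol, max_iter=max_iter, cluster_robust=False
        ).loglik
    return fit


def _weighted_ll(y: np.ndarray, eta: np.ndarray, w: np.ndarray) -> float:
    return float(np.sum(w * (y * eta - np.logaddexp(0.0, eta))))


def level_contrasts(fit: LogitFit) -> dict[str, np.ndarray]:
    """One unit contrast per non-intercept column (level vs its reference)."""
    out = {}
    for j, col in enumerate(fit.columns):
        if col == "intercept":
            continue
        c = np.zeros(len(fit.columns))
        c[j] = 1.0
        out[col] = c
    return out


def odds_ratios(
    fit: LogitFit, contrasts: Mapping[str, np.ndarray] | None = None
) -> pd.DataFrame:
    """Odds ratios ``exp(c'beta)`` with Wald 95% CIs for each contrast.

    ORs below one also carry the reciprocal ("x times less likely")."""
    if contrasts is None:
        contrasts = level_contrasts(fit)
    rows = []
    for name, c in contrasts.items():
        c = np.asarray(c, dtype=float)
        if c.size != len(fit.columns):
            raise DataError(
                f"contrast {name!r} has length {c.size}, expected {len(fit.columns)}"
            )
        est = float(c @ fit.beta)
        var = float(c @ fit.vcov @ c)
        if var < -1e-12:
            raise EstimationError(f"negative contrast variance for {name!r}")
        se = math.sqrt(max(var, 0.0))
        rows.append(
            {
                "contrast": name,
                "or": math.exp(est),
                "ci_low": math.exp(est - 1.96 * se),
                "ci_high": math.exp(est + 1.96 * se),
                "reciprocal": math.exp(-est),
            }
        )
    return pd.DataFrame(rows)


def predict_admission(
    fit: LogitFit,
    profile: PatientProfile,
    attributes: Sequence[AttributeSpec] | None = None,
) -> float:
    """Admission probability of a profile under an admit-model fit."""
    if fit.model != "admit":
        raise EstimationError("prediction requires an admit-model fit")
    attributes = attributes if attributes is not None else fit.attributes
    if attributes is None:
        raise DataError("attribute configuration required for prediction")
    x = np.concatenate(([1.0], profile_vector(profile, attributes)))
    if x.size != len(fit.columns):
        raise DataError("profile does not match the fit's attribute configuration")
    return float(1.0 / (1.0 + math.exp(-float(x @ fit.beta))))


def fit_to_json(fit: LogitFit, path: str | Path) -> None:
    doc = {
        "model": fit.model,
        "columns": fit.columns,
        "beta": fit.beta.tolist(),
        "vcov": fit.vcov.tolist(),
        "loglik": fit.loglik,
        "loglik_null": fit.loglik_null,
        "n_obs": fit.n_obs,
        "n_clusters": fit.n_clusters,
        "converged": fit.converged,
        "iterations": fit.iterations,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def fit_from_json(
    path: str | Path, attributes: Sequence[AttributeSpec] | None = None
) -> LogitFit:
    with open(path) as fh:
        doc = json.load(fh)
    return LogitFit(
        beta=np.asarray(doc["beta"]),
        vcov=np.asarray(doc["vcov"]),
        loglik=doc["loglik"],
        n_obs=doc["n_obs"],
        n_clusters=doc["n_clusters"],
        converged=doc["converged"],
        iterations=doc["iterations"],
        columns=list(doc["columns"]),
        model=doc["model"],
        loglik_null=doc.get("loglik_null"),
        attributes=list(attributes) if attributes is not None else None,
    )
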
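"""Comorbidity type x severity interaction model.

Replaces the two comorbidity main-effect blocks with one dummy per
type-by-severity cell (the severe prostate-cancer cell is the reference, so
4x3 cells give 11 dummies), keeping every other attribute's main-effect
coding.  Cell odds ratios are reported against the reference cell with a flag
for confidence intervals crossing the null.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import AttributeSpec
from .errors import DataError
from .estimation import CodedData, LogitFit, fit_logit

__all__ = [
    "code_interaction_dataset",
    "fit_interaction_model",
    "interaction_or_grid",
    "lr_test",
    "plot_or_grid",
]

TYPE_ATTR = "comorbidity_type"
SEVERITY_ATTR = "comorbidity_severity"


def _cell_name(type_level: str, severity_level: str) -> str:
    return f"cell:{type_level}|{severity_level}"


def code_interaction_dataset(
    responses: pd.DataFrame,
    attributes: Sequence[AttributeSpec],
    type_attr: str = TYPE_ATTR,
    severity_attr: str = SEVERITY_ATTR,
    task_types: Sequence[str] = ("standard",),
) -> CodedData:
    """Admit-model coding with saturated type x severity cell dummies."""
    by_name = {a.name: a for a in attributes}
    if type_attr not in by_name or severity_attr not in by_name:
        raise DataError("type/severity attributes not in configuration")
    t_attr, s_attr = by_name[type_attr], by_name[severity_attr]
    ref_cell = (t_attr.reference, s_attr.reference)
    cells = [
        (tl, sl)
        for tl in t_attr.levels
        for sl in s_attr.levels
        if (tl, sl) != ref_cell
    ]
    rows = responses[responses["task_type"].isin(task_types)]
    if rows.empty:
        raise DataError("no rows left after task-type filtering")
    observed = set(zip(rows[type_attr].astype(str), rows[severity_attr].astype(str)))
    missing = [c for c in cells + [ref_cell] if c not in observed]
    if missing:
        raise DataError(f"type x severity cells never observed: {sorted(missing)}")

    other = [a for a in attributes if a.name not in (type_attr, severity_attr)]
    columns = ["intercept"]
    columns += [_cell_name(tl, sl) for tl, sl in cells]
    for a in other:
        columns += [f"{a.name}:{l}" for l in a.non_reference_levels()]

    n = len(rows)
    X = np.zeros((n, len(columns)))
    X[:, 0] = 1.0
    col_of = {c: j for j, c in enumerate(columns)}
    tvals = rows[type_attr].astype(str).to_numpy()
    svals = rows[severity_attr].astype(str).to_numpy()
    for tl, sl in cells:
        X[(tvals == tl) & (svals == sl), col_of[_cell_name(tl, sl)]] = 1.0
    for a in other:
        vals = rows[a.name].astype(str).to_numpy()
        bad = set(vals) - set(a.levels)
        if bad:
            raise DataError(f"unknown level(s) {sorted(bad)} for attribute {a.name!r}")
        for l in a.non_reference_levels():
            X[vals == l, col_of[f"{a.name}:{l}"]] = 1.0
    return CodedData(
        y=rows["admit"].to_numpy(dtype=float),
        X=X,
        cluster_ids=rows["respondent_id"].to_numpy(),
        columns=columns,
        model="admit",
    )


def fit_interaction_model(
    responses: pd.DataFrame,
    attributes: Sequence[AttributeSpec],
    **fit_kwargs,
) -> LogitFit:
    coded = code_interaction_dataset(responses, attributes)
    fit = fit_logit(coded, **fit_kwargs)
    fit.attributes = list(attributes)
    return fit


def interaction_or_grid(
    fit: LogitFit,
    attributes: Sequence[AttributeSpec] | None = None,
    type_attr: str = TYPE_ATTR,
    severity_attr: str = SEVERITY_ATTR,
) -> pd.DataFrame:
    """Per-cell odds ratios against the reference cell (OR fixed at 1 there)."""
    attributes = attributes if attributes is not None else fit.attributes
    if attributes is None:
        raise DataError("attribute configuration required")
    by_name = {a.name: a for a in attributes}
    t_attr, s_attr = by_name[type_attr], by_name[severity_attr]
    rows = []
    for tl in t_attr.levels:
        for sl in s_attr.levels:
            if (tl, sl) == (t_attr.reference, s_attr.reference):
                rows.append(
                    {
                        "type": tl,
                        "severity": sl,
                        "or": 1.0,
                        "ci_low": np.nan,
                        "ci_high": np.nan,
                        "crosses_null": False,
                        "reference": True,
                    }
                )
                continue
            col = _cell_name(tl, sl)
            if col not in fit.columns:
                raise DataError(f"fit lacks cell column {col!r}")
            j = fit.columns.index(col)
            est = float(fit.beta[j])
            se = math.sqrt(float(fit.vcov[j, j]))
            lo, hi = math.exp(est - 1.96 * se), math.exp(est + 1.96 * se)
            rows.append(
                {
                    "type": tl,
                    "severity": sl,
                    "or": math.exp(est),
                    "ci_low": lo,
                    "ci_high": hi,
                    "crosses_null": bool(lo <= 1.0 <= hi),
                    "reference": False,
                }
            )
    return pd.DataFrame(rows)


def lr_test(restricted: LogitFit, full: LogitFit) -> tuple[float, int, float]:
    """Likelihood-ratio test of the interaction model against main effects."""
    stat = 2.0 * (full.loglik - restricted.loglik)
    df = len(full.columns) - len(restricted.columns)
    if df <= 0:
        raise DataError("full model has no extra parameters")
    return stat, df, float(stats.chi2.sf(max(stat, 0.0), df))


def plot_or_grid(grid: pd.DataFrame, path: str) -> None:
    """Forest-style plot of cell odds ratios with the OR=1 dashed line."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 5))
    labels = [f"{t}, {s}" for t, s in zip(grid["type"], grid["severity"])]
    ypos = np.arange(len(grid))[::-1]
    ax.scatter(grid["or"], ypos, color="#4878a8", zorder=3)
    for yp, (_, row) in zip(ypos, grid.iterrows()):
        if not row["reference"]:
            ax.plot([row["ci_low"], row["ci_high"]], [yp, yp], color="black", lw=1)
    ax.axvline(1.0, linestyle="--", color="grey")
    ax.set_yticks(ypos)
    ax.set_yticklabels(labels)
    ax.set_xscale("log")
    ax.set_xlabel("odds ratio vs reference cell")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
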
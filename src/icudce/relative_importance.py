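"""Range-based relative attribute importance.

An attribute's range is the spread of its level coefficients with the
reference level counted as zero; importances are ranges normalized to sum to
100%.  With eight attributes, equal weighting corresponds to the 12.5%
(100/8) benchmark.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, EstimationError
from .estimation import LogitFit

__all__ = [
    "attribute_ranges",
    "relative_importance",
    "ri_from_fit",
    "ri_uncertainty",
    "plot_ri",
    "EQUAL_BENCHMARK_PERCENT",
]

EQUAL_BENCHMARK_PERCENT = 100.0 / 8.0


def attribute_ranges(
    beta: Mapping[str, float] | np.ndarray,
    columns: Sequence[str] | None = None,
) -> dict[str, float]:
    """Per-attribute coefficient ranges ``max(0, betas) - min(0, betas)``.

    ``beta`` is either a mapping ``"attribute:level" -> coefficient`` or a
    vector aligned with ``columns``.  The intercept is ignored.
    """
    if not isinstance(beta, Mapping):
        if columns is None:
            raise DataError("columns metadata required with a coefficient vector")
        if len(columns) != np.asarray(beta).size:
            raise DataError("beta / columns length mismatch")
        beta = dict(zip(columns, np.asarray(beta, dtype=float)))
    groups: dict[str, list[float]] = {}
    for key, val in beta.items():
        if key == "intercept":
            continue
        if ":" not in key:
            raise DataError(f"coefficient {key!r} has no attribute mapping")
        attr = key.split(":", 1)[0]
        groups.setdefault(attr, []).append(float(val))
    return {
        attr: max(0.0, *vals) - min(0.0, *vals) for attr, vals in groups.items()
    }


def relative_importance(ranges: Mapping[str, float]) -> pd.DataFrame:
    """Normalize ranges to percentages summing to 100."""
    if not ranges:
        raise DataError("no attributes")
    for attr, r in ranges.items():
        if r < 0:
            raise DataError(f"negative range for {attr!r}")
    total = sum(ranges.values())
    if total <= 0:
        raise DataError("all attribute ranges are zero; importance undefined")
    return pd.DataFrame(
        {
            "attribute": list(ranges.keys()),
            "range": list(ranges.values()),
            "ri_percent": [100.0 * r / total for r in ranges.values()],
        }
    )


def ri_from_fit(fit: LogitFit) -> pd.DataFrame:
    """Plug-in relative importance of an admit- or priority-model fit."""
    return relative_importance(attribute_ranges(fit.beta, fit.columns))


def ri_uncertainty(
    fit: LogitFit, n_draws: int = 5000, seed: int = 0
) -> pd.DataFrame:
    """Percentile 95% CIs for RI by parametric simulation from (beta, vcov)."""
    if n_draws < 100:
        raise DataError("n_draws must be >= 100")
    eig = np.linalg.eigvalsh(fit.vcov)
    if eig.min() < -1e-8 * max(eig.max(), 1.0):
        raise EstimationError("covariance matrix is not positive semidefinite")
    rng = np.random.default_rng(seed)
    draws = rng.multivariate_normal(
        fit.beta, fit.vcov, size=n_draws, method="eigh"
    )
    point = ri_from_fit(fit)
    attrs = list(point["attribute"])
    sims = np.empty((n_draws, len(attrs)))
    for i in range(n_draws):
        ranges = attribute_ranges(draws[i], fit.columns)
        total = sum(ranges.values())
        if total <= 0:
            sims[i] = np.nan
            continue
        sims[i] = [100.0 * ranges[a] / total for a in attrs]
    lo = np.nanpercentile(sims, 2.5, axis=0)
    hi = np.nanpercentile(sims, 97.5, axis=0)
    out = point.copy()
    out["ci_low"] = lo
    out["ci_high"] = hi
    return out


def plot_ri(ri: pd.DataFrame, path: str, title: str = "Relative importance") -> None:
    """Bar chart with the equal-importance 12.5% benchmark line."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 4))
    ax.bar(ri["attribute"], ri["ri_percent"], color="#4878a8")
    if "ci_low" in ri.columns:
        ax.errorbar(
            ri["attribute"],
            ri["ri_percent"],
            yerr=[
                ri["ri_percent"] - ri["ci_low"],
                ri["ci_high"] - ri["ri_percent"],
            ],
            fmt="none",
            ecolor="black",
            capsize=3,
        )
    ax.axhline(EQUAL_BENCHMARK_PERCENT, linestyle="--", color="grey")
    ax.set_ylabel("relative importance (%)")
    ax.set_title(title)
    plt.xticks(rotation=30, ha="right")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
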
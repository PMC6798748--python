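"""Synthetic respondents and choice behaviour.

Simulates a population mixing four latent preference classes whose
share-weighted coefficients reproduce the documented pooled odds-ratio
anchors, a covariate-driven class-membership logit, and per-task answers
(admit A, admit B, priority) with response times.  A configurable fraction of
"careless" respondents answers uniformly at random with short response times.

Careful respondents derive all three answers for a task from one realized
utility per profile, ``u = alpha + V + logistic noise``: the two admit answers
are the indicators ``u > 0`` (so each admit margin is exactly logistic) and
priority goes to the profile with the larger ``u``.  This coupling makes a
careful respondent logically consistent by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .config import AttributeSpec, column_names, default_attributes
from .covariates import COVARIATE_DOMAINS, MEMBERSHIP_TERMS, code_covariates
from .design import ChoiceDesign, ChoiceTask, profile_vector
from .errors import ConfigError, DataError

__all__ = [
    "PreferenceClassSpec",
    "RespondentRecord",
    "ResponseRecord",
    "default_population",
    "pooled_beta",
    "beta_vector",
    "default_membership_theta",
    "intercept_only_theta",
    "with_calibrated_intercepts",
    "simulate_respondents",
    "simulate_responses",
    "ideal_responses",
    "responses_frame",
    "covariates_frame",
    "truth_frame",
    "write_dataset",
]


@dataclass(frozen=True)
class PreferenceClassSpec:
    """One latent preference class: share, level coefficients, admit intercept."""

    label: str
    share: float
    beta: Mapping[str, float]  # "attribute:level" -> coefficient, non-reference only
    intercept: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.share < 1.0):
            raise ConfigError(f"class {self.label!r}: share must lie in (0,1)")
        for k, v in self.beta.items():
            if not math.isfinite(v):
                raise ConfigError(f"class {self.label!r}: non-finite beta for {k}")


@dataclass
class RespondentRecord:
    respondent_id: int
    covariates: dict[str, str]
    true_class: str
    quality_type: str = "careful"
    block_id: int | None = None


@dataclass(frozen=True)
class ResponseRecord:
    respondent_id: int
    task_id: int
    admit_a: int
    admit_b: int
    priority: str  # "A" or "B"
    response_time_ms: int


# ---------------------------------------------------------------------------
# default generating population
# ---------------------------------------------------------------------------

_LN12 = math.log(12.0)

# Pooled (share-weighted) coefficients.  OR-pinned entries use the documented
# odds-ratio anchors exactly; the remaining entries are generator defaults
# scaled so the pooled per-attribute ranges are ordered
# age > family > severity > functional > registrar > NEWS > type > ward.
_POOLED_BETA: dict[str, float] = {
    "age:66 yr": math.log(5.0),
    "age:39 yr": _LN12,
    "comorbidity_type:COPD": -math.log(1.04),
    "comorbidity_type:heart failure": -math.log(1.34),
    "comorbidity_type:dementia": -math.log(1.48),
    "comorbidity_severity:moderate": 0.5 * math.log(6.4),
    "comorbidity_severity:mild": math.log(6.4),
    "family_view:against admission": -math.log(6.0),
    "family_view:insists on admission": _LN12 * 19.9 / 23.9 - math.log(6.0),
    "functional_status:good": _LN12 * 13.5 / 23.9,
    "acute_severity:high": 0.5 * _LN12 * 7.5 / 23.9,
    "acute_severity:very high": _LN12 * 7.5 / 23.9,
    "registrar_report:struggling": _LN12 * 11.0 / 23.9,
    "ward_safety:reduced": _LN12 * 2.5 / 23.9,
}

_CLASS_SHARES: dict[str, float] = {
    "age_oriented": 0.310,
    "age_dominant": 0.332,
    "holistic": 0.174,
    "family_dominant": 0.184,
}

# Per-attribute multiplicative tilts of the pooled coefficient block.  The
# "holistic" class is solved as the exact residual so the share-weighted
# average multiplier is 1 for every attribute, making pooled contrasts exact.
_CLASS_TILTS: dict[str, dict[str, float]] = {
    "age_oriented": {"age": 1.00, "family_view": 0.85, "_default": 0.95},
    "age_dominant": {"age": 1.70, "_default": 0.35},
    "family_dominant": {"age": 0.45, "family_view": 2.30, "_default": 0.80},
}


def _tilt(label: str, attr: str) -> float:
    t = _CLASS_TILTS[label]
    return t.get(attr, t["_default"])


def pooled_beta(classes: Sequence[PreferenceClassSpec]) -> dict[str, float]:
    """Share-weighted average coefficient vector of a population."""
    keys = set()
    for c in classes:
        keys.update(c.beta)
    return {
        k: sum(c.share * c.beta.get(k, 0.0) for c in classes) for k in sorted(keys)
    }


def default_population(
    attributes: Sequence[AttributeSpec] | None = None,
) -> list[PreferenceClassSpec]:
    """Four latent classes with shares (0.310, 0.332, 0.174, 0.184).

    The share-weighted average of the class coefficient vectors equals the
    pooled anchor vector exactly, so pooled contrasts reproduce the documented
    odds ratios (e.g. age 39 vs 89 -> 12, mild vs severe -> 6.4).
    """
    attributes = list(attributes) if attributes is not None else default_attributes()
    shares = _CLASS_SHARES
    classes: list[PreferenceClassSpec] = []
    residual_label = "holistic"
    for label in ("age_oriented", "age_dominant", "family_dominant"):
        beta = {
            key: _tilt(label, key.split(":", 1)[0]) * val
            for key, val in _POOLED_BETA.items()
        }
        classes.append(PreferenceClassSpec(label, shares[label], beta))
    # residual class: exact so that sum_c share_c * beta_c == pooled
    resid_share = shares[residual_label]
    beta_resid = {}
    for key, val in _POOLED_BETA.items():
        acc = sum(c.share * c.beta[key] for c in classes)
        beta_resid[key] = (val - acc) / resid_share
    classes.insert(2, PreferenceClassSpec(residual_label, resid_share, beta_resid))
    total = sum(c.share for c in classes)
    if abs(total - 1.0) > 1e-12:
        raise ConfigError(f"class shares sum to {total}")  # pragma: no cover
    return classes


def beta_vector(
    beta: Mapping[str, float], attributes: Sequence[AttributeSpec]
) -> np.ndarray:
    """Align an ``attr:level -> value`` mapping with the model column order."""
    cols = column_names(attributes, intercept=False)
    unknown = set(beta) - set(cols)
    if unknown:
        raise ConfigError(f"beta keys not in model columns: {sorted(unknown)}")
    return np.array([beta.get(c, 0.0) for c in cols])


def default_membership_theta(
    classes: Sequence[PreferenceClassSpec],
) -> pd.DataFrame:
    """Covariate coefficients of the class-membership logit.

    The last class is the reference (coefficients fixed at zero).  Intercepts
    reproduce the class shares for a reference-category respondent; the
    non-zero covariate effects tilt older consultants toward the first and
    third classes, medium-ICU consultants away from the first and
    university-hospital consultants away from the third.
    """
    ref = classes[-1]
    theta = pd.DataFrame(
        0.0,
        index=[c.label for c in classes[:-1]],
        columns=list(MEMBERSHIP_TERMS),
    )
    for c in classes[:-1]:
        theta.loc[c.label, "intercept"] = math.log(c.share / ref.share)
    first, third = classes[0].label, classes[2].label
    theta.loc[first, ["age_40_50", "age_gt50", "icu_medium"]] = [0.4, 0.8, -0.5]
    theta.loc[third, ["age_40_50", "age_gt50", "university"]] = [0.4, 0.8, -0.5]
    return theta


def intercept_only_theta(
    classes: Sequence[PreferenceClassSpec],
) -> pd.DataFrame:
    """Membership model with intercepts only: class shares are exact."""
    ref = classes[-1]
    return pd.DataFrame(
        {"intercept": [math.log(c.share / ref.share) for c in classes[:-1]]},
        index=[c.label for c in classes[:-1]],
    )


def with_calibrated_intercepts(
    classes: Sequence[PreferenceClassSpec], design: ChoiceDesign
) -> list[PreferenceClassSpec]:
    """Fill in missing admit intercepts so each class's mean admit probability
    over the design's standard-task profiles is 0.5."""
    out = []
    profiles = []
    for t in design.standard_tasks():
        profiles.append(profile_vector(t.profile_a, design.attributes))
        profiles.append(profile_vector(t.profile_b, design.attributes))
    X = np.vstack(profiles)
    for c in classes:
        if c.intercept is not None:
            out.append(c)
            continue
        v = X @ beta_vector(c.beta, design.attributes)

        def mean_minus_half(alpha: float) -> float:
            return float(np.mean(1.0 / (1.0 + np.exp(-(alpha + v))))) - 0.5

        alpha = brentq(mean_minus_half, -30.0, 30.0)
        out.append(PreferenceClassSpec(c.label, c.share, dict(c.beta), float(alpha)))
    return out


# ---------------------------------------------------------------------------
# respondents
# ---------------------------------------------------------------------------

# Sample-description marginals; icu_size is a generator default.
DEFAULT_COVARIATE_FREQS: dict[str, dict[str, float]] = {
    "age_band": {"<40": 0.211, "40-50": 0.508, ">50": 0.281},
    "years_in_icu": {"<=10": 0.231, ">10": 0.769},
    "icu_size": {"small": 0.30, "medium": 0.45, "large": 0.25},
    "hospital_type": {"general": 0.664, "university": 0.336},
    "gender": {"male": 0.795, "female": 0.205},
}


def simulate_respondents(
    n: int,
    classes: Sequence[PreferenceClassSpec],
    membership_theta: pd.DataFrame | None = None,
    seed: int = 0,
    covariate_freqs: Mapping[str, Mapping[str, float]] | None = None,
) -> list[RespondentRecord]:
    """Draw covariates from their marginals and latent classes from the
    membership logit ``pi_c(z; theta)`` (last class = reference)."""
    if n < 1:
        raise DataError("n must be >= 1")
    freqs = covariate_freqs or DEFAULT_COVARIATE_FREQS
    for cov, dist in freqs.items():
        if cov not in COVARIATE_DOMAINS:
            raise ConfigError(f"unknown covariate {cov!r}")
        vals = list(dist.values())
        if any(p < 0 for p in vals) or abs(sum(vals) - 1.0) > 1e-9:
            raise ConfigError(f"covariate {cov!r}: frequencies must sum to 1")
        bad = set(dist) - set(COVARIATE_DOMAINS[cov])
        if bad:
            raise ConfigError(f"covariate {cov!r}: unknown categories {sorted(bad)}")
    if membership_theta is None:
        membership_theta = default_membership_theta(classes)
    labels = [c.label for c in classes]
    if list(membership_theta.index) != labels[:-1]:
        raise ConfigError(
            "membership_theta rows must be the non-reference classes in order"
        )
    rng = np.random.default_rng(seed)
    cov_rows = []
    for _ in range(n):
        cov_rows.append(
            {
                cov: str(
                    rng.choice(list(dist.keys()), p=np.array(list(dist.values())))
                )
                for cov, dist in freqs.items()
            }
        )
    cov_df = pd.DataFrame(cov_rows)
    Z, _ = code_covariates(cov_df, terms=list(membership_theta.columns))
    util = Z @ membership_theta.to_numpy().T  # n x (C-1)
    util = np.column_stack([util, np.zeros(n)])
    util -= util.max(axis=1, keepdims=True)
    pi = np.exp(util)
    pi /= pi.sum(axis=1, keepdims=True)
    draws = [labels[rng.choice(len(labels), p=pi[i])] for i in range(n)]
    return [
        RespondentRecord(i + 1, cov_rows[i], draws[i]) for i in range(n)
    ]


# ---------------------------------------------------------------------------
# responses
# ---------------------------------------------------------------------------

CAREFUL_MEDIAN_MS = 8000.0
CARELESS_MEDIAN_MS = CAREFUL_MEDIAN_MS / 5.0
_RT_SIGMA = 0.5


def _presented_tasks(design: ChoiceDesign, block_id: int) -> list[ChoiceTask]:
    block = design.block(block_id)
    warmups = [t for t in block if t.task_type == "warmup"]
    rest = sorted(
        (t for t in block if t.task_type != "warmup"), key=lambda t: t.task_id
    )
    return warmups + rest


def simulate_responses(
    respondents: Sequence[RespondentRecord],
    design: ChoiceDesign,
    classes: Sequence[PreferenceClassSpec],
    careless_rate: float = 0.0,
    seed: int = 0,
) -> list[ResponseRecord]:
    """Simulate the three answers and a response time for every presented task.

    Respondents are dealt round-robin over design blocks (recorded on the
    respondent records).  Repeat tasks are re-answered with fresh noise, not
    copied.  Careless respondents (drawn at ``careless_rate``) answer
    uniformly at random with short response times.
    """
    if not (0.0 <= careless_rate <= 1.0):
        raise ConfigError("careless_rate must lie in [0,1]")
    classes = with_calibrated_intercepts(classes, design)
    by_label = {c.label: c for c in classes}
    rng = np.random.default_rng(seed)
    blocks = sorted({t.block_id for t in design.tasks})
    # per-profile utility index cache per class
    vcache: dict[tuple[str, int, str], float] = {}
    for c in classes:
        bvec = beta_vector(c.beta, design.attributes)
        for t in design.tasks:
            for alt, prof in (("A", t.profile_a), ("B", t.profile_b)):
                vcache[(c.label, t.task_id, alt)] = float(
                    profile_vector(prof, design.attributes) @ bvec
                )
    out: list[ResponseRecord] = []
    for i, r in enumerate(respondents):
        if r.block_id is None:
            r.block_id = blocks[i % len(blocks)]
        elif r.block_id not in blocks:
            raise DataError(
                f"respondent {r.respondent_id} references unknown block {r.block_id}"
            )
        careless = rng.random() < careless_rate
        r.quality_type = "careless" if careless else "careful"
        if r.true_class not in by_label:
            raise DataError(
                f"respondent {r.respondent_id} has unknown class {r.true_class!r}"
            )
        cls = by_label[r.true_class]
        median = CARELESS_MEDIAN_MS if careless else CAREFUL_MEDIAN_MS
        for t in _presented_tasks(design, r.block_id):
            if careless:
                admit_a = int(rng.integers(2))
                admit_b = int(rng.integers(2))
                priority = "A" if rng.integers(2) == 0 else "B"
            else:
                ua = cls.intercept + vcache[(cls.label, t.task_id, "A")] + rng.logistic()
                ub = cls.intercept + vcache[(cls.label, t.task_id, "B")] + rng.logistic()
                admit_a = int(ua > 0.0)
                admit_b = int(ub > 0.0)
                priority = "A" if ua > ub else "B"
            rt = int(round(median * math.exp(_RT_SIGMA * rng.standard_normal())))
            out.append(
                ResponseRecord(r.respondent_id, t.task_id, admit_a, admit_b, priority, max(rt, 1))
            )
    return out


def ideal_responses(
    respondents: Sequence[RespondentRecord],
    design: ChoiceDesign,
    beta: Mapping[str, float],
    alpha: float = 0.0,
    response_time_ms: int = 8000,
) -> list[ResponseRecord]:
    """Noise-free answers under a strict utility ordering (test fixture aid).

    Admit iff ``alpha + V > 0``; priority to the higher-V profile (ties to A);
    constant generous response time.  Such a respondent passes all four
    quality criteria whenever the coefficients respect the ordinal orderings.
    """
    bvec = beta_vector(beta, design.attributes)
    blocks = sorted({t.block_id for t in design.tasks})
    out = []
    for i, r in enumerate(respondents):
        if r.block_id is None:
            r.block_id = blocks[i % len(blocks)]
        for t in _presented_tasks(design, r.block_id):
            va = float(profile_vector(t.profile_a, design.attributes) @ bvec)
            vb = float(profile_vector(t.profile_b, design.attributes) @ bvec)
            out.append(
                ResponseRecord(
                    r.respondent_id,
                    t.task_id,
                    int(alpha + va > 0.0),
                    int(alpha + vb > 0.0),
                    "A" if va >= vb else "B",
                    response_time_ms,
                )
            )
    return out


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def responses_frame(
    responses: Sequence[ResponseRecord], design: ChoiceDesign
) -> pd.DataFrame:
    """Long-format analysis table: one row per respondent x task x alternative.

    Ground-truth class labels are deliberately absent (they go to the truth
    file only)."""
    tasks = {t.task_id: t for t in design.tasks}
    rows = []
    for r in responses:
        t = tasks.get(r.task_id)
        if t is None:
            raise DataError(f"response references unknown task {r.task_id}")
        for alt, prof, admit in (
            ("A", t.profile_a, r.admit_a),
            ("B", t.profile_b, r.admit_b),
        ):
            row = {
                "respondent_id": r.respondent_id,
                "task_id": t.task_id,
                "block_id": t.block_id,
                "alternative": alt,
                "task_type": t.task_type,
                "repeat_of": "" if t.repeat_of is None else t.repeat_of,
            }
            row.update(prof.to_dict())
            row["admit"] = admit
            row["priority_chosen"] = int(r.priority == alt)
            row["response_time_ms"] = r.response_time_ms
            rows.append(row)
    return pd.DataFrame(rows)


def covariates_frame(respondents: Sequence[RespondentRecord]) -> pd.DataFrame:
    rows = []
    for r in respondents:
        row = {"respondent_id": r.respondent_id}
        row.update(r.covariates)
        rows.append(row)
    return pd.DataFrame(rows)


def truth_frame(respondents: Sequence[RespondentRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "respondent_id": [r.respondent_id for r in respondents],
            "true_class": [r.true_class for r in respondents],
            "quality_type": [r.quality_type for r in respondents],
        }
    )


def write_dataset(
    out_dir: str | Path,
    responses: Sequence[ResponseRecord],
    respondents: Sequence[RespondentRecord],
    design: ChoiceDesign,
) -> dict[str, Path]:
    """Write choices.csv / respondents.csv / truth.csv into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "choices": out / "choices.csv",
        "respondents": out / "respondents.csv",
        "truth": out / "truth.csv",
    }
    responses_frame(responses, design).to_csv(paths["choices"], index=False)
    covariates_frame(respondents).to_csv(paths["respondents"], index=False)
    truth_frame(respondents).to_csv(paths["truth"], index=False)
    return paths
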
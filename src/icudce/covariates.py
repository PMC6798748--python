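"""Respondent covariate domains and dummy coding for membership models."""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DataError

__all__ = ["COVARIATE_DOMAINS", "MEMBERSHIP_TERMS", "code_covariates"]

COVARIATE_DOMAINS: dict[str, tuple[str, ...]] = {
    "age_band": ("<40", "40-50", ">50"),
    "years_in_icu": ("<=10", ">10"),
    "icu_size": ("small", "medium", "large"),
    "hospital_type": ("general", "university"),
    "gender": ("male", "female"),
}

# reference categories: <40, <=10, small, general, male
MEMBERSHIP_TERMS: tuple[str, ...] = (
    "intercept",
    "age_40_50",
    "age_gt50",
    "years_gt10",
    "icu_medium",
    "icu_large",
    "university",
    "female",
)

_TERM_RULES = {
    "age_40_50": ("age_band", "40-50"),
    "age_gt50": ("age_band", ">50"),
    "years_gt10": ("years_in_icu", ">10"),
    "icu_medium": ("icu_size", "medium"),
    "icu_large": ("icu_size", "large"),
    "university": ("hospital_type", "university"),
    "female": ("gender", "female"),
}


def code_covariates(
    covariates: pd.DataFrame, terms: Sequence[str] = MEMBERSHIP_TERMS
) -> tuple[np.ndarray, list[str]]:
    """Dummy-code a respondent covariate table into a membership design matrix.

    ``covariates`` must be indexed (or indexable) by ``respondent_id`` order;
    rows are taken as given.  Returns ``(Z, term_names)``.
    """
    for col, domain in COVARIATE_DOMAINS.items():
        if col in covariates.columns:
            bad = set(covariates[col].astype(str)) - set(domain)
            if bad:
                raise DataError(f"unknown {col} values {sorted(bad)}")
    n = len(covariates)
    cols = []
    names = []
    for term in terms:
        if term == "intercept":
            cols.append(np.ones(n))
            names.append(term)
            continue
        if term not in _TERM_RULES:
            raise DataError(f"unknown membership term {term!r}")
        col, value = _TERM_RULES[term]
        if col not in covariates.columns:
            raise DataError(f"covariate table lacks column {col!r}")
        cols.append((covariates[col].astype(str) == value).to_numpy(dtype=float))
        names.append(term)
    return np.column_stack(cols), names
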
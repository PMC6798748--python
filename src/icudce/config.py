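"""Attribute/level configuration for the choice experiment.

An attribute is one patient factor (age, comorbidity type, ...) with a small
ordered set of discrete levels.  One level per attribute is the reference and
carries a coefficient of zero in every model.  Attributes flagged ``ordinal``
have their levels listed from least to most admission-favourable, which is
what the dominance quality task and the design search rely on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import yaml

from .errors import ConfigError

__all__ = [
    "AttributeSpec",
    "default_attributes",
    "load_attributes",
    "dump_attributes",
    "column_names",
    "n_model_columns",
]


@dataclass(frozen=True)
class AttributeSpec:
    """One patient factor and its discrete levels.

    Parameters
    ----------
    name
        Short machine identifier, used as a column name in data files.
    label
        Human-readable display text.
    levels
        Ordered level labels.  For ordinal attributes the order is from the
        least to the most admission-favourable level.
    reference
        The level whose coefficient is pinned at zero.
    ordinal
        Whether the levels carry a dominance ordering.
    """

    name: str
    label: str
    levels: tuple[str, ...]
    reference: str
    ordinal: bool = False

    def __post_init__(self) -> None:
        if len(self.levels) < 2:
            raise ConfigError(f"attribute {self.name!r} needs >=2 levels")
        if len(set(self.levels)) != len(self.levels):
            raise ConfigError(f"attribute {self.name!r} has duplicate levels")
        if self.reference not in self.levels:
            raise ConfigError(
                f"reference {self.reference!r} is not a level of {self.name!r}"
            )
        object.__setattr__(self, "levels", tuple(self.levels))

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    def non_reference_levels(self) -> tuple[str, ...]:
        return tuple(l for l in self.levels if l != self.reference)

    def rank(self, level: str) -> int:
        """Position of ``level`` in the ordinal ordering (0 = least favourable)."""
        return self.levels.index(level)


def default_attributes() -> list[AttributeSpec]:
    """The packaged eight-factor study configuration.

    Level lists follow the documented reconstruction; reference levels are the
    least admission-favourable level of each attribute except family view,
    whose natural reference is "not known".
    """
    return [
        AttributeSpec(
            "age", "Patient's age", ("89 yr", "66 yr", "39 yr"), "89 yr", ordinal=True
        ),
        AttributeSpec(
            "comorbidity_type",
            "Type of main comorbidity",
            ("prostate cancer", "COPD", "heart failure", "dementia"),
            "prostate cancer",
            ordinal=False,
        ),
        AttributeSpec(
            "comorbidity_severity",
            "Severity of main comorbidity",
            ("severe", "moderate", "mild"),
            "severe",
            ordinal=True,
        ),
        AttributeSpec(
            "family_view",
            "Family's view on admission",
            ("against admission", "not known", "insists on admission"),
            "not known",
            ordinal=True,
        ),
        AttributeSpec(
            "functional_status",
            "Functional status",
            ("limited", "good"),
            "limited",
            ordinal=True,
        ),
        AttributeSpec(
            "acute_severity",
            "Severity of acute condition (NEWS band)",
            ("medium", "high", "very high"),
            "medium",
            ordinal=True,
        ),
        AttributeSpec(
            "registrar_report",
            "Registrar's subjective report",
            ("not struggling", "struggling"),
            "not struggling",
            ordinal=True,
        ),
        AttributeSpec(
            "ward_safety",
            "Ward nursing capacity",
            ("normal", "reduced"),
            "normal",
            ordinal=True,
        ),
    ]


def load_attributes(path: str | Path) -> list[AttributeSpec]:
    """Read an attribute configuration from YAML."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "attributes" not in doc:
        raise ConfigError(f"{path}: expected a mapping with an 'attributes' key")
    attrs = []
    for entry in doc["attributes"]:
        try:
            attrs.append(
                AttributeSpec(
                    name=entry["name"],
                    label=entry.get("label", entry["name"]),
                    levels=tuple(str(l) for l in entry["levels"]),
                    reference=str(entry.get("reference", entry["levels"][0])),
                    ordinal=bool(entry.get("ordinal", False)),
                )
            )
        except KeyError as exc:  # pragma: no cover - config typo path
            raise ConfigError(f"{path}: attribute entry missing key {exc}") from exc
    if not attrs:
        raise ConfigError(f"{path}: empty attribute list")
    return attrs


def dump_attributes(attributes: Sequence[AttributeSpec], path: str | Path) -> None:
    """Write an attribute configuration to YAML."""
    doc = {
        "attributes": [
            {
                "name": a.name,
                "label": a.label,
                "levels": list(a.levels),
                "reference": a.reference,
                "ordinal": a.ordinal,
            }
            for a in attributes
        ]
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def column_names(
    attributes: Iterable[AttributeSpec], intercept: bool = True
) -> list[str]:
    """Model column labels: optional intercept then ``attr:level`` dummies."""
    cols = ["intercept"] if intercept else []
    for a in attributes:
        cols.extend(f"{a.name}:{l}" for l in a.non_reference_levels())
    return cols


def n_model_columns(attributes: Iterable[AttributeSpec], intercept: bool = True) -> int:
    return len(column_names(attributes, intercept=intercept))
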
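"""End-to-end orchestration: design -> simulate -> quality -> fit -> RI ->
latent class -> interactions, with every stage reading its predecessor's
serialized artifact so a run is restartable and reproducible."""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml

from . import quality as quality_mod
from .config import default_attributes, dump_attributes, load_attributes
from .design import ChoiceDesign, generate_design, inject_quality_tasks
from .errors import ConfigError, DataError
from .estimation import code_dataset, fit_logit, fit_to_json, odds_ratios
from .interactions import fit_interaction_model, interaction_or_grid
from .latent_class import (
    class_ri_profiles,
    fit_latent_class,
    membership_effects,
    select_classes,
)
from .relative_importance import ri_uncertainty
from .synthetic import (
    default_population,
    simulate_respondents,
    simulate_responses,
    write_dataset,
)

logger = logging.getLogger("icudce")

__all__ = ["RunConfig", "run_all"]


@dataclass
class RunConfig:
    out_dir: str
    attributes_path: str | None = None
    n_tasks: int = 24
    n_blocks: int = 2
    n_sweeps: int = 5
    design_seed: int = 1
    n_respondents: int = 303
    careless_rate: float = 0.1
    sim_seed: int = 7
    min_median_ms: int = 2000
    max_inconsistencies: int = 1
    drop_failures: int | None = None
    lc_classes: int = 4
    lc_starts: int = 5
    lc_seed: int = 11
    lc_covariate_terms: list[str] | None = None
    lc_scan: list[int] | None = None
    ri_draws: int = 2000
    ri_seed: int = 3
    make_plots: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        extra = set(doc) - known
        if extra:
            raise ConfigError(f"unknown run-config keys {sorted(extra)}")
        if "out_dir" not in doc:
            raise ConfigError("run config must set out_dir")
        return cls(**doc)

    def to_dict(self) -> dict[str, Any]:
        return {f: getattr(self, f) for f in self.__dataclass_fields__}


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.perf_counter()
            logger.info("stage %s: start", name)
            out = fn(*args, **kwargs)
            logger.info("stage %s: done in %.1fs", name, time.perf_counter() - t0)
            return out

        return wrapped

    return deco


def run_all(config: RunConfig) -> dict[str, Any]:
    """Execute every stage in order and write a consolidated report.

    Returns the report dictionary (also written as report.json/report.md).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "run_config.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)

    attributes = (
        load_attributes(config.attributes_path)
        if config.attributes_path
        else default_attributes()
    )
    dump_attributes(attributes, out / "attributes.yaml")

    # --- design ---------------------------------------------------------
    @_stage("design")
    def stage_design() -> ChoiceDesign:
        des = generate_design(
            attributes,
            n_tasks=config.n_tasks,
            n_blocks=config.n_blocks,
            n_sweeps=config.n_sweeps,
            seed=config.design_seed,
        )
        des = inject_quality_tasks(des, seed=config.design_seed)
        des.to_csv(out / "design.csv")
        return des

    design = stage_design()

    # --- simulate -------------------------------------------------------
    @_stage("simulate")
    def stage_simulate():
        if config.n_respondents < 1:
            raise DataError("n_respondents must be >= 1")
        classes = default_population(attributes)
        respondents = simulate_respondents(
            config.n_respondents, classes, seed=config.sim_seed
        )
        responses = simulate_responses(
            respondents,
            design,
            classes,
            careless_rate=config.careless_rate,
            seed=config.sim_seed,
        )
        write_dataset(out / "data", responses, respondents, design)
        return respondents

    stage_simulate()
    choices = pd.read_csv(out / "data" / "choices.csv")
    covariates = pd.read_csv(out / "data" / "respondents.csv")

    # --- quality --------------------------------------------------------
    @_stage("quality")
    def stage_quality():
        reports = quality_mod.assess_quality(
            choices,
            design,
            min_median_ms=config.min_median_ms,
            max_inconsistencies=config.max_inconsistencies,
        )
        frame = quality_mod.reports_frame(reports)
        frame.to_csv(out / "quality.csv", index=False)
        summary = quality_mod.quality_summary(reports)
        with open(out / "quality_summary.json", "w") as fh:
            json.dump(summary, fh, indent=1)
        return frame, summary

    quality_frame, quality_summary = stage_quality()

    analysis_rows = choices
    if config.drop_failures is not None:
        keep = quality_frame.loc[
            quality_frame["n_failed"] <= config.drop_failures, "respondent_id"
        ]
        analysis_rows = choices[choices["respondent_id"].isin(set(keep))]

    # --- pooled fit + odds ratios --------------------------------------
    @_stage("fit")
    def stage_fit():
        coded = code_dataset(analysis_rows, attributes, model="admit")
        fit = fit_logit(coded, compute_null=True)
        fit.attributes = list(attributes)
        fit_to_json(fit, out / "fit.json")
        table = odds_ratios(fit)
        table.to_csv(out / "or_table.csv", index=False)
        return fit, table

    fit, or_table = stage_fit()

    # --- relative importance -------------------------------------------
    @_stage("ri")
    def stage_ri():
        ri = ri_uncertainty(fit, n_draws=config.ri_draws, seed=config.ri_seed)
        ri.to_csv(out / "ri.csv", index=False)
        if config.make_plots:
            from .relative_importance import plot_ri

            plot_ri(ri, str(out / "ri.png"))
        return ri

    ri_table = stage_ri()

    # --- latent class ---------------------------------------------------
    @_stage("latent_class")
    def stage_lc():
        coded = code_dataset(analysis_rows, attributes, model="admit")
        lc_dir = out / "lc"
        lc_dir.mkdir(exist_ok=True)
        selection = None
        if config.lc_scan:
            selection = select_classes(
                coded,
                covariates,
                config.lc_scan,
                n_starts=config.lc_starts,
                seed=config.lc_seed,
                covariate_terms=config.lc_covariate_terms,
            )
            selection.to_csv(lc_dir / "selection.csv", index=False)
        lc = fit_latent_class(
            coded,
            covariates,
            config.lc_classes,
            n_starts=config.lc_starts,
            seed=config.lc_seed,
            covariate_terms=config.lc_covariate_terms,
        )
        lc.beta_frame().to_csv(lc_dir / "class_betas.csv")
        pd.DataFrame(
            lc.posterior, columns=lc.class_labels
        ).assign(respondent_id=lc.respondent_ids).to_csv(
            lc_dir / "posterior.csv", index=False
        )
        pd.DataFrame(
            {"class": lc.class_labels, "share": lc.shares}
        ).to_csv(lc_dir / "shares.csv", index=False)
        effects = None
        if lc.n_classes >= 2:
            effects = membership_effects(lc)
            effects.to_csv(lc_dir / "membership_effects.csv", index=False)
        profiles = class_ri_profiles(lc)
        pd.concat(
            [df.assign(**{"class": label}) for label, df in profiles.items()]
        ).to_csv(lc_dir / "class_ri.csv", index=False)
        return lc, selection, effects, profiles

    lc, selection, effects, lc_profiles = stage_lc()

    # --- interactions ---------------------------------------------------
    @_stage("interactions")
    def stage_interactions():
        ifit = fit_interaction_model(analysis_rows, attributes)
        grid = interaction_or_grid(ifit)
        grid.to_csv(out / "interaction_grid.csv", index=False)
        if config.make_plots:
            from .interactions import plot_or_grid

            plot_or_grid(grid, str(out / "interaction_grid.png"))
        return grid

    grid = stage_interactions()

    # --- report ---------------------------------------------------------
    report = {
        "config": config.to_dict(),
        "quality_summary": quality_summary,
        "or_table": or_table.to_dict(orient="records"),
        "ri_table": ri_table.to_dict(orient="records"),
        "class_shares": dict(zip(lc.class_labels, map(float, lc.shares))),
        "class_selection": (
            selection.to_dict(orient="records") if selection is not None else None
        ),
        "membership_effects": (
            effects.to_dict(orient="records") if effects is not None else None
        ),
        "class_ri": {
            label: df.to_dict(orient="records") for label, df in lc_profiles.items()
        },
        "interaction_grid": grid.to_dict(orient="records"),
        "artifacts": sorted(p.name for p in out.iterdir()),
    }
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, default=float)
    _write_markdown(report, out / "report.md")
    return report


def _fmt_or(row: dict) -> str:
    if row["or"] >= 1.0:
        return f"{row['or']:.2f} times more likely"
    return f"{row['reciprocal']:.2f} times less likely"


def _write_markdown(report: dict, path: Path) -> None:
    lines = ["# Choice-experiment analysis report", ""]
    qs = report["quality_summary"]
    lines += [
        "## Response quality",
        "",
        f"- {qs['proportion_all_pass']:.1%} of respondents pass all four criteria",
        f"- maximum failures observed: {qs['max_failures_observed']}",
        "",
        "## Admission odds ratios",
        "",
        "| contrast | OR | 95% CI | reading |",
        "|---|---|---|---|",
    ]
    for row in report["or_table"]:
        lines.append(
            f"| {row['contrast']} | {row['or']:.2f} | "
            f"[{row['ci_low']:.2f}, {row['ci_high']:.2f}] | {_fmt_or(row)} |"
        )
    lines += [
        "",
        "## Relative importance (equal-importance benchmark: 12.5%)",
        "",
        "| attribute | RI (%) | 95% CI |",
        "|---|---|---|",
    ]
    for row in report["ri_table"]:
        ci = (
            f"[{row['ci_low']:.1f}, {row['ci_high']:.1f}]"
            if "ci_low" in row
            else ""
        )
        lines.append(f"| {row['attribute']} | {row['ri_percent']:.1f} | {ci} |")
    lines += ["", "## Latent classes", ""]
    for label, share in report["class_shares"].items():
        lines.append(f"- {label}: share {share:.1%}")
    lines += [
        "",
        "## Comorbidity type x severity odds ratios (vs reference cell)",
        "",
        "| type | severity | OR | crosses null |",
        "|---|---|---|---|",
    ]
    for row in report["interaction_grid"]:
        lines.append(
            f"| {row['type']} | {row['severity']} | {row['or']:.2f} | "
            f"{'yes' if row['crosses_null'] else 'no'} |"
        )
    path.write_text("\n".join(lines) + "\n")
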
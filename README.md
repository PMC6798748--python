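# icudce

Design, simulation and analysis toolkit for paired-profile discrete choice
experiments on ICU admission decisions.

The package covers the full pipeline for a stated-preference study in which
clinicians compare two hypothetical patient profiles per task and answer
three questions (admit A? admit B? which has priority?):

- **design** — D-error-minimizing generation of blocked paired-profile choice
  tasks by coordinate exchange, plus injection of one warm-up, one dominance
  and one repeat quality-check task per block.
- **synthetic** — simulation of respondents with latent preference classes
  (four by default, shares 31% / 33.2% / 17.4% / 18.4%), covariate-driven
  class membership, response times, and an optional fraction of careless
  responders.
- **quality** — the four response-quality criteria (desirability, stability,
  logical consistency, response time) with per-respondent and sample
  summaries.
- **estimation** — pooled binary logit of the admit answers (Newton with
  step-halving, respondent-clustered sandwich covariance), a paired
  conditional logit of the priority answers, odds-ratio tables, and
  admission-probability prediction for arbitrary profiles.
- **relative_importance** — range-based attribute importance percentages
  (summing to 100, with the 12.5% equal-importance benchmark) and
  simulation-based confidence intervals.
- **latent_class** — latent-class logit with covariate-driven membership,
  fitted by EM with random restarts and a quasi-Newton polish; class-count
  selection by information criteria; membership-effect tables; per-class
  importance profiles.
- **interactions** — comorbidity type-by-severity cell model (11 dummies
  against the severe prostate-cancer reference) and the odds-ratio grid.
- **pipeline** — one-command orchestration of all stages with serialized,
  reproducible artifacts.

## Command line

```bash
# blocked design with quality tasks
icudce design --tasks 24 --blocks 2 --seed 1 --out design.csv

# synthetic cohort answering the design
icudce simulate --design design.csv --n 303 --careless-rate 0.1 --seed 7 --out data/

# response-quality screening
icudce quality --data data/ --design design.csv --out quality.csv

# pooled logit, odds ratios, prediction
icudce fit --data data/ --model admit --out fit.json
icudce predict --fit fit.json --profile profile.yaml

# relative importance with simulation CIs
icudce ri --fit fit.json --draws 5000 --seed 3 --out ri.csv

# latent classes (single count or a scan such as --classes 1:6)
icudce lc --data data/ --classes 4 --starts 20 --seed 11 --out lc/

# type x severity interaction grid
icudce interactions --data data/ --out grid.csv

# everything at once from a YAML run configuration
icudce run-all --config run.yaml
```

A run configuration needs only `out_dir`; every other key
(`n_tasks`, `n_blocks`, `n_respondents`, `careless_rate`, seeds, latent-class
options, ...) has a documented default — see `icudce.pipeline.RunConfig`.
The attribute space (eight patient factors with their levels and reference
categories) is configurable via YAML; `icudce default-config --out cfg.yaml`
writes the packaged default.

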
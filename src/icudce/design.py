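"""Choice-task design: full factorial, D-error, coordinate-exchange search,
blocking, and injection of warm-up / quality-check tasks.

The design criterion is the D-error of the paired conditional logit,
``det(M)^(-1/K)`` with ``M`` the Fisher information at a prior coefficient
vector (zero by default, i.e. a utility-neutral design) summed over the
standard tasks.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .config import AttributeSpec, column_names
from .errors import ConfigError, DesignError, SingularDesignError

__all__ = [
    "PatientProfile",
    "ChoiceTask",
    "ChoiceDesign",
    "enumerate_full_factorial",
    "profile_vector",
    "dominates",
    "d_error",
    "generate_design",
    "inject_quality_tasks",
    "level_balance",
]

TASK_TYPES = ("standard", "warmup", "dominance", "repeat")


@dataclass(frozen=True)
class PatientProfile:
    """One hypothetical patient: an ordered (attribute, level) assignment."""

    assignment: tuple[tuple[str, str], ...]

    @classmethod
    def from_dict(
        cls, levels: Mapping[str, str], attributes: Sequence[AttributeSpec]
    ) -> "PatientProfile":
        items = []
        for a in attributes:
            if a.name not in levels:
                raise ConfigError(f"profile missing attribute {a.name!r}")
            lev = levels[a.name]
            if lev not in a.levels:
                raise ConfigError(f"{lev!r} is not a level of {a.name!r}")
            items.append((a.name, lev))
        extra = set(levels) - {a.name for a in attributes}
        if extra:
            raise ConfigError(f"profile has unknown attributes {sorted(extra)}")
        return cls(tuple(items))

    def level(self, attribute: str) -> str:
        for name, lev in self.assignment:
            if name == attribute:
                return lev
        raise KeyError(attribute)

    def to_dict(self) -> dict[str, str]:
        return dict(self.assignment)


@dataclass(frozen=True)
class ChoiceTask:
    task_id: int
    block_id: int
    profile_a: PatientProfile
    profile_b: PatientProfile
    task_type: str = "standard"
    repeat_of: int | None = None

    def __post_init__(self) -> None:
        if self.task_type not in TASK_TYPES:
            raise ConfigError(f"unknown task type {self.task_type!r}")
        if self.task_type == "standard" and self.profile_a == self.profile_b:
            raise DesignError(f"standard task {self.task_id} pairs identical profiles")
        if self.task_type == "repeat" and self.repeat_of is None:
            raise DesignError(f"repeat task {self.task_id} lacks repeat_of")


@dataclass
class ChoiceDesign:
    attributes: list[AttributeSpec]
    tasks: list[ChoiceTask]
    n_blocks: int
    d_error: float
    seed: int

    def standard_tasks(self, block_id: int | None = None) -> list[ChoiceTask]:
        return [
            t
            for t in self.tasks
            if t.task_type == "standard"
            and (block_id is None or t.block_id == block_id)
        ]

    def block(self, block_id: int) -> list[ChoiceTask]:
        return [t for t in self.tasks if t.block_id == block_id]

    def task(self, task_id: int) -> ChoiceTask:
        for t in self.tasks:
            if t.task_id == task_id:
                return t
        raise KeyError(task_id)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.tasks:
            for alt, prof in (("A", t.profile_a), ("B", t.profile_b)):
                row = {
                    "task_id": t.task_id,
                    "block_id": t.block_id,
                    "alternative": alt,
                    "task_type": t.task_type,
                    "repeat_of": "" if t.repeat_of is None else t.repeat_of,
                }
                row.update(prof.to_dict())
                rows.append(row)
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        attributes: Sequence[AttributeSpec],
        n_blocks: int | None = None,
        d_error: float = float("nan"),
        seed: int = 0,
    ) -> "ChoiceDesign":
        tasks = []
        for task_id, grp in frame.groupby("task_id", sort=True):
            grp = grp.set_index("alternative")
            profs = {}
            for alt in ("A", "B"):
                row = grp.loc[alt]
                profs[alt] = PatientProfile.from_dict(
                    {a.name: str(row[a.name]) for a in attributes}, attributes
                )
            first = grp.iloc[0]
            rep = first["repeat_of"]
            rep = None if (pd.isna(rep) or str(rep) == "") else int(float(rep))
            tasks.append(
                ChoiceTask(
                    task_id=int(task_id),
                    block_id=int(first["block_id"]),
                    profile_a=profs["A"],
                    profile_b=profs["B"],
                    task_type=str(first["task_type"]),
                    repeat_of=rep,
                )
            )
        blocks = n_blocks or frame["block_id"].nunique()
        return cls(list(attributes), tasks, int(blocks), d_error, seed)

    @classmethod
    def from_csv(
        cls, path: str | Path, attributes: Sequence[AttributeSpec]
    ) -> "ChoiceDesign":
        return cls.from_frame(pd.read_csv(path, dtype={"repeat_of": "object"}), attributes)


def enumerate_full_factorial(
    attributes: Sequence[AttributeSpec],
) -> list[PatientProfile]:
    """All level combinations, lexicographic by attribute then level order."""
    if not attributes:
        raise ConfigError("empty attribute list")
    for a in attributes:
        if a.n_levels < 2:
            raise ConfigError(f"attribute {a.name!r} has <2 levels")
    names = [a.name for a in attributes]
    profiles = []
    for combo in itertools.product(*(a.levels for a in attributes)):
        profiles.append(PatientProfile(tuple(zip(names, combo))))
    return profiles


def profile_vector(
    profile: PatientProfile, attributes: Sequence[AttributeSpec]
) -> np.ndarray:
    """Dummy coding of a profile against each attribute's reference (no intercept)."""
    out = []
    for a in attributes:
        lev = profile.level(a.name)
        out.extend(1.0 if lev == l else 0.0 for l in a.non_reference_levels())
    return np.asarray(out)


def dominates(
    p: PatientProfile, q: PatientProfile, attributes: Sequence[AttributeSpec]
) -> bool:
    """True iff ``p`` weakly beats ``q`` on every ordinal attribute, strictly on
    at least one, with all non-ordinal attributes held equal."""
    strict = False
    for a in attributes:
        lp, lq = p.level(a.name), q.level(a.name)
        if not a.ordinal:
            if lp != lq:
                return False
            continue
        rp, rq = a.rank(lp), a.rank(lq)
        if rp < rq:
            return False
        if rp > rq:
            strict = True
    return strict


def _information(
    tasks: Iterable[ChoiceTask],
    attributes: Sequence[AttributeSpec],
    beta: np.ndarray,
) -> np.ndarray:
    K = beta.size
    M = np.zeros((K, K))
    for t in tasks:
        d = profile_vector(t.profile_a, attributes) - profile_vector(
            t.profile_b, attributes
        )
        p = 1.0 / (1.0 + math.exp(-float(d @ beta)))
        M += p * (1.0 - p) * np.outer(d, d)
    return M


def d_error(design: ChoiceDesign, prior_beta: np.ndarray | None = None) -> float:
    """D-error of the paired conditional logit at ``prior_beta`` over standard tasks."""
    std = design.standard_tasks()
    if not std:
        raise DesignError("design has no standard tasks")
    K = len(column_names(design.attributes, intercept=False))
    beta = np.zeros(K) if prior_beta is None else np.asarray(prior_beta, dtype=float)
    if beta.size != K:
        raise ConfigError(f"prior_beta has size {beta.size}, expected {K}")
    M = _information(std, design.attributes, beta)
    sign, logdet = np.linalg.slogdet(M)
    if sign <= 0:
        raise SingularDesignError("singular information matrix")
    return math.exp(-logdet / K)


def _random_pair(
    rng: np.random.Generator,
    attributes: Sequence[AttributeSpec],
    max_tries: int = 1000,
) -> tuple[PatientProfile, PatientProfile]:
    names = [a.name for a in attributes]
    for _ in range(max_tries):
        pa = PatientProfile(
            tuple((n, a.levels[rng.integers(a.n_levels)]) for n, a in zip(names, attributes))
        )
        pb = PatientProfile(
            tuple((n, a.levels[rng.integers(a.n_levels)]) for n, a in zip(names, attributes))
        )
        if pa == pb:
            continue
        if dominates(pa, pb, attributes) or dominates(pb, pa, attributes):
            continue
        return pa, pb
    raise DesignError(
        "could not draw a distinct non-dominated profile pair; "
        "attribute space too small"
    )


def _valid_pair(
    pa: PatientProfile, pb: PatientProfile, attributes: Sequence[AttributeSpec]
) -> bool:
    if pa == pb:
        return False
    return not (dominates(pa, pb, attributes) or dominates(pb, pa, attributes))


def _try_d_error(design: ChoiceDesign, beta: np.ndarray) -> float:
    try:
        return d_error(design, beta)
    except SingularDesignError:
        return float("inf")


def generate_design(
    attributes: Sequence[AttributeSpec],
    n_tasks: int,
    n_blocks: int,
    prior_beta: np.ndarray | None = None,
    n_sweeps: int = 10,
    seed: int = 0,
) -> ChoiceDesign:
    """Coordinate-exchange search for a low-D-error blocked paired design.

    Starts from a random feasible design and accepts the first strictly
    improving level swap in a seeded sweep order, so the returned design never
    has a higher D-error than its random starting point.  Tasks are then dealt
    into ``n_blocks`` equal blocks.
    """
    if n_tasks % n_blocks != 0:
        raise ConfigError(f"n_tasks={n_tasks} not divisible by n_blocks={n_blocks}")
    if n_sweeps < 1:
        raise ConfigError("n_sweeps must be >= 1")
    rng = np.random.default_rng(seed)
    K = len(column_names(attributes, intercept=False))
    beta = np.zeros(K) if prior_beta is None else np.asarray(prior_beta, dtype=float)

    pairs = [_random_pair(rng, attributes) for _ in range(n_tasks)]

    def make(pairs_) -> ChoiceDesign:
        tasks = [
            ChoiceTask(i + 1, 1 + i % n_blocks, pa, pb) for i, (pa, pb) in enumerate(pairs_)
        ]
        return ChoiceDesign(list(attributes), tasks, n_blocks, float("nan"), seed)

    current = _try_d_error(make(pairs), beta)
    start_error = current
    for _ in range(n_sweeps):
        improved = False
        for ti in rng.permutation(n_tasks):
            for side in rng.permutation(2):
                for ai in rng.permutation(len(attributes)):
                    attr = attributes[ai]
                    pa, pb = pairs[ti]
                    target = pa if side == 0 else pb
                    cur_level = target.level(attr.name)
                    for lev in attr.levels:
                        if lev == cur_level:
                            continue
                        new_assign = tuple(
                            (n, lev if n == attr.name else l)
                            for n, l in target.assignment
                        )
                        cand = PatientProfile(new_assign)
                        new_pair = (cand, pb) if side == 0 else (pa, cand)
                        if not _valid_pair(new_pair[0], new_pair[1], attributes):
                            continue
                        pairs[ti] = new_pair
                        val = _try_d_error(make(pairs), beta)
                        if val < current:
                            current = val
                            improved = True
                            break
                        pairs[ti] = (pa, pb)
                    else:
                        continue
                    break
        if not improved:
            break

    if not math.isinf(start_error) and current > start_error + 1e-12:
        raise DesignError("coordinate exchange worsened the design")  # pragma: no cover

    # deal tasks into equal blocks in a seeded random order, renumber by block
    order = rng.permutation(n_tasks)
    per_block = n_tasks // n_blocks
    tasks: list[ChoiceTask] = []
    tid = 1
    for b in range(n_blocks):
        for i in order[b * per_block : (b + 1) * per_block]:
            pa, pb = pairs[i]
            tasks.append(ChoiceTask(tid, b + 1, pa, pb))
            tid += 1
    return ChoiceDesign(list(attributes), tasks, n_blocks, current, seed)


def _dominance_pair(
    rng: np.random.Generator, attributes: Sequence[AttributeSpec]
) -> tuple[PatientProfile, PatientProfile]:
    """Build (dominant, dominated): strictly better on every ordinal attribute,
    equal on the rest."""
    hi, lo = [], []
    for a in attributes:
        if a.ordinal:
            r1, r2 = sorted(rng.choice(a.n_levels, size=2, replace=False))
            hi.append((a.name, a.levels[r2]))
            lo.append((a.name, a.levels[r1]))
        else:
            lev = a.levels[rng.integers(a.n_levels)]
            hi.append((a.name, lev))
            lo.append((a.name, lev))
    return PatientProfile(tuple(hi)), PatientProfile(tuple(lo))


def inject_quality_tasks(design: ChoiceDesign, seed: int = 0) -> ChoiceDesign:
    """Add one warm-up, one dominance and one repeat task to every block.

    Raises if a block already holds a warm-up (injection is not repeatable) or
    if no ordinal attribute is configured.
    """
    if not any(a.ordinal for a in design.attributes):
        raise ConfigError("no ordinal attribute: cannot build a dominance task")
    for t in design.tasks:
        if t.task_type == "warmup":
            raise DesignError(
                f"block {t.block_id} already contains a warm-up task; "
                "quality tasks may be injected only once"
            )
    rng = np.random.default_rng(seed)
    tasks = list(design.tasks)
    next_id = max(t.task_id for t in tasks) + 1
    for b in range(1, design.n_blocks + 1):
        std = design.standard_tasks(b)
        if not std:
            raise DesignError(f"block {b} has no standard tasks")
        wa, wb = _random_pair(rng, design.attributes)
        tasks.append(ChoiceTask(next_id, b, wa, wb, "warmup"))
        next_id += 1
        dom, sub = _dominance_pair(rng, design.attributes)
        if rng.integers(2) == 0:
            tasks.append(ChoiceTask(next_id, b, dom, sub, "dominance"))
        else:
            tasks.append(ChoiceTask(next_id, b, sub, dom, "dominance"))
        next_id += 1
        src = std[rng.integers(len(std))]
        tasks.append(
            ChoiceTask(next_id, b, src.profile_a, src.profile_b, "repeat", src.task_id)
        )
        next_id += 1
    return ChoiceDesign(
        design.attributes, tasks, design.n_blocks, design.d_error, design.seed
    )


def level_balance(design: ChoiceDesign) -> pd.DataFrame:
    """Diagnostic: appearance count of every level across standard tasks."""
    rows = []
    for a in design.attributes:
        counts = {l: 0 for l in a.levels}
        for t in design.standard_tasks():
            counts[t.profile_a.level(a.name)] += 1
            counts[t.profile_b.level(a.name)] += 1
        for l, c in counts.items():
            rows.append({"attribute": a.name, "level": l, "count": c})
    return pd.DataFrame(rows)
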
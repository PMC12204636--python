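"""Simulated patient cohorts for exercising the screening-validation pipeline.

A cohort is a pandas DataFrame with one row per patient: true cognitive
status, per-task drawing correctness, total battery score, and demographic
covariates.  Status is Bernoulli(prevalence); task correctness is independent
Bernoulli given status (impairment raises every failure probability);
covariates are drawn from categorical/normal marginals and by default carry
no effect on the score, so regression specificity is testable.

The closed-form oracle enumerates the eight correctness patterns per status
(probabilities multiply across tasks), giving exact screening metrics and AUC
with no simulation — the Monte-Carlo convergence target for every
simulation-based estimate downstream.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .drawing import TASKS
from .scoring import ScreenPolicy, TaskRubric, score_battery

COHORT_COLUMNS = ("id", "status", "cube", "infinity", "clock", "score",
                  "age", "sex", "education", "employment", "ethnicity", "exam")

#: Default demographic marginals (proportions of a 46-patient clinic cohort).
DEFAULT_COVARIATES: dict[str, dict[str, float]] = {
    "sex": {"female": 24 / 46, "male": 22 / 46},
    "education": {"secondary": 36 / 46, "postsecondary": 8 / 46,
                  "less-than-secondary": 2 / 46},
    "employment": {"employed": 29 / 46, "unemployed": 17 / 46},
    "ethnicity": {"caucasian": 31 / 46, "indigenous": 6 / 46, "indian": 4 / 46,
                  "filipino": 3 / 46, "european": 1 / 46, "african": 1 / 46},
    "exam": {"ACE-3": 35 / 46, "MoCA": 11 / 46},
}


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions for one simulated cohort.

    ``task_fail`` maps task -> (P(incorrect | intact), P(incorrect | impaired));
    impairment must not lower a failure probability.  The default failure
    probabilities encode a clearly-but-imperfectly separating battery: intact
    patients rarely fail any task, impaired patients often fail the clock and
    frequently fail the copying tasks.
    """

    n: int = 46
    prevalence: float = 17 / 46
    task_fail: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"cube": (0.05, 0.40),
                                 "infinity": (0.10, 0.45),
                                 "clock": (0.08, 0.60)})
    age_mean: Mapping[str, float] = field(
        default_factory=lambda: {"intact": 49.1, "impaired": 49.1})
    age_sd: float = 15.0
    covariates: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_COVARIATES.items()})
    age_impairment_interaction: float = 0.0  # per-task fail-prob shift per z(age), impaired only
    rubric: TaskRubric = field(default_factory=TaskRubric)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be at least 1")
        if not (0.0 <= self.prevalence <= 1.0):
            raise ValueError("prevalence must lie in [0, 1]")
        if set(self.task_fail) != set(TASKS):
            raise ValueError(f"task_fail must cover exactly {TASKS}")
        for task, (p_int, p_imp) in self.task_fail.items():
            if not (0.0 <= p_int <= 1.0 and 0.0 <= p_imp <= 1.0):
                raise ValueError(f"{task}: probabilities must lie in [0, 1]")
            if p_imp < p_int:
                raise ValueError(f"{task}: impairment must not reduce the failure "
                                 f"probability ({p_imp} < {p_int})")
        for name, dist in self.covariates.items():
            if abs(sum(dist.values()) - 1.0) > 1e-6:
                raise ValueError(f"covariate {name!r} probabilities must sum to 1")


def with_status_effect(spec: CohortSpec, effect: float) -> CohortSpec:
    """Respecify impaired failure probabilities for a target mean-score gap.

    Returns a copy whose expected score difference (intact minus impaired)
    equals ``effect`` points, split across tasks in proportion to nothing in
    particular — the same per-task failure-probability increment d, so that
    sum(points) * d = effect.
    """
    d = effect / spec.rubric.max_total
    new_fail = {}
    for task, (p_int, _) in spec.task_fail.items():
        p_imp = p_int + d
        if not (0.0 <= p_imp <= 1.0):
            raise ValueError(f"effect {effect} drives {task} probability out of [0,1]")
        new_fail[task] = (p_int, p_imp)
    return replace(spec, task_fail=new_fail)


def simulate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw one cohort; deterministic per ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    impaired = rng.random(n) < spec.prevalence
    status = np.where(impaired, "impaired", "intact")
    age = np.where(impaired,
                   rng.normal(spec.age_mean["impaired"], spec.age_sd, n),
                   rng.normal(spec.age_mean["intact"], spec.age_sd, n))
    data: dict = {"id": [f"p{i:05d}" for i in range(n)], "status": status,
                  "age": np.round(age, 1)}

    z_age = (age - np.mean(list(spec.age_mean.values()))) / spec.age_sd
    correctness = {}
    for task in TASKS:
        p_int, p_imp = spec.task_fail[task]
        p_fail = np.where(impaired, p_imp, p_int).astype(float)
        if spec.age_impairment_interaction:
            p_fail = np.where(impaired,
                              np.clip(p_fail + spec.age_impairment_interaction * z_age, 0, 1),
                              p_fail)
        correctness[task] = rng.random(n) >= p_fail
        data[task] = correctness[task]
    data["score"] = [score_battery({t: bool(correctness[t][i]) for t in TASKS},
                                   spec.rubric) for i in range(n)]

    for name, dist in spec.covariates.items():
        levels = list(dist)
        probs = np.array([dist[lv] for lv in levels], dtype=float)
        probs = probs / probs.sum()
        data[name] = rng.choice(levels, size=n, p=probs)
    return pd.DataFrame(data)[list(COHORT_COLUMNS)]


def validate_cohort(df: pd.DataFrame, rubric: TaskRubric = TaskRubric()) -> None:
    """Check the cohort-table contract (columns, score consistency)."""
    missing = set(COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"cohort table is missing columns: {sorted(missing)}")
    expected = df.apply(lambda r: score_battery(
        {t: bool(r[t]) for t in TASKS}, rubric), axis=1)
    if not (expected == df["score"]).all():
        raise ValueError("score column inconsistent with task correctness under the rubric")


# ---------------------------------------------------------------------------
# closed-form oracle
# ---------------------------------------------------------------------------

def score_distributions(spec: CohortSpec) -> dict[str, dict[int, float]]:
    """Exact score pmf per status by enumerating the 8 correctness patterns."""
    pmf: dict[str, dict[int, float]] = {}
    for status_idx, status in enumerate(("intact", "impaired")):
        dist: dict[int, float] = {}
        for pattern in itertools.product([False, True], repeat=len(TASKS)):
            prob = 1.0
            for task, correct in zip(TASKS, pattern):
                p_fail = spec.task_fail[task][status_idx]
                prob *= (1.0 - p_fail) if correct else p_fail
            s = score_battery(dict(zip(TASKS, pattern)), spec.rubric)
            dist[s] = dist.get(s, 0.0) + prob
        pmf[status] = dist
    return pmf


def closed_form_performance(spec: CohortSpec,
                            policy: ScreenPolicy | None = None) -> dict:
    """Exact sensitivity/specificity/accuracy/PPV/NPV and AUC — no simulation.

    AUC is the concordance P(score_impaired < score_intact) + half the tie
    probability, i.e. the population value of the empirical (-score) ROC.
    """
    policy = policy or ScreenPolicy(rubric=spec.rubric)
    pmf = score_distributions(spec)
    prev = spec.prevalence

    def p_positive(status: str) -> float:
        cut = (lambda s: s <= policy.threshold) if policy.inclusive \
            else (lambda s: s < policy.threshold)
        return sum(p for s, p in pmf[status].items() if cut(s))

    sens = p_positive("impaired")
    spec_ = 1.0 - p_positive("intact")
    accuracy = prev * sens + (1 - prev) * spec_
    p_pos_total = prev * sens + (1 - prev) * (1 - spec_)
    ppv = prev * sens / p_pos_total if p_pos_total > 0 else float("nan")
    p_neg_total = 1.0 - p_pos_total
    npv = (1 - prev) * spec_ / p_neg_total if p_neg_total > 0 else float("nan")

    auc = 0.0
    for s_imp, p_imp in pmf["impaired"].items():
        for s_int, p_int in pmf["intact"].items():
            if s_imp < s_int:
                auc += p_imp * p_int
            elif s_imp == s_int:
                auc += 0.5 * p_imp * p_int
    return {"sensitivity": sens, "specificity": spec_, "accuracy": accuracy,
            "ppv": ppv, "npv": npv, "auc": auc, "score_pmf": pmf,
            "threshold": policy.threshold}
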
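"""The point rubric and the threshold-based screening decision.

Each task is scored all-or-nothing: a correct cube is worth 2 points, the
overlapping infinities 1 point, and the clock 5 points; incorrect drawings
score zero, for a total of 0-8.  Screening calls a patient positive
(suspected impairment) when the total falls at or below a cut-off; the
default cut of 7 means only a perfect 8 screens negative, which is the
high-sensitivity operating point a screening examination wants.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .drawing import TASKS


@dataclass(frozen=True)
class TaskRubric:
    points: Mapping[str, int] = field(
        default_factory=lambda: {"cube": 2, "infinity": 1, "clock": 5})

    def __post_init__(self) -> None:
        if set(self.points) != set(TASKS):
            raise ValueError(f"rubric must cover exactly the tasks {TASKS}")
        if any(p <= 0 for p in self.points.values()):
            raise ValueError("all task point values must be positive")

    @property
    def max_total(self) -> int:
        return sum(self.points.values())

    def reachable_scores(self) -> tuple[int, ...]:
        """All totals attainable by some correctness pattern (2^3 patterns)."""
        totals = set()
        for mask in range(8):
            totals.add(sum(p for i, (t, p) in enumerate(sorted(self.points.items()))
                           if mask >> i & 1))
        return tuple(sorted(totals))


DEFAULT_RUBRIC = TaskRubric()


@dataclass(frozen=True)
class ScreenPolicy:
    """Screen positive iff total score <= threshold (or < with inclusive=False)."""

    threshold: int = 7
    inclusive: bool = True
    rubric: TaskRubric = field(default_factory=TaskRubric)

    def __post_init__(self) -> None:
        if not (0 <= self.threshold <= self.rubric.max_total):
            raise ValueError(f"threshold must lie in 0..{self.rubric.max_total}")

    @property
    def rule(self) -> str:
        op = "<=" if self.inclusive else "<"
        return f"positive iff score {op} {self.threshold}"


def score_battery(correctness: Mapping[str, bool],
                  rubric: TaskRubric = DEFAULT_RUBRIC) -> int:
    """Total score for one battery: sum of points over correctly drawn tasks."""
    missing = set(TASKS) - set(correctness)
    if missing:
        raise ValueError(f"battery is missing tasks: {sorted(missing)}")
    return sum(rubric.points[t] for t in TASKS if correctness[t])


def screen_decision(total: int, policy: ScreenPolicy = ScreenPolicy()) -> dict:
    """Apply the screening cut-off to a total score.

    Returns ``{"decision": "positive"|"negative", "rule": ...}`` with the rule
    that produced it, so reports are self-describing.
    """
    if not (0 <= total <= policy.rubric.max_total):
        raise ValueError(f"score {total} outside 0..{policy.rubric.max_total}")
    positive = total <= policy.threshold if policy.inclusive else total < policy.threshold
    return {"decision": "positive" if positive else "negative",
            "threshold": policy.threshold, "rule": policy.rule}
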
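"""Two-arm rating-scale comparison: pooled z-tests, attrition, feedback.

The embedded trial randomised Delphi panellists 1:1 to a 5-point or a
9-point importance scale and compared, per round, the proportion of
candidate outcomes reaching the a priori consensus criterion in each arm.
The test statistic is the classic pooled two-proportion z:

    z = (p1 - p2) / sqrt( p (1 - p) (1/n1 + 1/n2) )

with p the pooled proportion (x1 + x2) / (n1 + n2), no continuity
correction, and a two-sided normal p-value (alpha 0.05; the analysis is
exploratory, so no multiple-testing correction is applied).  The reported
statistic is |z| alongside the signed value, matching the convention of
printing positive z regardless of direction.

Attrition is the share of round-1 panellists lost at each transition,
reported per stakeholder group and overall, per arm, as integer
percentages under round-half-up rounding.  Scale feedback (ease of use,
clarity) is tallied from closed categories with per-question denominators.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence, Union

from scipy.stats import norm

from .delphi_data import (
    CANONICAL_GROUPS,
    Participant,
    StakeholderGroup,
    ValidationError,
)
from .consensus_engine import RoundDecision, Status

__all__ = [
    "DegenerateComparisonError",
    "ProportionComparison",
    "two_proportion_z",
    "compare_round_consensus",
    "compare_preliminary_cos",
    "AttritionTable",
    "attrition_rates",
    "attrition_comparison",
    "feedback_tally",
    "round_half_up",
    "TRANSITIONS",
]

#: Attrition transitions, in chronological order.
TRANSITIONS = ("r1_to_r2", "r2_to_r3", "overall")


class DegenerateComparisonError(ValueError):
    """Raised when the pooled proportion is 0 or 1 (zero pooled variance)."""


def round_half_up(value: float) -> int:
    """Round to the nearest integer with halves away from zero (upward).

    Spreadsheet-style rounding, used for all printed integer percentages
    (e.g. 24.75 -> 25, 31.68 -> 32, 39.42 -> 39); Python's built-in
    ``round`` rounds halves to even and would disagree on exact halves.
    """
    return int(math.floor(value + 0.5)) if value >= 0 else -int(math.floor(-value + 0.5))


@dataclass(frozen=True)
class ProportionComparison:
    """Inputs and results of one pooled two-proportion z comparison.

    ``p1``/``n1`` refer to the first arm (the 5-point survey in all study
    comparisons), ``p2``/``n2`` to the second.  ``z`` is signed (positive
    when p1 > p2); ``z_abs`` is the reported magnitude.
    """

    x1: int
    n1: int
    x2: int
    n2: int

    def __post_init__(self) -> None:
        for x, n, label in ((self.x1, self.n1, "1"), (self.x2, self.n2, "2")):
            if n <= 0:
                raise ValidationError(f"n{label} must be positive, got {n}")
            if not 0 <= x <= n:
                raise ValidationError(f"need 0 <= x{label} <= n{label}, got {x}/{n}")

    @property
    def p1(self) -> float:
        return self.x1 / self.n1

    @property
    def p2(self) -> float:
        return self.x2 / self.n2

    @property
    def pooled_p(self) -> float:
        return (self.x1 + self.x2) / (self.n1 + self.n2)

    @property
    def z(self) -> float:
        p = self.pooled_p
        if p in (0.0, 1.0):
            raise DegenerateComparisonError(
                f"pooled proportion {p} gives zero variance; comparison is degenerate"
            )
        se = math.sqrt(p * (1.0 - p) * (1.0 / self.n1 + 1.0 / self.n2))
        return (self.p1 - self.p2) / se

    @property
    def z_abs(self) -> float:
        return abs(self.z)

    @property
    def p_value(self) -> float:
        """Two-sided tail probability of the standard normal at |z|."""
        return 2.0 * float(norm.sf(self.z_abs))

    def as_dict(self) -> dict:
        return {
            "x1": self.x1,
            "n1": self.n1,
            "x2": self.x2,
            "n2": self.n2,
            "p1": self.p1,
            "p2": self.p2,
            "pooled_p": self.pooled_p,
            "z": self.z,
            "z_abs": self.z_abs,
            "p_value": self.p_value,
        }


def two_proportion_z(x1: int, n1: int, x2: int, n2: int) -> ProportionComparison:
    """Pooled two-proportion z comparison of x1/n1 versus x2/n2.

    Raises :class:`DegenerateComparisonError` (when accessed) if the pooled
    proportion is 0 or 1.  The z computation is validated eagerly so the
    error surfaces at construction.
    """
    comparison = ProportionComparison(x1=int(x1), n1=int(n1), x2=int(x2), n2=int(n2))
    comparison.z  # trigger degenerate check eagerly
    return comparison


def compare_round_consensus(
    decision: RoundDecision, round: int, arms: Sequence[str] = ("5pt", "9pt")
) -> ProportionComparison:
    """Compare the per-arm proportions of outcomes reaching consensus in a round.

    x = consensus count, n = possible-outcome count (outcomes actually
    rated), per arm.
    """
    arm1, arm2 = arms
    return two_proportion_z(
        decision.in_count(arm1, round),
        decision.possible_count(arm1, round),
        decision.in_count(arm2, round),
        decision.possible_count(arm2, round),
    )


def compare_preliminary_cos(
    decision: RoundDecision,
    arms: Sequence[str] = ("5pt", "9pt"),
    candidate_round: int = 2,
) -> ProportionComparison:
    """Compare preliminary-COS sizes as shares of the full candidate list.

    The study expressed each arm's preliminary COS as a fraction of the 68
    outcomes on offer in round ``candidate_round`` (24/68 vs 11/68).
    """
    arm1, arm2 = arms
    return two_proportion_z(
        decision.in_count(arm1, 3),
        decision.possible_count(arm1, candidate_round),
        decision.in_count(arm2, 3),
        decision.possible_count(arm2, candidate_round),
    )


# ---------------------------------------------------------------------------
# Attrition
# ---------------------------------------------------------------------------


class AttritionTable:
    """Integer attrition percentages per (arm, group-or-overall, transition).

    ``None`` marks an undefined rate (a group with nobody enrolled at the
    transition's start) — deliberately distinct from 0%.
    """

    OVERALL = "overall"

    def __init__(self) -> None:
        self._cells: dict[tuple[str, str, str], Optional[float]] = {}

    def set(
        self, arm: str, group: str, transition: str, percent: Optional[float]
    ) -> None:
        if transition not in TRANSITIONS:
            raise ValidationError(f"unknown transition {transition!r}")
        if percent is not None and not 0 <= percent <= 100:
            raise ValidationError(f"attrition percentage {percent} outside [0, 100]")
        key = (arm, str(group), transition)
        self._cells[key] = percent

    def get(self, arm: str, group: str, transition: str) -> Optional[float]:
        return self._cells[(arm, str(group), transition)]

    def arms(self) -> list[str]:
        return sorted({a for (a, _, _) in self._cells})

    def rows(self) -> list[dict]:
        return [
            {"arm": a, "group": g, "transition": t, "percent": p}
            for (a, g, t), p in sorted(self._cells.items())
        ]


def _round_counts(participants: Sequence[Participant]) -> dict:
    counts: dict[tuple[str, Optional[StakeholderGroup], int], int] = {}
    for p in participants:
        for round in p.rounds_completed:
            counts[(p.arm, p.group, round)] = counts.get((p.arm, p.group, round), 0) + 1
            counts[(p.arm, None, round)] = counts.get((p.arm, None, round), 0) + 1
    return counts


def attrition_rates(participants: Sequence[Participant]) -> AttritionTable:
    """Per-group and overall attrition percentages, per arm.

    A transition rate is (n_start - n_end) / n_start x 100, rounded
    half-up to an integer percent; "overall" compares round 1 with round 3.
    Groups empty at the start of a transition get ``None`` (undefined),
    never 0.
    """
    counts = _round_counts(participants)
    arms = sorted({p.arm for p in participants})
    table = AttritionTable()
    transitions = {"r1_to_r2": (1, 2), "r2_to_r3": (2, 3), "overall": (1, 3)}
    for arm in arms:
        for group in list(CANONICAL_GROUPS) + [None]:
            label = group.value if group is not None else AttritionTable.OVERALL
            for name, (start, end) in transitions.items():
                n_start = counts.get((arm, group, start), 0)
                n_end = counts.get((arm, group, end), 0)
                if n_start == 0:
                    table.set(arm, label, name, None)
                else:
                    table.set(
                        arm, label, name, round_half_up(100.0 * (n_start - n_end) / n_start)
                    )
    return table


def attrition_comparison(
    participants: Sequence[Participant], arms: Sequence[str] = ("5pt", "9pt")
) -> ProportionComparison:
    """Pooled z comparison of overall (round 1 -> 3) attrition between arms.

    x = round-1 enrolees absent at round 3, n = round-1 enrolees, per arm.
    Depends only on counts, so it is invariant under participant relabelling.
    """
    counts = _round_counts(participants)
    values = []
    for arm in arms:
        n1 = counts.get((arm, None, 1), 0)
        n3 = counts.get((arm, None, 3), 0)
        if n1 == 0:
            raise ValidationError(f"arm {arm!r} has no round-1 participants")
        values.extend([n1 - n3, n1])
    return two_proportion_z(values[0], values[1], values[2], values[3])


# ---------------------------------------------------------------------------
# Feedback tallies
# ---------------------------------------------------------------------------


def feedback_tally(
    responses: Mapping[str, Mapping[str, Mapping[str, int]]],
) -> dict[str, dict[str, dict]]:
    """Counts, denominators and integer percentages of closed feedback categories.

    ``responses[question][arm][category]`` holds raw counts (the questions
    were optional, so denominators differ per question and arm).  No text
    analysis happens here — categories are closed inputs.  Returns, per
    question and arm, each category's count and round-half-up percentage of
    that question's per-arm denominator; empty tallies yield no entries and
    no division.
    """
    result: dict[str, dict[str, dict]] = {}
    for question, by_arm in responses.items():
        result[question] = {}
        for arm, categories in by_arm.items():
            denominator = sum(categories.values())
            cells = {}
            for category, count in categories.items():
                if count < 0:
                    raise ValidationError(f"negative count for {question}/{arm}/{category}")
                cells[category] = {
                    "count": count,
                    "denominator": denominator,
                    "percent": round_half_up(100.0 * count / denominator)
                    if denominator
                    else None,
                }
            result[question][arm] = cells
    return result
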
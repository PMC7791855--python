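"""The a priori consensus criterion and multi-round Delphi filtering.

The engine implements the pre-registered inclusion rule used in the PGP-COS
Delphi: an outcome reaches consensus in a round when at least 70% of a
stakeholder group rates it "important" (at or above the arm's scale cutoff)
in at least 3 of the 5 groups, and the patient group is necessarily one of
them.  Both comparisons are ``>=``: a group at exactly 70% qualifies, and
exactly ``min_groups`` qualifying groups suffice.

Round mechanics follow the usual COS design: round 1 presents the initial
registry; round 2 re-presents everything plus outcomes minted from round-1
free-text suggestions (adjudicated externally); round 3 presents only the
outcomes that reached consensus in round 2.  The two scale arms are fully
independent surveys — a decision in one arm never reads the other arm's
data.  After round 3 each arm yields a preliminary core outcome set and the
two are unioned.

Two evaluation inputs are supported: raw rating records (exact rational
proportions are compared to the threshold, so display rounding can never
change a decision) and published percentage tables (the printed integers
are compared as given, since the underlying counts were never published).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from fractions import Fraction
from typing import Iterable, Mapping, Optional, Sequence, Union

from .delphi_data import (
    CANONICAL_GROUPS,
    AdjudicatedSuggestion,
    GroupProportionTable,
    Outcome,
    OutcomeSource,
    RatingRecord,
    RatingScale,
    StakeholderGroup,
    SuggestionDecision,
    ValidationError,
)

__all__ = [
    "Status",
    "ConsensusRule",
    "RoundDecision",
    "importance_proportion",
    "group_consensus",
    "evaluate_round",
    "next_round_outcomes",
    "merge_suggestions",
    "preliminary_cos",
    "PreliminaryCOS",
    "overlap_count",
    "track_source_outcomes",
    "SourceTrackingSummary",
]


class Status(str, Enum):
    """Per-(outcome, arm, round) consensus status."""

    IN = "in"
    OUT = "out"
    NOT_RATED = "not_rated"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class ConsensusRule:
    """Parameters of the a priori consensus criterion.

    Defaults encode the pre-registered PGP-COS rule: >= 70% important in
    >= 3 of 5 stakeholder groups, the patient group mandatory.
    """

    importance_threshold: float = 0.70
    min_groups: int = 3
    total_groups: int = 5
    mandatory_groups: frozenset[StakeholderGroup] = frozenset({StakeholderGroup.PATIENT})

    def __post_init__(self) -> None:
        if not 0 < self.importance_threshold <= 1:
            raise ValidationError(
                f"importance_threshold must be in (0, 1], got {self.importance_threshold}"
            )
        mandatory = frozenset(StakeholderGroup(g) for g in self.mandatory_groups)
        object.__setattr__(self, "mandatory_groups", mandatory)
        if not mandatory <= set(CANONICAL_GROUPS):
            raise ValidationError("mandatory_groups must be canonical stakeholder groups")
        if not len(mandatory) <= self.min_groups <= self.total_groups:
            raise ValidationError(
                f"need |mandatory_groups| <= min_groups <= total_groups, got "
                f"{len(mandatory)} <= {self.min_groups} <= {self.total_groups}"
            )

    @property
    def threshold_percent(self) -> float:
        return 100.0 * self.importance_threshold

    @classmethod
    def from_dict(cls, data: Mapping) -> "ConsensusRule":
        return cls(
            importance_threshold=float(data.get("importance_threshold", 0.70)),
            min_groups=int(data.get("min_groups", 3)),
            total_groups=int(data.get("total_groups", 5)),
            mandatory_groups=frozenset(
                StakeholderGroup(g) for g in data.get("mandatory_groups", ["patient"])
            ),
        )

    def to_dict(self) -> dict:
        return {
            "importance_threshold": self.importance_threshold,
            "min_groups": self.min_groups,
            "total_groups": self.total_groups,
            "mandatory_groups": sorted(g.value for g in self.mandatory_groups),
        }


class RoundDecision:
    """In/out/not-rated status of every outcome per arm and round.

    ``not_rated`` marks rounds before an outcome entered the survey and
    rounds it did not survive into; it is distinct from ``out`` (rated but
    below the criterion).
    """

    def __init__(self) -> None:
        self._entries: dict[tuple[str, str, int], Status] = {}

    def set(self, outcome_id: str, arm: str, round: int, status: Union[str, Status]) -> None:
        self._entries[(outcome_id, arm, int(round))] = Status(status)

    def status(self, outcome_id: str, arm: str, round: int) -> Status:
        return self._entries.get((outcome_id, arm, int(round)), Status.NOT_RATED)

    def arms(self) -> list[str]:
        return sorted({arm for (_, arm, _) in self._entries})

    def rounds(self) -> list[int]:
        return sorted({r for (_, _, r) in self._entries})

    def outcome_ids(self) -> list[str]:
        return sorted({o for (o, _, _) in self._entries})

    def outcomes_with_status(self, arm: str, round: int, status: Status) -> list[str]:
        return sorted(
            o
            for (o, a, r), s in self._entries.items()
            if a == arm and r == int(round) and s is status
        )

    def in_count(self, arm: str, round: int) -> int:
        return len(self.outcomes_with_status(arm, round, Status.IN))

    def possible_count(self, arm: str, round: int) -> int:
        """Number of outcomes actually rated (in or out) in a round/arm."""
        return len(self.outcomes_with_status(arm, round, Status.IN)) + len(
            self.outcomes_with_status(arm, round, Status.OUT)
        )

    def update(self, other: "RoundDecision") -> None:
        self._entries.update(other._entries)

    def to_rows(self) -> list[dict]:
        """Long-format export (one row per outcome/arm/round), sorted."""
        return [
            {"outcome_id": o, "arm": a, "round": r, "status": s.value}
            for (o, a, r), s in sorted(self._entries.items())
        ]


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------


def importance_proportion(
    records: Iterable[RatingRecord],
    outcome_id: str,
    group: Union[str, StakeholderGroup],
    round: int,
    scale: RatingScale,
) -> Optional[float]:
    """Percentage of a group's raters scoring an outcome at/above the cutoff.

    The denominator is the number of the group's members who rated that
    specific outcome in that round in the scale's arm (partial responses
    reduce the denominator per outcome).  Returns ``None`` when the group
    has no raters — an empty group is a distinct state from 0%.
    """
    group = StakeholderGroup(group)
    total = 0
    important = 0
    for rec in records:
        if (
            rec.outcome_id == outcome_id
            and rec.group is group
            and rec.round == int(round)
            and rec.arm == scale.scale_id
        ):
            total += 1
            if scale.is_important(rec.rating):
                important += 1
    if total == 0:
        return None
    return 100.0 * important / total


def _exact_proportions(
    records: Sequence[RatingRecord], outcome_id: str, round: int, scale: RatingScale
) -> dict[StakeholderGroup, Optional[Fraction]]:
    """Per-group importance proportions as exact rationals (None = no raters)."""
    totals: dict[StakeholderGroup, int] = {g: 0 for g in CANONICAL_GROUPS}
    important: dict[StakeholderGroup, int] = {g: 0 for g in CANONICAL_GROUPS}
    for rec in records:
        if (
            rec.outcome_id == outcome_id
            and rec.round == int(round)
            and rec.arm == scale.scale_id
        ):
            totals[rec.group] += 1
            if scale.is_important(rec.rating):
                important[rec.group] += 1
    return {
        g: (Fraction(important[g], totals[g]) if totals[g] else None)
        for g in CANONICAL_GROUPS
    }


def group_consensus(
    proportions: Mapping[StakeholderGroup, Optional[Union[float, Fraction]]],
    rule: ConsensusRule = ConsensusRule(),
) -> bool:
    """Apply the consensus criterion to one outcome's per-group percentages.

    ``proportions`` maps every canonical group to a percentage in [0, 100]
    (float or exact :class:`~fractions.Fraction`) or ``None`` for a group
    with no respondents.  An empty group never meets the threshold and can
    never satisfy a mandatory-group requirement: consensus cannot be
    claimed from absent voices.  Comparison is ``>=`` with no re-rounding
    of the supplied values; the threshold is compared as an exact rational
    so a printed value of exactly 70 qualifies under the default rule.
    """
    threshold = Fraction(rule.importance_threshold).limit_denominator(10**6) * 100
    qualifying = {
        StakeholderGroup(g)
        for g, value in proportions.items()
        if value is not None and value >= threshold
    }
    if len(qualifying) < rule.min_groups:
        return False
    return rule.mandatory_groups <= qualifying


def evaluate_round(
    data: Union[Sequence[RatingRecord], GroupProportionTable],
    candidates: Iterable[Union[str, Outcome]],
    round: int,
    arm: str,
    rule: ConsensusRule = ConsensusRule(),
    scale: Optional[RatingScale] = None,
) -> RoundDecision:
    """Decide in/out for every candidate outcome of one round in one arm.

    ``data`` is either raw rating records (requires ``scale``; exact
    rational proportions are compared to the threshold) or a published
    :class:`GroupProportionTable` (printed percentages compared as given).
    Candidates with no ratings at all are flagged ``not_rated`` and do not
    enter the possible-outcome count.  Only records of the requested arm
    are read, so arms remain fully independent.
    """
    decision = RoundDecision()
    candidate_ids = [c.outcome_id if isinstance(c, Outcome) else c for c in candidates]

    if isinstance(data, GroupProportionTable):
        for outcome_id in candidate_ids:
            percents = data.group_percents(outcome_id, round, arm)
            if all(v is None for v in percents.values()):
                decision.set(outcome_id, arm, round, Status.NOT_RATED)
                continue
            ok = group_consensus(percents, rule)
            decision.set(outcome_id, arm, round, Status.IN if ok else Status.OUT)
        return decision

    if scale is None:
        raise ValueError("scale is required when evaluating raw rating records")
    if scale.scale_id != arm:
        raise ValueError(f"scale {scale.scale_id!r} does not match arm {arm!r}")
    for outcome_id in candidate_ids:
        fractions = _exact_proportions(data, outcome_id, round, scale)
        if all(v is None for v in fractions.values()):
            decision.set(outcome_id, arm, round, Status.NOT_RATED)
            continue
        # exact rational comparison: 7/10 of a group >= 70% with no rounding
        percents = {g: (None if f is None else f * 100) for g, f in fractions.items()}
        ok = group_consensus(percents, rule)
        decision.set(outcome_id, arm, round, Status.IN if ok else Status.OUT)
    return decision


# ---------------------------------------------------------------------------
# Round transitions
# ---------------------------------------------------------------------------


def next_round_outcomes(
    decision: RoundDecision,
    round: int,
    mode: str,
    arm: Optional[str] = None,
) -> Union[list[str], dict[str, list[str]]]:
    """Outcomes carried from ``round`` into the next round.

    ``mode="carry_all"`` re-presents every rated outcome regardless of
    status (the round 1 -> 2 transition); ``mode="filter"`` keeps only the
    outcomes that reached consensus (round 2 -> 3).  Per-arm lists may
    differ because the arms are independent surveys.  With ``arm=None``
    a dict over all arms in the decision is returned.
    """
    if mode not in ("carry_all", "filter"):
        raise ValueError("mode must be 'carry_all' or 'filter'")

    def _one(a: str) -> list[str]:
        kept = decision.outcomes_with_status(a, round, Status.IN)
        if mode == "carry_all":
            kept = sorted(set(kept) | set(decision.outcomes_with_status(a, round, Status.OUT)))
        return kept

    if arm is not None:
        return _one(arm)
    return {a: _one(a) for a in decision.arms()}


def merge_suggestions(
    suggestions: Iterable[AdjudicatedSuggestion],
    registry: Sequence[Outcome],
) -> list[Outcome]:
    """Fold adjudicated round-1 suggestions into the outcome registry.

    ``include_new`` suggestions mint outcomes with ``first_round=2``
    (offered to both arms in round 2); ``already_included`` and
    ``not_an_outcome`` leave the registry unchanged.  The engine never
    classifies free text — decisions are inputs.  Duplicate mints of an
    existing id or display name raise, demanding explicit adjudication.
    """
    merged = list(registry)
    ids = {o.outcome_id for o in merged}
    names = {o.name.casefold() for o in merged}
    for suggestion in suggestions:
        if suggestion.decision is SuggestionDecision.ALREADY_INCLUDED:
            if suggestion.mapped_outcome_id not in ids:
                raise ValidationError(
                    f"suggestion maps to unknown outcome {suggestion.mapped_outcome_id!r}"
                )
            continue
        if suggestion.decision is SuggestionDecision.NOT_AN_OUTCOME:
            continue
        assert suggestion.new_outcome_id and suggestion.new_outcome_name
        if suggestion.new_outcome_id in ids or suggestion.new_outcome_name.casefold() in names:
            raise ValidationError(
                f"new outcome {suggestion.new_outcome_id!r} duplicates an existing "
                f"outcome; adjudicate explicitly as already_included"
            )
        outcome = Outcome(
            outcome_id=suggestion.new_outcome_id,
            name=suggestion.new_outcome_name,
            sources=frozenset({OutcomeSource.ROUND1_SUGGESTION}),
            first_round=2,
        )
        merged.append(outcome)
        ids.add(outcome.outcome_id)
        names.add(outcome.name.casefold())
    return merged


@dataclass
class PreliminaryCOS:
    """Per-arm preliminary core outcome sets and their deduplicated union."""

    per_arm: dict[str, list[str]]
    union: list[str]

    def size(self, arm: str) -> int:
        return len(self.per_arm[arm])


def preliminary_cos(decision: RoundDecision, final_round: int = 3) -> PreliminaryCOS:
    """Outcomes reaching consensus in the final round, per arm and unioned.

    An outcome enters the combined preliminary COS if it reached consensus
    on *either* survey version; the union is deduplicated by outcome id and
    sorted for reproducibility.
    """
    per_arm = {
        arm: decision.outcomes_with_status(arm, final_round, Status.IN)
        for arm in decision.arms()
    }
    union = sorted(set().union(*per_arm.values())) if per_arm else []
    return PreliminaryCOS(per_arm=per_arm, union=union)


def overlap_count(list_a: Iterable[str], list_b: Iterable[str]) -> int:
    """Size of the intersection of two outcome-id lists."""
    return len(set(list_a) & set(list_b))


# ---------------------------------------------------------------------------
# Source tracking (e.g. interview-derived outcomes)
# ---------------------------------------------------------------------------


@dataclass
class SourceTrackingSummary:
    """How outcomes from one source fared across rounds and arms.

    ``per_round[(arm, round)]`` holds ``{"in": ..., "out": ..., "not_rated": ...}``
    counts over the tagged outcomes; ``reached_preliminary`` counts those in
    the preliminary COS on at least one arm; ``reached_final`` counts those
    in a supplied final COS list (``None`` when no list was given).
    """

    source: OutcomeSource
    outcome_ids: list[str]
    per_round: dict[tuple[str, int], dict[str, int]]
    preliminary_ids: list[str]
    reached_preliminary: int
    reached_final: Optional[int] = None


def track_source_outcomes(
    decision: RoundDecision,
    registry: Sequence[Outcome],
    source: Union[str, OutcomeSource],
    final_cos: Optional[Iterable[str]] = None,
) -> SourceTrackingSummary:
    """Summarise the fate of all outcomes carrying a given source tag."""
    source = OutcomeSource(source)
    tagged = sorted(o.outcome_id for o in registry if source in o.sources)
    arms = decision.arms() or ["5pt", "9pt"]
    rounds = decision.rounds() or [1, 2, 3]
    per_round: dict[tuple[str, int], dict[str, int]] = {}
    for arm in arms:
        for round in rounds:
            counts = {"in": 0, "out": 0, "not_rated": 0}
            for oid in tagged:
                counts[decision.status(oid, arm, round).value] += 1
            per_round[(arm, round)] = counts
    prelim = preliminary_cos(decision) if tagged or decision.arms() else PreliminaryCOS({}, [])
    preliminary_ids = sorted(set(tagged) & set(prelim.union))
    reached_final = None
    if final_cos is not None:
        reached_final = overlap_count(tagged, final_cos)
    return SourceTrackingSummary(
        source=source,
        outcome_ids=tagged,
        per_round=per_round,
        preliminary_ids=preliminary_ids,
        reached_preliminary=len(preliminary_ids),
        reached_final=reached_final,
    )
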
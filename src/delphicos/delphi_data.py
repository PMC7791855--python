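"""Domain types, validation and I/O for multi-round Delphi consensus surveys.

A core outcome set (COS) Delphi presents a list of candidate outcomes to
panellists drawn from several stakeholder groups over successive survey
rounds.  Each panellist rates every outcome on an ordinal importance scale;
ratings at or above the scale's *importance cutoff* count as "important".
This module holds the building blocks shared by the whole pipeline:

* :class:`RatingScale`, :class:`StakeholderGroup`, :class:`Participant`,
  :class:`Outcome`, :class:`RatingRecord` — the validated domain types;
* :class:`GroupProportionTable` — per-(outcome, group, round, arm)
  percentages of "important" ratings, the unit of published feedback;
* :class:`AdjudicatedSuggestion` — a free-text outcome suggestion together
  with the steering-committee decision about it;
* CSV readers/writers for long-format rating records and participant
  rosters;
* :func:`load_paper_fixture` — bundled transcriptions of the published
  pelvic girdle pain (PGP) COS study tables, used for replay and testing.

All data flows in plain text (UTF-8 CSV/JSON) so that simulated panels and
transcribed study data move through identical code paths.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

__all__ = [
    "ValidationError",
    "StakeholderGroup",
    "CANONICAL_GROUPS",
    "RatingScale",
    "FIVE_POINT",
    "NINE_POINT",
    "DEFAULT_SCALES",
    "Participant",
    "Outcome",
    "OutcomeSource",
    "RatingRecord",
    "GroupProportionTable",
    "SuggestionDecision",
    "AdjudicatedSuggestion",
    "load_ratings",
    "write_ratings",
    "load_participants",
    "write_participants",
    "load_paper_fixture",
    "PanelCounts",
]


class ValidationError(ValueError):
    """Raised when input data violates a domain invariant."""


class StakeholderGroup(str, Enum):
    """The five canonical panellist categories of a COS Delphi panel."""

    CLINICIAN = "clinician"
    CLINICIAN_RESEARCHER = "clinician_researcher"
    PATIENT = "patient"
    RESEARCHER = "researcher"
    SERVICE_PROVIDER_POLICY_MAKER = "service_provider_policy_maker"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Canonical group ordering used for all tabular output.
CANONICAL_GROUPS: tuple[StakeholderGroup, ...] = tuple(StakeholderGroup)


def _coerce_group(value: Union[str, StakeholderGroup]) -> StakeholderGroup:
    if isinstance(value, StakeholderGroup):
        return value
    try:
        return StakeholderGroup(value)
    except ValueError:
        valid = ", ".join(g.value for g in StakeholderGroup)
        raise ValidationError(f"unknown stakeholder group {value!r}; valid groups: {valid}")


@dataclass(frozen=True)
class RatingScale:
    """An ordinal importance rating scale with a dichotomising cutoff.

    Parameters
    ----------
    scale_id:
        Short identifier, doubling as the trial arm label (e.g. ``"5pt"``).
    n_points:
        Number of response options (>= 2).
    labels:
        One anchor text per option.
    importance_cutoff:
        The minimum rating counted as "important" (e.g. 4 on a 5-point
        scale, 7 on a 9-point scale).
    """

    scale_id: str
    n_points: int
    labels: tuple[str, ...]
    importance_cutoff: int

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ValidationError(f"scale {self.scale_id!r}: n_points must be >= 2")
        if not (1 <= self.importance_cutoff <= self.n_points):
            raise ValidationError(
                f"scale {self.scale_id!r}: importance_cutoff {self.importance_cutoff} "
                f"outside 1..{self.n_points}"
            )
        if len(self.labels) != self.n_points:
            raise ValidationError(
                f"scale {self.scale_id!r}: expected {self.n_points} labels, "
                f"got {len(self.labels)}"
            )

    def is_important(self, rating: int) -> bool:
        """True if ``rating`` meets the importance cutoff."""
        return rating >= self.importance_cutoff


FIVE_POINT = RatingScale(
    scale_id="5pt",
    n_points=5,
    labels=(
        "not important",
        "slightly important",
        "unsure unimportant or important",
        "important",
        "very important",
    ),
    importance_cutoff=4,
)

NINE_POINT = RatingScale(
    scale_id="9pt",
    n_points=9,
    labels=(
        "not important (1)",
        "not important (2)",
        "not important (3)",
        "important but not critical (4)",
        "unsure unimportant or important (5)",
        "important but not critical (6)",
        "critically important (7)",
        "critically important (8)",
        "critically important (9)",
    ),
    importance_cutoff=7,
)

#: The two randomized arms of the embedded rating-scale trial.
DEFAULT_SCALES: tuple[RatingScale, ...] = (FIVE_POINT, NINE_POINT)


def scales_by_id(scales: Iterable[RatingScale]) -> dict[str, RatingScale]:
    return {s.scale_id: s for s in scales}


@dataclass(frozen=True)
class Participant:
    """One Delphi panellist, allocated to a single scale arm for all rounds.

    ``rounds_completed`` must be downward closed: attrition is monotone, so
    completing round 3 implies completing rounds 1 and 2.
    """

    participant_id: str
    arm: str
    group: StakeholderGroup
    rounds_completed: frozenset[int] = frozenset({1})
    demographics: Optional[Mapping[str, str]] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "group", _coerce_group(self.group))
        rounds = frozenset(int(r) for r in self.rounds_completed)
        if not rounds or not rounds <= {1, 2, 3}:
            raise ValidationError(
                f"participant {self.participant_id!r}: rounds_completed must be a "
                f"non-empty subset of {{1,2,3}}, got {sorted(rounds)}"
            )
        if rounds != set(range(1, max(rounds) + 1)):
            raise ValidationError(
                f"participant {self.participant_id!r}: rounds_completed "
                f"{sorted(rounds)} is not downward-closed (attrition is monotone)"
            )
        object.__setattr__(self, "rounds_completed", rounds)

    @property
    def last_round(self) -> int:
        return max(self.rounds_completed)


class OutcomeSource(str, Enum):
    """Where a candidate outcome entered the outcome registry from."""

    SYSTEMATIC_REVIEW = "systematic_review"
    INTERVIEW = "interview"
    ROUND1_SUGGESTION = "round1_suggestion"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class Outcome:
    """A candidate outcome with provenance annotations.

    ``first_round`` is 2 exactly for outcomes minted from round-1 free-text
    suggestions; everything identified beforehand is presented from round 1.
    """

    outcome_id: str
    name: str
    sources: frozenset[OutcomeSource]
    first_round: int = 1

    def __post_init__(self) -> None:
        sources = frozenset(OutcomeSource(s) for s in self.sources)
        if not sources:
            raise ValidationError(f"outcome {self.outcome_id!r}: sources must be non-empty")
        object.__setattr__(self, "sources", sources)
        suggestion_only = sources == {OutcomeSource.ROUND1_SUGGESTION}
        if (self.first_round == 2) != suggestion_only:
            raise ValidationError(
                f"outcome {self.outcome_id!r}: first_round must be 2 iff the sole "
                f"source is round1_suggestion"
            )
        if self.first_round not in (1, 2):
            raise ValidationError(f"outcome {self.outcome_id!r}: first_round must be 1 or 2")


@dataclass(frozen=True)
class RatingRecord:
    """One participant's rating of one outcome in one round.

    The participant's arm and stakeholder group are carried on the record so
    that aggregation never needs a roster join; the rating is validated
    against the arm's scale at load time.
    """

    participant_id: str
    outcome_id: str
    round: int
    rating: int
    arm: str
    group: StakeholderGroup

    def __post_init__(self) -> None:
        object.__setattr__(self, "group", _coerce_group(self.group))
        if self.round not in (1, 2, 3):
            raise ValidationError(
                f"rating by {self.participant_id!r}: round must be 1, 2 or 3, got {self.round}"
            )


class GroupProportionTable:
    """Percentages of "important" ratings per (outcome, group, round, arm).

    Cells absent from the table mean the outcome was not rated by that
    group in that round/arm (it had been dropped, or entered later); they
    are reported as ``None``, never as ``0``.  Optional denominators record
    how many panellists the percentage is over, when known.
    """

    def __init__(self) -> None:
        self._cells: dict[tuple[str, StakeholderGroup, int, str], float] = {}
        self._denominators: dict[tuple[str, StakeholderGroup, int, str], int] = {}

    def set(
        self,
        outcome_id: str,
        group: Union[str, StakeholderGroup],
        round: int,
        arm: str,
        percent: float,
        denominator: Optional[int] = None,
    ) -> None:
        group = _coerce_group(group)
        if not 0.0 <= percent <= 100.0:
            raise ValidationError(
                f"percentage {percent!r} for ({outcome_id}, {group}, {round}, {arm}) "
                f"outside [0, 100]"
            )
        key = (outcome_id, group, int(round), arm)
        self._cells[key] = float(percent)
        if denominator is not None:
            self._denominators[key] = int(denominator)

    def get(
        self,
        outcome_id: str,
        group: Union[str, StakeholderGroup],
        round: int,
        arm: str,
    ) -> Optional[float]:
        """The percentage, or ``None`` where the cell was not rated."""
        return self._cells.get((outcome_id, _coerce_group(group), int(round), arm))

    def denominator(
        self,
        outcome_id: str,
        group: Union[str, StakeholderGroup],
        round: int,
        arm: str,
    ) -> Optional[int]:
        return self._denominators.get((outcome_id, _coerce_group(group), int(round), arm))

    def group_percents(
        self, outcome_id: str, round: int, arm: str
    ) -> dict[StakeholderGroup, Optional[float]]:
        """All five groups' percentages for a cell block (``None`` = not rated)."""
        return {g: self.get(outcome_id, g, round, arm) for g in CANONICAL_GROUPS}

    def is_rated(self, outcome_id: str, round: int, arm: str) -> bool:
        """True if any group has a percentage for this outcome/round/arm."""
        return any(v is not None for v in self.group_percents(outcome_id, round, arm).values())

    @property
    def outcomes(self) -> list[str]:
        return sorted({key[0] for key in self._cells})

    def __len__(self) -> int:
        return len(self._cells)

    def items(self):
        return self._cells.items()


class SuggestionDecision(str, Enum):
    """Steering-committee adjudication of a free-text suggestion."""

    INCLUDE_NEW = "include_new"
    ALREADY_INCLUDED = "already_included"
    NOT_AN_OUTCOME = "not_an_outcome"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class AdjudicatedSuggestion:
    """A free-text outcome suggestion plus its external adjudication.

    The pipeline never classifies free text itself; the decision is an
    input.  ``already_included`` must name the registry outcome it maps to,
    ``include_new`` must mint a new outcome id and display name.
    """

    raw_text: str
    decision: SuggestionDecision
    mapped_outcome_id: Optional[str] = None
    new_outcome_id: Optional[str] = None
    new_outcome_name: Optional[str] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "decision", SuggestionDecision(self.decision))
        if self.decision is SuggestionDecision.ALREADY_INCLUDED and not self.mapped_outcome_id:
            raise ValidationError(
                f"suggestion {self.raw_text[:40]!r}: already_included requires mapped_outcome_id"
            )
        if self.decision is SuggestionDecision.INCLUDE_NEW and not (
            self.new_outcome_id and self.new_outcome_name
        ):
            raise ValidationError(
                f"suggestion {self.raw_text[:40]!r}: include_new requires a new outcome id and name"
            )


# ---------------------------------------------------------------------------
# CSV readers / writers
# ---------------------------------------------------------------------------

RATINGS_COLUMNS = ("participant_id", "arm", "group", "round", "outcome_id", "rating")
PARTICIPANTS_COLUMNS = (
    "participant_id",
    "arm",
    "group",
    "gender",
    "age_band",
    "country",
    "last_round",
)


def load_ratings(
    path: Union[str, Path],
    scales: Iterable[RatingScale] = DEFAULT_SCALES,
    known_outcomes: Optional[Iterable[str]] = None,
    on_error: str = "raise",
) -> list[RatingRecord]:
    """Read long-format rating records, validating each row against its arm's scale.

    Parameters
    ----------
    path:
        CSV file with header ``participant_id,arm,group,round,outcome_id,rating``.
    scales:
        The rating scales in play; a row's ``arm`` must match one of their ids.
    known_outcomes:
        If given, rows naming other outcomes are rejected.
    on_error:
        ``"raise"`` (default) aborts on the first invalid row, naming it;
        ``"skip"`` drops invalid rows and reports them on the returned
        list's ``.rejected`` attribute is not used — skipped rows are
        collected and attached to the raised/returned report.

    Returns
    -------
    list of :class:`RatingRecord` in file order.
    """
    if on_error not in ("raise", "skip"):
        raise ValueError("on_error must be 'raise' or 'skip'")
    by_id = scales_by_id(scales)
    outcome_set = set(known_outcomes) if known_outcomes is not None else None
    records: list[RatingRecord] = []
    rejected: list[tuple[int, str]] = []
    seen: set[tuple[str, str, int]] = set()
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle)
        if reader.fieldnames is None or not set(RATINGS_COLUMNS) <= set(reader.fieldnames):
            raise ValidationError(
                f"{path}: expected header with columns {', '.join(RATINGS_COLUMNS)}"
            )
        for lineno, row in enumerate(reader, start=2):
            try:
                arm = row["arm"].strip()
                if arm not in by_id:
                    raise ValidationError(
                        f"unknown arm {arm!r}; valid arms: {', '.join(sorted(by_id))}"
                    )
                scale = by_id[arm]
                outcome_id = row["outcome_id"].strip()
                if outcome_set is not None and outcome_id not in outcome_set:
                    raise ValidationError(f"unknown outcome {outcome_id!r}")
                rating = int(row["rating"])
                if not 1 <= rating <= scale.n_points:
                    raise ValidationError(
                        f"rating {rating} outside 1..{scale.n_points} for arm {arm!r}"
                    )
                record = RatingRecord(
                    participant_id=row["participant_id"].strip(),
                    outcome_id=outcome_id,
                    round=int(row["round"]),
                    rating=rating,
                    arm=arm,
                    group=row["group"].strip(),
                )
                key = (record.participant_id, record.outcome_id, record.round)
                if key in seen:
                    raise ValidationError(
                        f"duplicate rating for participant {record.participant_id!r}, "
                        f"outcome {record.outcome_id!r}, round {record.round}"
                    )
            except (ValidationError, KeyError, ValueError) as exc:
                message = f"{path}, row {lineno}: {exc}"
                if on_error == "raise":
                    raise ValidationError(message) from None
                rejected.append((lineno, message))
                continue
            seen.add(key)
            records.append(record)
    if rejected:
        import logging

        for _, message in rejected:
            logging.getLogger(__name__).warning("rejected row: %s", message)
    return records


def write_ratings(records: Iterable[RatingRecord], path: Union[str, Path]) -> None:
    """Write rating records to CSV in the canonical long-format schema."""
    with Path(path).open("w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(RATINGS_COLUMNS)
        for r in records:
            writer.writerow(
                [r.participant_id, r.arm, r.group.value, r.round, r.outcome_id, r.rating]
            )


def load_participants(
    path: Union[str, Path], scales: Iterable[RatingScale] = DEFAULT_SCALES
) -> list[Participant]:
    """Read a participant roster CSV (``last_round`` encodes monotone attrition)."""
    by_id = scales_by_id(scales)
    participants: list[Participant] = []
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle)
        if reader.fieldnames is None or "participant_id" not in reader.fieldnames:
            raise ValidationError(f"{path}: expected a participant roster header")
        for lineno, row in enumerate(reader, start=2):
            arm = row["arm"].strip()
            if arm not in by_id:
                raise ValidationError(f"{path}, row {lineno}: unknown arm {arm!r}")
            last_round = int(row["last_round"])
            demographics = {
                k: row[k] for k in ("gender", "age_band", "country") if row.get(k)
            }
            participants.append(
                Participant(
                    participant_id=row["participant_id"].strip(),
                    arm=arm,
                    group=row["group"].strip(),
                    rounds_completed=frozenset(range(1, last_round + 1)),
                    demographics=demographics or None,
                )
            )
    return participants


def write_participants(participants: Iterable[Participant], path: Union[str, Path]) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(PARTICIPANTS_COLUMNS)
        for p in participants:
            demo = p.demographics or {}
            writer.writerow(
                [
                    p.participant_id,
                    p.arm,
                    p.group.value,
                    demo.get("gender", ""),
                    demo.get("age_band", ""),
                    demo.get("country", ""),
                    p.last_round,
                ]
            )


# ---------------------------------------------------------------------------
# Bundled study fixtures
# ---------------------------------------------------------------------------


@dataclass
class PanelCounts:
    """Participant counts per stakeholder group, arm and round, with
    demographic breakdowns (gender, age band, country) per arm and round.

    ``blocks`` maps block name (``stakeholder_group``, ``gender``, ``age``,
    ``country``) to ``{(category, arm, round): n}``.
    """

    blocks: dict[str, dict[tuple[str, str, int], int]]
    arms: tuple[str, ...] = ("5pt", "9pt")

    def round_n(self, arm: str, round: int) -> int:
        """Total panellists in an arm completing a round."""
        block = self.blocks["stakeholder_group"]
        return sum(n for (cat, a, r), n in block.items() if a == arm and r == round)

    def group_n(self, arm: str, group: Union[str, StakeholderGroup], round: int) -> int:
        group = _coerce_group(group)
        return self.blocks["stakeholder_group"].get((group.value, arm, round), 0)

    def block_total(self, block: str, arm: str, round: int) -> int:
        return sum(
            n for (cat, a, r), n in self.blocks[block].items() if a == arm and r == round
        )

    def to_roster(self) -> list[Participant]:
        """Expand group-level counts into an individual roster.

        Group counts fix each participant's last completed round (attrition
        is monotone, so counts per round determine how many stop after each
        round); the individual identities are synthetic.
        """
        roster: list[Participant] = []
        serial = 0
        for arm in self.arms:
            for group in CANONICAL_GROUPS:
                n1 = self.group_n(arm, group, 1)
                n2 = self.group_n(arm, group, 2)
                n3 = self.group_n(arm, group, 3)
                if not n1 >= n2 >= n3:
                    raise ValidationError(
                        f"non-monotone counts for {group.value} in arm {arm}: {n1}, {n2}, {n3}"
                    )
                last_rounds = [3] * n3 + [2] * (n2 - n3) + [1] * (n1 - n2)
                for last in last_rounds:
                    serial += 1
                    roster.append(
                        Participant(
                            participant_id=f"P{serial:04d}",
                            arm=arm,
                            group=group,
                            rounds_completed=frozenset(range(1, last + 1)),
                        )
                    )
        return roster


_FIXTURE_FILES = {
    "table1": "table1_interview_outcome_ratings.csv",
    "table2": "table2_patient_suggestions.json",
    "table3": "table3_panel_demographics.csv",
    "table4": "table4_round_decisions.csv",
    "table5": "table5_attrition_rates.csv",
    "feedback": "scale_feedback.json",
    "final_cos": "final_cos_synthetic.json",
    "other_suggestions": "suggestions_other_groups_synthetic.json",
}


def _fixture_path(filename: str):
    return resources.files("delphicos.fixtures").joinpath(filename)


def load_paper_fixture(table_name: str):
    """Load a bundled transcription of one of the published study tables.

    ``table1`` — :class:`GroupProportionTable` of the eight interview-derived
    outcomes (five groups x three rounds x two arms; unrated cells absent);
    ``table2`` — the adjudicated patient suggestions;
    ``table3`` — :class:`PanelCounts` of participants per group/arm/round with
    demographics; ``table4`` — ``(registry, RoundDecision)`` covering all 70
    candidate outcomes; ``table5`` — the published attrition-rate grid.
    Additional names: ``feedback`` (scale ease/clarity tallies), ``final_cos``
    (reconstructed final COS membership), ``other_suggestions`` (synthetic
    adjudications minting the non-patient round-2 entrants).
    """
    if table_name not in _FIXTURE_FILES:
        raise KeyError(
            f"unknown fixture {table_name!r}; valid names: "
            + ", ".join(sorted(_FIXTURE_FILES))
        )
    filename = _FIXTURE_FILES[table_name]
    path = _fixture_path(filename)

    if table_name == "table1":
        table = GroupProportionTable()
        with path.open(encoding="utf-8") as handle:
            for row in csv.DictReader(handle):
                table.set(
                    row["outcome_id"],
                    row["group"],
                    int(row["round"]),
                    row["arm"],
                    float(row["percent"]),
                )
        return table

    if table_name in ("table2", "other_suggestions"):
        with path.open(encoding="utf-8") as handle:
            raw = json.load(handle)
        return [
            AdjudicatedSuggestion(
                raw_text=item["raw_text"],
                decision=item["decision"],
                mapped_outcome_id=item.get("mapped_outcome_id"),
                new_outcome_id=item.get("new_outcome_id"),
                new_outcome_name=item.get("new_outcome_name"),
            )
            for item in raw
        ]

    if table_name == "table3":
        blocks: dict[str, dict[tuple[str, str, int], int]] = {}
        with path.open(encoding="utf-8") as handle:
            for row in csv.DictReader(handle):
                block = blocks.setdefault(row["block"], {})
                block[(row["category"], row["arm"], int(row["round"]))] = int(row["n"])
        return PanelCounts(blocks=blocks)

    if table_name == "table4":
        from .consensus_engine import RoundDecision, Status  # local to avoid cycle

        registry: list[Outcome] = []
        decision = RoundDecision()
        with path.open(encoding="utf-8") as handle:
            for row in csv.DictReader(handle):
                registry.append(
                    Outcome(
                        outcome_id=row["outcome_id"],
                        name=row["name"],
                        sources=frozenset(row["sources"].split("|")),
                        first_round=int(row["first_round"]),
                    )
                )
                for round in (1, 2, 3):
                    for arm in ("5pt", "9pt"):
                        decision.set(
                            row["outcome_id"], arm, round, Status(row[f"r{round}_{arm}"])
                        )
        return registry, decision

    if table_name == "table5":
        from .scale_comparison import AttritionTable  # local to avoid cycle

        table = AttritionTable()
        with path.open(encoding="utf-8") as handle:
            for row in csv.DictReader(handle):
                table.set(row["arm"], row["group"], row["transition"], float(row["percent"]))
        return table

    if table_name == "feedback":
        with path.open(encoding="utf-8") as handle:
            return json.load(handle)

    if table_name == "final_cos":
        with path.open(encoding="utf-8") as handle:
            return json.load(handle)["outcomes"]

    raise AssertionError("unreachable")
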
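"""Latent-trait simulator of a two-arm, multi-round Delphi panel.

Each simulated panellist belongs to one of the five stakeholder groups and
is allocated to a scale arm by simple randomisation (a uniform draw).  A
rating arises from an ordinal measurement model: the (outcome, group) pair
carries a latent mean importance ``theta`` on a canonical [0, 1] axis, the
rater adds Gaussian noise with spread ``sigma`` (clamped back to [0, 1]),
and the latent value is discretised through the arm scale's ordered
interior cutpoints.  With equally spaced cutpoints the published cutoffs
dichotomise the axis differently per scale — "important" covers the top
2/5 of the axis on the 5-point scale but only the top 3/9 on the 9-point
scale — which lets the simulator probe scale-granularity effects on
consensus counts as a measurement artefact.

Dropout is applied between rounds per stakeholder group and is monotone: a
panellist who leaves never returns.  Everything is reproducible from a
single integer seed.  Simulated rosters and ratings use the same schemas
as the data module, so they flow through the whole pipeline unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
from scipy.stats import norm

from .delphi_data import (
    CANONICAL_GROUPS,
    FIVE_POINT,
    NINE_POINT,
    Participant,
    RatingRecord,
    RatingScale,
    StakeholderGroup,
    ValidationError,
)
from .consensus_engine import ConsensusRule, RoundDecision, evaluate_round

__all__ = [
    "ScaleCutpoints",
    "SimulationConfig",
    "default_config",
    "equally_spaced_cutpoints",
    "discretize",
    "simulate_panel",
    "estimate_importance_probability",
    "importance_probability",
    "run_scale_experiment",
    "ScaleExperimentSummary",
]


def equally_spaced_cutpoints(n_points: int) -> tuple[float, ...]:
    """The ``n_points - 1`` interior boundaries splitting [0, 1] evenly."""
    return tuple(k / n_points for k in range(1, n_points))


@dataclass(frozen=True)
class ScaleCutpoints:
    """A rating scale together with its interior cutpoints on the [0, 1] axis."""

    scale: RatingScale
    cutpoints: tuple[float, ...]

    def __post_init__(self) -> None:
        cuts = tuple(float(c) for c in self.cutpoints)
        if len(cuts) != self.scale.n_points - 1:
            raise ValidationError(
                f"scale {self.scale.scale_id!r} needs {self.scale.n_points - 1} cutpoints"
            )
        if any(not 0 < c < 1 for c in cuts):
            raise ValidationError("cutpoints must lie strictly inside (0, 1)")
        if any(b <= a for a, b in zip(cuts, cuts[1:])):
            raise ValidationError("cutpoints must be strictly increasing")
        object.__setattr__(self, "cutpoints", cuts)

    @property
    def importance_boundary(self) -> float:
        """The axis position a latent value must exceed to rate "important"."""
        return self.cutpoints[self.scale.importance_cutoff - 2]


@dataclass
class SimulationConfig:
    """Generating parameters for a synthetic Delphi panel.

    ``theta`` maps (outcome_id, group) to the latent mean importance on the
    canonical [0, 1] axis; ``sigma`` is the rater noise standard deviation
    on the same axis; ``dropout`` maps (group, transition) to a
    per-panellist probability of leaving at that transition.
    ``group_sizes`` are recruitment totals per stakeholder group — the arm
    split itself is random (simple randomisation).
    """

    outcomes: list[str]
    group_sizes: dict[StakeholderGroup, int]
    theta: dict[tuple[str, StakeholderGroup], float]
    sigma: float
    scales: list[ScaleCutpoints]
    dropout: dict[tuple[StakeholderGroup, str], float]
    rounds: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValidationError("sigma must be >= 0")
        if any(n < 0 for n in self.group_sizes.values()):
            raise ValidationError("group sizes must be >= 0")
        for key, p in self.dropout.items():
            if not 0 <= p <= 1:
                raise ValidationError(f"dropout probability {p} for {key} outside [0, 1]")
        for key, t in self.theta.items():
            if not 0 <= t <= 1:
                raise ValidationError(f"theta {t} for {key} outside [0, 1]")

    def scale_for_arm(self, arm: str) -> ScaleCutpoints:
        for sc in self.scales:
            if sc.scale.scale_id == arm:
                return sc
        raise KeyError(arm)


#: Recruitment totals per group, matching the study's round-1 panel (both
#: arms pooled: 91 clinicians, 38 clinician-researchers, 42 patients, 23
#: researchers, 11 service providers / policy makers).
STUDY_GROUP_SIZES: dict[StakeholderGroup, int] = {
    StakeholderGroup.CLINICIAN: 91,
    StakeholderGroup.CLINICIAN_RESEARCHER: 38,
    StakeholderGroup.PATIENT: 42,
    StakeholderGroup.RESEARCHER: 23,
    StakeholderGroup.SERVICE_PROVIDER_POLICY_MAKER: 11,
}

#: Per-group dropout probabilities per transition, the observed per-group
#: attrition pooled over both arms of the study panel.
STUDY_DROPOUT: dict[tuple[StakeholderGroup, str], float] = {
    (StakeholderGroup.CLINICIAN, "r1_to_r2"): 32 / 91,
    (StakeholderGroup.CLINICIAN, "r2_to_r3"): 7 / 59,
    (StakeholderGroup.CLINICIAN_RESEARCHER, "r1_to_r2"): 5 / 38,
    (StakeholderGroup.CLINICIAN_RESEARCHER, "r2_to_r3"): 0.0,
    (StakeholderGroup.PATIENT, "r1_to_r2"): 16 / 42,
    (StakeholderGroup.PATIENT, "r2_to_r3"): 8 / 26,
    (StakeholderGroup.RESEARCHER, "r1_to_r2"): 2 / 23,
    (StakeholderGroup.RESEARCHER, "r2_to_r3"): 0.0,
    (StakeholderGroup.SERVICE_PROVIDER_POLICY_MAKER, "r1_to_r2"): 3 / 11,
    (StakeholderGroup.SERVICE_PROVIDER_POLICY_MAKER, "r2_to_r3"): 0.0,
}


def default_config(
    n_outcomes: int = 53,
    sigma: float = 0.15,
    seed: int = 0,
    group_sizes: Optional[Mapping[StakeholderGroup, int]] = None,
) -> SimulationConfig:
    """A study-shaped configuration: five groups at the panel's recruitment
    sizes, the 5-point and 9-point arms with equally spaced cutpoints, three
    rounds, and the panel's observed per-group dropout probabilities.

    The study published no data from which latent importances could be
    calibrated, so ``theta`` is illustrative: per-outcome means drawn
    uniformly from [0.35, 0.9] with small per-group offsets, seeded.
    """
    rng = np.random.default_rng(seed)
    outcomes = [f"outcome_{i:02d}" for i in range(1, n_outcomes + 1)]
    theta: dict[tuple[str, StakeholderGroup], float] = {}
    for outcome in outcomes:
        base = rng.uniform(0.35, 0.9)
        for group in CANONICAL_GROUPS:
            theta[(outcome, group)] = float(np.clip(base + rng.normal(0.0, 0.05), 0.0, 1.0))
    sizes = dict(group_sizes) if group_sizes is not None else dict(STUDY_GROUP_SIZES)
    return SimulationConfig(
        outcomes=outcomes,
        group_sizes=sizes,
        theta=theta,
        sigma=sigma,
        scales=[
            ScaleCutpoints(FIVE_POINT, equally_spaced_cutpoints(5)),
            ScaleCutpoints(NINE_POINT, equally_spaced_cutpoints(9)),
        ],
        dropout=dict(STUDY_DROPOUT),
        rounds=3,
        seed=seed,
    )


def discretize(latent_value: float, cutpoints: Sequence[float]) -> int:
    """Map a latent axis value to a 1-based ordinal rating.

    The rating is 1 plus the number of cutpoints strictly below the latent
    value, giving the full range 1..n_points.
    """
    cuts = np.asarray(cutpoints, dtype=float)
    return int(np.searchsorted(cuts, latent_value, side="left")) + 1


def importance_probability(theta: float, sigma: float, boundary: float) -> float:
    """Closed-form P(rating >= cutoff) under the Gaussian noise model.

    "Important" requires the noisy latent value to exceed the cutoff
    cutpoint; clamping to [0, 1] does not change this event for a boundary
    strictly inside (0, 1), so the probability is Phi((theta - c) / sigma).
    With sigma = 0 the model is deterministic.
    """
    if sigma == 0:
        return 1.0 if theta > boundary else 0.0
    return float(norm.cdf((theta - boundary) / sigma))


def simulate_panel(
    config: SimulationConfig,
    rule: ConsensusRule = ConsensusRule(),
) -> tuple[list[Participant], list[RatingRecord]]:
    """Simulate a full multi-round, two-arm panel.

    Round 1 presents every outcome to every active panellist; rounds carry
    all outcomes forward until the penultimate transition, which keeps only
    the outcomes reaching the consensus rule per arm (the study's
    carry-all-then-filter design).  Dropout is drawn per panellist between
    rounds and is monotone.  Fully reproducible from ``config.seed``.

    Returns the roster (with ``rounds_completed`` reflecting dropout) and
    all rating records.
    """
    rng = np.random.default_rng(config.seed)
    arms = [sc.scale.scale_id for sc in config.scales]

    # ---- recruit and allocate (simple randomisation)
    panellists: list[dict] = []
    serial = 0
    for group in CANONICAL_GROUPS:
        for _ in range(config.group_sizes.get(group, 0)):
            serial += 1
            panellists.append(
                {
                    "id": f"S{serial:05d}",
                    "group": group,
                    "arm": arms[rng.integers(0, len(arms))],
                    "last_round": config.rounds,
                }
            )

    # ---- per-round presentation lists, initially everything in both arms
    presented: dict[str, list[str]] = {arm: list(config.outcomes) for arm in arms}
    records: list[RatingRecord] = []
    active = list(panellists)
    round_records: dict[int, list[RatingRecord]] = {}
    for round in range(1, config.rounds + 1):
        round_records[round] = []
        for person in active:
            sc = config.scale_for_arm(person["arm"])
            for outcome in presented[person["arm"]]:
                theta = config.theta[(outcome, person["group"])]
                latent = theta + (rng.normal(0.0, config.sigma) if config.sigma > 0 else 0.0)
                latent = float(np.clip(latent, 0.0, 1.0))
                rating = discretize(latent, sc.cutpoints)
                round_records[round].append(
                    RatingRecord(
                        participant_id=person["id"],
                        outcome_id=outcome,
                        round=round,
                        rating=rating,
                        arm=person["arm"],
                        group=person["group"],
                    )
                )
        records.extend(round_records[round])

        if round == config.rounds:
            break

        # ---- filter outcomes for the final round only (carry-all before)
        if round == config.rounds - 1:
            for arm in arms:
                sc = config.scale_for_arm(arm)
                decision = evaluate_round(
                    round_records[round], presented[arm], round, arm, rule, scale=sc.scale
                )
                presented[arm] = decision.outcomes_with_status(arm, round, "in")

        # ---- monotone dropout between rounds
        transition = f"r{round}_to_r{round + 1}"
        survivors = []
        for person in active:
            p_drop = config.dropout.get((person["group"], transition), 0.0)
            if rng.random() < p_drop:
                person["last_round"] = round
            else:
                survivors.append(person)
        active = survivors

    roster = [
        Participant(
            participant_id=person["id"],
            arm=person["arm"],
            group=person["group"],
            rounds_completed=frozenset(range(1, person["last_round"] + 1)),
        )
        for person in panellists
    ]
    return roster, records


def estimate_importance_probability(
    records: Iterable[RatingRecord],
    outcome_id: str,
    group: Union[str, StakeholderGroup],
    scale: RatingScale,
    round: int = 1,
) -> Optional[float]:
    """Empirical share (0..1) of a group's ratings at/above the cutoff.

    The Monte-Carlo counterpart of :func:`importance_probability`, used for
    parameter-recovery checks against the closed form.  ``None`` when the
    group has no ratings.
    """
    from .consensus_engine import importance_proportion

    percent = importance_proportion(records, outcome_id, group, round, scale)
    return None if percent is None else percent / 100.0


@dataclass
class ScaleExperimentSummary:
    """Replicate-level and summarised consensus counts per arm and round.

    ``counts[(arm, round)]`` is the list of per-replicate consensus counts;
    ``mean``/``std`` summarise it.
    """

    replicates: int
    counts: dict[tuple[str, int], list[int]]

    def mean(self, arm: str, round: int) -> float:
        values = self.counts[(arm, round)]
        return float(np.mean(values)) if values else float("nan")

    def std(self, arm: str, round: int) -> float:
        values = self.counts[(arm, round)]
        return float(np.std(values)) if values else float("nan")


def run_scale_experiment(
    config: SimulationConfig,
    rule: ConsensusRule = ConsensusRule(),
    replicates: int = 100,
) -> ScaleExperimentSummary:
    """Monte-Carlo distribution of per-arm consensus counts.

    Each replicate simulates a fresh panel (seeded from ``config.seed`` and
    the replicate index), evaluates every round with the consensus rule per
    arm independently, and records the number of outcomes reaching
    consensus.  The summary exposes per-(arm, round) means and spreads —
    the synthetic analogue of comparing how many outcomes each scale lets
    through.
    """
    if len(config.scales) < 2:
        raise ValidationError("run_scale_experiment needs at least two scales")
    arms = [sc.scale.scale_id for sc in config.scales]
    counts: dict[tuple[str, int], list[int]] = {
        (arm, round): [] for arm in arms for round in range(1, config.rounds + 1)
    }
    seed_root = np.random.SeedSequence(config.seed)
    child_seeds = seed_root.generate_state(max(replicates, 1) * 2)
    for rep in range(replicates):
        rep_config = SimulationConfig(
            outcomes=config.outcomes,
            group_sizes=config.group_sizes,
            theta=config.theta,
            sigma=config.sigma,
            scales=config.scales,
            dropout=config.dropout,
            rounds=config.rounds,
            seed=int(child_seeds[rep] % (2**31)),
        )
        _, records = simulate_panel(rep_config, rule)
        by_round: dict[int, list[RatingRecord]] = {}
        for rec in records:
            by_round.setdefault(rec.round, []).append(rec)
        for arm in arms:
            sc = rep_config.scale_for_arm(arm)
            for round in range(1, config.rounds + 1):
                round_recs = by_round.get(round, [])
                candidates = sorted({r.outcome_id for r in round_recs if r.arm == arm})
                decision = evaluate_round(
                    round_recs, candidates, round, arm, rule, scale=sc.scale
                )
                counts[(arm, round)].append(decision.in_count(arm, round))
    return ScaleExperimentSummary(replicates=replicates, counts=counts)
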
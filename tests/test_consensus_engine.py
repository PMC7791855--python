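"""Consensus criterion, round mechanics, and registry merging."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from delphicos import delphi_data as dd
from delphicos import consensus_engine as ce

GROUPS = list(dd.CANONICAL_GROUPS)
RULE = ce.ConsensusRule()


def _records(ratings_by_group, outcome="o1", rnd=1, arm="5pt"):
    """Build rating records from {group: [ratings]}."""
    records = []
    for group, ratings in ratings_by_group.items():
        for i, rating in enumerate(ratings):
            records.append(
                dd.RatingRecord(f"{group.value}_{i}", outcome, rnd, rating, arm, group)
            )
    return records


class TestImportanceProportion:
    def test_unanimous_top_rating_gives_100(self):
        recs = _records({dd.StakeholderGroup.PATIENT: [5] * 5})
        pct = ce.importance_proportion(recs, "o1", "patient", 1, dd.FIVE_POINT)
        assert pct == 100.0

    def test_counts_ratings_at_or_above_cutoff(self):
        recs = _records({dd.StakeholderGroup.PATIENT: [4, 4, 3, 2]})
        pct = ce.importance_proportion(recs, "o1", "patient", 1, dd.FIVE_POINT)
        assert pct == 50.0

    def test_exact_boundary_meets_the_threshold(self):
        # 7 of 10 at the cutoff is exactly 70%, which qualifies under >=
        recs = _records({dd.StakeholderGroup.PATIENT: [4] * 7 + [3] * 3})
        pct = ce.importance_proportion(recs, "o1", "patient", 1, dd.FIVE_POINT)
        assert pct == 70.0
        proportions = {g: None for g in GROUPS}
        proportions[dd.StakeholderGroup.PATIENT] = pct
        proportions[dd.StakeholderGroup.CLINICIAN] = 90.0
        proportions[dd.StakeholderGroup.RESEARCHER] = 70.0
        assert ce.group_consensus(proportions, RULE)

    def test_no_raters_is_distinct_from_zero_percent(self):
        recs = _records({dd.StakeholderGroup.PATIENT: [1, 1]})
        assert ce.importance_proportion(recs, "o1", "clinician", 1, dd.FIVE_POINT) is None
        assert ce.importance_proportion(recs, "o1", "patient", 1, dd.FIVE_POINT) == 0.0


class TestGroupConsensus:
    @pytest.mark.parametrize(
        "percents, expected",
        [
            # all five groups above threshold
            ({"clinician": 93, "clinician_researcher": 95, "patient": 100,
              "researcher": 100, "service_provider_policy_maker": 100}, True),
            # only two groups reach 70
            ({"clinician": 82, "clinician_researcher": 42, "patient": 70,
              "researcher": 30, "service_provider_policy_maker": 67}, False),
            # two qualifying groups but the mandatory patient group fails
            ({"clinician": 75, "clinician_researcher": 58, "patient": 60,
              "researcher": 20, "service_provider_policy_maker": 100}, False),
            # exactly three groups at/above 70 including patients
            ({"clinician": 70, "clinician_researcher": 0, "patient": 70,
              "researcher": 70, "service_provider_policy_maker": 0}, True),
        ],
    )
    def test_criterion_on_group_percentages(self, percents, expected):
        proportions = {dd.StakeholderGroup(g): v for g, v in percents.items()}
        assert ce.group_consensus(proportions, RULE) is expected

    def test_empty_group_never_qualifies_nor_satisfies_mandatory(self):
        proportions = {g: 100.0 for g in GROUPS}
        proportions[dd.StakeholderGroup.PATIENT] = None
        assert not ce.group_consensus(proportions, RULE)

    def test_rule_parameter_validation(self):
        with pytest.raises(dd.ValidationError):
            ce.ConsensusRule(importance_threshold=0.0)
        with pytest.raises(dd.ValidationError):
            ce.ConsensusRule(min_groups=0)  # below |mandatory_groups|
        with pytest.raises(dd.ValidationError):
            ce.ConsensusRule(min_groups=6, total_groups=5)


def _brute_force_round(records, candidates, rnd, arm, rule, scale):
    """Independent oracle: enumerate groups and count ratings directly."""
    statuses = {}
    for outcome in candidates:
        any_rating = False
        qualifying = set()
        for group in GROUPS:
            ratings = [
                r.rating for r in records
                if r.outcome_id == outcome and r.group is group
                and r.round == rnd and r.arm == arm
            ]
            if not ratings:
                continue
            any_rating = True
            n_important = sum(1 for x in ratings if x >= scale.importance_cutoff)
            # integer cross-multiplication avoids float proportions entirely
            if n_important * 100 >= rule.importance_threshold * 100 * len(ratings):
                qualifying.add(group)
        if not any_rating:
            statuses[outcome] = "not_rated"
        else:
            ok = len(qualifying) >= rule.min_groups and rule.mandatory_groups <= qualifying
            statuses[outcome] = "in" if ok else "out"
    return statuses


class TestEvaluateRound:
    def test_agrees_with_brute_force_oracle_on_small_panels(self):
        rng = random.Random(20240917)
        for _ in range(30):
            n_outcomes = rng.randint(1, 6)
            candidates = [f"o{i}" for i in range(n_outcomes)]
            records = []
            for outcome in candidates:
                for group in GROUPS:
                    for i in range(rng.randint(0, 4)):
                        records.append(
                            dd.RatingRecord(
                                f"{group.value}{i}", outcome, 1,
                                rng.randint(1, 5), "5pt", group,
                            )
                        )
            decision = ce.evaluate_round(
                records, candidates, 1, "5pt", RULE, scale=dd.FIVE_POINT
            )
            expected = _brute_force_round(records, candidates, 1, "5pt", RULE, dd.FIVE_POINT)
            for outcome in candidates:
                assert decision.status(outcome, "5pt", 1).value == expected[outcome]

    def test_unrated_candidates_are_flagged_and_not_counted(self):
        recs = _records({dd.StakeholderGroup.PATIENT: [5, 5, 5]})
        decision = ce.evaluate_round(
            recs, ["o1", "ghost"], 1, "5pt", RULE, scale=dd.FIVE_POINT
        )
        assert decision.status("ghost", "5pt", 1) is ce.Status.NOT_RATED
        assert decision.possible_count("5pt", 1) == 1

    def test_arm_independence(self):
        rng = random.Random(7)
        records = []
        for arm, scale in (("5pt", dd.FIVE_POINT), ("9pt", dd.NINE_POINT)):
            for group in GROUPS:
                for i in range(3):
                    records.append(
                        dd.RatingRecord(
                            f"{arm}{group.value}{i}", "o1", 1,
                            rng.randint(1, scale.n_points), arm, group,
                        )
                    )
        baseline = ce.evaluate_round(records, ["o1"], 1, "5pt", RULE, scale=dd.FIVE_POINT)
        # mutate the other arm's records arbitrarily
        mutated = [
            dd.RatingRecord(r.participant_id, r.outcome_id, r.round, 9, r.arm, r.group)
            if r.arm == "9pt" else r
            for r in records
        ]
        after = ce.evaluate_round(mutated, ["o1"], 1, "5pt", RULE, scale=dd.FIVE_POINT)
        assert baseline.status("o1", "5pt", 1) == after.status("o1", "5pt", 1)

    def test_unanimity_rule_on_published_round3_percentages(self, table1, registry):
        interview_ids = [o.outcome_id for o in registry
                         if dd.OutcomeSource.INTERVIEW in o.sources]
        strict = ce.ConsensusRule(importance_threshold=1.0)
        decision = ce.evaluate_round(table1, interview_ids, 3, "5pt", strict)
        survivors = decision.outcomes_with_status("5pt", 3, ce.Status.IN)
        assert survivors == ["family_life_impact"]


percent_values = st.one_of(st.none(), st.integers(min_value=0, max_value=100))


class TestMonotonicity:
    @settings(max_examples=200, derandomize=True)
    @given(
        percents=st.lists(percent_values, min_size=5, max_size=5),
        threshold=st.integers(min_value=1, max_value=100),
        bump=st.integers(min_value=0, max_value=30),
        extra_min=st.integers(min_value=0, max_value=2),
        add_mandatory=st.booleans(),
    )
    def test_tightening_the_rule_never_flips_out_to_in(
        self, percents, threshold, bump, extra_min, add_mandatory
    ):
        proportions = dict(zip(GROUPS, percents))
        base = ce.ConsensusRule(importance_threshold=threshold / 100, min_groups=3)
        tighter = ce.ConsensusRule(
            importance_threshold=min(threshold + bump, 100) / 100,
            min_groups=min(3 + extra_min, 5),
            mandatory_groups=frozenset(
                {dd.StakeholderGroup.PATIENT}
                | ({dd.StakeholderGroup.CLINICIAN} if add_mandatory else set())
            ),
        )
        if not ce.group_consensus(proportions, base):
            assert not ce.group_consensus(proportions, tighter)


class TestRoundTransitions:
    def test_filter_is_a_subset_of_carry_all(self, decision):
        for rnd in (1, 2):
            carried = ce.next_round_outcomes(decision, rnd, "carry_all")
            filtered = ce.next_round_outcomes(decision, rnd, "filter")
            for arm in decision.arms():
                assert set(filtered[arm]) <= set(carried[arm])

    def test_round_three_candidate_lists_match_the_study(self, decision):
        filtered = ce.next_round_outcomes(decision, 2, "filter")
        assert len(filtered["5pt"]) == 37
        assert len(filtered["9pt"]) == 20

    def test_carry_all_returns_everything_rated(self, decision):
        carried = ce.next_round_outcomes(decision, 1, "carry_all", arm="5pt")
        assert len(carried) == 53


class TestMergeSuggestions:
    def test_patient_suggestions_mint_four_new_outcomes(self, registry):
        initial = [o for o in registry if o.first_round == 1]
        assert len(initial) == 53
        suggestions = dd.load_paper_fixture("table2")
        merged = ce.merge_suggestions(suggestions, initial)
        minted = [o for o in merged if o.first_round == 2]
        assert len(minted) == 4
        assert all(o.sources == {dd.OutcomeSource.ROUND1_SUGGESTION} for o in minted)

    def test_all_stakeholder_suggestions_give_68_round_two_candidates(self, registry):
        initial = [o for o in registry if o.first_round == 1]
        merged = ce.merge_suggestions(dd.load_paper_fixture("table2"), initial)
        merged = ce.merge_suggestions(dd.load_paper_fixture("other_suggestions"), merged)
        assert len(merged) == 68

    def test_empty_suggestion_list_is_identity(self, registry):
        assert ce.merge_suggestions([], registry) == list(registry)

    def test_duplicate_mint_demands_explicit_adjudication(self, registry):
        dupe = dd.AdjudicatedSuggestion(
            "pain again", "include_new",
            new_outcome_id="pain_frequency_2", new_outcome_name="Pain frequency",
        )
        with pytest.raises(dd.ValidationError, match="adjudicate"):
            ce.merge_suggestions([dupe], registry)

    def test_mapping_to_unknown_outcome_is_rejected(self):
        suggestion = dd.AdjudicatedSuggestion(
            "something", "already_included", mapped_outcome_id="nonexistent"
        )
        with pytest.raises(dd.ValidationError, match="unknown outcome"):
            ce.merge_suggestions([suggestion], [])


class TestPreliminaryCOS:
    def test_union_follows_inclusion_exclusion(self, decision):
        prelim = ce.preliminary_cos(decision)
        overlap = ce.overlap_count(prelim.per_arm["5pt"], prelim.per_arm["9pt"])
        assert len(prelim.union) == (
            len(prelim.per_arm["5pt"]) + len(prelim.per_arm["9pt"]) - overlap
        )

    def test_overlap_count_identity_and_symmetry(self):
        a = ["x", "y", "z"]
        b = ["y", "z", "w"]
        assert ce.overlap_count(a, a) == 3
        assert ce.overlap_count(a, b) == ce.overlap_count(b, a) == 2


class TestSourceTracking:
    def test_interview_outcomes_reaching_preliminary_cos(self, decision, registry):
        summary = ce.track_source_outcomes(decision, registry, "interview")
        assert len(summary.outcome_ids) == 8
        assert summary.reached_preliminary == 4
        assert summary.preliminary_ids == [
            "emotional_symptoms", "family_life_impact",
            "sexual_functioning", "social_life_impact",
        ]

    def test_suggested_outcomes_missing_from_final_cos(self, decision, registry):
        final = dd.load_paper_fixture("final_cos")
        summary = ce.track_source_outcomes(
            decision, registry, "round1_suggestion", final_cos=final
        )
        assert summary.reached_final == 0

    def test_tag_matching_nothing_gives_all_zero_summary(self, decision):
        plain = [dd.Outcome("only_sr", "Only SR", frozenset({"systematic_review"}))]
        summary = ce.track_source_outcomes(decision, plain, "interview")
        assert summary.outcome_ids == []
        assert summary.reached_preliminary == 0
        assert all(
            counts == {"in": 0, "out": 0, "not_rated": 0}
            for counts in summary.per_round.values()
        )
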
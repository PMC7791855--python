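# Methods

## The consensus model

A core outcome set (COS) Delphi reduces a registry of candidate outcomes
over successive survey rounds. Each panellist belongs to one of five
stakeholder groups and is allocated once, by simple randomisation, to a
rating-scale arm (5-point or 9-point by default); arms are fully
independent surveys and no computation for one arm ever reads the other
arm's data.

The a priori criterion is parameterised by `ConsensusRule`:

| parameter | default | meaning |
|---|---|---|
| `importance_threshold` | 0.70 | minimum within-group share of "important" ratings |
| `min_groups` | 3 | number of groups that must reach the threshold |
| `total_groups` | 5 | canonical group count |
| `mandatory_groups` | {patient} | groups that must be among the qualifiers |

"Important" means a rating at or above the arm scale's cutoff (4 on the
5-point scale, 7 on the 9-point scale). Both comparisons are inclusive
(`>=`): a group at exactly 70% qualifies and exactly three qualifying
groups suffice. This is forced by the data the engine must replay —
published group percentages of exactly 70 belong to included outcomes.

Conventions the design left open, fixed here:

* **Denominators.** A group's proportion is over the group members who
  rated that specific outcome in that round and arm; panellists who
  skipped individual items reduce the denominator per outcome. The source
  design does not state how partial responses were handled; this is the
  package's choice.
* **Empty groups.** A group with zero respondents in a round returns a
  designated empty result (`None`), which never meets the threshold and
  can never satisfy a mandatory-group requirement — consensus cannot be
  claimed from absent voices. It is reported distinctly from 0%.
* **Exactness.** When evaluating raw rating records, proportions are
  compared to the threshold as exact rationals (`Fraction`), so display
  rounding can never change a decision. When replaying published integer
  percentages, the printed values are compared as given, with no
  re-rounding — the underlying counts were never published.
* **Transitions.** Round 1→2 is `carry_all` (everything re-rated, plus
  suggestion-derived outcomes minted by external adjudication); round
  2→3 is `filter` (consensus outcomes only). Both are exposed so other
  COS designs can be expressed.
* **Ordering.** All outputs are sorted by outcome id; repeated runs on
  identical input are byte-identical.

## Two-arm statistics

The pooled two-proportion z uses the classic formula
`z = (p1 − p2) / sqrt(p(1 − p)(1/n1 + 1/n2))` with the pooled proportion
`p = (x1 + x2)/(n1 + n2)`, no continuity correction, and a two-sided
standard-normal p-value (full precision retained internally, displayed to
2 d.p.). The magnitude `|z|` is reported alongside the signed value,
matching the convention of printing positive z regardless of direction.
The analysis is exploratory by design, so no multiple-testing correction
is applied. Degenerate comparisons (pooled proportion 0 or 1) raise
rather than return 0.

Attrition per transition is `(n_start − n_end)/n_start × 100` with
"overall" comparing rounds 1 and 3, computed per group and overall, per
arm. Printed integer percentages use round-half-up (spreadsheet
rounding): 24.75 → 25, 31.68 → 32, 39.42 → 39; Python's bankers' rounding
would disagree on exact halves. Groups empty at a transition's start get
an undefined rate (`None`), never 0. Feedback tallies are pure counts
over closed categories with per-question denominators — no text analysis.

One reconciliation worth knowing: the overall attrition z computed from
the panel counts (32/101 vs 41/104) is 1.157, which rounds to 1.16,
whereas the source analysis reported 1.15 — consistent with rounding in
the original spreadsheet workflow. The package reports the exact-formula
value; verification accepts the reported figure within one unit in the
second decimal.

## Fixture transcription

The bundled fixtures transcribe the source study's printed tables: the
interview-derived outcome percentages, the adjudicated patient
suggestions, the panel demographics, the per-round In/Out decisions over
all 70 candidate outcomes, and the attrition grid. Missing cells ("–")
are an explicit not-rated status, never zero. Outcome identity across
rounds and tables is by one canonical id per outcome; printed name
variants map to a single id.

The printed per-cell round-3 decision column for the 5-point arm is
internally inconsistent with its own marginal totals (the cells imply 26
consensus outcomes of 36 rated; every marginal — the totals row, the 65%
share, the z of 0.73 and the 24-outcome preliminary COS — implies 24 of
37). The fixture follows the marginals, which all downstream statistics
corroborate: the entrant outcome missing a round-3 cell is encoded as
rated/out, and the two excess cells not pinned down by any other printed
statement (depression, self-efficacy) are encoded as out. Two further
reconstructions are labelled synthetic in their filenames: the final
five-outcome COS (implied uniquely by the printed congruency statements,
not itemised in the source) and the adjudications minting the eleven
non-patient round-2 entrant outcomes (whose suggestion texts were not
published).

## The simulator

Each (outcome, group) pair carries a latent mean importance `theta` on a
canonical [0, 1] axis. A rating is generated as
`clamp(theta + N(0, sigma), 0, 1)` discretised through the arm scale's
ordered interior cutpoints: the rating is one plus the number of
cutpoints strictly below the latent value. Defaults: equally spaced
cutpoints; `sigma = 0.15`; group recruitment sizes matching the study
panel (91/38/42/23/11 across the five groups); per-group dropout
probabilities set to the panel's observed per-transition attrition;
three rounds with carry-all then filter. The study published no data
from which `theta` could be calibrated, so the default latent means are
illustrative (per-outcome draws from U(0.35, 0.9) with small group
offsets, seeded).

The Gaussian noise model is the minimal symmetric choice that yields a
closed-form importance probability, `Phi((theta − c)/sigma)` with `c`
the cutoff cutpoint — clamping does not alter the tail event for a
boundary strictly inside (0, 1). This supports parameter-recovery tests
(empirical shares against the analytic tail) and the matched-cutpoint
equivalence check: two scales whose cutoff boundaries coincide on the
axis measure the same dichotomy and must yield equal expected consensus
counts. With equally spaced cutpoints the conventional cutoffs dichotomise
the axis differently — "important" spans the top 2/5 of the axis on a
5-point scale versus the top 3/9 on a 9-point scale — giving a candidate
measurement-artefact mechanism for the 5-point arm's consensus excess; the
simulator treats this as a hypothesis to explore, not an established
explanation.

What the simulator does **not** emulate, and hence what passing tests do
not show about real panels: between-round anchoring (real panellists saw
prior group proportions before re-rating; no mechanism is modelled),
special semantics of the mid "unsure" option (it simply falls below the
cutoff), non-Gaussian or asymmetric rater noise, and within-group
correlation beyond the shared latent mean.

## Problem sizes and numerical choices

Monte-Carlo tests use sizes chosen to keep the suite fast while leaving
headroom over sampling noise: parameter recovery at group size 5000 over
100 seeded replicates (coverage within two binomial standard errors in at
least 95), and the scale-equivalence and dominance checks at 200
replicates of small single-round panels with three-standard-error bands.
All randomness flows through `numpy.random.default_rng` seeded from a
single integer; replicate seeds derive from a `SeedSequence` and stay
below 2^31. Verification of replayed statistics uses exact equality for
counts and percentages and one unit in the last printed digit for z
statistics.

## Known limitations

* Published group percentages come without denominators, so replay from
  them can verify decisions but not reconstruct counts.
* The roster derived from panel counts fixes each panellist's last
  completed round exactly but assigns synthetic identities; any statistic
  depending on more than counts would not be identifiable from it.
* The final-COS congruency figures depend on the reconstructed final
  list; the reconstruction is uniquely consistent with the printed
  statements but is still an inference.
* The simulator's latent parameters are illustrative, not calibrated;
  simulated consensus counts should be compared between arms, not to the
  study's absolute numbers.
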
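# Methods

This note documents the statistical procedures, the synthetic-data model,
and the design choices made where the underlying study design is open to
interpretation.

## Time-loss injury events

An injury is operationalized as *time loss*: at least one competitive game
missed. Because practice and training dates are unobservable in
transaction/box-score data, **onset is dated at the first missed team game**
and **recovery at the first game played afterwards** — external validation
of scraped basketball data shows exactly this offset against sources that
record the true calendar date, which is why exact-date agreement across
sources is much lower than missed-games or injury-site agreement.

Linkage semantics: for each player, the relevant schedule is the union of
the schedules of every (team, season) the player appeared in (multi-team
seasons are flagged as trade windows rather than resolved). A maximal run
of consecutively missed team games becomes one event when a deactivation
transaction points into it, i.e. the first scheduled game on or after the
transaction date is part of the run. A deactivation followed by no missed
game (player reactivated before any game) produces no event. Games missed
counts team games strictly between the last game played and the return
game; intervals are closed on onset, open on return.

Events whose player never plays again are *retained* with
`return_observed = False` (games missed = remaining observed team games)
and counted in the validation report; they contribute to the severely
injured denominator but never to recovery-time or post-season analyses.
Only events with negative or undefined games missed are excluded outright.

## Severity and body region

Severity bands on games missed: Slight (1), Minor (2–3), Moderate (4–13),
Severe (14+) — the consensus time-loss gradations; the bands partition the
positive integers with no gaps or overlaps. Body region is assigned from
free-text notes with an editable keyword lexicon
(`courtside/data/region_lexicon.tsv`), whole-word and case-insensitive,
earliest keyword wins. Coding is regional, not diagnosis-level. Two
conventions to be aware of:

* **Achilles keywords map to ankle.** Published analyses of severe
  lower-extremity injury do not state where Achilles tendon injuries were
  filed; the default lexicon files them under ankle. Edit the lexicon to
  change this.
* Unmatched notes map to `unknown`, which is a value, not an error.

## Cohort rules

The primary severe lower-extremity injury (first severe event in
groin/hip/thigh, knee or ankle) defines the index season; missed games
spilling into the next season do not shift it. Pre-injury season = index −
1. Year 1 (post1) = season of return if the return game falls in a later
season, otherwise the next season played. Year 2 (post2) = the season
immediately after post1, if played — "did not play a second season" is
season-level attrition, not a gap-tolerant search.

Eligibility: 18+ at injury; ≥1 game in each of ≥3 distinct seasons inside
the study window (game-level play is the only observable notion of "played
a season"); played the pre-injury season; no event with more than 3 games
missed (more than Minor) in the pre-injury season; and no time-loss event
with onset within 14 calendar days of the return date (day 14 inclusive).
Players with missing roster metadata keep their cohort entry with absent
covariates; they drop out only of the covariate-adjusted model
(complete-case principle — second-season attrition is missing **not** at
random, being driven by release from the league, so imputation is not
defensible).

The strata counts (overall and per region: severely injured / played year 1
/ played year 2) are the denominators of every prevalence table and are
monotone by construction.

## Return to performance and prevalence

"Returned to pre-injury performance" has no standard operational
definition. The default rule is the only parameter-free reading:
post-season metric ≥ pre-season metric. A relative tolerance τ
(post ≥ (1−τ)·pre) is exposed for sensitivity analyses; results are
sensitive to this choice and it should be reported alongside any table.

Prevalence uses the Wald normal-approximation interval
p ± z·√(p(1−p)/n) with z = Φ⁻¹(0.975) ≈ 1.959964, clipped to [0, 1].
Wald (rather than Wilson or Clopper–Pearson) is the method that reproduces
published whole-cohort interval bounds for counts such as 58/196 and 48/130
after rounding; for 58/196 the Wilson lower bound rounds to 24 where 23 is
printed. Reporting rounds percentages half away from zero to integers.
Descriptive tables use the sample SD (n−1); a single-observation cell
reports SD 0. A published-report inconsistency worth noting: 130 of 285 is
45.6%, printed as 45% — integer rounding conventions in source material are
not always half-away; this package does not attempt to match that cell.

## Regression models

The prognostic models are separate OLS fits per metric (season minutes,
points, rebounds) and year: post-year value regressed on pre-injury value
with intercept. The slope is the reported coefficient — on same-unit
variables it reads as the retained fraction per marginal pre-injury unit,
which is why published coefficients near 0.5–0.8 are interpretable without
standardization. `fit_post_pre` uses the closed-form normal equations
(slope = cov/var), t-based 95% CIs with n−2 df, two-sided p-values, no
multiple-testing correction (the number of models run is visible in the
results bundle).

"Controlling for minutes played" enters post-season minutes as an
additional covariate (default), reporting the pre coefficient; constant
covariates are dropped with a note, and numerically collinear designs raise
an error carrying the condition number. The covariate-adjusted model adds
age at injury, seasons played at injury, injury year, body region
(reference: knee), position (reference: guard) and the age × seasons
interaction, on complete cases.

One-way fixed-effects ANOVA on days to return to sport is computed from
sums of squares with p from the F distribution; on two groups it equals the
squared pooled t statistic.

Restricted cubic splines use the Harrell parameterization: k knots at
conventional quantiles (10/50/90% for k = 3) give k−1 regression columns
including the linear term; each nonlinear column is a truncated-cubic
combination constructed to have zero second derivative beyond the boundary
knots, normalized by (t_k−t_1)². With the nonlinear coefficients at zero
the fit reduces exactly to the straight line; knot count and placement are
a convention, not an estimate.

## Synthetic league model

The generator's defaults are the study conditions, fixed once:

| parameter | default | rationale |
|---|---|---|
| teams × games × seasons | 30 × 82 × 5 | league shape |
| roster size | 15 | active roster |
| minutes/game baseline | truncated normal(25.8, 8.1) on [10, 44] | cross-player mean (SD) of per-game minutes |
| per-game minutes noise | Gamma, SD 3 | exact mean, positive support |
| points, rebounds, FGA per minute | 0.434, 0.140, 0.38 | 11.2 pts and 3.6 reb per game at 25.8 min |
| injury hazard | 0.005 per player-game | a starter accrues ≈ 0.4 time-loss injuries per season |
| severity mix | 45/30/17/8% (Slight/Minor/Moderate/Severe) | decreasing severity mass |
| severe region mix | 20/57/23% (groin-hip-thigh/knee/ankle) | observed severe-injury region shares |
| decrements year 1 / 2 | 0.70 / 0.85 | year-1 performance drop with partial year-2 recovery |
| dropout probability | 0.33 per post-return season | one third of severely injured players do not play a second season |

Structural choices:

* **Schedule**: 82 league-wide game dates per season, daily from a November
  anchor; every team plays every date. Opponent pairings carry no
  information used anywhere downstream, so they are not materialised; only
  ordering and counts matter to the statistics.
* **Minutes are two-level**: a per-player baseline mean (truncated normal —
  this is what makes the post-on-pre regressions identifiable and matches a
  cross-player SD of 8.1) and per-game Gamma noise around it. Gamma rather
  than a zero-floored normal because flooring biases E[minutes] upward for
  low-minute players, which would contaminate planted-decrement slope
  recovery; the Gamma has the exact mean and positive support. A season
  total of iid per-game Gammas is itself Gamma, which is how
  `simulate_pre_post_cohort` draws season totals exactly.
* **Injuries** occur only on played games (one hazard draw per played
  game). The games-missed draw is uniform within the severity band, capped
  at 54 for severe so that an injury spilling into the next season always
  returns within it when one exists; the only never-return events are
  horizon truncations in the final season, recorded in the ground truth
  with their *realized* (observable) games missed and severity.
* **Decrement** multiplies the minutes baseline *and* the per-minute rates
  in post-injury seasons (offset 1 from the index season: year-1 factor;
  offset ≥ 2: year-2 factor), so season minutes scale by the factor and
  scoring drops both through minutes and through rates.
* **Dropout** is drawn at season starts, only for players past their
  primary-injury return season and not mid-injury, and is absorbing:
  P(play year 1) = 1−p, P(play year 2) = (1−p)², i.e. ≈ 67% and 45% at
  p = 0.33.

What the generator does **not** emulate: trades and multi-team seasons,
rest-day/DNP-coach-decision absences without a transaction, practice
injuries, playoff/preseason exposure, schedule density effects, aging
curves, and any correlation between skill and injury risk. Passing tests
therefore demonstrate that the pipeline recovers what this model plants —
correctness of linkage, classification, cohort logic and estimators — not
that real scraped data would be this clean; real transaction logs in
particular contain date noise that the agreement machinery is designed to
quantify, not eliminate.

## Problem sizes and numerics

The test suite and acceptance script use: a 30-team × 82-game × 3–5-season
league for end-to-end recovery (≈ 450 players, ≈ 10⁵ player-games); 200
random 2–4-team toy leagues for linkage-oracle equivalence; 500 replicates
of 200-player cohorts for decrement recovery (season totals drawn directly
as Gammas); and 1000 null replicates for ANOVA calibration. These sizes
give Monte-Carlo error comfortably inside the asserted tolerances (e.g.
binomial SE of a 95% coverage estimate at 500 replicates is ≈ 1
percentage point). Degenerate inputs raise typed errors rather than
returning NaN: zero-variance predictors, empty complete-case sets,
duplicate knots, sub-minimum group sizes, denominators of zero.
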
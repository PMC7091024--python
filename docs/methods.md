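# Methods

`quitsense` models a three-arm smoking-cessation trial built around a
just-in-time adaptive intervention (JITAI): participants carry a phone for a
35-day ecological momentary assessment (EMA) window (7 days before a
scheduled quit date, 28 after), answer five prompted assessments per day,
and — in the tailored arm — receive one automated treatment message at the
completion of every EMA, selected from their momentary lapse risk. This
note records the models, the defaults and why they were chosen, and what
the synthetic data can and cannot establish.

## Prompt scheduling

Each study day carries one daily diary plus four random assessments inside
a waking window (default 08:00–22:00, configurable). The diary is pinned to
the window start so that "the first assessment of the day" — the only one
carrying the percent-chance-of-smoking-today item — is well defined. Random
times are drawn by the sorted-uniform spacing construction on integer
minutes: four draws on the gap-shrunk interval, sorted, plus multiples of
the minimum gap (default 40 min, enforced pairwise and against the diary).
The construction guarantees the gap exactly and is uniform up to the
shrink. A window shorter than five gaps is rejected as infeasible. All
randomness flows through a NumPy `Generator`; one seed yields one schedule.

## Lapse-risk score and classification

The momentary risk score is a convex combination of six predictors:
Likert items (urge, stress, cigarette availability, motivation) rescaled
from {1..5} to [0, 1] via (x − 1)/4, and two binaries (interacting with a
smoker, alcohol in the last hour) as {0, 1}. The motivation item is
administered reverse-coded (higher = lower motivation to avoid smoking), so
its raw scale already points in the risk direction and the score is
monotone nondecreasing in every input. Weights are normalized to sum to
one, making the score weight-scale invariant and bounded in [0, 1].

The weights and the risk threshold belong to a previously estimated lapse
model and are **required configuration**; the shipped defaults
(urge .25, stress .15, alcohol .05, interaction .15, motivation .15,
availability .25; threshold 0.5) are an illustrative, non-canonical
weighting for desk use.

A moment is *high risk* iff any of: score ≥ threshold; the participant
smoked today; smoked yesterday; or the first daily assessment put the
chance of smoking today **strictly above** 25%. The likelihood flag holds
for the whole calendar day by default; a config switch
(`likelihood_flag_scope: next_assessment`) restricts it to the assessment
that carried the item, since the original protocol leaves the flag's
duration open.

## Message routing

Exactly one message per completed EMA:

| context | category |
|---|---|
| prequit | quit-preparation |
| postquit, low risk | motivation / general advice |
| postquit, high risk | tailored to the highest-rated trigger + gum prompt |
| postquit, lapsed & no longer interested | lapse recovery |

The trigger is the argmax of the four current ratings (urge, stress,
availability, reverse-coded motivation compared raw — an assumption, since
the protocol does not state how the "highest rate" compares the
reverse-coded item); ties break by a configured priority, default
urge > availability > stress > motivation, urge being the most proximal
lapse antecedent. Within a category the least-recently-delivered message is
chosen, so content rotates rather than repeats. The nicotine-gum prompt
accompanies every tailored high-risk message and only those. A participant
who reported a lapse and answered that they are no longer interested in
quitting is routed to recovery content until a later report flips the flag;
this keeps the engine's invariant that a trigger is attached exactly to
high-risk, postquit, still-interested decisions. Daily treatment messages
(e.g. quit-date reminders) are *additional* day-level deliveries, not
replacements for EMA-completion messages.

The interest flag travels on in-memory smoking reports only; the fixed EMA
CSV dialect has no column for it, so file-driven `decide` runs treat
everyone as still interested. Smoking flags derive from self-initiated
smoking reports (the diary's previous-day items carry no smoking question
in this schema).

## Synthetic cohort

The generator emulates the statistical structure the engine and analyses
assume, per participant:

- **Compliance** p ~ Beta(8.4, 1.6) (mean 0.84, matching the reported
  overall prompted-EMA compliance); each scheduled prompt before dropout is
  answered with probability p. The compliance denominator excludes
  post-withdrawal prompts — the printed completion totals are consistent
  only with a withdrawal-adjusted denominator, so that convention is used
  rather than reverse-engineering one.
- **Items**: each Likert item is a discretized latent normal
  round(N(μ_item + u, σ_item)) clipped to 1..5, with a person-level trait
  u ~ N(0, 1.0) shared across items and time. The trait produces the
  between-person heterogeneity typical of EMA data (intraclass correlation
  ≈ 0.45 at the default) and gives the risk score enough between-moment
  spread for the lapse slope to be identifiable. Item means/SDs default to
  urge (2.6, 1.1), stress (2.4, 1.1), availability (2.9, 1.3), motivation
  (2.0, 1.0); binaries are Bernoulli (smoker contact .12, alcohol .05);
  the morning likelihood item is 100·Beta(1.2, 2.8).
- **Lapse**: at each answered postquit assessment, lapse ~
  Bernoulli(logistic(α + β·score)), default α = −4, β = 3 (per-assessment
  lapse probability ≈ 2–12% over the typical score range); a lapse emits a
  self-initiated smoking report 10–60 min later. Lapses can only occur at
  answered assessments — a deliberate simplification.
- **Visits** at the quit date, week 4 and week 12: smoking status is "any
  lapse in the preceding 7 days" (1 day at the quit date); beyond the EMA
  window the participant's mean per-assessment lapse probability is carried
  forward as a daily hazard. Expired CO is N(15, 1.5) ppm when smoking,
  N(3, 1.5) when abstinent, truncated at zero; self-report is truthful.
  Only the <6 ppm (<10 quit-date) classification cutoffs are fixed by the
  verification protocol; the CO means are invented and configurable.
- **Dropout**: geometric per-day hazard, default 0.004 (≈ one third of the
  cohort lost by week 13, as in the trial); visits after dropout are
  missing and count as smoking under intent-to-treat.

One global seed fans out through `SeedSequence.spawn` into independent
per-participant streams, so datasets are byte-reproducible and participant
records do not shift when the cohort grows.

What the generator does **not** emulate: time-of-day or day-of-quit trends
in the items (marginals are stationary), item-level missingness within an
answered assessment, misreported abstinence, NRT pharmacology, or any arm
effect on lapse risk (all arms share one generating process). Passing
tests therefore demonstrate that the engine and statistics are correct
under the assumed structure — not that the intervention works, and not
that real EMA trajectories look like these.

## Trial statistics

- **Abstinence**: verified 7-day point prevalence, intent-to-treat —
  abstinent iff self-reported no puff *and* CO strictly below the cutoff;
  any missing component counts as smoking. Pooled percentages are rounded
  half-up to integers for presentation.
- **Chi-square**: Pearson test of independence without continuity
  correction (scipy backend), upper-tail p; zero marginals and nonpositive
  expected counts are rejected.
- **Summary ANOVA**: one-way F rebuilt from per-group (n, mean, SD):
  SSB = Σ nᵢ(mᵢ − m̄)², SSW = Σ (nᵢ−1)sᵢ², F = (SSB/(k−1))/(SSW/(N−k)) —
  algebraically identical to the raw-data ANOVA, verified to 1e-9 in
  tests. Zero within-variance with unequal means is a degenerate input and
  raises.
- **Compensation**: $30/$30/$30/$50 per attended visit plus a tiered bonus
  on the prompted-EMA completion percent, rounded to 0.1 and banded with
  inclusive integer lower edges (50–74 → $50, 75–89 → $100, ≥90 → $150);
  self-initiated reports are never compensated.
- **Patch wear-time recode**: ordinal category → midpoint hours. The three
  anchor recodings (0, 2, 5 h) are fixed; the remaining six labels follow
  the same arithmetic-midpoint rule and are a documented reconstruction of
  the full label set ("7-9"→8 … "at least 22-24"→23).
- **Message distribution**: per-category counts, shares over the four
  high-risk trigger categories (sum to 1 when any exist; flagged
  unavailable on an empty log), per-participant means, per-day counts for
  time-course summaries.

## Numerical and I/O choices

Floating-point output is fixed-format (scores at 6 decimals, CO at 2,
percents at 1) so reruns are byte-stable and checksummable; the pipeline's
provenance record carries the effective config, seed, version and SHA-256
of every artifact. Configs are YAML with unknown keys rejected and a
mandatory seed; tabular logs are CSV with empty strings for missing
fields; decision and event streams are JSON-lines. CLI exit codes: 0
success, 2 validation failure, 3 runtime failure.

## Problem sizes used in the checks

The test suite and the acceptance script size their simulations for desk
runs: compliance recovery uses one 500-participant arm, lapse-slope
recovery refits on 2 000 assessments in tests (≈ 6 400 in the acceptance
script, from a 54-participant arm at α = −2, β = 3 as in the calibration
condition), and the end-to-end pipeline mirrors the 27-per-arm, 81-person
cohort. Slope recovery to ±0.3 at 2 000 assessments is comfortable under
the default trait heterogeneity; with a homogeneous cohort (trait_sd = 0)
the score spread shrinks and the same tolerance would need several-fold
more data.

## Known limitations

The engine's default weights are placeholders, not the estimated ones; the
simulator's arms are exchangeable by construction, so between-arm tests are
calibrated under the null but have no power story; the likelihood-flag
scope and the reverse-coded trigger comparison are documented assumptions;
and the CSV dialect cannot carry the quit-interest flag, so lapse-recovery
routing is exercised only on in-memory logs.
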
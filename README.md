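# quitsense

A just-in-time adaptive intervention (JITAI) engine for smoking cessation,
together with a synthetic trial simulator and the outcome statistics of a
three-arm randomized pilot design.

Smoking lapses are momentary events: most happen within minutes of a
craving, in contexts — stress, easy access to cigarettes, other people
smoking — that a phone can measure in real time. `quitsense` implements the
decision core of such an intervention. Participants answer ecological
momentary assessments (EMAs) five times a day (four random prompts plus a
daily diary) across a 35-day window spanning one prequit and four postquit
weeks. At the completion of every EMA the engine computes a weighted lapse
risk

    score = Σᵢ wᵢ·xᵢ ∈ [0, 1]

over six momentary predictors (urge, stress, cigarette availability,
reverse-coded motivation, smoker contact, recent alcohol), classifies the
moment high risk iff `score ≥ τ`, **or** the participant smoked today or
yesterday, **or** the first daily assessment put their chance of smoking
today strictly above 25% — and then selects exactly one message: quit
preparation before the quit date, motivation/general advice at low risk,
content tailored to the highest-rated of the four lapse triggers (plus a
nicotine-gum prompt) at high risk, and lapse-recovery framing after a lapse
when interest in quitting lapses too.

Around the engine the package provides:

- `quitsense.ema` — study calendar, prompt scheduler (seeded, min-gap
  constrained), response validation, state replay, the CSV dialect;
- `quitsense.engine` — risk scoring, classification, trigger selection,
  least-recently-used message rotation, engagement-event logging;
- `quitsense.simulate` — a seeded synthetic cohort with Beta-distributed
  compliance, latent-normal Likert items, a logistic risk→lapse process,
  CO-verified visits, and dropout;
- `quitsense.stats` — CO-verified intent-to-treat abstinence, per-arm
  tables, Pearson χ², one-way ANOVA from (n, mean, SD) summaries,
  compensation tiers, patch wear-time recoding, message distributions;
- a `quitsense` command line (`simulate`, `decide`, `analyze`,
  `anova-summary`, `run`, `validate`).

It is aimed at mHealth methodologists who want a testable reference
implementation of EMA-driven tailoring rules and the analyses that go with
them; no participant data ship with it.

## Worked example

```python
from quitsense import (GroupSummary, MessageBank, RiskConfig, SimConfig,
                       anova_from_summary, chisq_independence,
                       decide_responses, message_distribution,
                       pooled_abstinence, simulate_trial)

# One-way ANOVA rebuilt from per-arm satisfaction summaries (n, mean, SD)
groups = [GroupSummary(label="usual_care", n=21, mean=4.33, sd=0.66),
          GroupSummary(label="quitguide",  n=22, mean=3.59, sd=1.14),
          GroupSummary(label="smart_t2",   n=22, mean=3.95, sd=0.95)]
print(anova_from_summary(groups))
# (3.318828721050496, 2, 62, 0.042727386995841846)
#  -> F(2,62) = 3.32, p = .043: satisfaction differs across arms

# Across-arm abstinence comparison on a 3x2 count table
print(chisq_independence([[6, 21], [4, 23], [4, 23]]))
# (0.6908315565031982, 2, 0.7079259520545818)
#  -> chi2 = 0.69, p = .71: no detectable arm difference

print(pooled_abstinence({"smart_t2": (6, 27), "quitguide": (4, 27),
                         "usual_care": (4, 27)})["pooled_percent"])
# 17   -> 14/81 verified abstinent, intent-to-treat

# A full synthetic cohort through the tailoring engine
trial = simulate_trial(SimConfig(seed=42, n_per_arm=27))
print(round(trial.completion_rate(), 3))
# 0.839  -> prompted-EMA compliance, Beta(8.4, 1.6) target mean 0.84

decisions = decide_responses(trial.responses(), MessageBank.default(),
                             RiskConfig())
dist = message_distribution([d.to_record() for d in decisions])
print(dist["n_decisions"], round(dist["per_participant_mean"], 1),
      dist["gum_prompts"])
# 4516 167.3 2381  -> one decision per completed EMA in the tailored arm,
#                     gum prompted at every high-risk postquit moment
```

Or from the shell:

```sh
printf 'seed: 42\n' > config.yaml
quitsense run --config config.yaml --out-dir out/
# out/: ema.csv, visits.csv, truth.csv, events.jsonl, decisions.jsonl,
#       report.json, provenance.json (config + SHA-256 checksums;
#       re-running the same seed reproduces identical checksums)
```

The default risk weights and threshold are illustrative placeholders — the
canonical weights belong to a separately estimated lapse model and are
supplied through `RiskConfig` / the YAML `risk:` block. See
`docs/methods.md` for the full model description, defaults, and
limitations.

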
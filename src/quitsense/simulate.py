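"""Synthetic three-arm trial generator.

Emulates the statistical structure the engine and the outcome analyses
assume — per-participant EMA compliance, ordinal momentary items, a
risk-dependent lapse process, biochemically verified visits, and dropout —
so every downstream stage is testable at desk scale without participant
data.

Generating model, per participant:

* prompt-answer probability ``p ~ Beta(compliance_alpha, compliance_beta)``
  (default mean 0.84); each scheduled prompt before dropout is answered
  independently with probability ``p``;
* a person-level risk trait ``u ~ N(0, trait_sd)`` shifts every item's
  latent mean, giving the between-person heterogeneity typical of EMA data;
* Likert items are discretized latent normals ``round(N(mu + u, sigma))``
  clipped to 1..5 (the motivation item is generated on its reverse-coded
  scale, so larger trait means riskier on all items);
* at each answered postquit assessment a lapse occurs with probability
  ``logistic(lapse_intercept + lapse_slope * risk_score)`` and produces a
  self-initiated smoking report shortly afterwards;
* expired CO at a visit is ``N(15, co_noise_sd)`` ppm for a smoking
  participant and ``N(3, co_noise_sd)`` for an abstinent one, truncated at
  zero; missed visits (dropout) have no readings;
* dropout is a per-day geometric hazard; once dropped, prompts, reports and
  visits stop.

Everything is driven by one mandatory seed; identical seeds yield
byte-identical serialized datasets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, Field
from scipy.special import expit

from .ema import (
    PATCH_CATEGORIES,
    EmaResponse,
    StudyCalendar,
    WakingWindow,
    build_schedule,
    write_ema_csv,
)
from .engine import EngagementEvent, RiskConfig, risk_score_values
from .errors import ConfigurationError

ARMS = ("smart_t2", "quitguide", "usual_care")


class LikertParams(BaseModel):
    """Latent-normal mean/SD for one 1-5 item."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    mu: float
    sigma: float = Field(gt=0)


class SimConfig(BaseModel):
    """All tunables of the synthetic cohort (seed is mandatory).

    Defaults mirror the study conditions: 27 participants per arm, mean
    prompted-EMA compliance 0.84, and a lapse process steep enough in the
    risk score that high-risk moments carry materially higher lapse odds.
    """

    model_config = ConfigDict(frozen=True, extra="forbid")

    seed: int
    n_per_arm: int = Field(default=27, ge=1)
    compliance_alpha: float = Field(default=8.4, gt=0)
    compliance_beta: float = Field(default=1.6, gt=0)
    trait_sd: float = Field(default=1.0, ge=0)
    urge: LikertParams = LikertParams(mu=2.6, sigma=1.1)
    stress: LikertParams = LikertParams(mu=2.4, sigma=1.1)
    availability: LikertParams = LikertParams(mu=2.9, sigma=1.3)
    motivation: LikertParams = LikertParams(mu=2.0, sigma=1.0)
    p_with_smoker: float = Field(default=0.12, ge=0, le=1)
    p_alcohol: float = Field(default=0.05, ge=0, le=1)
    likelihood_alpha: float = Field(default=1.2, gt=0)
    likelihood_beta: float = Field(default=2.8, gt=0)
    lapse_intercept: float = -4.0
    lapse_slope: float = 3.0
    p_prequit_smoke_report: float = Field(default=0.9, ge=0, le=1)
    p_urge_report: float = Field(default=0.3, ge=0, le=1)
    p_still_interested: float = Field(default=0.9, ge=0, le=1)
    p_gum_yes: float = Field(default=0.652, ge=0, le=1)
    dropout_hazard: float = Field(default=0.004, ge=0, le=1)
    co_abstinent_mean: float = Field(default=3.0, ge=0)
    co_smoking_mean: float = Field(default=15.0, ge=0)
    co_noise_sd: float = Field(default=1.5, ge=0)
    min_gap: int = Field(default=40, ge=0)


@dataclass
class ParticipantRecord:
    participant_id: str
    arm: str
    compliance_p: float
    dropout_day: Optional[int]
    n_scheduled: int  # prompted EMAs scheduled while still enrolled
    responses: list[EmaResponse]
    truth: list[dict]  # per answered postquit assessment: day, time, risk_score, lapse
    visits: list[dict]
    events: list[EngagementEvent]


@dataclass
class TrialDataset:
    """A full synthetic trial: per-participant logs, events and visits."""

    config: SimConfig
    calendar: StudyCalendar
    participants: list[ParticipantRecord] = field(default_factory=list)

    def responses(self) -> list[EmaResponse]:
        out: list[EmaResponse] = []
        for p in self.participants:
            out.extend(p.responses)
        return out

    def truth_rows(self) -> list[dict]:
        out = []
        for p in self.participants:
            for row in p.truth:
                out.append({"participant_id": p.participant_id, "arm": p.arm, **row})
        return out

    def visit_rows(self) -> list[dict]:
        out = []
        for p in self.participants:
            for row in p.visits:
                out.append({"participant_id": p.participant_id, "arm": p.arm, **row})
        return out

    def completion_rate(self) -> float:
        """Pooled prompted-EMA completion over prompts scheduled while
        enrolled (the denominator excludes post-dropout prompts; self-
        initiated reports never enter the numerator)."""
        scheduled = sum(p.n_scheduled for p in self.participants)
        completed = sum(
            1 for p in self.participants for r in p.responses if r.initiation == "prompted"
        )
        return completed / scheduled if scheduled else float("nan")

    def write(self, out_dir) -> dict[str, Path]:
        """Serialize to ema.csv / visits.csv / truth.csv / events.jsonl."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "ema": out / "ema.csv",
            "visits": out / "visits.csv",
            "truth": out / "truth.csv",
            "events": out / "events.jsonl",
        }
        write_ema_csv(self.responses(), paths["ema"])
        write_visits_csv(self.visit_rows(), paths["visits"])
        with open(paths["truth"], "w") as fh:
            fh.write("participant_id,arm,day,time,risk_score,lapse\n")
            for row in self.truth_rows():
                fh.write(
                    f"{row['participant_id']},{row['arm']},{row['day']},"
                    f"{row['time']},{row['risk_score']:.6f},{int(row['lapse'])}\n"
                )
        with open(paths["events"], "w") as fh:
            for p in self.participants:
                for e in p.events:
                    fh.write(json.dumps(e.model_dump()) + "\n")
        return paths


def write_visits_csv(rows: Sequence[dict], path) -> None:
    with open(path, "w") as fh:
        fh.write("participant_id,arm,visit,day,attended,self_report_no_puff,co_ppm\n")
        for r in rows:
            sr = "" if r["self_report_no_puff"] is None else str(int(r["self_report_no_puff"]))
            co = "" if r["co_ppm"] is None else f"{r['co_ppm']:.2f}"
            fh.write(
                f"{r['participant_id']},{r['arm']},{r['visit']},{r['day']},"
                f"{int(r['attended'])},{sr},{co}\n"
            )


def _draw_likert(rng: np.random.Generator, params: LikertParams, trait: float) -> int:
    return int(np.clip(np.rint(rng.normal(params.mu + trait, params.sigma)), 1, 5))


def _items(config: SimConfig, rng: np.random.Generator, trait: float) -> dict:
    return {
        "urge": _draw_likert(rng, config.urge, trait),
        "stress": _draw_likert(rng, config.stress, trait),
        "cigarette_availability": _draw_likert(rng, config.availability, trait),
        "motivation_to_avoid": _draw_likert(rng, config.motivation, trait),
        "interacting_with_smoker": bool(rng.random() < config.p_with_smoker),
        "alcohol_last_hour": bool(rng.random() < config.p_alcohol),
    }


def simulate_participant(
    config: SimConfig,
    arm: str,
    rng: np.random.Generator,
    participant_id: str,
    calendar: StudyCalendar | None = None,
    window: WakingWindow | None = None,
    risk_config: RiskConfig | None = None,
) -> ParticipantRecord:
    """Simulate one participant's full EMA trajectory, visits and events."""
    if arm not in ARMS:
        raise ConfigurationError(f"unknown arm {arm!r}")
    calendar = calendar or StudyCalendar()
    window = window or WakingWindow()
    risk_config = risk_config or RiskConfig()

    compliance_p = float(rng.beta(config.compliance_alpha, config.compliance_beta))
    trait = float(rng.normal(0.0, config.trait_sd)) if config.trait_sd > 0 else 0.0
    horizon = calendar.followup_days[-1]
    if config.dropout_hazard > 0:
        d = int(rng.geometric(config.dropout_hazard))
        dropout_day: Optional[int] = d if d <= horizon else None
    else:
        dropout_day = None

    schedule = build_schedule(calendar, window, config.min_gap, rng, participant_id)
    responses: list[EmaResponse] = []
    truth: list[dict] = []
    lapse_days: set[int] = set()
    n_scheduled = 0

    for prompt in schedule:
        if dropout_day is not None and prompt.day >= dropout_day:
            continue
        n_scheduled += 1
        if rng.random() >= compliance_p:
            continue
        items = _items(config, rng, trait)
        completed_at = int(prompt.time + rng.integers(0, 6))
        extras: dict = {}
        if prompt.kind == "daily_diary":
            extras = {
                "likelihood_smoke_today": round(
                    100.0 * float(rng.beta(config.likelihood_alpha, config.likelihood_beta)), 1
                ),
                "gum_pieces": int(min(rng.poisson(5.1), 8)),
                "patch_category": PATCH_CATEGORIES[int(np.clip(np.rint(rng.normal(7.0, 1.5)), 0, 8))],
                "drinks": int(min(rng.poisson(0.5), 8)),
            }
        resp = EmaResponse(
            participant_id=participant_id,
            arm=arm,  # type: ignore[arg-type]
            day=prompt.day,
            time=prompt.time,
            kind=prompt.kind,
            initiation="prompted",
            completed_at=completed_at,
            **items,
            **extras,
        )
        responses.append(resp)

        if prompt.day >= calendar.quit_day:
            score = float(
                risk_score_values(
                    items["urge"],
                    items["stress"],
                    items["cigarette_availability"],
                    items["motivation_to_avoid"],
                    items["interacting_with_smoker"],
                    items["alcohol_last_hour"],
                    risk_config,
                )
            )
            lapse = bool(
                rng.random() < expit(config.lapse_intercept + config.lapse_slope * score)
            )
            truth.append(
                {"day": prompt.day, "time": prompt.time, "risk_score": score, "lapse": lapse}
            )
            if lapse:
                lapse_days.add(prompt.day)
                report_at = int(min(completed_at + rng.integers(10, 61), 1439))
                responses.append(
                    EmaResponse(
                        participant_id=participant_id,
                        arm=arm,  # type: ignore[arg-type]
                        day=prompt.day,
                        time=report_at,
                        kind=None,
                        initiation="smoking_report",
                        completed_at=report_at,
                        still_interested_in_quitting=bool(
                            rng.random() < config.p_still_interested
                        ),
                        **_items(config, rng, trait),
                    )
                )

    # self-initiated reports: prequit smoking, postquit urges
    for day in calendar.ema_days:
        if dropout_day is not None and day >= dropout_day:
            break
        at = int(rng.integers(window.start, window.end))
        if day < calendar.quit_day:
            if rng.random() < config.p_prequit_smoke_report:
                responses.append(
                    EmaResponse(
                        participant_id=participant_id,
                        arm=arm,  # type: ignore[arg-type]
                        day=day,
                        time=at,
                        kind=None,
                        initiation="smoking_report",
                        completed_at=at,
                        **_items(config, rng, trait),
                    )
                )
        elif rng.random() < config.p_urge_report:
            responses.append(
                EmaResponse(
                    participant_id=participant_id,
                    arm=arm,  # type: ignore[arg-type]
                    day=day,
                    time=at,
                    kind=None,
                    initiation="urge_report",
                    completed_at=at,
                    **_items(config, rng, trait),
                )
            )

    responses.sort(key=lambda r: (r.day, r.completed_at, r.time))

    # smoking beyond the EMA window (needed for the 12-week visit): carry the
    # participant's mean per-assessment lapse probability forward as a daily
    # hazard over ~4.2 answered assessments per day
    if truth:
        p_assess = float(np.mean([expit(config.lapse_intercept + config.lapse_slope * t["risk_score"]) for t in truth]))
    else:
        p_assess = float(expit(config.lapse_intercept + config.lapse_slope * 0.3))
    p_daily = 1.0 - (1.0 - p_assess) ** 4.2
    for day in range(calendar.ema_end_day, horizon):
        if dropout_day is not None and day >= dropout_day:
            break
        if rng.random() < p_daily:
            lapse_days.add(day)

    visits = _visits(calendar, dropout_day, lapse_days, config, rng)
    events = _events(config, arm, rng, participant_id, calendar, dropout_day, window)
    return ParticipantRecord(
        participant_id=participant_id,
        arm=arm,
        compliance_p=compliance_p,
        dropout_day=dropout_day,
        n_scheduled=n_scheduled,
        responses=responses,
        truth=truth,
        visits=visits,
        events=events,
    )


def _visits(calendar, dropout_day, lapse_days, config, rng) -> list[dict]:
    co_sd = config.co_noise_sd
    out = []
    for visit, day, lookback in (
        ("quit_date", calendar.quit_day, 1),
        ("week4", calendar.followup_days[0], 7),
        ("week12", calendar.followup_days[1], 7),
    ):
        attended = dropout_day is None or day < dropout_day
        if not attended:
            out.append(
                {"visit": visit, "day": day, "attended": False, "self_report_no_puff": None, "co_ppm": None}
            )
            continue
        smoking = any(d in lapse_days for d in range(day - lookback, day + 1))
        mean = config.co_smoking_mean if smoking else config.co_abstinent_mean
        co = float(max(0.0, rng.normal(mean, co_sd))) if co_sd > 0 else float(mean)
        out.append(
            {
                "visit": visit,
                "day": day,
                "attended": True,
                "self_report_no_puff": not smoking,
                "co_ppm": round(co, 2),
            }
        )
    return out


def _events(config, arm, rng, participant_id, calendar, dropout_day, window) -> list[EngagementEvent]:
    """Light-touch on-demand engagement; app arms only."""
    if arm == "usual_care":
        return []
    last_day = calendar.ema_end_day if dropout_day is None else min(dropout_day, calendar.ema_end_day)
    if last_day <= 0:
        return []
    kinds = [("app_open", 10.0), ("quit_tip_view", 2.0), ("medication_tip_view", 1.0), ("call_counselor", 0.9), ("order_nrt", 0.8)]
    events = []
    for kind, lam in kinds:
        for _ in range(int(rng.poisson(lam))):
            day = int(rng.integers(0, last_day))
            events.append(
                EngagementEvent(
                    participant_id=participant_id,
                    kind=kind,
                    day=day,
                    at=int(rng.integers(window.start, window.end)),
                )
            )
    events.sort(key=lambda e: (e.day, e.at, e.kind))
    return events


def simulate_trial(
    config: SimConfig,
    arms: Sequence[str] = ARMS,
    calendar: StudyCalendar | None = None,
    window: WakingWindow | None = None,
    risk_config: RiskConfig | None = None,
) -> TrialDataset:
    """Simulate balanced arms of ``n_per_arm`` independent participants.

    Each participant consumes an independent child stream of the global
    seed, so the dataset is reproducible and participants are exchangeable.
    """
    calendar = calendar or StudyCalendar()
    dataset = TrialDataset(config=config, calendar=calendar)
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(len(arms) * config.n_per_arm)
    idx = 0
    for arm in arms:
        for j in range(config.n_per_arm):
            pid = f"{arm[:2].upper()}{j + 1:03d}"
            rng = np.random.default_rng(children[idx])
            idx += 1
            dataset.participants.append(
                simulate_participant(config, arm, rng, pid, calendar, window, risk_config)
            )
    return dataset


def refit_lapse_model(scores, lapses) -> tuple[float, float]:
    """Maximum-likelihood logistic refit of (intercept, slope) from
    per-assessment (risk score, lapse) pairs — the simulator's own
    parameter-recovery check."""
    import statsmodels.api as sm

    x = sm.add_constant(np.asarray(scores, dtype=float))
    fit = sm.Logit(np.asarray(lapses, dtype=float), x).fit(disp=0)
    return float(fit.params[0]), float(fit.params[1])
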
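"""The tailoring engine: lapse-risk scoring, high-risk classification,
trigger-tailored message selection, gum prompting, and engagement logging.

At the completion of every EMA the engine computes a weighted lapse-risk
score from six momentary predictors, classifies the moment as low or high
risk, and selects exactly one intervention message:

* prequit phase — quit-preparation content;
* postquit, low risk — abstinence-motivation / general-advice content;
* postquit, high risk — content tailored to the highest-rated of four
  current lapse triggers (urge, stress, cigarette availability, low
  motivation), accompanied by a prompt to chew a piece of nicotine gum;
* postquit, lapsed and no longer interested in quitting — lapse-recovery
  content framing the lapse as a learning experience.

The six predictor weights and the risk threshold come from a previously
estimated lapse-risk model and are therefore required configuration inputs
here; the shipped defaults are an illustrative, non-canonical weighting for
desk use only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .ema import EmaResponse, ParticipantState, StudyCalendar, initial_state, update_state
from .errors import BankError, ConfigurationError, QuitsenseError

Trigger = Literal["urge", "stress", "availability", "motivation"]
RiskClass = Literal["low", "high"]

TRIGGERS: tuple[Trigger, ...] = ("urge", "stress", "availability", "motivation")

MessageCategory = Literal[
    "prequit_prep",
    "low_risk",
    "high_risk_urge",
    "high_risk_stress",
    "high_risk_availability",
    "high_risk_motivation",
    "lapse_recovery",
    "daily_treatment",
    "gum_prompt",
]
MESSAGE_CATEGORIES: tuple[str, ...] = MessageCategory.__args__  # type: ignore[attr-defined]

#: Fixed text of the nicotine-gum prompt shown at every high-risk moment.
GUM_PROMPT_TEXT = (
    "Chewing a piece of nicotine gum right now may reduce your risk for "
    "smoking. Will you chew a piece of nicotine gum right now?"
)

EVENT_KINDS = (
    "quit_tip_view",
    "medication_tip_view",
    "call_counselor",
    "order_nrt",
    "call_staff",
    "payment_view",
    "gum_yes",
    "gum_no",
    "app_open",
    "app_action",
)


class RiskConfig(BaseModel):
    """Weights and thresholds of the lapse-risk classifier.

    Weights must be nonnegative and are normalized to sum to one, so the
    score always lands in [0, 1] regardless of the raw weight scale.  The
    default weights are illustrative only — the canonical values belong to
    the prior lapse-estimator study and must be supplied by the user.

    ``likelihood_threshold`` is the percent answer to the morning "chance I
    smoke today" item above which (strictly) the whole day is flagged
    high risk; ``likelihood_flag_scope`` can restrict the flag to the next
    assessment instead of the full calendar day.
    """

    model_config = ConfigDict(frozen=True, extra="forbid")

    w_urge: float = 0.25
    w_stress: float = 0.15
    w_alcohol: float = 0.05
    w_interaction: float = 0.15
    w_motivation: float = 0.15
    w_availability: float = 0.25
    risk_threshold: float = Field(default=0.5, ge=0.0, le=1.0)
    likelihood_threshold: float = Field(default=25.0, ge=0.0, le=100.0)
    trigger_priority: tuple[Trigger, Trigger, Trigger, Trigger] = (
        "urge",
        "availability",
        "stress",
        "motivation",
    )
    likelihood_flag_scope: Literal["day", "next_assessment"] = "day"

    @model_validator(mode="after")
    def _normalize(self) -> "RiskConfig":
        raw = [
            self.w_urge,
            self.w_stress,
            self.w_alcohol,
            self.w_interaction,
            self.w_motivation,
            self.w_availability,
        ]
        if any(w < 0 for w in raw):
            raise ValueError("risk weights must be nonnegative")
        total = sum(raw)
        if total <= 0:
            raise ValueError("risk weights must not all be zero")
        if abs(total - 1.0) > 1e-12:
            for name, w in zip(
                ("w_urge", "w_stress", "w_alcohol", "w_interaction", "w_motivation", "w_availability"),
                raw,
            ):
                object.__setattr__(self, name, w / total)
        if set(self.trigger_priority) != set(TRIGGERS):
            raise ValueError("trigger_priority must be a permutation of the four triggers")
        return self


def risk_score_values(urge, stress, availability, motivation, with_smoker, alcohol, config: RiskConfig):
    """Weighted lapse-risk score from raw item values; array-compatible.

    Likert items are rescaled from {1..5} to [0, 1] via (x - 1) / 4.  The
    motivation item arrives reverse-coded (higher = lower motivation to
    avoid smoking), so its raw value is used directly and the score is
    monotone *increasing* in every argument.  Booleans map to {0, 1}.
    """
    u = (np.asarray(urge, dtype=float) - 1.0) / 4.0
    s = (np.asarray(stress, dtype=float) - 1.0) / 4.0
    a = (np.asarray(availability, dtype=float) - 1.0) / 4.0
    m = (np.asarray(motivation, dtype=float) - 1.0) / 4.0
    smoker = np.asarray(with_smoker, dtype=float)
    alc = np.asarray(alcohol, dtype=float)
    score = (
        config.w_urge * u
        + config.w_stress * s
        + config.w_availability * a
        + config.w_motivation * m
        + config.w_interaction * smoker
        + config.w_alcohol * alc
    )
    return score if score.ndim else float(score)


def compute_risk_score(response: EmaResponse, config: RiskConfig) -> float:
    """Score one validated response; returns a fraction in [0, 1]."""
    return float(
        risk_score_values(
            response.urge,
            response.stress,
            response.cigarette_availability,
            response.motivation_to_avoid,
            response.interacting_with_smoker,
            response.alcohol_last_hour,
            config,
        )
    )


def classify_values(score, smoked_today, smoked_yesterday, first_daily_likelihood, config: RiskConfig):
    """High/low decision from precomputed inputs; array-compatible.

    High iff the score reaches the threshold, OR the participant smoked
    today or yesterday, OR the first daily assessment put the chance of
    smoking today strictly above the likelihood threshold.  Absent
    likelihood answers are encoded as NaN (never exceed the threshold).
    """
    lik = np.asarray(first_daily_likelihood, dtype=float)
    lik_flag = np.where(np.isnan(lik), False, lik > config.likelihood_threshold)
    high = (
        (np.asarray(score, dtype=float) >= config.risk_threshold)
        | np.asarray(smoked_today, dtype=bool)
        | np.asarray(smoked_yesterday, dtype=bool)
        | lik_flag
    )
    return high if high.ndim else bool(high)


def classify_risk(state: ParticipantState, response: EmaResponse, config: RiskConfig) -> RiskClass:
    """Classify the current moment as ``"low"`` or ``"high"`` risk."""
    likelihood = state.first_daily_likelihood
    if config.likelihood_flag_scope == "next_assessment" and response.likelihood_smoke_today is None:
        # flag applies only to the assessment that carried the item
        likelihood = None
    score = compute_risk_score(response, config)
    high = classify_values(
        score,
        state.smoked_today,
        state.smoked_yesterday,
        np.nan if likelihood is None else likelihood,
        config,
    )
    return "high" if high else "low"


def select_trigger(response: EmaResponse, priority: Sequence[Trigger]) -> Trigger:
    """Pick the highest-rated of the four current lapse triggers.

    The motivation item is already reverse-coded, so all four ratings live
    on a comparable 1-5 scale where higher = more trigger-like.  Ties break
    by the configured priority order.
    """
    ratings = {
        "urge": response.urge,
        "stress": response.stress,
        "availability": response.cigarette_availability,
        "motivation": response.motivation_to_avoid,
    }
    best = priority[0]
    for trig in priority[1:]:
        if ratings[trig] > ratings[best]:
            best = trig
    return best


@dataclass(frozen=True)
class Message:
    id: str
    category: MessageCategory
    text: str

    def __post_init__(self):
        if self.category not in MESSAGE_CATEGORIES:
            raise BankError(f"unknown message category {self.category!r}")


class MessageBank:
    """Categorized intervention content with least-recently-used rotation."""

    def __init__(self, messages: Iterable[Message]):
        self._by_category: dict[str, list[Message]] = {c: [] for c in MESSAGE_CATEGORIES}
        for msg in messages:
            self._by_category[msg.category].append(msg)

    @classmethod
    def from_json(cls, source) -> "MessageBank":
        """Load from a JSON list of ``{id, category, text}`` objects."""
        if hasattr(source, "read"):
            entries = json.load(source)
        else:
            with open(source) as fh:
                entries = json.load(fh)
        return cls(Message(e["id"], e["category"], e["text"]) for e in entries)

    @classmethod
    def default(cls) -> "MessageBank":
        """The stub bank shipped with the package (non-clinical content)."""
        with resources.files("quitsense.data").joinpath("default_bank.json").open() as fh:
            return cls.from_json(fh)

    def messages(self, category: str) -> list[Message]:
        if category not in self._by_category:
            raise BankError(f"unknown message category {category!r}")
        return list(self._by_category[category])

    def require(self, category: str) -> list[Message]:
        msgs = self.messages(category)
        if not msgs:
            raise BankError(f"message bank has no messages in category {category!r}")
        return msgs

    @property
    def gum_message(self) -> Message:
        return self.require("gum_prompt")[0]


class DeliveryHistory:
    """Tracks delivery order so each category rotates least-recently-used."""

    def __init__(self):
        self._last_used: dict[str, int] = {}
        self._counter = 0

    def pick(self, candidates: Sequence[Message]) -> Message:
        # never-delivered messages sort first (in bank order), then oldest
        best = min(
            range(len(candidates)),
            key=lambda i: (self._last_used.get(candidates[i].id, -1), i),
        )
        msg = candidates[best]
        self._counter += 1
        self._last_used[msg.id] = self._counter
        return msg


@dataclass(frozen=True)
class Decision:
    """The engine's output for one completed EMA."""

    participant_id: str
    day: int
    time: int
    risk_score: float
    risk_class: RiskClass
    trigger: Optional[Trigger]
    message: Message
    gum_prompt: bool

    def to_record(self) -> dict:
        return {
            "participant_id": self.participant_id,
            "day": self.day,
            "time": self.time,
            "score": round(self.risk_score, 6),
            "class": self.risk_class,
            "trigger": self.trigger,
            "message_id": self.message.id,
            "gum": self.gum_prompt,
        }


def deliver_message(
    state: ParticipantState,
    response: EmaResponse,
    bank: MessageBank,
    history: DeliveryHistory,
    config: RiskConfig,
) -> Decision:
    """Route one completed EMA to exactly one intervention message.

    ``state`` must already reflect this response (i.e. be the post-update
    state), so same-moment smoking reports and the morning likelihood answer
    participate in the classification.
    """
    score = compute_risk_score(response, config)
    risk_class: RiskClass = classify_risk(state, response, config)
    trigger: Optional[Trigger] = None
    gum = False

    if state.phase == "prequit":
        category = "prequit_prep"
    elif state.quit_interest == "not_interested":
        # lapsed and disengaged from the quit attempt: recovery framing
        category = "lapse_recovery"
    elif risk_class == "high":
        trigger = select_trigger(response, config.trigger_priority)
        category = f"high_risk_{trigger}"
        gum = True
    else:
        category = "low_risk"

    message = history.pick(bank.require(category))
    return Decision(
        participant_id=response.participant_id,
        day=response.day,
        time=response.completed_at,
        risk_score=score,
        risk_class=risk_class,
        trigger=trigger,
        message=message,
        gum_prompt=gum,
    )


def daily_treatment_message(
    day: int, calendar: StudyCalendar, bank: MessageBank, history: DeliveryHistory
) -> Message:
    """One additional day-level treatment message (e.g. quit-date reminders).

    Delivered in addition to, not instead of, the per-EMA messages.
    """
    if day not in calendar.ema_days:
        raise QuitsenseError(f"day {day} is outside the EMA window")
    return history.pick(bank.require("daily_treatment"))


def decide_responses(
    responses: Iterable[EmaResponse],
    bank: MessageBank,
    config: RiskConfig,
    calendar: StudyCalendar | None = None,
    arm_filter: str | None = "smart_t2",
) -> list[Decision]:
    """Replay a chronological multi-participant response log through the
    engine, producing exactly one decision per completed EMA.

    Responses are grouped by participant; each participant gets an
    independent state trajectory and delivery history.  ``arm_filter``
    restricts tailoring to participants in the given arm (the engine runs
    only for the tailored-treatment arm in a trial); pass ``None`` to decide
    for every participant.
    """
    calendar = calendar or StudyCalendar()
    states: dict[str, ParticipantState] = {}
    histories: dict[str, DeliveryHistory] = {}
    decisions: list[Decision] = []
    for resp in responses:
        if arm_filter is not None and resp.arm is not None and resp.arm != arm_filter:
            continue
        pid = resp.participant_id
        if pid not in states:
            states[pid] = initial_state(resp.arm or "smart_t2", calendar)
            histories[pid] = DeliveryHistory()
        states[pid] = update_state(states[pid], resp, resp.day)
        decisions.append(deliver_message(states[pid], resp, bank, histories[pid], config))
    return decisions


# ---------------------------------------------------------------------------
# Engagement events
# ---------------------------------------------------------------------------


class EngagementEvent(BaseModel):
    """A single on-demand/app interaction (append-only audit record)."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    participant_id: str
    kind: str
    subcategory: Optional[str] = None
    day: int = Field(ge=0)
    at: int = Field(ge=0)  # minutes from midnight

    @model_validator(mode="after")
    def _known_kind(self) -> "EngagementEvent":
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")
        return self


@dataclass
class EventLog:
    """Append-only store of engagement events with count queries."""

    events: list[EngagementEvent] = field(default_factory=list)

    def record(self, event: EngagementEvent) -> "EventLog":
        if event.kind not in EVENT_KINDS:
            raise QuitsenseError(f"unknown event kind {event.kind!r}")
        self.events.append(event)
        return self

    def count(self, kind: str | None = None, subcategory: str | None = None, day: int | None = None) -> int:
        return sum(
            1
            for e in self.events
            if (kind is None or e.kind == kind)
            and (subcategory is None or e.subcategory == subcategory)
            and (day is None or e.day == day)
        )

    def gum_yes_fraction(self) -> float | None:
        """Fraction of gum prompts answered yes; None when none were answered."""
        yes = self.count("gum_yes")
        no = self.count("gum_no")
        if yes + no == 0:
            return None
        return yes / (yes + no)

    def to_records(self) -> list[dict]:
        return [e.model_dump() for e in self.events]


def write_decisions_jsonl(decisions: Iterable[Decision], path) -> None:
    with open(path, "w") as fh:
        for d in decisions:
            fh.write(json.dumps(d.to_record()) + "\n")


def read_decisions_jsonl(path) -> list[dict]:
    with open(path) as fh:
        return [json.loads(line) for line in fh if line.strip()]
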
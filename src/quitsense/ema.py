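"""Study calendar, EMA prompts/responses, and the prompt scheduler.

The study design places a quit date one week after baseline and follows
participants with ecological momentary assessments (EMAs) for 35 consecutive
days: 7 prequit days and 28 postquit days.  Each day carries five prompted
assessments — one daily diary (scheduled first, and the only assessment that
asks the "chance I smoke today" item and the previous-day diary items) and
four random assessments at unpredictable times within the waking window.
Participants may additionally self-initiate urge or smoking reports at any
time; those never count toward prompted-EMA compliance.
"""

from __future__ import annotations

import csv
import dataclasses
from dataclasses import dataclass
from typing import Iterable, Iterator, Literal, Mapping, Optional, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .errors import ConfigurationError, OrderingError, ResponseValidationError

PREQUIT_DAYS = 7
POSTQUIT_DAYS = 28
PROMPTS_PER_DAY = 5
RANDOM_PROMPTS_PER_DAY = 4

Arm = Literal["smart_t2", "quitguide", "usual_care"]
PromptKind = Literal["random", "daily_diary"]
Initiation = Literal["prompted", "urge_report", "smoking_report"]
Phase = Literal["prequit", "postquit"]

#: Ordinal labels for the nightly patch wear-time item, in increasing order.
PATCH_CATEGORIES = (
    "I did not wear it at all",
    "Less than 3 hours",
    "4-6 hours",
    "7-9 hours",
    "10-12 hours",
    "13-15 hours",
    "16-18 hours",
    "19-21 hours",
    "At least 22-24 hours",
)


class StudyCalendar(BaseModel):
    """Day indexing for the trial: 0-based days from the baseline visit.

    The quit date is exactly one week after baseline and the EMA window ends
    four weeks after the quit date, so the window spans 35 consecutive days
    (``ema_end_day`` is exclusive).  ``followup_days`` hold the 4-week and
    12-week postquit visit days.
    """

    model_config = ConfigDict(frozen=True)

    baseline_day: int = 0
    quit_day: int = 7
    ema_end_day: int = 35
    followup_days: tuple[int, int] = (35, 91)

    @model_validator(mode="after")
    def _check_span(self) -> "StudyCalendar":
        if self.quit_day != self.baseline_day + PREQUIT_DAYS:
            raise ValueError("quit_day must be exactly 7 days after baseline_day")
        if self.ema_end_day != self.quit_day + POSTQUIT_DAYS:
            raise ValueError("ema_end_day must be exactly 28 days after quit_day")
        if list(self.followup_days) != sorted(self.followup_days):
            raise ValueError("followup_days must be increasing")
        return self

    @property
    def ema_days(self) -> range:
        return range(self.baseline_day, self.ema_end_day)

    @property
    def n_ema_days(self) -> int:
        return self.ema_end_day - self.baseline_day

    def phase(self, day: int) -> Phase:
        return "prequit" if day < self.quit_day else "postquit"


class WakingWindow(BaseModel):
    """Daily window (minutes from midnight) in which prompts may fire."""

    model_config = ConfigDict(frozen=True)

    start: int = Field(default=480, ge=0, lt=1440)  # 08:00
    end: int = Field(default=1320, gt=0, le=1440)  # 22:00

    @model_validator(mode="after")
    def _check(self) -> "WakingWindow":
        if self.end <= self.start:
            raise ValueError("window end must be after start")
        return self

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True, order=True)
class EmaPrompt:
    """One scheduled assessment: a daily diary or a random prompt."""

    participant_id: str
    day: int
    time: int  # minutes from midnight
    kind: PromptKind


def build_schedule(
    calendar: StudyCalendar,
    window: WakingWindow | None = None,
    min_gap: int = 40,
    seed: int | np.random.Generator = 0,
    participant_id: str = "P001",
) -> list[EmaPrompt]:
    """Generate the full 35-day prompt schedule for one participant.

    The daily diary is pinned to the start of the waking window (it is the
    first assessment of every day).  The four random prompts are drawn
    uniformly over the remainder of the window under a pairwise minimum gap,
    enforced against the diary as well, using the standard spacing
    construction: sort four uniform draws on the gap-shrunk interval and add
    back ``min_gap`` multiples.

    Parameters
    ----------
    min_gap:
        Minimum separation in minutes between any two same-day prompts.
    seed:
        Integer seed or an existing :class:`numpy.random.Generator`; the same
        seed always yields the identical schedule.
    """
    window = window or WakingWindow()
    if min_gap < 0:
        raise ConfigurationError("min_gap must be nonnegative")
    if window.length < PROMPTS_PER_DAY * min_gap:
        raise ConfigurationError(
            f"waking window of {window.length} min cannot hold "
            f"{PROMPTS_PER_DAY} prompts {min_gap} min apart"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    k = RANDOM_PROMPTS_PER_DAY
    lo = window.start + min_gap  # diary occupies window.start
    hi = window.end - (k - 1) * min_gap
    if hi < lo:
        raise ConfigurationError("window/min_gap combination is infeasible")

    prompts: list[EmaPrompt] = []
    offsets = min_gap * np.arange(k)
    for day in calendar.ema_days:
        prompts.append(EmaPrompt(participant_id, day, window.start, "daily_diary"))
        draws = np.sort(rng.integers(lo, hi + 1, size=k)) + offsets
        for t in draws:
            prompts.append(EmaPrompt(participant_id, day, int(t), "random"))
    return prompts


class EmaResponse(BaseModel):
    """One completed assessment (prompted or self-initiated).

    All four Likert items share the 1-5 agreement scale.  The motivation item
    is reverse-coded (1 = strongly agree I am motivated to avoid smoking,
    5 = strongly disagree), so a *higher* value means *lower* motivation and
    therefore higher lapse risk; it is used raw everywhere downstream.

    The "likelihood I smoke today" percent item appears only on the daily
    diary (the first assessment of each day); the previous-day diary items
    (gum pieces, patch wear category, drinks) likewise appear iff the
    response is a daily diary.

    ``still_interested_in_quitting`` is the follow-up question attached to a
    postquit smoking report; it has no column in the CSV dialect and is only
    populated on in-memory records.
    """

    model_config = ConfigDict(frozen=True, extra="forbid")

    participant_id: str
    arm: Optional[Arm] = None
    day: int = Field(ge=0)
    time: int = Field(ge=0, lt=1440)
    kind: Optional[PromptKind] = None
    initiation: Initiation = "prompted"
    urge: int = Field(ge=1, le=5)
    stress: int = Field(ge=1, le=5)
    cigarette_availability: int = Field(ge=1, le=5)
    motivation_to_avoid: int = Field(ge=1, le=5)
    interacting_with_smoker: bool = False
    alcohol_last_hour: bool = False
    likelihood_smoke_today: Optional[float] = Field(default=None, ge=0, le=100)
    gum_pieces: Optional[int] = Field(default=None, ge=0, le=8)
    patch_category: Optional[str] = None
    drinks: Optional[int] = Field(default=None, ge=0, le=8)
    completed_at: int = Field(ge=0)
    still_interested_in_quitting: Optional[bool] = None

    @model_validator(mode="after")
    def _presence_rules(self) -> "EmaResponse":
        if self.initiation == "prompted" and self.kind is None:
            raise ValueError("prompted responses must carry the prompt kind")
        if self.initiation != "prompted" and self.kind is not None:
            raise ValueError("self-initiated responses have no prompt kind")
        is_diary = self.kind == "daily_diary"
        diary_extras = {
            "gum_pieces": self.gum_pieces,
            "patch_category": self.patch_category,
            "drinks": self.drinks,
        }
        if not is_diary:
            for name, value in diary_extras.items():
                if value is not None:
                    raise ValueError(f"{name} is a daily-diary item only")
            if self.likelihood_smoke_today is not None:
                raise ValueError(
                    "likelihood_smoke_today is asked only on the daily diary"
                )
        if self.patch_category is not None and self.patch_category not in PATCH_CATEGORIES:
            raise ValueError(f"unknown patch category {self.patch_category!r}")
        return self

    @property
    def is_daily_diary(self) -> bool:
        return self.kind == "daily_diary"


def validate_response(data: "EmaResponse | Mapping") -> EmaResponse:
    """Validate a raw record, returning the typed response or raising
    :class:`ResponseValidationError` naming the offending field."""
    try:
        if isinstance(data, EmaResponse):
            return EmaResponse.model_validate(data.model_dump())
        return EmaResponse.model_validate(dict(data))
    except ValidationError as exc:
        err = exc.errors()[0]
        field = ".".join(str(p) for p in err["loc"]) or "record"
        raise ResponseValidationError(field, err["msg"]) from exc


@dataclass(frozen=True)
class ParticipantState:
    """Running per-participant state replayed from the response log.

    ``smoked_today``/``smoked_yesterday`` derive from self-initiated smoking
    reports; the day rollover shifts today's flag into yesterday's.
    ``first_daily_likelihood`` holds the percent answer from the first
    assessment of the current day that carried the item, and resets at each
    rollover.
    """

    arm: Arm
    quit_day: int
    day: int = 0
    smoked_today: bool = False
    smoked_yesterday: bool = False
    first_daily_likelihood: Optional[float] = None
    quit_interest: Literal["interested", "not_interested"] = "interested"
    last_completed_at: int = -1

    @property
    def phase(self) -> Phase:
        return "prequit" if self.day < self.quit_day else "postquit"


def initial_state(arm: Arm, calendar: StudyCalendar) -> ParticipantState:
    return ParticipantState(arm=arm, quit_day=calendar.quit_day, day=calendar.baseline_day)


def update_state(state: ParticipantState, response: EmaResponse, day: int) -> ParticipantState:
    """Apply one response (in chronological order) and return the new state."""
    if day < state.day:
        raise OrderingError(f"response for day {day} after state already at day {state.day}")
    if day == state.day and response.completed_at < state.last_completed_at:
        raise OrderingError(
            f"response at {response.completed_at} min precedes the previous "
            f"response at {state.last_completed_at} min on day {day}"
        )

    smoked_today = state.smoked_today
    smoked_yesterday = state.smoked_yesterday
    likelihood = state.first_daily_likelihood
    cur_day = state.day
    last_at = state.last_completed_at
    while cur_day < day:  # rollover: today's flag becomes yesterday's
        smoked_yesterday = smoked_today
        smoked_today = False
        likelihood = None
        last_at = -1
        cur_day += 1

    quit_interest = state.quit_interest
    if response.initiation == "smoking_report":
        smoked_today = True
        if response.still_interested_in_quitting is not None:
            quit_interest = (
                "interested" if response.still_interested_in_quitting else "not_interested"
            )
    if response.likelihood_smoke_today is not None and likelihood is None:
        likelihood = response.likelihood_smoke_today

    return dataclasses.replace(
        state,
        day=cur_day,
        smoked_today=smoked_today,
        smoked_yesterday=smoked_yesterday,
        first_daily_likelihood=likelihood,
        quit_interest=quit_interest,
        last_completed_at=max(last_at, response.completed_at),
    )


def replay(
    responses: Iterable[EmaResponse], state: ParticipantState
) -> Iterator[tuple[ParticipantState, EmaResponse]]:
    """Yield ``(state_after, response)`` pairs, replaying chronologically."""
    for resp in responses:
        state = update_state(state, resp, resp.day)
        yield state, resp


# ---------------------------------------------------------------------------
# CSV dialect
# ---------------------------------------------------------------------------

EMA_COLUMNS = [
    "participant_id",
    "arm",
    "day",
    "time",
    "kind",
    "initiation",
    "urge",
    "stress",
    "availability",
    "motivation",
    "with_smoker",
    "alcohol",
    "likelihood",
    "gum_pieces",
    "patch_category",
    "drinks",
    "completed",
]

SCHEDULE_COLUMNS = ["participant_id", "day", "time", "kind"]


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "1" if value else "0"
    if isinstance(value, float):
        return f"{value:.1f}"
    return str(value)


def response_to_row(resp: EmaResponse) -> dict[str, str]:
    return {
        "participant_id": resp.participant_id,
        "arm": _fmt(resp.arm),
        "day": _fmt(resp.day),
        "time": _fmt(resp.time),
        "kind": _fmt(resp.kind),
        "initiation": resp.initiation,
        "urge": _fmt(resp.urge),
        "stress": _fmt(resp.stress),
        "availability": _fmt(resp.cigarette_availability),
        "motivation": _fmt(resp.motivation_to_avoid),
        "with_smoker": _fmt(resp.interacting_with_smoker),
        "alcohol": _fmt(resp.alcohol_last_hour),
        "likelihood": _fmt(resp.likelihood_smoke_today),
        "gum_pieces": _fmt(resp.gum_pieces),
        "patch_category": _fmt(resp.patch_category),
        "drinks": _fmt(resp.drinks),
        "completed": _fmt(resp.completed_at),
    }


def row_to_response(row: Mapping[str, str]) -> EmaResponse:
    def opt(name, conv):
        raw = row.get(name, "")
        return conv(raw) if raw not in ("", None) else None

    data = {
        "participant_id": row["participant_id"],
        "arm": opt("arm", str),
        "day": int(row["day"]),
        "time": int(row["time"]),
        "kind": opt("kind", str),
        "initiation": row["initiation"],
        "urge": int(row["urge"]),
        "stress": int(row["stress"]),
        "cigarette_availability": int(row["availability"]),
        "motivation_to_avoid": int(row["motivation"]),
        "interacting_with_smoker": row["with_smoker"] == "1",
        "alcohol_last_hour": row["alcohol"] == "1",
        "likelihood_smoke_today": opt("likelihood", float),
        "gum_pieces": opt("gum_pieces", int),
        "patch_category": opt("patch_category", str),
        "drinks": opt("drinks", int),
        "completed_at": int(row["completed"]),
    }
    return validate_response(data)


def write_ema_csv(responses: Iterable[EmaResponse], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=EMA_COLUMNS, lineterminator="\n")
        writer.writeheader()
        for resp in responses:
            writer.writerow(response_to_row(resp))


def read_ema_csv(path) -> list[EmaResponse]:
    with open(path, newline="") as fh:
        return [row_to_response(row) for row in csv.DictReader(fh)]


def write_schedule_csv(prompts: Sequence[EmaPrompt], path) -> None:
    """Schedules use the same dialect without the item columns."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(SCHEDULE_COLUMNS)
        for p in prompts:
            writer.writerow([p.participant_id, p.day, p.time, p.kind])
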
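"""Outcome and engagement statistics for the three-arm trial.

Covers biochemically verified intent-to-treat abstinence classification,
per-arm abstinence tables, Pearson chi-square across arms, one-way ANOVA
reconstructed from group summaries (n, mean, SD), compliance-tier
compensation, the patch wear-time recoding, and message-distribution
summaries of the engine's decision log.
"""

from __future__ import annotations

import math
from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator
from scipy import stats as sps

from .errors import ConfigurationError, QuitsenseError

VisitName = Literal["quit_date", "week4", "week12"]

#: CO cutoffs (ppm, exclusive upper bounds) for verified abstinence.
CO_CUTOFF_PPM = 6.0
CO_CUTOFF_QUIT_DATE_PPM = 10.0

HIGH_RISK_CATEGORIES = (
    "high_risk_urge",
    "high_risk_stress",
    "high_risk_availability",
    "high_risk_motivation",
)


@dataclass(frozen=True)
class VisitRecord:
    """One in-person assessment visit's abstinence measurements."""

    participant_id: str
    visit: VisitName
    self_report_no_puff: Optional[bool] = None
    co_ppm: Optional[float] = None

    def __post_init__(self):
        if self.co_ppm is not None and self.co_ppm < 0:
            raise ValueError("co_ppm must be nonnegative")


class GroupSummary(BaseModel):
    """(n, mean, SD) triple for one group, e.g. one row of a summary table."""

    model_config = ConfigDict(frozen=True)

    label: str
    n: int = Field(ge=2)
    mean: float
    sd: float = Field(ge=0)


class CompensationRule(BaseModel):
    """Visit payments plus tiered EMA-completion bonuses (USD).

    ``ema_tiers`` are (lower %, upper %, payment) bands with inclusive
    integer edges; completion below the lowest band earns no bonus.  The
    completion percent is rounded to 0.1 before banding, and band matching
    uses the inclusive lower bounds.
    """

    model_config = ConfigDict(frozen=True)

    visit_payments: tuple[float, ...] = (30.0, 30.0, 30.0, 50.0)
    ema_tiers: tuple[tuple[float, float, float], ...] = (
        (50.0, 74.0, 50.0),
        (75.0, 89.0, 100.0),
        (90.0, 100.0, 150.0),
    )

    @model_validator(mode="after")
    def _check_tiers(self) -> "CompensationRule":
        prev_upper = -math.inf
        prev_pay = -math.inf
        for lower, upper, pay in self.ema_tiers:
            if lower <= prev_upper:
                raise ValueError("ema_tiers must be ordered and non-overlapping")
            if upper < lower:
                raise ValueError("tier upper bound below lower bound")
            if pay < prev_pay:
                raise ValueError("tier payments must be nondecreasing")
            prev_upper, prev_pay = upper, pay
        return self


def classify_abstinent(visit: VisitRecord, co_cutoff: Optional[float] = None) -> bool:
    """Biochemically verified 7-day point-prevalence abstinence (ITT).

    Abstinent iff the participant self-reported not smoking even a puff AND
    the expired-CO reading is strictly below 6 ppm (10 ppm at the quit-date
    visit).  Any missing component — a missed visit, no self-report, no CO
    reading — counts as smoking, per intent-to-treat.  ``co_cutoff``
    overrides the standard cutoff (sensitivity analyses only).
    """
    if visit.self_report_no_puff is not True or visit.co_ppm is None:
        return False
    if co_cutoff is None:
        co_cutoff = CO_CUTOFF_QUIT_DATE_PPM if visit.visit == "quit_date" else CO_CUTOFF_PPM
    return visit.co_ppm < co_cutoff


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def abstinence_table(
    visits: "pd.DataFrame | Iterable[Mapping]",
    visit: VisitName,
    arms: Sequence[str] = ("smart_t2", "quitguide", "usual_care"),
) -> dict:
    """Per-arm (abstinent, total) counts and the pooled percent for a visit.

    ``visits`` rows need participant_id, arm, visit, self_report_no_puff and
    co_ppm columns (missing encoded as None/NaN); every randomized
    participant appearing anywhere in the table is analyzed (ITT), so a
    participant with no row for this visit counts as smoking.
    """
    df = pd.DataFrame(visits)
    unknown = set(df["arm"].dropna()) - set(arms)
    if unknown:
        raise QuitsenseError(f"unknown arm labels: {sorted(unknown)}")
    participants = df[["participant_id", "arm"]].drop_duplicates("participant_id")
    rows = df[df["visit"] == visit]
    abstinent_ids = set()
    for _, r in rows.iterrows():
        sr = r.get("self_report_no_puff")
        co = r.get("co_ppm")
        rec = VisitRecord(
            participant_id=str(r["participant_id"]),
            visit=visit,
            self_report_no_puff=None if pd.isna(sr) else bool(sr),
            co_ppm=None if pd.isna(co) else float(co),
        )
        if classify_abstinent(rec):
            abstinent_ids.add(rec.participant_id)
    per_arm = {}
    for arm in arms:
        ids = participants.loc[participants["arm"] == arm, "participant_id"]
        per_arm[arm] = (sum(1 for i in ids if str(i) in abstinent_ids), len(ids))
    return _pool_table(per_arm)


def pooled_abstinence(per_arm: Mapping[str, tuple[int, int]]) -> dict:
    """Pool printed per-arm (abstinent, total) counts into the ITT summary."""
    return _pool_table(dict(per_arm))


def _pool_table(per_arm: dict[str, tuple[int, int]]) -> dict:
    abst = sum(a for a, _ in per_arm.values())
    total = sum(n for _, n in per_arm.values())
    return {
        "per_arm": per_arm,
        "pooled_abstinent": abst,
        "pooled_total": total,
        "pooled_percent": _round_half_up(100.0 * abst / total) if total else None,
    }


def chisq_independence(table) -> tuple[float, int, float]:
    """Pearson chi-square test of independence on an r x c count table.

    Returns ``(statistic, df, p)`` with the upper-tail p-value and no
    continuity correction, matching the textbook sum of (O-E)^2 / E.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise QuitsenseError("table must be at least 2x2")
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise QuitsenseError("table has a zero marginal")
    stat, p, df, expected = sps.chi2_contingency(obs, correction=False)
    if (expected <= 0).any():
        raise QuitsenseError("expected counts must be positive")
    return float(stat), int(df), float(p)


def anova_from_summary(groups: Sequence[GroupSummary]) -> tuple[float, int, int, float]:
    """One-way ANOVA reconstructed from per-group (n, mean, SD).

    Between-group and within-group sums of squares follow directly from the
    summaries::

        SSB = sum n_i (m_i - grand_mean)^2
        SSW = sum (n_i - 1) s_i^2
        F   = (SSB / (k - 1)) / (SSW / (N - k))

    and reproduce the raw-data one-way ANOVA exactly when the summaries were
    computed from the raw data.  Returns ``(F, df_between, df_within, p)``.
    """
    if len(groups) < 2:
        raise QuitsenseError("ANOVA needs at least two groups")
    ns = np.array([g.n for g in groups], dtype=float)
    means = np.array([g.mean for g in groups], dtype=float)
    sds = np.array([g.sd for g in groups], dtype=float)
    n_total = ns.sum()
    grand = float((ns * means).sum() / n_total)
    ssb = float((ns * (means - grand) ** 2).sum())
    ssw = float(((ns - 1.0) * sds**2).sum())
    df_b = len(groups) - 1
    df_w = int(n_total) - len(groups)
    if ssw == 0.0:
        if ssb == 0.0:
            return 0.0, df_b, df_w, 1.0
        raise QuitsenseError("zero within-group variance with unequal means")
    f = (ssb / df_b) / (ssw / df_w)
    p = float(sps.f.sf(f, df_b, df_w))
    return float(f), df_b, df_w, p


def compensation(
    completed_prompted: int,
    scheduled_prompted: int,
    visits_attended: Sequence[bool],
    rule: CompensationRule | None = None,
) -> float:
    """Total USD compensation: visit payments plus the EMA-completion tier.

    The completion percent (prompted EMAs only — self-initiated reports are
    never compensated) is rounded to 0.1 before banding; each band's lower
    edge is inclusive, and completion below the lowest band earns no bonus.
    """
    rule = rule or CompensationRule()
    if completed_prompted < 0 or scheduled_prompted < 0:
        raise ConfigurationError("counts must be nonnegative")
    if completed_prompted > scheduled_prompted:
        raise ConfigurationError("completed cannot exceed scheduled")
    if len(visits_attended) != len(rule.visit_payments):
        raise ConfigurationError(
            f"expected {len(rule.visit_payments)} visit flags, got {len(visits_attended)}"
        )
    total = sum(p for p, attended in zip(rule.visit_payments, visits_attended) if attended)
    if scheduled_prompted > 0:
        pct = round(100.0 * completed_prompted / scheduled_prompted, 1)
        bonus = 0.0
        for lower, _upper, payment in rule.ema_tiers:
            if pct >= lower:
                bonus = payment
        total += bonus
    return float(total)


#: Patch wear-time category -> hours at the category midpoint.  The three
#: anchor recodings (0, 2, 5 hours) are fixed; the remaining categories
#: follow the same arithmetic-midpoint rule and are a documented
#: reconstruction of the full ordinal label set (0 through "at least 22-24").
PATCH_HOURS = {
    "I did not wear it at all": 0,
    "Less than 3 hours": 2,
    "4-6 hours": 5,
    "7-9 hours": 8,
    "10-12 hours": 11,
    "13-15 hours": 14,
    "16-18 hours": 17,
    "19-21 hours": 20,
    "At least 22-24 hours": 23,
}


def recode_patch_hours(category: str) -> int:
    """Recode a nightly patch wear-time category to midpoint hours."""
    try:
        return PATCH_HOURS[category]
    except KeyError:
        raise QuitsenseError(f"unknown patch wear-time category {category!r}") from None


def message_distribution(decisions: Iterable[Mapping]) -> dict:
    """Summaries of a decision log (dicts as written to decisions.jsonl).

    Returns per-category delivery counts, proportions over the four
    high-risk trigger categories (summing to 1 when any were delivered),
    per-participant mean deliveries, gum-prompt totals, and per-day counts
    usable for time-course summaries.  An empty log yields zero counts with
    proportions flagged as unavailable.
    """
    decisions = list(decisions)
    participants = set()
    category_counts: Counter = Counter()
    per_day: dict[int, Counter] = defaultdict(Counter)
    gum_count = 0
    for d in decisions:
        participants.add(d["participant_id"])
        if d.get("class") == "high" and d.get("trigger"):
            cat = f"high_risk_{d['trigger']}"
        elif "category" in d:
            cat = d["category"]
        else:
            cat = d.get("class", "unknown")
        category_counts[cat] += 1
        per_day[int(d["day"])][cat] += 1
        if d.get("gum"):
            gum_count += 1

    high_total = sum(category_counts[c] for c in HIGH_RISK_CATEGORIES)
    high_risk_share = (
        {c: category_counts[c] / high_total for c in HIGH_RISK_CATEGORIES}
        if high_total
        else None
    )
    n_participants = len(participants)
    return {
        "n_decisions": len(decisions),
        "n_participants": n_participants,
        "category_counts": dict(category_counts),
        "high_risk_total": high_total,
        "high_risk_share": high_risk_share,
        "per_participant_mean": len(decisions) / n_participants if n_participants else 0.0,
        "gum_prompts": gum_count,
        "gum_per_participant": gum_count / n_participants if n_participants else 0.0,
        "per_day_counts": {day: dict(c) for day, c in sorted(per_day.items())},
    }


def high_risk_shares_from_counts(counts: Mapping[str, int]) -> dict[str, float]:
    """Percent share of each high-risk trigger category from raw counts
    (e.g. a printed table of delivered-message totals)."""
    total = sum(counts.values())
    if total == 0:
        raise QuitsenseError("no high-risk messages")
    return {k: 100.0 * v / total for k, v in counts.items()}
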